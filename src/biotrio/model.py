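"""Core three-subpopulation ODE model of a social-microbe community.

The community is split into resistant (R), producer (P) and motile (M)
cells.  R cells proliferate on a shared nutrient pool N, convert into
motile cells at rate ``k4``, and pay a cost-of-resistance coupling
``k2*R*P``; motile cells mature into public-goods producers at rate
``k5``; producers decay (cost of production / stress) at rate ``k3``:

    dR/dt = k1*N*R - k4*R - k2*R*P
    dP/dt = -k3*P + k5*M
    dM/dt = k4*R - k5*M

The module holds the right-hand side, the closed-form steady states, the
Jacobian, the characteristic polynomial at the positive steady state and
the closed-form Hopf condition ``k3* = k1*N - k4 - k5``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "ModelParameters",
    "PopulationState",
    "CharacteristicCoefficients",
    "StabilityReport",
    "rhs",
    "analytic_steady_states",
    "jacobian_at",
    "characteristic_coefficients",
    "hopf_k3_critical",
    "hopf_k3_numeric",
    "stability_report",
    "classify_eigenvalues",
]

#: real parts closer to zero than this are treated as marginal (nonhyperbolic)
HYPERBOLICITY_TOL = 1e-9


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants (h^-1) and nutrient level of the three-variable model.

    Defaults follow the reference parameterisation: every rate constant
    equal to 1 h^-1 and nutrient level N = 4 (dimensionless).
    """

    k1: float = 1.0
    k2: float = 1.0
    k3: float = 1.0
    k4: float = 1.0
    k5: float = 1.0
    N: float = 4.0

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "k4", "k5", "N"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(
                    f"parameter {name} must be strictly positive and finite, got {value!r}"
                )

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        fields = asdict(self)
        fields.update(changes)
        return ModelParameters(**fields)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ModelParameters":
        return cls(**{k: float(v) for k, v in d.items()})

    def to_config(self) -> str:
        """Flat ``key: value`` text (YAML subset), one parameter per line."""
        return "".join(f"{k}: {v!r}\n" for k, v in self.to_dict().items())

    @classmethod
    def from_config(cls, text: str) -> "ModelParameters":
        fields: dict[str, float] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition(":")
            fields[key.strip()] = float(value)
        return cls(**fields)


@dataclass(frozen=True)
class PopulationState:
    """Abundances of the three subpopulations (arbitrary units, >= 0)."""

    R: float
    P: float
    M: float

    def __post_init__(self) -> None:
        for name in ("R", "P", "M"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"population {name} must be finite, got {value!r}")
            if value < 0:
                raise ValueError(f"population {name} must be non-negative, got {value!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.R, self.P, self.M], dtype=float)


@dataclass(frozen=True)
class CharacteristicCoefficients:
    """Coefficients of lambda^3 + a1*lambda^2 + a2*lambda + a3 at the
    positive steady state."""

    a1: float
    a2: float
    a3: float

    def roots(self) -> np.ndarray:
        return np.roots([1.0, self.a1, self.a2, self.a3])

    @property
    def routh_hurwitz_stable(self) -> bool:
        """a1>0, a3>0 and a1*a2>a3: all eigenvalues in the open left half-plane."""
        return self.a1 > 0 and self.a3 > 0 and self.a1 * self.a2 > self.a3


@dataclass(frozen=True)
class StabilityReport:
    """A steady state with its eigenvalues and local classification."""

    steady_state: PopulationState
    eigenvalues: tuple[complex, complex, complex]
    classification: str


def rhs(state: PopulationState | Sequence[float], params: ModelParameters) -> tuple[float, float, float]:
    """Time derivatives (dR/dt, dP/dt, dM/dt) in h^-1.

    Negative or non-finite populations are rejected: the model is only
    meaningful on the non-negative orthant.
    """
    if isinstance(state, PopulationState):
        R, P, M = state.R, state.P, state.M
    else:
        R, P, M = (float(x) for x in state)
        if not all(math.isfinite(x) for x in (R, P, M)):
            raise ValueError(f"non-finite population state {(R, P, M)}")
        if min(R, P, M) < 0:
            raise ValueError(f"negative population state {(R, P, M)}")
    p = params
    return (
        p.k1 * p.N * R - p.k4 * R - p.k2 * R * P,
        -p.k3 * P + p.k5 * M,
        p.k4 * R - p.k5 * M,
    )


def analytic_steady_states(params: ModelParameters) -> list[PopulationState]:
    """Closed-form fixed points: the washout state (origin) always, plus the
    positive coexistence state when k1*N > k4.

    Setting dR/dt = 0 with R != 0 gives P* = (k1*N - k4)/k2; the P and M
    balances then give R* = k3*P*/k4 and M* = k4*R*/k5.
    """
    states = [PopulationState(0.0, 0.0, 0.0)]
    p = params
    if p.k1 * p.N > p.k4:
        P_star = (p.k1 * p.N - p.k4) / p.k2
        R_star = p.k3 * P_star / p.k4
        M_star = p.k4 * R_star / p.k5
        states.append(PopulationState(R_star, P_star, M_star))
    return states


def positive_steady_state(params: ModelParameters) -> PopulationState:
    """The coexistence fixed point; raises if k1*N <= k4 (washout only)."""
    states = analytic_steady_states(params)
    if len(states) < 2:
        raise ValueError(
            f"no positive steady state: k1*N = {params.k1 * params.N} <= k4 = {params.k4}"
        )
    return states[1]


def jacobian_at(state: PopulationState | Sequence[float], params: ModelParameters) -> np.ndarray:
    """3x3 Jacobian of the vector field at ``state``."""
    if isinstance(state, PopulationState):
        R, P = state.R, state.P
    else:
        R, P = float(state[0]), float(state[1])
    p = params
    return np.array(
        [
            [p.k1 * p.N - p.k4 - p.k2 * P, -p.k2 * R, 0.0],
            [0.0, -p.k3, p.k5],
            [p.k4, 0.0, -p.k5],
        ]
    )


def characteristic_coefficients(params: ModelParameters) -> CharacteristicCoefficients:
    """Characteristic polynomial lambda^3 + a1 l^2 + a2 l + a3 at the
    positive steady state.

    At the coexistence point the growth term vanishes, so the Jacobian is
    [[0, -k2*R*, 0], [0, -k3, k5], [k4, 0, -k5]] and expansion gives
    a1 = k3 + k5, a2 = k3*k5, a3 = k3*k5*(k1*N - k4).
    """
    positive_steady_state(params)  # raises if absent
    p = params
    return CharacteristicCoefficients(
        a1=p.k3 + p.k5,
        a2=p.k3 * p.k5,
        a3=p.k3 * p.k5 * (p.k1 * p.N - p.k4),
    )


def hopf_k3_critical(params: ModelParameters) -> float | None:
    """Closed-form Hopf point in k3, from the Routh-Hurwitz marginal case.

    a1*a2 = a3 reads (k3 + k5)*k3*k5 = k3*k5*(k1*N - k4), i.e.
    k3* = k1*N - k4 - k5.  Returns None when k1*N <= k4 + k5 (no positive
    critical value: the coexistence state is stable for every k3 > 0).
    """
    p = params
    k3_crit = p.k1 * p.N - p.k4 - p.k5
    return k3_crit if k3_crit > 0 else None


def _max_real_of_complex_pair(params: ModelParameters) -> float:
    """Largest real part among non-real eigenvalues at the positive steady
    state (falls back to the overall max real part if all roots are real)."""
    roots = characteristic_coefficients(params).roots()
    complex_roots = roots[np.abs(roots.imag) > 1e-12]
    pool = complex_roots if complex_roots.size else roots
    return float(pool.real.max())


def hopf_k3_numeric(
    params: ModelParameters,
    bracket: tuple[float, float] = (0.5, 3.0),
    tol: float = 1e-10,
) -> float | None:
    """Locate the Hopf point by bisection on the maximal real part of the
    complex eigenvalue pair over k3 in ``bracket``.

    Independent of :func:`hopf_k3_critical` (works on numerically computed
    polynomial roots).  Returns None if the real part does not change sign
    over the bracket.
    """
    lo, hi = bracket
    f_lo = _max_real_of_complex_pair(params.replace(k3=lo))
    f_hi = _max_real_of_complex_pair(params.replace(k3=hi))
    if f_lo * f_hi > 0:
        return None
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        f_mid = _max_real_of_complex_pair(params.replace(k3=mid))
        if f_lo * f_mid <= 0:
            hi = mid
        else:
            lo, f_lo = mid, f_mid
    return 0.5 * (lo + hi)


def classify_eigenvalues(eigenvalues: np.ndarray, tol: float = HYPERBOLICITY_TOL) -> str:
    """Local classification of a fixed point from its eigenvalues.

    Real parts within ``tol`` of zero make the point nonhyperbolic (this
    deliberately catches the marginal Hopf case).  A complex pair makes it
    a focus; mixed-sign real parts a saddle; otherwise a node.
    """
    re = np.real(eigenvalues)
    im = np.imag(eigenvalues)
    if np.any(np.abs(re) < tol):
        return "nonhyperbolic"
    if np.any(np.abs(im) > tol):
        # a complex pair rotates the local flow: focus, stable iff the
        # pair (and everything else) decays
        return "stable_focus" if np.all(re < 0) else "unstable_focus"
    if np.all(re < 0):
        return "stable_node"
    if np.all(re > 0):
        return "unstable_node"
    return "saddle"


def stability_report(state: PopulationState, params: ModelParameters) -> StabilityReport:
    """Eigenvalues and classification of the Jacobian at ``state``."""
    eig = np.linalg.eigvals(jacobian_at(state, params))
    # order by real part for reproducible output
    eig = eig[np.argsort(eig.real)]
    return StabilityReport(
        steady_state=state,
        eigenvalues=tuple(complex(z) for z in eig),
        classification=classify_eigenvalues(eig),
    )
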