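"""Time-course integration of the three-subpopulation model.

Wraps :func:`scipy.integrate.solve_ivp` with LSODA (automatic stiffness
switching — the very stiff high-k3 parameterisation needs it) and reports
dense output on a uniform grid together with the resistant-cell fraction
R/(R+P), the observable used throughout the dynamical analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .model import ModelParameters, PopulationState, jacobian_at

__all__ = ["SimulationSettings", "Trajectory", "simulate", "ratio_series"]

#: denominators R+P below this are reported as undefined ratio (NaN)
RATIO_EPS = 1e-12


@dataclass(frozen=True)
class SimulationSettings:
    """Integration horizon, output grid and tolerances.

    The default horizon/step (25 h, 0.025 h) mirror the reference
    time-course protocol: 1000 output steps of 1.5 min each.  Tolerances
    default tight (rel 1e-8, abs 1e-10) because both the stiff high-k3
    case and the spike regime need careful error control.
    """

    t_end: float = 25.0
    dt_out: float = 0.025
    initial_state: PopulationState = field(default_factory=lambda: PopulationState(1.0, 1.0, 1.0))
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10

    def __post_init__(self) -> None:
        if not self.t_end > 0:
            raise ValueError(f"t_end must be positive, got {self.t_end}")
        if not self.dt_out > 0:
            raise ValueError(f"dt_out must be positive, got {self.dt_out}")
        if self.t_end / self.dt_out < 10:
            raise ValueError(
                f"t_end/dt_out = {self.t_end / self.dt_out:.1f} yields fewer than 10 output points"
            )

    def time_grid(self) -> np.ndarray:
        n = int(round(self.t_end / self.dt_out))
        return np.linspace(0.0, n * self.dt_out, n + 1)


@dataclass(frozen=True)
class Trajectory:
    """Uniform time grid (h) with (R, P, M) columns and the R/(R+P) series.

    Ratio entries are NaN where R+P vanishes (undefined, not zero).
    """

    times: np.ndarray
    states: np.ndarray  # shape (n, 3): columns R, P, M
    ratio: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.states) == len(self.ratio)):
            raise ValueError("times, states and ratio must have equal length")

    def state_at(self, index: int) -> PopulationState:
        R, P, M = self.states[index]
        return PopulationState(R, P, M)

    @property
    def final_state(self) -> PopulationState:
        return self.state_at(-1)


def ratio_series(states: np.ndarray | Trajectory) -> np.ndarray:
    """Resistant fraction R/(R+P), elementwise; NaN where R+P ~ 0."""
    if isinstance(states, Trajectory):
        states = states.states
    states = np.asarray(states, dtype=float)
    if states.size == 0:
        raise ValueError("empty trajectory")
    R = states[..., 0]
    total = R + states[..., 1]
    out = np.full_like(total, np.nan)
    ok = total >= RATIO_EPS
    out[ok] = R[ok] / total[ok]
    return out


def simulate(params: ModelParameters, settings: SimulationSettings | None = None) -> Trajectory:
    """Integrate the model and sample it on the uniform output grid.

    Internal stepping is adaptive (LSODA with the analytic Jacobian);
    only the reporting grid is fixed.

    Strictly positive initial states are integrated in log abundances.
    The positive orthant is invariant but spike-regime minima dip many
    orders of magnitude below the absolute tolerance of a linear-space
    integrator, which then lets the state cross into the negative
    orthant, where the flow genuinely blows up in finite time.  Working
    in logs keeps positivity exact and resolves the deep minima.
    Initial states with a zero component (invariant faces, the origin)
    use the linear-space path, where tiny negative excursions are
    clamped to zero.
    """
    settings = settings or SimulationSettings()
    y0 = settings.initial_state.as_array()
    times = settings.time_grid()

    if y0.min() > 0:
        states = _integrate_log(y0, times, params, settings)
    else:
        states = _integrate_linear(y0, times, params, settings)
    return Trajectory(times=times, states=states, ratio=ratio_series(states))


def _log_rhs(u: np.ndarray, p: ModelParameters) -> np.ndarray:
    """Per-capita rates d(log R, log P, log M)/dt."""
    uR, uP, uM = u
    return np.array(
        [
            p.k1 * p.N - p.k4 - p.k2 * np.exp(uP),
            -p.k3 + p.k5 * np.exp(uM - uP),
            p.k4 * np.exp(uR - uM) - p.k5,
        ]
    )


def _log_jac(u: np.ndarray, p: ModelParameters) -> np.ndarray:
    uR, uP, uM = u
    e_p = p.k2 * np.exp(uP)
    e_mp = p.k5 * np.exp(uM - uP)
    e_rm = p.k4 * np.exp(uR - uM)
    return np.array(
        [
            [0.0, -e_p, 0.0],
            [0.0, -e_mp, e_mp],
            [e_rm, 0.0, -e_rm],
        ]
    )


def _integrate_log(y0: np.ndarray, times: np.ndarray, params: ModelParameters, settings: SimulationSettings) -> np.ndarray:
    # absolute tolerance on log abundance == relative tolerance on abundance
    sol = solve_ivp(
        lambda _t, u: _log_rhs(u, params),
        (times[0], times[-1]),
        np.log(y0),
        method="LSODA",
        t_eval=times,
        rtol=settings.rel_tol,
        atol=settings.rel_tol,
        jac=lambda _t, u: _log_jac(u, params),
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed for parameters {params.to_dict()}: {sol.message}"
        )
    with np.errstate(under="ignore"):
        return np.exp(sol.y.T)


def _integrate_linear(y0: np.ndarray, times: np.ndarray, params: ModelParameters, settings: SimulationSettings) -> np.ndarray:
    sol = solve_ivp(
        lambda _t, y: rhs_array(y, params),
        (times[0], times[-1]),
        y0,
        method="LSODA",
        t_eval=times,
        rtol=settings.rel_tol,
        atol=settings.abs_tol,
        jac=lambda _t, y: jacobian_at(y, params),
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed for parameters {params.to_dict()}: {sol.message}"
        )
    states = sol.y.T.copy()
    # clamp integrator round-off; anything larger is a genuine failure
    negative = states < 0
    if negative.any():
        worst = float(-states[negative].min())
        if worst > 10 * settings.abs_tol:
            raise RuntimeError(
                f"trajectory left the non-negative orthant by {worst:.3e} "
                f"for parameters {params.to_dict()}"
            )
        states[negative] = 0.0
    return states


def rhs_array(y: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Vector-field evaluation on a raw array (no orthant checks; used by
    the integrator, which may probe slightly negative values)."""
    R, P, M = y
    p = params
    return np.array(
        [
            p.k1 * p.N * R - p.k4 * R - p.k2 * R * P,
            -p.k3 * P + p.k5 * M,
            p.k4 * R - p.k5 * M,
        ]
    )
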