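"""Evolutionary-game companion to the subpopulation model.

Two payoff structures describe the community:

* a three-strategy zero-sum game between the resistant (R), motile (M)
  and producer (P) types with rock-paper-scissors cyclic dominance
  (R beats P, P beats M, M beats R); winners earn +1, losers -1, ties 0;
* a two-strategy bimatrix game between a nascent cell (row player,
  an invading rare mutant) and the mature community (column player),
  over strategies P and R, under three antibiotic-stress conditions.
  The moderate-stress matrix is primitive; the no-stress and high-stress
  matrices follow by adding or subtracting one point from every payoff a
  player earns while playing P.

Equilibrium analysis is done twice on independent routes: exhaustive
best-response enumeration for pure equilibria, support enumeration for
mixed ones, and (for zero-sum games) the minimax linear program as a
cross-check.  Replicator dynamics for symmetric games round out the
toolbox.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import linprog

__all__ = [
    "BimatrixGame",
    "NashResult",
    "ReplicatorTrajectory",
    "payoff_rps",
    "payoff_two_strategy",
    "pure_nash",
    "mixed_nash",
    "zero_sum_equilibrium",
    "replicator_dynamics",
]

STRESS_CONDITIONS = ("no_stress", "moderate", "high")

_EQ_TOL = 1e-9
_DEDUP_TOL = 1e-7


@dataclass(frozen=True)
class BimatrixGame:
    """Two-player game in bimatrix form.

    ``payoff_p1[i, j]`` / ``payoff_p2[i, j]`` are the row and column
    player's points when row plays strategy ``i`` and column plays ``j``.
    """

    strategies_p1: tuple[str, ...]
    strategies_p2: tuple[str, ...]
    payoff_p1: np.ndarray
    payoff_p2: np.ndarray
    condition: str | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.payoff_p1, dtype=float)
        b = np.asarray(self.payoff_p2, dtype=float)
        object.__setattr__(self, "payoff_p1", a)
        object.__setattr__(self, "payoff_p2", b)
        if a.shape != b.shape:
            raise ValueError(f"payoff matrices differ in shape: {a.shape} vs {b.shape}")
        if a.shape != (len(self.strategies_p1), len(self.strategies_p2)):
            raise ValueError("payoff shape does not match strategy labels")
        if self.condition is not None and self.condition not in STRESS_CONDITIONS:
            raise ValueError(f"unknown stress condition {self.condition!r}")

    @property
    def zero_sum(self) -> bool:
        return bool(np.allclose(self.payoff_p1 + self.payoff_p2, 0.0))

    @property
    def symmetric(self) -> bool:
        """True when player 2's payoffs are the transpose of player 1's."""
        return self.payoff_p1.shape[0] == self.payoff_p1.shape[1] and bool(
            np.allclose(self.payoff_p2, self.payoff_p1.T)
        )


@dataclass(frozen=True)
class PureEquilibrium:
    row: int
    col: int
    strict: bool
    labels: tuple[str, str]


@dataclass(frozen=True)
class MixedEquilibrium:
    p1: np.ndarray
    p2: np.ndarray


@dataclass(frozen=True)
class NashResult:
    """Pure and mixed equilibria of a bimatrix game.

    ``degenerate`` is set when some equilibrium admits best responses
    outside its support (equilibrium continua possible; the listed mixed
    profiles are then representatives).
    """

    pure: tuple[PureEquilibrium, ...] = ()
    mixed: tuple[MixedEquilibrium, ...] = ()
    degenerate: bool = False


# ---------------------------------------------------------------------------
# payoff constructors
# ---------------------------------------------------------------------------

def payoff_rps() -> BimatrixGame:
    """The three-strategy zero-sum game over (R, M, P).

    Cyclic dominance: M beats R (motility escapes local stress), P beats
    M (producers hold the community resources), R beats P (resistance
    freeloads on public goods).  +1 to the winner, -1 to the loser, 0 on
    ties, hence zero-sum.
    """
    a = np.array(
        [
            [0.0, -1.0, 1.0],
            [1.0, 0.0, -1.0],
            [-1.0, 1.0, 0.0],
        ]
    )
    labels = ("R", "M", "P")
    return BimatrixGame(labels, labels, a, -a)


_TWO_STRATEGY_LABELS = ("P", "R")

# moderate stress (cost of production equals cost of resistance):
# rows = nascent (P, R), cols = mature (P, R), payoffs nascent\mature
_MODERATE_P1 = np.array([[1.0, 0.5], [2.0, 0.0]])
_MODERATE_P2 = np.array([[2.0, 1.5], [0.0, 2.0]])


def payoff_two_strategy(condition: str) -> BimatrixGame:
    """Nascent-vs-mature bimatrix game for a given stress condition.

    ``moderate`` is the base game.  ``no_stress`` adds one point to every
    payoff a player earns while playing P (production is cheap without
    antibiotics); ``high`` subtracts one (production is the costlier
    investment under stress).  The shift applies to player 1 along its P
    row and to player 2 along its P column.
    """
    if condition not in STRESS_CONDITIONS:
        raise ValueError(
            f"unknown stress condition {condition!r}; expected one of {STRESS_CONDITIONS}"
        )
    a = _MODERATE_P1.copy()
    b = _MODERATE_P2.copy()
    shift = {"no_stress": 1.0, "moderate": 0.0, "high": -1.0}[condition]
    p_row = _TWO_STRATEGY_LABELS.index("P")
    a[p_row, :] += shift  # player 1 playing P
    b[:, p_row] += shift  # player 2 playing P
    return BimatrixGame(_TWO_STRATEGY_LABELS, _TWO_STRATEGY_LABELS, a, b, condition=condition)


# ---------------------------------------------------------------------------
# equilibrium analysis
# ---------------------------------------------------------------------------

def pure_nash(game: BimatrixGame) -> NashResult:
    """Exhaustive best-response enumeration of pure equilibria.

    A cell (i, j) is an equilibrium iff no unilateral deviation strictly
    improves either player; strict iff every deviation is strictly worse.
    """
    a, b = game.payoff_p1, game.payoff_p2
    found = []
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            row_dev = np.delete(a[:, j], i)
            col_dev = np.delete(b[i, :], j)
            if (row_dev.size and row_dev.max() > a[i, j] + _EQ_TOL) or (
                col_dev.size and col_dev.max() > b[i, j] + _EQ_TOL
            ):
                continue
            strict = bool(
                (not row_dev.size or row_dev.max() < a[i, j] - _EQ_TOL)
                and (not col_dev.size or col_dev.max() < b[i, j] - _EQ_TOL)
            )
            found.append(
                PureEquilibrium(
                    row=i,
                    col=j,
                    strict=strict,
                    labels=(game.strategies_p1[i], game.strategies_p2[j]),
                )
            )
    return NashResult(pure=tuple(found))


def _support_lp(payoff: np.ndarray, own_support: tuple[int, ...], mix_support: tuple[int, ...]) -> np.ndarray | None:
    """Mixture for the *other* player over ``mix_support`` making strategies
    in ``own_support`` indifferent best responses against ``payoff``.

    Feasibility LP in (q, v): payoff[i] . q == v on the support,
    <= v off it, q a probability vector supported on ``mix_support``.
    Returns the full-length mixture or None if infeasible.
    """
    n_own, n_mix = payoff.shape
    nq = len(mix_support)
    # variables: q over mix_support (nq), then v (free)
    a_eq = []
    b_eq = []
    a_ub = []
    b_ub = []
    for i in range(n_own):
        row = np.append(payoff[i, list(mix_support)], -1.0)
        if i in own_support:
            a_eq.append(row)
            b_eq.append(0.0)
        else:
            a_ub.append(row)
            b_ub.append(0.0)
    a_eq.append(np.append(np.ones(nq), 0.0))
    b_eq.append(1.0)
    res = linprog(
        c=np.zeros(nq + 1),
        A_ub=np.array(a_ub) if a_ub else None,
        b_ub=np.array(b_ub) if a_ub else None,
        A_eq=np.array(a_eq),
        b_eq=np.array(b_eq),
        bounds=[(0.0, 1.0)] * nq + [(None, None)],
        method="highs",
    )
    if not res.success:
        return None
    q = np.zeros(n_mix)
    q[list(mix_support)] = res.x[:nq]
    return q


def _is_equilibrium(game: BimatrixGame, p: np.ndarray, q: np.ndarray, tol: float = _EQ_TOL) -> bool:
    """No pure (hence no mixed) unilateral deviation improves either player."""
    u1 = game.payoff_p1 @ q
    u2 = game.payoff_p2.T @ p
    return bool(u1.max() <= p @ u1 + tol and u2.max() <= q @ u2 + tol)


def _best_response_count(payoffs: np.ndarray, tol: float = _DEDUP_TOL) -> int:
    return int(np.sum(payoffs >= payoffs.max() - tol))


def mixed_nash(game: BimatrixGame) -> NashResult:
    """Equilibria by support enumeration, cross-checked by a deviation test.

    All support pairs are searched in increasing size; each candidate
    solves two feasibility linear programs (one per player's indifference
    system) and is kept only if it passes the no-profitable-deviation
    check.  For zero-sum games the minimax LP value/strategies are
    additionally available via :func:`zero_sum_equilibrium`.  Duplicate
    profiles are merged; profiles whose best-response set strictly
    exceeds the support mark the game degenerate.
    """
    n1, n2 = game.payoff_p1.shape
    if max(n1, n2) > 4:
        raise ValueError("support enumeration limited to at most 4 strategies per player")
    pure = pure_nash(game).pure

    mixed: list[MixedEquilibrium] = []
    degenerate = False
    supports1 = [s for size in range(1, n1 + 1) for s in itertools.combinations(range(n1), size)]
    supports2 = [s for size in range(1, n2 + 1) for s in itertools.combinations(range(n2), size)]
    for sup1 in supports1:
        for sup2 in supports2:
            q = _support_lp(game.payoff_p1, sup1, sup2)
            if q is None:
                continue
            p = _support_lp(game.payoff_p2.T, sup2, sup1)
            if p is None:
                continue
            if not _is_equilibrium(game, p, q):
                continue
            if any(
                np.allclose(p, eq.p1, atol=_DEDUP_TOL) and np.allclose(q, eq.p2, atol=_DEDUP_TOL)
                for eq in mixed
            ):
                continue
            if _best_response_count(game.payoff_p1 @ q) > np.count_nonzero(p > _DEDUP_TOL) or _best_response_count(
                game.payoff_p2.T @ p
            ) > np.count_nonzero(q > _DEDUP_TOL):
                degenerate = True
            mixed.append(MixedEquilibrium(p1=p, p2=q))
    return NashResult(pure=pure, mixed=tuple(mixed), degenerate=degenerate)


def zero_sum_equilibrium(game: BimatrixGame) -> tuple[np.ndarray, np.ndarray, float]:
    """Minimax solution (row mixture, column mixture, game value) of a
    zero-sum game via two linear programs.

    Independent of support enumeration; the row player maximises its
    guaranteed payoff ``v`` subject to x'A >= v against every column.
    """
    if not game.zero_sum:
        raise ValueError("minimax LP applies to zero-sum games only")
    a = game.payoff_p1
    n1, n2 = a.shape

    # row player: maximise v s.t. sum_i x_i a[i,j] >= v for all j
    res_row = linprog(
        c=np.append(np.zeros(n1), -1.0),
        A_ub=np.hstack([-a.T, np.ones((n2, 1))]),
        b_ub=np.zeros(n2),
        A_eq=np.append(np.ones(n1), 0.0).reshape(1, -1),
        b_eq=[1.0],
        bounds=[(0.0, 1.0)] * n1 + [(None, None)],
        method="highs",
    )
    # column player: minimise u s.t. sum_j a[i,j] q_j <= u for all i
    res_col = linprog(
        c=np.append(np.zeros(n2), 1.0),
        A_ub=np.hstack([a, -np.ones((n1, 1))]),
        b_ub=np.zeros(n1),
        A_eq=np.append(np.ones(n2), 0.0).reshape(1, -1),
        b_eq=[1.0],
        bounds=[(0.0, 1.0)] * n2 + [(None, None)],
        method="highs",
    )
    if not (res_row.success and res_col.success):
        raise RuntimeError("minimax linear program failed")
    return res_row.x[:n1], res_col.x[:n2], float(res_row.x[-1])


# ---------------------------------------------------------------------------
# replicator dynamics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReplicatorTrajectory:
    """Strategy-frequency trajectory on the probability simplex."""

    times: np.ndarray
    frequencies: np.ndarray  # shape (n_times, n_strategies)

    def __post_init__(self) -> None:
        if len(self.times) != len(self.frequencies):
            raise ValueError("times and frequencies must have equal length")


def replicator_dynamics(
    game: BimatrixGame,
    x0,
    t_end: float,
    n_out: int = 1001,
) -> ReplicatorTrajectory:
    """Single-population replicator dynamics x_i' = x_i((Ax)_i - x'Ax).

    Requires a symmetric game (player 2's payoffs the transpose of
    player 1's, which the zero-sum cyclic game satisfies) and a starting
    point on the simplex.  The flow conserves the simplex; for the
    zero-sum cyclic game interior orbits are closed and conserve the
    product of the frequencies.
    """
    if not game.symmetric:
        raise ValueError("replicator dynamics requires a symmetric game")
    a = game.payoff_p1
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (a.shape[0],):
        raise ValueError(f"x0 must have {a.shape[0]} entries")
    if abs(x0.sum() - 1.0) > 1e-9 or x0.min() < -1e-9:
        raise ValueError(f"x0 is not on the probability simplex: {x0}")

    def field(_t: float, x: np.ndarray) -> np.ndarray:
        fitness = a @ x
        return x * (fitness - x @ fitness)

    times = np.linspace(0.0, t_end, n_out)
    sol = solve_ivp(
        field,
        (0.0, t_end),
        x0,
        t_eval=times,
        method="DOP853",
        rtol=1e-10,
        atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"replicator integration failed: {sol.message}")
    return ReplicatorTrajectory(times=sol.t, frequencies=sol.y.T.copy())
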