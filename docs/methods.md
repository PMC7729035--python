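# Methods

## Model and assumptions

The community is described by three abundances: resistant cells R that
draw on a constant nutrient supply N and proliferate at rate k1·N,
differentiate into motile cells at rate k4, and pay a
cost-of-resistance coupling k2·R·P; motile cells M that mature into
producers at rate k5; and public-goods producers P that decay at rate
k3 (the cost of production, used as the antibiotic-stress dial):

    dR/dt = k1·N·R − k4·R − k2·R·P
    dP/dt = −k3·P + k5·M
    dM/dt = k4·R − k5·M

All rates are per hour; abundances are arbitrary units. The model
assumes a well-mixed community (no space), a constant nutrient level
for the resistant reserve, and the differentiation order R → M → P.
The defaults k1=…=k5=1 h⁻¹, N=4 are the reference parameterisation
analysed throughout.

## Closed-form analysis

Setting the right-hand side to zero gives the washout state and, when
k1·N > k4, the coexistence state P* = (k1N−k4)/k2, R* = k3P*/k4,
M* = k4R*/k5. At the coexistence state the growth term of R vanishes,
so the Jacobian is

    [[0, −k2R*, 0], [0, −k3, k5], [k4, 0, −k5]]

with characteristic polynomial λ³ + a1λ² + a2λ + a3 where
a1 = k3+k5, a2 = k3·k5, a3 = k3·k5·(k1N−k4); the test suite proves this
identity symbolically (sympy) and confirms it numerically against the
Jacobian eigenvalues on random parameter sets. The Routh–Hurwitz
marginal case a1·a2 = a3 yields the Hopf point

    k3* = k1·N − k4 − k5,

independent of k2 (k2 rescales R* but cancels from the polynomial).
A second, independent route — bisection on the real part of the complex
eigenvalue pair of the numerically computed polynomial roots — must
agree to 1e-6 and does. Note the damped-oscillation regime is sometimes
loosely associated with a condition involving k2; the derivation shows
the bifurcation point itself cannot depend on k2, and a property test
pins this down.

Eigenvalue classification treats |Re λ| < 1e-9 as nonhyperbolic so the
marginal Hopf case is not misreported as stable or unstable. A complex
pair makes the point a focus (stable iff every real part is negative);
otherwise signs of the real eigenvalues decide node vs saddle.

## Numerical integration

`simulate` wraps scipy's LSODA with the analytic Jacobian, adaptive
internal stepping and a fixed output grid (default 0.025 h over 25 h,
the reference reporting protocol; tolerances rel 1e-8).

Strictly positive initial states are integrated in **log abundances**.
This is not cosmetic: in the spike regime the true R minima fall to
1e-16 and far below, many orders of magnitude under any sensible
absolute tolerance of a linear-space integrator. The linear integrator
then lets R cross zero, and in the negative orthant the flow blows up
in finite time (R′ = −k2RP with R,P < 0 feeds back positively), which
manifests as a numerically exploding, hanging run. In log space
positivity is exact, the deep minima are resolved, and the absolute
tolerance on log abundance is a relative tolerance on abundance.
Initial states with a zero component (the invariant faces and the
origin) use the linear-space path, where negative excursions beyond
10× the absolute tolerance abort the run and smaller ones are clamped
to zero.

The ratio R/(R+P) is reported as NaN (undefined), never 0, where
R+P < 1e-12.

## Regime classification

The classifier works on the post-transient half of the ratio series
(transient discard: first 50% of the horizon) with four exposed
thresholds, all dimensionless:

* `osc_tol` (1e-3): envelope gap above which the tail counts as
  oscillatory at that horizon;
* `damped_ratio` (0.9): last-to-first peak amplitude below which the
  oscillation counts as decaying;
* `spike_duty` (0.25): duty cycle (fraction of time above the envelope
  midline) below which a sustained oscillation counts as spike-like;
* `min_peaks` (3): peaks needed to judge decay from the tail alone.

When the tail holds fewer than `min_peaks` peaks but the envelope is
open, the decision falls back to the full-series peak sequence: if the
last peak is within `damped_ratio` of the largest, the trajectory is a
long-period sustained cycle (spike vs sinusoid by duty cycle); this
matters because the spike period grows from cycle to cycle (~33, 45,
52 h at k3=0.1) as the minima deepen, so a fixed window can contain a
single spike. Otherwise the label is damped-to-steady if the series
ever overshoots its final level by more than `osc_tol`, else monotonic
relaxation. The very stiff k3=1000 case is labelled monotonic even
though its eigenvalues are formally complex: the overshoot of the
*ratio* is far below any observable threshold, which matches how the
regime is described qualitatively.

The boundaries between regimes are visual in origin; the thresholds
are therefore configuration, not science, and the tests check the four
reference parameterisations (k3 = 0.1, 1, 10, 1000) are labelled
robustly across random positive initial conditions rather than chasing
exact trace values (initial conditions for the reference figures are
not published; trajectories are reproduced qualitatively).

## Bifurcation scan

`bifurcation_scan` integrates each grid point for t_end hours (default
1500), discards the first half, and records the min/max of the ratio.
The long default horizon is set by the physics: one 0.1-wide grid step
above the critical point the focus decays at only |Re λ| ≈ 0.009 h⁻¹,
so pushing the envelope gap below `osc_tol` after discarding the
transient needs on the order of 10³ h. (A 300 h horizon leaves a gap
of ~3e-2 at k3 = 2.2 — an order of magnitude above threshold.) The
Hopf estimate is the first grid value whose gap falls below `osc_tol`;
on the reference grid (0.2…3.0, step 0.1) it lands at 2.1, one grid
step above the closed-form value, and the closed arm matches
k3/(k3+1) to ~5e-6.

## Games

Payoff construction is exact integer/half-integer arithmetic: the
cyclic three-strategy game awards +1/−1/0, and the two-strategy
nascent-vs-mature game is built from the moderate-stress table by
adding (no stress) or subtracting (high stress) one point from every
payoff a player earns while playing P — player 1 along its P row,
player 2 along its P column.

Pure equilibria come from exhaustive best-response enumeration with a
1e-9 tie tolerance; ties are reported as weak equilibria rather than
dropped, because the no-stress analysis turns on such a tie. Mixed
equilibria come from support enumeration (all support pairs in
increasing size, each solved as two feasibility linear programs via
HiGHS), verified by an independent no-profitable-deviation check and
deduplicated at 1e-7. Zero-sum games are additionally solved by the
minimax linear program as a cross-check. Games where a best-response
set strictly exceeds an equilibrium support are flagged degenerate and
the reported profiles are representatives of a possible continuum.
Support enumeration is limited to four strategies per player — beyond
that the method a practitioner would want is Lemke–Howson, which is out
of scope for the games analysed here.

Replicator dynamics uses the standard single-population symmetric form
ẋᵢ = xᵢ((Ax)ᵢ − xᵀAx), integrated with DOP853 at rtol 1e-10; it is an
extension beyond the payoff-table analysis, grounded in the standard
ODE treatment of cyclic games. For the zero-sum cyclic game the tests
verify the two known invariants: the simplex sum (to 1e-8) and the
product x₁x₂x₃ (to 1e-6 over 100 time units).

## Synthetic fixtures

`generate_fixtures(seed)` produces the regime-stratified parameter
family (k3 = 0.1, 1, 10, 1000 at the defaults) and random 2×2/3×3
bimatrices (payoffs uniform in [−2, 2], rounded to 3 decimals) plus
zero-sum 3×3 matrices for the equilibrium-oracle property tests. The
same seed reproduces identical fixtures. These exercise the solvers,
not the biology: random payoff matrices say nothing about microbial
communities, and the regime family covers exactly the four reference
parameterisations rather than the full parameter space.

## Problem sizes

The default test-and-acceptance workloads are sized for a laptop core:
regime checks run 200 h horizons (≈0.05 s each), the reference
bifurcation scan is 29 grid points × 1500 h (≈40 s), and the
property batteries use 100 random parameter sets and 200 random
bimatrices (≈30 s).

## Known limitations

* Spike-regime orbits deepen their minima from cycle to cycle; in
  double precision R eventually underflows (at ~1e-308), so horizons
  beyond a few thousand hours in the deep spike regime are not
  meaningful even in log space.
* The classifier's labels are only as good as its thresholds; regimes
  near the boundaries (e.g. k3 just below the Hopf point) legitimately
  drift between damped and sinusoidal depending on horizon.
* No spatial structure, stochasticity or agent-based detail: the model
  is deliberately the minimal ODE caricature of the biology.
* No parameter estimation — nothing here fits data.
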