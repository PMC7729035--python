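# biotrio

A minimal dynamical model of a social-microbe community that hedges its
bets between **resistant** (R), **producer** (P) and **motile** (M)
subpopulations, together with the tools to analyse it: steady states and
their stability, the Hopf bifurcation in the cost of public-goods
production, classification of the oscillation regimes of the resistant
fraction, and the evolutionary-game companion (a cyclic three-strategy
game and stress-conditioned two-strategy games with their Nash
equilibria and replicator dynamics).

The package is aimed at theoretical/systems biologists studying division
of labour, bet hedging and public-goods production in microbial
communities (biofilms, fruiting bodies), and at anyone who wants a small,
fully analysed three-variable oscillator.

## The model

Abundances evolve as

```
dR/dt = k1·N·R − k4·R − k2·R·P
dP/dt = −k3·P + k5·M
dM/dt = k4·R − k5·M
```

with rate constants `k1…k5` (h⁻¹) and a constant nutrient supply `N`
reserved for the resistant cells. `k2·R·P` is the cost of resistance
(bet-hedging coupling), `k3` the cost of public-goods production —
the antibiotic-stress dial. Defaults are `k1=…=k5=1 h⁻¹`, `N=4`.

Besides the washout state, the model has a coexistence fixed point
`P* = (k1N−k4)/k2`, `R* = k3P*/k4`, `M* = k4R*/k5`, whose characteristic
polynomial is `λ³ + (k3+k5)λ² + k3k5·λ + k3k5(k1N−k4)`. The
Routh–Hurwitz marginal condition `a1·a2 = a3` gives a closed-form Hopf
point

```
k3* = k1·N − k4 − k5        (= 2 h⁻¹ at the defaults)
```

below which the resistant fraction `R/(R+P)` oscillates (spikes, then
sinusoids as k3 grows) and above which it settles to the steady ratio
`k3/(k3+1)`.

The game-theoretic layer encodes the same biology as payoffs: R beats P
(freeloading), P beats M, M beats R — a zero-sum rock–paper–scissors
game whose unique (mixed) Nash equilibrium plays every strategy with
probability 1/3 — plus a nascent-cell-vs-mature-community bimatrix game
whose pure-equilibrium structure flips with antibiotic stress.

## Worked example

```
$ python examples/stability_and_hopf.py
(R*, P*, M*) = (0, 0, 0)  ->  saddle  [-1+0j, -1+0j, 3+0j]
(R*, P*, M*) = (3, 3, 3)  ->  unstable_focus  [-2.175+0j, 0.08728+1.171j, 0.08728-1.171j]
closed-form Hopf point : k3* = 2 / h
bisection on eigenvalues: k3* = 2.000000 / h
```

At the default parameters the coexistence state `(3,3,3)` is an unstable
focus — the complex pair `0.087 ± 1.171j` has a positive real part, so
the resistant fraction cycles — and both the closed form and a numeric
bisection place the oscillation boundary at a production cost of
2 h⁻¹. The other examples print the four dynamic regimes
(`dynamic_regimes.py`), the amplitude bifurcation diagram
(`bifurcation_diagram.py`) and the game-theoretic analysis
(`games_and_replicator.py`).

A thin CLI wraps the same library calls:

```
biotrio simulate --k3 1 --t-end 25 --dt 0.025 --out trajectory.csv
biotrio stability
biotrio game --strategies 3
```

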