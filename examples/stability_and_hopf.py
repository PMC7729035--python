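"""Steady states, eigenvalues and the Hopf point of the reference model.

The community model has a washout state at the origin and, whenever the
resistant cells' net growth k1*N - k4 is positive, a coexistence state.
Raising the cost of public-goods production k3 stabilises the
coexistence state at the critical value k3* = k1*N - k4 - k5.
"""

from biotrio import (
    ModelParameters,
    analytic_steady_states,
    hopf_k3_critical,
    hopf_k3_numeric,
    stability_report,
)

params = ModelParameters()  # k1..k5 = 1 per hour, N = 4

for state in analytic_steady_states(params):
    rep = stability_report(state, params)
    eig = ", ".join(f"{z:.4g}" for z in rep.eigenvalues)
    print(f"(R*, P*, M*) = ({state.R:g}, {state.P:g}, {state.M:g})"
          f"  ->  {rep.classification}  [{eig}]")

print(f"closed-form Hopf point : k3* = {hopf_k3_critical(params):g} / h")
print(f"bisection on eigenvalues: k3* = {hopf_k3_numeric(params):.6f} / h")

# The coexistence state (3, 3, 3) is an unstable focus at k3 = 1 (the
# ratio R/(R+P) oscillates), and both routes agree that oscillations die
# out once the production cost exceeds 2 per hour.
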