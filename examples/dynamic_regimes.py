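"""Four qualitative regimes of the resistant fraction R/(R+P).

Sweeping the cost of public-goods production k3 (with every other rate
at 1 per hour) takes the observable through spike-like oscillations,
sinusoidal cycling, damped oscillations and finally a monotonic
relaxation to a producer-poor steady state.
"""

from biotrio import ModelParameters, SimulationSettings, classify_regime, simulate

settings = SimulationSettings(t_end=200.0, dt_out=0.025)

for k3 in (0.1, 1.0, 10.0, 1000.0):
    traj = simulate(ModelParameters(k3=k3), settings)
    label = classify_regime(traj)
    print(f"k3 = {k3:6g} / h  ->  {label.label:24s}"
          f" (swing {label.amplitude:.3f}, duty cycle {label.duty_cycle:.2f},"
          f" final ratio {traj.ratio[-1]:.4f})")

# The swing is the post-transient max-min gap of the ratio; the duty
# cycle is the fraction of time the ratio spends above its midline
# (low for narrow spikes).  The final ratio approaches the steady value
# k3/(k3+1) once oscillations are damped.
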