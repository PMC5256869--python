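"""Simulate the mRNA-transfection model with its state-jump event.

An amount m0 of mRNA is released instantly at t_r = 2; it decays at rate
deg_m while driving synthesis of a reporter G (rate k_syn) that decays at
rate deg_G.  The simulation stops exactly at the event, applies the jump
and restarts, so the discontinuity is resolved exactly.
"""

import numpy as np

from adjfit import compile_model, make_fixture, simulate
from adjfit.fixtures import TRANSFECTION_RELEASE_TIME, TRANSFECTION_THETA

cm = compile_model(make_fixture("transfection"))
times = np.linspace(0.0, 10.0, 11)
traj = simulate(cm, TRANSFECTION_THETA, times)

deg_m, _, _, m0 = TRANSFECTION_THETA
print(" t      mRNA m    reporter G   closed-form m")
for t, (m, G) in zip(traj.times, traj.states):
    exact = 0.0 if t < TRANSFECTION_RELEASE_TIME else m0 * np.exp(
        -deg_m * (t - TRANSFECTION_RELEASE_TIME)
    )
    print(f"{t:4.1f}  {m:9.5f}  {G:10.5f}   {exact:12.5f}")

print(
    "\nm is zero before the release at t_r = "
    f"{TRANSFECTION_RELEASE_TIME}, jumps to m0 = {m0} and then decays "
    "exponentially; the simulated column matches the closed form to solver "
    "accuracy."
)
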