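"""Compute the objective gradient with all three engines and compare.

The decay fixture (dx/dt = -k x, x0 given, y = x) with a single datum at
t = ln 2 has the closed-form gradient (-log(2)/2, 1/4) at theta = (1, 2),
so every engine can be checked against an exact value.
"""

import numpy as np

from adjfit import ExperimentData, compile_model, gradient, make_fixture

cm = compile_model(make_fixture("decay"))
data = ExperimentData(times=[np.log(2.0)], values=[[0.5]], sigmas=1.0)
theta = [1.0, 2.0]

exact = np.array([-np.log(2.0) / 2.0, 0.25])
print(f"exact gradient: {exact}")
for method in ("fd", "forward", "adjoint"):
    res = gradient(cm, theta, data, method=method)
    err = np.max(np.abs(res.grad - exact))
    d = res.diagnostics
    cost = (
        f"{d['n_simulations']} simulations" if method == "fd"
        else f"augmented dim {d['augmented_dim']}" if method == "forward"
        else f"{d['n_forward_solves']} forward + {d['n_backward_solves']} backward solve"
    )
    print(f"{method:8s} grad = {res.grad}  max err = {err:.2e}  ({cost})")

print(
    "\nAll three agree with the closed form; finite differences pay one "
    "simulation per perturbation, the forward method enlarges the ODE "
    "system per parameter, and the adjoint method needs a single backward "
    "solve however many parameters are differentiated."
)
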