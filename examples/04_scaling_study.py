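"""Gradient-cost scaling with the number of differentiated parameters.

A random 8-species, 20-reaction mass-action network is generated; each
engine computes the gradient with respect to nested parameter subsets of
size 1, 5, 10 and 20.  Solve counts make the structural scaling visible
without relying on wall-clock timing: finite differences cost 2k
simulations, the forward system grows to dimension n_x(1+k), and the
adjoint always performs one forward plus one backward solve.
"""

import numpy as np

from adjfit import (
    NetworkSpec,
    compile_model,
    generate_data,
    make_random_network,
    scaling_experiment,
)

model, theta = make_random_network(NetworkSpec(n_x=8, n_r=20, seed=0))
cm = compile_model(model)
data = generate_data(cm, theta, np.linspace(0.5, 5.0, 5), sigma=0.1, seed=77)

table = scaling_experiment(cm, theta, data, subset_sizes=[1, 5, 10, 20])
cols = ["method", "subset_size", "mean_time_s", "n_simulations",
        "n_backward_solves", "augmented_dim"]
print(table[cols].to_string(index=False))
print(
    "\nThe adjoint rows keep n_backward_solves = 1 for every subset size "
    "while the FD simulation count and the forward augmented dimension "
    "grow linearly — the structural reason adjoint gradients scale to "
    "many-parameter models."
)
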