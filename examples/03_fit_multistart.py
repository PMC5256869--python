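"""Multi-start maximum-likelihood fit of the transfection model.

Noise-free synthetic data are generated at known parameters; 20 local
optimizations start from a latin hypercube over [1e-2, 1e2]^4 on the
log10 scale, using adjoint gradients with L-BFGS-B.  The sorted final
objective values (the waterfall) reveal the global optimum plateau.
"""

import numpy as np

from adjfit import (
    EstimationProblem,
    compile_model,
    generate_data,
    make_fixture,
    multistart,
    waterfall,
)
from adjfit.fixtures import TRANSFECTION_THETA

cm = compile_model(make_fixture("transfection"))
times = np.linspace(0.0, 10.0, 16)
data = generate_data(cm, TRANSFECTION_THETA, times, sigma=0.0, seed=2)

problem = EstimationProblem(
    cm, data,
    lower=np.full(4, 1e-2), upper=np.full(4, 1e2),
    scale="log10", grad_method="adjoint", max_iter=300,
)
result = multistart(problem, n_starts=20, seed=7)

best = result.best
print(f"best final J = {best.J:.3e}  ({result.n_failed}/20 starts failed)")
print(f"best theta   = {best.theta}")
print(f"true theta   = {TRANSFECTION_THETA}")
print(f"decay pair   {sorted(best.theta[[0, 2]])} vs {sorted(TRANSFECTION_THETA[[0, 2]])}")
print(f"k_syn * m0   {best.theta[1] * best.theta[3]:.6f} vs "
      f"{TRANSFECTION_THETA[1] * TRANSFECTION_THETA[3]:.6f}")
print("\nwaterfall (rank, J, optimum group):")
print(waterfall(result).head(10).to_string(index=False))
print(
    "\nJ ~ 1e-16 at the best starts: the optimum reproduces the data "
    "exactly.  Only the decay-rate pair and the product k_syn*m0 are "
    "identifiable from observing G alone, and both are recovered; the "
    "individual values of k_syn and m0 are not determined by the data."
)
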