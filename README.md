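# adjfit

Gradient-based maximum-likelihood parameter estimation for ODE models of
biochemical reaction networks, built around three interchangeable gradient
engines: finite differences, forward sensitivity analysis, and
**discrete-time adjoint sensitivity analysis**.

## The problem

Kinetic models of reaction networks take the form

    dx/dt = f(x, θ),   x(t₀) = x₀(θ),   y = h(x, θ),

with states `x ∈ ℝ^{n_x}` (concentrations), parameters `θ ∈ ℝ^{n_θ}`
(rate constants, initial amounts), and an output map `h` describing what
is actually measured.  Fixed-time state jumps `x(t_e⁺) = g(x(t_e⁻), θ)`
model instantaneous interventions such as a bolus release of mRNA.
Given discrete-time noisy measurements `ȳ_ij = y_i(t_j, θ) + ε_ij`,
`ε_ij ~ N(0, σ_ij²)` (missing values allowed), the maximum-likelihood
estimate minimizes the weighted least squares

    J(θ) = ½ Σ_ij [ (ȳ_ij − y_i(t_j, θ)) / σ_ij ]².

Gradient-based multi-start optimization needs ∇J, and computing ∇J is
the bottleneck for models with many parameters:

* **finite differences** — n_θ+1 (one-sided) or 2·n_θ (central)
  simulations;
* **forward sensitivities** — one solve of an augmented system of
  dimension n_x·(1+n_θ);
* **adjoint sensitivities** — one forward solve plus **one** backward
  solve of the adjoint state `p(t)` (dimension n_x), independent of n_θ:
  `p = 0` beyond the last measurement, `p` jumps by
  `(∂h/∂x)ᵀ (ȳ−y)/σ²` at each measurement time, evolves backward via
  `ṗ = −(∂f/∂x)ᵀ p`, and the gradient assembles from error-controlled
  quadratures `∫ pᵀ ∂f/∂θ_k dt` plus cheap boundary terms.

Models are defined symbolically (plain YAML/JSON, or an SBML subset);
all derivatives (`∂f/∂x`, `∂f/∂θ`, `∂h/∂x`, `∂h/∂θ`, `∂x₀/∂θ`, event
Jacobians) are generated by exact symbolic differentiation.

## Worked example

```python
import numpy as np
from adjfit import ExperimentData, compile_model, gradient, make_fixture

cm = compile_model(make_fixture("decay"))          # dx/dt = -k x, y = x
data = ExperimentData(times=[np.log(2.0)], values=[[0.5]], sigmas=1.0)
for method in ("fd", "forward", "adjoint"):
    print(method, gradient(cm, [1.0, 2.0], data, method=method).grad)
```

prints (see `examples/02_compare_gradient_engines.py`):

```
exact gradient: [-0.34657359  0.25      ]
fd       grad = [-0.34657387  0.25000002]  max err = 2.79e-07  (4 simulations)
forward  grad = [-0.34657359  0.25      ]  max err = 2.25e-10  (augmented dim 3)
adjoint  grad = [-0.34657358  0.24999999]  max err = 1.01e-08  (1 forward + 1 backward solve)
```

For this fixture the gradient has the closed form `(-log 2 / 2, 1/4)`;
all three engines reproduce it, and the diagnostics show their cost
structure: FD pays simulations per parameter, the forward engine enlarges
the ODE system, the adjoint performs a single backward solve regardless
of how many parameters are differentiated.

The `examples/` directory walks through the other capabilities: event
simulation against a closed form, multi-start fitting with a waterfall
table, the gradient-cost scaling study, and the file formats / CLI.
A thin command line mirrors the library:

```sh
adjfit gradient --model decay.yaml --data measurements.csv \
    --theta 1.0,2.0 --method adjoint -o grad.json
adjfit fit --model model.yaml --data data.csv \
    --lower 0.01,0.01 --upper 100,100 --n-starts 20 --seed 0 -o fit.json
```

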