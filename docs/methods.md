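# Methods

## Model class

`adjfit` targets ODE models of biochemical reaction networks,

    dx/dt = f(x, θ),   x(t₀) = x₀(θ),   y(t, θ) = h(x(t, θ), θ),

with `n_x ≥ 1` states (concentrations), `n_θ ≥ 1` parameters and
`n_y ≥ 1` observables.  Expressions for `f`, `x₀` and `h` are written in
a small grammar — arithmetic (`+ − * / ^`), `exp`, `log`, `sqrt`, and
rational terms, which covers mass-action, Michaelis–Menten and Hill
kinetics — and parsed into sympy trees.  Anything outside the grammar is
rejected at parse time with the offending identifier or function named.
All derivative callables (`∂f/∂x`, `∂f/∂θ`, `∂h/∂x`, `∂h/∂θ`, `∂x₀/∂θ`,
and per-event `∂g/∂x`, `∂g/∂θ`) are exact symbolic derivatives of those
trees, lambdified to numpy; no derivative in the package is obtained by
differentiating solver output.

**Events.** The model may contain fixed-time state jumps
`x(t_e⁺) = g(x(t_e⁻), θ)` (e.g. an instantaneous release of material).
Event times are plain numbers, never functions of `θ`: the gradient
formulas below have no trigger-sensitivity term, so parameter-dependent
event *times* would silently produce wrong gradients and are excluded by
construction.  Parameter-dependent event *assignments* are fully
supported and differentiated.

## Simulation

The initial value problem is solved with `scipy.integrate.solve_ivp`
(LSODA by default, switching between stiff and non-stiff regimes; BDF or
Radau selectable), with the analytic Jacobian supplied to the stiff
solvers.  Integration stops exactly at each event time, applies the
assignment and restarts — measurement values are never interpolated
across a discontinuity.  When a measurement time coincides with an event
time the post-event state is observed (a measurement sees the system
after an instantaneous release).

Default tolerances are rtol `1e-8`, atol `1e-16`.  Each inter-event
interval retains its dense-output interpolant so that the backward
adjoint solve can evaluate `x(t)` anywhere without re-integration; this
checkpoint-free strategy trades memory for speed and is the right choice
at desk scale (thousands of steps, not millions).  A terminal "divergence
guard" event aborts integration once any state magnitude exceeds `1e12`,
converting finite-time blow-ups into clean errors instead of stalled
step-size collapse.

## Objective

For known per-point noise standard deviations the negative
log-likelihood is, up to an additive constant, the weighted least squares

    J(θ) = ½ Σ_{(i,j) observed} [ (ȳ_ij − y_i(t_j, θ)) / σ_ij ]².

Missing values are carried as an explicit boolean mask (populated from
NaN/absent cells on read) and skipped by every consumer — the objective,
all three gradient engines and the FIM.  σ may be given per point, per
observable, or as a scalar.

## Gradient engines

All three engines return the exact derivative of `J`; the signs of every
term were fixed by requiring agreement with a finite-difference oracle,
and the engines are tested against closed forms and against each other.

**Finite differences.**
`∂J/∂θ_k ≈ [J(θ + a e_k) − J(θ − b e_k)]/(a+b)` with presets forward
(`a=ϵ, b=0`), backward (`a=0, b=ϵ`) and central (`a=b=ϵ`), default
`ϵ = 1e-3`.  Central differences cost exactly `2K` simulations for `K`
differentiated parameters, one-sided `K+1`.  A perturbed simulation that
fails flags its component as NaN rather than aborting the whole gradient.

**Forward sensitivities.**  The sensitivities
`s_k = ∂x/∂θ_k` obey `ṡ_k = (∂f/∂x) s_k + ∂f/∂θ_k`,
`s_k(t₀) = ∂x₀/∂θ_k`, and are integrated *jointly* with the state as one
augmented system of dimension `n_x(1+K)` under shared error control (the
model Jacobian is reused block-diagonally for the Newton iterations).
Across an event, `s⁺ = (∂g/∂x) s⁻ + ∂g/∂θ`.  Output sensitivities follow
by the chain rule and the gradient is
`∂J/∂θ_k = −Σ_ij w_ij s^y_{i,k}(t_j)` with `w_ij = (ȳ_ij − y_ij)/σ_ij²`.

**Adjoint sensitivities.**  The adjoint state `p(t) ∈ ℝ^{n_x}` is zero
beyond the last measurement time; walking backward from `t_N` to `t₀` it
is reinitialised at each measurement time by

    p(t_j) = p(t_j⁺) + (∂h/∂x)ᵀ w_j,

evolves between measurements by the linear ODE `ṗ = −(∂f/∂x)ᵀ p`, and
transfers through an event as `p(t_e⁻) = (∂g/∂x)ᵀ p(t_e⁺)`.  The
per-parameter quadratures `q_k = ∫ pᵀ ∂f/∂θ_k dt` ride along as auxiliary
states of the *same* backward integration, so they share its error
control (no post-hoc trapezoid on saved points).  The gradient assembles
as

    ∂J/∂θ_k = −q_k − Σ_ij (∂h_i/∂θ_k) w_ij − p(t₀)ᵀ ∂x₀/∂θ_k
              − Σ_events p(t_e⁺)ᵀ ∂g/∂θ_k.

The event term mirrors the initial-condition term — the jump acts as a
re-initialisation at `t_e` — and its sign was verified both analytically
on a jump-only toy model (`ẋ = 0`, `x₀ = 0`, jump `x += θ`) and by the
finite-difference oracle on the transfection fixture.  When a
measurement coincides with an event, the measurement jump is applied on
the post-event side first (matching the observation of the post-event
state), then the event transfer.  Exactly one backward solve is
performed regardless of the subset size; diagnostics record forward and
backward solve counts so scaling claims are assertable without timing.

**Step-1 accuracy safety factor.**  The backward solve and its
quadratures condition on the forward trajectory `x(t)`: trajectory
errors are amplified into the gradient by the objective's curvature,
which can exceed the forward *output* accuracy requirement by orders of
magnitude.  The forward pass that feeds the adjoint is therefore
integrated with a `1e-2` safety factor on both tolerances (floored at
rtol `1e-12` / atol `1e-20`, where LSODA's step selection saturates).
This is the standard recommendation for adjoint implementations and
costs a few extra forward steps.

**Fisher information matrix.**
`FIM = Σ_{ij observed} s^y_{i,·}(t_j)ᵀ s^y_{i,·}(t_j)/σ_ij²` — a Gram
matrix, hence symmetric positive semidefinite, used as the Hessian
approximation for trust-region least-squares fits.  Only the forward
engine yields output sensitivities, so only it can supply a FIM; the
adjoint engine pairs with quasi-Newton optimization instead.

## Estimation

Multi-start local optimization: start points from a latin hypercube
design over the parameter box, by default on the log10 scale (kinetic
constants span decades; bounds are always given on the linear scale and
must then be positive).  Two optimizer routes behind one contract:

* **trust-region** — `scipy.optimize.least_squares` (TRF) on the weighted
  residual vector with the exact residual Jacobian from forward
  sensitivities (the Gauss–Newton/FIM route);
* **bfgs** — L-BFGS-B on `(J, ∇J)` from any engine; the default partner
  for adjoint gradients.

`optimizer="auto"` picks trust-region for the forward engine and BFGS
otherwise.  Gradients are chain-ruled into log10 space
(`∂J/∂log₁₀θ = θ ln 10 · ∂J/∂θ`).  A simulation or gradient failure
produces a flagged `gradient-failure` start result — recorded, sortable,
excluded from "best" — never a silent omission or an exception that
kills the other starts.  Results are sorted ascending by final `J`;
`waterfall()` groups final values agreeing within `1e-4` as one optimum
and lists failures separately.

## Synthetic fixtures and what they do (not) show

Three named fixtures have closed-form solutions and anchor the tests:
`const` (`ẋ=0, x₀=θ, y=x`; the objective is an exact quadratic),
`decay` (`ẋ=−kx`), and `transfection` — mRNA release `m ← m + m₀` at
`t_r = 2`, `ṁ = −δm`, `Ġ = km − γG`, observing `G` only, with nominal
parameters `(δ, k, γ, m₀) = (0.8, 1.2, 0.4, 2.0)` on a 10-hour horizon.
Observing `G` alone leaves two structural non-identifiabilities: `k` and
`m₀` enter only through their product, and `(δ, γ)` are exchangeable
(two-exponential symmetry).  Recovery tests therefore check the
identifiable combinations — the unordered rate pair and the product —
not the raw vector.

The random-network generator draws strictly mass-action reactions
(orders 0–2, so polynomial right-hand sides of degree ≤ 2) among `n_x`
species, one log-uniform rate constant per reaction from `[1e-2, 1]`,
random positive initial values in `[0.5, 2]`, and a random subset of
species as outputs.  Candidates whose nominal simulation fails or leaves
`[−10⁶, 10⁶]` on a 10-unit horizon are rejected and redrawn, so every
returned network is integrable at its nominal parameters.  The data
simulator adds independent Gaussian noise (default σ = 0.1, roughly 10%
of typical output magnitudes) and can mask an exact fraction of entries
uniformly at random; everything is reproducible bit-for-bit from seeds.

These fixtures validate *correctness* — oracle gradients, cross-method
agreement, structural solve counts — on desk-scale problems
(`n_x ≤ 10`, `n_θ ≤ 20`, tens of data points).  They do not emulate
genome-scale networks, stiff signaling cascades with thousands of
species, real measurement error structure, or wall-clock behaviour at
scale; the scaling study therefore reports *solve counts and dimensions*
(which are exact structural facts) alongside wall time (which is
indicative only at this size, where per-call overhead dominates).

## Numerical choices

* Default tolerances rtol `1e-8` / atol `1e-16`; the FD default
  `ϵ = 1e-3` applies on the scale the optimizer works in.
* FD-vs-adjoint comparisons at small steps are themselves limited by
  integration accuracy (the FD quotient inherits `~rtol·J/(a+b)` of
  noise), so tight-step FD validations run at rtol `1e-11`.
* Backward breakpoints are the union of measurement and event times;
  within each leg the forward dense interpolant of the covering segment
  supplies `x(t)`.
* The waterfall plateau tolerance is `1e-4` in `J`.
* Degenerate inputs are rejected loudly: non-positive σ on observed
  entries, unsorted times, event times ≤ t₀, out-of-range parameter
  subsets, bounds with `lower ≥ upper`.

## Design decisions

* **JSON result files** (gradient results, multi-start results with full
  traces) round-trip exactly; no binary result format.
* **SBML is a convenience subset reader** (reactions → ODEs via
  stoichiometry, compartment volumes folded in, initial
  amounts/concentrations; content-MathML kinetic laws).  Trigger-based
  events, rules of any type, function definitions, fast reactions and
  boundary/constant species are rejected with the construct named.  The
  native YAML/JSON format is the canonical, fully tested path.
* **No second-order sensitivities**: Hessians come from the FIM (forward
  route) or quasi-Newton accumulation (adjoint route).
* **No steady-state pre-equilibration, root-finding event triggers, or
  delay equations.**

## Known limitations

* The adjoint backward problem inherits the forward problem's stiffness
  reversed in time; for networks whose forward dynamics are strongly
  contracting the backward solve can need substantially more steps than
  the forward one.  The engine reports step counts so such cases are
  visible.
* Gradient accuracy for any engine is bounded by the objective's
  conditioning times the trajectory accuracy; on harshly curved
  objectives components of small magnitude carry larger relative error.
* The checkpoint-free dense-output strategy stores every integration
  step of the forward solve; for very long horizons or very stiff runs a
  checkpointing scheme would be needed.
* Event times must be constants; see "Events" above.
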