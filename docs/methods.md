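# Methods

## Model and procedure

The package solves likelihood equations `U(θ) = 0` by a reparameterization
plus constrained entropy maximisation. Each of the J parameters is written as
`θ_j = z_jᵀ p_j`, where `z_j` is a fixed, strictly increasing grid of K
admissible values and `p_j` an unknown probability vector. The program

    max H(p) = −Σ_j p_jᵀ log p_j   s.t.   U(θ(p)) = 0,  p_jᵀ1 = 1

is solved over the product of simplices. Entropy is strictly concave; when
the score constraint is linear in `p` (normal, and the Poisson constraint
after clearing the positive denominator) the feasible set is convex and the
optimum is unique and of Gibbs form, `p_j ∝ exp(c_j z_j)`. For nonlinear
constraints (gamma, logistic) local uniqueness is not guaranteed in general;
runs are repeatable because the initialization is always the uniform weight
matrix and all randomness is seeded.

Assumptions worth stating explicitly: the model is regular and correctly
specified, the score root (when it exists) lies inside the box
`[min z_j, max z_j]^J`, and inference is deferred to standard likelihood
asymptotics — the package computes no standard errors or intervals.

## Solver

Phase one is an equality-constrained sequential quadratic program (SciPy's
SLSQP) from uniform weights, with analytic objective gradient and, for every
bundled model, an analytic constraint Jacobian
`dU/dp = (dU/dθ) · blockdiag(z_1, …, z_J)`. Defaults: 500 iterations,
objective tolerance 1e−12, feasibility declared when `max |U| ≤ 1e−8`.
Probabilities are floored at 1e−12 inside logarithms only; reported weights
are not floored.

If phase one ends infeasible — typically because no score root exists in the
box, as under complete separation — phase two minimises
`½‖U(θ(p))‖² − 10⁻³·H(p)` subject only to the simplex constraints and the
fit is returned with `feasible=False`. The entropy term selects a unique
interior violation minimiser; the resulting point estimates are
solver-dependent by nature (different NLP algorithms report different finite
surrogates for an infinite MLE) and should be read qualitatively, the same
way Firth-corrected estimates are a finite stand-in for a diverging fit.

The normal-mean case has a closed Gibbs-form solution indexed by one
multiplier; `solve_me_normal_closed` recovers it by bracketed Brent root
finding (bracket grown geometrically from [−1, 1]), replacing a grid search
with something more precise that finds the same answer. Because
`z ᵀ p(λ)` is strictly monotone in λ, the root is unique; this path is the
independent oracle against which the general solver is tested to 1e−6.

A note on reported weight vectors: for the Poisson example the weight vector
circulating in the literature alongside the rate estimate is feasible but not
a stationary point of the program above (its log is not affine in `z`, which
the first-order conditions force). The rate estimate itself is unaffected —
any feasible point has `zᵀp = ȳ` — but exact optima have monotone
Gibbs-form weights, and that is what this implementation returns. The
corresponding regression test documents the discrepancy.

## Support rules

Supports are equally spaced (`linspace`) and data-driven:

| family   | rule                                                   | default |
|----------|--------------------------------------------------------|---------|
| normal   | `[min y, max y]`; constant samples widened to ±1       | K = 7   |
| Poisson  | `[0, max y]`                                           | K = 5   |
| gamma    | `[0, ᾱ+δ]`, `[0, ρ̄+δ]`, `ᾱ = 1/(2M)`, `ρ̄ = ᾱ/ȳ`,
             `M = log ȳ − mean(log y)`                              | δ = 3   |
| logistic | common symmetric `[−b, b]` for all coefficients        | b = 10  |

The logistic bound b = 10 covers the practically distinguishable range of
the logistic curve; it is configurable (the separated iris example uses 25).
K ∈ {5, 7} suffices for these regular problems; K = 1 grids are rejected.

## Baselines

Newton–Raphson is plain IRLS (score tolerance 1e−8, 50 iterations), with a
divergence flag when any coefficient passes 10³ or the working weights
collapse everywhere (`max π(1−π) < 10⁻⁶`). Firth's correction solves the
modified score `Xᵀ(y − π + h⊙(½ − π)) = 0` (h the hat diagonal) by Newton
steps with step-halving on the Jeffreys-penalized likelihood
`l(β) + ½ log det I(β)`; it is verified in tests against direct maximisation
of that penalized likelihood and against the published separated-iris fit.
Separation is detected by two small LPs over directions `d ∈ [−1,1]^J`:
maximise the minimum of the signed margins `(2y_i−1)x_iᵀd` (positive optimum
⇒ complete separation), else maximise their sum (positive ⇒ quasi). Returned
certificates satisfy their defining inequalities exactly and are asserted in
tests.

## Monte-Carlo study and its generator

Cells cross n ∈ {15, 50, 200} with p ∈ {1, 5, 10}. Per cell: predictors are
iid standard normal with an intercept column, coefficients are drawn once
from N(0, 2.5²), π = logistic(Xβ) is held fixed, and only the responses
y ~ Bernoulli(π) are resampled across the Q replicates. The 2.5 is a
standard deviation; it makes the marginal separation frequency at n=15, p=1
land near one third, which is the calibration the study design targets.
Metrics per estimator: `B = mean_q Σ_j (β_j − β̂_qj)` (parameter-summed
bias), `B² `, `V = Σ_j var_q(β̂_qj)`, `MSE = V + B²` (an identity by
construction, asserted anyway), per-replicate relative bias
`RB = (β̂_j − β_j)/|β_j|` over all parameters including the intercept, and
the over/under-estimation ratio `r = #(RB>0)/#(RB<0)`. Non-converged
Newton–Raphson fits are counted in the non-convergence rate and excluded
from that estimator's averages; diverging-but-stopped fits are included,
mirroring how glm-style software reports them. Firth and entropy fits always
converge in the design range.

Because X and β are drawn once per cell, every cell-level summary is
conditional on that single draw, and the draw dominates the dispersion:
across independent draws the n=15, p=1 separation rate ranges from ~0.02 to
~0.85 (mean ≈ 0.30), and the n=200, p=1 MSE ranges over a factor of ~20
depending on `|β|`. The reproduction script therefore reports the separation
rate averaged over 24 independent design draws (60 replicates each — the
stable estimand the single published draw happens to sit near), but keeps
the literal single-draw protocol for the MSE and r targets, whose published
values are conditional quantities that averaging would systematically move
(design-draw means are inflated by heavy-tailed draws). Consequently those
two outputs inherit design-draw variability at any given seed; that is a
property of the protocol, not of the estimator.

What the generator does *not* emulate: correlated or non-Gaussian
predictors, model misspecification, and repeated (X, β) draws per cell.
Passing tests therefore speak to estimator behaviour under clean,
independent Gaussian designs, not to robustness beyond them.

## Scaled problem sizes

Tests and the reproduction script run the study at desk scale, chosen as the
smallest sizes at which the comparisons are meaningful: Q = 400–500
replicates for metric cells, 20–30 replicates per draw across 20+ design
draws for rate estimates. The full-scale design (Q = 10⁴ per cell) is
available through `run_design`/`me-score simulate` unchanged.

## Numerical choices and degenerate inputs

- logistic means via `expit`, log-likelihoods via `logaddexp` (no overflow);
- Gibbs weights computed with a max-subtracted softmax;
- gamma/Poisson scores clip θ at 10⁻¹⁰ above zero so solver line searches
  cannot step onto the boundary of the natural range;
- constant normal samples widen their degenerate support by ±1;
- samples whose mean falls outside the declared support raise with an
  instruction to widen the grid (no root exists in the box);
- ties/multiple optima: uniform initialization everywhere; seeds recorded in
  simulation results via per-cell spawned seed sequences.

## Known limitations

- No inferential output (standard errors, intervals, tests).
- Infeasible-case estimates are solver-dependent surrogates; only their
  finiteness, sign pattern and order of magnitude are meaningful.
- The weight matrices returned for nonlinear-constraint models are exact
  optima of the stated program; they need not match loosely converged
  augmented-Lagrangean output from other software (see the Poisson note).
- Dominance (inequality) constraints between parameters and prior-weighted
  (Kullback–Leibler) variants are out of scope.
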