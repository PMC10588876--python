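# Methods

## The problem

In toxicogenomic concentration–response screening, thousands of genes are
measured at a handful of concentrations with very few replicates. A
four-parameter log-logistic (4pLL) curve is fitted to each gene and the
log-EC50 — the log of the concentration at which half of the maximal effect
is attained — serves as the alert concentration. With ~27 observations per
gene the per-gene estimate of the log-EC50 can be very noisy, especially for
genes with flat slopes or inflection points near or beyond the tested range.
`ec50shrink` improves these estimates by sharing information across genes:
the ensemble of per-gene estimates defines an empirical prior, and each
gene's estimate is replaced by its posterior mean under that prior.

## Dose–response model and fitting

The response at concentration `x ≥ 0` is modelled as

    f(x; b, c, d, ẽ) = c + (d − c) / (1 + exp(b (log x − ẽ)))

with lower/upper asymptotes `c, d`, slope-proportional parameter `b`, and
`ẽ = log(EC50)`. Parameterizing the EC50 on the log scale keeps it positive
by construction and makes its estimator's sampling distribution closer to
normal on small designs, which the normal-normal shrinkage model assumes.
At `x = 0` the analytic limit is used (`d` for `b > 0`, `c` for `b < 0`,
`(c+d)/2` for `b = 0`), so control observations never require `log 0`.

Parameters are estimated by least squares. The default design is the
valproic-acid case-study layout: concentrations 0, 25, 150, 350, 450, 550,
800, 1000 μM with 6 control and 3 treated replicates (27 observations,
23 residual degrees of freedom).

Numerical choices:

* **Starting values** (self-starter): `d₀` = mean response at the lowest
  concentration, `c₀` = mean at the highest; `b₀` and `ẽ₀` from a linear
  regression of the clipped logit of the scaled response on log
  concentration over `x > 0`; a fallback start with the opposite slope sign
  (`b₀ = ∓1`) is always added, and both `±1` fallbacks when the logit
  regression is degenerate. All starts are deterministic.
* **Optimizer**: BFGS with an analytic gradient of the residual sum of
  squares, gradient tolerance `1e-8`, at most 500 iterations per start; the
  best SSE across starts is kept and is never worse than any starting value.
  On the noiseless design the generating parameters are recovered to ~1e-7.
* **Identifiability**: `(b, c, d) → (−b, d, c)` leaves the curve unchanged;
  fits are reported in the canonical orientation `d ≥ c`.
* **Uncertainty**: delta-method standard errors from
  `σ̂² (JᵀJ)⁻¹` with `σ̂² = SSE/(p−4)` and `J` the prediction Jacobian at
  the optimum; confidence intervals use the t distribution with `p − 4`
  degrees of freedom. A fit with a singular `JᵀJ` or a non-finite standard
  error for `ẽ` is flagged `converged=False` and treated as missing
  downstream — never raised — because simulation pipelines must tolerate
  per-run failures. No box constraints are imposed; `b` is free in sign.

## Empirical-Bayes shrinkage

Each gene's direct estimate `x = ẽ̂` is modelled as `X | μ ~ N(μ, σ²)` with
`σ²` fixed at the squared standard error of that gene's estimate, and
`μ ~ N(μ₀, τ²)`. The posterior is the conjugate normal

    μ | x ~ N( (τ²x + σ²μ₀) / (τ² + σ²),  τ²σ² / (τ² + σ²) ),

a precision-weighted compromise between the gene's own estimate and the
cross-gene prior mean — noisier genes are pulled harder. Three estimators of
the prior are provided, all computed from the converged genes' estimates:

| approach | prior mean | prior variance |
|----------|-----------|----------------|
| ML       | empirical mean | empirical variance (denominator n−1) |
| robust   | median | (1.4826 × MAD)², MAD unscaled |
| mixture  | 5-component normal mixture fitted by EM | — |

The factor 1.4826 = 1/Φ⁻¹(3/4) makes the MAD consistent for a normal
standard deviation. Under the mixture prior the posterior is again a
5-component normal mixture: each component is updated conjugately and its
weight is re-weighted by the component's marginal likelihood
`λᵢ · N(x; μᵢ, τᵢ² + σ²)`. Only `ẽ` is shared across genes; `b`, `c`, `d`
remain purely per-gene.

Point estimates are posterior means; interval estimates are equal-tailed
credible intervals from the `α/2` and `1 − α/2` posterior quantiles
(closed form for normals; bisection of the mixture CDF to `1e-10` on a
bracket spanning all component means ± 10 sd). A highest-density interval
is *not* used.

**EM details.** Soft-assignment E-step, moment-matching M-step; stops when
the observed-data log-likelihood improves by less than `1e-8` or after 1000
iterations; the log-likelihood is non-decreasing by construction and this is
asserted in tests. Component variances are floored at `1e-6 ×` the sample
variance to prevent degenerate spikes; a collapse the floor cannot rescue is
reported as a failure flag (the run's mixture arm becomes missing), not an
exception. Default initialisation for `k = 5`: equal weights, means at the
10/30/50/70/90% sample quantiles, common MAD-based sd. The initialisation
used for the valproic-acid case study (means 6.2, 5, 8, 12, 8; sds 0.3, 0.5,
0.5, 1, 0.3) is exposed as `VPA_EM_INIT` for reproduction runs. `k` is
configurable; 5 is the default (one mid-range component, two tails, two
artefact components). No label-switching resolution is attempted;
components are sorted by mean for display only.

## Gene filtering

Candidate genes must pass two screens computed from the expression matrix:
a one-way ANOVA across concentration groups with unadjusted `p < 0.001`
(multiplicity adjustment is deliberately not applied at this stage), and
biological relevance — some treated concentration's mean log2 fold change
versus control at least `log2(1.5) ≈ 0.585` in magnitude, with no two
concentrations exceeding the threshold in opposite directions. The
fold-change rule uses `≥` at the threshold (ties are measure-zero on real
data) and is computed concentration-wise against control, not as the range
of group means. Genes whose observations are all identical get `p = 1`
(never selected) so whole-matrix runs cannot abort, and per-gene errors
demote the gene with a logged warning.

## Plasmode-style simulation

`run_plasmode` repeats, for a configurable number of runs (default 1000):
evaluate every gene's truth curve on the design, add i.i.d. `N(0, 0.1²)`
noise (6 control + 3×7 treated replicates by default), refit every gene,
re-estimate all three priors from *that run's* direct estimates, and record
the posterior means and credible intervals. Failed fits make all of a
gene's estimates missing in that run; a failed EM makes only the mixture arm
missing for all genes in that run. Genes with missing values in more than
20% of runs (200 of 1000, the default cap) are dropped from evaluation.
One master seed drives per-run, per-gene substreams, so results are
bit-reproducible and adding genes never perturbs existing genes' noise.

Evaluation per gene and method: MSE against the true `ẽ` over that method's
non-missing runs; a four-way category — *low* if both direct and Bayes MSE
are below 0.1, else *better*/*worse* if one MSE beats the other by a factor
of at least 1.1 (ties at the factor count as better/worse), else *similar*;
interval coverage probabilities; and MA-type coordinates
`(log(MSE_direct·MSE_Bayes), log(MSE_Bayes/MSE_direct))` in natural log —
negative ordinate means shrinkage helped. An optional restriction keeps
only genes with true `ẽ < log(1000) ≈ 6.91` (inflection inside the tested
range); the shrinkage itself always uses all genes.

## Synthetic data

`generate_truths` draws per-gene truth parameters: `ẽ` from a single normal
or from a 5-component mixture defaulting to the case-study estimates
(weights 0.570/0.042/0.093/0.002/0.294; means 6.225/5.128/9.755/19.092/7.458;
sds 0.352/0.150/2.643/32.145/1.399) — including the heavy-tail components
that produce the hard, "worse"-category genes; `|b|` uniform on [0.3, 5]
(flat through steep regimes) with configurable sign; effect `d − c` uniform
on [0.585, 3] so genes are relevant by construction; baseline `c` uniform on
[5, 9] log2 units, typical of RMA-normalised microarray intensities.
`generate_expression_matrix` writes the matrix/sample-sheet files the CLI
consumes. What the generator does *not* emulate: probe-level structure,
normalisation artefacts, gene–gene correlation, and heteroscedastic or
non-Gaussian noise — so passing tests demonstrate correctness of the method
under its stated model, not robustness to those violations.

## Problem sizes used in tests and the acceptance script

The package's own validation runs at desk scale: the shrinkage-dominance
experiment uses 200 genes × 100 runs with `ẽ ~ N(6.2, 0.35²)` and
well-identified curves (`b ∈ [1, 3]`, effect ∈ [1, 2]); coverage calibration
uses 1000 runs of a single steep gene (`b = 2.5`, effect 3, EC50 450 μM),
chosen because a 3000-run scan showed the least-squares linearization is
accurate there (empirical coverage 0.951) — flatter genes genuinely
undercover, which is a property of the direct method, not a defect of the
implementation; the slope-enrichment experiment uses two 40-gene arms
(`|b| ∈ [0.3, 0.5]` vs `[2, 4]`) × 40 runs. These sizes reproduce the
qualitative findings (aggregate Bayes MSE below direct MSE under a correctly
specified prior; flat-slope genes enriched among the improved) with
comfortable margins.

## Known limitations

* `σ²` is plugged in as the squared standard error and treated as known;
  its own sampling error is ignored (as in the underlying method).
* The direct t-intervals undercover for flat or boundary-EC50 genes; the
  Bayes credible intervals inherit prior misspecification.
* Only the 4pLL family is implemented; no model selection or averaging, no
  count-data (RNA-seq) likelihoods, and no fully hierarchical joint model —
  prior estimation and per-gene posteriors are a two-step procedure.
* Per-gene shrinkage can *increase* MSE for genes whose true `ẽ` sits far
  in the prior's tails (large-EC50 genes); the gain is an aggregate,
  Stein-type property.
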