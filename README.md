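# ec50shrink

Empirical-Bayes information sharing across genes for EC50 estimation in
high-dimensional concentration–response screening.

## What it does, and for whom

Toxicogenomic screens (microarray or similar) measure expression for
thousands of genes at a few concentrations with few replicates. For each
gene a four-parameter log-logistic (4pLL) curve

    f(x) = c + (d − c) / (1 + exp(b (log x − ẽ))),   ẽ = log(EC50)

is fitted by least squares, and the log-EC50 `ẽ` — the alert concentration —
is the quantity of interest. With ~27 observations per gene the direct
estimate `ẽ̂` is often noisy. `ec50shrink` treats the per-gene estimates as
draws from a cross-gene prior `μ ~ N(μ₀, τ²)` estimated empirically from the
whole ensemble (ML moments, robust median/MAD, or a 5-component normal
mixture fitted by EM) and replaces each estimate by its posterior mean

    E[μ | x] = (τ² x + σ² μ₀) / (τ² + σ²),   σ² = se(ẽ̂)²,

a precision-weighted compromise that pulls noisy estimates toward the
ensemble centre. The package is aimed at biostatisticians running
concentration–response analyses: it includes the gene filter (ANOVA +
fold-change), the per-gene fitter, the three shrinkage variants with
credible intervals, a plasmode-style simulation framework for validating
the approach (MSE, categories, coverage, MA-type plots as tables), and a
synthetic-data generator so everything runs without any external download.

## Worked example

Fit one gene and shrink a 100-gene cohort (all data synthetic, seeded):

```python
import pandas as pd
from ec50shrink import (
    LL4Model, ShrinkageModel, TruthGeneratorConfig,
    fit_ll4, generate_expression_matrix, generate_truths,
)

cfg = TruthGeneratorConfig(n_genes=100, e_tilde_model="normal",
                           mu0=6.2, tau2=0.35**2, b_range=(0.5, 3.0),
                           effect_range=(1.0, 2.0), seed=0)
truths = generate_truths(cfg)
matrix, sheet = generate_expression_matrix(truths, noise_sd=0.1, seed=0)
x = sheet["concentration"].to_numpy()

res = LL4Model(matrix.iloc[0].drop("gene").to_numpy(float), x).fit()
print(res.summary())
```

```
4pLL least-squares fit
  n_obs=27  df=23  converged=True
  SSE=0.11038  resid_var=0.00479913
     param     estimate      std err
         b     -3.78565       0.4231
         c      7.37901    0.0206695
         d      9.13693    0.0685867
   e_tilde      6.17888    0.0309344
```

The fitted `e_tilde` of 6.179 means an EC50 of exp(6.179) ≈ 483 μM (the true
value for this gene is 6.244); the 95% confidence interval from the t
distribution with 23 degrees of freedom is (6.115, 6.243). Now fit all 100
genes and shrink:

```python
fits = pd.DataFrame(
    {"gene": row["gene"],
     "e_tilde": (r := fit_ll4(x, row.drop("gene").to_numpy(float))).params.e_tilde,
     "se_e_tilde": r.se("e_tilde"), "converged": r.converged}
    for _, row in matrix.iterrows()
)
shrunk = ShrinkageModel.from_fit_table(fits).fit(prior="robust")
print(shrunk.summary())
print(shrunk.estimates.head(3).to_string(index=False))
```

```
Empirical-Bayes shrinkage (robust prior), level=0.95
  genes: 100 total, 100 shrunk
  prior: mu0=6.1580  tau2=0.1790
  mean |shrinkage shift|: 0.7906
     gene  e_tilde_direct  se_e_tilde  e_tilde_robust    lower    upper
gene00000        6.178881    0.030934        6.178770 6.118302 6.239239
gene00001        6.220029    0.105919        6.216368 6.014987 6.417750
gene00002        5.975241    0.401009        6.061733 5.491324 6.632142
```

The robust prior centre is 6.158; precisely estimated genes (se ≈ 0.03)
barely move, while the noisy third gene (se ≈ 0.40) is pulled 0.09 log units
toward the prior mean, and its 95% credible interval is markedly narrower
than the direct confidence interval would be.

The same workflow is available from the shell:

```sh
ec50shrink synth --n-genes 100 --seed 0 --out-dir data/
ec50shrink pipeline --matrix data/expression.tsv --samples data/samples.tsv \
    --out-dir results/          # filter -> fit -> shrink (all three priors)
ec50shrink simulate --truths data/truths.tsv --seed 1 --out est.tsv
ec50shrink evaluate --estimates est.tsv --truths data/truths.tsv --out-dir eval/
```

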