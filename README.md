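# hdlmm — high-dimensional linear mixed-effects models

Sparse fixed-effect estimation for clustered omics data by penalized
maximum likelihood, with LASSO and SCAD penalties, a coordinate-descent
solver, and BIC-based selection of the regularization strength.

## The problem

Omics regressions routinely have far more candidate features than samples
(thousands of genes, SNPs or OTUs against a few hundred samples), and the
samples are rarely independent: they come in batches, families,
populations or body sites. Ignoring that grouping inflates false
positives; modelling it with only a handful of clusters rules out
per-cluster fixed effects. The linear mixed-effects model handles both at
once,

    y_i = X_i beta + Z_i b_i + eps_i,        i = 1, ..., g clusters,

with a high-dimensional fixed-effect vector `beta` (length p), a
low-dimensional random-effect vector per cluster `b_i ~ N_q(0, Psi)`, and
noise `eps_i ~ N(0, sigma^2 I)`. The random-effect covariance `Psi` is
parameterized through its lower-triangular Cholesky factor (scalar,
diagonal or unstructured), and the marginal covariance of cluster i is
`V_i = Z_i Psi Z_i' + sigma^2 I`. Estimation minimizes the penalized
negative log-likelihood

    Q_lam(beta, theta, sigma^2) = -l(beta, theta, sigma^2)
                                  + sum_j P_lam(|beta_j|),

where the penalty is either the LASSO, `P_lam(t) = lam * t`, or the SCAD,
which is lam-linear near zero, tapers quadratically, and is flat beyond
`a*lam` (shape `a = 3.7` by default), so large effects are estimated
essentially without shrinkage. Coefficients on columns that carry random
effects (and the intercept) are conventionally left unpenalized.

The solver is cyclic coordinate descent: each `beta_j` is updated by the
exact minimizer of its univariate surrogate (a soft-threshold step for
LASSO; exact piecewise-quadratic minimization of the adaptively rescaled
penalty for SCAD), with an active-set schedule that revisits the full
coordinate set every `D` iterations; each variance parameter is then
updated by bounded scalar minimization of the negative log-likelihood.
A grid of `lam` values is fitted and the final model minimizes

    BIC_lam = -2 l(beta_hat, theta_hat, sigma2_hat) + df_hat * log N,

with `df_hat` the number of nonzero coefficients plus the number of free
covariance parameters. When p > N and `lam` is too small the objective is
unbounded below (an interpolating solution with `sigma^2 -> 0`); such fits
are detected, flagged, and excluded from selection.

The package also ships generators for three synthetic study designs used
to probe the estimator: gene-expression-like Gaussian designs with AR(1)
inter-feature correlation, GWAS-like minor-allele-count designs, and
microbiome designs with network-structured OTU dependence, zero-inflated
counts and a log-ratio transform.

## Worked example

```python
import numpy as np
from hdlmm import HighDimLMM
from hdlmm.simulate import gene_expression_setting, simulate

# 180 samples in 30 clusters, 500 features, 5 true effects, random intercept
sim = simulate(gene_expression_setting(1, seed=42))
model = HighDimLMM.from_clustered_data(sim.data, penalty="scad")
path = model.fit_path(lams=np.arange(10.0, 101.0, 10.0))
res = path.best
print(res.summary())
rep = res.selection_report(sim.beta_true)
print(f"true positives: {rep.n_true_pos}, false positives: {rep.n_false_pos}")
```

prints

```
Penalized Linear Mixed Model Results
======================================================
Penalty:        SCAD (lam=10)
Cov structure:  scalar
N obs:          180    clusters: 30
p fixed:        500    q random: 1
Status:         converged in 5 iterations
log-likelihood: -219.5632
BIC:            470.2842   df: 6
sigma2:         0.4916
Psi (random-effect covariance):
     0.4500
------------------------------------------------------
Nonzero coefficients:
  beta_1    x1            0.9978  (unpenalized)
  beta_2    x2            2.1190  (penalized)
  beta_3    x3            3.9379  (penalized)
  beta_4    x4            3.0528  (penalized)
  beta_5    x5            3.1032  (penalized)

true positives: 5, false positives: 0
```

The generating truth here is `beta = (1, 2, 4, 3, 3)` on the first five
columns (the first being the intercept), `Psi = 0.56` and
`sigma^2 = 0.5`: the BIC-selected SCAD fit recovers the support exactly
and estimates the effects and both variance components close to their
generating values.

## Command line

```
hdlmm simulate --setting ge1 --seed 5 --out ds/            # write a data set
hdlmm fit  --x ds/X.csv --y ds/y.csv --groups ds/groups.csv \
           --z ds/Z.csv --nonpen 0 --penalty scad --lam 10 --out fit/
hdlmm path --x ds/X.csv ... --grid 10:100:10 --out fit/    # BIC selection
hdlmm study --setting gwas --q 3 --penalty scad --reps 5 --seed 7 --out st/
```

`fit`/`path` accept CSV/TSV matrices (header optional); `Z` may be given
as its own file or as a list of X columns. Outputs are a coefficient
table, variance-component estimates, a JSON fit summary, the per-lam path
table and an NDJSON iteration trace.

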