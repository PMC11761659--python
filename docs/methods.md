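# Methods

## Model

Clustered observations follow the linear mixed-effects model
`y_i = X_i beta + Z_i b_i + eps_i` for clusters `i = 1..g`, with
`b_i ~ N_q(0, Psi)` i.i.d. across clusters, `eps_i ~ N(0, sigma^2 I)`
independent of the `b_i`, and `q << p`. Marginally
`y_i ~ N(X_i beta, V_i)` with `V_i = Z_i Psi Z_i' + sigma^2 I`, so the
log-likelihood separates over clusters; all linear algebra is per-cluster
(Cholesky of each `n_i x n_i` block `V_i`), and nothing of size `N x N`
is ever formed. `Psi` is parameterized by the entries `theta` of its
lower-triangular Cholesky factor `L` (`Psi = L L'`), stored column-major,
with diagonal entries of `L` constrained nonnegative for identifiability.
Three structures are supported: scalar (`q* = 1` free parameter),
diagonal (`q* = q`) and unstructured (`q* = q(q+1)/2`).

Estimates minimize `Q_lam = -l + sum_j P_lam(|beta_j|)` over the
penalized coordinates. LASSO: `P_lam(t) = lam t`. SCAD (shape `a > 2`,
default 3.7): defined through its derivative — `lam` on `[0, lam]`,
decaying linearly as `max(0, a lam - t)/(a-1)` on `(lam, a lam]`, zero
beyond — whose antiderivative with `P(0) = 0` is `lam t` on `[0, lam]`,
`(2 a lam t - t^2 - lam^2) / (2(a-1))` on `(lam, a lam]`, and the
constant `lam^2 (a+1)/2` beyond `a lam`. The closed form is verified in
the tests by numerical quadrature of the derivative.

## Coordinate descent

One outer iteration is:

1. **Fixed-effect sweep.** Coordinates are visited in ascending index
   order. For each `j`, the first two derivatives of `-l` in `beta_j`
   are `g = -x_j' V^{-1} r` and `h = x_j' V^{-1} x_j > 0` (with
   `r = y - X beta` the current residual), and the update is the exact
   global minimizer of the surrogate
   `s(d) = g d + h d^2/2 + P~(|beta_j + d|)`:
   - unpenalized: the Newton step `-g/h`;
   - LASSO (`P~ = P`): the soft-threshold step
     `beta_j + d = soft(h beta_j - g, lam)/h`;
   - SCAD: the penalty is *adaptively rescaled*, `P~(|t|) = P(h |t|)`,
     and the minimizer is found by enumerating the stationary point of
     each quadratic piece clipped to its region, the region boundaries
     `±lam/h`, `±a lam/h`, and zero, evaluating `s` at each candidate.
     Ties within 1e-12 prefer the smaller `|beta_j + d|` (sparser
     solution, deterministic output). The enumeration is validated
     against a 1e5-point grid search in the tests — deliberately so,
     since closed forms circulating for this update are not all correct.
   Residual-dependent caches (`V^{-1} r`, `V^{-1} X` columns, the `h_j`)
   are computed once per sweep from the per-cluster factorizations and
   refreshed incrementally after each accepted step.
   With the LASSO the surrogate is the exact restriction of `Q_lam`, so
   every update weakly decreases the objective; with SCAD the rescaled
   surrogate is what decreases, and the original `Q_lam` may
   transiently rise — the tests assert exactly these two statements.

2. **Active-set schedule.** Every `D`-th iteration (default `D = 5`)
   sweeps all `p` coordinates; other iterations sweep only the currently
   nonzero coefficients plus the unpenalized set (which is always
   active). Zeroed coefficients therefore re-enter at every full sweep.

3. **Variance sweep.** Each of the `q* + 1` parameters (theta entries in
   storage order, then `sigma^2`) is updated by bounded Brent
   minimization of `-l` (absolute tolerance 1e-6), with lower bound 0
   for diagonal entries of `L`, a small positive floor for `sigma^2`,
   and a geometrically widened bracket for unconstrained off-diagonal
   entries. The incumbent value is kept whenever the search cannot
   improve on it, so the sweep never moves uphill.

4. **Convergence.** The criterion is a relative objective change below
   `tol` (default 1e-4) together with a maximum absolute parameter
   change below `sqrt(tol)`. If it first holds after an active-set
   sweep, a full sweep is forced; the solver terminates only when the
   criterion holds after a full sweep, or at `max_iter` (default 1000,
   reported with a warning, not an exception).

### Initialization

Unpenalized coefficients start at their least-squares fit; penalized
coefficients start from an ordinary sparse fit — a cyclic soft-threshold
coordinate descent with identity working covariance at the same `lam`
(the approach of the original LASSO-based treatment of this model).
The initial residual variance is then split evenly between the error
(`sigma^2_0 = var(r_0)/2`) and the random effects (diagonal of `L` set to
`sqrt(var(r_0)/2)`, off-diagonals 0). Starting instead from all-zero
penalized coefficients puts `sigma^2_0` near `var(y)`, which collapses
every coordinate curvature `h` and makes the solve bistable: no
coefficient can enter at working values of `lam`, and below them the
solve cascades to interpolation. The ordinary-fit start keeps the
initial scale consistent with the `lam` grid.

### Interpolation divergence

With `p > N` and `lam` small, `Q_lam` is unbounded below: the fit
interpolates and `log det V -> -inf` as `sigma^2 -> 0`. Divergence is
declared when `sigma^2` falls below a floor (default `1e-4 * var(y)`)
and either at least `N` coefficients are nonzero or the conditional
(BLUP) residuals vanish. The latter uses the identity
`r - Z Psi Z' V^{-1} r = sigma^2 V^{-1} r`: with random effects present,
the marginal fit can interpolate with far fewer than `N` nonzero
coefficients (the random intercept absorbs cluster means), so a count
criterion alone misses it. Diverged fits report an infinite objective,
are flagged on the result, and are excluded from BIC selection.

## Selection

`BIC_lam = -2 l + df log N` with `df` = number of nonzero coefficients
(unpenalized ones counted when nonzero) plus `q*`; `sigma^2` is not
counted. The path fit evaluates an explicit `lam` grid, or brackets one
automatically: the upper bound is found by doubling `lam` until all
penalized coefficients are zeroed, the lower bound by halving until the
interpolation flag raises, with a log-spaced grid strictly inside the
bracket. Ties in BIC resolve toward the larger `lam`. Fits whose
penalized block is entirely zero remain eligible — with a narrow working
window the overly sparse solution can genuinely win, and that behavior
is part of what the simulations measure. Selection performance against
a known truth is summarized by the false positive rate
`FPR = #{j : beta_j = 0, beta_hat_j != 0} / #{j : beta_j = 0}`, the
true-positive count, and an all-effects-recovered flag.

## Synthetic data generators

All three designs place the intercept in the first column of `X`, the
random-slope features immediately after (`Z = X[:, :q]`), and the
nonzero generating coefficients at the head of `beta`:
`(1, 2, 4, 3, 3)` when five effects are used, 
`(1, 2, 4, 3, 3, -1, 5, -3, 2, 2)` when ten. Defaults: `Psi = 0.56 I`
(scalar and diagonal structures; the unstructured default adds 0.2
off-diagonal covariance), `sigma^2 = 0.5`. Every generator is driven by
one seeded `numpy` generator; regeneration from the same setting is
bit-identical.

* **Gene expression.** `N` i.i.d. rows with `Cov(x_j, x_j') =
  rho^|j-j'|`, generated by the exact stationary AR(1) recursion.
  Fourteen named settings cover `N/g` of 180/30 and 250/50, `p` of 500
  and 1000, `q` in {1, 3, 5}, `rho` in {0, 0.6}, five or ten effects,
  and the three covariance structures.
* **GWAS.** 250 samples by 1000 columns (intercept plus 999 SNPs) in 10
  populations of 25. Genotypes are minor-allele counts: per-SNP
  frequency `f_j ~ U(0.05, 0.5)`, counts `Binomial(2, f_j)` i.i.d.
  across individuals. Population structure enters through the random
  effects only — this generator is a deliberate simplification that
  preserves the integer design and the clustered-error structure the
  solver faces, not a reimplementation of any population-genetics
  simulator.
* **Microbiome.** 120 samples by 127 OTUs in 10 groups of 12. A latent
  Gaussian copula carries inter-OTU dependence from a named network
  topology (band, cluster, scale-free, Erdos-Renyi, hub, block):
  signed edge weights on the adjacency are diagonally dominated into a
  positive-definite precision matrix, inverted and rescaled to
  correlation form. Marginals are zero-inflated negative binomial
  (zero-inflation `U(0.4, 0.8)` per OTU, log-mean `U(log 5, log 200)`,
  size 0.5) — a synthetic stand-in that reproduces the sparsity and
  right skew of real OTU tables without matching any particular
  dataset's empirical distribution. Zeros receive a pseudo-count of
  0.5, features are `log(c_ij / c_i,ref)` with the last OTU as
  reference, and one additional covariate, constant within each group,
  carries an unpenalized effect of -1 (eleven nonzero effects in
  total). All-zero rows are resampled with bounded retries.

What these generators do *not* emulate: linkage disequilibrium and
kinship among genotypes, empirical OTU abundance distributions,
non-Gaussian or heteroscedastic noise, and crossed or longitudinal
grouping. Passing tests therefore demonstrate correct recovery under
the stated generating laws, not robustness to those features of real
data.

## Numerical choices

* Per-cluster dense Cholesky is the single solve path (`n_i` is small in
  every supported design; cost `O(sum n_i^3)` worst case).
* Group labels are factorized to contiguous codes on ingestion; cluster
  order and within-cluster order do not affect the fit (asserted).
* No internal standardization by default — the simulation parameters are
  defined on the raw scale; an opt-in `standardize` flag rescales
  penalized columns to unit SD and back-transforms estimates.
* The convergence criterion combines objective and parameter movement;
  a fit restarted from its own solution re-converges within one full
  sweep.
* Text serialization uses `%.17g`, which round-trips IEEE doubles
  exactly.

## Study sizes in the acceptance script

The script reruns the simulation studies at reduced size and
replication: the gene-expression analogue at `N = 120, g = 20, p = 200`
with 8 replicates per penalty (the full design uses `N = 180..250,
p = 500..1000` and 100 replicates), the GWAS analogue at `p = 400` with
5 replicates, and the microbiome design at its native `120 x 127` with 6
replicates. `lam` grids: 10..100 step 10 for gene expression; for the
GWAS and microbiome stand-in generators the windows sit lower than with
unit-variance features, and the grids (1..10 step 1 and 2..20 step 2)
were bracketed once with the automatic recipe above — consistent with
the per-design grid calibration the selection protocol itself
prescribes. Reported quantities are Monte-Carlo means/medians over
replicates and are expected to fluctuate at these replication counts.

## Known limitations

* ML (not REML) estimation: variance components carry the usual
  downward finite-sample bias, amplified when many fixed effects are
  selected.
* Coordinate descent reaches a stationary point, not a certified
  global minimum; under SCAD different coordinate orders can reach
  different local minima, and near the edges of the working `lam`
  window small grid shifts can change which basin a fit lands in.
* BIC cannot discriminate against near-interpolating fits that stop
  just above the divergence floor; grids should not probe deep into
  the unstable region (the automatic bracket stays at its edge).
* Gaussian responses only; no crossed random effects; no pathwise warm
  starts across the `lam` grid; no post-selection inference.
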