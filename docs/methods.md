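# Methods

## Model

Each subject i (i = 1..n) contributes a D x T_i matrix X_i.  The
observation model is a lag-K vector autoregression with truncated early
conditionals and zero intercept:

    x_it | past  ~  N( Σ_{k=1..min(t-1,K)} A_ik x_{i,t-k},  Σ_i ),
    x_i1         ~  N(0, Σ_i),

so the likelihood is an exact product of conditional densities: the
first time point has zero mean and time points t <= K use only the lags
that exist.  The lag order K is pre-specified.  Coefficient matrices are
oriented rows = target variable, columns = source variable (in the
effective-connectivity literature these are often called "autocovariance
matrices" although they are regression coefficients).

Priors are independent Dirichlet processes on disjoint parameter blocks
("product of DP mixtures"), so the blocks cluster independently across
subjects:

* **whole-matrix** (`PDPMVAR`): one DP on the stacked (A_1..A_K), one DP
  on Σ;
* **per-lag** (`LagPDPMVAR`): K independent DPs, one per lag matrix,
  plus the Σ-scale DP.  With K = 1 this is exactly the whole-matrix
  model;
* **per-row** (`RowPDPMVAR`): D independent DPs, one per target
  variable, each on the stacked K rows for that target, plus the Σ-scale
  DP.

For independent data x_i ~ N(mu_i, Sigma_i) the analogous family is the
classic joint location-scale DP mixture (`DPMixture`), independent
mean/covariance DPs (`ProductDPMixture`), and one DP per mean coordinate
(`CoordinateProductDPMixture`); the covariance always clusters as one
block.

### Base measures

* Coefficients: independent double-exponential DE(λ) entries,
  represented as the scale mixture a | τ ~ N(0, τ), τ ~ Exp(λ²/2).  The
  full conditional of 1/τ is inverse-Gaussian with mean λ/|a| and shape
  λ²; |a| is floored at 1e-10 when forming that mean.  The Laplace form
  shrinks null coefficients and supports credible-interval feature
  selection.
* Residual covariance: parameter-expanded factor form
  Σ = Γ diag(Ξ) Γ' + diag(Ψ), Γ a D x B loadings matrix with
  standard-normal entries, Gamma(1/2, 1/2) priors on the precisions
  1/ξ_b (so the effective loadings Γ diag(Ξ)^{1/2} have Cauchy-type
  marginals, the heavy-tailed default of parameter-expanded factor
  models), and Gamma(a_σ, b_σ) priors on the precisions 1/ψ_d.  The
  Gamma-on-precision reading is the conjugate one and the one that
  induces the Cauchy marginal; a Gamma on ξ itself is neither.
* Independent-data models: normal bases for mean atoms and
  inverse-Wishart for covariance atoms, with hyperparameters set
  empirically from data moments (base mean = sample mean, diffuse
  diagonal base variance, IW degrees of freedom D + 2 and scale the
  sample covariance).

## Posterior computation

A truncated stick-breaking blocked Gibbs sampler with truncation H
(default 20): weights π_h = v_h Π_{l<h}(1 − v_l) with v_h ~ Beta(1, α)
and v_H = 1.  DP precisions α are fixed constants (default 1); no
hyperprior.  A warning is logged when the top H − 2 clusters hold less
than 99% of the occupancy mass, the sign that H is too small.

One sweep of the whole-matrix sampler:

1. **Coefficient-scale labels.**  Each subject's label is drawn from
   probabilities ∝ π_h × L(X_i | Θ_h, Σ_i), with the likelihood the
   exact product-of-conditionals form and the latent factors integrated
   out.  Because η is redrawn from its full conditional immediately
   afterwards, this is a valid blocked update of (labels, η).
2. **Latent factors.**  η_it ~ N over B dimensions with a posterior
   covariance shared within each covariance cluster.
3. **Coefficient atoms.**  Conditioning on η makes the residual
   covariance diagonal (Ψ), so the rows of each cluster's stacked
   coefficient matrix decouple: each row is one DK-variate
   multivariate-normal draw with prior precision diag(1/τ) and
   data precision Σ_i Z_i'Z_i/ψ_id over the cluster's members.  In the
   per-lag model, subjects mix lag-cluster memberships, so each row is
   drawn jointly across all occupied (lag, cluster) atoms — one
   (#occupied × D)-variate normal per row.  Empty clusters are refreshed
   from the base measure each sweep so new clusters can spawn.
4. **Laplace scales** τ by the inverse-Gaussian conditional.
5. **Sticks** at the coefficient scale from conjugate Beta updates.
6. **Covariance-scale labels** from the η-marginal residual likelihood
   (again blocked with the η redraw inside the factor update).
7. **Factor block** per covariance cluster: η, then loadings rows, then
   1/ξ_b ~ Gamma(1/2 + N/2, 1/2 + Ση²/2), then
   1/ψ_d ~ Gamma(a_σ + N/2, b_σ + RSS_d/2).
8. **Sticks** at the covariance scale.

The derivations all follow from conjugacy of the normal likelihood with
the normal-scale-mixture coefficient prior and the parameter-expanded
factor priors.  All three samplers pass a prior vs
successive-conditional ("getting it right") validation: moments of
coefficients, sticks, loadings and precisions along a chain that
alternates one sweep with regeneration of (η, X) given the parameters
match ancestral prior draws within Monte-Carlo error
(`pdpmvar.geweke_compare`; the packaged check runs at D = 2, K = 2,
n = 3, T = 10, H = 3 with λ = 4 and a_σ = b_σ = 2 — under very diffuse
hyperparameters prior VAR draws are frequently explosive and the chain
mixes too slowly for the comparison to be informative).

### Initialization and burn-in adaptation

Assignments are initialized by k-means on vectorized per-subject ridge
least-squares VAR estimates, with the cluster count chosen by silhouette
score (2–8); covariance labels by k-means on vectorized residual
covariances; coefficients at per-cluster pooled estimates; loadings at
zero.  The per-lag model initializes lag partitions as coarsenings of a
joint partition, because subject-level single-lag blocks are too noisy
to cluster directly.

With hundreds of time points per clustering unit, likelihood ratios
between established atoms are enormous and the blocked kernel
essentially never merges or splits clusters once settled.  During
burn-in only, the samplers therefore run greedy split/merge relocation
passes: merging two clusters is accepted unless the pooled atom loses
more log-likelihood than a BIC-style allowance (p/2 · log N for an atom
with p parameters and N observations), and splitting a cluster (by
2-means on least-squares features) is accepted only when the gain
exceeds the same allowance.  Moves are scored with each subject's
*profile* Gaussian log-likelihood, −T/2 log det of the residual
covariance MLE under the candidate coefficients, because comparisons at
a fixed covariance cannot escape co-adapted modes: near the unit root a
trajectory is effectively low-rank, a coefficient error produces
low-rank residual structure, and the factor covariance absorbs it.
Proposal atoms are ridge-pooled GLS estimates weighted by each subject's
own least-squares residual variances (coefficient precision is
scale-free in the residual variance, so a subject's information content
does not depend on its noise level).  Because the moves stop at the end
of burn-in, the post-burn-in kernel is the exact blocked Gibbs sampler
and retained draws target the exact posterior.

### Label switching and summaries

Draws are never relabeled.  All clustering summaries are
partition-invariant: the adjusted Rand index (reported both averaged
over retained draws and at a point partition), and the posterior
similarity matrix (pairwise co-clustering frequency) with a point
partition from complete-linkage clustering of 1 − similarity cut at 0.5.

### Forecasting

Point forecasts iterate the VAR mean recursion from the last K
observations; the posterior point forecast averages the per-draw mean
path over retained draws using each draw's subject-level coefficients,
so parameter and clustering uncertainty propagate.  Predictive draws add
N(0, Σ) innovations per step and feed them forward.

## Synthetic data

The generator produces the study conditions every test runs under.
Four panel settings share: sparse cluster-atom coefficient matrices
(nonzero positions drawn to hit the sparsity fraction, default 0.75);
residual covariances drawn per cluster from an inverse-Wishart with D
degrees of freedom and scale (D/2)·I — deliberately heavy-tailed (the
mean does not exist), so some realizations have residual condition
numbers above 1e5; coefficient labels independent of covariance labels;
series simulated exactly as the likelihood assumes (x_1 ~ N(0, Σ), no
presample), with a holdout block (default 5 columns) continuing each
series for forecasting evaluation.

* Setting 1: a fixed number of whole-matrix clusters (default 3).
* Setting 2: independent per-lag clusters (default 3 for lag 1, 2 for
  lag 2).
* Setting 3: per-row clusters, the count per row uniform on 2..5.
* Setting 4: as 3, plus subject-level row deviations with standard
  deviation 10% of the nonzero-coefficient spread (applied to nonzero
  positions, so structural zeros stay exact).

Choices the generator owns (configurable defaults): nonzero coefficient
values are signed magnitudes uniform on [0.5, 1.5] × `coef_scale`
(default scale 0.5) — bounded away from zero so that "structural zero"
recovery is a well-posed question; candidate draws are rescaled by a
common factor until every subject's companion spectral radius is at most
0.95, preserving the cluster structure.

The independent-data toy generator draws five mean clusters that differ
only in the first ⌊D/3⌋ coordinates (pairwise center separation ≥ 3
there, identical elsewhere) and five covariance clusters, independent of
the means, from inverse-Wisharts given distinct overall scales
(log-spaced 0.5–4×): without a scale contrast the covariance "clusters"
would not be mutually distinguishable and the covariance partition would
be unidentifiable.

What the simulations do *not* emulate: fMRI-like autocorrelated
measurement noise, non-Gaussian innovations, missing data, or
subject-varying lag order.  Passing tests show the samplers recover the
structures they model under Gaussian innovations at the stated sizes —
not robustness to those violations.  The `difference_and_demean` and
`winsorize` utilities (repeated lag-1 differencing plus demeaning;
clipping at ±4 robust SDs) are generic preprocessing helpers for raw
sensor series, not model components.

## Evaluation metrics

* **Adjusted Rand index**: chance-corrected partition agreement; for
  row/lag-clustered models the label spaces are column-specific, so ARIs
  are computed per column and averaged.
* **Relative L2 error**: ‖estimate − truth‖_F / ‖truth‖_F; subject-level
  errors are averaged per subject (primary) with pooled versions
  available.
* **Selection curves**: for each threshold q on a 99-point grid over
  (0.01, 0.99) a coefficient is called nonzero iff its equal-tailed
  (1 − q) credible interval excludes 0; sensitivity/specificity and
  precision/recall sweeps give ROC and PR curves, areas by the trapezoid
  rule with (0,0) and (1,1) appended to the ROC.
* **Forecast error**: pooled Frobenius ratio per horizon over subjects,
  plus cumulative-horizon versions.
* **Chain diagnostics**: effective sample size by the
  initial-monotone-positive-sequence autocorrelation estimator;
  stationarity by augmented Dickey–Fuller tests at the 5% level
  (constant traces reported as inapplicable).

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `trunc` (H) | 20 | stick-breaking truncation per scale |
| `alpha_theta`, `alpha_sigma` | 1.0 | DP precisions (fixed; larger spawns more clusters) |
| `lambda_de` (λ) | 1.0 | Laplace rate on coefficients; larger = stronger shrinkage |
| `a_sigma`, `b_sigma` | 1.0 | Gamma shape/rate on 1/ψ_d |
| `n_factors` (B) | 5 | residual-covariance factor rank, clamped to ≤ D; results are not very sensitive to it |
| `n_iter`, `n_burn` | 2000 / 500 (CLI: 5000 / 1500) | sweeps and burn-in |
| `burnin_move_every` | 10 | sweeps between burn-in relocation passes |
| `init_clusters` | "silhouette" (iid models: 10) | k-means initialization size |

## Numerical choices

Stability is judged by the companion-matrix spectral radius with a
strict inequality and 1e-10 boundary tolerance.  Assignment draws use
max-subtraction; the last stick absorbs the remaining mass so weights
sum to one exactly.  Latent scales τ are floored at 1e-12; covariance
factorizations floor eigenvalues and idiosyncratic variances at small
positive values.  Runs are bit-for-bit reproducible given
(`random_state`, parameters): all randomness flows through one
`numpy.random.Generator`.

## Problem sizes used by the packaged checks

The test suite and `scripts/acceptance.py` run desk-scale versions of
the study designs: panels of n = 60 subjects with D = 10 outcomes and
T = 150–200 time points (250–500 retained sweeps), the toy example at
n = 250, D = 30, and the sampler validation at n = 3, D = 2, T = 10
with 5000 sweeps.  These sizes were chosen so that each design is a
well-separated but nontrivial recovery problem for the sampler at a few
hundred sweeps.

## Known limitations

* Under the heavy-tailed covariance law, occasional realizations
  contain near-degenerate subjects (trajectories confined to a
  low-dimensional manifold) whose coefficients are unidentified in the
  orthogonal directions; the posterior can legitimately hold such
  subjects in separate coefficient clusters, so partition-recovery ARIs
  vary across generator seeds.
* The blocked kernel mixes poorly over partitions after burn-in (by
  design the relocation moves stop there); posterior uncertainty about
  the partition itself is therefore understated when clusters are
  strongly separated.
* Fixed lag order, zero intercept, no missing data, Gaussian
  innovations; a single covariance-clustering block (no partitioning of
  the covariance parameters).
* DP precisions are fixed, not learned.
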