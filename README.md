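# pdpmvar

Bayesian nonparametric modeling of *multi-subject* multivariate time
series with product-of-Dirichlet-process mixture priors on vector
autoregressions, plus the matching models for independent multivariate
data.

## The problem

Multi-subject studies — resting-state fMRI cohorts, networks of air
quality sensors, panels of patients — produce one multivariate time
series per subject.  Fitting a separate VAR to each subject wastes the
information subjects share; forcing all subjects into one model (or into
clusters that share *every* parameter) overstates it.  Real heterogeneity
is usually partial: two subjects may share their lagged dependence
structure but not their noise covariance, or agree on the dynamics of
some outcome variables and not others.

This package implements *multiscale clustering* for that setting.  Each
subject i follows a VAR(K)

    x_it = Σ_{k=1..min(t-1,K)} A_ik x_{i,t-k} + ε_it,   ε_it ~ N(0, Σ_i),

with x_i1 ~ N(0, Σ_i) and a zero intercept, and independent Dirichlet
process priors are placed on disjoint blocks of (Θ_i, Σ_i), where
Θ_i = (A_i1, ..., A_iK).  Because the DPs are independent, subjects
cluster *differently at each scale*:

| estimator      | coefficient clustering unit        | covariance unit |
|----------------|------------------------------------|-----------------|
| `PDPMVAR`      | the whole stack (A_1, ..., A_K)    | subject         |
| `LagPDPMVAR`   | one lag matrix A_k per lag         | subject         |
| `RowPDPMVAR`   | the stacked K rows of one target d | subject         |

`RowPDPMVAR` is the most flexible variant: clusters of subjects may share
effective connectivity for a subset of target variables only.
`SingleSubjectVAR` is the no-pooling baseline (one parametric Bayesian
VAR per subject).  For independent data x_i ~ N(μ_i, Σ_i) the same idea
gives `DPMixture` (classic joint clustering), `ProductDPMixture`
(independent mean and covariance partitions) and
`CoordinateProductDPMixture` (one DP per mean coordinate).

Posterior computation is a truncated stick-breaking blocked Gibbs
sampler.  Coefficients carry a Laplace (double-exponential) base measure
handled through its normal–exponential scale mixture, so zero entries of
the lag matrices are shrunk and can be selected via credible intervals.
Residual covariances use a parameter-expanded latent factor form
Σ = Γ diag(Ξ) Γ' + diag(Ψ) with B ≪ D factors; conditioning on the
latent factors makes every coefficient-row update a conjugate
multivariate-normal draw.  Samplers follow the scikit-learn estimator
convention (`fit` / `predict` / `get_params`), and every sampler is
validated by a prior vs successive-conditional ("getting it right")
check, exposed as `pdpmvar.geweke_compare`.

## Worked example

Generate a panel whose coefficient rows cluster independently across
subjects (between 2 and 5 clusters per target variable), fit the
row-level product mixture, and score it against the ground truth:

```python
import numpy as np
from pdpmvar import (SimulationDesign, gen_setting, RowPDPMVAR,
                     adjusted_rand_index, relative_l2, forecast_error)
from pdpmvar.sticks import posterior_similarity, similarity_partition

sim = gen_setting(SimulationDesign(setting=3, n=30, D=6, T=150, K=1,
                                   sparsity=0.7, n_sigma_clusters=2, seed=8))
model = RowPDPMVAR(n_lags=1, trunc=12, n_iter=250, n_burn=100,
                   n_factors=3, random_state=0).fit(sim.panel)

row_ari = np.mean([
    adjusted_rand_index(
        similarity_partition(posterior_similarity(model.draws_.c_theta[:, :, d])),
        sim.theta_labels[:, d])
    for d in range(6)])
rel = np.mean([relative_l2(model.coef_mean_[i], sim.theta_true[i])
               for i in range(30)])
per_h, _ = forecast_error(model.predict(horizon=5), sim.holdout)
print(f"mean row-level clustering ARI: {row_ari:.3f}")
print(f"mean coefficient relative L2 error: {rel:.3f}")
print(f"relative forecast error by horizon: {np.round(per_h, 3)}")
```

prints

```
mean row-level clustering ARI: 0.921
mean coefficient relative L2 error: 0.074
relative forecast error by horizon: [0.905 1.043 1.041 1.043 1.072]
```

The ARI of 0.92 says the row-level partitions of the 30 subjects were
recovered almost exactly (1 = identical up to relabeling); the relative
L2 error of 0.07 is the Frobenius distance between the posterior-mean
and true coefficient stacks, divided by the truth's norm.  One-step
forecasts beat the trivial zero forecast (error < 1); at this small,
weakly autocorrelated design the signal decays within a couple of steps,
so longer horizons approach 1, as they should.

## Command line

```bash
pdpmvar simulate --setting 1 --n-subjects 60 --dim 10 --n-time 200 --seed 0 --out sim/
pdpmvar fit --model rgpdpm_var --panel sim/panel.csv --n-lags 2 --seed 0 --out fit/
pdpmvar forecast --draws fit/draws.npz --panel sim/panel.csv --horizon 5 --out fc.csv
pdpmvar evaluate --draws fit/draws.npz --truth sim/truth.npz --out report.json
```

Panels are long-format CSV (`subject_id`, `time_index`, value columns;
time index 0-based and consecutive).  Draw archives are single `.npz`
files holding per-draw subject coefficients, covariances, labels at each
clustering scale, stick proportions and the log-likelihood trace, with a
JSON metadata entry; every run writes a provenance JSON (config + seed +
version).

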