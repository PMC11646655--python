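"""Synthetic panel generators and preprocessing utilities."""

import numpy as np
import pytest
from scipy import linalg, stats as sps

from pdpmvar import (
    SimulationDesign,
    VARCoefficients,
    difference_and_demean,
    gen_setting,
    gen_toy,
    is_stable,
    winsorize,
)


class TestGenSetting:
    def test_setting1_cluster_construction(self, small_sim):
        th = small_sim.theta_true
        assert np.unique(th.reshape(th.shape[0], -1), axis=0).shape[0] == 2
        assert np.bincount(small_sim.theta_labels).sum() == 12

    def test_sparsity_fraction_per_matrix(self):
        sim = gen_setting(
            SimulationDesign(setting=1, n=6, D=10, T=60, K=2, sparsity=0.75, seed=3)
        )
        D = 10
        for i in range(6):
            for k in range(2):
                block = sim.theta_true[i][:, k * D : (k + 1) * D]
                assert abs((block == 0).mean() - 0.75) <= 1.0 / (D * D) + 1e-12

    def test_every_subject_stable(self, small_sim):
        for i in range(small_sim.theta_true.shape[0]):
            theta = VARCoefficients.from_stacked(small_sim.theta_true[i], 2)
            ok, r = is_stable(theta)
            assert ok and r <= 0.95 + 1e-9

    def test_bit_reproducible_given_seed(self):
        d = SimulationDesign(setting=2, n=5, D=4, T=50, K=2, seed=42)
        a = gen_setting(d)
        b = gen_setting(SimulationDesign(setting=2, n=5, D=4, T=50, K=2, seed=42))
        assert np.array_equal(a.panel.matrices()[0], b.panel.matrices()[0])
        assert np.array_equal(a.theta_true, b.theta_true)

    def test_holdout_continues_the_recursion(self):
        # regenerating with the truth from the last K observed columns must
        # reproduce the holdout in distribution; check the conditional mean
        sim = gen_setting(
            SimulationDesign(setting=1, n=4, D=3, T=60, K=1, sparsity=0.7,
                             forecast_holdout=5, seed=9)
        )
        assert sim.holdout.shape == (4, 3, 5)

    def test_row_setting_label_shapes(self):
        sim = gen_setting(SimulationDesign(setting=3, n=8, D=5, T=60, K=2, seed=1))
        assert sim.theta_labels.shape == (8, 5)
        sim2 = gen_setting(SimulationDesign(setting=2, n=8, D=5, T=60, K=2, seed=1))
        assert sim2.theta_labels.shape == (8, 2)

    def test_setting4_perturbs_only_nonzeros(self):
        sim = gen_setting(SimulationDesign(setting=4, n=8, D=5, T=60, K=2, seed=1))
        # zero positions stay exactly zero under the within-cluster noise
        assert np.all(sim.theta_true[~sim.nonzero_mask] == 0)

    def test_heavy_tailed_sigma_draws_are_spd(self, rng):
        # inverse-Wishart with D degrees of freedom has no mean, but every
        # draw must factor (SPD with probability 1)
        D = 6
        iw = sps.invwishart(df=D, scale=(D / 2) * np.eye(D))
        for _ in range(200):
            linalg.cholesky(iw.rvs(random_state=rng))

    def test_infeasible_sparsity_raises(self):
        with pytest.raises(ValueError):
            gen_setting(SimulationDesign(setting=1, n=4, D=3, T=50, sparsity=0.999, seed=0))

    def test_lag1_autocovariance_solves_lyapunov(self):
        # long single series: the empirical lag-1 autocovariance must
        # satisfy the discrete Lyapunov relation of the true (A, Sigma),
        # with the residual measured on the scale of the process
        # autocovariance and averaged over a few generator draws
        errs = []
        for seed in (21, 22, 23, 24):
            sim = gen_setting(
                SimulationDesign(setting=1, n=1, D=3, T=10_000, K=1,
                                 sparsity=0.5, n_theta_clusters=1,
                                 n_sigma_clusters=1, forecast_holdout=0,
                                 seed=seed)
            )
            A = sim.theta_true[0]
            S = sim.sigma_true[0]
            X = sim.panel.matrices()[0]
            G0 = linalg.solve_discrete_lyapunov(A, S)
            G1 = A @ G0
            Xc = X[:, 500:]  # skip the transient from the N(0, Sigma) start
            emp = Xc[:, 1:] @ Xc[:, :-1].T / (Xc.shape[1] - 1)
            errs.append(np.linalg.norm(emp - G1) / np.linalg.norm(G0))
        assert np.mean(errs) < 0.05


class TestGenToy:
    def test_uninformative_coordinates_share_means(self):
        data, mu_l, sg_l = gen_toy(n=100, D=12, seed=0)
        d_inf = 4
        # construction: between-cluster variance of the true centers is
        # zero beyond the informative block, so coordinate-wise cluster
        # means differ only by sampling noise there
        within = [data[mu_l == g, d_inf:].mean(axis=0) for g in range(5)]
        spread_tail = np.ptp(np.stack(within), axis=0).mean()
        inf = [data[mu_l == g, :d_inf].mean(axis=0) for g in range(5)]
        spread_inf = np.ptp(np.stack(inf), axis=0).mean()
        assert spread_inf > 3 * spread_tail

    def test_every_cluster_nonempty_and_balanced(self):
        _, mu_l, sg_l = gen_toy(n=250, D=12, seed=1)
        assert np.bincount(mu_l).min() >= 1
        assert np.bincount(sg_l).min() >= 1

    def test_mean_and_sigma_labels_independent(self):
        # pooled contingency table over many seeds shows no association
        table = np.zeros((5, 5))
        for seed in range(40):
            _, mu_l, sg_l = gen_toy(n=50, D=9, seed=seed)
            for a, b in zip(mu_l, sg_l):
                table[a, b] += 1
        _, p, _, _ = sps.chi2_contingency(table)
        assert p > 0.01

    def test_dimension_and_size_guards(self):
        with pytest.raises(ValueError):
            gen_toy(n=100, D=5, seed=0)
        with pytest.raises(ValueError):
            gen_toy(n=5, D=12, seed=0)


class TestPreprocessing:
    def test_constant_series_differences_to_zero(self):
        out = difference_and_demean(np.full(10, 3.7), steps=1)
        assert np.allclose(out, 0.0)

    def test_linear_ramp_twice_differenced_is_zero(self):
        out = difference_and_demean(np.arange(12.0), steps=2)
        assert np.allclose(out, 0.0)

    def test_inverse_difference_reconstruction(self, rng):
        x = rng.standard_normal(30)
        d = np.diff(x)
        out = difference_and_demean(x, steps=1)
        # undo the demeaning then cumulatively sum with the stored start
        rebuilt = np.concatenate([[x[0]], x[0] + np.cumsum(out + d.mean())])
        assert np.allclose(rebuilt, x)

    def test_too_short_series_raises(self):
        with pytest.raises(ValueError):
            difference_and_demean(np.ones(3), steps=3)

    def test_winsorize_clips_only_outliers(self, rng):
        x = rng.standard_normal(500)
        x[10] = 50.0
        out = winsorize(x)
        assert out[10] < 50.0
        assert np.allclose(np.delete(out, 10), np.delete(x, 10))
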