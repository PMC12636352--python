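import numpy as np
import pytest

from kprob.bvs import (BVSModelSpec, SpikeSlabRegression, compute_delta0,
                       geweke_z, pip_fdr)


class TestDelta0:
    def test_formula(self):
        y = np.array([0, 2, 4, 2.0])        # Var(y) known
        X = np.diag([1.0, 2, 3, 4])
        expected = 0.05 * np.var(y, ddof=1) / np.var(X, axis=0, ddof=1).sum()
        assert compute_delta0(y, X) == pytest.approx(expected)

    def test_scaling_law(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=30)
        X = rng.poisson(1, (30, 4)).astype(float)
        assert compute_delta0(2 * y, X) == pytest.approx(4 * compute_delta0(y, X))

    def test_degenerate_inputs_rejected(self):
        y = np.arange(5.0)
        with pytest.raises(ValueError):
            compute_delta0(y, np.ones((5, 2)))       # zero column variance
        with pytest.raises(ValueError):
            compute_delta0(y, np.eye(5), q=0.0)      # q outside (0,1)


class TestPipFdr:
    def test_two_high_pips(self):
        thr, sel, table = pip_fdr(np.array([0.99, 0.98]), target=0.1)
        assert sel.tolist() == [0, 1]
        assert table["fdr"].iloc[-1] == pytest.approx(0.015)

    def test_third_pip_breaks_threshold(self):
        thr, sel, table = pip_fdr(np.array([0.99, 0.98, 0.5]), target=0.1)
        assert sel.tolist() == [0, 1]       # (0.01+0.02+0.5)/3 > 0.1
        assert table["fdr"].iloc[-1] == pytest.approx(0.53 / 3)

    def test_all_certain(self):
        thr, sel, _ = pip_fdr(np.ones(5), target=0.1)
        assert sel.size == 5

    def test_empty(self):
        _, sel, _ = pip_fdr(np.array([]), target=0.1)
        assert sel.size == 0

    def test_fdr_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        pips = rng.uniform(size=200)
        _, _, table = pip_fdr(pips, 0.1)
        assert (np.diff(table["fdr"]) >= -1e-12).all()

    def test_conservation_identity(self):
        pips = np.array([0.95, 0.9, 0.99, 0.2])
        _, sel, table = pip_fdr(pips, 0.2)
        est_false = (1 - pips[sel]).sum()
        fdr_at_sel = table.loc[table["n_selected"] == sel.size, "fdr"].iloc[0]
        assert est_false == pytest.approx(fdr_at_sel * sel.size)


class TestGeweke:
    def test_constant_trace(self):
        assert geweke_z(np.ones(100)) == 0.0

    def test_linear_ramp_flagged(self):
        assert abs(geweke_z(np.arange(1000.0))) > 1.96

    def test_white_noise_calibration(self):
        rng = np.random.default_rng(4)
        ok = sum(abs(geweke_z(rng.normal(size=500))) <= 1.96
                 for _ in range(100))
        assert ok >= 90


class TestFit:
    def _planted(self, seed=0, n=400, p=60, n_true=4, beta=1.0, sd=0.7):
        rng = np.random.default_rng(seed)
        X = rng.poisson(0.5, (n, p)).astype(float)
        b = np.zeros(p)
        b[:n_true] = beta * np.where(np.arange(n_true) % 2 == 0, 1, -1)
        y = 1.5 + X @ b + rng.normal(0, sd, n)
        return y, X, b

    def test_planted_columns_get_high_pip(self):
        y, X, b = self._planted()
        fit = SpikeSlabRegression(y, X, C=np.ones((y.size, 1))).fit(
            iters=2000, burn_in=500, thin=2, seed=1)
        assert (fit.pip[b != 0] > 0.9).all()
        assert fit.pip[b == 0].max() < 0.5

    def test_effects_are_per_occurrence(self):
        y, X, b = self._planted(sd=0.05)
        fit = SpikeSlabRegression(y, X, C=np.ones((y.size, 1))).fit(
            iters=2000, burn_in=500, thin=2, seed=2)
        assert np.allclose(fit.beta_mean[b != 0], b[b != 0], atol=0.1)

    def test_column_permutation_equivariance(self):
        y, X, _ = self._planted(seed=3, n=150, p=20)
        perm = np.random.default_rng(5).permutation(20)
        f1 = SpikeSlabRegression(y, X, C=np.ones((y.size, 1))).fit(
            iters=3000, burn_in=1000, seed=7)
        f2 = SpikeSlabRegression(y, X[:, perm], C=np.ones((y.size, 1))).fit(
            iters=3000, burn_in=1000, seed=7)
        # same posterior up to MC error, permuted
        assert np.abs(f2.pip - f1.pip[perm]).max() < 0.12

    def test_pure_noise_pip_calibration(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = rng.poisson(0.5, (500, 50)).astype(float)
            y = rng.normal(0, 1, 500)
            fit = SpikeSlabRegression(y, X, C=np.ones((500, 1))).fit(
                iters=1200, burn_in=400, thin=2, seed=seed)
            post_pi = fit.traces["pi"].mean()
            if fit.pip.max() < 0.5 and abs(fit.pip.mean() - post_pi) < 0.05:
                hits += 1
        assert hits >= 9

    def test_predict_paths(self):
        y, X, b = self._planted(sd=0.01)
        model = SpikeSlabRegression(y, X, C=np.ones((y.size, 1)))
        fit = model.fit(iters=1500, burn_in=500, seed=3)
        yhat = fit.predict(C_new=np.ones((y.size, 1)), X_new=X)
        assert np.corrcoef(yhat, y)[0, 1] > 0.99
        # zero X -> covariate-only prediction; duplicated rows identical
        base = fit.predict(C_new=np.ones((2, 1)), X_new=np.zeros((2, X.shape[1])))
        assert base[0] == base[1] == pytest.approx(fit.alpha_mean[0])
        with pytest.raises(ValueError, match="columns"):
            fit.predict(C_new=np.ones((2, 1)), X_new=np.zeros((2, 3)))

    def test_reproducible_under_seed(self):
        y, X, _ = self._planted(seed=8, n=100, p=15)
        f1 = SpikeSlabRegression(y, X, C=np.ones((100, 1))).fit(
            iters=500, burn_in=100, seed=42)
        f2 = SpikeSlabRegression(y, X, C=np.ones((100, 1))).fit(
            iters=500, burn_in=100, seed=42)
        assert np.array_equal(f1.pip, f2.pip)
        assert np.array_equal(f1.beta_mean, f2.beta_mean)

    def test_nonfinite_response_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            SpikeSlabRegression(np.array([1.0, np.inf]), np.ones((2, 1)))

    def test_prior_sampling_without_likelihood(self):
        # no informative rows: pi trace should match its Beta prior moments
        rng = np.random.default_rng(0)
        y = np.zeros(2)
        X = np.zeros((2, 3))
        spec = BVSModelSpec(delta0_sq=0.01, a_pi=2.0, b_pi=6.0,
                            fix_deltae_sq=1.0, fix_delta1_sq=1.0)
        fit = SpikeSlabRegression(y, X, spec=spec, center_y=False).fit(
            iters=22000, burn_in=2000, thin=1, seed=0)
        assert fit.traces["pi"].mean() == pytest.approx(0.25, abs=0.02)

    def test_summary_mentions_key_quantities(self):
        y, X, _ = self._planted(seed=9, n=80, p=10)
        fit = SpikeSlabRegression(y, X, C=np.ones((80, 1))).fit(
            iters=400, burn_in=100, seed=1)
        s = fit.summary()
        assert "n predictors:" in s and "Geweke" in s and "pip" in s
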