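"""VAR fitting and pairwise-conditional Granger causality."""

import numpy as np
import pytest

from exercog.granger import (
    GcResult,
    StationarityError,
    causal_density,
    edges_table,
    fit_var,
    pairwise_conditional_gc,
)


def simulate_bivariate(n, coupling=0.5, seed=0):
    """x drives y with one lag; unit-variance innovations."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    e = rng.standard_normal(n)
    y = np.zeros(n)
    y[1:] = coupling * x[:-1] + e[1:]
    return np.column_stack([x, y])


class TestFitVar:
    def test_order_recovery_var2(self):
        coefs = np.zeros((2, 3, 3))
        coefs[0] = [[0.4, 0.2, 0.0], [0.0, 0.3, 0.0], [0.0, 0.0, 0.3]]
        coefs[1] = [[0.0, 0.0, 0.25], [0.2, 0.0, 0.0], [0.0, 0.25, 0.0]]
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = np.zeros((3200, 3))
            innov = rng.standard_normal((3200, 3))
            for t in range(2, 3200):
                x[t] = coefs[0] @ x[t - 1] + coefs[1] @ x[t - 2] + innov[t]
            m = fit_var(x[200:], max_order=6)
            hits += m.order == 2
        assert hits >= 9

    def test_white_noise_coefficients_near_zero(self, rng):
        x = rng.standard_normal((3000, 3))
        m = fit_var(x, max_order=4, order=1)
        assert np.abs(m.coefs).max() < 0.1

    def test_coefficient_recovery_within_3se(self, rng):
        a = np.array([[0.5, 0.2], [0.0, 0.4]])
        x = np.zeros((5000, 2))
        innov = rng.standard_normal((5000, 2))
        for t in range(1, 5000):
            x[t] = a @ x[t - 1] + innov[t]
        m = fit_var(x[100:], max_order=5)
        se = 1.0 / np.sqrt(len(x) - 100)  # unit innovations, stationary scale ~1
        assert np.abs(m.coefs[0] - a).max() < 5 * se

    def test_unstable_model_rejected(self, rng):
        # mildly explosive bivariate system: fitted root outside unit circle
        x = np.zeros((400, 2))
        x[0] = [0.1, 0.1]
        innov = 0.01 * rng.standard_normal((400, 2))
        for t in range(1, 400):
            x[t] = 1.03 * x[t - 1] + innov[t]
        with pytest.raises(StationarityError):
            fit_var(x, max_order=3)

    def test_whiteness_recorded(self, rng):
        m = fit_var(rng.standard_normal((1500, 2)), max_order=3, order=1)
        assert m.whiteness_p.shape == (2,)
        assert np.all((m.whiteness_p >= 0) & (m.whiteness_p <= 1))


class TestPairwiseGc:
    def test_closed_form_population_value(self):
        # y_t = 0.5 x_{t-1} + e: GC(x->y) -> ln(1.25), GC(y->x) -> 0
        data = simulate_bivariate(100_000, seed=1)
        r = pairwise_conditional_gc(data, order=1)
        assert r.gc[0, 1] == pytest.approx(np.log(1.25), abs=0.01)
        assert r.gc[1, 0] == pytest.approx(0.0, abs=0.005)
        assert r.significant[0, 1]
        # the null direction carries no systematic effect: tiny magnitude
        assert r.gc[1, 0] < 0.01 * r.gc[0, 1]

    def test_consistency_with_sample_size(self):
        errs = []
        for n in (500, 3000, 10000):
            vals = [
                pairwise_conditional_gc(simulate_bivariate(n, seed=s), order=1).gc[0, 1]
                for s in range(8)
            ]
            errs.append(abs(np.mean(vals) - np.log(1.25)))
        assert errs[2] < 0.02
        assert errs[2] <= errs[0] + 0.01

    def test_matches_statsmodels_bivariate_ftest(self):
        from statsmodels.tsa.stattools import grangercausalitytests

        data = simulate_bivariate(2000, seed=3)
        r = pairwise_conditional_gc(data, order=1)
        ref = grangercausalitytests(data[:, [1, 0]], maxlag=[1], verbose=False)
        f_ref = ref[1][0]["ssr_ftest"][0]
        assert r.fstat[0, 1] == pytest.approx(f_ref, rel=5e-3)

    def test_relabeling_equivariance(self, rng):
        x = rng.standard_normal((1200, 4))
        for t in range(1, 1200):
            x[t, 1] += 0.4 * x[t - 1, 0]
        perm = [2, 0, 3, 1]
        r1 = pairwise_conditional_gc(x, order=1)
        r2 = pairwise_conditional_gc(x[:, perm], order=1)
        for i, pi in enumerate(perm):
            for j, pj in enumerate(perm):
                if i != j:
                    assert r2.gc[i, j] == pytest.approx(r1.gc[pi, pj], rel=1e-9)

    def test_planted_edges_dominate(self):
        from exercog.simulate import default_ground_truth

        truth = default_ground_truth(coupling=0.25)
        ratios = []
        for seed in range(6):
            x = truth.simulate(3000, np.random.default_rng(seed))
            r = pairwise_conditional_gc(x, order=1)
            off = ~np.eye(9, dtype=bool)
            planted = [r.gc[s, t] for s, t in truth.edge_set]
            null_vals = [
                r.gc[i, j] for i in range(9) for j in range(9)
                if i != j and (i, j) not in truth.edge_set
            ]
            ratios.append(np.median(planted) > np.quantile(null_vals, 0.95))
        assert all(ratios)

    def test_sign_and_scale_invariance_hbr_pathway(self, rng):
        """The HbR series (scaled, sign-flipped HbO) yields identical GC."""
        x = simulate_bivariate(3000, seed=5)
        r1 = pairwise_conditional_gc(x, order=1)
        r2 = pairwise_conditional_gc(-0.35 * x, order=1)
        np.testing.assert_allclose(r1.gc, r2.gc, rtol=1e-8)


class TestCausalDensity:
    def _result(self, signif):
        n = 3
        gc = np.full((n, n), 0.1)
        np.fill_diagonal(gc, np.nan)
        sig = np.zeros((n, n), dtype=bool)
        off = ~np.eye(n, dtype=bool)
        sig[off] = signif
        return GcResult(
            gc=gc, fstat=gc, p=gc, p_fdr=gc, significant=sig, order=1,
            rois=[f"r{i}" for i in range(n)], model=None,
        )

    def test_no_edges_zero_density(self):
        r = self._result(np.zeros(6, dtype=bool))
        assert causal_density(r)["unweighted"] == 0.0

    def test_all_edges_full_density(self):
        r = self._result(np.ones(6, dtype=bool))
        d = causal_density(r)
        assert d["unweighted"] == 1.0
        assert d["weighted"] == pytest.approx(0.1)

    def test_null_fdr_calibration(self):
        """On independent series the FDR keeps expected density <= q."""
        densities = []
        for seed in range(60):
            x = np.random.default_rng(seed).standard_normal((800, 5))
            r = pairwise_conditional_gc(x, order=1, fdr_q=0.05)
            densities.append(r.causal_density_unweighted)
        mean_density = np.mean(densities)
        assert mean_density <= 0.05 + 0.02  # q plus Monte-Carlo margin


def test_edges_table_layout(rng):
    x = rng.standard_normal((800, 3))
    r = pairwise_conditional_gc(x, order=1)
    tab = edges_table(r)
    assert len(tab) == 6
    assert set(tab.columns) >= {"from_roi", "to_roi", "gc", "f_stat", "p",
                                "p_fdr", "significant"}
    assert (tab["p_fdr"] >= tab["p"] - 1e-12).all()
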