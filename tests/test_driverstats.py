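import numpy as np
import pandas as pd
import pytest

from canopymort import driverstats
from canopymort.driverstats import (
    BinnedSeries, InsufficientDataError, beta_fit, bin_weighted,
    height_groups, mediation, mixed_fit, piecewise_fit, rf_importance_pdp,
    wls_fit,
)


def series_from(x, y, w=None):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.ones_like(x) if w is None else np.asarray(w, float)
    return BinnedSeries(edges=np.array([]), centers=x, mean=y,
                        q1=y, q3=y, weight=w)


class TestBinWeighted:
    def test_single_bin_weighted_mean(self):
        s = bin_weighted([1.0, 1.5], [0.0, 4.0], [1.0, 3.0], 2.0)
        assert len(s) == 1
        assert s.mean[0] == pytest.approx(3.0)

    def test_constant_rate_every_bin(self):
        x = np.linspace(0, 9.9, 50)
        s = bin_weighted(x, np.full(50, 2.5), np.ones(50), 2.0)
        np.testing.assert_allclose(s.mean, 2.5)

    def test_bin_count_on_half_open_range(self):
        x = np.arange(0, 10, 0.5)  # [0, 10)
        s = bin_weighted(x, np.ones_like(x), np.ones_like(x), 2.0)
        assert len(s) == 5

    def test_quartiles_ordered(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 500)
        s = bin_weighted(x, rng.uniform(0, 5, 500), np.ones(500), 1.0)
        assert (s.q1 <= s.q3).all()

    def test_empty_input_empty_series(self):
        s = bin_weighted([], [], [], 1.0)
        assert len(s) == 0


class TestWlsFit:
    def test_exact_line_recovered(self):
        x = np.arange(10.0)
        fit = wls_fit(series_from(x, 2 * x + 1, np.arange(1, 11.0)))
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_weight_two_equals_duplicated_point(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.1, 1.2, 1.9, 3.3])
        a = wls_fit(series_from(x, y, np.array([1, 1, 2, 1.0])))
        xb = np.array([0.0, 1.0, 2.0, 2.0, 3.0])
        yb = np.array([0.1, 1.2, 1.9, 1.9, 3.3])
        b = wls_fit(series_from(xb, yb))
        assert a.slope == pytest.approx(b.slope)
        assert a.intercept == pytest.approx(b.intercept)

    def test_small_negative_slope_recovered(self):
        # slope on the scale of the CCTH-mortality relationship
        rng = np.random.default_rng(4)
        x = np.linspace(0, 100, 50)
        y = -0.017 * x + 1.5 + rng.normal(0, 0.05, 50)
        fit = wls_fit(series_from(x, y))
        assert abs(fit.slope - (-0.017)) < 2 * fit.stderr
        assert fit.p_value < 0.001

    def test_too_few_bins_rejected(self):
        with pytest.raises(InsufficientDataError):
            wls_fit(series_from([1, 2], [1, 2]))


def piecewise_truth(x, b1=14.0, b2=39.0, s=(-0.3, 0.25, -0.2), c=8.0):
    return (c + s[0] * np.minimum(x, b1)
            + s[1] * np.clip(x - b1, 0, b2 - b1)
            + s[2] * np.maximum(x - b2, 0))


class TestPiecewiseFit:
    def test_exact_line_selects_zero_breaks(self):
        x = np.arange(5, 60, 2.0)
        fit = piecewise_fit(series_from(x, 0.5 * x + 1))
        assert fit.n_breakpoints == 0
        assert fit.r_squared == pytest.approx(1.0)

    def test_two_break_shape_recovered(self):
        rng = np.random.default_rng(11)
        x = np.arange(5, 61, 2.0)
        y = piecewise_truth(x) + rng.normal(0, 0.05, len(x))
        fit = piecewise_fit(series_from(x, y, np.full(len(x), 30.0)))
        assert fit.n_breakpoints == 2
        s1, s2, s3 = fit.slopes
        assert s1 < 0 < s2 and s3 < 0
        assert abs(fit.breakpoints[0] - 14) <= 4.0  # within 2 bin widths
        assert abs(fit.breakpoints[1] - 39) <= 4.0

    def test_matches_brute_force_enumeration(self):
        # independent oracle: enumerate every breakpoint pair directly
        rng = np.random.default_rng(21)
        x = np.arange(18.0)
        y = piecewise_truth(x, 5.0, 12.0) + rng.normal(0, 0.1, len(x))
        w = rng.uniform(1, 5, len(x))
        fit = piecewise_fit(series_from(x, y, w))

        def sse_for(breaks):
            cols = [np.ones_like(x), x] + \
                [np.clip(x - b, 0, None) for b in breaks]
            X = np.column_stack(cols)
            sw = np.sqrt(w)
            beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
            return float(np.sum(w * (y - X @ beta) ** 2)), X.shape[1]

        best_bic, best_breaks = np.inf, None
        n = len(x)
        candidates = [()]
        candidates += [(x[i],) for i in range(2, n - 3)]
        candidates += [(x[i], x[j]) for i in range(2, n - 3)
                       for j in range(i + 3, n - 3)]
        for breaks in candidates:
            sse, k = sse_for(breaks)
            bic = n * np.log(sse / n) + k * np.log(n)
            if bic < best_bic:
                best_bic, best_breaks = bic, breaks
        assert fit.breakpoints == tuple(best_breaks)
        assert fit.bic == pytest.approx(best_bic)

    def test_zero_breaks_equals_wls(self):
        rng = np.random.default_rng(5)
        x = np.arange(12.0)
        y = 0.3 * x + rng.normal(0, 0.2, 12)
        w = rng.uniform(1, 4, 12)
        s = series_from(x, y, w)
        pw = piecewise_fit(s, max_breaks=0)
        ls = wls_fit(s)
        assert pw.slopes[0] == pytest.approx(ls.slope, abs=1e-9)
        assert pw.intercept == pytest.approx(ls.intercept, abs=1e-9)
        assert pw.r_squared == pytest.approx(ls.r_squared)

    def test_short_series_falls_back_with_warning(self):
        x = np.arange(4.0)
        with pytest.warns(UserWarning, match="too few bins"):
            fit = piecewise_fit(series_from(x, 2 * x))
        assert fit.n_breakpoints == 0


class TestBetaFit:
    def test_mean_only_model_intercept(self):
        y = np.full(200, 0.2)
        y = driverstats.smithson_verkuilen(y)  # no-op inside (0,1), kept
        fit = beta_fit(y, np.zeros(200))
        assert fit.coef[0] == pytest.approx(np.log(0.2 / 0.8), abs=0.02)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(8)
        n = 500
        x = rng.uniform(0, 10, n)
        b0, b1, phi = -1.0, 0.15, 30.0
        mu = 1 / (1 + np.exp(-(b0 + b1 * x)))
        y = rng.beta(mu * phi, (1 - mu) * phi)
        fit = beta_fit(y, x)
        assert abs(fit.coef[1] - b1) < 2.5 * fit.stderr[1]
        assert fit.pvalues[1] < 0.001

    def test_unit_weight_fit_matches_statsmodels_betamodel(self):
        # independent oracle: statsmodels' beta regression on the same data
        import statsmodels.api as sm
        from statsmodels.othermod.betareg import BetaModel

        rng = np.random.default_rng(9)
        n = 300
        x = rng.uniform(0, 5, n)
        mu = 1 / (1 + np.exp(-(-0.5 + 0.3 * x)))
        y = rng.beta(mu * 20, (1 - mu) * 20)
        ours = beta_fit(y, x)
        ref = BetaModel(y, sm.add_constant(x)).fit(disp=0)
        np.testing.assert_allclose(ours.coef, ref.params[:2], atol=5e-3)

    def test_slope_sign_agrees_with_wls(self):
        rng = np.random.default_rng(10)
        x = np.linspace(0, 50, 60)
        rate = np.clip(0.3 - 0.004 * x + rng.normal(0, 0.02, 60), 0.01, 0.95)
        bf = beta_fit(rate, x)
        lf = wls_fit(series_from(x, rate))
        assert np.sign(bf.coef[1]) == np.sign(lf.slope) == -1


class TestMixedFit:
    def _simulate(self, group_sd, seed, n_per=40):
        rng = np.random.default_rng(seed)
        groups = np.repeat(["low", "mid", "tall"], n_per)
        offsets = {g: rng.normal(0, group_sd) for g in ("low", "mid", "tall")}
        x = rng.uniform(0, 50, 3 * n_per)
        y = 2.0 - 0.03 * x + np.array([offsets[g] for g in groups]) \
            + rng.normal(0, 0.3, 3 * n_per)
        return y, x, groups

    def test_null_simulation_rarely_rejects(self):
        rejections = 0
        n_sims = 100
        for s in range(n_sims):
            y, x, g = self._simulate(0.0, seed=s)
            fit = mixed_fit(y, x, g)
            rejections += fit.lrt_p < 0.05
        assert rejections <= 0.10 * n_sims

    def test_large_group_offsets_detected(self):
        y, x, g = self._simulate(2.0, seed=3, n_per=60)
        fit = mixed_fit(y, x, g)
        assert fit.lrt_p < 0.05
        assert fit.fixed_slope < 0  # CCTH slope keeps its sign

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            mixed_fit(np.ones(10), np.arange(10), np.repeat("g", 10))

    def test_height_groups_terciles(self):
        g = height_groups(np.arange(90.0))
        counts = pd.Series(g).value_counts()
        assert set(counts.index) == {"low", "mid", "tall"}
        assert counts.max() - counts.min() <= 1


class TestMediation:
    def _simulate(self, a, cprime, seed, n=200):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 50, n)
        m = a * x + rng.normal(0, 1.0, n)
        y = 0.3 * m + cprime * x + rng.normal(0, 1.0, n)
        return x, m, y

    def test_additivity_identity(self):
        x, m, y = self._simulate(0.5, 0.2, seed=1)
        res = mediation(x, m, y, n_boot=50, seed=0)
        assert res.total == pytest.approx(res.direct + res.indirect, abs=1e-8)

    def test_full_mediation_small_direct_effect(self):
        x, m, y = self._simulate(0.5, 0.0, seed=2, n=400)
        res = mediation(x, m, y, n_boot=199, seed=1)
        assert abs(res.direct) < 0.02
        assert res.ci_low > 0  # strong indirect path detected

    def test_null_indirect_ci_covers_zero(self):
        covered = 0
        n_sims = 40
        for s in range(n_sims):
            x, m, y = self._simulate(0.0, 0.3, seed=100 + s, n=120)
            res = mediation(x, m, y, n_boot=199, seed=s)
            covered += res.ci_low <= 0 <= res.ci_high
        assert covered >= 0.85 * n_sims

    def test_small_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            mediation(np.arange(10), np.arange(10), np.arange(10))


class TestRandomForest:
    def _table(self, seed, n=250, signal="ccth"):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame({
            "height": rng.uniform(5, 60, n),
            "ccth": rng.uniform(0, 80, n),
            "elevation": rng.uniform(700, 2600, n),
            "twi": rng.uniform(2, 12, n),
            "radiation": rng.uniform(2000, 4000, n),
        })
        y = -0.04 * X[signal] + rng.normal(0, 0.3, n)
        return X, y

    def test_signal_feature_ranks_first(self):
        firsts = 0
        for s in range(8):
            X, y = self._table(seed=s)
            res = rf_importance_pdp(X, y, n_estimators=100, seed=s)
            firsts += res.importance["feature"].iloc[0] == "ccth"
        assert firsts >= 7

    def test_noise_feature_importance_near_zero(self):
        X, y = self._table(seed=1)
        res = rf_importance_pdp(X, y, n_estimators=100, seed=1)
        imp = res.importance.set_index("feature")["pct_inc_mse"]
        assert imp["ccth"] > 10 * max(imp["twi"], 1e-9) or imp["twi"] < 5.0

    def test_pdp_of_monotone_truth_is_monotone(self):
        X, y = self._table(seed=2, n=400)
        res = rf_importance_pdp(X, y, n_estimators=150, seed=2)
        grid, vals = res.pdp["ccth"]
        diffs = np.diff(vals)
        assert (diffs < 0).sum() >= len(diffs) - 1  # allow one inversion

    def test_structure_features_add_explained_variance(self):
        X, y = self._table(seed=3, n=300)
        res = rf_importance_pdp(X, y, n_estimators=100, seed=3)
        assert res.r2_full >= res.r2_environment_only

    def test_constant_outcome_warns(self):
        X, _ = self._table(seed=4, n=60)
        with pytest.warns(UserWarning, match="constant outcome"):
            rf_importance_pdp(X, np.ones(60), n_estimators=20, seed=0)
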