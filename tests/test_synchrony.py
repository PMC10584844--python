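"""Pre-whitening and lagged cross-correlation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dyadsync.series import DyadRecord, ResidualSeries
from dyadsync.synchrony import (arima_prewhiten, compute_synchrony,
                                cross_correlation_profile, detrend_poly,
                                lagged_pearson, prewhiten)


def res(values, source="ibi"):
    return ResidualSeries(np.asarray(values, float), source=source)


class TestDetrend:
    def test_exact_quadratic_removed(self):
        t = np.arange(100, dtype=float)
        y = 3 + 2 * t + 0.5 * t ** 2
        assert np.abs(detrend_poly(y)).max() < 1e-8

    def test_matches_normal_equations_oracle(self, rng):
        y = rng.standard_normal(200)
        t = np.arange(200, dtype=float)
        X = np.column_stack([np.ones_like(t), t, t ** 2])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        oracle = y - X @ beta
        np.testing.assert_allclose(detrend_poly(y), oracle, atol=1e-10)

    def test_sinusoid_variance_mostly_retained(self):
        t = np.arange(300, dtype=float)
        y = np.sin(2 * np.pi * t / 20)
        r = detrend_poly(y)
        assert np.var(r) > 0.95 * np.var(y)


class TestArima:
    def test_constant_input_degenerate(self):
        r = arima_prewhiten(np.full(100, 5.0))
        assert r.report["degenerate"]
        np.testing.assert_array_equal(r.values, 0.0)
        assert r.n == 99

    def test_parameter_recovery_on_self_simulated_series(self):
        phi, theta = 0.5, 0.3
        rng = np.random.default_rng(7)
        n = 5000
        eps = rng.standard_normal(n + 1)
        w = np.empty(n)
        w[0] = eps[1]
        for t in range(1, n):
            w[t] = phi * w[t - 1] + eps[t + 1] + theta * eps[t]
        y = np.cumsum(w)        # integrate so ARIMA(1,1,1) is exact
        r = arima_prewhiten(y, order=(1, 1, 1))
        assert r.report["converged"]
        assert r.report["phi"] == pytest.approx(phi, abs=0.05)
        assert r.report["theta"] == pytest.approx(theta, abs=0.05)
        assert r.n == n - 1

    def test_residuals_white_after_prewhitening_ar1(self):
        rng = np.random.default_rng(8)
        n = 2000
        y = np.empty(n)
        y[0] = rng.standard_normal()
        for t in range(1, n):
            y[t] = 0.7 * y[t - 1] + rng.standard_normal()
        r = prewhiten(y)
        v = r.values - r.values.mean()
        rho1 = (v[1:] @ v[:-1]) / (v @ v)
        assert abs(rho1) < 2 / np.sqrt(r.n)


class TestCrossCorrelation:
    def test_identical_series_r0_is_one(self, rng):
        x = rng.standard_normal(100)
        p = cross_correlation_profile(res(x), res(x))
        assert p.r_at(0) == pytest.approx(1.0)

    def test_mother_leads_shows_at_positive_lag(self, rng):
        m = rng.standard_normal(200)
        child = np.roll(m, 2)          # child[t] = mother[t-2]
        child[:2] = rng.standard_normal(2)
        p = cross_correlation_profile(res(m), res(child))
        assert p.r_at(+2) > 0.95
        assert p.r_at(0) < p.r_at(+2)

    def test_matches_per_lag_brute_force_pearson(self, rng):
        from scipy.stats import pearsonr
        a = rng.standard_normal(12)
        b = rng.standard_normal(12)
        p = cross_correlation_profile(res(a), res(b))
        for lag in p.lags:
            if lag >= 0:
                x, y = a[: 12 - lag], b[lag:]
            else:
                x, y = a[-lag:], b[: 12 + lag]
            assert p.r_at(int(lag)) == pytest.approx(pearsonr(x, y)[0],
                                                     abs=1e-12)

    def test_zero_variance_overlap_is_invalid(self):
        p = cross_correlation_profile(res(np.zeros(50)),
                                      res(np.arange(50.0)))
        assert np.isnan(p.r).all()

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_bounds_and_swap_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal(40)
        b = rng.standard_normal(40)
        p = cross_correlation_profile(res(a), res(b))
        q = cross_correlation_profile(res(b), res(a))
        assert np.all(np.abs(p.r[np.isfinite(p.r)]) <= 1 + 1e-12)
        np.testing.assert_allclose(p.r, q.r[::-1], atol=1e-12)
        np.testing.assert_array_equal(p.n_overlap,
                                      p.n_overlap[0] + np.abs(p.lags[0])
                                      - np.abs(p.lags))


class TestPipelineComposition:
    def test_injected_lag_recovered(self, coupled_dyad):
        rec, truth, cfg = coupled_dyad
        p = compute_synchrony(rec, "ibi")
        assert p.argmax_lag() == cfg.coupling_lag_s == -2
        assert p.r_at(-2) > 0.1

    def test_null_dyad_small_correlations(self, null_dyad):
        rec, _, _ = null_dyad
        p = compute_synchrony(rec, "ibi")
        assert np.nanmax(np.abs(p.r)) < 0.3

    def test_prewhitening_controls_false_positives(self):
        """Independent but strongly autocorrelated pairs: raw lag-0
        correlation exceeds the nominal false-positive rate, the
        pre-whitened one does not."""
        rng = np.random.default_rng(9)
        n, reps = 270, 120
        crit = 1.96 / np.sqrt(n)
        raw_fp = white_fp = 0
        for _ in range(reps):
            pair = []
            for _ in range(2):
                y = np.empty(n)
                y[0] = rng.standard_normal()
                for t in range(1, n):
                    y[t] = 0.95 * y[t - 1] + 0.3 * rng.standard_normal()
                pair.append(y)
            raw_r, _ = lagged_pearson(pair[0], pair[1], 0)
            raw_fp += abs(raw_r) > crit
            w = [prewhiten(y).values for y in pair]
            white_r, _ = lagged_pearson(w[0], w[1], 0)
            white_fp += abs(white_r) > 1.96 / np.sqrt(len(w[0]))
        assert raw_fp / reps > 0.15          # raw is badly anticonservative
        assert white_fp / reps <= 0.10       # whitened near nominal 5%

    def test_golden_profile_regression(self, coupled_dyad):
        """End-to-end profile on one fixed dyad, frozen from an
        independently composed run of the stage primitives."""
        rec, _, _ = coupled_dyad
        p = compute_synchrony(rec, "ibi")
        # independent composition: epoch means -> numpy polyfit ->
        # statsmodels ARIMA innovations -> scipy pearson per lag
        from scipy.stats import pearsonr
        from statsmodels.tsa.arima.model import ARIMA
        from dyadsync.ibi import ibi_epoch_series

        def whiten(vals):
            t = np.arange(vals.size)
            resid = vals - np.polyval(np.polyfit(t, vals, 2), t)
            fit = ARIMA(resid, order=(1, 1, 1), trend="n").fit()
            return np.asarray(fit.resid)[1:]

        ms = ibi_epoch_series(rec.mother_rpeaks)
        cs = ibi_epoch_series(rec.child_rpeaks)
        both = np.flatnonzero(ms.valid & cs.valid)
        assert np.all(np.diff(both) == 1)      # contiguous span here
        wm = whiten(ms.values[both])
        wc = whiten(cs.values[both])
        for lag in p.lags:
            k = int(lag)
            if k >= 0:
                x, y = wm[: wm.size - k], wc[k:]
            else:
                x, y = wm[-k:], wc[: wc.size + k]
            assert p.r_at(k) == pytest.approx(pearsonr(x, y)[0], abs=1e-6)
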