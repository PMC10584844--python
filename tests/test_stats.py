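"""Cohort-level statistics: paired tests, FDR, mixed models, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dyadsync.stats import (across_dyad_correlations, compare_lag_signs,
                            condition_lmm, fdr_adjust, paired_t)


def bh_oracle(p):
    """Brute-force Benjamini-Hochberg step-up: adjusted p_(i) =
    min_{j>=i} ( m * p_(j) / j ), capped at 1."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    adj_sorted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        adj_sorted[rank - 1] = running
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestPairedT:
    def test_identical_vectors_degenerate_zero(self):
        r = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0 and r.p == 1.0 and r.degenerate

    def test_hand_computed_example(self):
        # diffs (0.2, 0.2, 0.3): mean .2333, sd .05774 -> t = 7.000
        r = paired_t([0.2, 0.3, 0.4], [0.0, 0.1, 0.1])
        assert r.t == pytest.approx(7.0, abs=1e-10)
        assert r.df == 2

    def test_matches_textbook_formula(self, rng):
        x = rng.standard_normal(25)
        y = rng.standard_normal(25)
        r = paired_t(x, y)
        d = x - y
        t = d.mean() / (d.std(ddof=1) / np.sqrt(25))
        from scipy.stats import ttest_rel
        assert r.t == pytest.approx(t, abs=1e-10)
        assert r.p == pytest.approx(ttest_rel(x, y).pvalue, abs=1e-10)
        assert r.d == pytest.approx(d.mean() / d.std(ddof=1), abs=1e-12)

    def test_incomplete_pairs_dropped_listwise(self):
        x = [0.1, 0.2, np.nan, 0.4]
        y = [0.0, 0.1, 0.2, 0.2]
        r = paired_t(x, y)
        assert r.n == 3

    def test_constant_nonzero_diff_flagged_without_p(self):
        r = paired_t([1.0, 2.0, 3.0], [0.5, 1.5, 2.5])
        assert r.degenerate and r.p is None


class TestFDR:
    def test_hand_stepped_example(self):
        np.testing.assert_allclose(fdr_adjust([0.005, 0.02, 0.03]),
                                   [0.015, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.42]), [0.42])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_matches_step_up_oracle(self, pvals):
        np.testing.assert_allclose(fdr_adjust(pvals), bh_oracle(pvals),
                                   atol=1e-12)

    def test_monotone_in_rank(self, rng):
        p = rng.random(15)
        adj = fdr_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestLagSigns:
    def test_identical_profiles_all_zero_t(self):
        from dyadsync.series import SynchronyProfile
        lags = np.arange(-3, 4)
        profiles = [SynchronyProfile(lags=lags, r=np.full(7, 0.1),
                                     n_overlap=np.full(7, 200))
                    for _ in range(5)]
        results = compare_lag_signs(profiles)
        assert all(r.t == 0 and r.degenerate for r in results)

    def test_detects_negative_lag_asymmetry(self, rng):
        from dyadsync.series import SynchronyProfile
        lags = np.arange(-3, 4)
        profiles = []
        for _ in range(30):
            r = rng.normal(0, 0.05, 7)
            r[lags == -2] += 0.2
            profiles.append(SynchronyProfile(lags=lags, r=r,
                                             n_overlap=np.full(7, 200)))
        results = compare_lag_signs(profiles)
        by_label = {r.label: r for r in results}
        assert by_label["lag -2 vs +2"].p_adj < 0.05
        assert by_label["lag -2 vs +2"].t > 0


class TestConditionLMM:
    def test_balanced_two_condition_equals_paired_t_squared(self, rng):
        rows = []
        b = rng.normal(0, 0.05, 15)
        x, y = [], []
        for i in range(15):
            va = b[i] + rng.normal(0, 0.04)
            vb = 0.06 + b[i] + rng.normal(0, 0.04)
            x.append(vb)
            y.append(va)
            rows += [{"r": va, "condition": "A", "dyad_id": f"d{i}"},
                     {"r": vb, "condition": "B", "dyad_id": f"d{i}"}]
        res = condition_lmm(pd.DataFrame(rows))
        t = paired_t(x, y).t
        assert res.F == pytest.approx(t ** 2, rel=0.01)
        assert res.df_den == pytest.approx(14, abs=0.5)

    def test_identical_values_give_zero_effect(self):
        rows = [{"r": 0.1, "condition": c, "dyad_id": f"d{i}"}
                for i in range(5) for c in ["A", "B"]]
        res = condition_lmm(pd.DataFrame(rows))
        assert res.var_fixed == pytest.approx(0.0, abs=1e-15)
        assert res.R2 == pytest.approx(0.0, abs=1e-12)

    def test_condition_effect_detected_with_contrasts(self, rng):
        rows = []
        effects = {"Rest": 0.0, "Single": 0.0, "La1": 0.1, "La2": 0.1}
        for i in range(20):
            b = rng.normal(0, 0.03)
            for c, e in effects.items():
                rows.append({"r": e + b + rng.normal(0, 0.05),
                             "condition": c, "dyad_id": f"d{i}"})
        res = condition_lmm(pd.DataFrame(rows))
        assert res.p < 0.01
        assert 0 < res.R2 < 1
        sig = res.contrasts.set_index("contrast")["p_adj"]
        assert sig["Rest - La1"] < 0.05
        assert sig["Single - La1"] < 0.05
        assert len(res.contrasts) == 6

    def test_type_one_error_calibrated(self):
        """Null condition effect: F-test rejects at ~nominal alpha."""
        rng = np.random.default_rng(99)
        rejections = 0
        reps = 300
        for _ in range(reps):
            rows = []
            for i in range(12):
                b = rng.normal(0, 0.05)
                for c in ["Rest", "Single", "La1", "La2"]:
                    rows.append({"r": b + rng.normal(0, 0.05),
                                 "condition": c, "dyad_id": f"d{i}"})
            res = condition_lmm(pd.DataFrame(rows), fdr_contrasts=False)
            rejections += res.p < 0.05
        assert rejections / reps <= 0.07

    def test_unbalanced_data_accepted(self, rng):
        rows = []
        for i in range(10):
            b = rng.normal(0, 0.05)
            for c in ["A", "B", "C"]:
                if c == "C" and i > 5:
                    continue
                rows.append({"r": b + rng.normal(0, 0.05),
                             "condition": c, "dyad_id": f"d{i}"})
        res = condition_lmm(pd.DataFrame(rows))
        assert np.isfinite(res.F)


class TestCorrelations:
    def test_self_correlation_is_one(self, rng):
        t = pd.DataFrame({"a": rng.standard_normal(10)})
        r, p = across_dyad_correlations(t)
        assert r.loc["a", "a"] == pytest.approx(1.0)

    def test_matches_formula_oracle(self):
        a = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        b = np.array([2.0, 1.0, 3.0, 5.0, 4.0])
        r, p = across_dyad_correlations(pd.DataFrame({"a": a, "b": b}))
        num = ((a - a.mean()) * (b - b.mean())).sum()
        den = np.sqrt(((a - a.mean()) ** 2).sum() *
                      ((b - b.mean()) ** 2).sum())
        assert r.loc["a", "b"] == pytest.approx(num / den, abs=1e-12)

    def test_pairwise_complete_deletion(self, rng):
        t = pd.DataFrame({"a": rng.standard_normal(12),
                          "b": rng.standard_normal(12)})
        t.loc[0, "a"] = np.nan
        r, p = across_dyad_correlations(t)
        assert np.isfinite(r.loc["a", "b"])

    def test_zero_variance_cell_missing(self, rng):
        t = pd.DataFrame({"a": np.ones(8), "b": rng.standard_normal(8)})
        r, p = across_dyad_correlations(t)
        assert np.isnan(r.loc["a", "b"])
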