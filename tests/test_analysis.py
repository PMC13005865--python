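import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import hepaflux as hf
from hepaflux.analysis import summarise
from hepaflux.errors import DataValidationError


def ts(times, values, unit="mmol/l"):
    return hf.TimeSeries(tuple(times), tuple(values), unit)


class TestIauc:
    def test_constant_series_has_zero_increment(self):
        s = ts([-60, 0, 60, 120, 180], [4.0] * 5)
        assert hf.iauc(s, (0, 180), 0.0).value == 0.0
        assert hf.iauc(s, (-60, 120), -60.0).value == 0.0

    def test_linear_ramp_closed_form(self):
        # v = v0 + m t with baseline at t=0: integral m T^2 / 2
        t = np.arange(0.0, 181.0, 20.0)
        s = ts(t, 3.0 + 0.01 * t)
        assert hf.iauc(s, (0, 180), 0.0).value == pytest.approx(0.01 * 180**2 / 2)
        assert hf.iauc(s, (0, 180), 0.0).value == pytest.approx(162.0)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(-10.0, 10.0), min_size=4, max_size=12))
    def test_additive_over_abutting_windows(self, values):
        n = len(values)
        t = np.linspace(0.0, 180.0, n)
        t[np.argmin(np.abs(t - 60.0))] = 60.0  # keep 60 on the grid
        if len(np.unique(t)) < n:
            return
        s = ts(np.sort(t), values)
        whole = hf.iauc(s, (0, 180), 0.0).value
        parts = hf.iauc(s, (0, 60), 0.0).value + hf.iauc(s, (60, 180), 0.0).value
        assert whole == pytest.approx(parts, abs=1e-9)

    def test_window_outside_support_rejected(self):
        with pytest.raises(DataValidationError):
            hf.iauc(ts([0, 60], [1, 2]), (0, 180), 0.0)

    def test_unit_carries_minutes(self):
        m = hf.iauc(ts([0, 60], [1.0, 2.0]), (0, 60), 0.0)
        assert m.unit == "mmol/l x min"


class TestPeakNadir:
    def test_monotone_series(self):
        s = ts([0, 30, 60, 90], [1, 2, 3, 4])
        peak, peak_t, nadir, nadir_t = hf.peak_nadir(s)
        assert (peak, peak_t, nadir, nadir_t) == (4, 90, 1, 0)

    def test_fasting_draw_excluded_from_search(self):
        # global max sits at T-60 but the reported peak is the post-dose one
        s = ts([-60, 0, 60, 120], [9.0, 5.0, 6.5, 6.0])
        peak, peak_t, _, _ = hf.peak_nadir(s)
        assert (peak, peak_t) == (6.5, 60)

    def test_tie_goes_to_earliest_time(self):
        s = ts([0, 60, 90, 120], [1.0, 7.0, 7.0, 2.0])
        _, peak_t, _, _ = hf.peak_nadir(s)
        assert peak_t == 60

    def test_everything_excluded_rejected(self):
        with pytest.raises(DataValidationError):
            hf.peak_nadir(ts([-60, -30], [1, 2]), exclude_before=0.0)


class TestTwoSampleT:
    def test_identical_groups(self):
        r = hf.two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t_statistic == 0.0
        assert r.p_value == 1.0

    def test_textbook_example(self):
        r = hf.two_sample_t([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert r.t_statistic == pytest.approx(-1.0)
        assert r.p_value == pytest.approx(0.3466, abs=2e-4)

    def test_ci_excludes_zero_iff_significant(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.normal(0, 1, 6)
            b = rng.normal(rng.uniform(0, 2), 1, 8)
            r = hf.two_sample_t(a, b)
            excludes = r.ci95[0] > 0 or r.ci95[1] < 0
            assert excludes == (r.p_value < 0.05)

    def test_matches_definition_oracle_on_random_samples(self):
        """Pooled-variance t from first principles, 100 random pairs."""
        rng = np.random.default_rng(12345)
        for _ in range(100):
            a = rng.normal(0, 2, rng.integers(2, 9))
            b = rng.normal(0.5, 1, rng.integers(2, 9))
            r = hf.two_sample_t(a, b)
            na, nb = len(a), len(b)
            sp2 = (((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1))
                   / (na + nb - 2))
            t_ref = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
            p_ref = 2 * stats.t.sf(abs(t_ref), na + nb - 2)
            assert abs(r.t_statistic - t_ref) < 1e-10
            assert abs(r.p_value - p_ref) < 1e-10

    def test_small_groups_rejected(self):
        with pytest.raises(DataValidationError):
            hf.two_sample_t([1.0], [1.0, 2.0])

    def test_welch_variant(self):
        r = hf.two_sample_t([1, 2, 3, 4], [10, 20, 30, 40, 50], welch=True)
        ref = stats.ttest_ind([1, 2, 3, 4], [10, 20, 30, 40, 50], equal_var=False)
        assert r.p_value == pytest.approx(ref.pvalue)


class TestClustering:
    def test_well_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        high = rng.normal([30, 30], 1.0, size=(6, 2))
        low = rng.normal([10, 10], 1.0, size=(4, 2))
        X = np.vstack([high, low])
        res = hf.cluster_subgroups(X, k=2)
        assert res.labels == tuple([1] * 6 + [2] * 4)
        assert res.silhouette > 0.5

    def test_label_one_has_higher_plasma_iauc(self):
        X = np.array([[1.0, 5.0], [1.2, 5.2], [9.0, 1.0], [9.1, 1.1]])
        res = hf.cluster_subgroups(X, k=2)
        assert res.labels == (2, 2, 1, 1)

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (5, 2)), rng.normal(8, 1, (5, 2))])
        res = hf.cluster_subgroups(X, k=2)
        perm = rng.permutation(10)
        res_p = hf.cluster_subgroups(X[perm], k=2)
        assert tuple(np.array(res.labels)[perm]) == res_p.labels

    def test_k1_single_cluster_silhouette_undefined(self):
        res = hf.cluster_subgroups(np.random.default_rng(0).normal(size=(5, 2)), k=1)
        assert res.labels == (1,) * 5
        assert res.silhouette is None

    def test_more_clusters_than_subjects_rejected(self):
        with pytest.raises(DataValidationError):
            hf.cluster_subgroups(np.zeros((1, 2)), k=2)


def test_summarise_sem_definition():
    values = [3.0, 5.0, 4.0, 8.0, 6.0]
    s = summarise(values)
    assert s["sem"] == pytest.approx(np.std(values, ddof=1) / np.sqrt(5))
    assert s["ci95_low"] < s["mean"] < s["ci95_high"]
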