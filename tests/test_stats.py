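import numpy as np
import pandas as pd
import pytest

from eegdays.stats import (
    StatReport,
    StatResult,
    cluster_band_tests,
    dichotomize,
    exclude_imbalanced_subjects,
    permutation_test,
    rating_regression,
    tendency_commonality,
    ttest_unpaired,
)


class TestDichotomize:
    def test_rating_four_positive(self):
        out = dichotomize(np.array([4]))
        assert out.binary[0] == 1

    def test_rating_three_excluded(self):
        out = dichotomize(np.array([3]))
        assert out.binary[0] == 0
        assert out.n_excluded == 1

    def test_rating_one_negative(self):
        out = dichotomize(np.array([1]))
        assert out.binary[0] == -1

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dichotomize(np.array([0, 4]))

    def test_full_vector(self):
        out = dichotomize(np.array([1, 2, 3, 4, 5]))
        assert list(out.binary) == [-1, -1, 0, 1, 1]


class TestExcludeImbalanced:
    def test_spec_fixture_with_clear_outlier(self):
        # oracle: counts {50,55,60,58,5}: mean 45.6, sd(ddof=1) 22.9489...,
        # threshold 22.651; only the 5 falls below
        counts = {"a": 50, "b": 55, "c": 60, "d": 58, "e": 5}
        arr = np.array(list(counts.values()), dtype=float)
        thr = arr.mean() - arr.std(ddof=1)
        assert (arr < thr).sum() == 1
        kept = exclude_imbalanced_subjects(counts)
        assert kept == {"a", "b", "c", "d"}

    def test_all_equal_none_excluded(self):
        kept = exclude_imbalanced_subjects({"a": 10, "b": 10, "c": 10})
        assert kept == {"a", "b", "c"}

    def test_near_threshold_fixture(self):
        # oracle: {10,10,10,9}: mean 9.75, sd(ddof=1) = 0.5, threshold 9.25;
        # 9 < 9.25 so that subject is excluded (verified independently)
        arr = np.array([10, 10, 10, 9], dtype=float)
        assert arr.mean() == 9.75
        assert arr.std(ddof=1) == pytest.approx(0.5)
        kept = exclude_imbalanced_subjects({"a": 10, "b": 10, "c": 10, "d": 9})
        assert kept == {"a", "b", "c"}

    def test_all_excluded_is_error(self):
        # impossible by construction (threshold below max), so force via n<3
        with pytest.raises(ValueError):
            exclude_imbalanced_subjects({"a": 1, "b": 2})


class TestTTest:
    def test_identical_samples(self):
        t, p = ttest_unpaired(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_textbook_oracle(self):
        # hand-computed pooled-variance formula for {1,2,3} vs {4,5,6}:
        # means 2, 5; s_p^2 = 1; t = -3 / sqrt(1 * (1/3 + 1/3)) = -3.6742346...
        a, b = np.array([1.0, 2, 3]), np.array([4.0, 5, 6])
        sp2 = (a.var(ddof=1) + b.var(ddof=1)) / 2
        t_oracle = (a.mean() - b.mean()) / np.sqrt(sp2 * (2 / 3))
        t, p = ttest_unpaired(a, b)
        assert t == pytest.approx(t_oracle, abs=1e-12)
        assert t == pytest.approx(-3.674234614174767, abs=1e-12)
        from scipy import stats as ss

        assert p == pytest.approx(2 * ss.t.sf(abs(t_oracle), 4), abs=1e-12)

    def test_location_invariance(self):
        a, b = np.array([1.0, 2, 3, 4]), np.array([2.0, 4, 4, 5])
        t1, p1 = ttest_unpaired(a, b)
        t2, p2 = ttest_unpaired(a + 100, b + 100)
        assert t1 == pytest.approx(t2, abs=1e-10)
        assert p1 == pytest.approx(p2, abs=1e-10)

    def test_zero_variance_equal_means(self):
        t, p = ttest_unpaired(np.array([2.0, 2.0]), np.array([2.0, 2.0]))
        assert (t, p) == (0.0, 1.0)

    def test_zero_variance_unequal_means(self):
        with pytest.raises(FloatingPointError):
            ttest_unpaired(np.array([2.0, 2.0]), np.array([3.0, 3.0]))

    def test_group_size_validation(self):
        with pytest.raises(ValueError):
            ttest_unpaired(np.array([1.0]), np.array([1.0, 2.0]))


class TestPermutationTest:
    def test_identical_values_p_one(self):
        v = np.ones(20)
        lab = np.zeros(20, dtype=bool)
        lab[:10] = True
        assert permutation_test(v, lab, n_perm=500, seed=0) == 1.0

    def test_strong_separation_extreme_p(self):
        rng = np.random.default_rng(0)
        n_perm = 2000
        v = np.concatenate([rng.normal(0, 1, 12), rng.normal(5, 1, 12)])
        lab = np.zeros(24, dtype=bool)
        lab[:12] = True
        p = permutation_test(v, lab, n_perm=n_perm, seed=1)
        assert p <= 3.0 / (n_perm + 1)

    def test_relabel_invariance(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=24)
        lab = np.zeros(24, dtype=bool)
        lab[:10] = True
        p1 = permutation_test(v, lab, n_perm=1000, seed=3)
        p2 = permutation_test(v, ~lab, n_perm=1000, seed=3)
        assert p1 == p2

    def test_deterministic(self):
        rng = np.random.default_rng(6)
        v = rng.normal(size=24)
        lab = rng.uniform(size=24) < 0.5
        lab[:2] = True
        lab[-2:] = False
        p1 = permutation_test(v, lab, n_perm=1000, seed=9)
        p2 = permutation_test(v, lab, n_perm=1000, seed=9)
        assert p1 == p2

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            permutation_test(np.arange(10.0), np.ones(10, dtype=bool), n_perm=500, seed=0)

    def test_add_one_bounds(self):
        rng = np.random.default_rng(7)
        for seed in range(5):
            v = rng.normal(size=20)
            lab = np.zeros(20, dtype=bool)
            lab[:10] = True
            p = permutation_test(v, lab, n_perm=500, seed=seed)
            assert 1.0 / 501 <= p <= 1.0

    def test_parametric_agreement_gaussian(self):
        # permutation and Student p agree for healthy Gaussian samples
        rng = np.random.default_rng(8)
        diffs = []
        for _ in range(30):
            a = rng.normal(0, 1, 20)
            b = rng.normal(0.3, 1, 20)
            _, p_param = ttest_unpaired(a, b)
            v = np.concatenate([a, b])
            lab = np.zeros(40, dtype=bool)
            lab[:20] = True
            p_perm = permutation_test(v, lab, n_perm=2000, seed=0)
            diffs.append(abs(p_param - p_perm))
        assert np.mean(diffs) < 0.02


class TestRatingRegression:
    def test_perfect_line(self):
        r, p, slope, intercept = rating_regression(
            np.array([1, 2, 3, 4, 5]), np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        )
        assert r == pytest.approx(1.0)
        assert p < 1e-6
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0)

    def test_closed_form_oracle(self):
        # Pearson r from the covariance formula on a fixed 10-point fixture
        x = np.array([1, 2, 3, 4, 5, 1, 2, 3, 4, 5], dtype=float)
        y = np.array([0.3, 0.1, 0.5, 0.9, 1.1, 0.2, 0.4, 0.4, 0.8, 1.3])
        r_oracle = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        r, _, _, _ = rating_regression(x, y)
        assert r == pytest.approx(r_oracle, abs=1e-12)

    def test_null_monte_carlo(self):
        rng = np.random.default_rng(9)
        small = 0
        n_rep = 40
        for _ in range(n_rep):
            x = rng.integers(1, 6, size=1000).astype(float)
            y = rng.normal(size=1000)
            r, _, _, _ = rating_regression(x, y)
            if abs(r) < 0.1:
                small += 1
        assert small >= int(0.95 * n_rep)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            rating_regression(np.array([3, 3, 3, 3]), np.array([1.0, 2.0, 3.0, 4.0]))


def _result(cluster, band, dim, p_perm, direction):
    return StatResult(
        cluster=cluster,
        band=band,
        dimension=dim,
        mean_pos=0.0,
        mean_neg=0.1,
        t=1.0,
        p_param=p_perm,
        p_perm=p_perm,
        n_pos=10,
        n_neg=10,
        direction=direction,
    )


class TestTendencyCommonality:
    def _reports(self, sig_subjects, directions, cluster="c00:central midline", band="beta"):
        reports = {}
        for i in range(10):
            s = f"S{i}"
            rep = StatReport(subject_id=s, scope="cross_day")
            if s in sig_subjects:
                rep.results.append(
                    _result(cluster, band, "valence", 0.01, directions[s])
                )
            else:
                rep.results.append(_result(cluster, band, "valence", 0.5, "negative"))
            reports[s] = rep
        return reports

    def test_four_of_ten_same_direction(self):
        sig = {f"S{i}" for i in range(4)}
        reports = self._reports(sig, {s: "negative" for s in sig})
        groups = {"central midline": {f"S{i}": "c00:central midline" for i in range(10)}}
        table = tendency_commonality(reports, groups, n_subjects=10)
        row = table.iloc[0]
        assert row["pct_significant"] == 40.0
        assert row["pct_same_tendency"] == 40.0
        assert row["label"] == "negative"

    def test_four_significant_three_share_direction(self):
        sig = {f"S{i}" for i in range(4)}
        dirs = {"S0": "negative", "S1": "negative", "S2": "negative", "S3": "positive"}
        reports = self._reports(sig, dirs)
        groups = {"frontal central": {f"S{i}": "c00:central midline" for i in range(10)}}
        table = tendency_commonality(reports, groups, n_subjects=10)
        row = table.iloc[0]
        assert row["pct_significant"] == 40.0
        assert row["pct_same_tendency"] == 30.0

    def test_single_subject_suppressed(self):
        sig = {"S0"}
        reports = self._reports(sig, {"S0": "negative"})
        groups = {"g": {f"S{i}": "c00:central midline" for i in range(10)}}
        table = tendency_commonality(reports, groups, n_subjects=10)
        assert len(table) == 0


class TestClusterBandTests:
    def _table(self, rng, effect=0.0):
        rows = []
        for trial in range(40):
            rating = int(rng.integers(1, 6))
            val = rng.normal() + (effect if rating > 3 else 0.0)
            rows.append(
                {
                    "cluster": "c0",
                    "band": "beta",
                    "trial": trial,
                    "trial_mean": val,
                    "valence": rating,
                    "arousal": int(rng.integers(1, 6)),
                }
            )
        return pd.DataFrame(rows)

    def test_midpoint_trials_excluded(self, rng):
        table = self._table(np.random.default_rng(0))
        rep = cluster_band_tests(table, "S0", n_perm=200, seed=0)
        res = [r for r in rep.results if r.dimension == "valence"][0]
        n3 = int((table["valence"] == 3).sum())
        assert res.n_pos + res.n_neg == 40 - n3

    def test_strong_effect_detected(self):
        table = self._table(np.random.default_rng(1), effect=3.0)
        rep = cluster_band_tests(table, "S0", n_perm=2000, seed=0)
        res = [r for r in rep.results if r.dimension == "valence"][0]
        assert res.p_perm < 0.05
        assert res.direction == "negative"  # positive state has higher power

    def test_report_roundtrip_frame(self):
        table = self._table(np.random.default_rng(2))
        rep = cluster_band_tests(table, "S0", n_perm=200, seed=0)
        df = rep.to_frame()
        assert {"cluster", "band", "dimension", "p_param", "p_perm", "q_bh"} <= set(df.columns)
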