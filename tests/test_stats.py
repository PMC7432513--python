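"""Statistical battery: Levene gate, t-tests, Cohen's d, AUC, kappa."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from movemetrics.core import MovementMatrix
from movemetrics.errors import ValidationError
from movemetrics.joints import ANALYSIS_JOINTS
from movemetrics.stats import (
    ObserverCounts,
    classify_auc,
    classify_d,
    cohens_d,
    cohens_kappa,
    compare_groups,
    contingency_table,
    levene_test,
    observer_kappa,
    roc_auc,
    two_sample_t,
    two_sample_t_from_stats,
)

from conftest import brute_force_auc


def hand_levene(x, y):
    """Independent oracle: one-way ANOVA on absolute deviations from the
    group means, coded directly from the definition."""
    zx = np.abs(np.asarray(x) - np.mean(x))
    zy = np.abs(np.asarray(y) - np.mean(y))
    z = np.concatenate([zx, zy])
    n1, n2, n = len(zx), len(zy), len(z)
    ssb = n1 * (zx.mean() - z.mean()) ** 2 + n2 * (zy.mean() - z.mean()) ** 2
    ssw = ((zx - zx.mean()) ** 2).sum() + ((zy - zy.mean()) ** 2).sum()
    return (ssb / 1) / (ssw / (n - 2))


class TestLevene:
    def test_identical_samples_give_zero(self):
        F, p = levene_test([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert F == 0.0 and p == 1.0

    def test_matches_hand_computed_anova_on_deviations(self):
        x, y = [1.0, 2, 3, 4], [1.0, 1, 1, 9]
        F, p = levene_test(x, y)
        assert F == pytest.approx(hand_levene(x, y), rel=1e-12)
        assert 0 < p <= 1

    def test_location_invariance(self, rng):
        x, y = rng.normal(0, 1, 20), rng.normal(0, 3, 25)
        F1, _ = levene_test(x, y)
        F2, _ = levene_test(x + 100.0, y)
        assert F1 == pytest.approx(F2, rel=1e-9)

    def test_degenerate_constant_samples(self):
        assert levene_test([2.0, 2, 2], [5.0, 5, 5]) == (0.0, 1.0)


class TestTwoSampleT:
    def test_paper_summary_row_pooled(self):
        # squirm-behaviour summaries: 8.50 (4.71) n=32 vs 5.27 (4.65) n=33
        t, df, p = two_sample_t_from_stats(8.50, 4.71, 32, 5.27, 4.65, 33, "pooled")
        assert df == 63
        assert t == pytest.approx(2.77, abs=0.02)
        assert p < 0.01

    def test_identical_samples_give_zero(self):
        x = [1.0, 2, 3, 4, 5]
        t, df, p = two_sample_t(x, x, "pooled")
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_welch_df_matches_hand_formula(self):
        x, y = np.array([1.0, 2, 3]), np.array([10.0, 20, 30, 40])
        _, df, _ = two_sample_t(x, y, "welch")
        a = x.var(ddof=1) / 3
        b = y.var(ddof=1) / 4
        expected = (a + b) ** 2 / (a**2 / 2 + b**2 / 3)
        assert df == pytest.approx(expected, rel=1e-12)

    def test_summary_equals_raw(self, rng):
        x, y = rng.normal(0, 1, 15), rng.normal(0.5, 2, 18)
        for rule in ("pooled", "welch"):
            t_raw, df_raw, p_raw = two_sample_t(x, y, rule)
            t_s, df_s, p_s = two_sample_t_from_stats(
                x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y), rule
            )
            assert t_raw == pytest.approx(t_s, abs=1e-9)
            assert df_raw == pytest.approx(df_s, abs=1e-9)
            assert p_raw == pytest.approx(p_s, abs=1e-9)

    def test_sign_convention(self):
        t, _, _ = two_sample_t([10.0, 11, 12], [1.0, 2, 3], "pooled")
        assert t > 0

    def test_auto_gates_on_levene(self, rng):
        x = rng.normal(0, 1, 40)
        y = rng.normal(0, 8, 40)  # wildly unequal variances -> Welch
        t_auto, df_auto, _ = two_sample_t(x, y, "auto")
        t_w, df_w, _ = two_sample_t(x, y, "welch")
        assert (t_auto, df_auto) == (t_w, df_w)
        y2 = rng.normal(0.5, 1, 40)  # homogeneous -> pooled integer df
        _, df2, _ = two_sample_t(x, y2, "auto")
        assert df2 == 78

    def test_zero_variance_unequal_means_signals_infinity(self):
        t, _, p = two_sample_t([1.0, 1, 1], [2.0, 2, 2], "pooled")
        assert np.isinf(t) and t < 0 and p == 0.0


class TestCohensD:
    def test_squirm_group_contrast(self):
        d = cohens_d(8.50, 4.71, 5.27, 4.65, 32, 33, weighting="df_weighted")
        assert round(d, 2) == 0.69

    def test_medication_contrast_equal_weighting(self):
        d = cohens_d(8.92, 4.88, 16.52, 12.54, weighting="equal")
        assert round(d, 2) == 0.80

    def test_identical_summaries_give_zero(self):
        assert cohens_d(3.0, 1.2, 3.0, 1.2, 10, 10) == 0.0

    def test_shift_invariance_and_scale_invariance(self, rng):
        x, y = rng.normal(0, 1, 30), rng.normal(1, 2, 35)

        def d_of(a, b):
            return cohens_d(a.mean(), a.std(ddof=1), b.mean(), b.std(ddof=1), len(a), len(b))

        base = d_of(x, y)
        assert d_of(x + 7, y + 7) == pytest.approx(base, rel=1e-12)
        assert d_of(3 * x, 3 * y) == pytest.approx(base, rel=1e-12)

    def test_zero_spread_unequal_means_is_infinite(self):
        assert np.isinf(cohens_d(1.0, 0.0, 2.0, 0.0, 5, 5))

    def test_zero_spread_equal_means_is_zero(self):
        assert cohens_d(2.0, 0.0, 2.0, 0.0, 5, 5) == 0.0


@pytest.mark.parametrize(
    "d,expected",
    [
        (0.0, "below_threshold"),
        (0.18, "below_threshold"),
        (0.20, "small"),
        (0.46, "small"),
        (0.50, "small"),
        (0.505, "moderate"),  # the printed bands leave (0.50, 0.51) open
        (0.69, "moderate"),
        (0.80, "moderate"),
        (0.81, "large"),
        (1.12, "large"),
    ],
)
def test_effect_size_bands(d, expected):
    assert classify_d(d) == expected


class TestRocAuc:
    def test_complete_separation(self):
        assert roc_auc([4.0, 5, 6], [1.0, 2, 3]) == 1.0

    def test_exchangeable_samples(self):
        x = [1.0, 2, 3, 4]
        assert roc_auc(x, x) == 0.5

    def test_tie_handling_matches_pair_counting(self):
        assert roc_auc([2.0, 3, 4], [1.0, 2, 3]) == pytest.approx(7 / 9)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        pos=st.lists(st.integers(0, 10), min_size=1, max_size=50),
        neg=st.lists(st.integers(0, 10), min_size=1, max_size=50),
    )
    def test_equals_brute_force_and_complement_identity(self, pos, neg):
        a = roc_auc(pos, neg)
        assert a == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)
        assert a + roc_auc(neg, pos) == pytest.approx(1.0, abs=1e-12)

    def test_cross_check_against_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        pos, neg = rng.normal(1, 1, 40), rng.normal(0, 1, 50)
        labels = np.r_[np.ones(40), np.zeros(50)]
        assert roc_auc(pos, neg) == pytest.approx(
            roc_auc_score(labels, np.r_[pos, neg]), abs=1e-12
        )


@pytest.mark.parametrize(
    "auc,band,inverted",
    [
        (0.5, "chance", False),
        (0.69, "lower", False),
        (0.7, "moderate", False),
        (0.79, "moderate", False),
        (0.9, "moderate", False),
        (0.95, "higher", False),
        (0.45, "chance", True),
    ],
)
def test_auc_bands(auc, band, inverted):
    assert classify_auc(auc) == (band, inverted)


class TestKappa:
    def test_perfect_agreement(self):
        assert cohens_kappa(np.diag([5, 7, 3])) == 1.0

    def test_hand_computed_two_by_two(self):
        # p_o = 35/50 = 0.7; p_e = 0.5*0.6 + 0.5*0.4 = 0.5; kappa = 0.4
        assert cohens_kappa([[20, 5], [10, 15]]) == pytest.approx(0.4)

    def test_degenerate_single_category(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert cohens_kappa([[12]]) == 1.0

    def test_bounds_and_perfect_iff_diagonal(self, rng):
        for _ in range(20):
            table = rng.integers(0, 10, (3, 3))
            if table.sum() == 0:
                continue
            k = cohens_kappa(table)
            assert -1 - 1e-12 <= k <= 1 + 1e-12
            off_diag = table.sum() - np.trace(table)
            if k == 1.0:
                assert off_diag == 0

    def test_cross_check_against_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score

        a = rng.integers(0, 4, 200)
        b = rng.integers(0, 4, 200)
        table = np.zeros((4, 4), dtype=int)
        for i, j in zip(a, b):
            table[i, j] += 1
        assert cohens_kappa(table) == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            cohens_kappa(np.zeros((2, 2)))

    def test_observer_counts_path(self):
        counts = [
            ObserverCounts("s1", "squirm", 3, 3),
            ObserverCounts("s1", "leave_seat", 1, 1),
            ObserverCounts("s2", "squirm", 5, 4),
        ]
        table = contingency_table(counts)
        assert table.sum() == 3
        assert -1 <= observer_kappa(counts) <= 1


def matrices_from_values(values_by_joint, subject_id="s"):
    joints = tuple(values_by_joint)
    vals = np.array([values_by_joint[j] for j in joints], dtype=float)
    return MovementMatrix(subject_id, joints, vals)


class TestCompareGroups:
    def test_duplicated_group_gives_null_rows(self, rng):
        mats = [
            matrices_from_values({j: rng.uniform(1, 5, 30) for j in ANALYSIS_JOINTS}, f"s{i}")
            for i in range(3)
        ]
        rows = compare_groups(mats, mats)
        assert len(rows) == 17
        for r in rows:
            assert r.t == 0.0
            assert r.d == 0.0
            assert r.magnitude == "below_threshold"

    def test_missing_joint_flagged_not_dropped(self, rng):
        full = matrices_from_values({j: rng.uniform(1, 5, 10) for j in ANALYSIS_JOINTS}, "a")
        partial = matrices_from_values({"head": rng.uniform(1, 5, 10)}, "b")
        rows = compare_groups([full], [partial])
        by_joint = {r.joint: r for r in rows}
        assert not by_joint["neck"].valid
        assert by_joint["head"].valid

    def test_missing_minutes_excluded(self, rng):
        x = rng.uniform(1, 5, 20)
        with_nan = np.r_[x, [np.nan] * 5]
        a = matrices_from_values({"head": with_nan}, "a")
        b = matrices_from_values({"head": rng.uniform(1, 5, 25)}, "b")
        row = compare_groups([a], [b], joints=("head",))[0]
        assert row.n1 == 20 and row.n2 == 25

    def test_subject_unit_uses_session_means(self, rng):
        mats1 = [matrices_from_values({"head": rng.uniform(1, 5, 30)}, f"a{i}") for i in range(5)]
        mats2 = [matrices_from_values({"head": rng.uniform(2, 6, 30)}, f"b{i}") for i in range(5)]
        row = compare_groups(mats1, mats2, unit="subject", joints=("head",))[0]
        assert row.n1 == 5 and row.n2 == 5

    def test_null_calibration_on_simulated_minutes(self):
        """Identical generating parameters: few joints reject at 5% and the
        mean |d| stays below threshold."""
        from movemetrics.simulate import SimConfig, sample_minute_paths

        rng = np.random.default_rng(123)
        cfg = SimConfig(frame_rate=5.0, seed=123)
        vals1 = {j: sample_minute_paths(3.0, 60, cfg, rng=rng) for j in ANALYSIS_JOINTS}
        vals2 = {j: sample_minute_paths(3.0, 60, cfg, rng=rng) for j in ANALYSIS_JOINTS}
        rows = compare_groups([matrices_from_values(vals1, "a")], [matrices_from_values(vals2, "b")])
        frac_sig = np.mean([r.p < 0.05 for r in rows])
        assert frac_sig <= 0.25  # 17 independent joints, binomial slack
        assert np.mean([r.d for r in rows]) < 0.2
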