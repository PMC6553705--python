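import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from netwell.behavior_features import BEHAVIOR_MEANS
from netwell.correlation_analysis import (
    ALL_PAIRS,
    STRUCTURE_COLUMNS,
    anova_by_level,
    as_percent,
    cohort_pair_matrix,
    count_pairs,
    high_low_tests,
    ncc,
    per_person_counts,
)


def _brute_pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))


class TestNcc:
    def test_self_correlation_is_one(self):
        x = [1.0, 4.0, 2.0, 8.0]
        assert ncc(x, x).r == pytest.approx(1.0)

    def test_anticorrelation_is_minus_one(self):
        x = np.array([1.0, 4.0, 2.0, 8.0])
        assert ncc(x, -x).r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        assert ncc([1, 2, 3], [1, 2, 4]).r == pytest.approx(0.982, abs=5e-4)

    def test_r_084_at_22_weeks_is_significant(self):
        # plant r ~ 0.84 on 22 points and check p < 0.05
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.standard_normal(22)
            y = 0.84 * (x - x.mean()) / x.std() + math.sqrt(1 - 0.84**2) * rng.standard_normal(22)
            res = ncc(x, y)
            if abs(res.r - 0.84) < 0.02:
                assert res.p < 0.05
                return
        # directly: the t statistic for r=0.84, n=22 gives p << 0.05
        from scipy import stats
        t = 0.84 * math.sqrt(20 / (1 - 0.84**2))
        assert 2 * stats.t.sf(t, 20) < 0.05

    def test_constant_series_flagged_not_raised(self):
        res = ncc([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert not res.defined and math.isnan(res.r)

    def test_short_series_flagged(self):
        assert not ncc([1.0, 2.0], [2.0, 1.0]).defined

    def test_pairwise_deletion_of_missing_weeks(self):
        x = [1.0, np.nan, 3.0, 4.0, 5.0]
        y = [2.0, 9.0, 6.0, np.nan, 10.0]
        res = ncc(x, y)
        assert res.n == 3
        assert res.r == pytest.approx(_brute_pearson([1, 3, 5], [2, 6, 10]))

    @given(
        data=st.lists(
            st.tuples(
                st.floats(-50, 50).map(lambda v: round(v, 2)),
                st.floats(-50, 50).map(lambda v: round(v, 2)),
            ),
            min_size=4,
            max_size=30,
        ),
        a=st.floats(-5, 5).filter(lambda v: abs(v) > 0.01),
        b=st.floats(-10, 10),
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetry_and_affine_invariance(self, data, a, b):
        x = np.array([d[0] for d in data])
        y = np.array([d[1] for d in data])
        res = ncc(x, y)
        if not res.defined:
            return
        assert ncc(y, x).r == pytest.approx(res.r, abs=1e-9)
        assert res.r == pytest.approx(_brute_pearson(x, y), abs=1e-9)
        scaled = ncc(a * x + b, y)
        if scaled.defined:
            assert scaled.r == pytest.approx(math.copysign(1, a) * res.r, abs=1e-6)


def _synthetic_table(rng, n_participants=12, n_weeks=12, couple=False):
    """Tiny feature table with all 16 analysis columns."""
    rows = []
    s_w = np.sin(np.linspace(0, 2 * np.pi, n_weeks))
    for p in range(n_participants):
        base = rng.normal(0, 1, size=(n_weeks, 16))
        for w in range(n_weeks):
            row = {"participant": f"P{p}", "week": w}
            for j, col in enumerate((*STRUCTURE_COLUMNS, *BEHAVIOR_MEANS)):
                val = base[w, j]
                if couple:
                    val += 3.0 * s_w[w]
                row[col] = val
            rows.append(row)
    return pd.DataFrame(rows)


class TestCohortMatrix:
    def test_matrix_has_exactly_sixty_pairs(self):
        table = _synthetic_table(np.random.default_rng(0))
        assert len(cohort_pair_matrix(table)) == len(ALL_PAIRS) == 60

    def test_duplicated_series_has_unit_correlation(self):
        table = _synthetic_table(np.random.default_rng(1))
        table["degree_whole"] = table["steps_mean"]
        m = cohort_pair_matrix(table)
        r = m.loc[(m.structure_feature == "degree_whole")
                  & (m.behavior_feature == "steps_mean"), "r"].iloc[0]
        assert r == pytest.approx(1.0)

    def test_coupled_table_saturates_counts(self):
        table = _synthetic_table(np.random.default_rng(2), couple=True)
        m = cohort_pair_matrix(table)
        assert count_pairs(m, 0.5) >= 55

    def test_median_mode_runs(self):
        table = _synthetic_table(np.random.default_rng(3))
        m = cohort_pair_matrix(table, stat="median")
        assert len(m) == 60


class TestCountPairs:
    def test_all_perfect(self):
        m = pd.DataFrame({"r": [1.0] * 60, "defined": [True] * 60})
        assert count_pairs(m, 0.5) == 60

    def test_tau_above_one_counts_nothing(self):
        m = pd.DataFrame({"r": [1.0] * 60, "defined": [True] * 60})
        assert count_pairs(m, 1.1) == 0

    def test_enumeration_with_threshold_inclusive(self):
        m = pd.DataFrame({"r": [0.7, 0.5, 0.49, -0.6], "defined": [True] * 4})
        assert count_pairs(m, 0.5) == 3

    def test_negative_tau_rejected(self):
        m = pd.DataFrame({"r": [0.0], "defined": [True]})
        with pytest.raises(ValueError):
            count_pairs(m, -0.1)

    def test_nonincreasing_in_tau(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame({"r": rng.uniform(-1, 1, 60), "defined": [True] * 60})
        counts = [count_pairs(m, tau) for tau in np.linspace(0, 1, 11)]
        assert counts == sorted(counts, reverse=True)

    def test_undefined_entries_never_counted(self):
        m = pd.DataFrame({"r": [np.nan, 0.9], "defined": [False, True]})
        assert count_pairs(m, 0.5) == 1


class TestPerPersonCounts:
    def test_identical_series_counted_for_pair(self):
        table = _synthetic_table(np.random.default_rng(6))
        table["degree_participant"] = table["hr_mean"]
        counts = per_person_counts(table)
        assert counts.pair_counts[("degree_participant", "hr_mean")] == counts.denominator

    def test_either_network_at_least_single_network(self):
        table = _synthetic_table(np.random.default_rng(7))
        counts = per_person_counts(table, tau=0.3)
        for b, d in counts.behavior_counts.items():
            assert d["either"] >= max(d["participant"], d["whole"])

    def test_integer_percentage_rule(self):
        assert as_percent(239, 325) == 74

    def test_short_participants_excluded_from_denominator(self):
        table = _synthetic_table(np.random.default_rng(8), n_participants=5)
        table = pd.concat(
            [table, pd.DataFrame([{"participant": "P99", "week": 0,
                                   **{c: 1.0 for c in (*STRUCTURE_COLUMNS, *BEHAVIOR_MEANS)}}])],
            ignore_index=True,
        )
        counts = per_person_counts(table, min_weeks=3)
        assert counts.denominator == 5 and counts.excluded == ["P99"]


class TestHighLowTests:
    def test_identical_groups_not_significant(self):
        table = _synthetic_table(np.random.default_rng(9))
        table["hr_mean"] = 1.0  # constant behavior: no group difference
        # constant series => ttest of identical values; use near-constant noise
        table["hr_mean"] += np.random.default_rng(0).normal(0, 1e-9, len(table))
        results = high_low_tests(table)
        hr = [t for t in results if t.behavior_feature == "hr_mean"]
        assert hr and all(not t.significant for t in hr)

    def test_large_shift_detected_after_correction(self):
        rng = np.random.default_rng(10)
        table = _synthetic_table(rng, n_weeks=22)
        series = table.groupby("week")["degree_participant"].transform("mean")
        med = table.groupby("week")["degree_participant"].mean().median()
        # shift the behavior by 10 sd on high-structure weeks
        table.loc[series > med, "steps_mean"] += 10.0
        results = high_low_tests(table)
        hit = [t for t in results
               if t.structure_feature == "degree_participant"
               and t.behavior_feature == "steps_mean"]
        assert hit[0].significant

    def test_bh_identity_when_all_raw_small(self):
        # BH with all 60 p_raw equal and tiny keeps p_adjusted = p_raw, all significant
        from statsmodels.stats.multitest import multipletests
        reject, p_adj, *_ = multipletests([0.001] * 60, alpha=0.05, method="fdr_bh")
        assert reject.all() and np.allclose(p_adj, 0.001)

    def test_adjusted_never_below_raw(self):
        table = _synthetic_table(np.random.default_rng(11))
        for t in high_low_tests(table):
            assert t.p_adjusted >= t.p_raw - 1e-12


def test_pair_boxplot_writes_figure(tmp_path):
    from netwell.correlation_analysis import pair_boxplot

    table = _synthetic_table(np.random.default_rng(30), n_participants=6, n_weeks=5)
    out = tmp_path / "pair.png"
    pair_boxplot(table, "degree_participant", "steps_mean", out)
    assert out.exists() and out.stat().st_size > 0


class TestAnova:
    def test_identical_group_means_give_zero_f(self):
        # every level sees the same value multiset, so between-group variance is 0
        means = pd.Series(np.tile([60.0, 61.0, 62.0, 63.0], 24))
        labels = pd.Series(np.repeat([1, 2, 3, 4], 24))
        f, _ = anova_by_level(means, labels)
        assert f == pytest.approx(0.0, abs=1e-9)

    def test_two_equal_groups_f_equals_t_squared(self):
        from scipy import stats
        rng = np.random.default_rng(13)
        a, b = rng.normal(0, 1, 30), rng.normal(0.8, 1, 30)
        means = pd.Series(np.concatenate([a, b]))
        labels = pd.Series([1] * 30 + [2] * 30)
        f, p = anova_by_level(means, labels)
        t, p_t = stats.ttest_ind(a, b, equal_var=True)
        assert f == pytest.approx(t**2, rel=1e-9)
        assert p == pytest.approx(p_t, rel=1e-9)

    def test_single_level_raises(self):
        with pytest.raises(ValueError):
            anova_by_level(pd.Series([1.0, 2.0, 3.0]), pd.Series([1, 1, 1]))

    def test_labels_driven_by_heart_rate_detected(self):
        rng = np.random.default_rng(14)
        hr = pd.Series(rng.normal(70, 5, 300))
        labels = pd.Series(pd.cut(hr + rng.normal(0, 1.0, 300), 4, labels=[1, 2, 3, 4]).astype(int))
        f, p = anova_by_level(hr, labels)
        assert p < 0.001
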