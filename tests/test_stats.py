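"""Cohort statistics against enumeration, simulation, and library oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dogmotion.data import load_reference_demographics
from dogmotion.stats import (
    cohens_d_pooled,
    compare_groups,
    comparison_table,
    fisher_exact_2x2,
    mann_whitney_u,
    phi_coefficient,
    posthoc_power,
    summarize_demographics,
)


def mann_whitney_oracle(a, b):
    """Exhaustive permutation distribution of U for untied pooled samples."""
    pooled = np.concatenate([a, b])
    n1 = len(a)

    def u_stat(sample_a, sample_b):
        gt = sum(1 for x in sample_a for y in sample_b if x > y)
        return min(gt, len(sample_a) * len(sample_b) - gt)

    observed = u_stat(a, b)
    us = [
        u_stat(pooled[list(idx)], np.delete(pooled, list(idx)))
        for idx in itertools.combinations(range(len(pooled)), n1)
    ]
    p = np.mean([u <= observed for u in us])
    return observed, p


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_multisets_land_on_the_midpoint(self):
        u, p = mann_whitney_u([5, 5, 5], [5, 5, 5])
        assert u == 4.5
        assert p == 1.0

    def test_matches_exhaustive_enumeration_for_all_small_untied_splits(self):
        # every partition of {1..2n} into two untied samples of size n <= 4
        for n in (2, 3, 4):
            values = np.arange(1, 2 * n + 1, dtype=float)
            for idx in itertools.combinations(range(2 * n), n):
                a = values[list(idx)]
                b = np.delete(values, list(idx))
                u, p = mann_whitney_u(a, b)
                u_exp, p_exp = mann_whitney_oracle(a, b)
                assert u == u_exp
                assert p == pytest.approx(p_exp, rel=1e-12)

    def test_u_bounded_and_complementary(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=15), rng.normal(1.0, size=13)
        u, _ = mann_whitney_u(a, b)
        assert 0 <= u <= len(a) * len(b) / 2

    def test_empty_sample_is_an_error(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestCohensD:
    @pytest.mark.parametrize(
        "m1,s1,m2,s2,expected",
        [
            (214.88, 169.63, 57.79, 38.81, 1.28),  # normalized distance
            (198.65, 62.51, 231.12, 195.05, -0.22),  # MSD rate
        ],
    )
    def test_reference_cohort_rows_round_trip(self, m1, s1, m2, s2, expected):
        assert cohens_d_pooled(m1, s1, m2, s2) == pytest.approx(expected, abs=0.005)

    def test_equal_means_give_zero(self):
        assert cohens_d_pooled(5.0, 1.0, 5.0, 2.0) == 0.0

    def test_antisymmetric_under_group_swap(self):
        assert cohens_d_pooled(3, 1, 1, 2) == -cohens_d_pooled(1, 2, 3, 1)

    def test_both_sds_zero_is_an_error(self):
        with pytest.raises(ValueError):
            cohens_d_pooled(1, 0, 2, 0)


class TestPosthocPower:
    def test_null_effect_power_equals_alpha(self):
        assert posthoc_power(0.0, 12, 12) == 0.05

    def test_monte_carlo_oracle_at_the_study_design(self, rng):
        # 1e5 simulated two-sample t-tests at a d=1.28 shift, n=12 per group
        d, n, sims = 1.28, 12, 100_000
        a = rng.normal(0.0, 1.0, size=(sims, n))
        b = rng.normal(d, 1.0, size=(sims, n))
        sp = np.sqrt((a.var(axis=1, ddof=1) + b.var(axis=1, ddof=1)) / 2)
        t = (b.mean(axis=1) - a.mean(axis=1)) / (sp * np.sqrt(2 / n))
        from scipy.stats import t as tdist

        tcrit = tdist.isf(0.025, 2 * n - 2)
        mc_power = np.mean(np.abs(t) > tcrit)
        analytic = posthoc_power(d, n, n)
        assert 0.80 <= analytic <= 0.90
        assert analytic == pytest.approx(mc_power, abs=0.01)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.power import TTestIndPower

        for d in (0.3, 0.8, 1.28, 2.0):
            ref = TTestIndPower().power(effect_size=d, nobs1=12, ratio=1.0, alpha=0.05)
            assert posthoc_power(d, 12, 12) == pytest.approx(ref, abs=1e-8)

    def test_extreme_effect_sizes_saturate_finite(self):
        # huge separations (synthetic cohorts) must give power ~1, never NaN
        for d in (4.255, 8.85, 13.24, -12.5):
            p = posthoc_power(d, 12, 12)
            assert np.isfinite(p)
            assert p == pytest.approx(1.0, abs=1e-6)

    def test_monotone_in_effect_size_and_sample_size(self):
        assert posthoc_power(1.64, 12, 12) > posthoc_power(1.28, 12, 12)
        assert posthoc_power(0.8, 24, 24) > posthoc_power(0.8, 12, 12)

    def test_invalid_alpha_is_an_error(self):
        with pytest.raises(ValueError):
            posthoc_power(1.0, 12, 12, alpha=1.5)


class TestFisherExact:
    def test_diagonal_two_by_two(self):
        _, p = fisher_exact_2x2([[1, 0], [0, 1]])
        assert p == 1.0  # both tables with these margins are equally likely

    def test_perfect_separation_of_five(self):
        _, p = fisher_exact_2x2([[5, 0], [0, 5]])
        assert p == pytest.approx(2 / 252)

    def test_symmetric_table_is_uninformative(self):
        _, p = fisher_exact_2x2([[4, 4], [4, 4]])
        assert p == 1.0

    def test_zero_margin_is_an_error(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0, 0], [1, 2]])


class TestPhiCoefficient:
    def test_perfect_association(self):
        assert phi_coefficient([[1, 0], [0, 1]]) == 1.0

    def test_no_association(self):
        assert phi_coefficient([[1, 1], [1, 1]]) == 0.0

    def test_matches_pearson_correlation_of_indicators(self, rng):
        for _ in range(10):
            x = rng.integers(0, 2, size=40)
            y = (x + (rng.random(40) < 0.3)) % 2
            table = [
                [np.sum((x == 1) & (y == 1)), np.sum((x == 1) & (y == 0))],
                [np.sum((x == 0) & (y == 1)), np.sum((x == 0) & (y == 0))],
            ]
            if min(np.sum(table, 0).min(), np.sum(table, 1).min()) == 0:
                continue
            assert phi_coefficient(table) == pytest.approx(np.corrcoef(x, y)[0, 1], rel=1e-9)


class TestDemographics:
    def test_reference_cohort_median_ages(self):
        summary = summarize_demographics(load_reference_demographics())
        cont = summary.continuous.set_index(["factor", "group"])
        assert cont.loc[("age", "C"), "median"] == pytest.approx(2.75)
        assert cont.loc[("age", "H"), "median"] == pytest.approx(1.50)

    def test_no_significant_demographic_differences_in_reference_cohort(self):
        summary = summarize_demographics(load_reference_demographics())
        assert all(t.p > 0.05 for t in summary.tests)

    def test_all_equal_ages_are_maximally_tied(self):
        from dogmotion.trajectory import SubjectMeta

        metas = [
            SubjectMeta(
                f"s{i}", "H" if i < 3 else "C", "mf"[i % 2], 2.0, 20.0, bool(i % 2)
            )
            for i in range(6)
        ]
        summary = summarize_demographics(metas)
        age = next(t for t in summary.tests if t.factor == "age")
        assert age.statistic == 4.5  # n^2 / 2 under midranks
        assert age.p == 1.0

    def test_single_group_is_an_error(self):
        from dogmotion.trajectory import SubjectMeta

        metas = [SubjectMeta(f"s{i}", "H", "m", 2.0, 20.0, True) for i in range(4)]
        with pytest.raises(ValueError):
            summarize_demographics(metas)


def make_metrics_frame(h_values, c_values, var="n_distance"):
    rows = [{"subject_id": f"h{i}", "group": "H", var: v} for i, v in enumerate(h_values)]
    rows += [{"subject_id": f"c{i}", "group": "C", var: v} for i, v in enumerate(c_values)]
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_identical_groups_all_disregarded(self):
        df = make_metrics_frame([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        rows = compare_groups(df, variables=["n_distance"])
        assert rows[0].d == 0.0
        assert rows[0].disregarded
        assert rows[0].p == 1.0

    def test_common_weight_rescaling_preserves_ranks(self, rng):
        h = rng.lognormal(1.0, 0.5, size=12)
        c = rng.lognormal(0.2, 0.5, size=12)
        full = compare_groups(make_metrics_frame(h, c), variables=["n_distance"])[0]
        halved = compare_groups(make_metrics_frame(h / 2, c / 2), variables=["n_distance"])[0]
        assert halved.mean_h == pytest.approx(full.mean_h / 2)
        assert halved.u == full.u
        assert halved.p == pytest.approx(full.p)

    def test_missing_values_excluded_pairwise(self):
        df = make_metrics_frame([1.0, 2.0, np.nan, 4.0], [0.5, np.nan, 0.7, 0.2])
        rows = compare_groups(df, variables=["n_distance"])
        assert rows[0].n_h == 3 and rows[0].n_c == 3
        assert not rows[0].untestable

    def test_too_few_observations_flags_untestable(self):
        df = make_metrics_frame([1.0, np.nan, np.nan], [0.5, 0.6, 0.7])
        rows = compare_groups(df, variables=["n_distance"])
        assert rows[0].untestable
        assert rows[0].disregarded

    def test_disregarded_flag_is_exactly_the_power_rule(self, rng):
        h = rng.normal(1.0, 1.0, size=12)
        c = rng.normal(0.0, 1.0, size=12)
        df = make_metrics_frame(h, c)
        df["st"] = np.concatenate([rng.normal(0, 1, 12), rng.normal(0.1, 1, 12)])
        table = comparison_table(compare_groups(df, variables=["n_distance", "st"]))
        for _, row in table.iterrows():
            assert row["disregarded"] == (row["power"] < 0.80)

    def test_single_group_input_is_an_error(self):
        df = make_metrics_frame([1.0, 2.0], []).iloc[:2]
        with pytest.raises(ValueError):
            compare_groups(df, variables=["n_distance"])
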