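"""Exact baseline tests and the sample-size rule."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats as sps

from sgus_ic.stats import (
    FourfoldTable,
    PowerSpec,
    UsabilityClass,
    baseline_table,
    fisher_exact_one_sided,
    fisher_exact_rxc,
    fisher_exact_two_sided,
    sample_size,
    wilcoxon_rank_sum,
)

# Baseline 2x2 counts (Group-1 yes/no, Group-2 yes/no) with their
# published p-values: male 7/18 vs 10/15, instructed-to-DPIs 8/18 vs
# 9/15, instructed-to-MDIs 5/18 vs 6/15, instructed-to-SMIs 1/18 vs 1/15.
BASELINE_TABLES = [
    (FourfoldTable(7, 11, 10, 5), 0.107, 3),
    (FourfoldTable(8, 10, 9, 6), 0.295, 3),
    (FourfoldTable(5, 13, 6, 9), 0.355, 3),
    (FourfoldTable(1, 17, 1, 14), 0.71, 2),
]


def _lower_tail_oracle(t: FourfoldTable) -> float:
    """Brute-force enumeration of the conditional null, via scipy's pmf."""
    n1, k_yes, n_tot = t.a + t.b, t.a + t.c, t.a + t.b + t.c + t.d
    return float(
        sum(sps.hypergeom.pmf(k, n_tot, k_yes, n1) for k in range(0, t.a + 1))
    )


class TestFisherExact:
    @pytest.mark.parametrize("table,published,decimals", BASELINE_TABLES)
    def test_reproduces_published_baseline_pvalues(self, table, published, decimals):
        assert round(fisher_exact_one_sided(table), decimals) == published

    @pytest.mark.parametrize(
        "table",
        [t for t, _, _ in BASELINE_TABLES]
        + [FourfoldTable(3, 1, 2, 6), FourfoldTable(0, 9, 4, 4)],
    )
    def test_agrees_with_enumeration_oracle(self, table):
        assert fisher_exact_one_sided(table) == pytest.approx(
            _lower_tail_oracle(table), abs=1e-12
        )

    @pytest.mark.parametrize("table", [t for t, _, _ in BASELINE_TABLES])
    def test_agrees_with_scipy_one_sided(self, table):
        ref = sps.fisher_exact(
            [[table.a, table.b], [table.c, table.d]], alternative="less"
        ).pvalue
        assert fisher_exact_one_sided(table) == pytest.approx(ref, abs=1e-12)

    def test_maximal_count_gives_p_one(self):
        # a at its maximum given margins: full lower tail
        assert fisher_exact_one_sided(FourfoldTable(5, 0, 1, 6)) == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [t for t, _, _ in BASELINE_TABLES])
    def test_two_sided_matches_scipy(self, table):
        ref = sps.fisher_exact([[table.a, table.b], [table.c, table.d]]).pvalue
        assert fisher_exact_two_sided(table) == pytest.approx(ref, abs=1e-9)

    def test_zero_margin_is_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_one_sided(FourfoldTable(0, 5, 0, 7))


class TestFisherRxc:
    def test_reduces_to_two_sided_fisher_for_2x2(self):
        t = FourfoldTable(7, 11, 10, 5)
        assert fisher_exact_rxc([[7, 11], [10, 5]]) == pytest.approx(
            fisher_exact_two_sided(t), abs=1e-12
        )

    def test_region_table_value(self):
        # 2x3 region-of-origin counts of the study design; frozen from the
        # exact probability-ordering enumeration (matches the published 0.199)
        assert fisher_exact_rxc([[15, 0, 3], [10, 3, 2]]) == pytest.approx(
            0.1991943910742576, abs=1e-12
        )


class TestWilcoxon:
    def test_identical_samples_give_p_one(self):
        assert wilcoxon_rank_sum([3, 1, 4, 1, 5], [3, 1, 4, 1, 5]) == 1.0

    def test_fully_separated_small_samples(self):
        # extreme rank sum: 2 of the C(6,3)=20 assignments are as extreme
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(2 / 20)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=8), rng.normal(0.8, size=7)
        assert wilcoxon_rank_sum(x, y) == pytest.approx(
            wilcoxon_rank_sum(np.exp(x), np.exp(y))
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_matches_scipy_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=7), rng.normal(0.5, size=6)
        ref = sps.mannwhitneyu(x, y, method="exact", alternative="two-sided").pvalue
        assert wilcoxon_rank_sum(x, y) == pytest.approx(ref, abs=1e-12)

    def test_exact_and_approximate_agree_on_10v10(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=10), rng.normal(0.7, size=10)
        exact = wilcoxon_rank_sum(x, y, method="exact")
        approx = wilcoxon_rank_sum(x, y, method="approx")
        assert abs(exact - approx) < 0.02

    def test_empty_sample_is_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestSampleSize:
    def test_direct_evaluation_of_the_formula(self):
        classes = (
            UsabilityClass("lo", 10.0, 10.0 - 1.959964 * 5, 10.0 + 1.959964 * 5),
            UsabilityClass("hi", 15.0, 15.0 - 1.959964 * 5, 15.0 + 1.959964 * 5),
        )
        result = sample_size(PowerSpec(classes=classes))
        # 2 * (1.959964 + 0.841621)^2 * 25 / 25 = 15.7 -> 16 per group
        assert result.comparisons["n_per_group"].iloc[0] == 16

    def test_huge_difference_needs_one_per_group(self):
        classes = (
            UsabilityClass("lo", 0.0, -1.0, 1.0),
            UsabilityClass("hi", 1e6, 1e6 - 1, 1e6 + 1),
        )
        assert sample_size(PowerSpec(classes=classes)).comparisons["n_per_group"].iloc[0] == 1

    def test_monotone_in_delta_and_sd(self):
        def n_for(delta, half_width):
            classes = (
                UsabilityClass("a", 0.0, -half_width, half_width),
                UsabilityClass("b", delta, delta - half_width, delta + half_width),
            )
            return sample_size(PowerSpec(classes=classes)).final_n

        assert n_for(2.0, 9.8) >= n_for(4.0, 9.8) >= n_for(8.0, 9.8)
        assert n_for(4.0, 4.9) <= n_for(4.0, 9.8) <= n_for(4.0, 19.6)

    def test_default_spec_compares_all_three_class_pairs(self):
        result = sample_size(PowerSpec())
        assert len(result.comparisons) == 3
        assert result.final_n == result.comparisons["n_total"].max()
        assert (result.comparisons["n_total"] == 2 * result.comparisons["n_per_group"]).all()

    def test_zero_difference_is_rejected(self):
        classes = (
            UsabilityClass("a", 10.0, 8.0, 12.0),
            UsabilityClass("b", 10.0, 7.0, 13.0),
        )
        with pytest.raises(ValueError, match="detectable"):
            sample_size(PowerSpec(classes=classes))

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            sample_size(PowerSpec(alpha=1.5))


class TestBaselineTable:
    def test_structure_and_methods(self, default_cohort):
        table = baseline_table(default_cohort.demographics)
        assert set(table["variable"]) == {
            "Instructed to DPIs", "Instructed to MDIs", "Instructed to SMIs",
            "Mean age (SD)", "Male", "Country", "Education",
        }
        valid = table["p_value"].dropna()
        assert ((valid >= 0) & (valid <= 1)).all()
        assert (table.loc[table["variable"] == "Mean age (SD)", "method"]
                == "wilcoxon rank-sum").all()
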