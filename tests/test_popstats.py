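"""Population statistics: frequencies, grouping, exact tests vs. oracles."""

import math
from fractions import Fraction

import pytest
from hypothesis import given, strategies as st

from pgxstar import datasets
from pgxstar.consensus import normalize_diplotype
from pgxstar.popstats import (
    FrequencyTable,
    count_distinct_alleles,
    estimate_allele_frequencies,
    fisher_compare,
    function_class_summary,
    hwe_exact_test,
    hwe_test_for_allele,
    round_pct,
    sv_carrier_proportion,
)
from pgxstar.synthetic_cohort import SimulationConfig, simulate_cohort


# ---------------------------------------------------------------------------
# Independent exact-arithmetic oracles


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration in Fractions."""
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2

    def table_prob(x):
        return Fraction(
            math.comb(row1, x) * math.comb(row2, col1 - x), math.comb(n, col1)
        )

    observed = table_prob(a)
    total = Fraction(0)
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        p = table_prob(x)
        if p <= observed:
            total += p
    return total


def hwe_oracle(n_aa, n_ab, n_bb):
    """Exact conditional heterozygote-count distribution via the allele-pairing
    formula, P(h) = n! / (nAA! h! nBB!) * 2^h * nA! nB! / (2n)!, in Fractions."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    nb = 2 * n - na
    if na == 0 or nb == 0:
        return Fraction(1)

    def prob(h):
        naa = (na - h) // 2
        nbb = n - naa - h
        return Fraction(
            math.factorial(n) * 2**h * math.factorial(na) * math.factorial(nb),
            math.factorial(naa) * math.factorial(h) * math.factorial(nbb) * math.factorial(2 * n),
        )

    observed = prob(n_ab)
    total = Fraction(0)
    for h in range(na % 2, min(na, nb) + 1, 2):
        p = prob(h)
        if p <= observed:
            total += p
    return total


# ---------------------------------------------------------------------------


class TestFrequencyEstimation:
    def test_single_homozygote(self):
        table = estimate_allele_frequencies({"s1": normalize_diplotype("*1/*1")})
        assert table.frequency("ALL", "*1") == 100.0

    def test_chromosome_counting(self):
        diplos = {
            "s1": normalize_diplotype("*1/*17"),
            "s2": normalize_diplotype("*17/*5"),
        }
        table = estimate_allele_frequencies(diplos)
        assert table.frequency("ALL", "*17") == 50.0
        assert table.frequency("ALL", "*5") == 25.0

    def test_tandem_and_xn_count_one_chromosome(self):
        diplos = {"s1": normalize_diplotype("*68+*4/*2x2")}
        table = estimate_allele_frequencies(diplos)
        assert table.frequency("ALL", "*68+*4") == 50.0
        assert table.frequency("ALL", "*2x2") == 50.0

    def test_observed_mode_sums_to_100(self, catalog, global_table):
        config = datasets.simulation_spec(global_table, "SSA", n_individuals=300, seed=2,
                                          n_callers=1)
        cohort = simulate_cohort(config, catalog)
        table = estimate_allele_frequencies(cohort.truth_diplotypes)
        assert table.column_total("ALL") == pytest.approx(100.0, abs=1e-9)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            estimate_allele_frequencies({})

    def test_population_labels_split_columns(self):
        diplos = {
            "s1": normalize_diplotype("*1/*1"),
            "s2": normalize_diplotype("*17/*17"),
        }
        table = estimate_allele_frequencies(diplos, {"s1": "P1", "s2": "P2"})
        assert table.frequency("P1", "*1") == 100.0
        assert table.frequency("P2", "*17") == 100.0


class TestDistinctAlleleCounting:
    def test_printed_column_groups(self, catalog, global_table):
        assert count_distinct_alleles(global_table, "SSA", catalog) == (38, 11)

    def test_reference_only_column(self):
        table = FrequencyTable(populations=[("P", 10)], freqs={("P", "*1"): 100.0})
        assert count_distinct_alleles(table, "P") == (1, 0)

    def test_xn_series_collapses_to_one_group(self):
        freqs = {("P", "*4"): 50.0, ("P", "*4x2"): 30.0, ("P", "*4x3"): 20.0}
        table = FrequencyTable(populations=[("P", 10)], freqs=freqs)
        total, structural = count_distinct_alleles(table, "P")
        assert (total, structural) == (2, 1)  # *4 (SNV) + one *4xN group

    def test_invariant_to_zero_rows(self, catalog, global_table):
        pruned = FrequencyTable(
            populations=[("SSA", 947)],
            freqs={
                k: v
                for k, v in global_table.freqs.items()
                if k[0] == "SSA" and v > 0
            },
        )
        assert count_distinct_alleles(pruned, "SSA", catalog) == (38, 11)


class TestFunctionClassSummary:
    def test_printed_column_rollup(self, catalog, global_table):
        summary = function_class_summary(global_table, catalog, "SSA")
        assert summary["no_function"]["total_pct"] == pytest.approx(14.9, abs=1e-9)
        assert summary["no_function"]["top_allele"] == "*5"
        assert summary["no_function"]["top_share_pct"] >= 52.0
        assert summary["uncertain"]["total_pct"] + summary["unknown"]["total_pct"] == (
            pytest.approx(3.5, abs=1e-9)
        )

    def test_all_reference_is_all_normal(self):
        table = FrequencyTable(populations=[("P", 5)], freqs={("P", "*1"): 100.0})
        catalog = datasets.load_default_catalog()
        summary = function_class_summary(table, catalog, "P")
        assert set(summary) == {"normal"}
        assert summary["normal"]["total_pct"] == 100.0

    def test_unmapped_allele_raises(self, catalog):
        table = FrequencyTable(populations=[("P", 5)], freqs={("P", "*777"): 100.0})
        with pytest.raises(KeyError):
            function_class_summary(table, catalog, "P")


class TestSvCarrierProportion:
    def test_hwe_mode_from_printed_column(self, catalog, global_table):
        pct = sv_carrier_proportion(table=global_table, population="SSA", catalog=catalog)
        assert round(pct) == 27

    def test_no_sv_cohort(self):
        diplos = {"s1": normalize_diplotype("*1/*2")}
        assert sv_carrier_proportion(diplotypes=diplos) == 0.0

    def test_all_deletion_carriers(self):
        diplos = {f"s{i}": normalize_diplotype("*5/*1") for i in range(4)}
        assert sv_carrier_proportion(diplotypes=diplos) == 100.0

    def test_hwe_and_observed_modes_agree_on_large_cohort(self, catalog, global_table):
        config = datasets.simulation_spec(global_table, "SSA", n_individuals=8000,
                                          seed=9, n_callers=1)
        cohort = simulate_cohort(config, catalog)
        observed = sv_carrier_proportion(diplotypes=cohort.truth_diplotypes, catalog=catalog)
        table = estimate_allele_frequencies(cohort.truth_diplotypes)
        hwe = sv_carrier_proportion(table=table, population="ALL", catalog=catalog)
        assert observed == pytest.approx(hwe, abs=2.0)


class TestHweExactTest:
    def test_extreme_heterozygote_deficit(self):
        assert hwe_exact_test(50, 0, 50).p_value < 1e-20

    def test_monomorphic_is_noted(self):
        res = hwe_exact_test(100, 0, 0)
        assert res.p_value == 1.0 and res.note == "monomorphic"

    def test_modal_configuration(self):
        assert hwe_exact_test(1, 2, 1).p_value == 1.0

    @given(
        n_aa=st.integers(0, 12), n_ab=st.integers(0, 12), n_bb=st.integers(0, 12)
    )
    def test_matches_enumeration_oracle(self, n_aa, n_ab, n_bb):
        if n_aa + n_ab + n_bb == 0:
            return
        p = hwe_exact_test(n_aa, n_ab, n_bb).p_value
        assert p == pytest.approx(float(hwe_oracle(n_aa, n_ab, n_bb)), abs=1e-12)

    def test_biallelic_collapse_from_diplotypes(self):
        diplos = {
            "s1": normalize_diplotype("*1/*1"),
            "s2": normalize_diplotype("*1/*17"),
            "s3": normalize_diplotype("*17/*17"),
            "s4": normalize_diplotype("*17/*5"),
        }
        res = hwe_test_for_allele(diplos, "*17")
        assert res.counts == (1, 2, 1)

    def test_uniform_conservative_under_null(self, catalog):
        """Rejection rate at alpha=0.05 stays <= 0.06 across 1000 seeded
        HWE cohorts of n=100 (exact tests are conservative)."""
        rejections = 0
        for seed in range(1000):
            config = SimulationConfig(
                frequency_spec={"*1": 0.7, "*4": 0.3},
                n_individuals=100, seed=10_000 + seed, n_callers=1,
            )
            cohort = simulate_cohort(config, catalog)
            counts = {"hom": 0, "het": 0, "other": 0}
            for call in cohort.truth_diplotypes.values():
                k = sum(t.base == "*1" for t in call.tokens)
                counts["hom" if k == 2 else "het" if k == 1 else "other"] += 1
            p = hwe_exact_test(counts["hom"], counts["het"], counts["other"]).p_value
            rejections += p < 0.05
        assert rejections / 1000 <= 0.06


class TestFisherCompare:
    def test_tea_tasting_table(self):
        assert fisher_compare(3, 4, 1, 4).p_value == pytest.approx(0.4857, abs=2e-4)

    def test_identical_proportions(self):
        assert fisher_compare(5, 10, 5, 10).p_value == 1.0

    def test_extreme_difference(self):
        assert fisher_compare(0, 100, 100, 100).p_value < 1e-20

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fisher_compare(1, 0, 1, 2)
        with pytest.raises(ValueError):
            fisher_compare(5, 4, 1, 2)

    @given(
        a=st.integers(0, 15), b=st.integers(0, 15),
        c=st.integers(0, 15), d=st.integers(0, 15),
    )
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if (a + b) == 0 or (c + d) == 0:
            return
        p = fisher_compare(a, a + b, c, c + d).p_value
        assert p == pytest.approx(float(fisher_oracle(a, b, c, d)), abs=1e-12)


class TestRounding:
    @pytest.mark.parametrize(
        "value,expected", [(0.25, 0.3), (0.24999, 0.2), (8.05, 8.1), (13.44, 13.4)]
    )
    def test_half_away_from_zero(self, value, expected):
        assert round_pct(value) == expected
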