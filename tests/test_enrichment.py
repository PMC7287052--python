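"""Fisher tests against enumeration oracles; gene filter; screens."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import fisher_2x2_oracle, fisher_2x3_all_probs, fisher_2x3_oracle
from timeprofiler.core import MutationTable
from timeprofiler.enrichment import (
    cytact_association,
    domain_tabulation,
    enrichment_screen,
    filter_genes,
    fisher_exact_2x2,
    fisher_exact_2x3,
)
from timeprofiler.simulate import CohortConfig, generate_cohort


def _mut_table(pairs, profiled):
    records = pd.DataFrame(
        [
            {"sample_id": s, "gene": g, "variant_class": "Missense_Mutation"}
            for s, g in pairs
        ],
        columns=["sample_id", "gene", "variant_class"],
    )
    return MutationTable(records, profiled_samples=frozenset(profiled))


class TestFilterGenes:
    def test_count_frequency_arithmetic(self):
        """10 records across 512 profiled samples -> 1.95% (2 d.p.)."""
        profiled = [f"s{i}" for i in range(512)]
        mut = _mut_table([(f"s{i}", "G") for i in range(10)], profiled)
        stats = filter_genes(mut, min_count=10)
        assert len(stats) == 1
        assert round(100 * stats.loc[0, "count_frequency"], 2) == 1.95

    def test_threshold_excludes_nine_records(self):
        profiled = [f"s{i}" for i in range(50)]
        mut = _mut_table([(f"s{i}", "G") for i in range(9)], profiled)
        assert filter_genes(mut, min_count=10).empty

    def test_records_vs_patients(self):
        """2 records in one sample + 1 in another: count 3, patients 2."""
        mut = _mut_table([("s1", "G"), ("s1", "G"), ("s2", "G")], ["s1", "s2", "s3"])
        stats = filter_genes(mut, min_count=1)
        row = stats.iloc[0]
        assert row["mutation_count"] == 3
        assert row["mutated_patient_count"] == 2

    def test_sort_order_count_desc_then_alpha(self):
        pairs = [(f"s{i}", "B") for i in range(3)]
        pairs += [(f"s{i}", "A") for i in range(3)]
        pairs += [(f"s{i}", "C") for i in range(5)]
        mut = _mut_table(pairs, [f"s{i}" for i in range(10)])
        assert filter_genes(mut, min_count=1)["gene"].tolist() == ["C", "A", "B"]


class TestFisher2x2:
    def test_known_values(self):
        _, p = fisher_exact_2x2([[2, 0], [0, 2]])
        assert p == pytest.approx(1 / 3, abs=1e-12)
        _, p = fisher_exact_2x2([[5, 5], [5, 5]])
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_empty_margin(self):
        odds, p = fisher_exact_2x2([[0, 0], [3, 4]])
        assert p == 1.0
        assert np.isnan(odds)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 12), min_size=4, max_size=4))
    def test_matches_rational_enumeration(self, cells):
        table = [cells[:2], cells[2:]]
        _, p = fisher_exact_2x2(table)
        assert p == pytest.approx(fisher_2x2_oracle(table), abs=1e-12)


class TestFisher2x3:
    def test_exchangeable_columns_modal(self):
        assert fisher_exact_2x3([[1, 1, 1], [9, 9, 9]]) == pytest.approx(1.0)

    def test_skewed_table_small_p(self):
        p = fisher_exact_2x3([[6, 0, 0], [4, 10, 10]])
        assert p == pytest.approx(fisher_2x3_oracle([[6, 0, 0], [4, 10, 10]]),
                                  abs=1e-12)
        assert p < 0.01

    def test_zero_row_margin(self):
        assert fisher_exact_2x3([[0, 0, 0], [3, 4, 5]]) == 1.0

    def test_probabilities_normalize(self):
        """Enumeration over fixed margins sums to 1 exactly."""
        for margins in (((4, 16), (7, 6, 7)), ((10, 10), (8, 6, 6))):
            probs = fisher_2x3_all_probs(*margins)
            assert float(sum(probs)) == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 7), min_size=6, max_size=6))
    def test_matches_rational_enumeration(self, cells):
        table = [cells[:3], cells[3:]]
        assert fisher_exact_2x3(table) == pytest.approx(
            fisher_2x3_oracle(table), abs=1e-12
        )


class TestEnrichmentScreen:
    def test_planted_gene_detected(self, small_cohort, small_cohort_z):
        from timeprofiler.classify import assign_subtypes

        labels = assign_subtypes(small_cohort_z)
        screen = enrichment_screen(labels, small_cohort.mutations)
        row = screen.set_index("gene").loc["EP300"]
        assert row["omnibus_p"] < 0.05
        assert row["direction"] == "activated"
        assert 0 < row["q_value"] <= 1

    def test_unmutated_gene_p_one(self, small_cohort, small_cohort_z):
        from timeprofiler.classify import assign_subtypes

        labels = assign_subtypes(small_cohort_z)
        screen = enrichment_screen(
            labels, small_cohort.mutations, genes=["NEVERMUT"]
        )
        row = screen.iloc[0]
        assert row["omnibus_p"] == 1.0
        assert row["direction"] is None

    def test_requires_two_subtypes(self, small_cohort):
        labels = pd.Series(
            "unclassified", index=small_cohort.truth.index
        )
        with pytest.raises(ValueError, match="2 nonempty"):
            enrichment_screen(labels, small_cohort.mutations)

    def test_invariant_to_sample_order(self, small_cohort, small_cohort_z):
        from timeprofiler.classify import assign_subtypes

        labels = assign_subtypes(small_cohort_z)
        a = enrichment_screen(labels, small_cohort.mutations)
        b = enrichment_screen(
            labels.iloc[::-1], small_cohort.mutations
        )
        pd.testing.assert_series_equal(
            a.set_index("gene")["omnibus_p"], b.set_index("gene")["omnibus_p"]
        )

    def test_hpv_stratified_returns_three_screens(self, small_cohort, small_cohort_z):
        from timeprofiler.classify import assign_subtypes

        labels = assign_subtypes(small_cohort_z)
        res = enrichment_screen(
            labels,
            small_cohort.mutations,
            hpv_status=small_cohort.clinical["hpv_status"],
        )
        assert set(res) == {"all", "hpv_positive", "hpv_negative"}

    def test_enriched_rate_monotone_in_median_p(self):
        """Raising the planted enrichment never raises the median omnibus p."""
        medians = []
        for rate in (0.1, 0.3, 0.6):
            ps = []
            for seed in range(15):
                c = generate_cohort(
                    CohortConfig(
                        n_samples=200,
                        subtype_proportions=(0.25, 0.25, 0.5, 0.0),
                        mut_enriched_rate=rate,
                        seed=1000 + seed,
                    )
                )
                screen = enrichment_screen(
                    c.truth["subtype"], c.mutations, genes=["EP300"]
                )
                ps.append(screen.loc[0, "omnibus_p"])
            medians.append(np.median(ps))
        assert medians[0] >= medians[1] >= medians[2]


class TestCytActAssociation:
    def test_planted_association(self):
        ids = [f"s{i}" for i in range(48)]
        mut = pd.Series([True] * 8 + [False] * 40, index=ids)
        cytact = pd.Series(["up"] * 8 + ["up"] * 10 + ["down"] * 30, index=ids)
        table, p = cytact_association(mut, cytact)
        assert table.tolist() == [[8, 0], [10, 30]]
        assert p == pytest.approx(fisher_2x2_oracle([[8, 0], [10, 30]]), abs=1e-12)
        assert p < 0.01

    def test_single_mutated_sample_robust(self):
        ids = [f"s{i}" for i in range(20)]
        mut = pd.Series([True] + [False] * 19, index=ids)
        cytact = pd.Series(["up"] * 10 + ["down"] * 10, index=ids)
        _, p = cytact_association(mut, cytact)
        assert 0 < p <= 1

    def test_all_neither_errors(self):
        ids = ["a", "b"]
        with pytest.raises(ValueError, match="CytAct"):
            cytact_association(
                pd.Series([True, False], index=ids),
                pd.Series(["neither", "neither"], index=ids),
            )


class TestDomainTabulation:
    def test_taz1_percentage(self):
        """3 CytAct-up of 8 TAZ1 mutations -> 37.5%."""
        records = pd.DataFrame(
            {
                "domain": ["TAZ1"] * 8 + ["KAT"] * 4,
                "cytact_up": [True] * 3 + [False] * 5 + [True] * 1 + [False] * 3,
            }
        )
        tab = domain_tabulation(records).set_index("domain")
        assert tab.loc["TAZ1", "percent_cytact_up"] == 37.5
        assert tab.loc["TAZ1", "n_mutations"] == 8

    def test_missing_domain_bucketed_other(self):
        records = pd.DataFrame({"domain": ["", None], "cytact_up": [True, False]})
        tab = domain_tabulation(records)
        assert tab["domain"].tolist() == ["other"]
        assert tab.loc[0, "n_mutations"] == 2

    def test_percentages_consistent_with_counts(self):
        rng = np.random.default_rng(0)
        records = pd.DataFrame(
            {
                "domain": rng.choice(["TAZ1", "KAT", "BR"], 200),
                "cytact_up": rng.random(200) < 0.3,
            }
        )
        tab = domain_tabulation(records)
        recomputed = 100.0 * tab["n_cytact_up"] / tab["n_mutations"]
        assert (abs(tab["percent_cytact_up"] - recomputed) <= 0.05).all()
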