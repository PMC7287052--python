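"""Subtype rules, CytAct calls, expression strata, and the Table-1 summary."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from conftest import random_zmatrix
from timeprofiler.classify import (
    GenePanel,
    SubtypeRuleSet,
    assign_subtypes,
    call_cytact,
    default_ruleset,
    panel_satisfied,
    stratify_expression,
    subtype_summary,
)
from timeprofiler.core import zscore
from timeprofiler.simulate import CohortConfig, generate_cohort


class TestPanelSatisfied:
    def test_definition_and_boundary(self, toy_z):
        panel = GenePanel("p", (("A", "up"), ("B", "down")))
        z = toy_z({"s": [0.5, -0.5], "t": [0.0, -0.5]}, ["A", "B"])
        assert panel_satisfied(z, "s", panel) is True
        assert panel_satisfied(z, "t", panel) is False  # z == threshold fails

    def test_matches_exhaustive_sign_enumeration(self):
        """A 3-up-gene panel agrees with brute force over all 2^3 sign patterns."""
        panel = GenePanel("p", (("A", "up"), ("B", "up"), ("C", "up")))
        for signs in itertools.product([-1.0, 1.0], repeat=3):
            df = pd.DataFrame({"x": signs}, index=["A", "B", "C"])
            from timeprofiler.core import ZExpressionMatrix

            z = ZExpressionMatrix(df)
            expected = all(s > 0 for s in signs)
            assert panel_satisfied(z, "x", panel) is expected

    def test_absent_gene_named_in_error(self):
        z = random_zmatrix(3, 4, seed=0)
        panel = GenePanel("p", (("NOPE", "up"),))
        with pytest.raises(KeyError, match="NOPE"):
            panel_satisfied(z, "s0", panel)


class TestAssignSubtypes:
    def test_planted_cohort_recovery(self, small_cohort, small_cohort_z):
        """>= 90% of true activated/suppressed/absent labels recovered."""
        labels = assign_subtypes(small_cohort_z)
        truth = small_cohort.truth["subtype"]
        mask = truth != "unclassified"
        acc = (labels[mask] == truth[mask]).mean()
        assert acc >= 0.90

    def test_boundary_sample_unclassified(self):
        """A z of exactly 0 on a required gene blocks every panel."""
        from timeprofiler.classify import IMMUNE_MARKERS
        from timeprofiler.core import ZExpressionMatrix

        vals = pd.DataFrame(
            {"s": [3.0] * len(IMMUNE_MARKERS)}, index=list(IMMUNE_MARKERS)
        )
        vals.loc["GZMB", "s"] = 0.0  # required up by the activated panel
        z = ZExpressionMatrix(vals)
        assert assign_subtypes(z)["s"] == "unclassified"

    def test_multi_panel_hit_is_unclassified(self):
        """Custom overlapping rules: a sample satisfying two panels is excluded."""
        from timeprofiler.core import ZExpressionMatrix

        up_a = GenePanel("activated", (("A", "up"),))
        up_b = GenePanel("suppressed", (("A", "up"), ("B", "up")))
        other = GenePanel("absent", (("A", "down"),))
        rules = SubtypeRuleSet(up_a, up_b, other)
        z = ZExpressionMatrix(
            pd.DataFrame({"s": [1.0, 1.0], "t": [1.0, -1.0]}, index=["A", "B"])
        )
        labels = assign_subtypes(z, rules)
        assert labels["s"] == "unclassified"  # satisfies both up-panels
        assert labels["t"] == "activated"

    def test_default_rules_cannot_overlap(self):
        """No random sample ever satisfies two default panels (GZMB conflict)."""
        z = random_zmatrix(1, 1, seed=0)  # placeholder; real draw below
        rng = np.random.default_rng(42)
        from timeprofiler.classify import IMMUNE_MARKERS
        from timeprofiler.core import ZExpressionMatrix

        vals = rng.standard_normal((len(IMMUNE_MARKERS), 500))
        z = ZExpressionMatrix(
            pd.DataFrame(
                vals,
                index=list(IMMUNE_MARKERS),
                columns=[f"s{i}" for i in range(500)],
            )
        )
        rules = default_ruleset()
        sat = np.zeros(500, dtype=int)
        for panel in rules.panels().values():
            ok = np.ones(500, dtype=bool)
            for gene, d in panel.entries:
                row = z.data.loc[gene].to_numpy()
                ok &= (row > 0) if d == "up" else (row < 0)
            sat += ok
        assert sat.max() <= 1

    def test_permutation_equivariance(self, small_cohort_z):
        labels = assign_subtypes(small_cohort_z)
        perm = list(reversed(small_cohort_z.data.columns))
        from timeprofiler.core import ZExpressionMatrix

        zp = ZExpressionMatrix(
            small_cohort_z.data[perm],
            degenerate_genes=small_cohort_z.degenerate_genes,
        )
        labels_p = assign_subtypes(zp)
        assert (labels_p[perm] == labels[perm]).all()

    def test_accuracy_monotone_in_immune_shift(self):
        """Raising the planted shift never lowers recovery (shared seed)."""
        accs = []
        for delta in (0.5, 1.0, 2.0, 3.0):
            c = generate_cohort(
                CohortConfig(n_samples=600, immune_shift=delta, seed=99)
            )
            labels = assign_subtypes(zscore(c.expression))
            truth = c.truth["subtype"]
            mask = truth != "unclassified"
            accs.append((labels[mask] == truth[mask]).mean())
        assert all(a <= b + 0.02 for a, b in zip(accs, accs[1:]))


class TestCytAct:
    def test_call_definitions(self):
        from timeprofiler.core import ZExpressionMatrix

        z = ZExpressionMatrix(
            pd.DataFrame(
                {"a": [1.0, 0.2], "b": [1.0, -0.2], "c": [-0.5, -0.1]},
                index=["GZMB", "PRF1"],
            )
        )
        calls = call_cytact(z)
        assert calls["a"] == "up"
        assert calls["b"] == "neither"
        assert calls["c"] == "down"

    def test_independent_null_gives_quarter_up(self):
        """Under independence P(both z > 0) = 1/4."""
        rng = np.random.default_rng(1)
        from timeprofiler.core import ZExpressionMatrix

        n = 10_000
        z = ZExpressionMatrix(
            pd.DataFrame(
                rng.standard_normal((2, n)),
                index=["GZMB", "PRF1"],
                columns=[f"s{i}" for i in range(n)],
            )
        )
        frac_up = (call_cytact(z) == "up").mean()
        assert frac_up == pytest.approx(0.25, abs=0.02)

    def test_alias_resolution(self):
        """Panels written with protein names find the HGNC rows."""
        from timeprofiler.core import ZExpressionMatrix

        z = ZExpressionMatrix(
            pd.DataFrame({"a": [1.0, 1.0]}, index=["GZMB", "PRF1"])
        )
        calls = call_cytact(z, up_genes=("Granzyme", "Perforin"))
        assert calls["a"] == "up"


class TestStratify:
    def test_definitions_inclusive_boundaries(self):
        from timeprofiler.core import ZExpressionMatrix

        z = ZExpressionMatrix(
            pd.DataFrame(
                {"a": [1.5], "b": [-1.2], "c": [0.3], "d": [1.0], "e": [-1.0]},
                index=["EP300"],
            )
        )
        s = stratify_expression(z, "EP300", 1.0)
        assert s.tolist() == ["high", "low", "mid", "high", "low"]

    def test_gaussian_tail_fraction(self):
        rng = np.random.default_rng(0)
        from timeprofiler.core import ZExpressionMatrix

        n = 20_000
        z = ZExpressionMatrix(
            pd.DataFrame(
                rng.standard_normal((1, n)),
                index=["EP300"],
                columns=[f"s{i}" for i in range(n)],
            )
        )
        s = stratify_expression(z, "EP300", 1.0)
        assert (s == "high").mean() == pytest.approx(norm.sf(1.0), abs=0.01)

    def test_kappa_zero_leaves_no_mid(self):
        from timeprofiler.core import ZExpressionMatrix

        z = ZExpressionMatrix(
            pd.DataFrame({"a": [0.4], "b": [-0.4], "c": [0.0]}, index=["G"])
        )
        s = stratify_expression(z, "G", 0.0)
        # z = 0 meets both inclusive bounds; the low rule is applied last
        assert s.tolist() == ["high", "low", "low"]
        assert "mid" not in set(s)


class TestSubtypeSummary:
    def test_table1_style_percentages(self):
        """9 HPV+ of 20 activated -> 45%; 6 of 100 absent -> 6%."""
        labels = (
            ["activated"] * 20 + ["suppressed"] * 35 + ["absent"] * 100
        )
        samples = [f"s{i}" for i in range(len(labels))]
        assignment = pd.Series(labels, index=samples)
        hpv = ["positive"] * 9 + ["negative"] * 11  # activated
        hpv += ["positive"] * 5 + ["negative"] * 30  # suppressed
        hpv += ["positive"] * 6 + ["negative"] * 94  # absent
        clinical = pd.DataFrame({"hpv_status": hpv}, index=samples)
        res = subtype_summary(assignment, clinical)
        tab = res.counts.set_index(["level", "subtype"])
        assert tab.loc[("positive", "activated"), "percent"] == 45
        assert tab.loc[("positive", "absent"), "percent"] == 6
        assert not res.pairwise_p.empty
        assert ((res.pairwise_p["p"] > 0) & (res.pairwise_p["p"] <= 1)).all()

    def test_empty_subtype_warns_and_skips(self):
        assignment = pd.Series(["activated", "absent"], index=["s1", "s2"])
        clinical = pd.DataFrame(
            {"hpv_status": ["positive", "negative"]}, index=["s1", "s2"]
        )
        with pytest.warns(UserWarning, match="suppressed"):
            res = subtype_summary(assignment, clinical)
        assert "suppressed" not in set(res.counts["subtype"])
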