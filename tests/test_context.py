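"""The context rule: essentiality from expression + medium, limiting
genes, linked knockouts."""

import numpy as np
import pandas as pd
import pytest

from ngmcs import (
    ActivityContext,
    CutSet,
    MetabolicModel,
    Metabolite,
    Reaction,
    apply_linked_knockouts,
    essential_elements,
    limiting_gene,
    max_target_flux,
    nutrient_dependency_matrix,
)
from ngmcs.model import DEFAULT_EPSILON, ModelError


def ctx(expr: dict, samples, threshold=1.0, presence=None):
    df = pd.DataFrame(expr, index=samples).T
    pres = None
    if presence is not None:
        pres = pd.DataFrame(presence, index=samples).T
    return ActivityContext(df, expression_threshold=threshold,
                           nutrient_presence=pres)


class TestEssentialElements:
    def test_nutrient_deprivation_makes_gene_essential(self):
        """An antifolate-style pair {gene, nutrient}: without the rescue
        nutrient, the gene is the only active element and becomes
        essential."""
        cs = CutSet.make({"DHFR", "Thymidine"}, {"Thymidine"})
        context = ctx({"DHFR": [40.0]}, ["s1"],
                      presence={"Thymidine": [False]})
        calls = essential_elements([cs], context, "s1")
        assert [c.element for c in calls] == ["DHFR"]
        assert calls[0].witnesses == (("DHFR", "Thymidine"),)

    def test_worked_three_element_cut(self):
        """{g1, g2, M2}: with g2 silent and M2 absent, g1 remains
        essential."""
        cs = CutSet.make({"g1", "g2", "M2"}, {"M2"})
        context = ctx({"g1": [8.0], "g2": [0.2]}, ["s1"],
                      presence={"M2": [False]})
        calls = essential_elements([cs], context, "s1")
        assert [c.element for c in calls] == ["g1"]

    def test_gene_losses_make_nutrient_essential(self):
        cs = CutSet.make({"g1", "g2", "M2"}, {"M2"})
        context = ctx({"g1": [0.0], "g2": [0.2]}, ["s1"])
        calls = essential_elements([cs], context, "s1")
        assert [c.element for c in calls] == ["M2"]

    def test_all_active_no_call(self):
        cs = CutSet.make({"g1", "g2", "M2"}, {"M2"})
        context = ctx({"g1": [8.0], "g2": [5.0]}, ["s1"])
        assert essential_elements([cs], context, "s1") == []

    def test_inactive_element_never_called(self):
        cs = CutSet.make({"g1", "g2"}, ())
        context = ctx({"g1": [0.0], "g2": [0.0]}, ["s1"])
        assert essential_elements([cs], context, "s1") == []

    def test_unmeasured_gene_treated_active_and_reported(self):
        cs = CutSet.make({"gUnknown", "g2"}, ())
        context = ctx({"g2": [0.0]}, ["s1"])
        calls = essential_elements([cs], context, "s1")
        assert [c.element for c in calls] == ["gUnknown"]
        assert context.unmeasured_genes([cs]) == ["gUnknown"]

    def test_unknown_sample_rejected(self):
        cs = CutSet.make({"g1"}, ())
        with pytest.raises(KeyError):
            essential_elements([cs], ctx({"g1": [1.0]}, ["s1"]), "s9")

    def test_threshold_monotone_for_active_witness(self):
        """For an element active at both thresholds, raising the threshold
        only deactivates other members, so calls are preserved."""
        cs = CutSet.make({"g1", "g2", "g3"}, ())
        expr = {"g1": [50.0], "g2": [0.5], "g3": [2.0]}
        low = essential_elements([cs], ctx(expr, ["s1"], threshold=1.0), "s1")
        high = essential_elements([cs], ctx(expr, ["s1"], threshold=5.0), "s1")
        low_elems = {c.element for c in low}
        high_elems = {c.element for c in high}
        assert low_elems == set()         # g3 still active at 1 TPM
        assert high_elems == {"g1"}       # g3 drops below 5 TPM
        assert low_elems <= high_elems


class TestNutrientDependencyMatrix:
    def test_auxotrophy_from_low_synthase(self):
        """Low expression of the biosynthetic gene makes its nutrient
        essential (inositol-synthase style); high expression does not."""
        cs = CutSet.make({"myo-Inositol", "ISYNA1"}, {"myo-Inositol"})
        context = ctx({"ISYNA1": [0.5, 50.0]}, ["aux", "proto"])
        mat = nutrient_dependency_matrix([cs], context)
        assert mat.at["myo-Inositol", "aux"] == 1
        assert mat.at["myo-Inositol", "proto"] == 0

    def test_matrix_matches_hand_truth_table(self):
        cutsets = [
            CutSet.make({"N1", "gA"}, {"N1"}),
            CutSet.make({"N2", "gA", "gB"}, {"N2"}),
        ]
        expr = {"gA": [0.0, 9.0, 0.0], "gB": [9.0, 9.0, 0.0]}
        context = ctx(expr, ["s1", "s2", "s3"])
        mat = nutrient_dependency_matrix(cutsets, context)
        expected = pd.DataFrame(
            [[1, 0, 1], [0, 0, 1]],
            index=["N1", "N2"],
            columns=["s1", "s2", "s3"],
        )
        pd.testing.assert_frame_equal(mat, expected)

    def test_consistent_with_per_sample_calls(self):
        cutsets = [CutSet.make({"N1", "gA"}, {"N1"})]
        context = ctx({"gA": [0.0, 5.0]}, ["s1", "s2"])
        mat = nutrient_dependency_matrix(cutsets, context)
        for sample in context.samples:
            called = {
                c.element for c in essential_elements(cutsets, context, sample)
            }
            assert mat.at["N1", sample] == int("N1" in called)


class TestLimitingGene:
    def test_max_within_one_cut_set(self):
        """Partners within one cut set are alternatives: the best-expressed
        one is the limiting value."""
        cs = CutSet.make({"N", "gA", "gB"}, {"N"})
        expr = pd.DataFrame({"s1": {"gA": 0.2, "gB": 3.1}})
        gene, value = limiting_gene([cs], expr, "s1", nutrient="N")
        assert (gene, value) == ("gB", 3.1)

    def test_min_across_cut_sets_is_weakest_backup_step(self):
        """Each cut set is one essential step of the backup route; the
        route fails at its weakest step, so 0.2 and 0.4 give 0.2 and the
        sample is auxotrophic at 1 TPM — consistently with the
        only-active-element rule, which already fires via {N, gA}."""
        cutsets = [
            CutSet.make({"N", "gA"}, {"N"}),
            CutSet.make({"N", "gB"}, {"N"}),
        ]
        expr = pd.DataFrame({"s1": {"gA": 0.2, "gB": 0.4}})
        gene, value = limiting_gene(cutsets, expr, "s1", nutrient="N")
        assert (gene, value) == ("gA", 0.2)
        assert value < 1.0

    def test_unconditional_nutrient_has_no_backup(self):
        cs = CutSet.make({"N"}, {"N"})
        gene, value = limiting_gene([cs], pd.DataFrame(), "s1", nutrient="N")
        assert gene is None and value == 0.0

    def test_below_threshold_iff_called_essential(self):
        """The limiting value crosses the threshold exactly when the
        essentiality rule calls the nutrient (measured genes, nutrient
        present)."""
        rng = np.random.default_rng(7)
        cutsets = [
            CutSet.make({"N", "gA"}, {"N"}),
            CutSet.make({"N", "gB", "gC"}, {"N"}),
        ]
        for _ in range(20):
            tpm = {g: float(rng.uniform(0, 3)) for g in ["gA", "gB", "gC"]}
            expr = pd.DataFrame({"s1": tpm})
            context = ActivityContext(expr)
            _, value = limiting_gene(cutsets, expr, "s1", nutrient="N")
            called = {
                c.element
                for c in essential_elements(cutsets, context, "s1")
            }
            assert (value < 1.0) == ("N" in called)

    def test_nutrient_absent_from_all_cut_sets(self):
        cs = CutSet.make({"M", "gA"}, {"M"})
        with pytest.raises(ValueError, match="absent"):
            limiting_gene([cs], pd.DataFrame(), "s1", nutrient="N")


class TestLinkedKnockouts:
    @pytest.fixture()
    def diamond(self):
        """Nutrient feeds the target through a gene route and a gene-less
        alternative rY; only a linked knockout can sever both."""
        from ngmcs.gpr import parse_gpr

        model = MetabolicModel(
            metabolites={m: Metabolite(m) for m in ["N", "C"]},
            reactions={
                "ex": Reaction("ex", {"N": -1.0}, -1.0, 1000.0),
                "rX": Reaction("rX", {"N": -1.0, "C": 1.0}, 0.0, 1000.0,
                               parse_gpr("gX")),
                "rY": Reaction("rY", {"N": -1.0, "C": 1.0}, 0.0, 1000.0),
                "bio": Reaction("bio", {"C": -1.0}, 0.0, 1000.0),
            },
            genes=["gX"],
            biomass_reaction_id="bio",
        )
        model.validate()
        return model

    def test_linked_reactions_zeroed(self, diamond):
        out = apply_linked_knockouts(diamond, "gX", {"gX": ["rY"]})
        assert out.reactions["rX"].upper_bound == 0.0
        assert out.reactions["rY"].upper_bound == 0.0

    def test_plain_knockout_without_links(self, diamond):
        out = apply_linked_knockouts(diamond, "gX", {})
        assert out.reactions["rX"].upper_bound == 0.0
        assert out.reactions["rY"].upper_bound == 1000.0

    def test_gene_lethal_only_with_links(self, diamond):
        plain = apply_linked_knockouts(diamond, "gX", {})
        linked = apply_linked_knockouts(diamond, "gX", {"gX": ["rY"]})
        assert max_target_flux(plain, "bio") > DEFAULT_EPSILON
        assert max_target_flux(linked, "bio") < DEFAULT_EPSILON

    def test_unknown_linked_reaction_rejected(self, diamond):
        with pytest.raises(ModelError, match="r99"):
            apply_linked_knockouts(diamond, "gX", {"gX": ["r99"]})
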