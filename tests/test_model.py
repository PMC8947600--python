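"""Model structure, media, the flux LP oracle, and the irreversible split."""

import math

import pytest

from ngmcs import (
    Medium,
    MediumEntry,
    MetabolicModel,
    Metabolite,
    PatchOp,
    Reaction,
    apply_medium,
    apply_patch,
    find_input_exchanges,
    max_target_flux,
    random_network,
    split_reversible,
    toy_network,
)
from ngmcs.fixtures import FixtureSpec
from ngmcs.model import (
    ConfigurationError,
    DEFAULT_EPSILON,
    ModelError,
    reactions_disabled_by_genes,
)


class TestInvariants:
    def test_toy_models_validate(self, cm1, cm2):
        cm1[0].validate()
        cm2[0].validate()
        assert len(cm1[0].reactions) == 6  # 5 pathway reactions + biomass
        assert len(cm1[0].metabolites) == 4
        assert cm1[0].genes == ["g1", "g2", "g3"]

    def test_bounds_must_be_ordered(self, cm1):
        model = cm1[0].copy()
        model.reactions["r1"].lower_bound = 5.0
        model.reactions["r1"].upper_bound = 1.0
        with pytest.raises(ModelError, match="lower bound"):
            model.validate()

    def test_zero_coefficient_rejected(self, cm1):
        model = cm1[0].copy()
        model.reactions["r1"].stoichiometry["A"] = 0.0
        with pytest.raises(ModelError, match="coefficient"):
            model.validate()

    def test_missing_biomass_rejected(self, cm1):
        model = cm1[0].copy()
        model.biomass_reaction_id = "nope"
        with pytest.raises(ConfigurationError, match="biomass"):
            model.validate()

    def test_uncatalogued_gpr_gene_rejected(self, cm1):
        model = cm1[0].copy()
        model.genes = ["g1", "g2"]
        with pytest.raises(ModelError, match="g3"):
            model.validate()


class TestInputExchanges:
    def test_cm1_single_nutrient(self, cm1):
        assert find_input_exchanges(cm1[0]) == ["r_E1"]

    def test_cm2_two_nutrients(self, cm2):
        assert set(find_input_exchanges(cm2[0])) == {"r_E1", "r_E2"}

    def test_internal_only_model(self):
        model = MetabolicModel(
            metabolites={"A": Metabolite("A"), "B": Metabolite("B")},
            reactions={"r": Reaction("r", {"A": -1.0, "B": 1.0})},
            genes=[],
            biomass_reaction_id="r",
        )
        assert find_input_exchanges(model) == []


class TestApplyMedium:
    def test_sub_medium_turns_cm2_into_cm1(self, cm2):
        model, _ = cm2
        restricted = apply_medium(
            model, Medium([MediumEntry("M1", "r_E1", 1.0)])
        )
        assert restricted.reactions["r_E2"].lower_bound == 0.0
        knocked = reactions_disabled_by_genes(restricted, {"g1", "g2"})
        assert max_target_flux(restricted, "biomass", knocked) < DEFAULT_EPSILON

    def test_full_medium_opens_both(self, cm2):
        model, medium = cm2
        out = apply_medium(model, medium)
        assert out.reactions["r_E1"].lower_bound == -1.0
        assert out.reactions["r_E2"].lower_bound == -1.0

    def test_empty_medium_starves(self, cm1):
        starved = apply_medium(cm1[0], Medium([]))
        assert max_target_flux(starved, "biomass") < DEFAULT_EPSILON

    def test_idempotent(self, cm2):
        model, medium = cm2
        once = apply_medium(model, medium)
        twice = apply_medium(once, medium)
        for rid in model.reactions:
            assert once.reactions[rid].lower_bound == twice.reactions[rid].lower_bound
            assert once.reactions[rid].upper_bound == twice.reactions[rid].upper_bound

    def test_unknown_exchange_rejected(self, cm1):
        with pytest.raises(ConfigurationError):
            apply_medium(cm1[0], Medium([MediumEntry("M9", "r_E9", 1.0)]))

    def test_unbounded_uptake_uses_big_bound(self, cm1):
        out = apply_medium(
            cm1[0], Medium([MediumEntry("M1", "r_E1", math.inf)])
        )
        assert out.reactions["r_E1"].lower_bound == -1000.0

    def test_monotone_in_medium(self):
        """Fewer nutrients can never increase achievable growth."""
        for seed in range(5):
            model, medium = random_network(FixtureSpec(seed=seed))
            full = apply_medium(model, medium)
            sub = apply_medium(model, Medium(medium.entries[:1]))
            assert (
                max_target_flux(sub, "biomass")
                <= max_target_flux(full, "biomass") + 1e-9
            )


class TestApplyPatch:
    def test_delete_rescue_route_recovers_cm1(self, cm1, cm2):
        patched = apply_patch(cm2[0], [PatchOp("delete", "r5")])
        # r_E2 remains but the rescue pathway is gone: same lethality as CM1
        knocked = reactions_disabled_by_genes(patched, {"g1", "g2"})
        assert max_target_flux(patched, "biomass", knocked) < DEFAULT_EPSILON
        assert set(patched.reactions) == set(cm1[0].reactions) | {"r_E2"}

    def test_empty_patch_is_identity(self, cm1):
        out = apply_patch(cm1[0], [])
        assert set(out.reactions) == set(cm1[0].reactions)

    def test_deleting_biomass_rejected(self, cm1):
        with pytest.raises(ConfigurationError, match="biomass"):
            apply_patch(cm1[0], [PatchOp("delete", "biomass")])

    def test_unknown_reaction_named(self, cm1):
        with pytest.raises(ModelError, match="r99"):
            apply_patch(cm1[0], [PatchOp("delete", "r99")])

    def test_set_bounds(self, cm1):
        out = apply_patch(
            cm1[0], [PatchOp("set_bounds", "r1", 0.0, 5.0)]
        )
        assert out.reactions["r1"].upper_bound == 5.0


class TestMaxTargetFlux:
    def test_wild_type_grows(self, cm1):
        assert max_target_flux(cm1[0], "biomass") > DEFAULT_EPSILON

    def test_synthetic_lethal_pair_blocks_cm1(self, cm1):
        knocked = reactions_disabled_by_genes(cm1[0], {"g1", "g2"})
        assert max_target_flux(cm1[0], "biomass", knocked) < DEFAULT_EPSILON

    def test_pair_rescued_in_cm2(self, cm2):
        knocked = reactions_disabled_by_genes(cm2[0], {"g1", "g2"})
        assert max_target_flux(cm2[0], "biomass", knocked) > DEFAULT_EPSILON

    def test_single_knockouts_viable(self, cm1):
        for gene in ["g1", "g2"]:
            knocked = reactions_disabled_by_genes(cm1[0], {gene})
            assert max_target_flux(cm1[0], "biomass", knocked) > DEFAULT_EPSILON

    def test_unknown_target_rejected(self, cm1):
        with pytest.raises(ModelError):
            max_target_flux(cm1[0], "nope")


class TestSplitReversible:
    def test_reversible_reaction_becomes_pair(self):
        model = MetabolicModel(
            metabolites={"A": Metabolite("A"), "B": Metabolite("B")},
            reactions={
                "ex_A": Reaction("ex_A", {"A": -1.0}, -1.0, 1000.0),
                "conv": Reaction("conv", {"A": -1.0, "B": 1.0}, -1000.0, 1000.0),
                "bio": Reaction("bio", {"B": -1.0}, 0.0, 1000.0),
            },
            genes=[],
            biomass_reaction_id="bio",
        )
        irr = split_reversible(model)
        cols = irr.columns_of("conv")
        assert len(cols) == 2
        fwd, back = (irr.model.reactions[c] for c in cols)
        assert fwd.stoichiometry == {"A": -1.0, "B": 1.0}
        assert back.stoichiometry == {"A": 1.0, "B": -1.0}
        assert all(r.lower_bound >= 0 for r in irr.model.reactions.values())

    def test_irreversible_model_unchanged(self, cm1):
        irr = split_reversible(cm1[0])
        # the only backward column is the exchange's uptake direction
        assert set(irr.backward) == {"r_E1"}
        assert set(irr.forward) == set(cm1[0].reactions)

    def test_flux_preserved_on_random_fixtures(self):
        """LP equivalence of the split: same biomass maximum, with and
        without knockouts, on 20 random fixtures."""
        for seed in range(20):
            model, medium = random_network(FixtureSpec(seed=seed))
            grown = apply_medium(model, medium)
            irr = split_reversible(grown)
            assert max_target_flux(grown, "biomass") == pytest.approx(
                max_target_flux(irr.model, "biomass"), abs=1e-6
            )
            some_gene = grown.genes[0]
            knocked = reactions_disabled_by_genes(grown, {some_gene})
            knocked_irr = {
                c for rid in knocked for c in irr.columns_of(rid)
            }
            assert max_target_flux(grown, "biomass", knocked) == pytest.approx(
                max_target_flux(irr.model, "biomass", knocked_irr), abs=1e-6
            )
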