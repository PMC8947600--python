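"""Constraint-based metabolic models, growth media, and the flux LP oracle.

The central object is :class:`MetabolicModel`: a stoichiometric matrix S
over metabolites × reactions, flux bounds ``lb ≤ v ≤ ub``, a boolean GPR
rule per reaction, and a designated biomass reaction whose maximal
steady-state flux (``max v_biomass  s.t.  S v = 0, lb ≤ v ≤ ub``) proxies
the proliferation capacity of the cell. A knockout set "blocks" growth
when that LP maximum falls below a small tolerance.

Exchange convention
-------------------
Boundary exchanges are written as export reactions (``metabolite → ∅``);
uptake is negative flux, so a nutrient is *available* when the exchange's
lower bound is negative and *deprived* when it is zero. Uptake limits are
the millimolar concentrations of the growth-medium formulation, used
directly as bounds in mmol·gDW⁻¹·h⁻¹; "unbounded" is encoded as the
conventional big bound of 1000. Import-written exchanges (``∅ →
metabolite``) are also recognized for interoperability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import lil_matrix

from . import gpr as gpr_mod
from .gpr import GPR, TRUE

#: Conventional bound standing in for "unbounded" flux (mmol·gDW⁻¹·h⁻¹).
DEFAULT_BOUND = 1000.0

#: A target is considered blocked when its LP maximum is below this.
DEFAULT_EPSILON = 1e-6


class ModelError(ValueError):
    """Invalid model structure or an operation referencing unknown elements."""


class ConfigurationError(ModelError):
    """Model/medium/patch configuration violates a documented invariant."""


class EngineError(RuntimeError):
    """Underlying LP/MILP solver failed; carries the solver status."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""


@dataclass
class Reaction:
    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    gpr: GPR = TRUE
    name: str = ""

    @property
    def gene_reaction_rule(self) -> str:
        return gpr_mod.to_string(self.gpr)


@dataclass
class MetabolicModel:
    """A stoichiometric model with bounds, GPR rules and a biomass target."""

    metabolites: Dict[str, Metabolite]
    reactions: Dict[str, Reaction]
    genes: List[str]
    biomass_reaction_id: str
    id: str = "model"

    def validate(self) -> None:
        """Check the structural invariants; raise :class:`ModelError` on the
        first violation."""
        if self.biomass_reaction_id not in self.reactions:
            raise ConfigurationError(
                f"biomass reaction {self.biomass_reaction_id!r} not in model"
            )
        catalogue = set(self.genes)
        for rxn in self.reactions.values():
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelError(
                    f"reaction {rxn.id}: lower bound {rxn.lower_bound} "
                    f"> upper bound {rxn.upper_bound}"
                )
            for met, coef in rxn.stoichiometry.items():
                if met not in self.metabolites:
                    raise ModelError(
                        f"reaction {rxn.id}: unknown metabolite {met!r}"
                    )
                if not math.isfinite(coef) or coef == 0.0:
                    raise ModelError(
                        f"reaction {rxn.id}: coefficient {coef} for {met!r}"
                    )
            missing = gpr_mod.genes_in(rxn.gpr) - catalogue
            if missing:
                raise ModelError(
                    f"reaction {rxn.id}: GPR genes not in catalogue: "
                    f"{sorted(missing)}"
                )

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites={m: replace(v) for m, v in self.metabolites.items()},
            reactions={
                r: replace(v, stoichiometry=dict(v.stoichiometry))
                for r, v in self.reactions.items()
            },
            genes=list(self.genes),
            biomass_reaction_id=self.biomass_reaction_id,
            id=self.id,
        )

    def reaction_order(self) -> List[str]:
        return list(self.reactions)


@dataclass
class MediumEntry:
    """One nutrient: extracellular metabolite, its input exchange reaction,
    and the maximum uptake in mmol·gDW⁻¹·h⁻¹ (``inf`` = unbounded)."""

    metabolite_id: str
    exchange_id: str
    max_uptake: float = math.inf


@dataclass
class Medium:
    """A growth medium: which input exchanges are open and at what limit."""

    entries: List[MediumEntry] = field(default_factory=list)

    def validate_against(self, model: MetabolicModel) -> None:
        inputs = set(find_input_exchanges(model))
        seen = set()
        for e in self.entries:
            if e.exchange_id not in model.reactions:
                raise ConfigurationError(
                    f"medium exchange {e.exchange_id!r} not in model"
                )
            if e.exchange_id not in inputs:
                raise ConfigurationError(
                    f"{e.exchange_id!r} is not an input exchange reaction"
                )
            key = (e.metabolite_id, e.exchange_id)
            if key in seen:
                raise ConfigurationError(
                    f"nutrient {e.metabolite_id!r} listed twice for "
                    f"{e.exchange_id!r}"
                )
            seen.add(key)

    def nutrient_ids(self) -> List[str]:
        return [e.metabolite_id for e in self.entries]

    def exchange_of(self, metabolite_id: str) -> str:
        for e in self.entries:
            if e.metabolite_id == metabolite_id:
                return e.exchange_id
        raise KeyError(metabolite_id)


@dataclass
class PatchOp:
    """One model correction: ``delete`` a reaction or ``set_bounds``."""

    action: str  # "delete" | "set_bounds"
    reaction_id: str
    lower_bound: Optional[float] = None
    upper_bound: Optional[float] = None


def is_exchange(rxn: Reaction) -> bool:
    return len(rxn.stoichiometry) == 1


def _import_capacity(rxn: Reaction) -> float:
    """How much net import the bounds allow (0 when closed to import)."""
    ((_, coef),) = rxn.stoichiometry.items()
    if coef < 0:  # export-written: import is negative flux
        return max(0.0, -rxn.lower_bound)
    return max(0.0, rxn.upper_bound)


def find_input_exchanges(model: MetabolicModel) -> List[str]:
    """Reactions that exchange a single metabolite with the environment and
    whose bounds permit net import of it."""
    return [
        r.id
        for r in model.reactions.values()
        if is_exchange(r) and _import_capacity(r) > 0
    ]


def apply_patch(
    model: MetabolicModel, patch: Sequence[PatchOp]
) -> MetabolicModel:
    """Apply deletions and bound edits (model-curation corrections).

    Deleting the biomass reaction is a configuration error; unknown
    reaction ids are reported by name.
    """
    out = model.copy()
    for op in patch:
        if op.reaction_id not in out.reactions:
            raise ModelError(f"patch references unknown reaction {op.reaction_id!r}")
        if op.action == "delete":
            if op.reaction_id == out.biomass_reaction_id:
                raise ConfigurationError("patch would delete the biomass reaction")
            del out.reactions[op.reaction_id]
        elif op.action == "set_bounds":
            rxn = out.reactions[op.reaction_id]
            if op.lower_bound is not None:
                rxn.lower_bound = op.lower_bound
            if op.upper_bound is not None:
                rxn.upper_bound = op.upper_bound
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelError(
                    f"patch leaves {op.reaction_id} with lb > ub"
                )
        else:
            raise ModelError(f"unknown patch action {op.action!r}")
    out.validate()
    return out


def apply_medium(model: MetabolicModel, medium: Medium) -> MetabolicModel:
    """Open the listed input exchanges at their uptake limits and close every
    other input exchange to import; the export direction is untouched.

    Idempotent: applying the same medium twice yields the same bounds.
    """
    medium.validate_against(model)
    out = model.copy()
    listed = {e.exchange_id: e for e in medium.entries}
    for rid in find_input_exchanges(model):
        rxn = out.reactions[rid]
        ((_, coef),) = rxn.stoichiometry.items()
        if rid in listed:
            uptake = listed[rid].max_uptake
            if not math.isfinite(uptake):
                uptake = DEFAULT_BOUND
            if coef < 0:
                rxn.lower_bound = -uptake
            else:
                rxn.upper_bound = uptake
        else:
            if coef < 0:
                rxn.lower_bound = max(rxn.lower_bound, 0.0)
            else:
                rxn.upper_bound = min(rxn.upper_bound, 0.0)
                rxn.lower_bound = min(rxn.lower_bound, rxn.upper_bound)
    return out


def reactions_disabled_by_genes(
    model: MetabolicModel, inactive_genes: Iterable[str]
) -> Set[str]:
    """Reactions whose GPR evaluates false with the given genes inactive.

    Gene-less reactions (GPR = TRUE) are never disabled by genes.
    """
    inactive = set(inactive_genes)
    return {
        r.id
        for r in model.reactions.values()
        if r.gpr is not TRUE and not gpr_mod.evaluate(r.gpr, inactive)
    }


def _stoichiometric_matrix(model: MetabolicModel):
    met_index = {m: i for i, m in enumerate(model.metabolites)}
    rxn_ids = model.reaction_order()
    S = lil_matrix((len(met_index), len(rxn_ids)))
    for j, rid in enumerate(rxn_ids):
        for met, coef in model.reactions[rid].stoichiometry.items():
            S[met_index[met], j] = coef
    return S.tocsr(), rxn_ids


def max_target_flux(
    model: MetabolicModel,
    target: str,
    knocked_reactions: Iterable[str] = (),
) -> float:
    """LP maximum of the target flux under steady state, bounds, and zero
    flux on the knocked reactions.

    This is the blocking oracle: a knockout set is a cut when this value
    drops below the blocked-flux tolerance.
    """
    knocked = set(knocked_reactions)
    unknown = knocked - set(model.reactions)
    if unknown:
        raise ModelError(f"knocked reactions not in model: {sorted(unknown)}")
    if target not in model.reactions:
        raise ModelError(f"target reaction {target!r} not in model")
    S, rxn_ids = _stoichiometric_matrix(model)
    n = len(rxn_ids)
    bounds = []
    for rid in rxn_ids:
        if rid in knocked:
            bounds.append((0.0, 0.0))
        else:
            r = model.reactions[rid]
            bounds.append((r.lower_bound, r.upper_bound))
    c = np.zeros(n)
    c[rxn_ids.index(target)] = -1.0  # linprog minimizes
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
    )
    if res.status == 2:  # infeasible (only possible with forced fluxes)
        return 0.0
    if not res.success:
        raise EngineError(f"LP solver failed: status {res.status} ({res.message})")
    return -res.fun


@dataclass
class IrreversibleModel:
    """Forward-only rewrite of a model, for the duality construction.

    Every reversible reaction becomes a forward/backward pair with swapped
    stoichiometry; the mapping back to original reaction ids is retained so
    that knocking an original reaction removes both directions. Reactions
    with zero capacity in a direction contribute no column for it, so every
    column can carry strictly positive flux.
    """

    model: MetabolicModel
    source: MetabolicModel
    forward: Dict[str, str]
    backward: Dict[str, str]

    def columns_of(self, original_id: str) -> List[str]:
        cols = []
        if original_id in self.forward:
            cols.append(self.forward[original_id])
        if original_id in self.backward:
            cols.append(self.backward[original_id])
        return cols


def split_reversible(model: MetabolicModel) -> IrreversibleModel:
    """Rewrite every reaction as forward-only; feasible flux projections are
    identical and ``max_target_flux`` is preserved for every target and
    knockout set."""
    irr = MetabolicModel(
        metabolites={m: replace(v) for m, v in model.metabolites.items()},
        reactions={},
        genes=list(model.genes),
        biomass_reaction_id=model.biomass_reaction_id,
        id=model.id + "_irrev",
    )
    forward: Dict[str, str] = {}
    backward: Dict[str, str] = {}
    for rid, rxn in model.reactions.items():
        if rxn.upper_bound > 0:
            forward[rid] = rid
            irr.reactions[rid] = Reaction(
                id=rid,
                stoichiometry=dict(rxn.stoichiometry),
                lower_bound=max(rxn.lower_bound, 0.0),
                upper_bound=rxn.upper_bound,
                gpr=rxn.gpr,
                name=rxn.name,
            )
        if rxn.lower_bound < 0:
            bid = rid + "__rev"
            while bid in model.reactions:
                bid += "_"
            backward[rid] = bid
            irr.reactions[bid] = Reaction(
                id=bid,
                stoichiometry={m: -c for m, c in rxn.stoichiometry.items()},
                lower_bound=max(-rxn.upper_bound, 0.0),
                upper_bound=-rxn.lower_bound,
                gpr=rxn.gpr,
                name=rxn.name,
            )
    if model.biomass_reaction_id not in forward:
        raise ConfigurationError(
            "biomass reaction has no forward capacity; cannot pose the target"
        )
    return IrreversibleModel(
        model=irr, source=model, forward=forward, backward=backward
    )
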