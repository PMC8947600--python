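"""Toy and random fixture networks.

``toy_network`` regenerates the two-medium example network used throughout
the docs and tests: a cell that must produce metabolite C to grow, fed by
nutrient M1 through two gene-dependent branches, with (CM2) or without
(CM1) a gene-less rescue route from a second nutrient M2. The topology is
a reconstruction — the smallest network consistent with the published
lethality statements — and is isolated here so it can be swapped if the
diagram is read differently:

    r_E1:  M1 exchange              r1: M1 -> A   (g1)
    r2:    M1 -> B   (g2)           r3: A  -> C   (g3)
    r4:    B  -> C   (g3)           biomass: C ->
    CM2 adds   r_E2: M2 exchange    r5: M2 -> C   (gene-less)

Under CM1, {g1, g2} is a synthetic lethal pair and {g3} a single lethal;
under CM2 no purely genetic cut exists (the M2 route has no gene), and the
worked nutrient-genetic cut set {g1, g2, M2} appears.

``random_network`` draws small, connected, growing pathway networks with
random AND/OR GPR rules for property-test campaigns; deterministic per
seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from . import gpr as gpr_mod
from .gmatrix import build_g_matrix, extend_with_nutrients
from .model import (
    DEFAULT_BOUND,
    DEFAULT_EPSILON,
    Medium,
    MediumEntry,
    Metabolite,
    MetabolicModel,
    Reaction,
    apply_medium,
    max_target_flux,
)

#: Default uptake limit for fixture media (mmol·gDW⁻¹·h⁻¹ ≙ 1 mM).
FIXTURE_UPTAKE = 1.0


class FixtureError(RuntimeError):
    """Raised when a random fixture cannot be made to grow."""


@dataclass
class FixtureSpec:
    """Parameters of a random fixture network."""

    fixture_id: str = "random"
    n_metabolites: int = 6
    n_reactions: int = 8
    n_genes: int = 5
    n_nutrients: int = 2
    gpr_probability: float = 0.75
    reversible_probability: float = 0.2
    max_knockout_units: int = 12
    seed: int = 0
    retry_cap: int = 40


def toy_network(medium_id: str) -> Tuple[MetabolicModel, Medium]:
    """The CM1 or CM2 toy network with its declared medium.

    The returned model already carries the medium bounds (1 mM uptake per
    nutrient), so it grows as returned; the Medium object is returned
    alongside for explicit `apply_medium` experiments.
    """
    if medium_id not in {"CM1", "CM2"}:
        raise ValueError(f"unknown toy fixture {medium_id!r} (CM1 or CM2)")
    mets = {
        m: Metabolite(m, compartment="c") for m in ["M1", "A", "B", "C"]
    }
    rxns = {
        "r_E1": Reaction("r_E1", {"M1": -1.0}, -FIXTURE_UPTAKE, DEFAULT_BOUND),
        "r1": Reaction("r1", {"M1": -1.0, "A": 1.0}, 0.0, DEFAULT_BOUND,
                       gpr_mod.parse_gpr("g1")),
        "r2": Reaction("r2", {"M1": -1.0, "B": 1.0}, 0.0, DEFAULT_BOUND,
                       gpr_mod.parse_gpr("g2")),
        "r3": Reaction("r3", {"A": -1.0, "C": 1.0}, 0.0, DEFAULT_BOUND,
                       gpr_mod.parse_gpr("g3")),
        "r4": Reaction("r4", {"B": -1.0, "C": 1.0}, 0.0, DEFAULT_BOUND,
                       gpr_mod.parse_gpr("g3")),
        "biomass": Reaction("biomass", {"C": -1.0}, 0.0, DEFAULT_BOUND),
    }
    entries = [MediumEntry("M1", "r_E1", FIXTURE_UPTAKE)]
    if medium_id == "CM2":
        mets["M2"] = Metabolite("M2", compartment="c")
        rxns["r_E2"] = Reaction(
            "r_E2", {"M2": -1.0}, -FIXTURE_UPTAKE, DEFAULT_BOUND
        )
        rxns["r5"] = Reaction("r5", {"M2": -1.0, "C": 1.0}, 0.0, DEFAULT_BOUND)
        entries.append(MediumEntry("M2", "r_E2", FIXTURE_UPTAKE))
    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        genes=["g1", "g2", "g3"],
        biomass_reaction_id="biomass",
        id=f"toy_{medium_id}",
    )
    model.validate()
    return model, Medium(entries)


#: Cut-set families of the toy networks, confirmed by the brute-force
#: oracle (nutrient-only sets are listed like any other; see docs).
GOLDEN_FAMILIES = {
    ("CM1", "genes"): [frozenset({"g3"}), frozenset({"g1", "g2"})],
    ("CM1", "full"): [
        frozenset({"M1"}),
        frozenset({"g3"}),
        frozenset({"g1", "g2"}),
    ],
    ("CM2", "genes"): [],
    ("CM2", "full"): [
        frozenset({"M1", "M2"}),
        frozenset({"M2", "g3"}),
        frozenset({"M2", "g1", "g2"}),
    ],
}


def _random_gpr(rng: np.random.Generator, pool: List[str]):
    """A random AND/OR tree over at most 4 genes from the pool."""
    shape = rng.integers(0, 5)
    k = min(len(pool), 4)
    picks = [str(p) for p in rng.choice(pool, size=k, replace=False)]
    g = [gpr_mod.Gene(p) for p in picks]
    if shape == 0 or len(picks) < 2:
        return g[0]
    if shape == 1:
        return gpr_mod.Or((g[0], g[1]))
    if shape == 2:
        return gpr_mod.And((g[0], g[1]))
    if shape == 3 and len(picks) >= 3:
        return gpr_mod.Or((g[0], gpr_mod.And((g[1], g[2]))))
    if len(picks) >= 3:
        return gpr_mod.And((g[0], gpr_mod.Or((g[1], g[2]))))
    return gpr_mod.And((g[0], g[1]))


def random_network(spec: FixtureSpec) -> Tuple[MetabolicModel, Medium]:
    """A connected, growing random pathway network (deterministic per seed).

    Structure: nutrients feed a topologically ordered chain of internal
    metabolites ending in a biomass precursor; every non-nutrient
    metabolite receives at least one producing reaction from an earlier
    one, extra edges are added up to ``n_reactions``, and internal
    reactions get random GPR trees. Draws failing the generation checks
    (positive wild-type growth; at most ``max_knockout_units`` G-matrix
    rows including nutrient rows) are rejected and redrawn up to
    ``retry_cap`` times.
    """
    rng = np.random.default_rng(spec.seed)
    for _ in range(spec.retry_cap):
        model, medium = _draw(rng, spec)
        grown = apply_medium(model, medium)
        if max_target_flux(grown, model.biomass_reaction_id) <= 10 * DEFAULT_EPSILON:
            continue
        g = build_g_matrix(model)
        g = extend_with_nutrients(g, grown, medium)
        if len(g.rows) > spec.max_knockout_units:
            continue
        return model, medium
    raise FixtureError(
        f"could not draw a growing fixture for seed {spec.seed} "
        f"within {spec.retry_cap} attempts"
    )


def _draw(rng: np.random.Generator, spec: FixtureSpec):
    n_nut = max(1, spec.n_nutrients)
    nutrients = [f"N{i + 1}" for i in range(n_nut)]
    n_internal = max(2, spec.n_metabolites - n_nut)
    internal = [f"X{i + 1}" for i in range(n_internal)]
    order = nutrients + internal  # topological order; last is the precursor
    target_met = internal[-1]

    mets = {m: Metabolite(m, compartment="c") for m in order}
    rxns = {}
    for i, nut in enumerate(nutrients):
        rxns[f"r_E{i + 1}"] = Reaction(
            f"r_E{i + 1}", {nut: -1.0}, -FIXTURE_UPTAKE, DEFAULT_BOUND
        )

    genes = [f"g{i + 1}" for i in range(spec.n_genes)]
    counter = itertools.count(1)

    def add_internal(src: str, dst: str):
        rid = f"r{next(counter)}"
        rev = rng.random() < spec.reversible_probability
        lb = -DEFAULT_BOUND if rev else 0.0
        gpr = (
            _random_gpr(rng, genes)
            if rng.random() < spec.gpr_probability
            else gpr_mod.TRUE
        )
        rxns[rid] = Reaction(
            rid, {src: -1.0, dst: 1.0}, lb, DEFAULT_BOUND, gpr
        )

    # connectivity backbone: every internal metabolite is produced from an
    # earlier one
    for k, met in enumerate(internal):
        earlier = order[: n_nut + k]
        add_internal(str(rng.choice(earlier)), met)
    # extra random edges (always pointing later in the order)
    extra = max(0, spec.n_reactions - n_internal)
    for _ in range(extra):
        j = int(rng.integers(1, len(order)))
        i = int(rng.integers(0, j))
        add_internal(order[i], order[j])

    rxns["biomass"] = Reaction("biomass", {target_met: -1.0}, 0.0, DEFAULT_BOUND)
    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        genes=genes,
        biomass_reaction_id="biomass",
        id=f"random_seed{spec.seed}",
    )
    model.validate()
    medium = Medium(
        [
            MediumEntry(nut, f"r_E{i + 1}", FIXTURE_UPTAKE)
            for i, nut in enumerate(nutrients)
        ]
    )
    return model, medium
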