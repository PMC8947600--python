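"""The binary G matrix: knockout units × reactions.

Each row is a *knockout unit* — either a minimal set of genes whose joint
loss disables at least one reaction, or a single nutrient standing for the
knockout of its input exchange reaction. Entry (i, j) is 1 iff knocking
out row i's members disables reaction j. Gene rows arise from the minimal
falsifying sets of the GPR rules; nutrient rows are the augmentation that
turns genetic cut-set search into nutrient-genetic cut-set search, one row
per nutrient in the environment with a single nonzero column (its input
exchange reaction) — conceptually an artificial gene per input exchange.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

import numpy as np

from . import gpr as gpr_mod
from .gpr import TRUE
from .model import ConfigurationError, Medium, MetabolicModel

GENE_SET = "gene_set"
NUTRIENT = "nutrient"


@dataclass(frozen=True)
class KnockoutUnit:
    """One G-matrix row: a gene set or a single nutrient, plus the reactions
    its knockout disables (the row's column support)."""

    kind: str
    members: FrozenSet[str]
    disabled_reactions: FrozenSet[str]

    def __post_init__(self):
        if self.kind == NUTRIENT and len(self.disabled_reactions) != 1:
            raise ValueError(
                "a nutrient unit disables exactly its input exchange"
            )


@dataclass(frozen=True)
class GMatrix:
    rows: Tuple[KnockoutUnit, ...]
    reaction_ids: Tuple[str, ...]

    def __len__(self):
        return len(self.rows)

    @property
    def gene_rows(self) -> Tuple[KnockoutUnit, ...]:
        return tuple(r for r in self.rows if r.kind == GENE_SET)

    @property
    def nutrient_rows(self) -> Tuple[KnockoutUnit, ...]:
        return tuple(r for r in self.rows if r.kind == NUTRIENT)

    @property
    def nutrient_ids(self) -> FrozenSet[str]:
        out: Set[str] = set()
        for r in self.nutrient_rows:
            out |= r.members
        return frozenset(out)

    @property
    def elements(self) -> Tuple[str, ...]:
        """All knockable elements (genes and nutrients), sorted."""
        out: Set[str] = set()
        for r in self.rows:
            out |= r.members
        return tuple(sorted(out))

    def drop_nutrient_rows(self) -> "GMatrix":
        return GMatrix(rows=self.gene_rows, reaction_ids=self.reaction_ids)

    def to_array(self) -> np.ndarray:
        """Dense binary incidence (rows × reactions)."""
        idx = {r: j for j, r in enumerate(self.reaction_ids)}
        arr = np.zeros((len(self.rows), len(self.reaction_ids)), dtype=np.int8)
        for i, unit in enumerate(self.rows):
            for rid in unit.disabled_reactions:
                arr[i, idx[rid]] = 1
        return arr

    def disabled_by(self, elements: Iterable[str]) -> Set[str]:
        """Reactions disabled by knocking out a set of elements: the union
        of the supports of every row whose members are contained in it."""
        elems = set(elements)
        out: Set[str] = set()
        for unit in self.rows:
            if unit.members <= elems:
                out |= unit.disabled_reactions
        return out


def build_g_matrix(
    model: MetabolicModel,
    scope: Optional[Iterable[str]] = None,
    max_sets_per_reaction: int = 10_000,
) -> GMatrix:
    """Assemble the gene rows of the G matrix from the model's GPR rules.

    For every reaction with a gene association, the minimal falsifying sets
    of its GPR are candidate rows; identical gene sets are merged into one
    row whose support is *every* reaction the set disables (evaluated
    against the full GPR, so the incidence invariant holds exactly). A row
    is pruned only when another row has a member subset and a support
    superset, which keeps the cut-set search space intact. When ``scope``
    is given, rows using genes outside it are dropped (restricting the
    search space to a predefined gene list).
    """
    if scope is not None:
        scope = set(scope)
        unknown = scope - set(model.genes)
        if unknown:
            raise ConfigurationError(
                f"scope genes not in catalogue: {sorted(unknown)}"
            )
    candidates: Set[FrozenSet[str]] = set()
    for rxn in model.reactions.values():
        if rxn.gpr is TRUE:
            continue
        for fs in gpr_mod.minimal_falsifying_sets(
            rxn.gpr, limit=max_sets_per_reaction
        ):
            if scope is not None and not fs <= scope:
                continue
            candidates.add(fs)

    rows: List[KnockoutUnit] = []
    for members in sorted(candidates, key=lambda s: (len(s), sorted(s))):
        support = frozenset(
            r.id
            for r in model.reactions.values()
            if r.gpr is not TRUE and not gpr_mod.evaluate(r.gpr, members)
        )
        rows.append(KnockoutUnit(GENE_SET, members, support))

    # dominance pruning: drop a row when a strict sub-member row covers at
    # least the same reactions
    kept: List[KnockoutUnit] = []
    for row in rows:
        dominated = any(
            other.members < row.members
            and other.disabled_reactions >= row.disabled_reactions
            for other in rows
        )
        if not dominated:
            kept.append(row)
    return GMatrix(rows=tuple(kept), reaction_ids=tuple(model.reaction_order()))


def extend_with_nutrients(
    g: GMatrix, model: MetabolicModel, medium: Medium
) -> GMatrix:
    """Append one nutrient row per open input exchange in the medium.

    Each appended row has a single nonzero column (the nutrient's input
    exchange reaction); gene rows are unchanged, so dropping the nutrient
    rows recovers the input matrix exactly.
    """
    new_rows = list(g.rows)
    seen = {(r.kind, r.members) for r in g.rows}
    for entry in medium.entries:
        if entry.exchange_id not in model.reactions:
            raise ConfigurationError(
                f"medium exchange {entry.exchange_id!r} not in model"
            )
        unit = KnockoutUnit(
            NUTRIENT,
            frozenset({entry.metabolite_id}),
            frozenset({entry.exchange_id}),
        )
        key = (unit.kind, unit.members)
        if key in seen:
            continue
        seen.add(key)
        new_rows.append(unit)
    return GMatrix(rows=tuple(new_rows), reaction_ids=g.reaction_ids)
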