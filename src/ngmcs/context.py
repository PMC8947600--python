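"""Context-specific essentiality: mapping expression and medium data onto
precomputed cut sets.

The calling rule is the one the cut-set formalism implies: a gene or
nutrient is essential for a sample when it is the *only active element* in
at least one cut set — every other member is already lost (gene below the
TPM threshold, nutrient absent from the medium), so losing the last active
element completes the cut and blocks growth. Genes absent from the
expression matrix are treated as active (conservative: an unmeasured gene
never manufactures an essentiality call); they are reported via
:meth:`ActivityContext.unmeasured_genes`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .engine import CutSet
from .model import (
    MetabolicModel,
    ModelError,
    reactions_disabled_by_genes,
)

DEFAULT_TPM_THRESHOLD = 1.0


@dataclass
class ActivityContext:
    """Per-sample gene activity (TPM vs threshold) and nutrient presence.

    ``expression``: genes × samples TPM matrix. ``nutrient_presence``:
    nutrients × samples booleans; when None, every nutrient is taken as
    present (the global-medium default).
    """

    expression: pd.DataFrame
    expression_threshold: float = DEFAULT_TPM_THRESHOLD
    nutrient_presence: Optional[pd.DataFrame] = None

    def __post_init__(self):
        if (self.expression.to_numpy(dtype=float) < 0).any():
            raise ValueError("TPM values must be >= 0")

    @property
    def samples(self) -> List[str]:
        return list(self.expression.columns)

    def gene_active(self, gene: str, sample: str) -> bool:
        if gene not in self.expression.index:
            return True  # unmeasured -> active (conservative)
        return float(self.expression.at[gene, sample]) >= self.expression_threshold

    def nutrient_present(self, nutrient: str, sample: str) -> bool:
        if self.nutrient_presence is None:
            return True
        if nutrient not in self.nutrient_presence.index:
            return True
        if sample not in self.nutrient_presence.columns:
            return True
        return bool(self.nutrient_presence.at[nutrient, sample])

    def element_active(self, element: str, nutrients: Iterable[str],
                       sample: str) -> bool:
        if element in set(nutrients):
            return self.nutrient_present(element, sample)
        return self.gene_active(element, sample)

    def unmeasured_genes(self, cutsets: Sequence[CutSet]) -> List[str]:
        """Genes queried by the cut sets but absent from the expression
        matrix (treated as active)."""
        queried: Set[str] = set()
        for cs in cutsets:
            queried |= cs.element_set - cs.nutrients
        return sorted(queried - set(self.expression.index))


@dataclass(frozen=True)
class EssentialityCall:
    """One positive call: ``element`` is the only active member of each
    ``witness`` cut set in ``sample``."""

    sample: str
    element: str
    essential: bool
    witnesses: Tuple[Tuple[str, ...], ...]


def essential_elements(
    cutsets: Sequence[CutSet],
    context: ActivityContext,
    sample: str,
) -> List[EssentialityCall]:
    """Call context-specific essential genes/nutrients for one sample.

    An element is essential iff some cut set has every *other* member
    inactive while the element itself is active; those cut sets are
    attached as witnesses.
    """
    if len(context.expression.columns) > 0 and sample not in context.samples:
        raise KeyError(f"sample {sample!r} not in expression matrix")
    witnesses: Dict[str, List[Tuple[str, ...]]] = {}
    for cs in cutsets:
        active = [
            e for e in cs.elements
            if context.element_active(e, cs.nutrients, sample)
        ]
        if len(active) == 1:
            witnesses.setdefault(active[0], []).append(cs.elements)
    return [
        EssentialityCall(
            sample=sample, element=e, essential=True,
            witnesses=tuple(ws),
        )
        for e, ws in sorted(witnesses.items())
    ]


def nutrient_dependency_matrix(
    cutsets: Sequence[CutSet],
    context: ActivityContext,
) -> pd.DataFrame:
    """Binary nutrients × samples matrix: 1 where the nutrient is called
    essential for the sample (the supplementary-table layout)."""
    nutrients: Set[str] = set()
    for cs in cutsets:
        nutrients |= cs.nutrients
    index = sorted(nutrients)
    mat = pd.DataFrame(
        0, index=index, columns=context.samples, dtype=int
    )
    for sample in context.samples:
        for call in essential_elements(cutsets, context, sample):
            if call.element in nutrients:
                mat.at[call.element, sample] = 1
    return mat


def limiting_gene(
    cutsets_for_nutrient: Sequence[CutSet],
    expression: pd.DataFrame,
    sample: str,
    nutrient: Optional[str] = None,
) -> Tuple[Optional[str], float]:
    """The most limiting backup gene for a nutrient in one sample.

    Each cut set containing the nutrient corresponds to one essential step
    of the endogenous backup route; within a cut set the partner genes are
    alternatives, so the step works as long as the *best-expressed* partner
    is active (max within the set). The route as a whole is only as strong
    as its weakest step, so the limiting value is the *minimum* across cut
    sets of those per-set maxima; the sample is auxotrophic when it falls
    below the TPM threshold, matching the only-active-element rule. A cut
    set with no partner genes (unconditionally essential nutrient) has
    limiting value 0. Unmeasured partners are treated as active
    (``inf``), consistently with the calling rule.

    Returns ``(gene, value)`` where ``gene`` realizes the per-set maximum
    of the weakest step (None when that step has no backup gene).
    """
    if nutrient is not None:
        cutsets_for_nutrient = [
            cs for cs in cutsets_for_nutrient if nutrient in cs.nutrients
        ]
    if not cutsets_for_nutrient:
        raise ValueError("nutrient absent from all cut sets")
    best: Optional[Tuple[float, Optional[str]]] = None
    for cs in cutsets_for_nutrient:
        partners = [e for e in cs.elements if e not in cs.nutrients]
        if not partners:
            per_set: Tuple[float, Optional[str]] = (0.0, None)
        else:
            tpms = [
                (
                    float(expression.at[g, sample])
                    if g in expression.index
                    else np.inf,
                    g,
                )
                for g in partners
            ]
            per_set = max(tpms)
        if best is None or per_set[0] < best[0]:
            best = per_set
    return best[1], best[0]


def apply_linked_knockouts(
    model: MetabolicModel,
    gene: str,
    links: Dict[str, List[str]],
) -> MetabolicModel:
    """Materialize a gene knockout with regulatory side-effects: zero the
    bounds of the gene's GPR-derived reactions plus all linked reactions
    (used before cut-set search when inhibition cascades are modelled,
    e.g. a knockout whose metabolite accumulation inhibits further
    enzymes)."""
    out = model.copy()
    to_zero = set(reactions_disabled_by_genes(model, {gene}))
    for rid in links.get(gene, []):
        if rid not in model.reactions:
            raise ModelError(f"linked reaction {rid!r} not in model")
        to_zero.add(rid)
    for rid in to_zero:
        out.reactions[rid].lower_bound = 0.0
        out.reactions[rid].upper_bound = 0.0
    return out
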