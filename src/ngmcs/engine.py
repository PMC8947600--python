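"""Cut-set enumeration: shortest-first MILP search with an LP oracle.

The method finds minimal combinations of G-matrix rows (gene sets and/or
nutrients) whose knockout blocks a target reaction — biomass, when
predicting synthetic lethality. "Blocked" is encoded through Farkas
duality on the irreversible model: the primal system

    S v = 0,   v ≥ 0,   v_target ≥ 1

is infeasible exactly when a dual vector u exists with (Sᵀu)_j ≤ 0 for
every remaining reaction j and (Sᵀu)_target ≤ −1. Selecting a row of G
relaxes the dual constraints of the reactions it disables through big-M
slacks, so a feasible MILP assignment is a certificate that the selected
knockouts block the target. Minimizing the number of distinct knocked
*elements* (genes/nutrients, deduplicated across rows) yields the shortest
cut set; integer cuts on the element indicators exclude found sets and all
their supersets, so repeated solves enumerate cut sets by increasing size
until the MILP goes infeasible.

Because all flux upper bounds are positive after the irreversible rewrite,
blocking is a property of the flux cone and the bound-free dual is exact;
every returned solution is nonetheless re-checked against the bounded LP
(`verify_cutset`), which also guards against big-M artifacts and against
non-minimal incumbents accepted at a solver time limit.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import csr_matrix, lil_matrix

from .gmatrix import GMatrix, NUTRIENT
from .model import (
    DEFAULT_EPSILON,
    EngineError,
    IrreversibleModel,
    MetabolicModel,
    max_target_flux,
    split_reversible,
)

log = logging.getLogger("ngmcs.engine")

GMCS = "gMCS"
NGMCS = "ngMCS"


@dataclass(frozen=True)
class CutSet:
    """One (nutrient-)genetic minimal cut set.

    ``elements`` are gene and/or nutrient identifiers, sorted; the cut is an
    ``ngMCS`` when at least one element is a nutrient and a ``gMCS`` when
    all are genes. ``verified_cut`` means one LP confirmed the knockout
    blocks the target; ``verified_minimal`` means every single-element
    removal restores target flux.
    """

    elements: Tuple[str, ...]
    nutrients: FrozenSet[str] = frozenset()
    verified_cut: bool = False
    verified_minimal: bool = False

    @property
    def size(self) -> int:
        return len(self.elements)

    @property
    def classification(self) -> str:
        return NGMCS if any(e in self.nutrients for e in self.elements) else GMCS

    @property
    def element_set(self) -> FrozenSet[str]:
        return frozenset(self.elements)

    @staticmethod
    def make(elements: Iterable[str], nutrient_ids: Iterable[str]) -> "CutSet":
        elems = tuple(sorted(set(elements)))
        return CutSet(
            elements=elems,
            nutrients=frozenset(nutrient_ids) & set(elems),
        )

    def to_dict(self) -> dict:
        return {
            "elements": list(self.elements),
            "nutrients": sorted(self.nutrients),
            "classification": self.classification,
            "size": self.size,
            "verified_cut": self.verified_cut,
            "verified_minimal": self.verified_minimal,
        }


@dataclass
class EngineOptions:
    """Termination and numerical parameters of the enumeration.

    ``time_limit_per_solution`` mirrors the per-solution heuristic limit of
    the underlying approach (default 60 s): an incumbent returned at the
    limit is accepted only if it passes LP verification, otherwise it is
    excluded and the search re-posed.
    """

    time_limit_per_solution: float = 60.0
    max_solutions: int = 100
    max_cutset_size: Optional[int] = None
    epsilon: float = DEFAULT_EPSILON
    big_M: float = 1000.0
    solver_seed: int = 0

    def __post_init__(self):
        if self.time_limit_per_solution <= 0:
            raise ValueError("time_limit_per_solution must be > 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.big_M <= 0:
            raise ValueError("big_M must be > 0")


def _as_irreversible(model) -> IrreversibleModel:
    if isinstance(model, IrreversibleModel):
        return model
    return split_reversible(model)


class _DualMILP:
    """The Farkas-dual MILP over G-matrix rows, built once per search.

    Variables (in order): u per metabolite (free), a per irreversible
    reaction (continuous in [0,1], may rise only when a selected row covers
    the reaction), z per G row (binary selection), y per element (binary;
    z_i ≤ y_e ties a selected row to all its member elements). Objective:
    minimize Σy.
    """

    def __init__(self, irr: IrreversibleModel, g: GMatrix, target: str,
                 opts: EngineOptions):
        self.irr = irr
        self.g = g
        self.opts = opts
        model = irr.model
        if target not in irr.forward:
            raise EngineError(f"target {target!r} has no forward column")
        self.target_col_id = irr.forward[target]

        self.met_ids = list(model.metabolites)
        self.rxn_ids = model.reaction_order()
        self.elements = list(g.elements)
        m, n = len(self.met_ids), len(self.rxn_ids)
        R, E = len(g.rows), len(self.elements)
        self.m, self.n, self.R, self.E = m, n, R, E
        self.off_u, self.off_a = 0, m
        self.off_z, self.off_y = m + n, m + n + R
        self.nvar = m + n + R + E

        met_idx = {x: i for i, x in enumerate(self.met_ids)}
        rxn_idx = {x: j for j, x in enumerate(self.rxn_ids)}
        t = rxn_idx[self.target_col_id]
        M = opts.big_M

        # which irreversible columns each row covers
        cover: List[List[int]] = [[] for _ in range(n)]
        for i, unit in enumerate(g.rows):
            for orig in unit.disabled_reactions:
                for cid in irr.columns_of(orig):
                    cover[rxn_idx[cid]].append(i)

        A = lil_matrix((2 * n + sum(len(u.members) for u in g.rows), self.nvar))
        ub: List[float] = []
        row = 0
        # dual feasibility: (S^T u)_j - M a_j <= 0 (target: <= -1)
        for j, rid in enumerate(self.rxn_ids):
            for met, coef in model.reactions[rid].stoichiometry.items():
                A[row, self.off_u + met_idx[met]] = coef
            A[row, self.off_a + j] = -M
            ub.append(-1.0 if j == t else 0.0)
            row += 1
        # coverage: a_j - sum(z_i over covering rows) <= 0
        for j in range(n):
            A[row, self.off_a + j] = 1.0
            for i in cover[j]:
                A[row, self.off_z + i] = -1.0
            ub.append(0.0)
            row += 1
        # linking: z_i - y_e <= 0 for every member e of row i
        elem_idx = {e: k for k, e in enumerate(self.elements)}
        for i, unit in enumerate(g.rows):
            for e in unit.members:
                A[row, self.off_z + i] = 1.0
                A[row, self.off_y + elem_idx[e]] = -1.0
                ub.append(0.0)
                row += 1
        self._A_static = csr_matrix(A)
        self._ub_static = np.array(ub)
        self._elem_idx = elem_idx

        lo = np.concatenate(
            [np.full(m, -np.inf), np.zeros(n + R + E)]
        )
        hi = np.concatenate(
            [np.full(m, np.inf), np.ones(n + R + E)]
        )
        self.bounds = Bounds(lo, hi)
        self.integrality = np.concatenate(
            [np.zeros(m + n), np.ones(R + E)]
        )
        self.c = np.concatenate([np.zeros(m + n + R), np.ones(E)])

    def solve(
        self,
        exclusions: Sequence[FrozenSet[str]],
        max_size: Optional[int],
    ) -> Optional[FrozenSet[str]]:
        """Return the element set of one shortest feasible selection, or
        None when the MILP is infeasible / no incumbent within the limit."""
        extra_rows = []
        extra_ub = []
        for exc in exclusions:
            # sum of y over the excluded set <= |set| - 1: removes the set
            # and every superset from the feasible region
            r = np.zeros(self.nvar)
            known = [e for e in exc if e in self._elem_idx]
            if len(known) < len(exc):
                continue  # contains an element this G matrix cannot knock
            for e in known:
                r[self.off_y + self._elem_idx[e]] = 1.0
            extra_rows.append(r)
            extra_ub.append(len(known) - 1.0)
        if max_size is not None:
            r = np.zeros(self.nvar)
            r[self.off_y:] = 1.0
            extra_rows.append(r)
            extra_ub.append(float(max_size))
        if extra_rows:
            A = csr_matrix(
                np.vstack([self._A_static.toarray(), np.array(extra_rows)])
            )
            ub = np.concatenate([self._ub_static, np.array(extra_ub)])
        else:
            A, ub = self._A_static, self._ub_static
        res = milp(
            c=self.c,
            constraints=LinearConstraint(A, -np.inf, ub),
            integrality=self.integrality,
            bounds=self.bounds,
            options={
                "time_limit": self.opts.time_limit_per_solution,
                "presolve": True,
            },
        )
        if res.status == 2:  # infeasible: enumeration closed
            return None
        if res.x is None:
            if res.status == 1:
                log.warning("MILP time limit reached with no incumbent")
                return None
            raise EngineError(f"MILP solver failure: {res.message}")
        if res.status == 1:
            log.warning("accepting incumbent at time limit (to be verified)")
        y = res.x[self.off_y:]
        return frozenset(
            e for e, k in self._elem_idx.items() if y[k] > 0.5
        )


def verify_cutset(
    model: MetabolicModel,
    g: GMatrix,
    candidate: CutSet,
    target: str,
    epsilon: float = DEFAULT_EPSILON,
) -> CutSet:
    """Set the verification flags of a candidate by direct LP.

    ``verified_cut``: with every reaction disabled by the candidate's
    elements knocked, the target LP maximum is below ``epsilon``.
    ``verified_minimal``: every single-element removal restores target flux
    to at least ``epsilon``. Non-minimal verified candidates are flagged,
    never shrunk.
    """
    disabled = g.disabled_by(candidate.elements)
    flux = max_target_flux(model, target, disabled)
    cut = flux < epsilon
    minimal = cut
    if cut:
        for e in candidate.elements:
            rest = set(candidate.elements) - {e}
            if max_target_flux(model, target, g.disabled_by(rest)) < epsilon:
                minimal = False
                break
    return replace(candidate, verified_cut=cut, verified_minimal=minimal)


def shortest_cutset(
    model,
    g: GMatrix,
    target: str,
    exclusions: Sequence = (),
    opts: Optional[EngineOptions] = None,
) -> Optional[CutSet]:
    """The shortest cut set not excluded, LP-verified, or None when no
    further cut set exists within the size limit."""
    opts = opts or EngineOptions()
    irr = _as_irreversible(model)
    dual = _DualMILP(irr, g, target, opts)
    excl = [
        cs.element_set if isinstance(cs, CutSet) else frozenset(cs)
        for cs in exclusions
    ]
    return _next_verified(dual, irr, g, target, excl, opts)


def _next_verified(dual, irr, g, target, excl, opts, max_retries=25):
    nutrient_ids = g.nutrient_ids
    for _ in range(max_retries):
        elems = dual.solve(excl, opts.max_cutset_size)
        if elems is None:
            return None
        candidate = CutSet.make(elems, nutrient_ids)
        candidate = verify_cutset(irr.source, g, candidate, target, opts.epsilon)
        if candidate.verified_cut:
            return candidate
        log.warning(
            "discarding unverifiable incumbent %s", sorted(elems)
        )
        excl.append(frozenset(elems))
    raise EngineError("too many unverifiable incumbents; raise big_M?")


def enumerate_cutsets(
    model,
    g: GMatrix,
    target: str,
    opts: Optional[EngineOptions] = None,
) -> List[CutSet]:
    """Enumerate cut sets by increasing size: shortest, second shortest, …

    After each solution the integer cut Σ_{e∈solution} y_e ≤ |solution|−1
    is added, which also excludes all supersets, so the output is an
    antichain with non-decreasing sizes. Stops at ``max_solutions``,
    ``max_cutset_size``, or MILP infeasibility (enumeration closed).
    """
    opts = opts or EngineOptions()
    irr = _as_irreversible(model)
    if opts.max_solutions <= 0:
        return []
    dual = _DualMILP(irr, g, target, opts)
    excl: List[FrozenSet[str]] = []
    found: List[CutSet] = []
    while len(found) < opts.max_solutions:
        cs = _next_verified(dual, irr, g, target, excl, opts)
        if cs is None:
            break
        log.info(
            "cut set #%d: %s (size %d, %s, minimal=%s)",
            len(found) + 1, "/".join(cs.elements), cs.size,
            cs.classification, cs.verified_minimal,
        )
        found.append(cs)
        excl.append(cs.element_set)
    return canonicalize(found)


def canonicalize(cutsets: Iterable[CutSet]) -> List[CutSet]:
    """Stable order: by size, then lexicographically by elements."""
    return sorted(cutsets, key=lambda cs: (cs.size, cs.elements))


def brute_force_cutsets(
    model,
    g: GMatrix,
    target: str,
    max_size: int,
    epsilon: float = DEFAULT_EPSILON,
) -> List[CutSet]:
    """Exhaustive oracle: all minimal cut sets up to ``max_size`` by direct
    subset enumeration with LP blocking tests.

    Exhaustive search is combinatorial and infeasible for genome-scale
    networks; a guard refuses G matrices with more than 20 rows, keeping
    the oracle on small fixtures where it cross-checks the MILP route.
    """
    if len(g.rows) > 20:
        raise EngineError(
            f"brute force refused: {len(g.rows)} rows exceeds the guard (20)"
        )
    source = model.source if isinstance(model, IrreversibleModel) else model
    elements = g.elements
    nutrient_ids = g.nutrient_ids
    found: List[CutSet] = []
    found_sets: List[FrozenSet[str]] = []
    flux_cache: Dict[FrozenSet[str], float] = {}
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(elements, size):
            cand = frozenset(combo)
            if any(f <= cand for f in found_sets):
                continue
            disabled = frozenset(g.disabled_by(cand))
            if disabled not in flux_cache:
                flux_cache[disabled] = max_target_flux(source, target, disabled)
            if flux_cache[disabled] < epsilon:
                cs = CutSet.make(cand, nutrient_ids)
                found.append(
                    replace(cs, verified_cut=True, verified_minimal=True)
                )
                found_sets.append(cand)
    return canonicalize(found)
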