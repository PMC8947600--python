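# Methods

## Model and conventions

A model is a stoichiometric matrix *S* (metabolites × reactions), flux
bounds, a boolean GPR rule per reaction, and a biomass reaction whose
maximal steady-state flux (`max v_t s.t. S v = 0, lb ≤ v ≤ ub`) proxies
proliferation. Exchanges are written as export reactions
(metabolite → ∅): uptake is negative flux, a nutrient is available when
the exchange's lower bound is negative, and "closing to import" sets that
lower bound to 0 while leaving the export direction untouched.
Import-written exchanges are recognized symmetrically. Uptake limits are
the millimolar medium concentrations used directly as bounds in
mmol·gDW⁻¹·h⁻¹; "unbounded" is the conventional ±1000.

A target is *blocked* when its LP maximum is below ε = 1e-6
(configurable). This tolerance balances solver noise against genuine
small leak fluxes; no tighter value is meaningful at HiGHS default
tolerances. Gene-less reactions (GPR = TRUE) are never knockable by
genes; they can only enter a cut through a nutrient row if they are input
exchanges.

## Minimal falsifying sets and the G matrix

GPR rules are monotone (AND/OR, no negation), so the minimal gene sets
that falsify a rule are well defined. They are computed as the prime
implicants of the negated rule by recursive expansion — falsifying an AND
takes the union of the children's families, falsifying an OR the
cross-product — with superset pruning at each step and a combinatorial
guard (default 10,000 sets per reaction) that aborts pathological rules
with a clear error. The exhaustive truth table over all gene subsets is
kept as the independent test oracle; the two agree on every random tree
campaign the suite runs. Gene identifiers are taken verbatim from the
model; no transcript collapsing.

Candidate member sets from all reactions are deduplicated, and each row's
support is then recomputed against *every* reaction's GPR, so the
incidence invariant — entry (i, j) = 1 iff knocking row *i*'s members
disables reaction *j* — holds exactly even when a set falsifies rules it
was not minimal for. A row is pruned only when another row has a strict
member subset and a support superset (total dominance), which provably
cannot remove any minimal cut from the search space. Nutrient rows are
appended one per medium entry, each with a single nonzero column (the
input exchange), and never alter gene rows.

## The dual MILP

On the irreversible rewrite (every reversible reaction split into a
forward/backward pair; zero-capacity directions contribute no column, so
every column can carry positive flux), blocking is a property of the flux
cone: with all upper bounds positive, `max v_t > 0` iff the cone contains
a direction with positive target flux. Farkas duality then gives an exact
certificate without bound variables: {S v = 0, v ≥ 0, v_t ≥ 1} is
infeasible iff some u satisfies (Sᵀu)_j ≤ 0 for all remaining j and
(Sᵀu)_t ≤ −1.

The MILP has continuous u (free), per-reaction slacks a ∈ [0,1], row
binaries z, and element binaries y (one per gene or nutrient):

- (Sᵀu)_j − M·a_j ≤ 0 for j ≠ t, and (Sᵀu)_t ≤ −1 (+M·a_t if the target
  is itself coverable);
- a_j ≤ Σ z_i over the rows covering j (both split directions of a
  knocked reaction are covered);
- z_i ≤ y_e for every member e of row i;
- minimize Σ y.

Minimizing *elements* rather than rows makes "shortest" mean cut-set
cardinality after deduplicating genes shared across rows, which is what
the brute-force oracle counts. Feasibility is sufficient for blocking
regardless of M (the certificate only relaxes covered reactions);
completeness needs M large enough to accommodate the certificate's
knocked components, with big_M = 1000 by default. Both directions are
guarded: every solution is re-verified by bounded LP, and the test suite
runs a 50-fixture equivalence campaign against exhaustive enumeration.

Enumeration adds, after each solution, the integer cut
Σ_{e∈solution} y_e ≤ |solution| − 1, which also excludes all supersets;
the output is therefore an antichain with non-decreasing sizes, ending
when the MILP goes infeasible (enumeration closed) or at
`max_solutions`/`max_cutset_size`. Tie-breaking among equal-size
solutions is solver-dependent and deliberately unspecified; outputs are
canonicalized (elements sorted, sets sorted by size then
lexicographically) so comparisons are stable as set families.

Per-solution time limits (default 60 s) may return an incumbent that is
feasible but not optimal; such incumbents are accepted only if they pass
LP verification as cuts — non-minimal ones are flagged
`verified_minimal = False`, never silently shrunk — and unverifiable ones
are excluded and the search re-posed. Under the test-suite problem sizes
the limit never binds.

## Verification

`verify_cutset` sets `verified_cut` with one LP (all reactions disabled
by the elements knocked; maximum target flux < ε) and `verified_minimal`
with |candidate| leave-one-out LPs (each must restore flux ≥ ε). The
brute-force oracle enumerates element subsets by increasing size with the
same LP test, skipping supersets of found cuts and caching LP results by
disabled-reaction set; a guard refuses G matrices with more than 20 rows,
keeping it an oracle for small fixtures only.

## Context essentiality

A gene or nutrient is essential for a sample iff it is the *only active
element* of at least one cut set: every other member inactive (gene TPM
below the threshold, default 1 TPM; nutrient absent), the element itself
active. Witness cut sets are attached to every call. Genes absent from
the expression matrix are treated as active — the conservative choice,
since an unmeasured gene can then never manufacture an essentiality
call — and reported per run. Nutrient presence defaults to the global
medium (all present) unless a per-sample presence table is supplied.

Threshold behaviour: raising the TPM threshold deactivates more members,
which grows the set of calls *for elements that remain active*; it can
also deactivate a witness element itself, which drops that call (a fully
inactive cut set means the context is already non-viable, and the rule
deliberately makes no call). The monotonicity property is therefore
stated, and tested, conditionally on the element being active at both
thresholds.

The *limiting gene* summary for a nutrient aggregates expression over the
cut sets containing it: within one cut set the partner genes are
alternatives, so the step survives as long as its best-expressed partner
is active (max within the set); the endogenous backup route fails at its
weakest step, so the limiting value is the minimum of those per-set
maxima across cut sets. With measured genes and the nutrient present,
"limiting value below the threshold" then coincides exactly with the
only-active-element rule calling the nutrient essential — the
equivalence is asserted in the tests. A cut set containing the nutrient
alone has limiting value 0 (no genetic backup). An alternative reading —
taking the maximum across cut sets as "the best backup pathway" — breaks
that equivalence (a silent gene in one cut set already creates the
dependency no matter how well another set is expressed) and was rejected;
this aggregation is an inference from the dependency definition, as the
source analyses describe only "the most limiting gene".

Linked knockouts model regulatory cascades (a knockout whose metabolite
accumulation inhibits further enzymes): `apply_linked_knockouts`
materializes a gene knockout as zeroed bounds on its GPR-derived
reactions plus a configured list of additional reactions, producing a
model on which cut-set search or growth tests run unchanged.

One narrative caveat: the worked three-element example {g1, g2, M2} is
sometimes narrated as "g2 inactive and M1 absent makes g1 essential";
consistency with the cut set itself requires M2, and this package's docs
and tests use M2 throughout. The discrepancy is flagged here rather than
silently resolved.

## Fixtures

`toy_network` rebuilds the two-medium example: nutrient M1 feeds C via
two branches (r1: M1→A under g1, r2: M1→B under g2, r3/r4: A/B→C both
under g3), biomass consumes C; the richer medium CM2 adds nutrient M2
with a *gene-less* rescue reaction r5: M2→C. The figure source is a
diagram, not a table, so this is the smallest reconstruction satisfying
all the stated lethality facts — in particular r5 carries no gene so that
no purely genetic cut exists under CM2. The topology lives in one
function and can be swapped if the diagram is read differently. Golden
cut-set families (confirmed by the brute-force oracle): genes-only under
CM1 {{g3}, {g1,g2}}; with nutrient rows CM1 adds {{M1}}; CM2
{{M1,M2}, {g3,M2}, {g1,g2,M2}}. Whether nutrient-only sets such as {M1}
belong in a published family listing is ambiguous; they are enumerated
like any other and distinguishable by their classification.

`random_network` draws small pathway networks for property campaigns:
1–2 nutrients with 1 mM uptake, a topologically ordered chain of internal
metabolites in which every metabolite is produced from an earlier one
(connectivity by construction), extra random forward edges, ~20%
reversible internal reactions, and random AND/OR GPR trees over ≤ 4 of 5
genes on ~75% of internal reactions. Draws are rejected unless the model
grows in its medium and has at most 12 knockout units (gene rows +
nutrient rows), and generation is deterministic per seed. These fixtures
emulate the *structure* that makes cut-set search nontrivial — branching,
isozyme/complex logic, shared genes, nutrient dependence — but not the
scale, flux magnitudes, compartments, or curation noise of genome-scale
reconstructions; passing the oracle campaigns demonstrates algorithmic
correctness, not predictive accuracy on real tumors.

## Problem sizes and defaults

The test suite and the acceptance script run entirely on regenerated
fixtures: 50-seed oracle-equivalence campaigns with cut sets up to size
4, 200 random GPR trees up to 10 genes, and the toy networks. These sizes
close the enumeration exhaustively on every fixture while keeping a full
run in tens of seconds on one CPU. Genome-scale reproduction (the
published counts for the reference human network) requires the external
model download and runs only through `ngmcs reproduce`, which reports
observed-vs-published count diffs and whether enumeration closed, since
published counts depend on solver and termination settings.

## Known limitations

- No thermodynamic/loopless constraints and no flux-variability
  analysis; cone-based blocking assumes no forced positive lower bounds
  on irreversible reactions.
- Nutrient knockout zeroes the whole exchange reaction (export too),
  matching the reaction-knockout definition; models that must excrete a
  medium nutrient to grow would need a dedicated export reaction.
- The MILP's completeness depends on big_M; solutions are LP-verified,
  but a too-small big_M could hide cuts on badly scaled models (raise
  `EngineOptions.big_M` if the oracle disagrees on a custom fixture).
- Expression thresholding is a binary proxy for enzyme activity; no
  partial activity, no post-transcriptional regulation.
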