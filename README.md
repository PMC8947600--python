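# ngmcs

Nutrient-genetic minimal cut sets for constraint-based metabolic models:
predicting synthetic lethality and nutrient auxotrophies that depend on
the growth environment.

## The problem

In a genome-scale metabolic model, a **genetic minimal cut set (gMCS)** is
a minimal set of genes whose simultaneous loss blocks flux through the
biomass reaction — a generalization of synthetic lethality to more than
two genes. But lethality depends on the environment: a gene pair that is
synthetic lethal in one growth medium can be rescued in another by a
nutrient that feeds an alternative pathway. Conversely, a tumor whose
biosynthetic route is silenced becomes dependent on the extracellular
supply of the product (an auxotrophy) — the classic example being
L-asparagine dependence upon loss of asparagine synthetase, exploited
clinically with asparaginase.

`ngmcs` treats genes and nutrients uniformly: a **nutrient-genetic
minimal cut set (ngMCS)** is a minimal set of gene losses and/or nutrient
deprivations whose combination blocks biomass production. Nutrient
deprivation is modelled as the knockout of the nutrient's input exchange
reaction.

## The method

For a model with stoichiometric matrix *S*, fluxes *v* with bounds, and a
biomass target *t*:

1. **G matrix.** Each reaction's GPR rule (AND = complex, OR = isozymes)
   is compiled into its minimal falsifying gene sets (prime implicants of
   the negated rule). Merged across reactions these form the binary
   matrix *G*: rows are knockout units, entry (i, j) = 1 iff knocking out
   unit *i* disables reaction *j*. One extra row per nutrient in the
   medium — an artificial gene for its input exchange reaction, with a
   single nonzero column — extends the search space from gMCSs to ngMCSs.
2. **Shortest-cut MILP.** On the irreversible model, blocked biomass is
   certified by Farkas duality: the system {*S v* = 0, *v* ≥ 0,
   *v_t* ≥ 1} is infeasible iff a dual vector *u* exists with
   (*Sᵀu*)_j ≤ 0 for every remaining reaction and (*Sᵀu*)_t ≤ −1.
   Selecting G rows (binaries *z*, element indicators *y*) relaxes the
   dual constraints of the reactions they disable via big-M slacks;
   minimizing Σ*y* yields the fewest-element cut. Integer cuts
   Σ_{e∈found} y_e ≤ |found| − 1 exclude each solution and its supersets,
   so repeated solves enumerate cut sets by increasing size until the
   MILP is infeasible.
3. **Verification.** Every solution is re-checked by LP: the full
   knockout must drive max *v_t* below 1e-6, and every leave-one-out must
   restore it (minimality). A brute-force subset enumerator provides an
   independent oracle on small networks.
4. **Context mapping.** Given expression data (TPM) and a per-sample
   medium, a gene or nutrient is *essential in that context* iff it is
   the only active element of at least one ngMCS (gene active ⇔
   TPM ≥ 1 by default; nutrient active ⇔ present in the medium). The
   nutrient × sample binary matrix of these calls identifies
   context-specific auxotrophies.

## Worked example

The bundled two-medium toy network (`toy_network`) has nutrient M1 feeding
metabolite C through two gene-dependent branches (g1, g2 on parallel
entry steps; g3 on both exit steps) and, under medium CM2, a second
nutrient M2 with a gene-less rescue route:

```python
from ngmcs import *

model, medium = toy_network("CM2")
g = build_g_matrix(model)
g = extend_with_nutrients(g, apply_medium(model, medium), medium)
for cs in enumerate_cutsets(model, g, "biomass", EngineOptions(max_solutions=20)):
    print(cs.classification, cs.size, "/".join(cs.elements),
          cs.verified_cut, cs.verified_minimal)
```

prints

```
ngMCS 2 M1/M2 True True
ngMCS 2 M2/g3 True True
ngMCS 3 M2/g1/g2 True True
```

Every cut set contains M2 — no purely genetic knockout is lethal under
CM2 because the rescue route carries no gene — and `{g1, g2, M2}` says
the g1/g2 pair becomes synthetic lethal exactly when M2 is deprived.
Mapping a sample where g2 is silent (0.2 TPM) and M2 absent:

```python
import pandas as pd
expr = pd.DataFrame({"patient_a": {"g1": 9.0, "g2": 0.2, "g3": 9.0}})
presence = pd.DataFrame({"patient_a": {"M1": True, "M2": False}})
ctxt = ActivityContext(expr, nutrient_presence=presence)
cutsets = enumerate_cutsets(model, g, "biomass", EngineOptions(max_solutions=20))
for call in essential_elements(cutsets, ctxt, "patient_a"):
    print(call.element, "<-", [";".join(w) for w in call.witnesses])
```

```
M1 <- ['M1;M2']
g1 <- ['M2;g1;g2']
g3 <- ['M2;g3']
```

g1 is essential for this sample (its witness cut set has every other
member already lost), and so are g3 and the M1 supply.

The same pipeline is available from the shell:

```sh
ngmcs fixtures --which CM2 --out-dir demo
ngmcs compute --model demo/cm2.json --medium demo/cm2.medium.tsv \
      --mode ngmcs --out-prefix demo/cutsets
ngmcs essentiality --cutsets demo/cutsets.jsonl --expression expr.tsv
```

For genome-scale runs, `ngmcs reproduce` re-runs pinned configurations
against a user-supplied reference human model (Recon3D_3.01, downloaded
separately from vmh.life) with its correction patch and medium tables,
and reports count diffs.

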