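"""File formats: model JSON/SBML, medium & patch TSV, expression TSV,
cut-set JSON-lines/TSV, G-matrix TSV.

SBML Level 3 + FBC is handled through cobrapy (python-libsbml underneath);
the JSON dialect mirrors cobrapy's schema closely enough that fixtures are
readable by either tool.
"""

from __future__ import annotations

import json
import math
import os
from typing import Dict, Iterable, List, Optional

import pandas as pd

from . import gpr as gpr_mod
from .model import (
    ConfigurationError,
    Medium,
    MediumEntry,
    Metabolite,
    MetabolicModel,
    ModelError,
    PatchOp,
    Reaction,
)


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gene_reaction_rule,
            }
            for r in model.reactions.values()
        ],
        "genes": list(model.genes),
        "biomass": model.biomass_reaction_id,
    }


def model_from_dict(data: dict) -> MetabolicModel:
    try:
        mets = {
            m["id"]: Metabolite(
                m["id"], m.get("name", ""), m.get("compartment", "")
            )
            for m in data["metabolites"]
        }
        rxns = {}
        for r in data["reactions"]:
            rxns[r["id"]] = Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["metabolites"].items()},
                lower_bound=float(r["lower_bound"]),
                upper_bound=float(r["upper_bound"]),
                gpr=gpr_mod.parse_gpr(r.get("gene_reaction_rule", "")),
                name=r.get("name", ""),
            )
        model = MetabolicModel(
            metabolites=mets,
            reactions=rxns,
            genes=list(data.get("genes", [])),
            biomass_reaction_id=data["biomass"],
            id=data.get("id", "model"),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelError(f"malformed model JSON: {exc}") from exc
    if not model.genes:
        seen: List[str] = []
        for r in model.reactions.values():
            for g in sorted(gpr_mod.genes_in(r.gpr)):
                if g not in seen:
                    seen.append(g)
        model.genes = seen
    model.validate()
    return model


def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy Model (objective = biomass)."""
    import cobra

    cm = cobra.Model(model.id)
    cm.add_metabolites(
        [
            cobra.Metabolite(
                m.id, name=m.name, compartment=m.compartment or "c"
            )
            for m in model.metabolites.values()
        ]
    )
    for r in model.reactions.values():
        rxn = cobra.Reaction(r.id, name=r.name)
        cm.add_reactions([rxn])
        rxn.add_metabolites(
            {cm.metabolites.get_by_id(m): c for m, c in r.stoichiometry.items()}
        )
        rxn.bounds = (r.lower_bound, r.upper_bound)
        rxn.gene_reaction_rule = r.gene_reaction_rule
    cm.objective = model.biomass_reaction_id
    return cm


def from_cobra(cobra_model, biomass_reaction_id: Optional[str] = None) -> MetabolicModel:
    """Convert a cobrapy Model; the biomass reaction defaults to the
    objective reaction."""
    if biomass_reaction_id is None:
        objective = [
            r.id for r in cobra_model.reactions if r.objective_coefficient
        ]
        if len(objective) != 1:
            raise ConfigurationError(
                "cannot infer a unique biomass reaction from the objective; "
                "pass biomass_reaction_id explicitly"
            )
        biomass_reaction_id = objective[0]
    mets = {
        m.id: Metabolite(m.id, m.name or "", m.compartment or "")
        for m in cobra_model.metabolites
    }
    rxns = {}
    for r in cobra_model.reactions:
        rxns[r.id] = Reaction(
            id=r.id,
            stoichiometry={m.id: c for m, c in r.metabolites.items()},
            lower_bound=float(r.lower_bound),
            upper_bound=float(r.upper_bound),
            gpr=gpr_mod.parse_gpr(r.gene_reaction_rule or ""),
            name=r.name or "",
        )
    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        genes=[g.id for g in cobra_model.genes],
        biomass_reaction_id=biomass_reaction_id,
        id=cobra_model.id or "model",
    )
    model.validate()
    return model


def read_model(
    path: str,
    format: Optional[str] = None,
    biomass_reaction_id: Optional[str] = None,
) -> MetabolicModel:
    """Read a model from ``sbml-fbc`` or ``json`` (inferred from the
    extension when not given)."""
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = "json" if ext == ".json" else "sbml-fbc"
    if format == "json":
        with open(path) as fh:
            try:
                data = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ModelError(f"malformed JSON in {path}: {exc}") from exc
        return model_from_dict(data)
    if format == "sbml-fbc":
        import cobra

        try:
            cm = cobra.io.read_sbml_model(path)
        except Exception as exc:  # libsbml raises a mix of types
            raise ModelError(f"malformed SBML in {path}: {exc}") from exc
        return from_cobra(cm, biomass_reaction_id)
    raise ValueError(f"unknown model format {format!r}")


def write_model(model: MetabolicModel, path: str, format: Optional[str] = None) -> None:
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = "json" if ext == ".json" else "sbml-fbc"
    if format == "json":
        with open(path, "w") as fh:
            json.dump(model_to_dict(model), fh, indent=1)
    elif format == "sbml-fbc":
        import cobra

        cobra.io.write_sbml_model(to_cobra(model), path)
    else:
        raise ValueError(f"unknown model format {format!r}")


# ---------------------------------------------------------------------------
# Medium / patch / expression tables
# ---------------------------------------------------------------------------

MEDIUM_COLUMNS = ["metabolite_id", "exchange_id", "max_uptake_mM"]


def read_medium_tsv(path: str) -> Medium:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MEDIUM_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"medium file missing columns {missing}")
    entries = []
    for _, row in df.iterrows():
        raw = str(row["max_uptake_mM"]).strip()
        uptake = math.inf if raw.lower() in {"inf", "unbounded"} else float(raw)
        entries.append(
            MediumEntry(row["metabolite_id"], row["exchange_id"], uptake)
        )
    return Medium(entries)


def write_medium_tsv(medium: Medium, path: str) -> None:
    rows = [
        {
            "metabolite_id": e.metabolite_id,
            "exchange_id": e.exchange_id,
            "max_uptake_mM": "inf" if math.isinf(e.max_uptake) else e.max_uptake,
        }
        for e in medium.entries
    ]
    pd.DataFrame(rows, columns=MEDIUM_COLUMNS).to_csv(path, sep="\t", index=False)


def read_patch_tsv(path: str) -> List[PatchOp]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    ops = []
    for _, row in df.iterrows():
        def _num(v):
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return None
            s = str(v).strip()
            return None if s in {"", "nan"} else float(s)

        ops.append(
            PatchOp(
                action=str(row["action"]).strip(),
                reaction_id=str(row["reaction_id"]).strip(),
                lower_bound=_num(row.get("lower_bound")),
                upper_bound=_num(row.get("upper_bound")),
            )
        )
    return ops


def read_expression_tsv(path: str) -> pd.DataFrame:
    """Expression matrix: first column gene id, remaining columns samples,
    values TPM."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise ConfigurationError(f"malformed expression TSV {path}: {exc}") from exc
    bad = df.columns[df.dtypes == object]
    if len(bad):
        for col in bad:
            try:
                df[col] = pd.to_numeric(df[col])
            except (TypeError, ValueError) as exc:
                line = df[col].map(
                    lambda v: isinstance(v, str)
                ).to_numpy().argmax()
                raise ConfigurationError(
                    f"non-numeric TPM in column {col!r} near line {line + 2}"
                ) from exc
    if (df.to_numpy() < 0).any():
        raise ConfigurationError("negative TPM values in expression matrix")
    return df


def read_gene_set(path: str) -> List[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_linked_ko_tsv(path: str) -> Dict[str, List[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    links: Dict[str, List[str]] = {}
    for _, row in df.iterrows():
        links.setdefault(row["gene_id"], []).append(row["reaction_id"])
    return links


# ---------------------------------------------------------------------------
# Cut sets
# ---------------------------------------------------------------------------

def write_cutsets_jsonl(cutsets: Iterable, path: str) -> None:
    with open(path, "w") as fh:
        for cs in cutsets:
            fh.write(json.dumps(cs.to_dict()) + "\n")


def read_cutsets_jsonl(path: str) -> List:
    from .engine import CutSet

    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            nutrients = frozenset(d.get("nutrients", []))
            out.append(
                CutSet(
                    elements=tuple(d["elements"]),
                    nutrients=nutrients,
                    verified_cut=bool(d.get("verified_cut", False)),
                    verified_minimal=bool(d.get("verified_minimal", False)),
                )
            )
    return out


def write_cutsets_tsv(cutsets: Iterable, path: str) -> None:
    """TSV mirror of the supplementary-table layout: one cut set per row,
    ;-joined elements."""
    rows = [
        {
            "size": cs.size,
            "classification": cs.classification,
            "elements": ";".join(cs.elements),
            "verified_cut": int(cs.verified_cut),
            "verified_minimal": int(cs.verified_minimal),
        }
        for cs in cutsets
    ]
    pd.DataFrame(
        rows,
        columns=["size", "classification", "elements", "verified_cut",
                 "verified_minimal"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# G matrix
# ---------------------------------------------------------------------------

def write_gmatrix(g, path: str) -> None:
    rows = [
        {
            "row_id": i,
            "kind": unit.kind,
            "members": ";".join(sorted(unit.members)),
            "reactions": ";".join(sorted(unit.disabled_reactions)),
        }
        for i, unit in enumerate(g.rows)
    ]
    pd.DataFrame(
        rows, columns=["row_id", "kind", "members", "reactions"]
    ).to_csv(path, sep="\t", index=False)
    with open(path + ".json", "w") as fh:
        json.dump({"reaction_ids": list(g.reaction_ids)}, fh)


def read_gmatrix(path: str):
    from .gmatrix import GMatrix, KnockoutUnit

    df = pd.read_csv(path, sep="\t", dtype=str)
    with open(path + ".json") as fh:
        header = json.load(fh)
    rows = tuple(
        KnockoutUnit(
            kind=r["kind"],
            members=frozenset(str(r["members"]).split(";")),
            disabled_reactions=frozenset(str(r["reactions"]).split(";")),
        )
        for _, r in df.iterrows()
    )
    return GMatrix(rows=rows, reaction_ids=tuple(header["reaction_ids"]))
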