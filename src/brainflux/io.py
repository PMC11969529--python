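"""Model and table I/O.

The model serialization dialect is plain JSON::

    {
      "id": "toy_neuron",
      "annotations": {"cell_type": "neuron"},
      "compartments": {"c": "cytosol", "e": "extracellular", "m": "mitochondria"},
      "metabolites": [
        {"id": "glc__D[c]", "name": "D-glucose", "compartment": "c",
         "formula": "C6H12O6", "charge": 0}
      ],
      "reactions": [
        {"id": "HEX1", "name": "hexokinase",
         "stoichiometry": {"glc__D[c]": -1, "atp[c]": -1, "g6p[c]": 1, "adp[c]": 1},
         "lower_bound": 0.0, "upper_bound": 1000.0,
         "gpr": "G0003 or G0004", "subsystem": "Glycolysis"}
      ]
    }

Writing canonicalizes (sorted ids, zero coefficients dropped), so
``read(write(m))`` is the identity on canonical models.  Schema violations
raise :class:`SchemaError` carrying the JSON path of the offending field.

Flux tables are TSV with columns ``reaction_id, flux`` (optionally
``lower, upper``); constraint tables ``reaction_id, lb, ub``; expression
tables ``gene, length, <sample columns>``; p-value tables ``gene, pvalue``;
pathway metabolite sets are GMT-style text (name, description, members).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Mapping, Optional, Union

import pandas as pd

from .model import MetabolicModel, Metabolite, ModelError, Reaction, canonicalize

__all__ = [
    "SchemaError",
    "read_model",
    "write_model",
    "read_flux_tsv",
    "write_flux_tsv",
    "read_constraints_tsv",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_pvalues_tsv",
    "write_pvalues_tsv",
    "read_gmt",
    "write_gmt",
]

PathLike = Union[str, Path]


class SchemaError(ValueError):
    """Model JSON does not conform to the dialect; message includes the path."""


def _expect(obj, typ, path: str):
    if not isinstance(obj, typ):
        name = typ.__name__ if not isinstance(typ, tuple) else "/".join(t.__name__ for t in typ)
        raise SchemaError(f"{path}: expected {name}, got {type(obj).__name__}")
    return obj


def _model_from_dict(doc: dict) -> MetabolicModel:
    _expect(doc, dict, "$")
    model = MetabolicModel(
        model_id=str(doc.get("id", "model")),
        annotations=_expect(doc.get("annotations", {}), dict, "$.annotations"),
        compartments=_expect(doc.get("compartments", {}), dict, "$.compartments"),
    )
    for i, m in enumerate(_expect(doc.get("metabolites", []), list, "$.metabolites")):
        path = f"$.metabolites[{i}]"
        _expect(m, dict, path)
        if "id" not in m:
            raise SchemaError(f"{path}.id: missing")
        charge = m.get("charge")
        if charge is not None:
            _expect(charge, int, f"{path}.charge")
        try:
            model.add_metabolite(
                Metabolite(
                    id=str(m["id"]),
                    name=str(m.get("name", "")),
                    compartment=str(m.get("compartment", "c")),
                    formula=m.get("formula"),
                    charge=charge,
                )
            )
        except ModelError as exc:
            raise SchemaError(f"{path}: {exc}") from exc
    for i, r in enumerate(_expect(doc.get("reactions", []), list, "$.reactions")):
        path = f"$.reactions[{i}]"
        _expect(r, dict, path)
        for key in ("id", "stoichiometry"):
            if key not in r:
                raise SchemaError(f"{path}.{key}: missing")
        stoich = _expect(r["stoichiometry"], dict, f"{path}.stoichiometry")
        lb = r.get("lower_bound", 0.0)
        ub = r.get("upper_bound", 1000.0)
        _expect(lb, (int, float), f"{path}.lower_bound")
        _expect(ub, (int, float), f"{path}.upper_bound")
        if lb > ub:
            raise SchemaError(f"{path}: lower_bound {lb} > upper_bound {ub}")
        try:
            model.add_reaction(
                Reaction(
                    id=str(r["id"]),
                    stoichiometry={str(k): float(v) for k, v in stoich.items()},
                    name=str(r.get("name", "")),
                    lower_bound=float(lb),
                    upper_bound=float(ub),
                    gpr=str(r.get("gpr", "")),
                    subsystem=str(r.get("subsystem", "")),
                )
            )
        except ModelError as exc:
            raise SchemaError(f"{path}: {exc}") from exc
    model.validate()
    return model


def _model_to_dict(model: MetabolicModel) -> dict:
    cm = canonicalize(model)
    return {
        "id": cm.id,
        "annotations": cm.annotations,
        "compartments": cm.compartments,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
                "charge": m.charge,
            }
            for m in cm.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr,
                "subsystem": r.subsystem,
            }
            for r in cm.reactions
        ],
    }


def read_model(path: PathLike) -> MetabolicModel:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"$: invalid JSON ({exc})") from exc
    return _model_from_dict(doc)


def write_model(model: MetabolicModel, path: PathLike) -> None:
    doc = _model_to_dict(model)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


# -- TSV tables ------------------------------------------------------------


def write_flux_tsv(
    fluxes: Mapping[str, float],
    path: PathLike,
    ranges: Optional[Mapping[str, tuple]] = None,
) -> None:
    rows = []
    for rid in sorted(fluxes):
        row = {"reaction_id": rid, "flux": f"{fluxes[rid]:.10g}"}
        if ranges is not None and rid in ranges:
            lo, hi = ranges[rid]
            row["lower"] = f"{lo:.10g}"
            row["upper"] = f"{hi:.10g}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_flux_tsv(path: PathLike) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["flux"].values, index=df["reaction_id"].values, name="flux")


def read_constraints_tsv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("reaction_id", "lb", "ub"):
        if col not in df.columns:
            raise SchemaError(f"constraint table {path}: missing column {col!r}")
    return df[["reaction_id", "lb", "ub"]]


def write_expression_tsv(counts: pd.DataFrame, lengths: pd.Series, path: PathLike) -> None:
    """counts: genes x samples (ints); lengths: per-gene transcript length (bp)."""
    out = counts.copy()
    out.insert(0, "length", lengths.reindex(counts.index).astype(int))
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_expression_tsv(path: PathLike) -> tuple[pd.DataFrame, pd.Series]:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    lengths = df.pop("length")
    return df, lengths


def write_pvalues_tsv(pvalues: Mapping[str, float], path: PathLike) -> None:
    rows = [{"gene": g, "pvalue": f"{pvalues[g]:.10g}"} for g in sorted(pvalues)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pvalues_tsv(path: PathLike) -> Dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["gene"].astype(str), df["pvalue"].astype(float)))


def read_gmt(path: PathLike) -> Dict[str, frozenset]:
    sets: Dict[str, frozenset] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = frozenset(p for p in parts[2:] if p)
    return sets


def write_gmt(sets: Mapping[str, frozenset], path: PathLike, description: str = "") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")
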