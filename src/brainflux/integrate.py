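"""Merging cell-type models into one brain model with intercellular links.

Each cell model is namespaced with a suffix token (neuron ``_N``, astrocyte
``_A``, microglia ``_M``, oligodendrocyte ``_O``): reaction ids, subsystem
labels, compartment tokens and metabolite compartments are all suffixed;
gene ids stay global.  A shared, unsuffixed "brain interstitial"
compartment (``ist``) is created for pooled species.  Exchange reactions
remain per-cell (each cell keeps its own uptake from blood).

Intercellular reactions then move a metabolite between the extracellular
interfaces of two cells (``met[e_N] -> met[e_A]``), or between a cell and
the interstitial pool (used for lactate, which is traded among all four
cells through one shared pool instead of pairwise reactions).  The default
spec encodes the transfers of the neuron-astrocyte cycle plus glial links:
glutamate N->A and N->M, glutamine A->N and A->M, GABA N->A,
glycine/aspartate/alanine N<->A, lactate among all four cells, and NAA
N->O.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .model import BIG_BOUND, MetabolicModel, Metabolite, ModelError, Reaction

__all__ = [
    "IntercellularSpec",
    "default_intercellular_spec",
    "merge_models",
    "add_intercellular_reactions",
    "DEFAULT_SUFFIXES",
]

DEFAULT_SUFFIXES = {
    "neuron": "N",
    "astrocyte": "A",
    "microglia": "M",
    "oligodendrocyte": "O",
}

#: token of the shared interstitial compartment
INTERSTITIAL = "ist"

_MET_RE = re.compile(r"(.+)\[([^\]]+)\]")


@dataclass(frozen=True)
class TransferRow:
    metabolite: str  # base name, e.g. "glu__L"
    from_cell: str  # suffix token ("N") or "ist"
    to_cell: str
    reversible: bool = False

    def __post_init__(self) -> None:
        if self.from_cell == self.to_cell:
            raise ModelError(f"intercellular row {self.metabolite!r}: from == to ({self.from_cell!r})")


@dataclass
class IntercellularSpec:
    rows: List[TransferRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for row in self.rows:
            key = (row.metabolite, row.from_cell, row.to_cell)
            if key in seen or (row.metabolite, row.to_cell, row.from_cell) in seen:
                raise ModelError(f"duplicate intercellular row {key}")
            seen.add(key)


def default_intercellular_spec(cells: Sequence[str] = ("N", "A", "M", "O")) -> IntercellularSpec:
    rows = [
        TransferRow("glu__L", "N", "A"),
        TransferRow("gln__L", "A", "N"),
        TransferRow("gaba", "N", "A"),
        TransferRow("gly", "N", "A", reversible=True),
        TransferRow("asp__L", "N", "A", reversible=True),
        TransferRow("ala__L", "N", "A", reversible=True),
        TransferRow("naa", "N", "O"),
        TransferRow("gln__L", "A", "M"),
        TransferRow("glu__L", "N", "M"),
    ]
    for cell in cells:
        rows.append(TransferRow("lac__L", cell, INTERSTITIAL, reversible=True))
    return IntercellularSpec(rows=rows)


def _suffix_met(met_id: str, suffix: str) -> str:
    m = _MET_RE.fullmatch(met_id)
    if not m:
        raise ModelError(f"metabolite id {met_id!r} lacks a [compartment] token")
    return f"{m.group(1)}[{m.group(2)}_{suffix}]"


def _suffix_model(model: MetabolicModel, suffix: str) -> MetabolicModel:
    out = MetabolicModel(
        model_id=f"{model.id}_{suffix}",
        annotations={"suffix": suffix, "source_model": model.id, **{
            k: v for k, v in model.annotations.items() if k == "cell_type"
        }},
    )
    for m in model.metabolites:
        out.add_metabolite(
            Metabolite(
                id=_suffix_met(m.id, suffix),
                name=m.name,
                compartment=f"{m.compartment}_{suffix}",
                formula=m.formula,
                charge=m.charge,
            )
        )
    for comp, name in model.compartments.items():
        out.compartments[f"{comp}_{suffix}"] = f"{name} ({suffix})"
    for r in model.reactions:
        out.add_reaction(
            Reaction(
                id=f"{r.id}_{suffix}",
                stoichiometry={_suffix_met(k, suffix): v for k, v in r.stoichiometry.items()},
                name=r.name,
                lower_bound=r.lower_bound,
                upper_bound=r.upper_bound,
                gpr=r.gpr,
                subsystem=f"{r.subsystem}_{suffix}" if r.subsystem else "",
            )
        )
    return out


def merge_models(
    models: Sequence[MetabolicModel],
    suffixes: Sequence[Optional[str]],
    model_id: str = "brain",
) -> MetabolicModel:
    """Merge cell models into one namespaced brain model.

    ``suffixes[i]`` is the token for ``models[i]``; a model that is already
    a merge result (annotation ``merged``) is passed with suffix None and
    incorporated as-is, which makes sequential pairwise merging equal to the
    one-shot merge up to canonical form.
    """
    if len(models) < 2:
        raise ModelError("merge needs at least two models")
    if len(models) != len(suffixes):
        raise ModelError("one suffix per model required")
    used: set[str] = set()
    parts: List[MetabolicModel] = []
    suffix_map: Dict[str, str] = {}
    for model, suffix in zip(models, suffixes):
        if suffix is None:
            if not model.annotations.get("merged"):
                raise ModelError(f"model {model.id!r} needs a suffix (not a previous merge)")
            prior = model.annotations.get("suffixes", {})
            clash = set(prior) & used
            if clash:
                raise ModelError(f"suffix collision: {sorted(clash)}")
            used |= set(prior)
            suffix_map.update(prior)
            parts.append(model)
        else:
            if suffix in used:
                raise ModelError(f"suffix collision: {suffix!r}")
            used.add(suffix)
            cell = model.annotations.get("cell_type", model.id)
            suffix_map[suffix] = str(cell)
            parts.append(_suffix_model(model, suffix))
    out = MetabolicModel(
        model_id=model_id,
        annotations={"merged": True, "suffixes": suffix_map},
    )
    out.compartments[INTERSTITIAL] = "brain interstitial"
    for part in parts:
        for m in part.metabolites:
            if not out.has_metabolite(m.id):
                out.add_metabolite(m)
        for comp, name in part.compartments.items():
            out.compartments.setdefault(comp, name)
        for r in part.reactions:
            out.add_reaction(r.copy())
    out.validate()
    return out


def add_intercellular_reactions(brain: MetabolicModel, spec: IntercellularSpec) -> MetabolicModel:
    """Wire the intercellular transfer reactions into a merged brain model.

    Each row becomes one transport reaction ``ICT_<met>_<from>_<to>`` moving
    the metabolite between the two extracellular interfaces (coefficient -1
    source, +1 target: mass-conserving).  Interstitial pool species are
    created on demand.  Missing interface metabolites raise, naming the
    cell and metabolite.
    """
    out = brain.copy()
    for row in spec.rows:
        ends = []
        for cell in (row.from_cell, row.to_cell):
            if cell == INTERSTITIAL:
                met_id = f"{row.metabolite}[{INTERSTITIAL}]"
                if not out.has_metabolite(met_id):
                    out.add_metabolite(
                        Metabolite(id=met_id, name=row.metabolite, compartment=INTERSTITIAL)
                    )
            else:
                met_id = f"{row.metabolite}[e_{cell}]"
                if not out.has_metabolite(met_id):
                    raise ModelError(
                        f"cell {cell!r} lacks extracellular metabolite "
                        f"{row.metabolite!r} (expected {met_id!r})"
                    )
            ends.append(met_id)
        rid = f"ICT_{row.metabolite}_{row.from_cell}_{row.to_cell}"
        if out.has_reaction(rid):
            raise ModelError(f"intercellular reaction {rid!r} already present")
        out.add_reaction(
            Reaction(
                id=rid,
                stoichiometry={ends[0]: -1.0, ends[1]: 1.0},
                name=f"{row.metabolite} transfer {row.from_cell}->{row.to_cell}",
                lower_bound=-BIG_BOUND if row.reversible else 0.0,
                upper_bound=BIG_BOUND,
                subsystem="Intercellular transport",
            )
        )
    return out
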