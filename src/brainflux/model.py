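"""Core data structures for compartmentalized stoichiometric models.

A :class:`MetabolicModel` is a list of metabolites and reactions with flux
bounds, gene-protein-reaction rules and subsystem labels — the information
needed to assemble the stoichiometric matrix S and pose flux-balance
problems.  Flux units are fixed at umol/g tissue/min throughout the package;
there is no unit-conversion layer.

Conventions
-----------
* Metabolite ids carry their compartment token in brackets: ``glc__D[c]``.
* Exchange/demand reactions have exactly one metabolite; for exchanges,
  negative flux means uptake into the system.
* Coupling pseudo-metabolites (see :mod:`brainflux.simulate`) live in the
  reserved compartment ``x`` and are prefixed ``CPL_``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional

import numpy as np
import scipy.sparse as sp

from .gpr import gpr_genes, parse_gpr

__all__ = [
    "ModelError",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "build_stoichiometric_matrix",
    "canonicalize",
]

#: default large bound used for "unconstrained" directions
BIG_BOUND = 1000.0


class ModelError(ValueError):
    """Structural error in a metabolic model (dangling ids, bad bounds...)."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: Optional[str] = None
    charge: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelError("metabolite id must be non-empty")
        if not self.compartment:
            raise ModelError(f"metabolite {self.id!r}: compartment token must be non-empty")


@dataclass
class Reaction:
    id: str
    stoichiometry: Dict[str, float]
    name: str = ""
    lower_bound: float = 0.0
    upper_bound: float = BIG_BOUND
    gpr: str = ""
    subsystem: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelError("reaction id must be non-empty")
        if not (self.lower_bound <= self.upper_bound):
            raise ModelError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id!r}: empty stoichiometry")
        if len(self.stoichiometry) == 1 and not self.subsystem:
            self.subsystem = "Exchange/demand"

    @property
    def is_boundary(self) -> bool:
        """True for exchange/demand reactions (single real metabolite).

        Coupling pseudo-metabolites (``CPL_`` prefix, compartment ``x``) are
        bookkeeping rows, not species, and do not count.
        """
        real = [m for m in self.stoichiometry if not m.startswith("CPL_")]
        return len(real) == 1

    @property
    def genes(self) -> frozenset[str]:
        return gpr_genes(self.gpr)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            name=self.name,
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            gpr=self.gpr,
            subsystem=self.subsystem,
        )


class MetabolicModel:
    """A compartmentalized reaction network with GPRs and subsystems."""

    def __init__(
        self,
        model_id: str = "model",
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        annotations: Optional[Mapping[str, object]] = None,
        compartments: Optional[Mapping[str, str]] = None,
    ) -> None:
        self.id = model_id
        self.metabolites: List[Metabolite] = []
        self.reactions: List[Reaction] = []
        self._met_index: Dict[str, int] = {}
        self._rxn_index: Dict[str, int] = {}
        self.annotations: Dict[str, object] = dict(annotations or {})
        self.compartments: Dict[str, str] = dict(compartments or {})
        for m in metabolites:
            self.add_metabolite(m)
        for r in reactions:
            self.add_reaction(r)

    # -- membership -------------------------------------------------------

    @property
    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= r.genes
        return frozenset(out)

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self.metabolites[self._met_index[met_id]]
        except KeyError:
            raise ModelError(f"unknown metabolite {met_id!r} in model {self.id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self.reactions[self._rxn_index[rxn_id]]
        except KeyError:
            raise ModelError(f"unknown reaction {rxn_id!r} in model {self.id!r}") from None

    # -- construction -----------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self._met_index:
            raise ModelError(f"duplicate metabolite id {met.id!r}")
        self._met_index[met.id] = len(self.metabolites)
        self.metabolites.append(met)
        self.compartments.setdefault(met.compartment, met.compartment)

    def add_reaction(self, rxn: Reaction, metabolites: Iterable[Metabolite] = ()) -> None:
        """Add a reaction, optionally supplying metabolites it introduces.

        Fails if the reaction id already exists or if the stoichiometry
        references a metabolite that neither exists nor is supplied.
        """
        if rxn.id in self._rxn_index:
            raise ModelError(f"duplicate reaction id {rxn.id!r}")
        for met in metabolites:
            if not self.has_metabolite(met.id):
                self.add_metabolite(met)
        for met_id in rxn.stoichiometry:
            if met_id not in self._met_index:
                raise ModelError(
                    f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                )
        parse_gpr(rxn.gpr)  # validate early
        self._rxn_index[rxn.id] = len(self.reactions)
        self.reactions.append(rxn)

    def remove_reactions(self, rxn_ids: Iterable[str], prune_orphans: bool = False) -> None:
        drop = set(rxn_ids)
        missing = drop - set(self._rxn_index)
        if missing:
            raise ModelError(f"cannot remove unknown reactions: {sorted(missing)}")
        self.reactions = [r for r in self.reactions if r.id not in drop]
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        if prune_orphans:
            used: set[str] = set()
            for r in self.reactions:
                used |= set(r.stoichiometry)
            self.metabolites = [m for m in self.metabolites if m.id in used]
            self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}

    def copy(self, model_id: Optional[str] = None) -> "MetabolicModel":
        return MetabolicModel(
            model_id=model_id or self.id,
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            annotations=dict(self.annotations),
            compartments=dict(self.compartments),
        )

    # -- queries ----------------------------------------------------------

    def reactions_of_metabolite(self, met_id: str) -> List[Reaction]:
        """All reactions producing or consuming the given metabolite."""
        self.metabolite(met_id)
        return [r for r in self.reactions if met_id in r.stoichiometry]

    def boundary_reactions(self) -> List[Reaction]:
        return [r for r in self.reactions if r.is_boundary]

    def exchanges_of(self, met_id: str) -> List[Reaction]:
        return [r for r in self.boundary_reactions() if met_id in r.stoichiometry]

    def validate(self) -> None:
        """Re-check all structural invariants; raise ModelError on violation."""
        seen_m: set[str] = set()
        for m in self.metabolites:
            if m.id in seen_m:
                raise ModelError(f"duplicate metabolite id {m.id!r}")
            seen_m.add(m.id)
        seen_r: set[str] = set()
        for r in self.reactions:
            if r.id in seen_r:
                raise ModelError(f"duplicate reaction id {r.id!r}")
            seen_r.add(r.id)
            if not (r.lower_bound <= r.upper_bound):
                raise ModelError(f"reaction {r.id!r}: lb > ub")
            for met_id, coeff in r.stoichiometry.items():
                if met_id not in self._met_index:
                    raise ModelError(
                        f"reaction {r.id!r} references unknown metabolite {met_id!r}"
                    )
                if not math.isfinite(coeff):
                    raise ModelError(f"reaction {r.id!r}: non-finite coefficient for {met_id!r}")
            parse_gpr(r.gpr)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions, {len(self.genes)} genes>"
        )


def build_stoichiometric_matrix(model: MetabolicModel) -> sp.csc_matrix:
    """Assemble S (metabolites x reactions) in model order.

    Entry (i, j) is the signed coefficient of metabolite i in reaction j
    (negative = consumed).  Raises :class:`ModelError`, naming the offending
    reaction, if a stoichiometry references an unknown metabolite.
    """
    n_met = len(model.metabolites)
    n_rxn = len(model.reactions)
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for j, rxn in enumerate(model.reactions):
        for met_id, coeff in rxn.stoichiometry.items():
            try:
                i = met_index[met_id]
            except KeyError:
                raise ModelError(
                    f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                ) from None
            rows.append(i)
            cols.append(j)
            vals.append(float(coeff))
    return sp.csc_matrix((vals, (rows, cols)), shape=(n_met, n_rxn))


def canonicalize(model: MetabolicModel) -> MetabolicModel:
    """Return a canonical copy: ids sorted, zero coefficients dropped.

    Canonical form is the equality domain for round-trip I/O and for
    merge-order associativity checks.
    """
    mets = sorted(model.metabolites, key=lambda m: m.id)
    rxns = []
    for r in sorted(model.reactions, key=lambda r: r.id):
        stoich = {k: float(v) for k, v in sorted(r.stoichiometry.items()) if v != 0}
        if not stoich:
            raise ModelError(f"reaction {r.id!r} has only zero coefficients")
        rxns.append(
            Reaction(
                id=r.id,
                stoichiometry=stoich,
                name=r.name,
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                gpr=" ".join(r.gpr.split()),
                subsystem=r.subsystem,
            )
        )
    used = set()
    for r in rxns:
        used |= set(r.stoichiometry)
    mets = [m for m in mets if m.id in used]
    out = MetabolicModel(
        model_id=model.id,
        metabolites=mets,
        reactions=rxns,
        annotations=dict(model.annotations),
        compartments={k: model.compartments[k] for k in sorted(model.compartments)},
    )
    return out


def models_equal(a: MetabolicModel, b: MetabolicModel) -> bool:
    """Structural equality on canonical form (ignores annotations)."""
    ca, cb = canonicalize(a), canonicalize(b)
    if ca.metabolite_ids != cb.metabolite_ids or ca.reaction_ids != cb.reaction_ids:
        return False
    for ma, mb in zip(ca.metabolites, cb.metabolites):
        if (ma.compartment, ma.formula, ma.charge) != (mb.compartment, mb.formula, mb.charge):
            return False
    for ra, rb in zip(ca.reactions, cb.reactions):
        if ra.stoichiometry != rb.stoichiometry:
            return False
        if (ra.lower_bound, ra.upper_bound, ra.subsystem) != (
            rb.lower_bound,
            rb.upper_bound,
            rb.subsystem,
        ):
            return False
        if gpr_genes(ra.gpr) != gpr_genes(rb.gpr) or ra.gpr != rb.gpr:
            return False
    return True
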