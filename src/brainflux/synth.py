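"""Synthetic toy brain network, expression counts, and DE p-values.

Everything downstream (extraction, integration, simulation protocols,
reporter scoring) is exercised on the networks built here, so the generator
encodes the qualitative physiology the simulations are expected to show:

* glucose is the primary fuel: glycolysis -> pyruvate -> TCA -> oxidative
  phosphorylation, with an anaerobic lactate branch and a lactate shuttle;
* ketone bodies (acetoacetate, (R)-3-hydroxybutanoate) enter as acetyl-CoA,
  bypassing glycolysis, so ketone supplementation shifts activity from
  glycolysis toward the TCA cycle and oxidative phosphorylation;
* oxygen caps oxidative phosphorylation, so lowering it shifts ATP
  production toward anaerobic glycolysis;
* the neuron-astrocyte glutamate/glutamine/GABA cycle, BCAA and serine
  shuttles, catecholamine and acetylcholine synthesis, NAA transfer to
  oligodendrocytes, and oligodendrocyte myelin formation (cholesterol,
  galactosylceramide, phosphatidylcholine, phosphatidylethanolamine,
  sphingomyelin) compete for shared carbon, NADPH and ATP.

Stoichiometries are lumped and illustrative: cofactor pairs (ATP/ADP,
NAD(P)H) are balanced so that energy accounting is meaningful, but elemental
mass balance is advisory only.  All reactions carry subsystem labels from a
fixed vocabulary and (for internal enzymatic steps) GPRs over a synthetic
global gene namespace G0001...; transporters for a few genetically
well-known carriers also carry genes.  Everything is deterministic given the
spec seed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .gpr import gpr_genes
from .model import BIG_BOUND, MetabolicModel, Metabolite, ModelError, Reaction
from .simulate import ConstraintTable

__all__ = [
    "CELL_TYPES",
    "PATHWAYS",
    "ToyBrainSpec",
    "PlantedDESpec",
    "SpecError",
    "generate_toy_cell_model",
    "generate_expression_profiles",
    "generate_de_pvalues",
    "default_constraints",
    "silent_genes",
    "expressed_genes",
]

CELL_TYPES = ("neuron", "astrocyte", "microglia", "oligodendrocyte", "OPC")
CELL_CODE = {"neuron": "N", "astrocyte": "A", "microglia": "M", "oligodendrocyte": "O", "OPC": "P"}

PATHWAYS = (
    "glycolysis",
    "TCA",
    "oxphos",
    "PPP",
    "beta_oxidation",
    "carnitine_shuttle",
    "ketone_utilization",
    "cholesterol_synthesis",
    "fatty_acid_synthesis",
    "glu_gln_gaba",
    "lactate_shuttle",
    "NAA",
    "myelin",
)


class SpecError(ValueError):
    """Invalid toy-network specification (toggle dependencies etc.)."""


@dataclass
class ToyBrainSpec:
    """Which cell types and pathways the toy network carries."""

    cell_types: Tuple[str, ...] = ("neuron", "astrocyte", "microglia", "oligodendrocyte")
    pathways: Dict[str, bool] = field(default_factory=lambda: {p: True for p in PATHWAYS})
    seed: int = 0
    #: override the myelin formation stoichiometry (component -> coefficient);
    #: default is equimolar in the five lipid components
    myelin_coefficients: Optional[Dict[str, float]] = None

    def __post_init__(self) -> None:
        unknown = set(self.cell_types) - set(CELL_TYPES)
        if unknown:
            raise SpecError(f"unknown cell types: {sorted(unknown)}")
        unknown = set(self.pathways) - set(PATHWAYS)
        if unknown:
            raise SpecError(f"unknown pathway toggles: {sorted(unknown)}")
        for p in PATHWAYS:
            self.pathways.setdefault(p, True)
        if self.pathways["glu_gln_gaba"] and not (
            "neuron" in self.cell_types and "astrocyte" in self.cell_types
        ):
            raise SpecError("glu_gln_gaba requires both neuron and astrocyte cell types")
        if self.pathways["myelin"] and "oligodendrocyte" not in self.cell_types:
            raise SpecError("myelin requires the oligodendrocyte cell type")
        if self.pathways["carnitine_shuttle"] and not self.pathways["beta_oxidation"]:
            raise SpecError("carnitine_shuttle requires beta_oxidation")
        # biomass needs ATP, an amino-acid precursor, lipid and a nucleotide
        # surrogate: these pathways cannot be disabled
        for needed in ("glycolysis", "TCA", "oxphos", "PPP", "fatty_acid_synthesis", "glu_gln_gaba"):
            if not self.pathways[needed]:
                raise SpecError(f"biomass precursors require pathway {needed!r} to be enabled")


@dataclass
class PlantedDESpec:
    """Planted differential-expression structure for reporter recovery tests.

    Genes in GPRs of reactions adjacent to ``hot_metabolites`` receive
    p-values whose -log10 has mean ``effect``; all other genes are
    Uniform(0,1).
    """

    hot_metabolites: Tuple[str, ...] = ()
    effect: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect < 0:
            raise SpecError("effect must be >= 0")


# ---------------------------------------------------------------------------
# metabolite and reaction templates
# ---------------------------------------------------------------------------

_MET_NAMES = {
    "glc__D": "D-glucose", "g6p": "glucose 6-phosphate", "r5p": "ribose 5-phosphate",
    "pyr": "pyruvate", "lac__L": "L-lactate", "o2": "oxygen", "co2": "carbon dioxide",
    "atp": "ATP", "adp": "ADP", "nad": "NAD+", "nadh": "NADH", "nadp": "NADP+",
    "nadph": "NADPH", "accoa": "acetyl-CoA", "oaa": "oxaloacetate", "cit": "citrate",
    "akg": "2-oxoglutarate", "acac": "acetoacetate", "bhb__R": "(R)-3-hydroxybutanoate",
    "hdca": "palmitate", "palcoa": "palmitoyl-CoA", "pmtcrn": "palmitoylcarnitine",
    "crn": "L-carnitine", "chln": "choline", "etha": "ethanolamine", "lipid": "membrane lipid",
    "hmgcoa": "HMG-CoA", "mev": "mevalonate", "chsterol": "cholesterol",
    "sphgn": "sphinganine", "cer": "ceramide", "sm": "sphingomyelin",
    "galcer": "galactosylceramide", "pc": "phosphatidylcholine",
    "pe": "phosphatidylethanolamine", "myelin": "myelin sheath unit",
    "gln__L": "L-glutamine", "glu__L": "L-glutamate", "gaba": "4-aminobutanoate",
    "asp__L": "L-aspartate", "ala__L": "L-alanine", "gly": "glycine", "ser__L": "L-serine",
    "leu__L": "L-leucine", "ile__L": "L-isoleucine", "val__L": "L-valine",
    "4mop": "4-methyl-2-oxopentanoate", "3mop": "3-methyl-2-oxopentanoate",
    "3mob": "3-methyl-2-oxobutanoate", "34dhphe": "levodopa", "dopa": "dopamine",
    "nrpphr": "norepinephrine", "adrnl": "adrenaline", "ach": "acetylcholine",
    "naa": "N-acetyl-L-aspartate", "ac": "acetate", "biomass": "biomass",
}

_COMP_NAMES = {"c": "cytosol", "m": "mitochondria", "e": "extracellular", "x": "coupling", "ist": "brain interstitial"}

_ALL = frozenset("NAMOP")


def _R(
    rid: str,
    stoich: Dict[str, float],
    subsystem: str,
    cells: str,
    gpr: str = "",
    lb: float = 0.0,
    ub: float = BIG_BOUND,
    pathway: Optional[str] = None,
    silent_in: str = "",
    name: str = "",
) -> dict:
    return {
        "id": rid, "stoich": stoich, "subsystem": subsystem, "cells": frozenset(cells),
        "gpr": gpr, "lb": lb, "ub": ub, "pathway": pathway, "silent_in": frozenset(silent_in),
        "name": name,
    }


def _ex(met: str, cells: str, pathway: Optional[str] = None) -> dict:
    return _R(f"EX_{met}", {f"{met}[e]": -1.0}, "Exchange/demand", cells, lb=-0.01, pathway=pathway)


# GPR placeholders: "g" single gene, "g|g" isozymes, "g&g" complex,
# "(g&g)|g" complex with isozyme.  Gene ids are allocated deterministically
# from the global registry in table order; a reaction keeps the same genes in
# every cell type (shared global namespace).
def _template() -> List[dict]:
    T: List[dict] = []
    # -- core energy metabolism (all cells) -------------------------------
    T += [
        _ex("glc__D", "NAMOP", "glycolysis"),
        _R("GLCt", {"glc__D[e]": -1, "glc__D[c]": 1}, "Transport", "NAMOP", gpr="g", pathway="glycolysis"),
        _R("HEX1", {"glc__D[c]": -1, "atp[c]": -1, "g6p[c]": 1, "adp[c]": 1}, "Glycolysis", "NAMOP", gpr="g|g", pathway="glycolysis"),
        _R("GLYCL", {"g6p[c]": -1, "adp[c]": -3, "nad[c]": -2, "pyr[c]": 2, "atp[c]": 3, "nadh[c]": 2},
           "Glycolysis", "NAMOP", gpr="g&g", pathway="glycolysis", name="lower glycolysis (lumped)"),
        _R("LDH_L", {"pyr[c]": -1, "nadh[c]": -1, "lac__L[c]": 1, "nad[c]": 1}, "Pyruvate metabolism", "NAMOP",
           gpr="g|g", lb=-BIG_BOUND, pathway="glycolysis", name="lactate dehydrogenase"),
        _R("L_LACt", {"lac__L[c]": -1, "lac__L[e]": 1}, "Transport", "NAMOP", gpr="g", lb=-BIG_BOUND, pathway="lactate_shuttle"),
        _ex("lac__L", "NAMOP", "lactate_shuttle"),
        _ex("o2", "NAMOP", "oxphos"),
        _R("O2t", {"o2[e]": -1, "o2[c]": 1}, "Transport", "NAMOP", pathway="oxphos"),
        _R("PDH", {"pyr[c]": -1, "nad[c]": -1, "accoa[m]": 1, "co2[c]": 1, "nadh[c]": 1},
           "Pyruvate metabolism", "NAMOP", gpr="g&g", pathway="TCA"),
        _R("PC", {"pyr[c]": -1, "atp[c]": -1, "co2[c]": -1, "oaa[m]": 1, "adp[c]": 1},
           "Pyruvate metabolism", "NAMOP", gpr="g", pathway="TCA", name="pyruvate carboxylase (anaplerosis)"),
        _R("CS", {"accoa[m]": -1, "oaa[m]": -1, "cit[m]": 1}, "TCA cycle", "NAMOP", gpr="g", pathway="TCA"),
        _R("ICDH", {"cit[m]": -1, "nad[c]": -1, "akg[m]": 1, "co2[c]": 1, "nadh[c]": 1},
           "TCA cycle", "NAMOP", gpr="g|g", pathway="TCA"),
        _R("AKGD", {"akg[m]": -1, "nad[c]": -2, "oaa[m]": 1, "co2[c]": 2, "nadh[c]": 2},
           "TCA cycle", "NAMOP", gpr="g&g", pathway="TCA", name="2-oxoglutarate -> oxaloacetate (lumped)"),
        _R("OXPHOS", {"nadh[c]": -1, "o2[c]": -0.5, "adp[c]": -1.5, "nad[c]": 1, "atp[c]": 1.5},
           "Oxidative phosphorylation", "NAMOP", gpr="(g&g)|g", pathway="oxphos",
           name="electron transport chain (P/O 1.5, lumped)"),
        _R("ATPM", {"atp[c]": -1, "adp[c]": 1}, "Energy maintenance", "NAMOP", name="ATP maintenance demand"),
        _R("CO2t", {"co2[c]": -1, "co2[e]": 1}, "Transport", "NAMOP", lb=-BIG_BOUND),
        _ex("co2", "NAMOP"),
    ]
    # -- pentose phosphate pathway ----------------------------------------
    T += [
        _R("G6PDH2", {"g6p[c]": -1, "nadp[c]": -2, "r5p[c]": 1, "co2[c]": 1, "nadph[c]": 2},
           "Pentose phosphate pathway", "NAMOP", gpr="g", pathway="PPP"),
        _R("PPPNOX", {"r5p[c]": -1, "g6p[c]": 0.833}, "Pentose phosphate pathway", "NAMOP",
           gpr="g", pathway="PPP", name="non-oxidative PPP (lumped)"),
        _R("NADPHD", {"nadph[c]": -1, "nadp[c]": 1}, "Miscellaneous", "NAMOP", name="NADPH-consuming defense demand"),
    ]
    # -- ketone body utilization ------------------------------------------
    T += [
        _ex("acac", "NAMOP", "ketone_utilization"),
        _R("ACACt", {"acac[e]": -1, "acac[m]": 1}, "Transport", "NAMOP", gpr="g", pathway="ketone_utilization"),
        _ex("bhb__R", "NAMOP", "ketone_utilization"),
        _R("BHBt", {"bhb__R[e]": -1, "bhb__R[m]": 1}, "Transport", "NAMOP", gpr="g", pathway="ketone_utilization"),
        _R("BDH", {"bhb__R[m]": -1, "nad[c]": -1, "acac[m]": 1, "nadh[c]": 1},
           "Ketone bodies metabolism", "NAMOP", gpr="g", pathway="ketone_utilization"),
        _R("AACOAT", {"acac[m]": -1, "accoa[m]": 2}, "Ketone bodies metabolism", "NAMOP",
           gpr="g&g", pathway="ketone_utilization", name="acetoacetate -> 2 acetyl-CoA (lumped)"),
    ]
    # -- fatty acid oxidation + carnitine shuttle -------------------------
    T += [
        _ex("hdca", "NAMOP", "beta_oxidation"),
        _R("FAt", {"hdca[e]": -1, "hdca[c]": 1}, "Transport", "NAMOP", pathway="beta_oxidation"),
        _R("FACOA", {"hdca[c]": -1, "atp[c]": -2, "palcoa[c]": 1, "adp[c]": 2},
           "Fatty acid oxidation", "NAMOP", gpr="g", pathway="beta_oxidation"),
        _ex("crn", "NAMOP", "carnitine_shuttle"),
        _R("CRNt", {"crn[e]": -1, "crn[c]": 1}, "Transport", "NAMOP", gpr="g", pathway="carnitine_shuttle",
           name="carnitine transporter (OCTN2-like)"),
        _R("CPT1", {"palcoa[c]": -1, "crn[c]": -1, "pmtcrn[c]": 1}, "Carnitine shuttle", "NAMOP",
           gpr="g", pathway="carnitine_shuttle"),
        _R("CPT2", {"pmtcrn[c]": -1, "palcoa[m]": 1, "crn[c]": 1}, "Carnitine shuttle", "NAMOP",
           gpr="g", pathway="carnitine_shuttle"),
        _R("FAOX", {"palcoa[m]": -1, "nad[c]": -2, "accoa[m]": 2, "nadh[c]": 2},
           "Fatty acid oxidation", "NAMOP", gpr="g&g", pathway="beta_oxidation", name="beta-oxidation (lumped)"),
    ]
    # -- fatty acid synthesis / membrane lipid ----------------------------
    T += [
        _R("FAS", {"accoa[m]": -2, "atp[c]": -1, "nadph[c]": -2, "hdca[c]": 1, "adp[c]": 1, "nadp[c]": 2},
           "Fatty acid biosynthesis", "NAMOP", gpr="g&g", pathway="fatty_acid_synthesis", name="fatty acid synthase (lumped)"),
        _R("LIPSYN", {"hdca[c]": -2, "atp[c]": -1, "lipid[c]": 1, "adp[c]": 1},
           "Glycerophospholipid metabolism", "NAMOP", gpr="g", pathway="fatty_acid_synthesis"),
    ]
    # -- cholesterol biosynthesis (silenced outside astrocyte/oligo) ------
    T += [
        _R("HMGCS", {"accoa[m]": -2, "hmgcoa[c]": 1}, "Cholesterol biosynthesis", "NAOP",
           gpr="g", pathway="cholesterol_synthesis", silent_in="N"),
        _R("HMGCR", {"hmgcoa[c]": -1, "nadph[c]": -2, "mev[c]": 1, "nadp[c]": 2},
           "Cholesterol biosynthesis", "NAOP", gpr="g", pathway="cholesterol_synthesis", silent_in="N"),
        _R("CHOLSYN", {"mev[c]": -2, "atp[c]": -2, "nadph[c]": -2, "chsterol[c]": 1, "adp[c]": 2, "nadp[c]": 2},
           "Cholesterol biosynthesis", "NAOP", gpr="g&g", pathway="cholesterol_synthesis", silent_in="N",
           name="mevalonate -> cholesterol (lumped)"),
    ]
    # -- sphingolipid and phospholipid synthesis (oligo; silent in microglia)
    T += [
        _R("SPHSYN", {"hdca[c]": -1, "ser__L[c]": -1, "nadph[c]": -1, "sphgn[c]": 1, "nadp[c]": 1},
           "Sphingolipid metabolism", "MO", gpr="g", pathway="myelin", silent_in="M"),
        _R("CERSYN", {"sphgn[c]": -1, "hdca[c]": -1, "cer[c]": 1}, "Sphingolipid metabolism", "MO",
           gpr="g", pathway="myelin", silent_in="M"),
        _R("SMSYN", {"cer[c]": -1, "chln[c]": -1, "atp[c]": -1, "sm[c]": 1, "adp[c]": 1},
           "Sphingolipid metabolism", "MO", gpr="g", pathway="myelin", silent_in="M"),
        _R("GALCS", {"cer[c]": -1, "g6p[c]": -1, "galcer[c]": 1}, "Sphingolipid metabolism", "MO",
           gpr="g", pathway="myelin", silent_in="M"),
        _R("PCSYN", {"hdca[c]": -2, "chln[c]": -1, "atp[c]": -2, "pc[c]": 1, "adp[c]": 2},
           "Glycerophospholipid metabolism", "O", gpr="g", pathway="myelin"),
        _R("PESYN", {"hdca[c]": -2, "etha[c]": -1, "atp[c]": -2, "pe[c]": 1, "adp[c]": 2},
           "Glycerophospholipid metabolism", "O", gpr="g", pathway="myelin"),
        _ex("etha", "O", "myelin"),
        _R("ETHAt", {"etha[e]": -1, "etha[c]": 1}, "Transport", "O", pathway="myelin"),
    ]
    # choline: neuron (acetylcholine) and sphingolipid-bearing cells
    T += [
        _ex("chln", "NMO"),
        _R("CHLNt", {"chln[e]": -1, "chln[c]": 1}, "Transport", "NMO", gpr="g"),
    ]
    # -- myelin formation (oligodendrocyte) -------------------------------
    T += [
        _R("MYELIN", {"chsterol[c]": -1, "galcer[c]": -1, "pc[c]": -1, "pe[c]": -1, "sm[c]": -1,
                      "atp[c]": -2, "myelin[c]": 1, "adp[c]": 2},
           "Myelin synthesis", "O", gpr="g", pathway="myelin", name="myelin sheath formation"),
        _R("DM_myelin", {"myelin[c]": -1}, "Exchange/demand", "O", pathway="myelin", name="myelin demand"),
    ]
    # -- glutamate / glutamine / GABA -------------------------------------
    T += [
        _ex("gln__L", "NAM", "glu_gln_gaba"),
        _R("GLNt", {"gln__L[e]": -1, "gln__L[c]": 1}, "Transport", "NAM", gpr="g", lb=-BIG_BOUND, pathway="glu_gln_gaba"),
        _ex("glu__L", "NAM", "glu_gln_gaba"),
        _R("GLUt", {"glu__L[e]": -1, "glu__L[c]": 1}, "Transport", "NAM", gpr="g", lb=-BIG_BOUND, pathway="glu_gln_gaba"),
        _R("GLS", {"gln__L[c]": -1, "glu__L[c]": 1}, "Glutamate metabolism", "NM", gpr="g", pathway="glu_gln_gaba",
           name="glutaminase"),
        _R("GLNS", {"glu__L[c]": -1, "atp[c]": -1, "gln__L[c]": 1, "adp[c]": 1},
           "Glutamine metabolism", "NA", gpr="g", ub=0.2, pathway="glu_gln_gaba", silent_in="N",
           name="glutamine synthetase (capacity-limited)"),
        _R("GAD", {"glu__L[c]": -1, "gaba[c]": 1, "co2[c]": 1}, "Glutamate metabolism", "NA",
           gpr="g", pathway="glu_gln_gaba", silent_in="A", name="glutamate decarboxylase"),
        _R("GABASH", {"gaba[c]": -1, "co2[c]": -1, "glu__L[c]": 1}, "Glutamate metabolism", "NA",
           gpr="g", pathway="glu_gln_gaba", name="GABA shunt to glutamate (lumped)"),
        _R("GLUDH", {"glu__L[c]": -1, "nad[c]": -1, "akg[m]": 1, "nadh[c]": 1},
           "Glutamate metabolism", "NAMOP", gpr="g|g", lb=-BIG_BOUND, pathway="glu_gln_gaba",
           name="glutamate dehydrogenase"),
        _R("GABAt", {"gaba[c]": -1, "gaba[e]": 1}, "Transport", "NA", gpr="g", lb=-BIG_BOUND, pathway="glu_gln_gaba"),
        _ex("gaba", "NA", "glu_gln_gaba"),
        _R("ASPTA", {"oaa[m]": -1, "glu__L[c]": -1, "asp__L[c]": 1, "akg[m]": 1},
           "Alanine, aspartate and glutamate metabolism", "NAO", gpr="g", lb=-BIG_BOUND, name="aspartate transaminase"),
        _R("ASPt", {"asp__L[c]": -1, "asp__L[e]": 1}, "Transport", "NA", gpr="g", lb=-BIG_BOUND),
        _ex("asp__L", "NA"),
        _R("ALATA", {"pyr[c]": -1, "glu__L[c]": -1, "ala__L[c]": 1, "akg[m]": 1},
           "Alanine, aspartate and glutamate metabolism", "NA", gpr="g", lb=-BIG_BOUND, name="alanine transaminase"),
        _R("ALAt", {"ala__L[c]": -1, "ala__L[e]": 1}, "Transport", "NA", gpr="g", lb=-BIG_BOUND),
        _ex("ala__L", "NA"),
    ]
    # -- serine / glycine --------------------------------------------------
    T += [
        _ex("ser__L", "NAO"),
        _R("SERt", {"ser__L[e]": -1, "ser__L[c]": 1}, "Transport", "NAO", gpr="g", lb=-BIG_BOUND),
        _R("SERGLY", {"ser__L[c]": -1, "gly[c]": 1}, "Glycine, serine and threonine metabolism", "N",
           gpr="g", name="serine -> glycine"),
        _R("GLYSER", {"gly[c]": -1, "co2[c]": -1, "ser__L[c]": 1}, "Glycine, serine and threonine metabolism", "A",
           gpr="g", name="glycine -> serine"),
        _R("GLYt", {"gly[c]": -1, "gly[e]": 1}, "Transport", "NA", gpr="g", lb=-BIG_BOUND),
        _ex("gly", "NA"),
    ]
    # -- branched-chain amino acids ---------------------------------------
    for aa, ka in (("leu__L", "4mop"), ("ile__L", "3mop"), ("val__L", "3mob")):
        T += [
            _ex(aa, "NA"),
            _R(f"{aa[:3].upper()}t", {f"{aa}[e]": -1, f"{aa}[c]": 1}, "Transport", "NA", gpr="g"),
            _R(f"{aa[:3].upper()}TA", {f"{aa}[c]": -1, "akg[m]": -1, f"{ka}[c]": 1, "glu__L[c]": 1},
               "Valine, leucine and isoleucine metabolism", "NA", gpr="g"),
            _R(f"{ka.upper()}t", {f"{ka}[c]": -1, f"{ka}[e]": 1}, "Transport", "NA"),
            _ex(ka, "NA"),
        ]
    # -- catecholamines and acetylcholine ---------------------------------
    T += [
        _ex("34dhphe", "NA"),
        _R("LDOPAt", {"34dhphe[e]": -1, "34dhphe[c]": 1}, "Transport", "NA", gpr="g"),
        _R("DDC", {"34dhphe[c]": -1, "dopa[c]": 1, "co2[c]": 1}, "Tyrosine metabolism", "N", gpr="g",
           name="dopa decarboxylase"),
        _R("DOPAt", {"dopa[e]": -1, "dopa[c]": 1}, "Transport", "NA", gpr="g", lb=-BIG_BOUND),
        _ex("dopa", "NA"),
        _R("DBH", {"dopa[c]": -1, "o2[c]": -0.5, "nrpphr[c]": 1}, "Tyrosine metabolism", "NA", gpr="g",
           name="dopamine beta-hydroxylase"),
        _R("NRPPHRt", {"nrpphr[c]": -1, "nrpphr[e]": 1}, "Transport", "NA"),
        _ex("nrpphr", "NA"),
        _R("PNMT", {"nrpphr[c]": -1, "adrnl[c]": 1}, "Tyrosine metabolism", "N", gpr="g"),
        _R("ADRNLt", {"adrnl[c]": -1, "adrnl[e]": 1}, "Transport", "N"),
        _ex("adrnl", "N"),
        _R("ACHSYN", {"chln[c]": -1, "accoa[m]": -1, "ach[c]": 1}, "Acetylcholine metabolism", "N",
           gpr="g", name="choline acetyltransferase"),
        _R("ACHt", {"ach[c]": -1, "ach[e]": 1}, "Transport", "N"),
        _ex("ach", "N"),
    ]
    # -- N-acetylaspartate -------------------------------------------------
    T += [
        _R("NAASYN", {"asp__L[c]": -1, "accoa[m]": -1, "naa[c]": 1}, "N-acetylaspartate metabolism", "N",
           gpr="g", pathway="NAA", name="NAA synthase"),
        _R("NAAt", {"naa[c]": -1, "naa[e]": 1}, "Transport", "NO", gpr="g", lb=-BIG_BOUND, pathway="NAA"),
        _ex("naa", "NO", "NAA"),
        _R("NAADEG", {"naa[c]": -1, "asp__L[c]": 1, "ac[c]": 1}, "N-acetylaspartate metabolism", "O",
           gpr="g", pathway="NAA", name="aspartoacylase"),
        _R("ACS", {"ac[c]": -1, "atp[c]": -2, "accoa[m]": 1, "adp[c]": 2}, "Acetate metabolism", "O",
           gpr="g", pathway="NAA", name="acetyl-CoA synthetase"),
        _R("ACt", {"ac[c]": -1, "ac[e]": 1}, "Transport", "O", lb=-BIG_BOUND, pathway="NAA"),
        _ex("ac", "O", "NAA"),
    ]
    # -- biomass -----------------------------------------------------------
    T += [
        _R("BIOMASS", {"atp[c]": -20, "glu__L[c]": -0.4, "lipid[c]": -0.3, "r5p[c]": -0.15,
                       "adp[c]": 20, "biomass[c]": 1},
           "Biomass", "NAMOP", name="biomass (ATP + amino acid + lipid + nucleotide surrogate)"),
        _R("DM_biomass", {"biomass[c]": -1}, "Exchange/demand", "NAMOP", name="biomass demand"),
    ]
    return T


_TEMPLATE = _template()

# deterministic global gene registry: reaction base id -> concrete GPR string
def _gene_registry() -> Dict[str, str]:
    reg: Dict[str, str] = {}
    counter = [0]

    def fresh() -> str:
        counter[0] += 1
        return f"G{counter[0]:04d}"

    for row in _TEMPLATE:
        spec = row["gpr"]
        if not spec:
            reg[row["id"]] = ""
            continue
        out = spec
        while "g" in out:
            out = out.replace("g", fresh(), 1)
        out = out.replace("&", " and ").replace("|", " or ")
        reg[row["id"]] = out
    return reg


GENE_REGISTRY = _gene_registry()
GLOBAL_GENES: Tuple[str, ...] = tuple(
    sorted({g for gpr in GENE_REGISTRY.values() for g in gpr_genes(gpr)})
)


def _rows_for(cell_type: str, spec: ToyBrainSpec) -> List[dict]:
    code = CELL_CODE[cell_type]
    rows = []
    for row in _TEMPLATE:
        if code not in row["cells"]:
            continue
        pw = row["pathway"]
        if pw is not None and not spec.pathways.get(pw, True):
            continue
        rows.append(row)
    return rows


def generate_toy_cell_model(cell_type: str, spec: Optional[ToyBrainSpec] = None) -> MetabolicModel:
    """Build the parent (pre-extraction) toy model for one brain cell type.

    The model is feasible by construction: biomass-optimal FBA carries
    positive flux, and the cell's full task list (see
    :mod:`brainflux.tasks`) passes.  Reactions whose genes are designated
    silent for this cell type are still present here — context-specific
    extraction is what removes them.
    """
    if spec is None:
        spec = ToyBrainSpec()
    if cell_type not in CELL_TYPES:
        raise SpecError(f"unknown cell type {cell_type!r}")
    rows = _rows_for(cell_type, spec)
    model = MetabolicModel(
        model_id=f"toy_{cell_type}",
        annotations={
            "cell_type": cell_type,
            "generator": "brainflux.synth",
            "seed": spec.seed,
        },
        compartments={k: v for k, v in _COMP_NAMES.items() if k in ("c", "m", "e")},
    )
    needed_mets: Dict[str, Metabolite] = {}
    for row in rows:
        stoich = dict(row["stoich"])
        if row["id"] == "MYELIN" and spec.myelin_coefficients:
            for comp, coeff in spec.myelin_coefficients.items():
                key = f"{comp}[c]"
                if key not in stoich:
                    raise SpecError(f"myelin override names unknown component {comp!r}")
                stoich[key] = -abs(float(coeff))
        for met_id in stoich:
            if met_id not in needed_mets:
                base, comp = _split_met(met_id)
                needed_mets[met_id] = Metabolite(
                    id=met_id, name=_MET_NAMES.get(base, base), compartment=comp
                )
    for met_id in sorted(needed_mets):
        model.add_metabolite(needed_mets[met_id])
    for row in rows:
        stoich = dict(row["stoich"])
        if row["id"] == "MYELIN" and spec.myelin_coefficients:
            for comp, coeff in spec.myelin_coefficients.items():
                stoich[f"{comp}[c]"] = -abs(float(coeff))
        model.add_reaction(
            Reaction(
                id=row["id"],
                stoichiometry=stoich,
                name=row["name"] or row["id"],
                lower_bound=row["lb"],
                upper_bound=row["ub"],
                gpr=GENE_REGISTRY[row["id"]],
                subsystem=row["subsystem"],
            )
        )
    model.annotations["silent_reactions"] = sorted(
        row["id"] for row in rows if CELL_CODE[cell_type] in row["silent_in"]
    )
    model.validate()
    return model


def _split_met(met_id: str) -> Tuple[str, str]:
    m = re.fullmatch(r"(.+)\[([^\]]+)\]", met_id)
    if not m:
        raise ModelError(f"metabolite id {met_id!r} lacks a [compartment] token")
    return m.group(1), m.group(2)


# ---------------------------------------------------------------------------
# expression and DE p-value emulation
# ---------------------------------------------------------------------------


def silent_genes(model: MetabolicModel) -> FrozenSet[str]:
    """Genes designated unexpressed in this cell type.

    A gene is silent only if *every* reaction carrying it in this model is
    marked silent; genes shared with an expressed reaction stay expressed.
    """
    silent_rxns = set(model.annotations.get("silent_reactions", []))
    silent: set[str] = set()
    expressed: set[str] = set()
    for rxn in model.reactions:
        target = silent if rxn.id in silent_rxns else expressed
        target |= rxn.genes
    return frozenset(silent - expressed)


def expressed_genes(model: MetabolicModel) -> FrozenSet[str]:
    return frozenset(model.genes - silent_genes(model))


def generate_expression_profiles(
    models: Mapping[str, MetabolicModel],
    seed: int = 0,
    n_samples: int = 20,
) -> Tuple[Dict[str, pd.DataFrame], pd.Series]:
    """Emulated single-cell read counts per cell type, plus gene lengths.

    All models share the global gene namespace; the row index is its union.
    For each cell type, designated expressed genes receive counts whose mean
    TPM is far above the cutoff of 1, silent genes receive zero counts in
    every sample (dropout-style silence), so ``tpm_normalize`` +
    ``mean_expression`` reproduce the intended expressed/silent partition.
    Counts differ between seeds; the partition does not.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(set().union(*[set(m.genes) for m in models.values()]) | set(GLOBAL_GENES))
    lengths = pd.Series(
        rng.integers(500, 3001, size=len(genes)), index=pd.Index(genes, name="gene"), name="length"
    )
    # per-gene base abundance (shared across cells, lognormal spread)
    base = pd.Series(rng.lognormal(mean=np.log(200.0), sigma=0.6, size=len(genes)), index=genes)
    profiles: Dict[str, pd.DataFrame] = {}
    for cell in sorted(models):
        model = models[cell]
        on = expressed_genes(model)
        cols = {}
        for s in range(n_samples):
            depth = rng.uniform(0.6, 1.4)
            lam = base * lengths / 1000.0 * depth
            counts = rng.poisson(lam.to_numpy())
            counts[~np.isin(genes, list(on))] = 0
            cols[f"{cell}_{s:02d}"] = counts
        profiles[cell] = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    return profiles, lengths


def generate_de_pvalues(model: MetabolicModel, planted: PlantedDESpec) -> Dict[str, float]:
    """Per-gene differential-expression p-values with planted hot spots.

    Genes appearing in GPRs of reactions adjacent to a hot metabolite draw
    p = 10**(-x) with x ~ Gamma(shape=16, scale=effect/16): mean(-log10 p)
    equals ``effect`` with modest spread (CV 0.25), i.e. the planted signal
    is coherent across the hot neighborhood.  All remaining genes are
    Uniform(0,1).  With effect=0 every gene is null.
    """
    rng = np.random.default_rng(planted.seed)
    hot_genes: set[str] = set()
    for met_id in planted.hot_metabolites:
        if not model.has_metabolite(met_id):
            raise SpecError(f"hot metabolite {met_id!r} not in model {model.id!r}")
        adjacent = model.reactions_of_metabolite(met_id)
        genes = set().union(*[r.genes for r in adjacent]) if adjacent else set()
        if not genes:
            raise SpecError(
                f"hot metabolite {met_id!r} has no gene-associated adjacent reactions"
            )
        hot_genes |= genes
    pvals: Dict[str, float] = {}
    for gene in sorted(model.genes):
        if gene in hot_genes and planted.effect > 0:
            x = rng.gamma(shape=16.0, scale=planted.effect / 16.0)
            pvals[gene] = float(np.clip(10.0 ** (-x), 1e-300, 1.0 - 1e-16))
        else:
            pvals[gene] = float(np.clip(rng.uniform(), 1e-300, 1.0 - 1e-16))
    return pvals


# ---------------------------------------------------------------------------
# default simulation constraints (the toy study conditions)
# ---------------------------------------------------------------------------

#: resting uptake capacities and maintenance demands, umol/g tissue/min.
#: Microglia and oligodendrocytes inherit astrocyte capacities with internal
#: lower bounds at zero (glial convention); PPP/glucose ratio couplings are
#: stated for neuron (5%) and astrocyte (6%) only.
#: Neurons carry a generous glucose capacity with a snug oxygen cap, so an
#: oxygen decrement forces a measurable anaerobic shift; astrocytes are
#: glucose-capped (their demand, maintenance plus the glutamine cycle, tops
#: out local fuels), so glucose supplementation is what relieves them.
RESTING = {
    "neuron": {"glc": 0.25, "o2": 0.30, "atpm": 1.0, "ppp": 0.05},
    "astrocyte": {"glc": 0.06, "o2": 0.52, "atpm": 1.3, "ppp": 0.06},
    "microglia": {"glc": 0.06, "o2": 0.52, "atpm": 0.9, "ppp": None},
    "oligodendrocyte": {"glc": 0.06, "o2": 0.52, "atpm": 0.6, "ppp": None},
    "OPC": {"glc": 0.06, "o2": 0.52, "atpm": 0.9, "ppp": None},
}


def default_constraints(cell_type: str) -> ConstraintTable:
    """Resting-state constraint table for a single toy cell model."""
    if cell_type not in RESTING:
        raise SpecError(f"no default constraints for cell type {cell_type!r}")
    p = RESTING[cell_type]
    rows = [
        ("EX_glc__D", -p["glc"], BIG_BOUND),
        ("EX_o2", -p["o2"], BIG_BOUND),
        ("ATPM", p["atpm"], BIG_BOUND),
    ]
    if cell_type == "neuron":
        # constitutive NAA synthesis: neurons maintain one of the brain's
        # most abundant metabolites; oligodendrocyte aspartoacylase is its
        # canonical disposal route
        rows.append(("NAASYN", 0.005, BIG_BOUND))
    if cell_type == "oligodendrocyte":
        # myelin lipid precursors: the resting myelin flux of 0.010 needs
        # more head-group and fatty-acid supply than the generic exchange cap
        rows += [
            ("EX_chln", -0.05, BIG_BOUND),
            ("EX_etha", -0.05, BIG_BOUND),
            ("EX_ser__L", -0.05, BIG_BOUND),
            ("EX_hdca", -0.12, BIG_BOUND),
        ]
    uptake = []
    if p["ppp"] is not None:
        uptake.append(("G6PDH2", "EX_glc__D", p["ppp"]))
    return ConstraintTable(rows=rows, uptake_couplings=uptake)
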