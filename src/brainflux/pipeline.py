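"""End-to-end driver: synth -> extract -> merge -> simulate -> reporter.

The pipeline reproduces the full protocol on the packaged toy brain:

1. generate parent cell models and synthetic expression;
2. TPM-normalize, score reactions, extract context-specific models, and
   verify their task lists;
3. apply resting constraints and run single-cell two-stage biomass FBA;
4. merge neuron/astrocyte/microglia/oligodendrocyte, add intercellular
   reactions, pin non-nutrient exchanges to the single-cell solutions, and
   fix myelin formation at its resting flux;
5. run the resting/ketogenic/hypoxia/demyelination protocols under the
   glutamate/glutamine/GABA-cycle objective;
6. plant DE p-values and score reporter metabolites + ORA for the
   microglia and oligodendrocyte disease contrasts.

Every stage is deterministic given the config seed; outputs are plain TSV/
JSON and a timestamp-free log, so identical seeds give byte-identical
output trees.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as bio
from .expression import EvidenceTable, mean_expression, tpm_normalize
from .extract import extract_context_model
from .integrate import DEFAULT_SUFFIXES, add_intercellular_reactions, default_intercellular_spec, merge_models
from .model import MetabolicModel
from .reporter import gene_p_to_z, ora_hypergeometric, reporter_metabolites
from .simulate import (
    GGG_COUPLING,
    FluxState,
    ProtocolConfig,
    activity_by_cell,
    apply_constraints,
    fba_two_stage,
    pin_exchanges,
    run_protocol,
    subsystem_activity,
)
from .synth import (
    PlantedDESpec,
    ToyBrainSpec,
    default_constraints,
    generate_de_pvalues,
    generate_expression_profiles,
    generate_toy_cell_model,
)
from .tasks import check_tasks, tasks_for

__all__ = ["RunConfig", "build_brain", "run_pipeline", "PIN_EXCLUDED_BASES"]

BRAIN_CELLS = ("neuron", "astrocyte", "microglia", "oligodendrocyte")

#: exchange base ids NOT pinned to single-cell values in the merged model:
#: protocol nutrients and waste outlets.  Traded neurotransmitters ARE
#: pinned (capacity mode): the blood-brain barrier does not dump them, so
#: their circulation must run through the intercellular reactions.
PIN_EXCLUDED_BASES = (
    "EX_glc__D", "EX_o2", "EX_acac", "EX_bhb__R", "EX_co2", "EX_lac__L",
)


@dataclass
class RunConfig:
    """All pipeline defaults mirror the shipped study conditions."""

    seed: int = 0
    cutoff: float = 1.0  # TPM expression cutoff
    n_samples: int = 20  # emulated cells per type
    exchange_default: Tuple[float, float] = (-0.01, 1000.0)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    ggg_coupling: float = GGG_COUPLING  # GABA = 25% of the gln cycle
    zero_tol: float = 1e-6
    reporter_alpha: float = 0.05
    reporter_alpha_strict: float = 0.025
    n_background: int = 10000
    de_effect: float = 3.0
    #: disease-contrast hot metabolites: cell type -> metabolite ids
    hot_metabolites: Dict[str, Tuple[str, ...]] = field(
        default_factory=lambda: {
            "microglia": ("crn[c]",),
            "oligodendrocyte": ("ac[c]",),
        }
    )

    def __post_init__(self) -> None:
        if not (self.cutoff > 0):
            raise ValueError(f"cutoff must be > 0, got {self.cutoff}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not (0 < self.reporter_alpha < 1):
            raise ValueError("reporter_alpha must be in (0,1)")
        if self.seed < 0 or self.seed >= 2**31:
            raise ValueError("seed must be in [0, 2^31)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hot_metabolites"] = {k: list(v) for k, v in d["hot_metabolites"].items()}
        return d


def extract_cells(
    config: RunConfig,
) -> Tuple[Dict[str, MetabolicModel], Dict[str, MetabolicModel], Dict[str, pd.DataFrame], pd.Series]:
    """Parent models, extracted context models, expression counts, lengths."""
    spec = ToyBrainSpec(seed=config.seed)
    parents = {c: generate_toy_cell_model(c, spec) for c in BRAIN_CELLS}
    profiles, lengths = generate_expression_profiles(parents, seed=config.seed, n_samples=config.n_samples)
    extracted = {}
    for cell in BRAIN_CELLS:
        tpm = profiles[cell].apply(lambda col: tpm_normalize(col, lengths), axis=0)
        evidence = EvidenceTable.from_expression(parents[cell], mean_expression(tpm), cutoff=config.cutoff)
        extracted[cell] = extract_context_model(parents[cell], evidence, tasks_for(cell))
    return parents, extracted, profiles, lengths


def single_cell_states(
    extracted: Mapping[str, MetabolicModel],
    config: RunConfig,
) -> Tuple[Dict[str, MetabolicModel], Dict[str, FluxState]]:
    """Apply resting constraints and run two-stage biomass FBA per cell."""
    constrained, states = {}, {}
    for cell, model in extracted.items():
        table = default_constraints(cell)
        table.exchange_default = config.exchange_default
        cm = apply_constraints(model, table, role=cell)
        if cell == "oligodendrocyte" and cm.has_reaction(config.protocol.myelin_reaction):
            # oligodendrocytes are simulated with active myelin formation
            rxn = cm.reaction(config.protocol.myelin_reaction)
            rxn.lower_bound = config.protocol.myelin_reference
            rxn.upper_bound = config.protocol.myelin_reference
        constrained[cell] = cm
        states[cell] = fba_two_stage(cm, "BIOMASS")
    return constrained, states


def build_brain(
    constrained: Mapping[str, MetabolicModel],
    states: Mapping[str, FluxState],
    config: Optional[RunConfig] = None,
) -> MetabolicModel:
    """Merge the four constrained cell models into the simulation-ready brain.

    Adds the default intercellular reactions, pins non-nutrient exchanges to
    the single-cell solution fluxes (+/- 1e-6), and fixes oligodendrocyte
    myelin formation at its resting flux of 0.010 umol/g tissue/min.
    """
    cfg = config or RunConfig()
    order = [c for c in BRAIN_CELLS if c in constrained]
    brain = merge_models([constrained[c] for c in order], [DEFAULT_SUFFIXES[c] for c in order])
    brain = add_intercellular_reactions(brain, default_intercellular_spec())
    brain = pin_exchanges(
        brain,
        {c: states[c] for c in order},
        {c: DEFAULT_SUFFIXES[c] for c in order},
        exclude_bases=PIN_EXCLUDED_BASES,
    )
    myelin = brain.reaction(f"{cfg.protocol.myelin_reaction}_{cfg.protocol.myelin_cell}")
    myelin.lower_bound = cfg.protocol.myelin_reference
    myelin.upper_bound = cfg.protocol.myelin_reference
    # NAA does not cross the blood-brain barrier: neuronal output must be
    # cleared through the intercellular transfer to oligodendrocytes
    for rid in ("EX_naa_N", "EX_naa_O"):
        if brain.has_reaction(rid):
            rxn = brain.reaction(rid)
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return brain


def run_pipeline(config: RunConfig, outdir: Path) -> Path:
    """Run the whole toy-brain protocol; returns the output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: List[str] = []

    def note(msg: str) -> None:
        log.append(msg)

    note(f"brainflux pipeline seed={config.seed}")
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    parents, extracted, profiles, lengths = extract_cells(config)
    (outdir / "models").mkdir(exist_ok=True)
    for cell in BRAIN_CELLS:
        bio.write_model(parents[cell], outdir / "models" / f"parent_{cell}.json")
        bio.write_model(extracted[cell], outdir / "models" / f"context_{cell}.json")
        results = check_tasks(extracted[cell], tasks_for(cell))
        n_ok = sum(r.feasible for r in results.values())
        note(f"extract {cell}: {len(parents[cell].reactions)} -> "
             f"{len(extracted[cell].reactions)} reactions, tasks {n_ok}/{len(results)}")
        if n_ok != len(results):
            raise RuntimeError(f"extracted {cell} model fails tasks")
    counts = pd.concat(profiles.values(), axis=1)
    bio.write_expression_tsv(counts, lengths, outdir / "expression_counts.tsv")

    constrained, states = single_cell_states(extracted, config)
    for cell in BRAIN_CELLS:
        st = states[cell]
        bio.write_flux_tsv(st.fluxes, outdir / f"fluxes_single_{cell}.tsv")
        note(f"single-cell {cell}: biomass={st.objective_value:.6f} status={st.status}")

    brain = build_brain(constrained, states, config)
    bio.write_model(brain, outdir / "models" / "brain.json")
    note(f"brain model: {len(brain.reactions)} reactions, {len(brain.metabolites)} metabolites")

    activities = {}
    for protocol in ("resting", "glucose", "ketogenic", "hypoxia", "demyelination"):
        result = run_protocol(brain, protocol, config.protocol)
        state = result.states[-1]
        if state.status == "optimal":
            bio.write_flux_tsv(state.fluxes, outdir / f"fluxes_brain_{protocol}.tsv")
        act = result.activity[-1]
        act.to_csv(outdir / f"activity_{protocol}.tsv", sep="\t")
        activities[protocol] = result
        if protocol == "resting":
            obj = result.reference_state.objective_value
            note(f"resting ggg cycle flux = {obj:.6f}")
        elif protocol == "demyelination":
            note(f"demyelination: {len(result.states)} levels, "
                 f"distances {['%.4g' % (s.distance or 0) for s in result.states]}")
        else:
            note(f"{protocol}: cycle flux = {result.states[-1].objective_value}")

    # reporter analysis on the two disease contrasts
    for cell, hot in config.hot_metabolites.items():
        model = extracted.get(cell) or parents[cell]
        planted = PlantedDESpec(hot_metabolites=tuple(hot), effect=config.de_effect, seed=config.seed)
        pvals = generate_de_pvalues(model, planted)
        bio.write_pvalues_tsv(pvals, outdir / f"de_pvalues_{cell}.tsv")
        scores = reporter_metabolites(
            model, gene_p_to_z(pvals), n_background=config.n_background, seed=config.seed
        )
        df = pd.DataFrame(
            [{"metabolite": s.metabolite, "k": s.k, "z_raw": f"{s.z_raw:.6g}",
              "z_corrected": f"{s.z_corrected:.6g}", "p": f"{s.p:.6g}"} for s in scores]
        )
        df.to_csv(outdir / f"reporter_{cell}.tsv", sep="\t", index=False)
        reporters = {s.metabolite for s in scores if s.p < config.reporter_alpha}
        universe = {s.metabolite for s in scores}
        pathways = _toy_pathway_sets(model)
        ora = ora_hypergeometric(reporters, pathways, universe, alpha=config.reporter_alpha_strict)
        ora.to_csv(outdir / f"ora_{cell}.tsv", sep="\t", index=False)
        note(f"reporter {cell}: top={scores[0].metabolite} (p={scores[0].p:.3g}), "
             f"{len(reporters)} reporters at p<{config.reporter_alpha}")

    (outdir / "run.log").write_text("\n".join(log) + "\n")
    return outdir


def _toy_pathway_sets(model: MetabolicModel) -> Dict[str, frozenset]:
    """Subsystem-derived metabolite sets standing in for KEGG pathways."""
    sets: Dict[str, set] = {}
    for rxn in model.reactions:
        if rxn.subsystem in ("Exchange/demand", "Transport", ""):
            continue
        members = sets.setdefault(rxn.subsystem, set())
        for met in rxn.stoichiometry:
            if not met.startswith("CPL_"):
                members.add(met)
    return {k: frozenset(v) for k, v in sets.items()}
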