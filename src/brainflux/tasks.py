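"""Metabolic tasks: feasibility queries used for extraction and validation.

A task asks: with the system boundary closed except for a stated set of
allowed inputs, can the model sustain each required output at its minimum
flux?  Tasks guard context-specific extraction — a reaction is only removed
if every task stays feasible without it — so extracted models are
functional by construction.

The shipped lists comprise essential tasks all brain cells must pass
(aerobic and anaerobic ATP regeneration, ketone-body utilization, biomass
precursor synthesis) plus cell-specific tasks: glutamine->glutamate (neuron,
microglia), glutamate->GABA (neuron), GABA->glutamate (neuron, astrocyte),
glutamate->glutamine (astrocyte), serine->glycine (neuron) and the reverse
(astrocyte), branched-chain amino acids -> keto acids (neuron, astrocyte),
levodopa->dopamine (neuron), dopamine->norepinephrine (neuron, astrocyte),
adrenaline and acetylcholine production (neuron), NAA synthesis (neuron)
and degradation (oligodendrocyte), and myelin formation (oligodendrocyte).
OPCs carry the essential tasks only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .model import BIG_BOUND, MetabolicModel, ModelError, Reaction, build_stoichiometric_matrix
from . import solver

__all__ = ["MetabolicTask", "TaskResult", "check_task", "check_tasks", "essential_tasks", "cell_tasks", "tasks_for"]


@dataclass(frozen=True)
class MetabolicTask:
    """A feasibility query: allowed inputs -> required outputs."""

    id: str
    description: str = ""
    #: (metabolite id, max uptake flux)
    allowed_inputs: Tuple[Tuple[str, float], ...] = ()
    #: (metabolite id, min production flux)
    required_outputs: Tuple[Tuple[str, float], ...] = ()
    #: byproduct sinks opened without a minimum (e.g. CO2)
    allowed_outputs: Tuple[str, ...] = ()
    #: additional fixed bounds, reaction id -> (lb, ub)
    bounds: Tuple[Tuple[str, Tuple[float, float]], ...] = ()

    def __post_init__(self) -> None:
        if not self.required_outputs:
            raise ValueError(f"task {self.id!r}: at least one required output")
        for met, f in self.allowed_inputs + self.required_outputs:
            if f < 0:
                raise ValueError(f"task {self.id!r}: negative flux for {met!r}")


@dataclass
class TaskResult:
    task_id: str
    feasible: bool
    achieved_flux: Optional[float] = None  # total required-output flux at optimum
    reason: str = ""


def check_task(model: MetabolicModel, task: MetabolicTask) -> TaskResult:
    """LP feasibility of a task on a model.

    All boundary (exchange/demand) reactions are closed; temporary source
    reactions supply the allowed inputs (bounded by their max uptake) and
    temporary sinks drain required outputs (bounded below by their minimum)
    and allowed byproducts.  A task metabolite missing from the model makes
    the task infeasible with a reason — it is not an error.  A genuine
    solver breakdown raises, distinct from infeasibility.
    """
    for met, _ in task.allowed_inputs + task.required_outputs:
        if not model.has_metabolite(met):
            return TaskResult(task.id, False, reason=f"metabolite {met!r} not in model")
    work = model.copy()
    for rxn in work.reactions:
        if rxn.is_boundary:
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    for rid, (lb, ub) in task.bounds:
        rxn = work.reaction(rid)
        rxn.lower_bound = lb
        rxn.upper_bound = ub
    out_ids: List[str] = []
    for met, cap in task.allowed_inputs:
        work.add_reaction(Reaction(id=f"TASK_IN_{met}", stoichiometry={met: 1.0},
                                   lower_bound=0.0, upper_bound=cap, subsystem="Task boundary"))
    for met, floor in task.required_outputs:
        rid = f"TASK_OUT_{met}"
        work.add_reaction(Reaction(id=rid, stoichiometry={met: -1.0},
                                   lower_bound=floor, upper_bound=BIG_BOUND, subsystem="Task boundary"))
        out_ids.append(rid)
    for met in task.allowed_outputs:
        if not work.has_metabolite(met):
            continue
        work.add_reaction(Reaction(id=f"TASK_FREE_{met}", stoichiometry={met: -1.0},
                                   lower_bound=0.0, upper_bound=BIG_BOUND, subsystem="Task boundary"))
    S = build_stoichiometric_matrix(work)
    lb = np.array([r.lower_bound for r in work.reactions])
    ub = np.array([r.upper_bound for r in work.reactions])
    c = np.zeros(len(work.reactions))
    idx = {r.id: i for i, r in enumerate(work.reactions)}
    for rid in out_ids:
        c[idx[rid]] = 1.0
    res = solver.solve_lp(c, S, np.zeros(S.shape[0]), lb, ub, sense="max")
    if res.status == "optimal":
        return TaskResult(task.id, True, achieved_flux=float(res.objective))
    if res.status == "infeasible":
        return TaskResult(task.id, False, reason="LP infeasible")
    if res.status == "unbounded":
        # outputs can grow without bound: the task is trivially satisfiable
        return TaskResult(task.id, True, achieved_flux=float("inf"))
    raise RuntimeError(f"solver failure on task {task.id!r}: {res.message}")


def check_tasks(model: MetabolicModel, tasks: Sequence[MetabolicTask]) -> Dict[str, TaskResult]:
    return {t.id: check_task(model, t) for t in tasks}


# ---------------------------------------------------------------------------
# shipped task lists for the toy models
# ---------------------------------------------------------------------------

_CO2 = ("co2[e]", "co2[c]")
_FUEL = (("glc__D[e]", 1.0), ("o2[e]", 10.0))


def essential_tasks() -> List[MetabolicTask]:
    """Viability tasks every toy brain cell must pass."""
    return [
        MetabolicTask(
            id="atp_aerobic",
            description="regenerate ATP from glucose and oxygen",
            allowed_inputs=_FUEL,
            required_outputs=(("co2[e]", 1.0),),
            bounds=(("ATPM", (10.0, BIG_BOUND)),),
        ),
        MetabolicTask(
            id="atp_anaerobic",
            description="regenerate ATP from glucose without oxygen",
            allowed_inputs=(("glc__D[e]", 1.0),),
            required_outputs=(("lac__L[e]", 1.5),),
            bounds=(("ATPM", (1.5, BIG_BOUND)),),
        ),
        MetabolicTask(
            id="atp_from_ketones",
            description="regenerate ATP from ketone bodies and oxygen",
            allowed_inputs=(("acac[e]", 1.0), ("bhb__R[e]", 1.0), ("o2[e]", 10.0)),
            required_outputs=(("co2[e]", 1.0),),
            bounds=(("ATPM", (5.0, BIG_BOUND)),),
        ),
        MetabolicTask(
            id="biomass_precursors",
            description="synthesize biomass from glucose and oxygen",
            allowed_inputs=_FUEL,
            required_outputs=(("biomass[c]", 0.01),),
            allowed_outputs=_CO2,
        ),
    ]


def cell_tasks(cell_type: str) -> List[MetabolicTask]:
    """Cell-specific tasks (empty for OPC)."""
    t: List[MetabolicTask] = []
    if cell_type in ("neuron", "microglia"):
        t.append(MetabolicTask(
            id="glutamate_from_glutamine",
            allowed_inputs=(("gln__L[e]", 1.0),),
            required_outputs=(("glu__L[e]", 0.5),),
        ))
    if cell_type == "neuron":
        t.append(MetabolicTask(
            id="gaba_from_glutamate",
            allowed_inputs=(("glu__L[e]", 1.0),),
            required_outputs=(("gaba[e]", 0.5),),
            allowed_outputs=_CO2,
        ))
    if cell_type in ("neuron", "astrocyte"):
        t.append(MetabolicTask(
            id="glutamate_from_gaba",
            allowed_inputs=(("gaba[e]", 1.0), ("co2[e]", 1.0)),
            required_outputs=(("glu__L[e]", 0.5),),
        ))
    if cell_type == "astrocyte":
        t.append(MetabolicTask(
            id="glutamine_from_glutamate",
            allowed_inputs=_FUEL + (("glu__L[e]", 1.0),),
            # glutamine synthetase is capacity-limited; ask for half capacity
            required_outputs=(("gln__L[e]", 0.1),),
            allowed_outputs=_CO2,
        ))
    if cell_type == "neuron":
        t.append(MetabolicTask(
            id="glycine_from_serine",
            allowed_inputs=(("ser__L[e]", 1.0),),
            required_outputs=(("gly[e]", 0.5),),
        ))
    if cell_type == "astrocyte":
        t.append(MetabolicTask(
            id="serine_from_glycine",
            allowed_inputs=(("gly[e]", 1.0), ("co2[e]", 1.0)),
            required_outputs=(("ser__L[e]", 0.5),),
        ))
    if cell_type in ("neuron", "astrocyte"):
        t.append(MetabolicTask(
            id="bcaa_to_keto_acids",
            description="transaminate leucine/isoleucine/valine to their 2-oxo acids",
            allowed_inputs=_FUEL + (("leu__L[e]", 1.0), ("ile__L[e]", 1.0), ("val__L[e]", 1.0)),
            required_outputs=(("4mop[e]", 0.3), ("3mop[e]", 0.3), ("3mob[e]", 0.3)),
            allowed_outputs=_CO2 + ("glu__L[e]",),
        ))
        t.append(MetabolicTask(
            id="norepinephrine_from_dopamine",
            allowed_inputs=(("dopa[e]", 1.0), ("o2[e]", 10.0)),
            required_outputs=(("nrpphr[e]", 0.5),),
        ))
    if cell_type == "neuron":
        t += [
            MetabolicTask(
                id="dopamine_from_levodopa",
                allowed_inputs=(("34dhphe[e]", 1.0),),
                required_outputs=(("dopa[e]", 0.5),),
                allowed_outputs=_CO2,
            ),
            MetabolicTask(
                id="adrenaline_production",
                allowed_inputs=(("34dhphe[e]", 1.0), ("o2[e]", 10.0)),
                required_outputs=(("adrnl[e]", 0.3),),
                allowed_outputs=_CO2,
            ),
            MetabolicTask(
                id="acetylcholine_production",
                allowed_inputs=_FUEL + (("chln[e]", 1.0),),
                required_outputs=(("ach[e]", 0.1),),
                allowed_outputs=_CO2,
            ),
            MetabolicTask(
                id="naa_synthesis",
                allowed_inputs=_FUEL + (("gln__L[e]", 1.0),),
                required_outputs=(("naa[e]", 0.1),),
                allowed_outputs=_CO2,
            ),
        ]
    if cell_type == "oligodendrocyte":
        t += [
            MetabolicTask(
                id="naa_degradation",
                description="cleave NAA to aspartate and acetate",
                allowed_inputs=_FUEL + (("naa[e]", 1.0),),
                required_outputs=(("asp__L[c]", 0.5), ("ac[c]", 0.1)),
                allowed_outputs=_CO2,
            ),
            MetabolicTask(
                id="myelin_formation",
                description="assemble the five-lipid myelin sheath unit",
                allowed_inputs=_FUEL + (
                    ("ser__L[e]", 1.0), ("chln[e]", 1.0), ("etha[e]", 1.0), ("hdca[e]", 1.0),
                ),
                required_outputs=(("myelin[c]", 0.001),),
                allowed_outputs=_CO2,
            ),
        ]
    return t


def tasks_for(cell_type: str) -> List[MetabolicTask]:
    """Essential + cell-specific task list for one cell type."""
    return essential_tasks() + cell_tasks(cell_type)
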