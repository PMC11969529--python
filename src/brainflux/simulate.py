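"""Flux simulation: FBA, FVA, MOMA, constraints, objectives and protocols.

The flux-balance problem is ``max/min c.v  s.t.  S v = 0, lb <= v <= ub``.
Because FBA optima are usually degenerate, production simulations use the
two-stage scheme: the linear objective is optimized first, then fixed, and
the squared flux sum is minimized — yielding a unique, parsimonious flux
state.  Perturbations are analysed with MOMA, which minimizes the Euclidean
distance to a reference flux distribution instead of re-optimizing.

Linear flux-ratio couplings ("reaction A flux = alpha x reaction B flux",
e.g. the pentose-phosphate / glucose-uptake ratios of 5% and 6% and the
GABA = 25% of glutamate-glutamine cycle rule) are materialized as extra
stoichiometric rows: a pseudo-metabolite with coefficient 1 in A and -alpha
in B, so every downstream solve respects them exactly.

Fluxes are umol/g tissue/min; a reaction is counted as active when
|v| > 1e-6 (the reporting threshold used throughout).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .model import BIG_BOUND, MetabolicModel, Metabolite, ModelError, Reaction, build_stoichiometric_matrix
from . import solver

__all__ = [
    "ZERO_FLUX_TOL",
    "FluxState",
    "ConstraintTable",
    "ProtocolConfig",
    "ProtocolResult",
    "add_flux_coupling",
    "apply_constraints",
    "fba",
    "fba_two_stage",
    "fva",
    "moma",
    "brain_objective_ggg",
    "pin_exchanges",
    "run_protocol",
    "subsystem_activity",
    "activity_by_cell",
]

#: reporting threshold: |v| above this counts as a nonzero flux
ZERO_FLUX_TOL = 1e-6

# conventional subsystem labels excluded from "mean subsystem flux" summaries
NON_METABOLIC_SUBSYSTEMS = ("Transport", "Exchange/demand", "Intercellular transport")


@dataclass
class FluxState:
    """One solver result: per-reaction fluxes + objective + status."""

    fluxes: Dict[str, float]
    objective_value: Optional[float]
    status: str  # optimal | infeasible | unbounded | error
    model_id: str = ""
    distance: Optional[float] = None  # Euclidean distance (MOMA only)

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]

    def as_series(self) -> pd.Series:
        return pd.Series(self.fluxes, name="flux")

    def steady_state_residual(self, model: MetabolicModel) -> float:
        """||S v||_inf; <= 1e-6 for any optimal state (usually ~1e-12)."""
        S = build_stoichiometric_matrix(model)
        v = np.array([self.fluxes.get(r.id, 0.0) for r in model.reactions])
        resid = S @ v
        return float(np.abs(resid).max()) if resid.size else 0.0


class SolverFailure(RuntimeError):
    """Solver broke down (distinct from a well-posed infeasible problem)."""


# -- constraint application ------------------------------------------------


@dataclass
class ConstraintTable:
    """Bounds + ratio couplings applied before simulation.

    ``rows``: (reaction_id, lb, ub); ``couplings``: (rxn, ref_rxn, alpha)
    meaning flux(rxn) = alpha * flux(ref_rxn); unlisted exchange reactions
    get ``exchange_default`` = (-0.01, 1000): bounded uptake, free release.
    """

    rows: List[Tuple[str, float, float]] = field(default_factory=list)
    couplings: List[Tuple[str, str, float]] = field(default_factory=list)
    #: (rxn, exchange, alpha): flux(rxn) = alpha * uptake(exchange), where
    #: uptake is the negated exchange flux (uptake is negative by convention)
    uptake_couplings: List[Tuple[str, str, float]] = field(default_factory=list)
    exchange_default: Tuple[float, float] = (-0.01, BIG_BOUND)

    def __post_init__(self) -> None:
        for rid, lb, ub in self.rows:
            if lb > ub:
                raise ValueError(f"constraint row {rid!r}: lb {lb} > ub {ub}")
        for rxn, ref, alpha in list(self.couplings) + list(self.uptake_couplings):
            if alpha < 0:
                raise ValueError(f"coupling {rxn!r}={alpha}x{ref!r}: alpha must be >= 0")


def add_flux_coupling(model: MetabolicModel, rxn_id: str, ref_id: str, alpha: float) -> None:
    """Impose flux(rxn) = alpha * flux(ref) via a pseudo-metabolite row.

    The pseudo-metabolite (compartment ``x``, prefix ``CPL_``) appears with
    coefficient +1 in ``rxn`` and -alpha in ``ref``; S v = 0 then enforces
    the ratio exactly in every feasible solution.
    """
    rxn = model.reaction(rxn_id)
    ref = model.reaction(ref_id)
    pseudo = f"CPL_{rxn_id}_{ref_id}[x]"
    if model.has_metabolite(pseudo):
        raise ModelError(f"coupling {pseudo!r} already present")
    model.add_metabolite(Metabolite(id=pseudo, name=f"coupling {rxn_id}={alpha}*{ref_id}", compartment="x"))
    rxn.stoichiometry[pseudo] = 1.0
    ref.stoichiometry[pseudo] = -float(alpha)


def apply_constraints(
    model: MetabolicModel,
    table: ConstraintTable,
    role: Optional[str] = None,
) -> MetabolicModel:
    """Return a copy of the model with the constraint table applied.

    ``role`` implements the glial convention: when a table written for
    astrocytes is applied to microglia or oligodendrocytes, upper bounds are
    kept and the lower bounds of constrained *internal* reactions are set to
    zero.  Exchange rows keep their (negative) uptake bound, which is the
    uptake capacity rather than a directionality constraint.
    """
    out = model.copy()
    glial = role in ("microglia", "oligodendrocyte")
    listed = set()
    for rid, lb, ub in table.rows:
        rxn = out.reaction(rid)  # raises ModelError if unknown
        if glial and not rxn.is_boundary:
            lb = max(lb, 0.0)
        if lb > ub:
            lb = ub
        rxn.lower_bound = float(lb)
        rxn.upper_bound = float(ub)
        listed.add(rid)
    dlb, dub = table.exchange_default
    for rxn in out.reactions:
        if rxn.is_boundary and rxn.id not in listed:
            rxn.lower_bound = float(dlb)
            rxn.upper_bound = float(dub)
    for rxn_id, ref_id, alpha in table.couplings:
        add_flux_coupling(out, rxn_id, ref_id, alpha)
    for rxn_id, ex_id, alpha in table.uptake_couplings:
        # flux(rxn) = alpha * (-flux(exchange)) -> row v_rxn + alpha v_ex = 0
        add_flux_coupling(out, rxn_id, ex_id, -alpha)
    return out


# -- core solves -----------------------------------------------------------


def _arrays(model: MetabolicModel):
    S = build_stoichiometric_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    return S, lb, ub


def _objective_vector(model: MetabolicModel, objective: Union[str, Mapping[str, float]]) -> np.ndarray:
    c = np.zeros(len(model.reactions))
    idx = {r.id: i for i, r in enumerate(model.reactions)}
    if isinstance(objective, str):
        objective = {objective: 1.0}
    for rid, coeff in objective.items():
        if rid not in idx:
            raise ModelError(f"objective reaction {rid!r} not in model {model.id!r}")
        c[idx[rid]] = float(coeff)
    return c


def _state_from(model: MetabolicModel, x: Optional[np.ndarray], objective: Optional[float], status: str, **kw) -> FluxState:
    fluxes = {} if x is None else {r.id: float(v) for r, v in zip(model.reactions, x)}
    return FluxState(fluxes=fluxes, objective_value=objective, status=status, model_id=model.id, **kw)


def fba(
    model: MetabolicModel,
    objective: Union[str, Mapping[str, float]],
    sense: str = "max",
) -> FluxState:
    """Plain flux balance analysis; status reported faithfully."""
    S, lb, ub = _arrays(model)
    c = _objective_vector(model, objective)
    res = solver.solve_lp(c, S, np.zeros(S.shape[0]), lb, ub, sense=sense)
    if res.status != "optimal":
        return _state_from(model, None, None, res.status)
    return _state_from(model, res.x, res.objective, "optimal")


def fba_two_stage(
    model: MetabolicModel,
    objective: Union[str, Mapping[str, float]],
    sense: str = "max",
) -> FluxState:
    """FBA followed by squared-flux-sum minimization at the fixed optimum.

    Stage 1 solves the LP; stage 2 appends the row c.v = c.v* to the
    equality system and minimizes sum v^2, returning the unique minimum-norm
    optimal flux distribution.
    """
    S, lb, ub = _arrays(model)
    c = _objective_vector(model, objective)
    res = solver.solve_lp(c, S, np.zeros(S.shape[0]), lb, ub, sense=sense)
    if res.status != "optimal":
        return _state_from(model, None, None, res.status)
    A = sp.vstack([S, sp.csr_matrix(c)], format="csr")
    b = np.concatenate([np.zeros(S.shape[0]), [res.objective]])
    qp = solver.solve_qp(A, b, lb, ub, np.zeros(len(c)))
    if qp.status != "optimal":
        raise SolverFailure(f"stage-2 QP failed on {model.id!r}: {qp.message}")
    return _state_from(model, qp.x, res.objective, "optimal")


def fva(
    model: MetabolicModel,
    reactions: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-reaction flux min/max under the model's current constraints.

    Returns a DataFrame indexed by reaction id with columns ``minimum`` and
    ``maximum``.  Per-reaction solver failures are recorded as NaN rows
    rather than aborting the scan.
    """
    S, lb, ub = _arrays(model)
    idx = {r.id: i for i, r in enumerate(model.reactions)}
    targets = list(reactions) if reactions is not None else [r.id for r in model.reactions]
    rows = {}
    b = np.zeros(S.shape[0])
    for rid in targets:
        if rid not in idx:
            raise ModelError(f"FVA target {rid!r} not in model")
        c = np.zeros(len(model.reactions))
        c[idx[rid]] = 1.0
        lo = solver.solve_lp(c, S, b, lb, ub, sense="min")
        hi = solver.solve_lp(c, S, b, lb, ub, sense="max")
        rows[rid] = (
            lo.objective if lo.status == "optimal" else np.nan,
            hi.objective if hi.status == "optimal" else np.nan,
        )
    return pd.DataFrame.from_dict(rows, orient="index", columns=["minimum", "maximum"])


def moma(model: MetabolicModel, reference: FluxState) -> FluxState:
    """Minimization of metabolic adjustment.

    Finds the feasible flux vector of the (perturbed) model nearest in
    Euclidean distance to ``reference``.  The reference must cover the same
    reaction set; the perturbation is expressed through the model's bounds.
    """
    missing = [r.id for r in model.reactions if r.id not in reference.fluxes]
    if missing:
        raise ModelError(f"MOMA reference missing reactions: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    S, lb, ub = _arrays(model)
    target = np.array([reference.fluxes[r.id] for r in model.reactions])
    qp = solver.solve_qp(S, np.zeros(S.shape[0]), lb, ub, target)
    if qp.status == "infeasible":
        return _state_from(model, None, None, "infeasible")
    if qp.status != "optimal":
        raise SolverFailure(f"MOMA QP failed on {model.id!r}: {qp.message}")
    dist = float(np.sqrt(qp.objective))
    state = _state_from(model, qp.x, None, "optimal", distance=dist)
    state.objective_value = qp.objective
    return state


# -- activity summaries ----------------------------------------------------


def subsystem_activity(state: FluxState, model: MetabolicModel) -> pd.DataFrame:
    """Per-subsystem (sum |v|, active count at |v|>1e-6, total reactions)."""
    rows: Dict[str, List[float]] = {}
    for rxn in model.reactions:
        sub = rxn.subsystem or "Unassigned"
        v = abs(state.fluxes.get(rxn.id, 0.0))
        acc = rows.setdefault(sub, [0.0, 0, 0])
        acc[0] += v
        acc[1] += 1 if v > ZERO_FLUX_TOL else 0
        acc[2] += 1
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["flux_sum", "active", "total"])
    df.index.name = "subsystem"
    return df.sort_index()


def mean_subsystem_flux(
    state: FluxState,
    model: MetabolicModel,
    exclude: Sequence[str] = NON_METABOLIC_SUBSYSTEMS,
) -> pd.Series:
    """Mean |flux| over active reactions per subsystem, transport and
    exchange/demand subsystems excluded."""
    act = subsystem_activity(state, model)
    base = act.index.to_series().map(_strip_suffix)
    keep = ~base.isin(set(exclude))
    act = act[keep & (act["active"] > 0)]
    return act["flux_sum"] / act["active"]


def _strip_suffix(subsystem: str) -> str:
    for suf in ("_N", "_A", "_M", "_O", "_P"):
        if subsystem.endswith(suf):
            return subsystem[: -len(suf)]
    return subsystem


def activity_by_cell(state: FluxState, model: MetabolicModel) -> pd.DataFrame:
    """Subsystem activity of a merged brain model, split by cell suffix.

    Returns a DataFrame indexed by (cell, subsystem) where ``cell`` is the
    merge suffix token (N/A/M/O) or "shared" for unsuffixed entries.
    """
    act = subsystem_activity(state, model)
    cells, bases = [], []
    for sub in act.index:
        base = _strip_suffix(sub)
        cells.append(sub[len(base) + 1 :] if base != sub else "shared")
        bases.append(base)
    act = act.copy()
    act["cell"] = cells
    act["subsystem"] = bases
    return act.set_index(["cell", "subsystem"]).sort_index()


# -- brain objective and protocols ----------------------------------------

#: intercellular reaction ids used by the glutamate/glutamine/GABA objective
GLN_A_TO_N = "ICT_gln__L_A_N"
GABA_N_TO_A = "ICT_gaba_N_A"
GGG_COUPLING = 0.25  # GABA(N->A) = 25% of glutamine(A->N) cycle flux


def brain_objective_ggg(
    brain: MetabolicModel,
    coupling: Optional[float] = GGG_COUPLING,
) -> FluxState:
    """Maximize the neuron-astrocyte glutamate/glutamine/GABA cycle.

    The cycle scalar is operationalized as the glutamine A->N transfer flux.
    Unless ``coupling`` is None, the intercellular GABA N->A flux is tied to
    25% of it (as an exact stoichiometric row) before the two-stage solve.
    """
    for rid in (GLN_A_TO_N, GABA_N_TO_A):
        if not brain.has_reaction(rid):
            raise ModelError(f"brain model lacks intercellular reaction {rid!r}")
    work = brain.copy()
    if coupling is not None:
        add_flux_coupling(work, GABA_N_TO_A, GLN_A_TO_N, coupling)
    state = fba_two_stage(work, GLN_A_TO_N, sense="max")
    state.model_id = brain.id
    return state


def pin_exchanges(
    brain: MetabolicModel,
    cell_states: Mapping[str, FluxState],
    suffixes: Mapping[str, str],
    exclude_bases: Iterable[str] = (),
    slack: float = 1e-6,
    mode: str = "capacity",
) -> MetabolicModel:
    """Constrain merged-model exchanges by the single-cell solution values.

    For each cell, every exchange flux from its standalone simulation
    becomes a constraint in the merged model.  ``mode="capacity"`` (default)
    bounds the merged flux between the single-cell value and zero (+/-
    ``slack``): a cell may take up or release at most what its standalone
    simulation did, but perturbations may reduce it — which keeps MOMA
    sweeps and the hypoxia/ketogenic protocols well posed.
    ``mode="equality"`` pins the flux to the value +/- ``slack`` exactly.
    Exchanges whose base id is in ``exclude_bases`` (protocol nutrients,
    waste outlets, intercellularly traded species) keep their capacity
    bounds.
    """
    if mode not in ("capacity", "equality"):
        raise ValueError(f"unknown pinning mode {mode!r}")
    out = brain.copy()
    excl = set(exclude_bases)
    for cell, state in cell_states.items():
        suf = suffixes[cell]
        for rid, v in state.fluxes.items():
            base = rid
            merged_id = f"{rid}_{suf}"
            if base in excl or not out.has_reaction(merged_id):
                continue
            rxn = out.reaction(merged_id)
            if not rxn.is_boundary:
                continue
            if mode == "equality":
                rxn.lower_bound = v - slack
                rxn.upper_bound = v + slack
            else:
                rxn.lower_bound = min(v, 0.0) - slack
                rxn.upper_bound = max(v, 0.0) + slack
    return out


@dataclass
class ProtocolConfig:
    """Perturbation parameters (umol/g tissue/min)."""

    ketone_uptake: float = 0.050  # acetoacetate and (R)-3-hydroxybutanoate caps
    glucose_uptake: float = 0.210  # glucose cap under supplementation
    o2_decrement: float = 0.100  # hypoxia: uptake capacity reduction
    myelin_reference: float = 0.010  # resting myelin formation flux
    myelin_levels: int = 11  # 0.010 -> 0 at 10% intervals
    glucose_exchange: str = "EX_glc__D"
    o2_exchange: str = "EX_o2"
    ketone_exchanges: Tuple[str, str] = ("EX_acac", "EX_bhb__R")
    myelin_reaction: str = "MYELIN"
    myelin_cell: str = "O"
    cells: Tuple[str, ...] = ("N", "A", "M", "O")


@dataclass
class ProtocolResult:
    protocol: str
    states: List[FluxState]
    levels: List[float]  # perturbation level per state (myelin flux, or 0/1)
    activity: List[pd.DataFrame]  # activity_by_cell per state
    reference_state: FluxState
    reference_activity: pd.DataFrame

    def activity_delta(self, i: int = -1) -> pd.Series:
        """flux_sum change of state i relative to the resting reference."""
        a = self.activity[i]["flux_sum"]
        r = self.reference_activity["flux_sum"]
        return (a - r).fillna(0.0)

    def intercellular_fluxes(self, i: int = -1) -> pd.Series:
        s = self.states[i].as_series()
        return s[s.index.str.startswith("ICT_")]


def _set_uptake(model: MetabolicModel, rxn_id: str, capacity: float) -> None:
    rxn = model.reaction(rxn_id)
    rxn.lower_bound = -abs(capacity)


def run_protocol(
    brain: MetabolicModel,
    protocol: str,
    config: Optional[ProtocolConfig] = None,
) -> ProtocolResult:
    """Run a perturbation protocol on a prepared brain model.

    resting        two-stage glutamate/glutamine/GABA-cycle FBA, no change
    glucose        per-cell glucose uptake flux set to 0.210
                   (supplementation: the supply is pushed in, not merely
                   allowed — a pure capacity raise is a no-op under the
                   parsimonious second stage)
    ketogenic      per-cell acetoacetate and 3-hydroxybutanoate uptake
                   fluxes set to 0.050, then re-solve
    hypoxia        per-cell O2 uptake capacity reduced by 0.100 (floored at
                   zero), then re-solve
    demyelination  myelin flux fixed at 11 levels 0.010 -> 0.000; each level
                   solved by MOMA against the resting reference

    Glucose and ketone supplementation are separate conditions: their
    subsystem activities are compared against each other (and resting) to
    show the glycolysis-vs-TCA/oxidative-phosphorylation shift.
    """
    cfg = config or ProtocolConfig()
    reference = brain_objective_ggg(brain)
    if reference.status != "optimal":
        raise SolverFailure(f"resting-state solve failed: {reference.status}")
    ref_act = activity_by_cell(reference, brain)
    states: List[FluxState] = []
    levels: List[float] = []
    acts: List[pd.DataFrame] = []

    if protocol == "resting":
        states, levels, acts = [reference], [0.0], [ref_act]
    elif protocol in ("glucose", "ketogenic", "hypoxia"):
        work = brain.copy()
        for cell in cfg.cells:
            if protocol == "ketogenic":
                for ex in cfg.ketone_exchanges:
                    rxn = work.reaction(f"{ex}_{cell}")
                    rxn.lower_bound = -cfg.ketone_uptake
                    rxn.upper_bound = -cfg.ketone_uptake
            elif protocol == "glucose":
                rxn = work.reaction(f"{cfg.glucose_exchange}_{cell}")
                rxn.lower_bound = -cfg.glucose_uptake
                rxn.upper_bound = -cfg.glucose_uptake
            else:
                rxn = work.reaction(f"{cfg.o2_exchange}_{cell}")
                cap = max(-rxn.lower_bound - cfg.o2_decrement, 0.0)
                rxn.lower_bound = -cap
        state = brain_objective_ggg(work)
        states, levels, acts = [state], [1.0], [activity_by_cell(state, work)]
    elif protocol == "demyelination":
        myelin_id = f"{cfg.myelin_reaction}_{cfg.myelin_cell}"
        grid = np.linspace(cfg.myelin_reference, 0.0, cfg.myelin_levels)
        # the resting reference for MOMA must include the GABA coupling row,
        # so rebuild it on the coupled model and perturb that model
        coupled = brain.copy()
        add_flux_coupling(coupled, GABA_N_TO_A, GLN_A_TO_N, GGG_COUPLING)
        ref = fba_two_stage(coupled, GLN_A_TO_N, sense="max")
        for level in grid:
            work = coupled.copy()
            rxn = work.reaction(myelin_id)
            rxn.lower_bound = float(level)
            rxn.upper_bound = float(level)
            state = moma(work, ref)
            states.append(state)
            levels.append(float(level))
            acts.append(activity_by_cell(state, work) if state.status == "optimal" else pd.DataFrame())
        reference, ref_act = ref, activity_by_cell(ref, coupled)
    else:
        raise ValueError(f"unknown protocol {protocol!r}")

    return ProtocolResult(
        protocol=protocol,
        states=states,
        levels=levels,
        activity=acts,
        reference_state=reference,
        reference_activity=ref_act,
    )
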