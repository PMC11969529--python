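"""Task-guaranteed context-specific model extraction ("tINIT-lite").

Given a parent model, per-reaction expression evidence, and a task list,
return the sub-model that (i) keeps every expressed reaction, (ii) keeps a
non-expressed reaction only if removing it would break some metabolic task,
and (iii) never touches protected reactions (biomass, myelin, exchanges and
candidates for intercellular transport) or evidence-neutral reactions
(empty GPR).  Removal is greedy in ascending evidence order with full task
re-checking after each tentative removal, with lexicographic tie-breaking,
so the result is deterministic.

This implements the task-safety contract of expression-driven extraction at
toy scale; it is not the original MILP formulation.
"""

from __future__ import annotations

import warnings
from typing import Iterable, List, Optional, Sequence, Set

from .expression import EvidenceTable
from .model import MetabolicModel
from .tasks import MetabolicTask, check_tasks

__all__ = ["ExtractionError", "extract_context_model", "default_protected"]

#: metabolite bases traded between cells in the integrated brain model;
#: their transporters and exchanges survive extraction so that the merge
#: can always wire intercellular reactions.
INTERCELLULAR_BASES = (
    "glu__L", "gln__L", "gaba", "gly", "asp__L", "ala__L", "lac__L", "naa",
)


class ExtractionError(RuntimeError):
    """Parent model fails its task list — extraction contract cannot hold."""


def default_protected(model: MetabolicModel) -> Set[str]:
    """Reactions never removed: biomass, myelin, intercellular candidates."""
    protected: Set[str] = set()
    for rxn in model.reactions:
        if rxn.id in ("BIOMASS", "DM_biomass", "MYELIN", "DM_myelin", "ATPM"):
            protected.add(rxn.id)
            continue
        for base in INTERCELLULAR_BASES:
            if f"{base}[e]" in rxn.stoichiometry:
                protected.add(rxn.id)
                break
    return protected


def extract_context_model(
    model: MetabolicModel,
    evidence: EvidenceTable,
    tasks: Sequence[MetabolicTask],
    protected: Optional[Iterable[str]] = None,
) -> MetabolicModel:
    """Extract the expression-supported, task-feasible sub-model.

    Raises :class:`ExtractionError` (listing the failing tasks) if the
    parent itself cannot perform the task list.  With empty evidence the
    parent is returned unchanged, with a warning.
    """
    parent_results = check_tasks(model, tasks)
    failing = [tid for tid, r in parent_results.items() if not r.feasible]
    if failing:
        raise ExtractionError(
            f"parent model {model.id!r} fails tasks: {failing}"
        )
    scored = {rid: s for rid, s in evidence.scores.items() if s is not None}
    if not scored:
        warnings.warn(
            f"empty evidence for {model.id!r}: returning the parent unchanged",
            stacklevel=2,
        )
        return model.copy(model_id=f"{model.id}_context")
    prot = set(protected) if protected is not None else default_protected(model)

    candidates = [
        rxn.id
        for rxn in model.reactions
        if rxn.id not in prot
        and not evidence.is_neutral(rxn.id)
        and not evidence.is_expressed(rxn.id)
    ]
    # ascending evidence, then lexicographic by id (deterministic)
    candidates.sort(key=lambda rid: (evidence.scores.get(rid, 0.0) or 0.0, rid))

    work = model.copy(model_id=f"{model.id}_context")
    for rid in candidates:
        trial = work.copy()
        trial.remove_reactions([rid])
        results = check_tasks(trial, tasks)
        if all(r.feasible for r in results.values()):
            work = trial
    work.remove_reactions([], prune_orphans=True)
    work.annotations["parent_model"] = model.id
    work.annotations["extraction"] = "tINIT-lite greedy task-checked removal"
    work.annotations["cutoff"] = evidence.cutoff
    return work
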