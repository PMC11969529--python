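"""Metabolic task checking and context-specific extraction (tINIT-lite)."""

import itertools

import numpy as np
import pandas as pd
import pytest

from brainflux.expression import EvidenceTable
from brainflux.extract import ExtractionError, default_protected, extract_context_model
from brainflux.model import MetabolicModel, Metabolite, Reaction
from brainflux.synth import generate_expression_profiles, generate_toy_cell_model
from brainflux.expression import mean_expression, tpm_normalize
from brainflux.tasks import MetabolicTask, check_task, check_tasks, tasks_for

from oracles import vertex_enumeration_lp


def evidence_for(model, seed=1, cutoff=1.0):
    profiles, lengths = generate_expression_profiles({model.annotations["cell_type"]: model}, seed=seed)
    counts = profiles[model.annotations["cell_type"]]
    tpm = counts.apply(lambda col: tpm_normalize(col, lengths), axis=0)
    return EvidenceTable.from_expression(model, mean_expression(tpm), cutoff=cutoff)


class TestCheckTask:
    def test_atp_from_glucose_and_oxygen_feasible(self, parent_models):
        task = next(t for t in tasks_for("neuron") if t.id == "atp_aerobic")
        res = check_task(parent_models["neuron"], task)
        assert res.feasible and res.achieved_flux > 0

    def test_infeasible_after_deleting_glycolysis_and_oxphos(self, parent_models):
        task = next(t for t in tasks_for("neuron") if t.id == "atp_aerobic")
        model = parent_models["neuron"].copy()
        model.remove_reactions(["HEX1", "GLYCL", "OXPHOS"])
        assert not check_task(model, task).feasible

    def test_naa_synthesis_neuron_vs_microglia(self, parent_models):
        """NAA synthesis is a neuron capability the microglia network lacks."""
        task = next(t for t in tasks_for("neuron") if t.id == "naa_synthesis")
        assert check_task(parent_models["neuron"], task).feasible
        res = check_task(parent_models["microglia"], task)
        assert not res.feasible
        assert res.reason  # missing metabolite reported, not an exception

    def test_missing_metabolite_is_reason_not_error(self, parent_models):
        task = MetabolicTask(id="x", allowed_inputs=(("nothing[c]", 1.0),),
                             required_outputs=(("co2[e]", 0.1),))
        res = check_task(parent_models["neuron"], task)
        assert not res.feasible and "nothing[c]" in res.reason

    def test_task_requires_at_least_one_output(self):
        with pytest.raises(ValueError, match="required output"):
            MetabolicTask(id="bad")

    def test_agrees_with_enumeration_oracle_on_small_models(self):
        """Task feasibility equals a brute-force vertex check on <=15 rxns."""
        rng = np.random.default_rng(11)
        for trial in range(10):
            m = MetabolicModel(f"small{trial}")
            mets = [f"M{i}[c]" for i in range(4)]
            for mid in mets:
                m.add_metabolite(Metabolite(id=mid))
            n = 6
            for j in range(n):
                picks = rng.choice(4, size=2, replace=False)
                m.add_reaction(Reaction(
                    id=f"r{j}",
                    stoichiometry={mets[picks[0]]: -1.0, mets[picks[1]]: 1.0},
                    lower_bound=0.0, upper_bound=float(rng.integers(1, 5)),
                ))
            task = MetabolicTask(
                id="probe",
                allowed_inputs=((mets[0], 2.0),),
                required_outputs=((mets[3], 0.5),),
            )
            res = check_task(m, task)
            # oracle: maximize sink flux on the augmented network
            work = m.copy()
            work.add_reaction(Reaction(id="IN", stoichiometry={mets[0]: 1.0}, upper_bound=2.0))
            work.add_reaction(Reaction(id="OUT", stoichiometry={mets[3]: -1.0}, upper_bound=1000.0))
            from brainflux.model import build_stoichiometric_matrix
            S = build_stoichiometric_matrix(work).toarray()
            lb = np.array([r.lower_bound for r in work.reactions])
            ub = np.array([min(r.upper_bound, 10.0) for r in work.reactions])
            c = np.zeros(len(work.reactions)); c[-1] = 1.0
            best = vertex_enumeration_lp(c, S, lb, ub, sense="max")
            assert res.feasible == (best is not None and best >= 0.5 - 1e-7)


class TestExtraction:
    def test_all_expressed_returns_parent(self, parent_models):
        model = parent_models["OPC"]
        ev = EvidenceTable(scores={r.id: (5.0 if r.gpr else None) for r in model.reactions})
        sub = extract_context_model(model, ev, tasks_for("OPC"))
        assert set(sub.reaction_ids) == set(model.reaction_ids)

    def test_single_irrelevant_unexpressed_reaction_removed(self, parent_models):
        model = parent_models["neuron"]
        scores = {r.id: (5.0 if r.gpr else None) for r in model.reactions}
        scores["PNMT"] = 0.0  # adrenaline synthesis not required by... it IS a task
        scores["ALATA"] = 0.0  # alanine transaminase is task-irrelevant
        ev = EvidenceTable(scores=scores)
        sub = extract_context_model(model, ev, tasks_for("neuron"))
        assert not sub.has_reaction("ALATA")
        assert sub.has_reaction("PNMT")  # kept: adrenaline task would break

    def test_empty_evidence_warns_and_returns_parent(self, parent_models):
        model = parent_models["OPC"]
        ev = EvidenceTable(scores={r.id: None for r in model.reactions})
        with pytest.warns(UserWarning, match="empty evidence"):
            sub = extract_context_model(model, ev, tasks_for("OPC"))
        assert set(sub.reaction_ids) == set(model.reaction_ids)

    def test_parent_task_failure_is_error(self, parent_models):
        model = parent_models["neuron"].copy()
        model.remove_reactions(["NAASYN"])
        ev = EvidenceTable(scores={r.id: (5.0 if r.gpr else None) for r in model.reactions})
        with pytest.raises(ExtractionError, match="naa_synthesis"):
            extract_context_model(model, ev, tasks_for("neuron"))

    def test_soundness_and_minimality_with_generated_expression(self, parent_models):
        """Extraction keeps every task feasible and leaves no removable
        zero-evidence reaction (exhaustive single-removal audit)."""
        model = parent_models["neuron"]
        ev = evidence_for(model, seed=3)
        tasks = tasks_for("neuron")
        sub = extract_context_model(model, ev, tasks)
        results = check_tasks(sub, tasks)
        assert all(r.feasible for r in results.values())
        protected = default_protected(sub)
        for rxn in sub.reactions:
            if rxn.id in protected or ev.is_neutral(rxn.id) or ev.is_expressed(rxn.id):
                continue
            trial = sub.copy()
            trial.remove_reactions([rxn.id])
            audit = check_tasks(trial, tasks)
            assert not all(r.feasible for r in audit.values()), (
                f"{rxn.id} is removable zero-evidence but was kept"
            )

    def test_monotonicity_more_evidence_never_shrinks(self, parent_models):
        model = parent_models["microglia"]
        tasks = tasks_for("microglia")
        base_scores = {r.id: (0.0 if r.gpr else None) for r in model.reactions}
        for rid in ("GLS", "HEX1", "GLYCL", "OXPHOS"):
            base_scores[rid] = 5.0
        lo = extract_context_model(model, EvidenceTable(scores=base_scores), tasks)
        more = dict(base_scores)
        for rid in ("FAS", "LIPSYN", "G6PDH2"):
            more[rid] = 5.0
        hi = extract_context_model(model, EvidenceTable(scores=more), tasks)
        assert set(lo.reaction_ids) <= set(hi.reaction_ids)

    def test_deterministic_given_inputs(self, parent_models):
        model = parent_models["astrocyte"]
        ev = evidence_for(model, seed=2)
        a = extract_context_model(model, ev, tasks_for("astrocyte"))
        b = extract_context_model(model, ev, tasks_for("astrocyte"))
        assert a.reaction_ids == b.reaction_ids
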