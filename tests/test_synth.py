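"""Toy network generator: structure, toggles, physiology, determinism."""

import numpy as np
import pandas as pd
import pytest

from brainflux.expression import mean_expression, tpm_normalize
from brainflux.simulate import apply_constraints, fba, fba_two_stage
from brainflux.synth import (
    CELL_TYPES,
    PlantedDESpec,
    SpecError,
    ToyBrainSpec,
    default_constraints,
    expressed_genes,
    generate_de_pvalues,
    generate_expression_profiles,
    generate_toy_cell_model,
    silent_genes,
)


class TestToyModels:
    def test_size_window_and_annotations(self, parent_models):
        for cell, model in parent_models.items():
            assert 40 <= len(model.reactions) <= 120, cell
            assert model.annotations["cell_type"] == cell
            model.validate()

    def test_every_internal_reaction_has_gpr_and_subsystem(self, parent_models):
        for model in parent_models.values():
            for rxn in model.reactions:
                assert rxn.subsystem, rxn.id
                if not rxn.is_boundary and rxn.subsystem not in ("Transport",
                        "Energy maintenance", "Miscellaneous", "Biomass"):
                    assert rxn.gpr, f"{model.id}:{rxn.id} lacks a GPR"

    def test_biomass_optimal_flux_positive(self, parent_models):
        for cell, model in parent_models.items():
            cm = apply_constraints(model, default_constraints(cell), role=cell)
            state = fba(cm, "BIOMASS")
            assert state.status == "optimal"
            assert state.objective_value > 0, cell

    def test_beta_oxidation_toggle_drops_carnitine_shuttle(self):
        spec = ToyBrainSpec(
            cell_types=("neuron", "astrocyte", "microglia", "oligodendrocyte"),
            pathways={"beta_oxidation": False, "carnitine_shuttle": False},
        )
        m = generate_toy_cell_model("microglia", spec)
        assert not any(r.subsystem == "Carnitine shuttle" for r in m.reactions)
        assert not m.has_reaction("CPT1")

    def test_toggle_dependency_errors(self):
        with pytest.raises(SpecError, match="carnitine_shuttle"):
            ToyBrainSpec(pathways={"beta_oxidation": False})
        with pytest.raises(SpecError, match="astrocyte"):
            ToyBrainSpec(cell_types=("neuron", "microglia"))
        with pytest.raises(SpecError, match="oligodendrocyte"):
            ToyBrainSpec(cell_types=("neuron", "astrocyte"))
        with pytest.raises(SpecError, match="biomass"):
            ToyBrainSpec(pathways={"PPP": False})

    def test_myelin_coefficient_override(self):
        spec = ToyBrainSpec(myelin_coefficients={"chsterol": 2.0})
        m = generate_toy_cell_model("oligodendrocyte", spec)
        assert m.reaction("MYELIN").stoichiometry["chsterol[c]"] == -2.0
        with pytest.raises(SpecError, match="unknown component"):
            generate_toy_cell_model(
                "oligodendrocyte", ToyBrainSpec(myelin_coefficients={"nope": 1.0})
            )

    def test_forced_myelin_reduces_biomass(self, parent_models):
        """Resource competition: maximal myelin output cuts into growth."""
        model = parent_models["oligodendrocyte"]
        cm = apply_constraints(model, default_constraints("oligodendrocyte"), role="oligodendrocyte")
        free = fba(cm, "BIOMASS")
        myelin_max = fba(cm, "MYELIN")
        assert myelin_max.objective_value > 0.01  # room above the resting flux
        forced = cm.copy()
        rxn = forced.reaction("MYELIN")
        rxn.lower_bound = rxn.upper_bound = myelin_max.objective_value
        capped = fba(forced, "BIOMASS")
        assert capped.status == "optimal"
        assert capped.objective_value < free.objective_value

    def test_biomass_nonincreasing_along_myelin_sweep(self, parent_models):
        model = parent_models["oligodendrocyte"]
        cm = apply_constraints(model, default_constraints("oligodendrocyte"), role="oligodendrocyte")
        top = fba(cm, "MYELIN").objective_value
        previous = None
        for level in np.linspace(0.0, top, 6):
            work = cm.copy()
            rxn = work.reaction("MYELIN")
            rxn.lower_bound = rxn.upper_bound = level
            b = fba(work, "BIOMASS").objective_value
            if previous is not None:
                assert b <= previous + 1e-9
            previous = b


class TestExpressionProfiles:
    def test_partition_respects_cutoff_after_tpm(self, parent_models):
        models = {c: parent_models[c] for c in ("neuron", "microglia")}
        profiles, lengths = generate_expression_profiles(models, seed=5)
        for cell, model in models.items():
            counts = profiles[cell]
            tpm = counts.apply(lambda col: tpm_normalize(col, lengths), axis=0)
            mean = mean_expression(tpm)
            on = expressed_genes(model)
            off = silent_genes(model)
            assert all(mean[g] >= 1.0 for g in on)
            assert all(mean[g] < 1.0 for g in off)

    def test_task_essential_genes_expressed_in_neuron(self, parent_models):
        model = parent_models["neuron"]
        on = expressed_genes(model)
        for rid in ("GLS", "GAD", "SERGLY", "DDC", "NAASYN"):
            assert model.reaction(rid).genes <= on

    def test_seed_changes_counts_not_partition(self, parent_models):
        models = {"neuron": parent_models["neuron"]}
        p1, l1 = generate_expression_profiles(models, seed=1)
        p2, l2 = generate_expression_profiles(models, seed=2)
        assert not p1["neuron"].equals(p2["neuron"])
        zero1 = (p1["neuron"].sum(axis=1) == 0)
        zero2 = (p2["neuron"].sum(axis=1) == 0)
        assert zero1.equals(zero2)
        # same seed reproduces exactly
        p1b, _ = generate_expression_profiles(models, seed=1)
        assert p1["neuron"].equals(p1b["neuron"])


class TestPlantedDE:
    def test_null_effect_gives_uniform_pvalues(self, parent_models):
        model = parent_models["microglia"]
        p = generate_de_pvalues(model, PlantedDESpec(effect=0.0, seed=3))
        vals = np.array(list(p.values()))
        assert len(vals) == len(model.genes)
        assert 0.3 < vals.mean() < 0.7  # Uniform(0,1) mean ~ 0.5

    def test_hot_neighborhood_mean_log10p_matches_effect(self, parent_models):
        model = parent_models["microglia"]
        hot_genes = set()
        for r in model.reactions_of_metabolite("crn[c]"):
            hot_genes |= r.genes
        draws = []
        for seed in range(30):
            p = generate_de_pvalues(
                model, PlantedDESpec(hot_metabolites=("crn[c]",), effect=3.0, seed=seed)
            )
            draws += [-np.log10(p[g]) for g in hot_genes]
        assert np.mean(draws) == pytest.approx(3.0, rel=0.1)

    def test_hot_metabolite_without_genes_rejected(self, parent_models):
        model = parent_models["microglia"]
        with pytest.raises(SpecError, match="no gene"):
            generate_de_pvalues(
                model, PlantedDESpec(hot_metabolites=("o2[e]",), effect=3.0)
            )
        with pytest.raises(SpecError, match="not in model"):
            generate_de_pvalues(
                model, PlantedDESpec(hot_metabolites=("ghost[c]",), effect=3.0)
            )

    def test_empty_hot_list_is_valid_null(self, parent_models):
        p = generate_de_pvalues(parent_models["neuron"], PlantedDESpec(seed=1))
        assert all(0 < v <= 1 for v in p.values())
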