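"""FBA/FVA/MOMA solvers, constraints, couplings, and activity summaries."""

import numpy as np
import pandas as pd
import pytest

from brainflux.model import MetabolicModel, Metabolite, ModelError, Reaction, build_stoichiometric_matrix
from brainflux.simulate import (
    ConstraintTable,
    ZERO_FLUX_TOL,
    add_flux_coupling,
    apply_constraints,
    brain_objective_ggg,
    fba,
    fba_two_stage,
    fva,
    moma,
    subsystem_activity,
)

from oracles import projection_qp, vertex_enumeration_lp


def chain_model(cap=10.0):
    """EX_in(<=cap) -> A -> biomass chain."""
    m = MetabolicModel("chain")
    m.add_metabolite(Metabolite(id="A[c]"))
    m.add_reaction(Reaction(id="EX_A", stoichiometry={"A[c]": 1}, lower_bound=0, upper_bound=cap))
    m.add_reaction(Reaction(id="GROW", stoichiometry={"A[c]": -1}, lower_bound=0, upper_bound=1000,
                            subsystem="Biomass"))
    return m


def random_network(rng, n_rxn=8, n_met=4):
    m = MetabolicModel("rand")
    mets = [f"M{i}[c]" for i in range(n_met)]
    for mid in mets:
        m.add_metabolite(Metabolite(id=mid))
    for j in range(n_rxn):
        k = int(rng.integers(1, 3))
        picks = rng.choice(n_met, size=min(k + 1, n_met), replace=False)
        stoich = {}
        for idx, p in enumerate(picks):
            stoich[mets[p]] = float(rng.choice([-2, -1, 1, 2]))
        lo = float(rng.choice([-3.0, -1.0, 0.0]))
        hi = float(rng.choice([1.0, 2.0, 4.0]))
        m.add_reaction(Reaction(id=f"r{j}", stoichiometry=stoich, lower_bound=lo, upper_bound=hi))
    return m


class TestFBA:
    def test_bottleneck_chain(self):
        state = fba(chain_model(cap=10.0), "GROW")
        assert state.status == "optimal"
        assert state.objective_value == pytest.approx(10.0)

    def test_closed_exchanges_give_zero(self):
        m = chain_model()
        m.reaction("EX_A").upper_bound = 0.0
        state = fba(m, "GROW")
        assert state.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_is_status_not_exception(self):
        m = chain_model()
        m.reaction("GROW").lower_bound = 20.0
        m.reaction("EX_A").upper_bound = 5.0
        assert fba(m, "GROW").status == "infeasible"

    def test_matches_vertex_enumeration_on_random_networks(self):
        """FBA optimum equals brute-force basic-solution enumeration."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 25:
            m = random_network(rng)
            state = fba(m, "r0", sense="max")
            if state.status != "optimal":
                continue
            S = build_stoichiometric_matrix(m).toarray()
            lb = np.array([r.lower_bound for r in m.reactions])
            ub = np.array([r.upper_bound for r in m.reactions])
            c = np.zeros(len(m.reactions)); c[0] = 1.0
            oracle = vertex_enumeration_lp(c, S, lb, ub, sense="max")
            assert oracle is not None
            assert state.objective_value == pytest.approx(oracle, abs=1e-6)
            checked += 1

    def test_steady_state_residual_within_tolerance(self, pipeline_ctx):
        state = brain_objective_ggg(pipeline_ctx["brain"])
        assert state.steady_state_residual(pipeline_ctx["brain"]) <= 1e-6


class TestTwoStage:
    def symmetric_model(self):
        """Two identical parallel routes A -> B."""
        m = MetabolicModel("sym")
        for mid in ("A[c]", "B[c]"):
            m.add_metabolite(Metabolite(id=mid))
        m.add_reaction(Reaction(id="EX_A", stoichiometry={"A[c]": 1}, upper_bound=4.0))
        m.add_reaction(Reaction(id="P1", stoichiometry={"A[c]": -1, "B[c]": 1}))
        m.add_reaction(Reaction(id="P2", stoichiometry={"A[c]": -1, "B[c]": 1}))
        m.add_reaction(Reaction(id="EX_B", stoichiometry={"B[c]": -1}))
        return m

    def test_equal_split_across_equivalent_routes(self):
        """KKT: min v1^2 + v2^2 s.t. v1 + v2 = f has v1 = v2 = f/2."""
        state = fba_two_stage(self.symmetric_model(), "EX_B")
        assert state.objective_value == pytest.approx(4.0)
        assert state.fluxes["P1"] == pytest.approx(2.0, abs=1e-7)
        assert state.fluxes["P2"] == pytest.approx(2.0, abs=1e-7)

    def test_single_pathway_identical_to_fba(self):
        m = chain_model(cap=7.0)
        plain = fba(m, "GROW")
        staged = fba_two_stage(m, "GROW")
        assert staged.objective_value == pytest.approx(plain.objective_value)
        assert staged.fluxes["GROW"] == pytest.approx(plain.fluxes["GROW"], abs=1e-8)

    def test_stage2_norm_not_above_stage1_solution(self):
        m = self.symmetric_model()
        lp = fba(m, "EX_B")
        qp = fba_two_stage(m, "EX_B")
        norm = lambda st: sum(v * v for v in st.fluxes.values())
        assert norm(qp) <= norm(lp) + 1e-9


class TestFVA:
    def test_blocked_reaction_is_zero_zero(self):
        m = chain_model()
        m.add_metabolite(Metabolite(id="C[c]"))
        m.add_reaction(Reaction(id="orphan", stoichiometry={"C[c]": 1}, upper_bound=5))
        # C has no consumer: steady state forces zero
        res = fva(m, ["orphan"])
        assert res.loc["orphan", "minimum"] == pytest.approx(0.0, abs=1e-9)
        assert res.loc["orphan", "maximum"] == pytest.approx(0.0, abs=1e-9)

    def test_exchange_without_consumer_pinned_at_zero(self):
        m = MetabolicModel("t")
        m.add_metabolite(Metabolite(id="X[e]"))
        m.add_reaction(Reaction(id="EX_X", stoichiometry={"X[e]": -1}, lower_bound=-0.01, upper_bound=1000))
        res = fva(m)
        assert res.loc["EX_X", "minimum"] == pytest.approx(0.0, abs=1e-9)
        assert res.loc["EX_X", "maximum"] == pytest.approx(0.0, abs=1e-9)

    def test_fba_flux_contained_in_fva_interval(self, pipeline_ctx):
        model = pipeline_ctx["constrained"]["microglia"]
        state = fba(model, "BIOMASS")
        opt = model.copy()
        rxn = opt.reaction("BIOMASS")
        rxn.lower_bound = state.objective_value - 1e-9
        rng = np.random.default_rng(0)
        targets = list(rng.choice(opt.reaction_ids, size=20, replace=False))
        res = fva(opt, targets)
        for rid in targets:
            lo, hi = res.loc[rid, "minimum"], res.loc[rid, "maximum"]
            assert lo - 1e-6 <= state.fluxes[rid] <= hi + 1e-6


class TestMOMA:
    def five_reaction_model(self):
        m = MetabolicModel("m5")
        for mid in ("A[c]", "B[c]"):
            m.add_metabolite(Metabolite(id=mid))
        m.add_reaction(Reaction(id="in", stoichiometry={"A[c]": 1}, lower_bound=-10, upper_bound=10))
        m.add_reaction(Reaction(id="p1", stoichiometry={"A[c]": -1, "B[c]": 1}, lower_bound=-10, upper_bound=10))
        m.add_reaction(Reaction(id="p2", stoichiometry={"A[c]": -1, "B[c]": 1}, lower_bound=-10, upper_bound=10))
        m.add_reaction(Reaction(id="p3", stoichiometry={"A[c]": -1, "B[c]": 1}, lower_bound=-10, upper_bound=10))
        m.add_reaction(Reaction(id="out", stoichiometry={"B[c]": -1}, lower_bound=-10, upper_bound=10))
        return m

    def test_unperturbed_returns_reference_with_zero_distance(self):
        m = self.five_reaction_model()
        ref = fba_two_stage(m, {"out": 1.0})
        state = moma(m, ref)
        assert state.distance == pytest.approx(0.0, abs=1e-7)
        for rid, v in ref.fluxes.items():
            assert state.fluxes[rid] == pytest.approx(v, abs=1e-6)

    def test_knockout_matches_closed_form_projection(self):
        """Forcing one route to zero: QP equals the interior projection."""
        m = self.five_reaction_model()
        ref_vec = {"in": 6.0, "p1": 2.0, "p2": 2.0, "p3": 2.0, "out": 6.0}
        from brainflux.simulate import FluxState
        ref = FluxState(fluxes=ref_vec, objective_value=6.0, status="optimal")
        pert = m.copy()
        rxn = pert.reaction("p1")
        rxn.lower_bound = rxn.upper_bound = 0.0
        state = moma(pert, ref)
        S = build_stoichiometric_matrix(m).toarray()
        target = np.array([ref_vec[r.id] for r in m.reactions])
        oracle = projection_qp(S, target, fixed={1: 0.0})
        for i, r in enumerate(m.reactions):
            assert state.fluxes[r.id] == pytest.approx(oracle[i], abs=1e-6)

    def test_infeasible_perturbation_reported(self):
        m = self.five_reaction_model()
        ref = fba_two_stage(m, {"out": 1.0})
        pert = m.copy()
        pert.reaction("out").lower_bound = 20.0
        pert.reaction("out").upper_bound = 30.0
        assert moma(pert, ref).status == "infeasible"

    def test_distance_monotone_in_myelin_departure(self, pipeline_ctx, protocol_results):
        res = protocol_results["demyelination"]
        distances = [s.distance for s in res.states]
        assert all(b >= a - 1e-9 for a, b in zip(distances, distances[1:]))


class TestConstraintsAndCouplings:
    def test_exchange_default_policy(self, parent_models):
        model = parent_models["OPC"]
        out = apply_constraints(model, ConstraintTable(rows=[("EX_glc__D", -0.1, 1000.0)]))
        for rxn in out.boundary_reactions():
            if rxn.id == "EX_glc__D":
                assert rxn.lower_bound == -0.1
            else:
                assert rxn.lower_bound == -0.01
                assert rxn.upper_bound == 1000.0

    def test_glial_role_zeroes_internal_lower_bounds(self, parent_models):
        model = parent_models["microglia"]
        table = ConstraintTable(rows=[("LDH_L", -5.0, 5.0), ("EX_glc__D", -0.06, 1000.0)])
        out = apply_constraints(model, table, role="microglia")
        assert out.reaction("LDH_L").lower_bound == 0.0  # internal: floored
        assert out.reaction("EX_glc__D").lower_bound == -0.06  # uptake kept

    def test_unknown_reaction_rejected(self, parent_models):
        with pytest.raises(ModelError):
            apply_constraints(parent_models["OPC"], ConstraintTable(rows=[("nope", 0, 1)]))

    def test_coupling_ratio_held_to_1e8(self):
        m = chain_model(cap=10.0)
        m.add_metabolite(Metabolite(id="B[c]"))
        m.add_reaction(Reaction(id="side", stoichiometry={"A[c]": -1, "B[c]": 1}))
        m.add_reaction(Reaction(id="EX_B", stoichiometry={"B[c]": -1}))
        add_flux_coupling(m, "side", "GROW", 0.05)
        state = fba_two_stage(m, "GROW")
        assert state.fluxes["side"] == pytest.approx(0.05 * state.fluxes["GROW"], abs=1e-8)

    def test_negative_alpha_rejected_in_table(self):
        with pytest.raises(ValueError, match="alpha"):
            ConstraintTable(couplings=[("a", "b", -0.1)])


class TestSubsystemActivity:
    def test_zero_flux_all_zero(self, parent_models):
        from brainflux.simulate import FluxState
        model = parent_models["OPC"]
        state = FluxState(fluxes={r.id: 0.0 for r in model.reactions}, objective_value=0.0, status="optimal")
        act = subsystem_activity(state, model)
        assert (act["flux_sum"] == 0).all()
        assert (act["active"] == 0).all()

    def test_absolute_value_and_threshold(self):
        from brainflux.simulate import FluxState
        m = MetabolicModel("t")
        m.add_metabolite(Metabolite(id="A[c]"))
        m.add_reaction(Reaction(id="r1", stoichiometry={"A[c]": 1}, lower_bound=-10, subsystem="S"))
        m.add_reaction(Reaction(id="r2", stoichiometry={"A[c]": -1}, lower_bound=-10, subsystem="S"))
        state = FluxState(fluxes={"r1": -2.0, "r2": 1e-8}, objective_value=None, status="optimal")
        act = subsystem_activity(state, m)
        assert act.loc["S", "flux_sum"] == pytest.approx(2.0 + 1e-8)
        assert act.loc["S", "active"] == 1  # 1e-8 below the 1e-6 threshold
        assert act.loc["S", "total"] == 2

    def test_totals_match_naive_loop(self, pipeline_ctx):
        model = pipeline_ctx["constrained"]["neuron"]
        state = fba_two_stage(model, "BIOMASS")
        act = subsystem_activity(state, model)
        for sub in act.index:
            s = sum(abs(state.fluxes[r.id]) for r in model.reactions if (r.subsystem or "Unassigned") == sub)
            assert act.loc[sub, "flux_sum"] == pytest.approx(s)


class TestCobraCrossCheck:
    def test_fba_optimum_agrees_with_cobra(self, pipeline_ctx):
        """Independent solver route: the same network built in COBRApy
        (GLPK) reproduces the biomass optimum."""
        cobra = pytest.importorskip("cobra")
        model = pipeline_ctx["constrained"]["microglia"]
        cm = cobra.Model("check")
        mets = {m.id: cobra.Metabolite(m.id.replace("[", "_").replace("]", "")) for m in model.metabolites}
        rxns = []
        for r in model.reactions:
            cr = cobra.Reaction(r.id)
            cr.lower_bound, cr.upper_bound = r.lower_bound, r.upper_bound
            rxns.append((cr, {mets[k]: v for k, v in r.stoichiometry.items()}))
        cm.add_reactions([cr for cr, _ in rxns])
        for cr, stoich in rxns:
            cr.add_metabolites(stoich)
        cm.objective = "BIOMASS"
        ours = fba(model, "BIOMASS")
        theirs = cm.slim_optimize()
        assert ours.objective_value == pytest.approx(theirs, abs=1e-6)
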