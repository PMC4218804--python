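import numpy as np
import pandas as pd
import pytest

from valveflux.cbm import (
    FluxSolution,
    SolverError,
    classify_genes_pfba,
    compare_capacity,
    count_carrying_flux,
    fba,
    fva,
    maximize_reaction_objective,
    pfba,
    single_gene_deletion,
)
from valveflux.synthetic import random_model, toy_class


class TestFBA:
    def test_linear_chain_optimum(self, lin):
        model, analytic = lin
        sol = fba(model)
        assert sol.optimal
        assert sol.f == pytest.approx(analytic["optimum"], abs=1e-9)

    def test_steady_state_and_bounds_hold(self, core):
        model, _ = core
        sol = fba(model)
        S = model.stoichiometric_matrix()
        assert np.abs(S @ sol.x.to_numpy()).max() < 1e-6
        for r in model.reactions:
            assert r.lower_bound - 1e-6 <= sol.x[r.id] <= r.upper_bound + 1e-6

    def test_closed_exchanges_give_zero_growth(self, lin):
        model, _ = lin
        model = model.copy()
        model.reaction("EX_A").upper_bound = 0.0
        assert fba(model).f == pytest.approx(0.0, abs=1e-9)

    def test_parallel_path_compensates_for_tight_branch(self, par):
        model, _ = par
        model = model.copy()
        model.reaction("R1").upper_bound = 3.0
        assert fba(model).f == pytest.approx(10.0, abs=1e-9)

    def test_strong_duality_residual_small(self, core):
        model, _ = core
        sol = fba(model)
        assert sol.duality_residual < 1e-6

    def test_infeasible_reported_in_status(self):
        from valveflux.model_core import MetabolicModel, Metabolite, Reaction

        model = MetabolicModel(
            id="forced",
            metabolites=[Metabolite("A")],
            reactions=[
                Reaction("IN", stoichiometry={"A": 1}, lower_bound=5, upper_bound=10,
                         objective_coefficient=1.0)
            ],
        )
        assert fba(model).status == "infeasible"


class TestCarryingFlux:
    @pytest.mark.parametrize(
        "x,expected",
        [
            ([10, 10, 10], (3, 3, 0)),
            ([10, -5, 10, 0], (3, 2, 1)),
            ([1e-12, 0, 0], (0, 0, 0)),  # below tolerance
        ],
    )
    def test_counts(self, x, expected):
        sol = FluxSolution(
            f=1.0,
            x=pd.Series(x, index=[f"r{i}" for i in range(len(x))]),
            y=pd.Series(dtype=float),
            w=pd.Series(dtype=float),
            status="optimal",
        )
        assert count_carrying_flux(sol) == expected

    def test_rejects_non_optimal_solution(self):
        sol = FluxSolution(float("nan"), pd.Series(dtype=float), pd.Series(dtype=float),
                           pd.Series(dtype=float), "infeasible")
        with pytest.raises(SolverError):
            count_carrying_flux(sol)


class TestFVA:
    def test_parallel_branches_full_range(self, par):
        model, analytic = par
        res = fva(model, 1.0)
        for rid, (lo, hi) in analytic["fva_at_optimum"].items():
            assert res.minimum[rid] == pytest.approx(lo, abs=1e-6)
            assert res.maximum[rid] == pytest.approx(hi, abs=1e-6)

    def test_linear_chain_fully_determined(self, lin):
        model, _ = lin
        res = fva(model, 1.0)
        for rid in model.reaction_ids:
            assert res.minimum[rid] == pytest.approx(10.0, abs=1e-6)
            assert res.maximum[rid] == pytest.approx(10.0, abs=1e-6)

    def test_half_optimum_frees_biomass_range(self, lin):
        model, _ = lin
        res = fva(model, 0.5)
        assert res.minimum["BIO"] == pytest.approx(5.0, abs=1e-6)
        assert res.maximum["BIO"] == pytest.approx(10.0, abs=1e-6)

    def test_invalid_fraction_rejected(self, lin):
        model, _ = lin
        with pytest.raises(ValueError):
            fva(model, 1.5)

    def test_pfba_flux_inside_fva_envelope(self, classify):
        model, _ = classify
        envelope = fva(model, 1.0)
        sol = pfba(model)
        # pFBA fixes growth with 1e-6 relative slack, so the envelope check
        # needs a matching scale-aware tolerance
        tol = 2e-6 * max(1.0, abs(sol.f))
        for rid in model.reaction_ids:
            assert envelope.minimum[rid] - tol <= sol.x[rid] <= envelope.maximum[rid] + tol


class TestCompareCapacity:
    def test_increase_and_decrease_partition(self, lin):
        from valveflux.cbm import FVAResult

        model, _ = lin
        wt = FVAResult(minimum=pd.Series({"EX_A": 0.0, "R_AB": 0.0, "BIO": 0.0}),
                       maximum=pd.Series({"EX_A": 10.0, "R_AB": 10.0, "BIO": 10.0}),
                       fraction_of_optimum=1.0)
        mut = FVAResult(minimum=pd.Series({"EX_A": 0.0, "R_AB": 0.0, "BIO": 0.0}),
                        maximum=pd.Series({"EX_A": 12.0, "R_AB": 7.0, "BIO": 10.0}),
                        fraction_of_optimum=1.0)
        cmp = compare_capacity(wt, mut, model, tol=1e-6)
        assert cmp.delta["EX_A"] == pytest.approx(2.0)
        assert cmp.increased_subsystems == {"exchange": ["EX_A"]}
        assert cmp.decreased_subsystems == {"conversion": ["R_AB"]}

    def test_identical_results_give_empty_sets(self, lin):
        model, _ = lin
        res = fva(model, 1.0)
        cmp = compare_capacity(res, res, model, tol=1e-6)
        assert cmp.increased_subsystems == {} and cmp.decreased_subsystems == {}

    def test_subsystem_can_appear_in_both_lists(self, par):
        from valveflux.cbm import FVAResult

        model, _ = par
        rids = model.reaction_ids
        wt = FVAResult(pd.Series(0.0, index=rids), pd.Series(10.0, index=rids), 1.0)
        mx = pd.Series(10.0, index=rids)
        mx["R1"] += 2.0  # same subsystem as R2
        mx["R2"] -= 3.0
        mut = FVAResult(pd.Series(0.0, index=rids), mx, 1.0)
        cmp = compare_capacity(wt, mut, model, tol=1e-6)
        assert "conversion" in cmp.increased_subsystems
        assert "conversion" in cmp.decreased_subsystems

    def test_mismatched_reaction_sets_rejected(self, lin, par):
        model, _ = lin
        with pytest.raises(ValueError):
            compare_capacity(fva(model, 1.0), fva(par[0], 1.0), model)


class TestSingleGeneDeletion:
    def test_chain_gene_is_essential(self, lin):
        model, _ = lin
        res = single_gene_deletion(model)
        assert res.growth["gB"] == pytest.approx(0.0, abs=1e-9)
        assert bool(res.essential["gB"])

    def test_redundant_gene_is_not_essential(self, par):
        model, _ = par
        res = single_gene_deletion(model)
        assert res.growth["g1"] == pytest.approx(10.0, abs=1e-6)
        assert not bool(res.essential["g1"])

    def test_isozyme_or_rule_protects_reaction(self, core):
        model, _ = core
        res = single_gene_deletion(model, genes=["gA1"])
        assert res.growth["gA1"] == pytest.approx(res.wt_growth, abs=1e-6)

    def test_complex_and_rule_disables_reaction(self, core):
        model, _ = core
        # Bx1 needs both subunits, but Bx2 is a parallel route: no growth loss
        res = single_gene_deletion(model, genes=["gB1"])
        assert res.growth["gB1"] == pytest.approx(res.wt_growth, abs=1e-6)

    def test_ratios_bounded(self, classify):
        model, _ = classify
        res = single_gene_deletion(model)
        assert ((res.ratio >= 0) & (res.ratio <= 1)).all()


class TestPFBA:
    def test_short_route_preferred(self, shortlong):
        model, analytic = shortlong
        sol = pfba(model)
        for rid, v in analytic["pfba_fluxes"].items():
            assert sol.x[rid] == pytest.approx(v, abs=1e-5)

    def test_objective_preserved_within_tolerance(self, classify):
        model, _ = classify
        assert abs(pfba(model).f - fba(model).f) < 1e-6 * max(1.0, abs(fba(model).f))

    def test_unique_optimum_unchanged(self, lin):
        model, _ = lin
        sol = pfba(model)
        assert sol.x["R_AB"] == pytest.approx(10.0, abs=1e-5)


class TestClassification:
    def test_planted_categories_recovered(self):
        model, analytic = toy_class()
        cls = classify_genes_pfba(model)
        for gene, expected in analytic["categories"].items():
            assert cls.category[gene] == expected, gene

    def test_categories_partition_gene_set(self, classify):
        model, _ = classify
        cls = classify_genes_pfba(model)
        assert set(cls.category.index) == set(model.genes)
        assert cls.category.notna().all()

    def test_essential_gene_is_classified_essential(self, lin):
        model, _ = lin
        cls = classify_genes_pfba(model)
        deletions = single_gene_deletion(model)
        for g in model.genes:
            if deletions.essential[g]:
                assert cls.category[g] == "essential"


class TestTargetedObjective:
    def test_chain_reaction_max_equals_uptake(self, lin):
        model, _ = lin
        assert maximize_reaction_objective(model, "R_AB").f == pytest.approx(10.0, abs=1e-9)

    def test_blocked_reaction_maximum_zero(self, classify):
        model, _ = classify
        assert maximize_reaction_objective(model, "R_DEAD").f == pytest.approx(0.0, abs=1e-9)

    def test_reversible_target_solved_with_zero_lower_bound(self, lin):
        model, _ = lin
        model = model.copy()
        model.reaction("R_AB").lower_bound = -1000.0
        sol = maximize_reaction_objective(model, "R_AB")
        assert sol.f == pytest.approx(10.0, abs=1e-9)
        # pure function: input model untouched
        assert model.reaction("R_AB").lower_bound == -1000.0

    def test_unknown_reaction_rejected(self, lin):
        with pytest.raises(KeyError):
            maximize_reaction_objective(lin[0], "nope")


class TestRandomModelsAgainstOracle:
    """Spot-check FBA/FVA against cobrapy (GLPK) on seeded random models;
    the full 200-model sweep lives in the acceptance suite."""

    @pytest.mark.parametrize("seed", range(20))
    def test_fba_and_fva_match_glpk(self, seed):
        from oracles import cobra_fba_optimum, cobra_fva

        model, _ = random_model(seed, n_reactions=10)
        sol = fba(model)
        expected = cobra_fba_optimum(model)
        assert sol.f == pytest.approx(expected, abs=1e-6)
        mins, maxs = cobra_fva(model, 1.0)
        res = fva(model, 1.0)
        for rid in model.reaction_ids:
            assert res.minimum[rid] == pytest.approx(mins[rid], abs=1e-6)
            assert res.maximum[rid] == pytest.approx(maxs[rid], abs=1e-6)
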