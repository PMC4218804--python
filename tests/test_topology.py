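import math

import networkx as nx
import numpy as np
import pytest

from oracles import (
    brute_betweenness_stress,
    brute_bottleneck,
    brute_closeness_harmonic,
    brute_clustering,
    brute_degree,
    brute_eccentricity,
    brute_epc_exact,
    brute_mcc,
    brute_mnc_dmnc,
    brute_radiality,
)
from valveflux.topology import (
    CentralityConfig,
    build_enzyme_network,
    compute_centralities,
    epc_scores,
    rank_and_flag,
)


def random_graph(seed: int, max_nodes: int = 8) -> nx.Graph:
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, max_nodes + 1))
    p = rng.uniform(0.15, 0.8)
    g = nx.Graph()
    nodes = [f"n{i}" for i in range(n)]
    g.add_nodes_from(nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(nodes[i], nodes[j])
    return g


class TestNetworkConstruction:
    def test_shared_metabolite_makes_edge(self, lin):
        model, _ = lin
        g = build_enzyme_network(model, excluded_metabolites=set())
        assert g.has_edge("gA", "gB")  # both reactions touch metabolite A

    def test_excluded_metabolite_removes_edge(self, lin):
        model, _ = lin
        g = build_enzyme_network(model, excluded_metabolites={"a", "b"})
        assert not g.has_edge("gA", "gB")

    def test_same_reaction_genes_always_joined(self, core):
        model, _ = core
        g = build_enzyme_network(model, excluded_metabolites={"p1", "b1"})
        assert g.has_edge("gA1", "gA1b")  # isozyme pair on one reaction
        assert g.has_edge("gB1", "gB1b")  # complex subunits

    def test_currency_exclusion_by_name(self):
        from valveflux.model_core import MetabolicModel, Metabolite, Reaction
        from valveflux.model_core import parse_gpr

        model = MetabolicModel(
            id="cur",
            metabolites=[Metabolite("atp_c", name="ATP"), Metabolite("X", name="X")],
            reactions=[
                Reaction("R1", stoichiometry={"atp_c": -1, "X": 1}, gpr=parse_gpr("g1"),
                         objective_coefficient=1.0),
                Reaction("R2", stoichiometry={"atp_c": 1}, gpr=parse_gpr("g2")),
            ],
        )
        g = build_enzyme_network(model)  # default currency list excludes ATP
        assert not g.has_edge("g1", "g2")

    def test_no_gpr_model_warns_and_returns_empty(self, caplog):
        from valveflux.model_core import MetabolicModel, Metabolite, Reaction

        model = MetabolicModel(
            id="bare",
            metabolites=[Metabolite("A")],
            reactions=[Reaction("R", stoichiometry={"A": 1}, objective_coefficient=1.0)],
        )
        with caplog.at_level("WARNING"):
            g = build_enzyme_network(model)
        assert g.number_of_nodes() == 0
        assert any("no GPR" in rec.message for rec in caplog.records)

    def test_simple_graph_no_self_loops(self, core):
        model, _ = core
        g = build_enzyme_network(model)
        assert all(a != b for a, b in g.edges)


class TestClosedForms:
    def test_triangle_k3(self):
        g = nx.complete_graph(3)
        t = compute_centralities(g, CentralityConfig(epc_realizations=50, seed=0))
        for v in g:
            assert t.scores.loc[v, "Degree"] == 2
            assert t.scores.loc[v, "ClusteringCoefficient"] == 1.0
            assert t.scores.loc[v, "MCC"] == 2.0  # one maximal clique of size 3: (3-1)!
            assert t.scores.loc[v, "MNC"] == 2.0
            assert t.scores.loc[v, "Eccentricity"] == 1.0
            assert t.scores.loc[v, "Closeness"] == 2.0
            assert t.scores.loc[v, "Betweenness"] == 0.0
            assert t.scores.loc[v, "Stress"] == 0.0
            # neighborhood component: single edge, 2 nodes
            assert t.scores.loc[v, "DMNC"] == pytest.approx(1.0 / 2**1.7)

    def test_path_p3_center_vs_ends(self):
        g = nx.path_graph(3)
        t = compute_centralities(g, CentralityConfig(epc_realizations=50, seed=0))
        assert t.scores.loc[1, "Betweenness"] == 1.0
        assert t.scores.loc[1, "Stress"] == 1.0
        assert t.scores.loc[0, "Betweenness"] == 0.0
        assert t.scores.loc[0, "Stress"] == 0.0
        assert t.scores.loc[1, "Eccentricity"] == 1.0
        assert t.scores.loc[0, "Eccentricity"] == 2.0
        # radiality: diameter 2; center: (2+1-1)*2/2 = 2; end: ((2+1-1)+(2+1-2))/2
        assert t.scores.loc[1, "Radiality"] == pytest.approx(2.0)
        assert t.scores.loc[0, "Radiality"] == pytest.approx(1.5)


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("seed", range(25))
    def test_all_indices_match_enumeration(self, seed):
        g = random_graph(seed)
        nodes, edges = list(g.nodes), list(g.edges)
        t = compute_centralities(g, CentralityConfig(epc_realizations=10, seed=0))
        expected = {
            "Degree": brute_degree(nodes, edges),
            "ClusteringCoefficient": brute_clustering(nodes, edges),
            "Eccentricity": brute_eccentricity(nodes, edges),
            "Closeness": brute_closeness_harmonic(nodes, edges),
            "Radiality": brute_radiality(nodes, edges),
            "MCC": brute_mcc(nodes, edges),
            "BottleNeck": brute_bottleneck(nodes, edges),
        }
        bet, stress = brute_betweenness_stress(nodes, edges)
        expected["Betweenness"] = bet
        expected["Stress"] = stress
        mnc, dmnc = brute_mnc_dmnc(nodes, edges)
        expected["MNC"] = mnc
        expected["DMNC"] = dmnc
        for index, ref in expected.items():
            for v in nodes:
                assert t.scores.loc[v, index] == pytest.approx(ref[v], abs=1e-9), (index, v)

    @pytest.mark.parametrize("seed", range(5))
    def test_epc_monte_carlo_matches_exact_expectation(self, seed):
        g = random_graph(seed, max_nodes=5)
        if g.number_of_edges() > 10:
            g.remove_edges_from(list(g.edges)[10:])
        exact = brute_epc_exact(list(g.nodes), list(g.edges), retention=0.5)
        mc = epc_scores(g, realizations=3000, retention=0.5, seed=seed)
        for v in g.nodes:
            se = math.sqrt(len(g) ** 2 / 4 / 3000)  # crude bound on MC error
            assert abs(mc[v] - exact[v]) < max(4 * se, 0.2), v

    def test_epc_retention_one_is_component_size(self):
        g = nx.disjoint_union(nx.path_graph(3), nx.complete_graph(4))
        scores = epc_scores(g, realizations=3, retention=1.0, seed=0)
        for comp in nx.connected_components(g):
            for v in comp:
                assert scores[v] == float(len(comp))

    @pytest.mark.parametrize("seed", range(5))
    def test_scores_invariant_under_relabeling(self, seed):
        g = random_graph(seed)
        rng = np.random.default_rng(seed + 99)
        perm = {v: f"z{j}" for v, j in zip(g.nodes, rng.permutation(len(g)))}
        h = nx.relabel_nodes(g, perm)
        tg = compute_centralities(g, CentralityConfig(epc_realizations=1, epc_retention_probability=0.999999, seed=0))
        th = compute_centralities(h, CentralityConfig(epc_realizations=1, epc_retention_probability=0.999999, seed=0))
        for col in tg.scores.columns:
            if col in ("EPC", "BottleNeck"):
                continue  # tie-breaks/seeds are id-dependent by design
            for v in g.nodes:
                assert tg.scores.loc[v, col] == pytest.approx(th.scores.loc[perm[v], col]), (col, v)


class TestRanking:
    def test_k_larger_than_graph_flags_all(self):
        g = nx.path_graph(3)
        t = compute_centralities(g, CentralityConfig(epc_realizations=5, seed=0))
        flags = rank_and_flag(t, set(g.nodes), k=5)
        for col, members in flags.items():
            assert sorted(members) == sorted(g.nodes)

    def test_tie_at_boundary_prefers_smaller_id(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("a", "c"), ("b", "c")])  # symmetric K3
        t = compute_centralities(g, CentralityConfig(epc_realizations=5, seed=0))
        flags = rank_and_flag(t, {"a", "b", "c"}, k=1)
        for col, members in flags.items():
            assert members == ["a"], col

    def test_disjoint_gene_set_empty_report(self, caplog):
        g = nx.path_graph(3)
        t = compute_centralities(g, CentralityConfig(epc_realizations=5, seed=0))
        with caplog.at_level("WARNING"):
            flags = rank_and_flag(t, {"missing"}, k=2)
        assert all(members == [] for members in flags.values())
        assert any("disjoint" in rec.message for rec in caplog.records)

    def test_ranks_are_permutations(self, core):
        model, _ = core
        g = build_enzyme_network(model)
        t = compute_centralities(g, CentralityConfig(epc_realizations=20, seed=0))
        n = len(t.ranks)
        for col in t.ranks.columns:
            assert sorted(t.ranks[col]) == list(range(1, n + 1))

    def test_invalid_k_rejected(self):
        g = nx.path_graph(2)
        t = compute_centralities(g, CentralityConfig(epc_realizations=5, seed=0))
        with pytest.raises(ValueError):
            rank_and_flag(t, set(), k=0)
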