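"""Enzyme-centric network construction and twelve centrality indices.

Nodes are genes (the network is "enzyme-centric" in the loose sense common
for metabolic networks; complexes and isozymes are not resolved).  Two genes
are joined iff their reactions share at least one non-excluded metabolite or
they annotate the same reaction.  Highly connected currency metabolites
(ATP, NAD(H), water, protons, ...) are excluded by default, since they would
otherwise join nearly everything to everything.

The twelve indices are the hub-detection set popularized by the CytoHubba
plugin: MCC, DMNC, MNC, Degree, EPC, BottleNeck, Eccentricity, Closeness
(reciprocal-distance form), Radiality, Betweenness, Stress and the local
clustering coefficient.  Distance-based indices are computed within
connected components; degenerate conventions for singletons are documented
on each function.
"""

from __future__ import annotations

import logging
import math
import re
from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .model_core import MetabolicModel

logger = logging.getLogger(__name__)

INDEX_COLUMNS = (
    "MCC",
    "DMNC",
    "MNC",
    "Degree",
    "EPC",
    "BottleNeck",
    "Eccentricity",
    "Closeness",
    "Radiality",
    "Betweenness",
    "Stress",
    "ClusteringCoefficient",
)

#: Eccentricity is the one index where *smaller* means more central.
ASCENDING_INDICES = ("Eccentricity",)

#: Currency metabolites excluded from edge construction, matched by name/id.
DEFAULT_CURRENCY_METABOLITES = frozenset(
    {
        "atp", "adp", "amp", "nad", "nadh", "nad+", "nadp", "nadph", "nadp+",
        "coa", "coenzyme a", "co2", "carbon dioxide", "h2o", "water", "h",
        "h+", "proton", "pi", "phosphate", "ppi", "diphosphate",
    }
)

_COMPARTMENT_SUFFIX = re.compile(r"(\s*\[[a-z0-9]+\]|_[a-z0-9]{1,2})$", re.IGNORECASE)


@dataclass
class CentralityConfig:
    """Constants for the stochastic / parameterized indices."""

    dmnc_epsilon: float = 1.7
    epc_realizations: int = 1000
    epc_retention_probability: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.dmnc_epsilon <= 0:
            raise ValueError("dmnc_epsilon must be positive")
        if not 0 < self.epc_retention_probability <= 1:
            raise ValueError("epc_retention_probability must be in (0, 1]")


def _is_currency(met, excluded: frozenset[str]) -> bool:
    for raw in (met.id, met.name):
        if not raw:
            continue
        base = _COMPARTMENT_SUFFIX.sub("", raw.strip()).strip().lower()
        if base in excluded or raw.strip().lower() in excluded:
            return True
    return False


def build_enzyme_network(
    model: MetabolicModel,
    excluded_metabolites: frozenset[str] | set[str] | None = None,
) -> nx.Graph:
    """Undirected simple graph over the model's genes.

    An edge joins two genes iff they annotate the same reaction or their
    reactions share a non-excluded metabolite.  ``excluded_metabolites``
    defaults to the currency list; pass an empty set to disable exclusion.
    """
    if excluded_metabolites is None:
        excluded = DEFAULT_CURRENCY_METABOLITES
    else:
        excluded = frozenset(str(m).lower() for m in excluded_metabolites)
    met_by_id = {m.id: m for m in model.metabolites}
    g = nx.Graph()
    g.add_nodes_from(sorted(model.genes))
    if not model.genes:
        logger.warning("model %r has no GPR annotations; enzyme network is empty", model.id)
        return g
    genes_by_met: dict[str, set[str]] = {}
    for r in model.reactions:
        gene_set = r.gene_set
        if not gene_set:
            continue
        for a in gene_set:  # same-reaction rule (complexes, isozymes)
            for b in gene_set:
                if a < b:
                    g.add_edge(a, b)
        for mid in r.stoichiometry:
            if _is_currency(met_by_id[mid], excluded):
                continue
            genes_by_met.setdefault(mid, set()).update(gene_set)
    for members in genes_by_met.values():
        ordered = sorted(members)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                g.add_edge(a, b)
    return g


# ---------------------------------------------------------------------------
# Individual indices
# ---------------------------------------------------------------------------


def mcc_scores(g: nx.Graph) -> dict:
    """Maximal Clique Centrality: sum of (|C|-1)! over maximal cliques
    containing the node.  A node whose neighborhood has no internal edges
    only belongs to 2-cliques, so the sum reduces to its degree."""
    scores = {v: 0.0 for v in g}
    for clique in nx.find_cliques(g):
        w = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += w
    for v in g:  # isolated node: no clique of size >= 2
        if g.degree(v) == 0:
            scores[v] = 0.0
    return scores


def _max_neighborhood_component(g: nx.Graph, v) -> nx.Graph:
    """Largest connected component of the subgraph induced by N(v); ties on
    node count break toward more edges, then lexicographically smallest node
    set, so the choice is deterministic."""
    nbrs = list(g.neighbors(v))
    if not nbrs:
        return nx.Graph()
    sub = g.subgraph(nbrs)
    comps = [sub.subgraph(c) for c in nx.connected_components(sub)]
    return max(
        comps,
        key=lambda c: (c.number_of_nodes(), c.number_of_edges(), tuple(sorted(c.nodes, reverse=True))),
    )


def mnc_scores(g: nx.Graph) -> dict:
    """Maximum Neighborhood Component: order of the largest connected
    component of the open neighborhood; 0 for isolated nodes."""
    return {v: float(_max_neighborhood_component(g, v).number_of_nodes()) for v in g}


def dmnc_scores(g: nx.Graph, epsilon: float = 1.7) -> dict:
    """Density of the Maximum Neighborhood Component: |E(M)| / |V(M)|**eps;
    0 when the component is empty or a single node."""
    out = {}
    for v in g:
        m = _max_neighborhood_component(g, v)
        n = m.number_of_nodes()
        out[v] = float(m.number_of_edges()) / n**epsilon if n > 0 else 0.0
    return out


def epc_scores(
    g: nx.Graph, realizations: int = 1000, retention: float = 0.5, seed: int = 0
) -> dict:
    """Edge Percolated Component: Monte-Carlo mean, over random edge
    retentions, of the size of the component containing the node (the node
    itself always counts, so retention 1.0 gives the exact component size).
    """
    rng = np.random.default_rng(seed)
    nodes = list(g.nodes)
    edges = list(g.edges)
    totals = {v: 0.0 for v in nodes}
    for _ in range(realizations):
        if retention >= 1.0:
            kept = edges
        else:
            mask = rng.random(len(edges)) < retention
            kept = [e for e, keep in zip(edges, mask) if keep]
        h = nx.Graph()
        h.add_nodes_from(nodes)
        h.add_edges_from(kept)
        for comp in nx.connected_components(h):
            size = float(len(comp))
            for v in comp:
                totals[v] += size
    return {v: t / realizations for v, t in totals.items()}


def _bfs_tree_parents(g: nx.Graph, root) -> dict:
    """Deterministic shortest-path tree: each node takes its smallest-id
    neighbor at the previous BFS level as parent."""
    dist = {root: 0}
    queue = deque([root])
    while queue:
        u = queue.popleft()
        for w in g.neighbors(u):
            if w not in dist:
                dist[w] = dist[u] + 1
                queue.append(w)
    parent = {root: None}
    for v, d in dist.items():
        if v != root:
            parent[v] = min(w for w in g.neighbors(v) if dist.get(w) == d - 1)
    return parent


def bottleneck_scores(g: nx.Graph) -> dict:
    """BottleNeck: over one deterministic shortest-path tree per root, count
    the trees in which the node lies on more than a quarter of the
    root-to-node paths (endpoints included; the root trivially lies on all).
    Singletons root trees with no paths and contribute nothing."""
    scores = {v: 0.0 for v in g}
    for root in g:
        parent = _bfs_tree_parents(g, root)
        members = [v for v in parent if v != root]
        if not members:
            continue
        on_path = {v: 0 for v in parent}
        for w in members:
            u = w
            while u is not None:
                on_path[u] += 1
                u = parent[u]
        threshold = len(members) / 4.0
        for v, cnt in on_path.items():
            if cnt > threshold:
                scores[v] += 1.0
    return scores


def _shortest_path_counts(g: nx.Graph, source):
    """BFS distances and shortest-path counts sigma from one source."""
    dist = {source: 0}
    sigma = {source: 1}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in g.neighbors(u):
            if w not in dist:
                dist[w] = dist[u] + 1
                sigma[w] = 0
                queue.append(w)
            if dist[w] == dist[u] + 1:
                sigma[w] += sigma[u]
    return dist, sigma


def stress_scores(g: nx.Graph) -> dict:
    """Stress: number of shortest paths passing through the node as an
    interior vertex, over unordered pairs."""
    nodes = list(g.nodes)
    dist = {}
    sigma = {}
    for s in nodes:
        dist[s], sigma[s] = _shortest_path_counts(g, s)
    scores = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            if t not in dist[s]:
                continue
            d_st = dist[s][t]
            for v in nodes:
                if v in (s, t) or v not in dist[s] or v not in dist[t]:
                    continue
                if dist[s][v] + dist[t][v] == d_st:
                    scores[v] += sigma[s][v] * sigma[t][v]
    return scores


def radiality_scores(g: nx.Graph) -> dict:
    """Radiality within components: mean over reachable others of
    (component diameter + 1 - distance); 0 for singletons."""
    scores = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        n = sub.number_of_nodes()
        if n == 1:
            scores[next(iter(comp))] = 0.0
            continue
        sp = dict(nx.all_pairs_shortest_path_length(sub))
        diam = max(max(d.values()) for d in sp.values())
        for v in sub:
            scores[v] = sum(diam + 1 - d for u, d in sp[v].items() if u != v) / (n - 1)
    return scores


def eccentricity_scores(g: nx.Graph) -> dict:
    """Eccentricity within components; 0 for singletons.  Smaller is more
    central — ranking treats this index ascending."""
    scores = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if sub.number_of_nodes() == 1:
            scores[next(iter(comp))] = 0.0
        else:
            scores.update({v: float(e) for v, e in nx.eccentricity(sub).items()})
    return scores


# ---------------------------------------------------------------------------
# Table assembly, ranking, top-k flagging
# ---------------------------------------------------------------------------


@dataclass
class CentralityTable:
    """Node-by-index score matrix with deterministic per-index ranks."""

    scores: pd.DataFrame  # nodes x INDEX_COLUMNS
    ranks: pd.DataFrame  # same shape; rank 1 = most central
    config: CentralityConfig = field(default_factory=CentralityConfig)


def compute_centralities(g: nx.Graph, cfg: CentralityConfig | None = None) -> CentralityTable:
    """All twelve indices for every node, plus deterministic ranks.

    Ties rank by node id (lexicographically smaller id = better rank).  The
    EPC Monte-Carlo seed is taken from the config and recorded with the
    result.
    """
    cfg = cfg or CentralityConfig()
    if any(u == v for u, v in g.edges):
        raise ValueError("enzyme network must be simple (self-loop found)")
    nodes = sorted(g.nodes)
    data = {
        "MCC": mcc_scores(g),
        "DMNC": dmnc_scores(g, cfg.dmnc_epsilon),
        "MNC": mnc_scores(g),
        "Degree": {v: float(g.degree(v)) for v in g},
        "EPC": epc_scores(g, cfg.epc_realizations, cfg.epc_retention_probability, cfg.seed),
        "BottleNeck": bottleneck_scores(g),
        "Eccentricity": eccentricity_scores(g),
        "Closeness": nx.harmonic_centrality(g),
        "Radiality": radiality_scores(g),
        "Betweenness": nx.betweenness_centrality(g, normalized=False),
        "Stress": stress_scores(g),
        "ClusteringCoefficient": nx.clustering(g),
    }
    scores = pd.DataFrame({k: pd.Series(v) for k, v in data.items()}).reindex(nodes)[
        list(INDEX_COLUMNS)
    ]
    ranks = pd.DataFrame(index=scores.index, columns=scores.columns, dtype=int)
    for col in scores.columns:
        ranks[col] = _deterministic_ranks(scores[col], ascending=col in ASCENDING_INDICES)
    return CentralityTable(scores=scores, ranks=ranks, config=cfg)


def _deterministic_ranks(series: pd.Series, ascending: bool) -> pd.Series:
    order = sorted(
        series.index, key=lambda v: ((series[v] if ascending else -series[v]), v)
    )
    return pd.Series({v: i + 1 for i, v in enumerate(order)})


def rank_and_flag(table: CentralityTable, gene_set, k: int = 100) -> dict[str, list[str]]:
    """Per index, which members of ``gene_set`` rank in the top k.

    Returns index name -> sorted list of flagged genes.  Genes absent from
    the network are ignored (warned once).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    gene_set = set(gene_set)
    present = gene_set & set(table.scores.index)
    if gene_set and not present:
        logger.warning("designated gene set is disjoint from the network nodes")
    report = {}
    for col in table.ranks.columns:
        top = set(table.ranks.index[table.ranks[col] <= k])
        report[col] = sorted(present & top)
    return report


def write_edge_list(g: nx.Graph, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for a, b in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{a}\t{b}\n")


def write_graphml(g: nx.Graph, path: str) -> None:
    nx.write_graphml(g, path)


def write_centrality_tsv(table: CentralityTable, path: str) -> None:
    out = table.scores.copy()
    for col in table.ranks.columns:
        out[f"rank_{col}"] = table.ranks[col]
    out.to_csv(path, sep="\t", index_label="node")
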