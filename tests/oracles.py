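"""Independent oracles used to cross-check the implementation.

These deliberately avoid the code paths under test: LP results are
recomputed through cobrapy on its GLPK backend, and every centrality index
is re-derived by exhaustive enumeration (paths, cliques, neighborhood
components, edge subsets) that only touches tiny graphs.
"""

from __future__ import annotations

import itertools
import math
from collections import deque


# ---------------------------------------------------------------------------
# LP oracle: cobrapy / GLPK
# ---------------------------------------------------------------------------


def to_cobra(model):
    """Convert a valveflux MetabolicModel into a cobra Model (GLPK solver)."""
    import cobra

    cm = cobra.Model(model.id)
    cm.solver = "glpk"
    mets = {
        m.id: cobra.Metabolite(m.id, compartment=m.compartment or "c")
        for m in model.metabolites
    }
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        rxns.append(cr)
    cm.add_reactions(rxns)
    objective = {}
    for r, cr in zip(model.reactions, cm.reactions):
        cr.add_metabolites({mets[k]: v for k, v in r.stoichiometry.items()})
        if r.gpr is not None:
            cr.gene_reaction_rule = r.gpr.to_string()
        if r.objective_coefficient:
            objective[cr] = r.objective_coefficient
    cm.objective = objective
    return cm


def cobra_fba_optimum(model) -> float:
    return float(to_cobra(model).slim_optimize())


def cobra_fva(model, fraction_of_optimum: float = 1.0):
    """(min, max) flux dicts keyed by reaction id."""
    from cobra.flux_analysis import flux_variability_analysis

    frame = flux_variability_analysis(to_cobra(model), fraction_of_optimum=fraction_of_optimum)
    return frame["minimum"].to_dict(), frame["maximum"].to_dict()


# ---------------------------------------------------------------------------
# Graph oracles: exhaustive enumeration on node/edge lists
# ---------------------------------------------------------------------------


def _adj(nodes, edges):
    nbrs = {v: set() for v in nodes}
    for a, b in edges:
        nbrs[a].add(b)
        nbrs[b].add(a)
    return nbrs


def _bfs_dist(nbrs, source):
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for w in nbrs[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                q.append(w)
    return dist


def _all_shortest_paths(nbrs, s, t):
    """Enumerate all shortest s-t paths as node tuples (tiny graphs only)."""
    dist = _bfs_dist(nbrs, s)
    if t not in dist:
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(tuple(path))
            return
        for w in nbrs[u]:
            if dist.get(w) == dist[u] + 1 and dist.get(w, 10**9) <= dist[t]:
                extend(path + [w])

    extend([s])
    return [p for p in paths if len(p) - 1 == dist[t]]


def brute_degree(nodes, edges):
    nbrs = _adj(nodes, edges)
    return {v: float(len(nbrs[v])) for v in nodes}


def brute_clustering(nodes, edges):
    nbrs = _adj(nodes, edges)
    out = {}
    for v in nodes:
        k = len(nbrs[v])
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(1 for a, b in itertools.combinations(sorted(nbrs[v]), 2) if b in nbrs[a])
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def brute_betweenness_stress(nodes, edges):
    """(betweenness, stress) by full shortest-path enumeration."""
    nbrs = _adj(nodes, edges)
    bet = {v: 0.0 for v in nodes}
    stress = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(sorted(nodes), 2):
        paths = _all_shortest_paths(nbrs, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            stress[v] += through
            bet[v] += through / len(paths)
    return bet, stress


def brute_eccentricity(nodes, edges):
    nbrs = _adj(nodes, edges)
    out = {}
    for v in nodes:
        dist = _bfs_dist(nbrs, v)
        out[v] = float(max(dist.values())) if len(dist) > 1 else 0.0
    return out


def brute_closeness_harmonic(nodes, edges):
    nbrs = _adj(nodes, edges)
    out = {}
    for v in nodes:
        dist = _bfs_dist(nbrs, v)
        out[v] = sum(1.0 / d for u, d in dist.items() if u != v)
    return out


def brute_radiality(nodes, edges):
    nbrs = _adj(nodes, edges)
    comps = []
    seen = set()
    for v in nodes:
        if v in seen:
            continue
        comp = set(_bfs_dist(nbrs, v))
        seen |= comp
        comps.append(comp)
    out = {}
    for comp in comps:
        if len(comp) == 1:
            out[next(iter(comp))] = 0.0
            continue
        dists = {v: _bfs_dist(nbrs, v) for v in comp}
        diam = max(max(d.values()) for d in dists.values())
        for v in comp:
            out[v] = sum(diam + 1 - d for u, d in dists[v].items() if u != v) / (len(comp) - 1)
    return out


def brute_mcc(nodes, edges):
    """Maximal cliques by subset enumeration (n <= ~10)."""
    nbrs = _adj(nodes, edges)
    node_list = sorted(nodes)
    cliques = []
    for r in range(1, len(node_list) + 1):
        for sub in itertools.combinations(node_list, r):
            if all(b in nbrs[a] for a, b in itertools.combinations(sub, 2)):
                cliques.append(set(sub))
    maximal = [
        c for c in cliques if not any(c < other for other in cliques)
    ]
    out = {v: 0.0 for v in nodes}
    for c in maximal:
        if len(c) < 2:
            continue
        w = math.factorial(len(c) - 1)
        for v in c:
            out[v] += w
    return out


def _neighborhood_components(nbrs, v):
    hood = nbrs[v]
    comps = []
    seen = set()
    for u in sorted(hood):
        if u in seen:
            continue
        comp = set()
        q = deque([u])
        while q:
            a = q.popleft()
            if a in comp:
                continue
            comp.add(a)
            for b in nbrs[a]:
                if b in hood and b not in comp:
                    q.append(b)
        seen |= comp
        comps.append(comp)
    return comps


def brute_mnc_dmnc(nodes, edges, epsilon=1.7):
    nbrs = _adj(nodes, edges)
    mnc, dmnc = {}, {}
    for v in nodes:
        comps = _neighborhood_components(nbrs, v)
        if not comps:
            mnc[v], dmnc[v] = 0.0, 0.0
            continue
        def n_edges(comp):
            return sum(1 for a, b in itertools.combinations(sorted(comp), 2) if b in nbrs[a])
        best = max(comps, key=lambda c: (len(c), n_edges(c), tuple(sorted(c, reverse=True))))
        mnc[v] = float(len(best))
        dmnc[v] = n_edges(best) / len(best) ** epsilon
    return mnc, dmnc


def brute_epc_exact(nodes, edges, retention=0.5):
    """Exact expected percolated-component size by edge-subset enumeration
    (requires few edges; 2^|E| subsets)."""
    edges = list(edges)
    out = {v: 0.0 for v in nodes}
    for kept_mask in itertools.product([0, 1], repeat=len(edges)):
        p = 1.0
        kept = []
        for bit, e in zip(kept_mask, edges):
            p *= retention if bit else (1 - retention)
            if bit:
                kept.append(e)
        nbrs = _adj(nodes, kept)
        for v in nodes:
            out[v] += p * len(_bfs_dist(nbrs, v))
    return out


def brute_bottleneck(nodes, edges):
    """Deterministic shortest-path trees (smallest-id parent), counting
    trees where the node covers more than a quarter of root-to-node paths."""
    nbrs = _adj(nodes, edges)
    scores = {v: 0.0 for v in nodes}
    for root in sorted(nodes):
        dist = _bfs_dist(nbrs, root)
        parent = {root: None}
        for v in sorted(dist):
            if v == root:
                continue
            parent[v] = min(u for u in nbrs[v] if dist.get(u) == dist[v] - 1)
        members = [v for v in parent if v != root]
        if not members:
            continue
        counts = {v: 0 for v in parent}
        for w in members:
            u = w
            while u is not None:
                counts[u] += 1
                u = parent[u]
        for v, cnt in counts.items():
            if cnt > len(members) / 4.0:
                scores[v] += 1.0
    return scores
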