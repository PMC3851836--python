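"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written against the *definitions* (exhaustive
enumeration, dynamic programming on BFS levels, closed-form combinatorics)
rather than reusing the package's own algorithms, so agreement is evidence of
correctness rather than tautology.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np

from tfmirnet.library import NodeType
from tfmirnet.network import RegulatoryNetwork

# ---------------------------------------------------------------------------
# typed triad enumeration (independent of tfmirnet.topology)
# ---------------------------------------------------------------------------

_LEGAL_PAIRS = {
    ("TF", "gene"), ("TF", "TF"), ("TF", "miRNA"),
    ("miRNA", "gene"), ("miRNA", "TF"),
}


def _iso_key(types, adj):
    """Max-encoding canonical key over all vertex permutations (adjacency bits)."""
    best = None
    for perm in itertools.permutations(range(3)):
        t = tuple(types[perm.index(i)] for i in range(3))
        bits = tuple(
            adj[perm.index(i)][perm.index(j)]
            for i in range(3) for j in range(3) if i != j
        )
        key = (t, bits)
        if best is None or key > best:
            best = key
    return best


def brute_force_triad_catalog() -> dict[tuple[str, ...], set]:
    """All typed closed triads with >=1 TF and >=1 miRNA, by composition.

    Enumerates every 6-bit directed-edge configuration on 3 typed vertices,
    keeps those where all edges are type-legal and every vertex pair is
    joined, and deduplicates by a permutation-canonical adjacency encoding.
    """
    out: dict[tuple[str, ...], set] = {}
    for types in itertools.product(["TF", "miRNA", "gene"], repeat=3):
        if types.count("TF") < 1 or types.count("miRNA") < 1:
            continue
        comp = tuple(sorted(types))
        bucket = out.setdefault(comp, set())
        for bits in itertools.product([0, 1], repeat=6):
            adj = [[0] * 3 for _ in range(3)]
            k = 0
            for i in range(3):
                for j in range(3):
                    if i != j:
                        adj[i][j] = bits[k]
                        k += 1
            ok = True
            for i in range(3):
                for j in range(3):
                    if i != j and adj[i][j] and (types[i], types[j]) not in _LEGAL_PAIRS:
                        ok = False
            if not ok:
                continue
            if not all(
                adj[i][j] or adj[j][i] for i, j in [(0, 1), (0, 2), (1, 2)]
            ):
                continue
            bucket.add(_iso_key(types, adj))
    return {k: v for k, v in out.items() if v}


def brute_force_triad_count(network: RegulatoryNetwork) -> dict:
    """Motif counts by exhaustive iteration over all C(n,3) vertex triples.

    Returns a dict canonical-adjacency-key -> count, using the same key
    encoding as :func:`brute_force_triad_catalog`.
    """
    g = network.graph
    nodes = sorted(g.nodes)
    counts: dict = {}
    for u, v, w in itertools.combinations(nodes, 3):
        trip = (u, v, w)
        pairs_joined = all(
            g.has_edge(a, b) or g.has_edge(b, a)
            for a, b in itertools.combinations(trip, 2)
        )
        if not pairs_joined:
            continue
        types = tuple(network.node_type(x).value for x in trip)
        if types.count("TF") < 1 or types.count("miRNA") < 1:
            continue
        adj = [
            [1 if i != j and g.has_edge(trip[i], trip[j]) else 0 for j in range(3)]
            for i in range(3)
        ]
        key = _iso_key(types, adj)
        counts[key] = counts.get(key, 0) + 1
    return counts


def triad_key_of_motif(motif) -> tuple:
    """Map a package MotifType onto the oracle's canonical key."""
    types = tuple(motif.vertex_types)
    adj = [[0] * 3 for _ in range(3)]
    for u, v in motif.edges:
        adj[u][v] = 1
    return _iso_key(types, adj)


# ---------------------------------------------------------------------------
# betweenness by explicit shortest-path counting
# ---------------------------------------------------------------------------

def _bfs_counts(adj: dict, source):
    dist = {source: 0}
    sigma = {source: 1}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                sigma[v] = 0
                q.append(v)
            if dist[v] == dist[u] + 1:
                sigma[v] += sigma[u]
    return dist, sigma


def brute_force_betweenness(network: RegulatoryNetwork):
    """Directed unweighted vertex and edge betweenness via all-pairs DP.

    For every ordered pair (s, t), each intermediate vertex v contributes
    sigma_sv * sigma_vt / sigma_st when d(s,v) + d(v,t) = d(s,t); an edge
    (u, v) contributes sigma_su * sigma_vt / sigma_st when
    d(s,u) + 1 + d(v,t) = d(s,t).
    """
    g = network.graph
    nodes = sorted(g.nodes)
    adj = {n: sorted(g.successors(n)) for n in nodes}
    dist = {}
    sigma = {}
    for s in nodes:
        dist[s], sigma[s] = _bfs_counts(adj, s)
    vb = {n: 0.0 for n in nodes}
    eb = {(u, v): 0.0 for u in nodes for v in adj[u]}
    for s in nodes:
        for t in nodes:
            if s == t or t not in dist[s]:
                continue
            d_st = dist[s][t]
            s_st = sigma[s][t]
            for v in nodes:
                if v in (s, t) or v not in dist[s] or t not in dist[v]:
                    continue
                if dist[s][v] + dist[v][t] == d_st:
                    vb[v] += sigma[s][v] * sigma[v][t] / s_st
            for (u, v) in eb:
                if u not in dist[s] or t not in dist[v]:
                    continue
                if dist[s][u] + 1 + dist[v][t] == d_st:
                    eb[(u, v)] += sigma[s][u] * sigma[v][t] / s_st
    return vb, eb


# ---------------------------------------------------------------------------
# one-sided two-sample K-S permutation oracle
# ---------------------------------------------------------------------------

def ks_permutation_pvalue(
    targets: np.ndarray, nontargets: np.ndarray, n_perm: int, seed: int
) -> float:
    """Monte-Carlo label-permutation p for D+ = sup(ECDF_t - ECDF_nt).

    Vectorised over permutations: pooled values are sorted once; for each
    permutation the running difference of group ECDFs over the sorted pool is
    a cumulative sum of +-1/n steps.
    """
    t = np.asarray(targets, float)
    nt = np.asarray(nontargets, float)
    n, m = len(t), len(nt)
    pooled = np.concatenate([t, nt])
    order = np.argsort(pooled, kind="mergesort")
    # observed statistic
    labels = np.zeros(n + m, dtype=bool)
    labels[:n] = True
    obs = _dplus_sorted(labels[order], n, m)
    rng = np.random.default_rng(seed)
    count = 0
    batch = 2000
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        # permute labels: one permutation per row
        lab = np.tile(labels[order], (b, 1))
        idx = rng.permuted(np.tile(np.arange(n + m), (b, 1)), axis=1)
        lab = np.take_along_axis(lab, idx, axis=1)
        steps = np.where(lab, 1.0 / n, -1.0 / m)
        dplus = np.maximum(np.cumsum(steps, axis=1).max(axis=1), 0.0)
        count += int((dplus >= obs - 1e-12).sum())
        done += b
    return (1 + count) / (1 + n_perm)


def _dplus_sorted(labels_sorted: np.ndarray, n: int, m: int) -> float:
    steps = np.where(labels_sorted, 1.0 / n, -1.0 / m)
    return max(float(np.cumsum(steps).max()), 0.0)


# ---------------------------------------------------------------------------
# exhaustive best-subset AIC (stepwise oracle)
# ---------------------------------------------------------------------------

def best_subset_aic(y: np.ndarray, X, candidates: list[str]):
    """Exhaustive best-subset-by-AIC over all 2^k candidate subsets.

    AIC computed the same way as the definition used for model comparison:
    n*log(RSS/n) + 2*(p+1) with an intercept always included.  Returns the
    winning subset (as a frozenset) and its AIC; ties broken toward smaller
    subsets then lexicographic order.
    """
    y = np.asarray(y, float)
    n = len(y)
    best = None
    for r in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, r):
            M = np.column_stack([np.ones(n)] + [np.asarray(X[c], float) for c in subset])
            if np.linalg.matrix_rank(M) < M.shape[1]:
                continue
            beta, _, _, _ = np.linalg.lstsq(M, y, rcond=None)
            resid = y - M @ beta
            rss = float(resid @ resid)
            aic = n * math.log(max(rss, 1e-300) / n) + 2 * M.shape[1]
            key = (aic, len(subset), subset)
            if best is None or key < best:
                best = key
    return frozenset(best[2]), best[0]


# ---------------------------------------------------------------------------
# random valid typed networks for fuzzing
# ---------------------------------------------------------------------------

def random_typed_network(
    rng: np.random.Generator,
    n_tf: int = 10,
    n_mir: int = 8,
    n_gene: int = 12,
    p_edge: float = 0.15,
) -> RegulatoryNetwork:
    """A random network drawing each type-legal ordered pair independently."""
    net = RegulatoryNetwork()
    tfs = [f"T{i}" for i in range(n_tf)]
    mirs = [f"hsa-miR-{200 + i}" for i in range(n_mir)]
    genes = [f"g{i}" for i in range(n_gene)]
    for x in tfs:
        net.add_node(x, NodeType.TF)
    for x in mirs:
        net.add_node(x, NodeType.MIRNA)
    for x in genes:
        net.add_node(x, NodeType.GENE)
    for src in tfs:
        for tgt in tfs + genes + mirs:
            if src != tgt and rng.random() < p_edge:
                net.add_edge(src, tgt)
    for src in mirs:
        for tgt in tfs + genes:
            if rng.random() < p_edge:
                net.add_edge(src, tgt)
    return net
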