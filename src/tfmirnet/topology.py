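"""Topological analysis of combinatorial regulatory networks.

Three analyses run on an inferred :class:`~tfmirnet.network.RegulatoryNetwork`:

* **vertex / edge ranking** by total degree and by betweenness (directed,
  unweighted shortest paths, path-count-normalised contributions);
* **co-regulating regulator pairs**: for every pair of regulators, a one-sided
  Fisher's exact test of target-set overlap over the universe of regulated
  nodes (hypergeometric enrichment of shared targets);
* **typed triple-vertex motifs**: all closed three-vertex circuits (every
  vertex pair joined by at least one directed edge) containing at least one
  TF and one miRNA.  Under the edge-type rules exactly 18 such motif types
  exist — 3 on the {TF, miRNA, gene} composition and 15 on {TF, TF, miRNA} —
  each a feed-forward loop (FFL, acyclic) or a feed-backward loop (FBL,
  containing a directed cycle).  Observed motif counts are compared against
  degree-preserving randomised networks to obtain empirical p-values.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .library import EdgeClass, NodeType
from .network import RegulatoryNetwork, legal_edge_class

logger = logging.getLogger(__name__)

__all__ = [
    "MotifType",
    "MotifCatalog",
    "TopologyRanks",
    "rank_vertices_edges",
    "coregulating_pairs",
    "enumerate_motif_types",
    "count_motif_instances",
    "shuffle_network",
    "motif_pvalues",
]


# ---------------------------------------------------------------------------
# motif catalog
# ---------------------------------------------------------------------------

def _canonical_form(
    types: Sequence[NodeType], edges: Iterable[tuple[int, int]]
) -> tuple[tuple[str, ...], tuple[tuple[int, int], ...]]:
    """Canonical (types, edges) labelling of a typed 3-vertex digraph.

    Minimises over all six vertex relabellings, so two triads are isomorphic
    (respecting vertex types) iff their canonical forms are equal.
    """
    edges = list(edges)
    best = None
    for perm in itertools.permutations(range(3)):
        new_types = [None, None, None]
        for i in range(3):
            new_types[perm[i]] = types[i].value
        new_edges = tuple(sorted((perm[u], perm[v]) for u, v in edges))
        key = (tuple(new_types), new_edges)
        if best is None or key < best:
            best = key
    return best  # type: ignore[return-value]


def _code(types: tuple[str, ...], edges: tuple[tuple[int, int], ...]) -> str:
    return "|".join(types) + "||" + ";".join(f"{u}>{v}" for u, v in edges)


def _has_cycle(edges: set[tuple[int, int]]) -> bool:
    for u, v in edges:
        if (v, u) in edges:
            return True
    for a, b, c in itertools.permutations(range(3)):
        if (a, b) in edges and (b, c) in edges and (c, a) in edges:
            return True
    return False


@dataclass(frozen=True)
class MotifType:
    """One typed three-vertex closed-circuit motif, up to isomorphism."""

    canonical_code: str
    vertex_types: tuple[str, ...]           # canonical per-position types
    edges: tuple[tuple[int, int], ...]      # canonical directed edges
    loop_class: str                         # "FFL" (acyclic) or "FBL" (cyclic)

    @property
    def composition(self) -> tuple[str, ...]:
        return tuple(sorted(self.vertex_types))


class MotifCatalog:
    """The complete catalog of typed triple-vertex motifs."""

    def __init__(self, motifs: list[MotifType]):
        self.motifs = sorted(motifs, key=lambda m: (m.composition, m.canonical_code))
        self._by_code = {m.canonical_code: m for m in self.motifs}

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __getitem__(self, code: str) -> MotifType:
        return self._by_code[code]

    def by_composition(self) -> dict[tuple[str, ...], list[MotifType]]:
        out: dict[tuple[str, ...], list[MotifType]] = {}
        for m in self.motifs:
            out.setdefault(m.composition, []).append(m)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "motif": [m.canonical_code for m in self.motifs],
                "composition": ["+".join(m.composition) for m in self.motifs],
                "loop_class": [m.loop_class for m in self.motifs],
                "n_edges": [len(m.edges) for m in self.motifs],
            }
        )


def enumerate_motif_types() -> MotifCatalog:
    """Exhaustively enumerate the typed triple-vertex closed-circuit motifs.

    A motif is a 3-vertex digraph in which every vertex pair is joined by at
    least one directed edge (mutual edges allowed where both directions are
    type-legal), all edges obey the regulation type rules, and the vertex
    composition contains at least one TF and at least one miRNA.  Motifs are
    deduplicated by canonical form.  The resulting catalog has exactly 18
    entries: 3 for composition {TF, miRNA, gene} and 15 for {TF, TF, miRNA}.
    """
    found: dict[str, MotifType] = {}
    for types in itertools.product(list(NodeType), repeat=3):
        counts = {t: sum(1 for x in types if x is t) for t in NodeType}
        if counts[NodeType.TF] < 1 or counts[NodeType.MIRNA] < 1:
            continue
        pairs = [(0, 1), (0, 2), (1, 2)]
        pair_options: list[list[tuple[tuple[int, int], ...]]] = []
        feasible = True
        for i, j in pairs:
            fwd_ok = legal_edge_class(types[i], types[j]) is not None
            rev_ok = legal_edge_class(types[j], types[i]) is not None
            opts: list[tuple[tuple[int, int], ...]] = []
            if fwd_ok:
                opts.append(((i, j),))
            if rev_ok:
                opts.append(((j, i),))
            if fwd_ok and rev_ok:
                opts.append(((i, j), (j, i)))
            if not opts:
                feasible = False
                break
            pair_options.append(opts)
        if not feasible:
            continue
        for combo in itertools.product(*pair_options):
            edges = set(itertools.chain.from_iterable(combo))
            ctypes, cedges = _canonical_form(types, edges)
            code = _code(ctypes, cedges)
            if code not in found:
                found[code] = MotifType(
                    canonical_code=code,
                    vertex_types=ctypes,
                    edges=cedges,
                    loop_class="FBL" if _has_cycle(edges) else "FFL",
                )
    return MotifCatalog(list(found.values()))


# ---------------------------------------------------------------------------
# motif counting
# ---------------------------------------------------------------------------

def count_motif_instances(
    network: RegulatoryNetwork, catalog: MotifCatalog | None = None
) -> tuple[dict[str, int], pd.DataFrame]:
    """Count every triple-vertex motif instance in the network.

    Each unordered vertex triple whose three pairs are all joined by at least
    one directed edge is classified by the canonical form of its induced
    typed subgraph; triples without both a TF and a miRNA are ignored.

    Returns ``(counts, instances)`` where ``counts`` maps every catalog code
    (including absent ones) to its occurrence count and ``instances`` lists
    one row per (motif, vertex triple).
    """
    if catalog is None:
        catalog = enumerate_motif_types()
    counts = {m.canonical_code: 0 for m in catalog}
    rows: list[tuple[str, str, str, str]] = []
    g = network.graph
    und = g.to_undirected(as_view=False)
    nodes = sorted(und.nodes)
    pos = {n: i for i, n in enumerate(nodes)}
    adj = {n: {x for x in und.neighbors(n) if pos[x] > pos[n]} for n in nodes}
    for u in nodes:
        for v in sorted(adj[u]):
            common = adj[u] & adj[v]
            for w in sorted(common):
                triple = (u, v, w)
                types = tuple(network.node_type(x) for x in triple)
                tvals = [t.value for t in types]
                if NodeType.TF.value not in tvals or NodeType.MIRNA.value not in tvals:
                    continue
                edges = [
                    (i, j)
                    for i in range(3)
                    for j in range(3)
                    if i != j and g.has_edge(triple[i], triple[j])
                ]
                ctypes, cedges = _canonical_form(types, edges)
                code = _code(ctypes, cedges)
                if code not in counts:  # cannot happen for a valid network
                    raise ValueError(f"induced triad {triple} not in the motif catalog")
                counts[code] += 1
                rows.append((code, *triple))
    instances = pd.DataFrame(rows, columns=["motif", "vertex_1", "vertex_2", "vertex_3"])
    instances = instances.sort_values(
        ["motif", "vertex_1", "vertex_2", "vertex_3"], kind="mergesort"
    ).reset_index(drop=True)
    return counts, instances


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

@dataclass
class TopologyRanks:
    """Vertex and edge importance rankings."""

    vertex_degree: pd.DataFrame       # node, type, in_degree, out_degree, degree
    vertex_betweenness: pd.DataFrame  # node, type, betweenness
    edge_betweenness: pd.DataFrame    # source, target, edge_type, betweenness


def rank_vertices_edges(network: RegulatoryNetwork) -> TopologyRanks:
    """Rank vertices by total degree and vertices/edges by betweenness.

    Betweenness is computed on the directed graph with unweighted shortest
    paths; each (source, target) pair contributes the fraction of its
    shortest paths passing through the vertex/edge (no global rescaling by
    the number of pairs).  Ties are broken by identifier.
    """
    if network.number_of_nodes == 0:
        raise ValueError("empty network")
    g = network.graph
    deg = pd.DataFrame(
        {
            "node": list(g.nodes),
            "type": [network.node_type(n).value for n in g.nodes],
            "in_degree": [g.in_degree(n) for n in g.nodes],
            "out_degree": [g.out_degree(n) for n in g.nodes],
        }
    )
    deg["degree"] = deg["in_degree"] + deg["out_degree"]
    deg = deg.sort_values(["degree", "node"], ascending=[False, True], kind="mergesort")
    deg = deg.reset_index(drop=True)

    vb = nx.betweenness_centrality(g, normalized=False)
    vbet = pd.DataFrame(
        {
            "node": list(vb),
            "type": [network.node_type(n).value for n in vb],
            "betweenness": [vb[n] for n in vb],
        }
    ).sort_values(["betweenness", "node"], ascending=[False, True], kind="mergesort")
    vbet = vbet.reset_index(drop=True)

    eb = nx.edge_betweenness_centrality(g, normalized=False)
    ebet = pd.DataFrame(
        {
            "source": [u for u, _ in eb],
            "target": [v for _, v in eb],
            "edge_type": [g.edges[u, v]["edge_class"].value for u, v in eb],
            "betweenness": list(eb.values()),
        }
    ).sort_values(
        ["betweenness", "source", "target"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    return TopologyRanks(deg, vbet, ebet)


# ---------------------------------------------------------------------------
# co-regulating pairs
# ---------------------------------------------------------------------------

def coregulating_pairs(network: RegulatoryNetwork, alpha: float = 0.01) -> pd.DataFrame:
    """One-sided Fisher's exact test of shared targets for every regulator pair.

    The universe is the set of regulated nodes (in-degree >= 1).  For
    regulators A and B the 2x2 table splits the universe by membership of
    targets(A) and targets(B); the one-sided (enrichment) p is the
    hypergeometric upper tail of the shared-target count.

    Returns every pair sorted by ascending p (ties by identifiers) with a
    boolean ``significant`` column marking ``p < alpha``.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    g = network.graph
    regulators = sorted(n for n in g.nodes if g.out_degree(n) >= 1)
    if len(regulators) < 2:
        raise ValueError("need at least two regulators (out-degree >= 1)")
    universe = {n for n in g.nodes if g.in_degree(n) >= 1}
    n_universe = len(universe)
    targets = {r: set(g.successors(r)) & universe for r in regulators}
    rows = []
    for a, b in itertools.combinations(regulators, 2):
        ta, tb = targets[a], targets[b]
        shared = len(ta & tb)
        only_a = len(ta) - shared
        only_b = len(tb) - shared
        neither = n_universe - shared - only_a - only_b
        _, p = stats.fisher_exact(
            [[shared, only_a], [only_b, neither]], alternative="greater"
        )
        rows.append((a, b, shared, only_a, only_b, neither, float(p)))
    df = pd.DataFrame(
        rows,
        columns=[
            "regulator_a",
            "regulator_b",
            "shared_targets",
            "a_only",
            "b_only",
            "neither",
            "p_value",
        ],
    )
    df["significant"] = df["p_value"] < alpha
    return df.sort_values(
        ["p_value", "regulator_a", "regulator_b"], kind="mergesort"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# null model and motif significance
# ---------------------------------------------------------------------------

def shuffle_network(
    network: RegulatoryNetwork,
    rng: np.random.Generator,
    swap_factor: int = 10,
) -> RegulatoryNetwork:
    """Degree-preserving randomisation by double edge swaps within each class.

    For each regulation class, pairs of edges (a->b, c->d) are repeatedly
    rewired to (a->d, c->b) — ``swap_factor * n_edges`` attempts — rejecting
    swaps that would create a self-loop or a duplicate ordered pair.  Every
    node's typed in/out degree and each class's edge count are preserved
    exactly.  Classes with fewer than two edges are left unshuffled with a
    warning.  Edge weights are not carried into the null networks.
    """
    by_class: dict[EdgeClass, list[tuple[str, str]]] = {c: [] for c in EdgeClass}
    for e in network.edges():
        by_class[e.edge_class].append((e.source, e.target))
    pair_set = {(u, v) for pairs in by_class.values() for (u, v) in pairs}

    for cls_, edges in by_class.items():
        n = len(edges)
        if n == 0:
            continue
        if n < 2:
            logger.warning("shuffle: %s has < 2 edges; left unshuffled", cls_.value)
            continue
        attempts = swap_factor * n
        idx_pairs = rng.integers(0, n, size=(attempts, 2))
        for i, j in idx_pairs:
            if i == j:
                continue
            a, b = edges[i]
            c, d = edges[j]
            if a == c or b == d:
                continue
            if a == d or c == b:
                continue
            if (a, d) in pair_set or (c, b) in pair_set:
                continue
            pair_set.discard((a, b))
            pair_set.discard((c, d))
            pair_set.add((a, d))
            pair_set.add((c, b))
            edges[i] = (a, d)
            edges[j] = (c, b)

    node_types = {n: network.node_type(n) for n in network.graph.nodes}
    out = RegulatoryNetwork()
    for node, ntype in node_types.items():
        out.add_node(node, ntype)
    for cls_, edges in by_class.items():
        for u, v in edges:
            out.add_edge(u, v)
    return out


def motif_pvalues(
    network: RegulatoryNetwork,
    replicates: int = 1000,
    seed: int | None = None,
    swap_factor: int = 10,
    catalog: MotifCatalog | None = None,
) -> pd.DataFrame:
    """Empirical motif enrichment against the degree-preserving null model.

    For each of the 18 catalog motif types, the observed instance count is
    compared with its counts over ``replicates`` shuffled networks; the
    upper-tail empirical p is ``(1 + #{null >= observed}) / (1 + replicates)``.

    Returns one row per catalog motif: observed count, null mean/sd and p,
    ordered as in the catalog.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if catalog is None:
        catalog = enumerate_motif_types()
    rng = np.random.default_rng(seed)
    observed, _ = count_motif_instances(network, catalog)
    codes = [m.canonical_code for m in catalog]
    null = np.zeros((replicates, len(codes)), dtype=int)
    for r in range(replicates):
        shuffled = shuffle_network(network, rng, swap_factor=swap_factor)
        counts, _ = count_motif_instances(shuffled, catalog)
        null[r] = [counts[c] for c in codes]
    obs = np.array([observed[c] for c in codes])
    p = (1.0 + (null >= obs[None, :]).sum(axis=0)) / (1.0 + replicates)
    return pd.DataFrame(
        {
            "motif": codes,
            "composition": ["+".join(m.composition) for m in catalog],
            "loop_class": [m.loop_class for m in catalog],
            "observed": obs,
            "null_mean": null.mean(axis=0),
            "null_sd": null.std(axis=0),
            "p_value": p,
        }
    )
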