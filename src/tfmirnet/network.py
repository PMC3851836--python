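"""Typed directed regulatory networks.

A :class:`RegulatoryNetwork` is a directed graph whose nodes are typed
(TF / miRNA / gene) and whose edges belong to one of the three regulation
classes.  The admissible edges are

====================  =============  ==========
source type           target type    edge class
====================  =============  ==========
TF                    gene or TF     TF2gene
TF                    miRNA          TF2miR
miRNA                 gene or TF     miR2gene
====================  =============  ==========

gene nodes have no outgoing edges and miRNA->miRNA edges never occur.  Edges
may carry a regression coefficient (``weight``) and a p-value.  The class is
a thin façade over :class:`networkx.DiGraph` (exposed as ``.graph``) so all
networkx algorithms remain available.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import networkx as nx
import pandas as pd

from .library import EdgeClass, NodeType, RegulationLibrary

__all__ = ["RegulatoryNetwork", "TypedEdge", "legal_edge_class", "merge_reference_network"]

_LEGAL: dict[tuple[NodeType, NodeType], EdgeClass] = {
    (NodeType.TF, NodeType.GENE): EdgeClass.TF2GENE,
    (NodeType.TF, NodeType.TF): EdgeClass.TF2GENE,
    (NodeType.TF, NodeType.MIRNA): EdgeClass.TF2MIR,
    (NodeType.MIRNA, NodeType.GENE): EdgeClass.MIR2GENE,
    (NodeType.MIRNA, NodeType.TF): EdgeClass.MIR2GENE,
}


def legal_edge_class(source_type: NodeType, target_type: NodeType) -> EdgeClass | None:
    """The regulation class joining two node types, or None if forbidden."""
    return _LEGAL.get((source_type, target_type))


class TypedEdge(NamedTuple):
    source: str
    target: str
    edge_class: EdgeClass
    weight: float | None
    p_value: float | None


class RegulatoryNetwork:
    """Directed TF/miRNA/gene graph with class-typed, optionally weighted edges."""

    def __init__(self) -> None:
        self.graph = nx.DiGraph()

    # -- construction -------------------------------------------------------
    def add_node(self, node_id: str, ntype: NodeType) -> None:
        ntype = NodeType(ntype)
        existing = self.graph.nodes.get(node_id, {}).get("ntype")
        if existing is not None and existing is not ntype:
            raise ValueError(f"node {node_id!r} typed both {existing.value} and {ntype.value}")
        self.graph.add_node(node_id, ntype=ntype)

    def add_edge(
        self,
        source: str,
        target: str,
        *,
        weight: float | None = None,
        p_value: float | None = None,
    ) -> None:
        """Add a typed edge; both endpoints must already be typed nodes."""
        if source == target:
            raise ValueError(f"self-loop on {source!r} not allowed")
        for node in (source, target):
            if node not in self.graph or "ntype" not in self.graph.nodes[node]:
                raise ValueError(f"untyped node {node!r}; call add_node first")
        cls = legal_edge_class(self.node_type(source), self.node_type(target))
        if cls is None:
            raise ValueError(
                f"forbidden edge {source!r}({self.node_type(source).value}) -> "
                f"{target!r}({self.node_type(target).value})"
            )
        if self.graph.has_edge(source, target):
            # at most one edge per ordered pair; identical re-insertion is a no-op
            old = self.graph.edges[source, target]
            if old.get("weight") != weight or old.get("p_value") != p_value:
                raise ValueError(f"duplicate edge {source!r}->{target!r} with conflicting attributes")
            return
        self.graph.add_edge(source, target, edge_class=cls, weight=weight, p_value=p_value)

    # -- inspection ----------------------------------------------------------
    def node_type(self, node_id: str) -> NodeType:
        return self.graph.nodes[node_id]["ntype"]

    def nodes_of_type(self, ntype: NodeType) -> tuple[str, ...]:
        return tuple(sorted(n for n, d in self.graph.nodes(data=True) if d["ntype"] is ntype))

    @property
    def node_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.graph.nodes))

    def edges(self) -> Iterator[TypedEdge]:
        for u, v, d in sorted(self.graph.edges(data=True)):
            yield TypedEdge(u, v, d["edge_class"], d.get("weight"), d.get("p_value"))

    @property
    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def validate(self) -> None:
        """Re-check every structural invariant; raises on violation."""
        for u, v, d in self.graph.edges(data=True):
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            cls = legal_edge_class(self.node_type(u), self.node_type(v))
            if cls is None or cls is not d["edge_class"]:
                raise ValueError(f"edge {u!r}->{v!r} violates type rules")

    def __repr__(self) -> str:
        return (
            f"RegulatoryNetwork({self.number_of_nodes} nodes, "
            f"{self.number_of_edges} edges)"
        )

    def copy(self) -> "RegulatoryNetwork":
        out = RegulatoryNetwork()
        out.graph = self.graph.copy()
        return out

    # -- tabular / file interchange -----------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "source": e.source,
                "target": e.target,
                "edge_type": e.edge_class.value,
                "weight": e.weight,
                "p_value": e.p_value,
            }
            for e in self.edges()
        ]
        return pd.DataFrame(rows, columns=["source", "target", "edge_type", "weight", "p_value"])

    def write_edge_list(self, path: str | Path, *, include_p_values: bool = False) -> None:
        """Write a tab-delimited edge list (source, target, edge_type, weight[, p_value])."""
        df = self.to_frame()
        if not include_p_values:
            df = df.drop(columns=["p_value"])
        df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")

    @classmethod
    def read_edge_list(cls, path: str | Path) -> "RegulatoryNetwork":
        """Load a network from an edge list written by :meth:`write_edge_list`.

        Node types are reconstructed from edge roles: sources of TF-class
        edges are TFs, miRNAs are sources of miR2gene or targets of TF2miR
        edges, and every remaining identifier is a plain gene.
        """
        df = pd.read_csv(path, sep="\t", comment=None)
        required = {"source", "target", "edge_type"}
        if not required.issubset(df.columns):
            raise ValueError(f"{path}: edge list needs columns {sorted(required)}")
        records = []
        for row in df.itertuples(index=False):
            cls_ = EdgeClass(row.edge_type)
            weight = getattr(row, "weight", None)
            pval = getattr(row, "p_value", None)
            weight = None if weight is None or (isinstance(weight, float) and math.isnan(weight)) else float(weight)
            pval = None if pval is None or (isinstance(pval, float) and math.isnan(pval)) else float(pval)
            records.append((str(row.source), str(row.target), cls_, weight, pval))
        tf_ids = {r[0] for r in records if r[2] in (EdgeClass.TF2GENE, EdgeClass.TF2MIR)}
        mir_ids = {r[0] for r in records if r[2] is EdgeClass.MIR2GENE}
        mir_ids |= {r[1] for r in records if r[2] is EdgeClass.TF2MIR}
        collision = tf_ids & mir_ids
        if collision:
            raise ValueError(f"{path}: identifiers typed both TF and miRNA: {sorted(collision)}")
        net = cls()
        for src, tgt, cls_, weight, pval in records:
            for node in (src, tgt):
                if node in tf_ids:
                    net.add_node(node, NodeType.TF)
                elif node in mir_ids:
                    net.add_node(node, NodeType.MIRNA)
                else:
                    net.add_node(node, NodeType.GENE)
            net.add_edge(src, tgt, weight=weight, p_value=pval)
        return net

    @classmethod
    def from_typed_edges(
        cls,
        node_types: dict[str, NodeType],
        edges: Iterable[tuple[str, str, float | None, float | None]],
    ) -> "RegulatoryNetwork":
        """Build a network from an explicit node-typing map and (src, tgt, w, p) rows."""
        net = cls()
        for node, ntype in node_types.items():
            net.add_node(node, ntype)
        for src, tgt, weight, pval in edges:
            net.add_edge(src, tgt, weight=weight, p_value=pval)
        return net


def merge_reference_network(
    tf2gene: RegulationLibrary,
    tf2mir: RegulationLibrary,
    mir2gene: RegulationLibrary,
) -> RegulatoryNetwork:
    """Union of the three putative-regulation libraries as one typed graph.

    Node types are inferred from regulatory roles: any identifier acting as a
    TF regulator is typed TF (even when it is also a miRNA target); miRNAs
    are miR2gene regulators and TF2miR targets; everything else is a gene.
    An identifier claimed by both the TF and the miRNA namespace is an error.
    The merged reference network is unweighted.
    """
    expected = {
        EdgeClass.TF2GENE: tf2gene,
        EdgeClass.TF2MIR: tf2mir,
        EdgeClass.MIR2GENE: mir2gene,
    }
    for cls_, lib in expected.items():
        if lib.edge_class is not cls_:
            raise ValueError(f"expected a {cls_.value} library, got {lib.edge_class.value}")

    tf_ids = set(tf2gene.regulators) | set(tf2mir.regulators)
    mir_ids = set(mir2gene.regulators) | set(tf2mir.targets)
    collision = tf_ids & mir_ids
    if collision:
        raise ValueError(f"identifiers typed both TF and miRNA: {sorted(collision)}")

    def type_of(node: str) -> NodeType:
        if node in tf_ids:
            return NodeType.TF
        if node in mir_ids:
            return NodeType.MIRNA
        return NodeType.GENE

    net = RegulatoryNetwork()
    for lib in (tf2gene, tf2mir, mir2gene):
        for reg, tgt in lib.pairs:
            net.add_node(reg, type_of(reg))
            net.add_node(tgt, type_of(tgt))
            net.add_edge(reg, tgt)
    return net
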