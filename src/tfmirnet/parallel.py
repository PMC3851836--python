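"""Genome-wide network inference from parallel miRNA/mRNA expression.

Given two expression matrices over identical conditions (miRNA rows and mRNA
rows) plus the three putative-regulation libraries, two families of
multivariate regressions are fitted:

* per protein-coding gene ``g``:
  ``E_g = sum a_tfg * E_tf + sum a_mg * E_mir + const + noise`` over the
  candidate TFs and miRNAs that putatively regulate ``g`` — retained TF->gene
  and miRNA->gene edges come from here;
* per miRNA ``m``: ``E_m = sum a_tfm * E_tf + const + noise`` over the TFs
  that putatively regulate ``m`` — retained TF->miRNA edges come from here.

Candidate columns are selected by bidirectional stepwise AIC; survivors must
additionally reach a coefficient p-value below ``survivor_p``.  The union of
retained edges of the three classes is the combinatorial regulatory network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import ParallelExpressionDataset
from .library import EdgeClass, NodeType, RegulationLibrary
from .network import RegulatoryNetwork
from .stepwise import stepwise_ols

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionConfig",
    "ParallelNetworkModel",
    "ParallelNetworkResults",
    "fit_gene_equation",
    "fit_mirna_equation",
    "assemble_network",
]

_EDGE_COLUMNS = ["source", "target", "edge_type", "weight", "p_value"]


@dataclass(frozen=True)
class SelectionConfig:
    """Regulator-selection settings shared by both regression families.

    survivor_p : coefficient p-value a stepwise-selected regulator must reach
        to be kept (default 0.05).
    repression_only : if True, drop retained miRNA->gene edges with a
        positive coefficient (miRNA action on its target is degradation, so
        a negative sign is the mechanistically expected one).
    """

    survivor_p: float = 0.05
    repression_only: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.survivor_p < 1:
            raise ValueError(f"survivor_p must lie in (0, 1), got {self.survivor_p}")


def _select_regulators(
    response: np.ndarray,
    profiles: pd.DataFrame,
    candidates: list[str],
    n_conditions: int,
    config: SelectionConfig,
    what: str,
) -> list[tuple[str, float, float]]:
    """Stepwise-select regulator columns for one response; returns (id, coef, p)."""
    usable = []
    for c in candidates:
        if float(np.std(profiles[c].to_numpy())) == 0.0:
            logger.warning("%s: zero-variance regulator profile %r dropped", what, c)
            continue
        usable.append(c)
    if not usable:
        return []
    max_k = n_conditions - 2
    if len(usable) > max_k:
        corr = {
            c: abs(float(np.corrcoef(profiles[c].to_numpy(), response)[0, 1]))
            for c in usable
        }
        order = sorted(usable, key=lambda c: (-corr[c], usable.index(c)))
        keep = set(order[:max_k])
        logger.warning(
            "%s: %d candidates exceed the %d supportable by %d conditions; "
            "truncated by univariate |correlation|",
            what, len(usable), max_k, n_conditions,
        )
        usable = [c for c in usable if c in keep]
    sel = stepwise_ols(response, profiles[usable], usable)
    out = []
    for c in sel.included:
        p = float(sel.fit.pvalues[c])
        if p <= config.survivor_p:
            out.append((c, float(sel.fit.params[c]), p))
    return out


def fit_gene_equation(
    gene: str,
    dataset: ParallelExpressionDataset,
    tf2gene: RegulationLibrary,
    mir2gene: RegulationLibrary,
    config: SelectionConfig = SelectionConfig(),
) -> pd.DataFrame:
    """Retained TF->gene and miRNA->gene regulations for one gene.

    Candidate TFs are the gene's library regulators with a measured mRNA row
    (a TF's own transcript profile serves as its regulator profile); candidate
    miRNAs are its library regulators with a measured miRNA row.  Candidate
    order is TFs then miRNAs, each lexicographic.  Returns an edge table with
    columns source, target, edge_type, weight (coefficient) and p_value.
    """
    if gene not in dataset.genes:
        raise KeyError(f"gene {gene!r} not in the mRNA matrix")
    tf_cands = sorted(
        tf for tf in tf2gene.regulators_of(gene) if tf in dataset.genes and tf != gene
    )
    mir_cands = sorted(m for m in mir2gene.regulators_of(gene) if m in dataset.mirnas)
    if not tf_cands and not mir_cands:
        return pd.DataFrame(columns=_EDGE_COLUMNS)
    profiles = pd.concat(
        [
            dataset.mrna_matrix.loc[tf_cands].T if tf_cands else pd.DataFrame(index=list(dataset.conditions)),
            dataset.mirna_matrix.loc[mir_cands].T if mir_cands else pd.DataFrame(index=list(dataset.conditions)),
        ],
        axis=1,
    )
    response = dataset.mrna_matrix.loc[gene].to_numpy()
    retained = _select_regulators(
        response, profiles, [*tf_cands, *mir_cands], dataset.n_conditions, config,
        what=f"gene {gene}",
    )
    rows = []
    for reg, coef, p in retained:
        is_tf = reg in set(tf_cands)
        if (not is_tf) and config.repression_only and coef > 0:
            continue
        rows.append(
            (reg, gene, EdgeClass.TF2GENE.value if is_tf else EdgeClass.MIR2GENE.value, coef, p)
        )
    return pd.DataFrame(rows, columns=_EDGE_COLUMNS)


def fit_mirna_equation(
    mirna: str,
    dataset: ParallelExpressionDataset,
    tf2mir: RegulationLibrary,
    config: SelectionConfig = SelectionConfig(),
) -> pd.DataFrame:
    """Retained TF->miRNA regulations for one miRNA (same contract as genes)."""
    if mirna not in dataset.mirnas:
        raise KeyError(f"miRNA {mirna!r} not in the miRNA matrix")
    tf_cands = sorted(tf for tf in tf2mir.regulators_of(mirna) if tf in dataset.genes)
    if not tf_cands:
        return pd.DataFrame(columns=_EDGE_COLUMNS)
    profiles = dataset.mrna_matrix.loc[tf_cands].T
    response = dataset.mirna_matrix.loc[mirna].to_numpy()
    retained = _select_regulators(
        response, profiles, tf_cands, dataset.n_conditions, config,
        what=f"miRNA {mirna}",
    )
    rows = [(reg, mirna, EdgeClass.TF2MIR.value, coef, p) for reg, coef, p in retained]
    return pd.DataFrame(rows, columns=_EDGE_COLUMNS)


def assemble_network(
    gene_fits: pd.DataFrame, mirna_fits: pd.DataFrame
) -> RegulatoryNetwork:
    """Union of retained edges as one typed, coefficient-weighted network.

    Node types follow roles: edge sources of TF classes are TFs, miRNA-class
    sources and TF2miR targets are miRNAs; a target gene that elsewhere acts
    as a TF source is typed TF.
    """
    frames = [f for f in (gene_fits, mirna_fits) if len(f)]
    if not frames:
        return RegulatoryNetwork()
    edges = pd.concat(frames, ignore_index=True)
    tf_ids = set(edges.loc[edges["edge_type"].isin([EdgeClass.TF2GENE.value, EdgeClass.TF2MIR.value]), "source"])
    mir_ids = set(edges.loc[edges["edge_type"] == EdgeClass.MIR2GENE.value, "source"])
    mir_ids |= set(edges.loc[edges["edge_type"] == EdgeClass.TF2MIR.value, "target"])
    collision = tf_ids & mir_ids
    if collision:
        raise ValueError(f"identifiers typed both TF and miRNA: {sorted(collision)}")
    node_types: dict[str, NodeType] = {}
    for _, row in edges.iterrows():
        for node in (row["source"], row["target"]):
            if node in tf_ids:
                node_types[node] = NodeType.TF
            elif node in mir_ids:
                node_types[node] = NodeType.MIRNA
            else:
                node_types[node] = NodeType.GENE
    net = RegulatoryNetwork.from_typed_edges(
        node_types,
        [
            (row["source"], row["target"], float(row["weight"]), float(row["p_value"]))
            for _, row in edges.iterrows()
        ],
    )
    net.validate()
    return net


@dataclass
class ParallelNetworkResults:
    """Results of the genome-wide parallel-expression inference."""

    model: "ParallelNetworkModel"
    edge_table: pd.DataFrame      # source, target, edge_type, weight, p_value
    network: RegulatoryNetwork

    def summary(self) -> str:
        counts = self.edge_table["edge_type"].value_counts() if len(self.edge_table) else {}
        lines = [
            "Parallel miRNA/mRNA combinatorial network inference",
            "=" * 51,
            (
                f"dataset: {len(self.model.dataset.mirnas)} miRNAs, "
                f"{len(self.model.dataset.genes)} mRNAs, "
                f"{self.model.dataset.n_conditions} conditions"
            ),
            f"retained edges: {len(self.edge_table)}",
        ]
        for cls_ in EdgeClass:
            n = int(counts.get(cls_.value, 0)) if len(self.edge_table) else 0
            lines.append(f"  {cls_.value}: {n}")
        lines.append(
            f"network: {self.network.number_of_nodes} nodes, "
            f"{self.network.number_of_edges} edges"
        )
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / "network.edge.txt"
        self.network.write_edge_list(path, include_p_values=True)
        return {"network": path}


class ParallelNetworkModel:
    """Combinatorial network model for a parallel miRNA/mRNA dataset.

    Fits one stepwise regression per mRNA row (TF/miRNA regulators of that
    gene) and one per miRNA row (TF regulators of that miRNA), then unions
    the retained regulations into a typed network.

    Parameters
    ----------
    dataset : ParallelExpressionDataset
    tf2gene, tf2mir, mir2gene : RegulationLibrary
    config : SelectionConfig, optional
    """

    def __init__(
        self,
        dataset: ParallelExpressionDataset,
        tf2gene: RegulationLibrary,
        tf2mir: RegulationLibrary,
        mir2gene: RegulationLibrary,
        config: SelectionConfig = SelectionConfig(),
    ) -> None:
        for lib, cls_ in (
            (tf2gene, EdgeClass.TF2GENE),
            (tf2mir, EdgeClass.TF2MIR),
            (mir2gene, EdgeClass.MIR2GENE),
        ):
            if lib.edge_class is not cls_:
                raise ValueError(f"expected a {cls_.value} library, got {lib.edge_class.value}")
        self.dataset = dataset
        self.tf2gene = tf2gene
        self.tf2mir = tf2mir
        self.mir2gene = mir2gene
        self.config = config

    @classmethod
    def from_files(
        cls,
        mirna_matrix: str | Path,
        mrna_matrix: str | Path,
        tf2gene_path: str | Path,
        tf2mir_path: str | Path,
        mir2gene_path: str | Path,
        config: SelectionConfig = SelectionConfig(),
    ) -> "ParallelNetworkModel":
        return cls(
            ParallelExpressionDataset.read(mirna_matrix, mrna_matrix),
            RegulationLibrary.load(tf2gene_path, EdgeClass.TF2GENE),
            RegulationLibrary.load(tf2mir_path, EdgeClass.TF2MIR),
            RegulationLibrary.load(mir2gene_path, EdgeClass.MIR2GENE),
            config,
        )

    def fit(self) -> ParallelNetworkResults:
        """Fit all per-gene and per-miRNA equations; return the network."""
        gene_frames = [
            fit_gene_equation(g, self.dataset, self.tf2gene, self.mir2gene, self.config)
            for g in sorted(self.dataset.genes)
        ]
        mirna_frames = [
            fit_mirna_equation(m, self.dataset, self.tf2mir, self.config)
            for m in sorted(self.dataset.mirnas)
        ]
        gene_fits = (
            pd.concat([f for f in gene_frames if len(f)], ignore_index=True)
            if any(len(f) for f in gene_frames)
            else pd.DataFrame(columns=_EDGE_COLUMNS)
        )
        mirna_fits = (
            pd.concat([f for f in mirna_frames if len(f)], ignore_index=True)
            if any(len(f) for f in mirna_frames)
            else pd.DataFrame(columns=_EDGE_COLUMNS)
        )
        network = assemble_network(gene_fits, mirna_fits)
        edge_table = (
            pd.concat([gene_fits, mirna_fits], ignore_index=True)
            .sort_values(["edge_type", "source", "target"], kind="mergesort")
            .reset_index(drop=True)
        )
        return ParallelNetworkResults(model=self, edge_table=edge_table, network=network)
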