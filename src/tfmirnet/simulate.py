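"""Seeded synthetic datasets with planted ground truth.

Both network-building engines assume additive linear regulation with
Gaussian noise, so the generators emulate exactly that data-generating
process — planted regulator->target edges with known coefficients, decoy
library edges with zero effect, and i.i.d. normal noise — and emit the same
containers/file formats the engines consume.  Recovered networks can then be
scored against the planted truth.

``gen_mpge`` emulates a miRNA transfection experiment: per-gene expression
log-ratios equal to the planted miRNA shift plus planted TF effects plus
noise.  ``gen_parallel`` emulates a parallel miRNA/mRNA profiling study: TF
transcript profiles are i.i.d. standard normal across conditions, miRNA
profiles are planted linear combinations of their regulating TFs plus noise,
and mRNA profiles are planted combinations of TF and miRNA regulators plus
noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .datasets import MPGEDataset, ParallelExpressionDataset
from .library import EdgeClass, NodeType, RegulationLibrary
from .network import RegulatoryNetwork

logger = logging.getLogger(__name__)

__all__ = ["TFSpec", "PlantedTruth", "gen_mpge", "gen_parallel", "DEFAULT_TF_SPEC"]


class TFSpec(NamedTuple):
    """Specification of one planted TF for :func:`gen_mpge`.

    coefficient : additive effect on the log-ratio of each of the TF's
        targets (0 for a decoy TF that exists only in the library);
    n_targets : number of library targets assigned to the TF;
    mir_target : whether the TF is itself a putative target of the perturbed
        miRNA (a nonzero-coefficient miR-target TF is a planted mediator).
    """

    coefficient: float
    n_targets: int
    mir_target: bool


# Three effective mediating TFs plus seven decoy TFs: a miRNA perturbation
# typically touches a handful of functional mediators while the binding-site
# library nominates many more.
DEFAULT_TF_SPEC: tuple[TFSpec, ...] = (
    TFSpec(1.0, 60, True),
    TFSpec(-1.0, 60, True),
    TFSpec(0.8, 60, True),
) + tuple(TFSpec(0.0, 60, False) for _ in range(7))


@dataclass
class PlantedTruth:
    """Ground truth planted by a generator, for scoring recovered results."""

    true_direct_targets: dict[str, float]   # gene -> shift
    decoy_targets: tuple[str, ...]
    true_mediator_tfs: dict[str, float]     # TF -> coefficient
    decoy_tfs: tuple[str, ...]
    true_network: RegulatoryNetwork
    noise_sd: float
    seed: int

    @property
    def true_edges(self) -> set[tuple[str, str]]:
        return {(e.source, e.target) for e in self.true_network.edges()}

    def edge_recovery_scores(self, recovered: RegulatoryNetwork) -> dict[str, float]:
        """Precision / recall / F1 of recovered edges against the planted ones."""
        truth = self.true_edges
        found = {(e.source, e.target) for e in recovered.edges()}
        tp = len(truth & found)
        precision = tp / len(found) if found else 0.0
        recall = tp / len(truth) if truth else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
        return {"precision": precision, "recall": recall, "f1": f1, "tp": tp}


def _gene_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def gen_mpge(
    n_genes: int = 2000,
    n_mir_targets: int = 50,
    n_decoy_targets: int = 50,
    mir_effect: float = -2.0,
    tf_spec: Sequence[TFSpec] | None = None,
    noise_sd: float = 0.5,
    seed: int = 0,
    perturbed_mirna: str = "hsa-miR-1",
) -> tuple[MPGEDataset, RegulationLibrary, RegulationLibrary, PlantedTruth]:
    """Generate an MPGE dataset plus miR2gene/TF2gene libraries with truth.

    Log-ratios follow ``E_g = mir_effect * b(m,g) + sum_i a_i * b(TFi,g) +
    N(0, noise_sd)`` where ``b(m,g)`` is 1 only for the *true* miRNA targets
    (decoy targets sit in the library with zero effect) and each planted TF
    shifts its own targets by its coefficient.  TFs appear as dataset rows
    too; TFs marked ``mir_target`` are genuinely degraded (their own
    log-ratio includes ``mir_effect``) and are listed in the miR2gene
    library, making the effective ones planted mediators.

    Returns ``(dataset, mir2gene, tf2gene, truth)``; byte-identical for a
    fixed seed.
    """
    if tf_spec is None:
        tf_spec = DEFAULT_TF_SPEC
    if n_mir_targets + n_decoy_targets > n_genes:
        raise ValueError("more planted miRNA targets than genes")
    if any(s.n_targets > n_genes for s in tf_spec):
        raise ValueError("a TF cannot target more genes than exist")
    if n_mir_targets < 1:
        raise ValueError("need at least one true miRNA target")
    rng = np.random.default_rng(seed)

    genes = _gene_names(n_genes)
    tf_names = [f"TF{i + 1:02d}" for i in range(len(tf_spec))]

    perm = rng.permutation(n_genes)
    true_targets = [genes[i] for i in sorted(perm[:n_mir_targets])]
    decoy_targets = [genes[i] for i in sorted(perm[n_mir_targets : n_mir_targets + n_decoy_targets])]

    tf_targets: dict[str, list[str]] = {}
    for tf, spec in zip(tf_names, tf_spec):
        pick = rng.choice(n_genes, size=spec.n_targets, replace=False)
        tf_targets[tf] = [genes[i] for i in sorted(pick)]

    all_rows = genes + tf_names
    values = pd.Series(rng.normal(0.0, noise_sd, size=len(all_rows)), index=all_rows)
    values[true_targets] += mir_effect
    for tf, spec in zip(tf_names, tf_spec):
        if spec.coefficient != 0.0:
            values[tf_targets[tf]] += spec.coefficient
        if spec.mir_target:
            values[tf] += mir_effect

    mir_pairs = [(perturbed_mirna, g) for g in true_targets + decoy_targets]
    mir_pairs += [
        (perturbed_mirna, tf) for tf, spec in zip(tf_names, tf_spec) if spec.mir_target
    ]
    mir2gene = RegulationLibrary(EdgeClass.MIR2GENE, mir_pairs)
    tf2gene = RegulationLibrary(
        EdgeClass.TF2GENE,
        [(tf, g) for tf in tf_names for g in tf_targets[tf]],
    )

    node_types: dict[str, NodeType] = {perturbed_mirna: NodeType.MIRNA}
    edges: list[tuple[str, str, float | None, float | None]] = []
    for g in true_targets:
        node_types.setdefault(g, NodeType.GENE)
        edges.append((perturbed_mirna, g, mir_effect, None))
    mediators: dict[str, float] = {}
    decoy_tfs: list[str] = []
    for tf, spec in zip(tf_names, tf_spec):
        if spec.coefficient != 0.0:
            node_types[tf] = NodeType.TF
            if spec.mir_target:
                mediators[tf] = spec.coefficient
                edges.append((perturbed_mirna, tf, mir_effect, None))
            for g in tf_targets[tf]:
                node_types.setdefault(g, NodeType.GENE)
                edges.append((tf, g, spec.coefficient, None))
        else:
            decoy_tfs.append(tf)
    truth_net = RegulatoryNetwork.from_typed_edges(node_types, edges)

    dataset = MPGEDataset(perturbed_mirna, values)
    truth = PlantedTruth(
        true_direct_targets={g: mir_effect for g in true_targets},
        decoy_targets=tuple(decoy_targets),
        true_mediator_tfs=mediators,
        decoy_tfs=tuple(decoy_tfs),
        true_network=truth_net,
        noise_sd=noise_sd,
        seed=seed,
    )
    return dataset, mir2gene, tf2gene, truth


def gen_parallel(
    n_conditions: int = 60,
    n_tfs: int = 30,
    n_mirnas: int = 20,
    n_genes: int = 150,
    edge_density: float = 1.5,
    coeff_range: tuple[float, float] = (0.5, 2.0),
    noise_sd: float = 0.5,
    seed: int = 0,
    decoy_ratio: float = 1.0,
) -> tuple[
    ParallelExpressionDataset,
    RegulationLibrary,
    RegulationLibrary,
    RegulationLibrary,
    PlantedTruth,
]:
    """Generate a parallel miRNA/mRNA dataset plus all three libraries.

    Each miRNA and each gene receives 0–3 planted regulators
    (``Binomial(3, edge_density / 3)`` of them, so ``edge_density`` is the
    mean in-degree); planted coefficients have magnitude uniform in
    ``coeff_range`` and random sign.  Gene regulators are drawn from the
    pooled TFs and miRNAs, miRNA regulators from the TFs.  The libraries
    contain the planted edges plus ``decoy_ratio`` times as many decoy edges
    with zero effect.

    Returns ``(dataset, tf2gene, tf2mir, mir2gene, truth)``.
    """
    if n_conditions < 3:
        raise ValueError("need at least 3 conditions")
    lo, hi = coeff_range
    if not 0 < lo <= hi:
        raise ValueError("coeff_range must be 0 < lo <= hi")
    rng = np.random.default_rng(seed)
    conditions = [f"C{i + 1:02d}" for i in range(n_conditions)]
    tfs = [f"TF{i + 1:02d}" for i in range(n_tfs)]
    mirnas = [f"hsa-miR-{100 + i}" for i in range(n_mirnas)]
    genes = _gene_names(n_genes)

    p_reg = min(1.0, edge_density / 3.0)

    def draw_coef() -> float:
        return float(rng.uniform(lo, hi) * rng.choice([-1.0, 1.0]))

    tf_expr = pd.DataFrame(
        rng.normal(size=(n_tfs, n_conditions)), index=tfs, columns=conditions
    )

    planted: list[tuple[str, str, float]] = []  # (regulator, target, coefficient)
    mir_expr = pd.DataFrame(0.0, index=mirnas, columns=conditions)
    for m in mirnas:
        k = int(rng.binomial(3, p_reg))
        regs = [tfs[i] for i in sorted(rng.choice(n_tfs, size=k, replace=False))] if k else []
        # a miRNA with no planted TF driver is an exogenous regulator like the
        # TFs: unit intrinsic variance (otherwise it would be flat at noise 0
        # and its own targets unidentifiable); driven miRNAs carry residual
        # noise at noise_sd around their TF combination
        profile = rng.normal(size=n_conditions) * (noise_sd if regs else 1.0)
        for tf in regs:
            c = draw_coef()
            planted.append((tf, m, c))
            profile = profile + c * tf_expr.loc[tf].to_numpy()
        mir_expr.loc[m] = profile

    regulator_pool = tfs + mirnas
    gene_expr = pd.DataFrame(0.0, index=genes, columns=conditions)
    for g in genes:
        k = int(rng.binomial(3, p_reg))
        regs = (
            [regulator_pool[i] for i in sorted(rng.choice(len(regulator_pool), size=k, replace=False))]
            if k
            else []
        )
        if noise_sd == 0.0 and len(regs) > 1:
            # in a zero-noise cascade a TF-driven miRNA profile is an *exact*
            # linear combination of its drivers, so a gene planted with both
            # would have an unidentifiable (rank-deficient) design; keep only
            # regulators that add rank
            kept: list[str] = []
            cols: list[np.ndarray] = []
            for r in regs:
                src = tf_expr.loc[r] if r in tf_expr.index else mir_expr.loc[r]
                trial = np.column_stack([*cols, src.to_numpy()])
                if np.linalg.matrix_rank(trial) == len(cols) + 1:
                    kept.append(r)
                    cols.append(src.to_numpy())
            regs = kept
        profile = rng.normal(0.0, noise_sd, size=n_conditions)
        for r in regs:
            c = draw_coef()
            planted.append((r, g, c))
            src = tf_expr.loc[r] if r in tf_expr.index else mir_expr.loc[r]
            profile = profile + c * src.to_numpy()
        gene_expr.loc[g] = profile

    if not planted:
        logger.warning("gen_parallel: edge density produced no planted edges")

    planted_pairs = {(r, t) for r, t, _ in planted}

    def split_class(pred) -> list[tuple[str, str]]:
        return sorted((r, t) for r, t in planted_pairs if pred(r, t))

    tf2gene_pairs = split_class(lambda r, t: r in set(tfs) and t in set(genes))
    tf2mir_pairs = split_class(lambda r, t: r in set(tfs) and t in set(mirnas))
    mir2gene_pairs = split_class(lambda r, t: r in set(mirnas))

    def add_decoys(pairs: list[tuple[str, str]], regs: list[str], tgts: list[str]):
        n_decoy = int(round(decoy_ratio * len(pairs)))
        existing = set(pairs)
        out = list(pairs)
        guard = 0
        while n_decoy > 0 and guard < 100000:
            guard += 1
            r = regs[int(rng.integers(len(regs)))]
            t = tgts[int(rng.integers(len(tgts)))]
            if r == t or (r, t) in existing:
                continue
            existing.add((r, t))
            out.append((r, t))
            n_decoy -= 1
        return out

    tf2gene = RegulationLibrary(EdgeClass.TF2GENE, add_decoys(tf2gene_pairs, tfs, genes))
    tf2mir = RegulationLibrary(EdgeClass.TF2MIR, add_decoys(tf2mir_pairs, tfs, mirnas))
    mir2gene = RegulationLibrary(EdgeClass.MIR2GENE, add_decoys(mir2gene_pairs, mirnas, genes))

    node_types = {t: NodeType.TF for t in tfs}
    node_types.update({m: NodeType.MIRNA for m in mirnas})
    node_types.update({g: NodeType.GENE for g in genes})
    used = {r for r, _, _ in planted} | {t for _, t, _ in planted}
    truth_net = RegulatoryNetwork.from_typed_edges(
        {n: t for n, t in node_types.items() if n in used},
        [(r, t, c, None) for r, t, c in sorted(planted)],
    )

    mrna_matrix = pd.concat([tf_expr, gene_expr])
    dataset = ParallelExpressionDataset(mir_expr, mrna_matrix)
    truth = PlantedTruth(
        true_direct_targets={},
        decoy_targets=(),
        true_mediator_tfs={},
        decoy_tfs=(),
        true_network=truth_net,
        noise_sd=noise_sd,
        seed=seed,
    )
    return dataset, tf2gene, tf2mir, mir2gene, truth
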