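"""Two-layer network inference from miRNA-perturbed gene expression (MPGE).

An MPGE experiment transfects a single miRNA into a cell line and measures
per-gene expression log-ratios (after vs. before).  Given the perturbation
data plus the miR2gene and TF2gene putative-regulation libraries, this engine
pursues three linked goals:

1. **Degradation significance** — a one-sided two-sample Kolmogorov–Smirnov
   test asking whether the miRNA's putative targets are expressed lower than
   the non-targets (degradation shifts target log-ratios down).
2. **Target refinement** — a per-gene nonparametric tail test of each
   putative target's log-ratio against the non-target empirical distribution,
   with Benjamini–Hochberg control of the FDR.
3. **Mediating TFs** — a univariate prefilter followed by bidirectional
   stepwise multivariate regression of the log-ratios on binary
   target-membership indicators,

   ``E_g = a_m * b_(m,g) + sum_i a_TFi * b_(TFi,g) + const + noise``,

   where ``b_(m,g)`` marks refined miRNA targets and ``b_(TFi,g)`` marks
   putative targets of TF i.  TFs surviving selection that are themselves
   putative targets of the perturbed miRNA are its *mediating* TFs.

The retained miRNA->gene and TF->gene regulations form a two-layer network
centred on the perturbed miRNA.  :class:`MPGEModel` wraps the full pipeline;
each stage is also exposed as a standalone function.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import MPGEDataset
from .library import EdgeClass, NodeType, RegulationLibrary
from .network import RegulatoryNetwork
from .stepwise import StepwiseResult, stepwise_ols

logger = logging.getLogger(__name__)

__all__ = [
    "DegradationTestResult",
    "MPGELinearModel",
    "MPGEModel",
    "MPGEResults",
    "ks_degradation_test",
    "refine_targets",
    "prefilter_tfs",
    "fit_combinatorial_model",
    "build_two_layer_network",
]

# Largest group size for which the exact (permutation-equivalent) one-sided
# K-S null distribution is computed; beyond it the asymptotic tail is used.
_KS_EXACT_MAX_N = 500


def _split_targets(dataset: MPGEDataset, mir2gene: RegulationLibrary):
    if mir2gene.edge_class is not EdgeClass.MIR2GENE:
        raise ValueError("a miR2gene library is required")
    putative = set(mir2gene.targets_of(dataset.perturbed_mirna))
    if not putative:
        raise ValueError(
            f"perturbed miRNA {dataset.perturbed_mirna!r} has no targets in the miR2gene library"
        )
    mask = dataset.genes.isin(putative)
    targets = dataset.ratios[mask]
    nontargets = dataset.ratios[~mask]
    if len(targets) == 0:
        raise ValueError("no putative target of the perturbed miRNA is present in the dataset")
    if len(nontargets) == 0:
        raise ValueError("dataset contains no non-target genes")
    return targets, nontargets


@dataclass(frozen=True)
class DegradationTestResult:
    """One-sided K-S comparison of target vs non-target log-ratios."""

    ks_statistic: float
    p_value: float
    n_targets: int
    n_nontargets: int
    pp_points: pd.DataFrame  # columns: value, cdf_nontargets, cdf_targets

    def __str__(self) -> str:
        return (
            f"one-sided K-S degradation test: D+ = {self.ks_statistic:.4f}, "
            f"p = {self.p_value:.3g} ({self.n_targets} targets vs "
            f"{self.n_nontargets} non-targets)"
        )


def ks_degradation_test(
    dataset: MPGEDataset, mir2gene: RegulationLibrary
) -> DegradationTestResult:
    """Test whether putative-target log-ratios are shifted down vs non-targets.

    The statistic is ``D+ = sup_x [ECDF_targets(x) - ECDF_nontargets(x)]``;
    large values mean the targets' distribution sits below (to the left of)
    the non-targets', i.e. the miRNA degrades its putative targets.  The null
    tail probability is exact (equivalent to the full label-permutation
    distribution) for group sizes up to 500 and asymptotic beyond.

    Returns the statistic, p-value, group sizes and the paired
    empirical-CDF coordinates used for a PP plot.
    """
    targets, nontargets = _split_targets(dataset, mir2gene)
    t = targets.to_numpy()
    nt = nontargets.to_numpy()
    method = "exact" if max(len(t), len(nt)) <= _KS_EXACT_MAX_N else "asymp"
    res = stats.ks_2samp(t, nt, alternative="greater", method=method)
    grid = np.unique(np.concatenate([t, nt]))
    pp = pd.DataFrame(
        {
            "value": grid,
            "cdf_nontargets": np.searchsorted(np.sort(nt), grid, side="right") / len(nt),
            "cdf_targets": np.searchsorted(np.sort(t), grid, side="right") / len(t),
        }
    )
    return DegradationTestResult(
        ks_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_targets=len(t),
        n_nontargets=len(nt),
        pp_points=pp,
    )


def refine_targets(
    dataset: MPGEDataset,
    mir2gene: RegulationLibrary,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Refine degraded targets out of the putative target list.

    For each putative target ``g`` the one-sided empirical tail probability
    against the non-target distribution is

    ``p(g) = (1 + #{non-targets with log-ratio <= E_g}) / (1 + n_nontargets)``

    (rank-based, hence invariant to monotone transforms of the log-ratios).
    Targets whose Benjamini–Hochberg adjusted p is <= ``alpha`` form the
    refined set.

    Returns a DataFrame indexed by gene with columns ``log_ratio``, ``p_raw``,
    ``p_adj`` and boolean ``refined``, sorted by ascending ``p_raw`` with ties
    broken by gene symbol.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    targets, nontargets = _split_targets(dataset, mir2gene)
    nt_sorted = np.sort(nontargets.to_numpy())
    n_nt = len(nt_sorted)
    ranks = np.searchsorted(nt_sorted, targets.to_numpy(), side="right")
    p_raw = (1.0 + ranks) / (1.0 + n_nt)
    _, p_adj, _, _ = multipletests(p_raw, method="fdr_bh")
    out = pd.DataFrame(
        {
            "log_ratio": targets.to_numpy(),
            "p_raw": p_raw,
            "p_adj": p_adj,
            "refined": p_adj <= alpha,
        },
        index=targets.index.rename("gene"),
    )
    return out.sort_values(["p_raw", "gene"], kind="mergesort")


def prefilter_tfs(
    dataset: MPGEDataset,
    tf2gene: RegulationLibrary,
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Univariate prefilter of candidate TFs.

    Each TF with at least one putative target in the dataset is screened by
    the simple regression ``E_g = c0 + c1 * b_(TF,g)`` over all genes; TFs
    whose slope p-value is <= ``p_threshold`` are retained, ordered by
    ascending p with ties broken lexicographically.  TFs whose indicator is
    constant over the dataset genes are skipped with a warning.

    Returns a DataFrame indexed by TF with columns ``slope`` and ``p_value``.
    """
    if tf2gene.edge_class is not EdgeClass.TF2GENE:
        raise ValueError("a TF2gene library is required")
    if not 0 < p_threshold < 1:
        raise ValueError(f"p_threshold must lie in (0, 1), got {p_threshold}")
    y = dataset.ratios.to_numpy()
    gene_pos = {g: i for i, g in enumerate(dataset.genes)}
    rows = []
    for tf in tf2gene.regulators:
        idx = [gene_pos[g] for g in tf2gene.targets_of(tf) if g in gene_pos]
        if not idx:
            continue
        b = np.zeros(len(y))
        b[idx] = 1.0
        if b.all() or not b.any():
            logger.warning("prefilter: TF %r has a constant indicator column; skipped", tf)
            continue
        res = stats.linregress(b, y)
        rows.append((tf, float(res.slope), float(res.pvalue)))
    if not rows:
        raise ValueError("no TF with a non-constant target indicator in the dataset")
    df = pd.DataFrame(rows, columns=["tf", "slope", "p_value"]).set_index("tf")
    df = df.sort_values(["p_value", "tf"], kind="mergesort")
    return df[df["p_value"] <= p_threshold]


@dataclass
class MPGELinearModel:
    """Fitted combinatorial indicator-regression model for one MPGE dataset."""

    perturbed_mirna: str
    a_m: float                    # regulating strength of the perturbed miRNA
    a_m_pvalue: float
    tf_coefficients: pd.Series    # retained TFs -> a_TFi
    tf_pvalues: pd.Series
    intercept: float
    resid_var: float
    n_genes: int
    candidate_tfs: tuple[str, ...]
    dropped_collinear: tuple[str, ...] = ()

    @property
    def retained_tfs(self) -> tuple[str, ...]:
        return tuple(self.tf_coefficients.index)


def fit_combinatorial_model(
    dataset: MPGEDataset,
    refined_mirna_indicator: pd.Series,
    candidate_tfs: list[str],
    tf2gene: RegulationLibrary,
) -> MPGELinearModel:
    """Bidirectional stepwise selection of combinatorial regulators.

    The design holds one binary column per candidate TF (library-target
    membership) plus the refined miRNA-target indicator, which is forced into
    the model.  Selection minimises AIC; candidates enter in the given
    (prefilter) order, so the fit is deterministic.  Exactly collinear
    candidate columns are dropped (later-ordered column loses) with a
    warning.
    """
    y = dataset.ratios
    n = len(y)
    if n <= len(candidate_tfs) + 2:
        raise ValueError(
            f"{n} genes cannot support {len(candidate_tfs)} candidate predictors"
        )
    b_m = refined_mirna_indicator.reindex(dataset.genes, fill_value=0.0).astype(float)
    design = {"b_m": b_m.to_numpy()}
    gene_pos = {g: i for i, g in enumerate(dataset.genes)}
    for tf in candidate_tfs:
        col = np.zeros(n)
        idx = [gene_pos[g] for g in tf2gene.targets_of(tf) if g in gene_pos]
        col[idx] = 1.0
        design[tf] = col
    X = pd.DataFrame(design, index=dataset.genes)
    sel: StepwiseResult = stepwise_ols(
        y.to_numpy(), X, list(candidate_tfs), forced=("b_m",)
    )
    params, pvals = sel.fit.params, sel.fit.pvalues
    return MPGELinearModel(
        perturbed_mirna=dataset.perturbed_mirna,
        a_m=float(params["b_m"]),
        a_m_pvalue=float(pvals["b_m"]),
        tf_coefficients=params[sel.included].rename("a_TF"),
        tf_pvalues=pvals[sel.included].rename("p_value"),
        intercept=float(params["const"]),
        resid_var=sel.fit.resid_var,
        n_genes=n,
        candidate_tfs=tuple(candidate_tfs),
        dropped_collinear=tuple(sel.dropped_collinear),
    )


def build_two_layer_network(
    model: MPGELinearModel,
    refined_targets: set[str] | list[str],
    mir2gene: RegulationLibrary,
    tf2gene: RegulationLibrary,
    dataset_genes: pd.Index | None = None,
) -> RegulatoryNetwork:
    """Assemble the miRNA-centred two-layer network.

    Edges: perturbed miRNA -> each refined target; perturbed miRNA -> each
    mediating TF (a retained TF that is itself a putative target of the
    miRNA); each retained TF -> its library targets present in the dataset.
    miRNA out-edges carry the fitted ``a_m``; TF out-edges carry ``a_TFi``.
    Only miRNA->gene/TF and TF->gene/TF edges can appear.
    """
    mir = model.perturbed_mirna
    refined = set(refined_targets)
    retained = set(model.retained_tfs)
    mediators = retained & set(mir2gene.targets_of(mir))

    node_types: dict[str, NodeType] = {mir: NodeType.MIRNA}
    for tf in retained:
        node_types[tf] = NodeType.TF
    edges: list[tuple[str, str, float | None, float | None]] = []
    for g in sorted(refined):
        if g == mir:
            continue
        node_types.setdefault(g, NodeType.GENE)
        edges.append((mir, g, model.a_m, model.a_m_pvalue))
    for tf in sorted(mediators - refined):
        edges.append((mir, tf, model.a_m, model.a_m_pvalue))
    for tf in sorted(retained):
        if tf in refined:
            edges.append((mir, tf, model.a_m, model.a_m_pvalue))
        coef = float(model.tf_coefficients[tf])
        pval = float(model.tf_pvalues[tf])
        for g in tf2gene.targets_of(tf):
            if dataset_genes is not None and g not in dataset_genes:
                continue
            if g == mir or g == tf:
                continue
            node_types.setdefault(g, NodeType.GENE)
            edges.append((tf, g, coef, pval))
    # de-duplicate (a refined target that is also a mediator appears once)
    seen: set[tuple[str, str]] = set()
    unique_edges = []
    for src, tgt, w, p in edges:
        if (src, tgt) in seen:
            continue
        seen.add((src, tgt))
        unique_edges.append((src, tgt, w, p))
    return RegulatoryNetwork.from_typed_edges(node_types, unique_edges)


@dataclass
class MPGEResults:
    """Results of the full MPGE pipeline (see :class:`MPGEModel`)."""

    model: "MPGEModel"
    degradation: DegradationTestResult
    target_table: pd.DataFrame
    prefiltered_tfs: pd.DataFrame
    linear_model: MPGELinearModel
    network: RegulatoryNetwork

    @property
    def refined_targets(self) -> tuple[str, ...]:
        return tuple(self.target_table.index[self.target_table["refined"]])

    @property
    def mediating_tfs(self) -> tuple[str, ...]:
        mir_targets = set(self.model.mir2gene.targets_of(self.linear_model.perturbed_mirna))
        return tuple(tf for tf in self.linear_model.retained_tfs if tf in mir_targets)

    def mediator_table(self) -> pd.DataFrame:
        lm = self.linear_model
        mediators = set(self.mediating_tfs)
        return pd.DataFrame(
            {
                "coefficient": lm.tf_coefficients,
                "p_value": lm.tf_pvalues,
                "mediating": [tf in mediators for tf in lm.retained_tfs],
            },
            index=pd.Index(lm.retained_tfs, name="tf"),
        )

    def summary(self) -> str:
        lm = self.linear_model
        lines = [
            f"MPGE two-layer network inference: {lm.perturbed_mirna}",
            "=" * 58,
            str(self.degradation),
            (
                f"refined targets: {len(self.refined_targets)} of "
                f"{len(self.target_table)} putative (BH alpha = {self.model.alpha})"
            ),
            (
                f"miRNA regulating strength a_m = {lm.a_m:.4f} "
                f"(p = {lm.a_m_pvalue:.3g})"
            ),
            f"candidate TFs after prefilter: {len(self.prefiltered_tfs)}",
            f"retained TFs: {len(lm.retained_tfs)} ({len(self.mediating_tfs)} mediating)",
        ]
        med = self.mediator_table()
        if len(med):
            lines.append("")
            lines.append(med.to_string(float_format=lambda v: f"{v:.4f}"))
        lines.append("")
        lines.append(
            f"network: {self.network.number_of_nodes} nodes, "
            f"{self.network.number_of_edges} edges"
        )
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> dict[str, Path]:
        """Write the three report sections plus the PP-plot table.

        Files: ``targets.tsv`` (per-putative-target refinement statistics),
        ``ppplot.tsv`` (paired ECDF coordinates), ``mediators.tsv`` (retained
        TFs with coefficients) and ``network.edge.txt`` (tab-delimited edge
        list).
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "targets": outdir / "targets.tsv",
            "ppplot": outdir / "ppplot.tsv",
            "mediators": outdir / "mediators.tsv",
            "network": outdir / "network.edge.txt",
        }
        self.target_table.to_csv(paths["targets"], sep="\t", float_format="%.10g")
        self.degradation.pp_points.to_csv(
            paths["ppplot"], sep="\t", index=False, float_format="%.10g"
        )
        self.mediator_table().to_csv(paths["mediators"], sep="\t", float_format="%.10g")
        self.network.write_edge_list(paths["network"])
        return paths

    def plot_pp(self, path: str | Path) -> None:
        """Write the target-vs-nontarget PP plot as an image (needs matplotlib)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        pp = self.degradation.pp_points
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.plot([0, 1], [0, 1], "k--", lw=1, label="no degradation")
        ax.plot(pp["cdf_nontargets"], pp["cdf_targets"], lw=1.5, label="targets vs non-targets")
        ax.set_xlabel("non-target ECDF")
        ax.set_ylabel("target ECDF")
        ax.set_title(
            f"{self.linear_model.perturbed_mirna}: D+ = {self.degradation.ks_statistic:.3f}, "
            f"p = {self.degradation.p_value:.2g}"
        )
        ax.legend(loc="lower right")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


class MPGEModel:
    """miRNA-perturbation network model (K-S test + refinement + stepwise TFs).

    Parameters
    ----------
    dataset : MPGEDataset
    mir2gene, tf2gene : RegulationLibrary
        Putative miRNA->gene and TF->gene regulation libraries.
    alpha : float
        BH false-discovery level for target refinement (default 0.05).
    prefilter_p : float
        Univariate slope p-value threshold for TF candidacy (default 0.01).

    Examples
    --------
    >>> model = MPGEModel(dataset, mir2gene, tf2gene)   # doctest: +SKIP
    >>> res = model.fit()                               # doctest: +SKIP
    >>> print(res.summary())                            # doctest: +SKIP
    """

    def __init__(
        self,
        dataset: MPGEDataset,
        mir2gene: RegulationLibrary,
        tf2gene: RegulationLibrary,
        *,
        alpha: float = 0.05,
        prefilter_p: float = 0.01,
    ) -> None:
        if not 0 < alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
        if not 0 < prefilter_p < 1:
            raise ValueError(f"prefilter_p must lie in (0, 1), got {prefilter_p}")
        self.dataset = dataset
        self.mir2gene = mir2gene
        self.tf2gene = tf2gene
        self.alpha = alpha
        self.prefilter_p = prefilter_p

    @classmethod
    def from_files(
        cls,
        mpge_csv: str | Path,
        perturbed_mirna: str,
        mir2gene_path: str | Path,
        tf2gene_path: str | Path,
        **kwargs,
    ) -> "MPGEModel":
        return cls(
            MPGEDataset.read_csv(mpge_csv, perturbed_mirna),
            RegulationLibrary.load(mir2gene_path, EdgeClass.MIR2GENE),
            RegulationLibrary.load(tf2gene_path, EdgeClass.TF2GENE),
            **kwargs,
        )

    def fit(self) -> MPGEResults:
        """Run the full pipeline and return an :class:`MPGEResults`."""
        degradation = ks_degradation_test(self.dataset, self.mir2gene)
        target_table = refine_targets(self.dataset, self.mir2gene, self.alpha)
        refined = set(target_table.index[target_table["refined"]])
        prefiltered = prefilter_tfs(self.dataset, self.tf2gene, self.prefilter_p)
        indicator = pd.Series(
            [1.0 if g in refined else 0.0 for g in self.dataset.genes],
            index=self.dataset.genes,
        )
        linear = fit_combinatorial_model(
            self.dataset, indicator, list(prefiltered.index), self.tf2gene
        )
        network = build_two_layer_network(
            linear, refined, self.mir2gene, self.tf2gene, self.dataset.genes
        )
        return MPGEResults(
            model=self,
            degradation=degradation,
            target_table=target_table,
            prefiltered_tfs=prefiltered,
            linear_model=linear,
            network=network,
        )
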