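# tfmirnet

Combinatorial TF–miRNA gene regulatory network inference from expression
data.

Transcription factors (TFs) and microRNAs (miRNAs) are the two principal
regulator classes of metazoan gene expression — TFs act transcriptionally,
miRNAs post-transcriptionally — and they regulate each other as well as
their shared targets. Sequence evidence (conserved binding sites, seed
matching) yields large *putative* regulation libraries of three classes:

* `TF2gene` — TF → protein-coding gene (the target may itself be a TF),
* `TF2miR` — TF → miRNA gene,
* `miR2gene` — miRNA → protein-coding gene (including miRNA → TF).

These libraries are condition-blind. `tfmirnet` sifts them with expression
data to build *condition-specific* combinatorial networks, and then analyses
the resulting typed directed graphs. It is a library-plus-CLI for
computational biologists who have either a miRNA perturbation experiment or
a parallel miRNA/mRNA profiling study in hand.

## The two inference engines

**`MPGEModel` — miRNA-perturbed gene expression (MPGE).** One miRNA *m* is
transfected into a cell line; per-gene expression log-ratios E_g (after vs
before) are measured. With binary library indicators b_(m,g) and b_(TFi,g)
(1 iff the pair is in the putative library), the engine

1. tests degradation globally with a one-sided two-sample
   Kolmogorov–Smirnov statistic, D+ = sup_x [F̂_targets(x) − F̂_nontargets(x)];
2. refines the degraded targets with a per-gene empirical tail test against
   the non-target distribution (Benjamini–Hochberg at level α);
3. screens candidate TFs with univariate regressions E_g = c₀ + c₁ b_(TFi,g),
   then selects combinatorial regulators by bidirectional stepwise AIC on

   E_g = a_m·b_(m,g) + Σᵢ a_TFi·b_(TFi,g) + c₀ + ε_g,

   with the miRNA indicator always retained. Retained TFs that are
   themselves putative miRNA targets are the *mediating TFs*.

The output is a two-layer network: miRNA → refined targets, miRNA →
mediating TFs, and each retained TF → its targets.

**`ParallelNetworkModel` — parallel miRNA/mRNA expression.** Two matrices
over the same conditions (miRNA rows; mRNA rows). Per gene g and per miRNA
m, regulators are selected by stepwise AIC over the measured profiles of the
library candidates:

E_g = Σ a_tfg·E_tf + Σ a_mg·E_mir + c₀ + ε,  E_m = Σ a_tfm·E_tf + c₀ + ε,

with survivors additionally requiring coefficient p ≤ 0.05. The union of
retained TF→gene, miRNA→gene and TF→miRNA edges is a genome-wide
combinatorial network.

**Topology module.** Degree and betweenness rankings; co-regulating
regulator pairs by one-sided Fisher's exact test on shared targets;
and typed triple-vertex motif analysis: all closed three-vertex circuits
containing at least one TF and one miRNA — exactly 18 types exist under the
edge-type rules (3 on {TF, miRNA, gene}, 15 on {TF, TF, miRNA}), classified
as feed-forward loops (acyclic) or feed-backward loops (cyclic) — with
empirical enrichment p-values against degree-preserving shuffled networks.

## Worked example

Generate a synthetic MPGE experiment with planted truth (2000 genes, 50
true targets shifted by −2, three mediating TFs with coefficients +1.0,
−1.0, +0.8, noise sd 0.5) and run the pipeline:

```bash
tfmirnet simulate mpge --seed 1 --out fixture
tfmirnet mpge --data fixture/mpge.csv --mirna hsa-miR-1 \
    --mir2gene fixture/mir2gene.tsv --tf2gene fixture/tf2gene.tsv \
    --out run
```

which prints

```
MPGE two-layer network inference: hsa-miR-1
==========================================================
one-sided K-S degradation test: D+ = 0.4870, p = 5.23e-21 (103 targets vs 1907 non-targets)
refined targets: 52 of 103 putative (BH alpha = 0.05)
miRNA regulating strength a_m = -1.9764 (p = 2.75e-147)
candidate TFs after prefilter: 3
retained TFs: 3 (3 mediating)

      coefficient  p_value  mediating
tf
TF02      -1.0740   0.0000       True
TF03       0.9314   0.0000       True
TF01       0.8590   0.0000       True

network: 224 nodes, 232 edges
```

Reading the numbers: the K-S test finds the 103 putative targets strongly
down-shifted (D+ = 0.49); 52 survive per-gene refinement (the 50 planted
targets plus mediators minus noise casualties); the fitted miRNA strength
a_m ≈ −1.98 recovers the planted −2; and the three planted mediating TFs
are retained with sign-correct coefficients close to (+1, −1, +0.8). The
same library API:

```python
from tfmirnet import MPGEModel, gen_mpge

dataset, mir2gene, tf2gene, truth = gen_mpge(seed=1)
results = MPGEModel(dataset, mir2gene, tf2gene).fit()
print(results.summary())
results.save("run/")         # targets.tsv, mediators.tsv, ppplot.tsv, network.edge.txt
```

The parallel engine and topology report run the same way
(`tfmirnet parallel ... --replicates 1000 --seed 0`), producing the edge
list, rankings, co-regulating pair table and the 18-row motif significance
table.

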