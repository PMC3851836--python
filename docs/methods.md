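# Methods

This note records the statistical models behind `tfmirnet`, the numerical
choices made where the procedures leave room, what the synthetic generators
do and do not emulate, and the known limitations.

## Data model

Networks are typed directed graphs over three node classes. Edges follow
the regulation-type rules: TF → {gene, TF} (`TF2gene`), TF → miRNA
(`TF2miR`), miRNA → {gene, TF} (`miR2gene`). Plain genes have no out-edges
and miRNA → miRNA edges do not exist (miRNAs repress transcripts; another
miRNA gene is not a transcript target in this model). TFs are themselves
protein-coding genes, which is why miRNA → TF edges live in the
`miR2gene` class and TF → TF edges in `TF2gene`.

miRNA transcript identifiers are consolidated to root form on every input
path: a trailing `-<digits>` group is a genomic-copy index — and is removed
— only when the preceding name token already carries the miR number (so
`hsa-let-7a-1` → `hsa-let-7a` but `hsa-miR-1` is untouched, as are the
`-3p`/`-5p` arm suffixes). The rule is idempotent; unrecognised names pass
through unchanged.

Library files are two-column tab-separated text (`regulator_id`,
`target_id`; `#` comments). Duplicate pairs collapse silently with a logged
count, since real binding-site libraries contain redundant records. Targets
that look like miRBase names inside a gene-class library are rejected as
type violations; this is a heuristic (regex on the `xxx-miR-`/`xxx-let-`
prefix) and assumes conventional naming.

## MPGE engine

Model: per-gene log-ratios are an additive linear function of binary
library-membership indicators,

    E_g = a_m * b_(m,g) + sum_i a_TFi * b_(TFi,g) + c0 + eps_g,

with i.i.d. Gaussian errors. The assumptions that matter: additivity of
regulator effects on the log scale, homoscedastic noise across genes, and
the library indicators being a superset of the true wiring.

**Degradation test.** One-sided two-sample Kolmogorov–Smirnov with
D+ = sup_x [ECDF_targets(x) − ECDF_nontargets(x)]; large D+ means target
log-ratios sit below the non-targets', i.e. degradation. The null tail is
computed exactly (the conditional permutation distribution, via the
path-counting algorithm) whenever the larger group has ≤ 500 observations,
and with the asymptotic formula beyond that. The exact branch matters
because the asymptotic one-sided tail has percent-level error at n ≈ 100,
which is visible against a Monte-Carlo permutation check; the cutoff of 500
keeps the exact computation well under a second while covering every
dataset where the asymptotic error is non-negligible.

**Target refinement.** Per putative target g, the empirical one-sided tail
probability against the non-target distribution,

    p(g) = (1 + #{non-targets with log-ratio <= E_g}) / (1 + n_nontargets),

followed by Benjamini–Hochberg at level alpha (default 0.05). The +1
smoothing keeps p > 0 and matches the standard empirical-p convention.
The statistic is rank-based, hence invariant under any monotone increasing
transform of the log-ratios. A global refinement test (shift the whole
target distribution) was the alternative; the per-gene test was chosen
because the refined *set* is the object of interest downstream and a
global test cannot name genes.

**TF prefilter.** Univariate slope test of E_g on b_(TFi,g) per TF
(equivalent to a pooled two-sample t-test), keeping p ≤ 0.01 by default,
ordered by ascending p with lexicographic tie-break. This is a screening
device to keep the stepwise search small and stable; the threshold is
configurable and deliberately loose relative to the final selection.

**Combinatorial selection.** Bidirectional stepwise OLS minimising AIC over
the candidate indicator columns, with the refined miRNA indicator forced
into every model. Candidates are examined in prefilter order and the
first-encountered best move wins ties, so the selection is deterministic.
An intercept is always included: log-ratio data are not guaranteed
zero-centred, and with an intercept the indicator coefficients read as
mean shifts relative to background. Exactly collinear candidate columns
are dropped (the later-ordered column loses) with a warning.

Mediating TFs are retained TFs that are putative targets of the perturbed
miRNA (library membership). They are not additionally required to pass the
refinement test themselves: mediation is a wiring property, and demanding
refinement would silently drop mediators whose own down-shift is masked by
their targets' compensation.

## Parallel engine

Per mRNA row g: stepwise OLS of E_g on the measured profiles of its
library-candidate TFs (their own mRNA rows) and miRNAs; per miRNA row m:
the same over its candidate TFs. Candidate order is TFs then miRNAs, each
lexicographic. After selection, survivors must reach coefficient p ≤ 0.05
(configurable). When a response has more candidates than the conditions can
support, the candidate list is truncated to the top (n_conditions − 2) by
univariate |Pearson correlation| with the response, with a warning;
zero-variance profiles are dropped. No multiple-testing correction is
applied across the thousands of per-response regressions — the survivor
threshold is per-edge, and genome-wide FDR control is left to the user's
interpretation of the p-value column in the edge list.

No sign constraint is imposed on miRNA → gene coefficients by default;
an optional repression-only filter drops positive ones, since degradation
mechanistically predicts negative signs but measured positives can reflect
indirect effects. Expression values are used as given: normalisation is the
user's responsibility.

## Topology

**Rankings.** Betweenness uses the directed graph with unweighted shortest
paths (regression coefficients are strengths, not distances); each ordered
source–target pair contributes the fraction of its shortest paths through
the vertex or edge, with no global pair-count rescaling. Ties rank
lexicographically.

**Co-regulating pairs.** For every ordered-by-identifier pair of regulators
(out-degree ≥ 1), a one-sided Fisher's exact test of target overlap. The
universe is the set of regulated nodes of the *inferred* network (in-degree
≥ 1), not the genome: the question answered is whether two regulators share
targets more than expected within this network. The p-value is the
hypergeometric upper tail of the shared count.

**Motif catalog.** A motif is a typed 3-vertex digraph in which every
vertex pair is joined by at least one directed edge ("closed circuit";
mutual edges allowed where both directions are type-legal), edges obey the
type rules, and the composition includes ≥ 1 TF and ≥ 1 miRNA. Two motifs
are the same type iff a type-preserving vertex permutation maps one edge
set onto the other. Exhaustive enumeration gives exactly 18 types:
3 for {TF, miRNA, gene} (the TF–miRNA pair can be wired 3 ways; the two
gene in-edges are forced) and 15 for {TF, TF, miRNA} (3×3×3 pair options
reduced by the TF-swap symmetry: (27 + 3)/2). Compositions with two miRNAs
are impossible since the miRNA–miRNA pair cannot be joined. A motif is a
feed-backward loop (FBL) iff it contains a directed cycle — a mutual pair
or a 3-cycle — and a feed-forward loop (FFL) otherwise.

**Counting.** Each unordered vertex triple whose induced subgraph is a
closed circuit is counted once under its canonical type. Enumeration walks
the triangles of the undirected projection, so cost scales with the number
of connected triples rather than C(n,3).

**Null model.** Degree-preserving double edge swaps performed within each
edge class separately: swap (a→b, c→d) to (a→d, c→b) unless it creates a
self-loop or duplicates an ordered pair. Because classes are shuffled
separately, every node's typed in/out degree and every class's edge count
are preserved exactly, and all rewired edges remain type-legal. Defaults:
1000 replicates, 10×|edges| swap attempts per class (a standard mixing
budget at these densities); classes with < 2 edges stay fixed with a
warning. The empirical enrichment p is (1 + #{null ≥ observed}) /
(1 + replicates) — upper tail only; depletion is visible in the null mean
column but is not assigned a p-value.

## Synthetic generators

The generators emit the same containers and file formats the engines read,
with planted truth for scoring. They emulate the engines' own generative
assumptions — additive linear regulation, Gaussian noise, binary library
membership with decoys — and deliberately nothing else: no probe effects,
no normalisation artifacts, no correlated noise, no sequence realism.
Passing recovery tests therefore demonstrates correctness of the inference
machinery under its stated model, not robustness to real-data violations
of that model.

`gen_mpge` defaults: 2000 genes, 50 true miRNA targets shifted by −2, 50
decoy library targets with zero shift, three mediating TFs with
coefficients (+1.0, −1.0, +0.8) and 60 targets each, seven decoy TFs, noise
sd 0.5. Mediating TFs appear as dataset rows and are themselves degraded
(their log-ratio includes the miRNA effect), which is what makes them
mediators rather than independent regulators. The magnitudes mirror a
strong transfection experiment where the direct effect exceeds secondary
TF effects.

`gen_parallel` defaults: 60 conditions, 30 TFs, 20 miRNAs, 150 genes, mean
in-degree 1.5 (0–3 regulators per target, binomial), coefficient magnitudes
uniform on [0.5, 2] with random signs, noise sd 0.5, decoy:planted library
ratio 1:1. TF profiles are i.i.d. standard normal across conditions
(exogenous drivers); miRNAs with planted TF drivers are their linear
combination plus residual noise, while undriven miRNAs get unit intrinsic
variance — a flat profile would make their own targets unidentifiable, and
a regulator with no variation carries no information in any case.

Degenerate input handling: at `noise_sd = 0` a TF-driven miRNA profile is an
*exact* linear combination of its drivers, so a gene planted with both the
miRNA and one of its drivers would have a rank-deficient design that no
method can resolve; the zero-noise generator therefore skips planted
regulator sets that do not add rank. Noisy conditions are unaffected.

## Numerical choices

* AIC is computed as n·log(RSS/n) + 2k (k including the intercept);
  constant terms cancel in comparisons. RSS is floored at 1e−20 times the
  response sum of squares so that all numerically-exact fits share one
  log-term and the 2k penalty (not floating-point junk in a zero residual)
  breaks ties among them — this is what makes zero-noise recovery exact.
* For an exact fit (RSS at the floor), coefficient p-values are 0 for
  nonzero coefficients and 1 otherwise.
* Stepwise ties (equal AIC improvements) resolve to the first move in
  candidate order; candidate order itself is always deterministic
  (prefilter order in the MPGE engine; TFs-then-miRNAs lexicographic in
  the parallel engine), so fixed inputs give byte-identical outputs.
* All randomness (shuffles, generators) flows through
  `numpy.random.default_rng` seeds supplied by the caller.

## Problem sizes used by the test suite and acceptance script

Unit and property tests run on fixtures of 10–3000 genes, networks of
≤ 50 nodes (where brute-force oracles — exhaustive triple enumeration,
all-pairs shortest-path counting, 1e5-shuffle permutation tests, exhaustive
best-subset regression — remain exact and fast). The acceptance script
scores ten replicate seeds of each engine at the generator defaults above.
These sizes were chosen so the whole battery completes in a few minutes on
one core while every statistical claim is still measured, not assumed.

## Limitations

* Linear additive regulation only; saturation, synergy and combinatorial
  logic beyond additivity are invisible to both engines.
* Stepwise selection inherits the usual caveats: p-values of survivors are
  conditional on selection and optimistic; the edge p-value column should
  be read as a ranking score, not a calibrated error rate.
* The indicator-based MPGE design cannot separate two TFs with identical
  target sets in the dataset (exact collinearity; the later-ordered one is
  dropped).
* The motif null model conditions on typed degree sequences within edge
  classes; other null choices (e.g. preserving mutual-edge counts) would
  shift motif p-values.
* Library quality bounds everything: regulations absent from the libraries
  can never be recovered, and the co-regulation universe is the inferred
  network, so its p-values are conditional on the inference step.
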