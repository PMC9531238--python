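# Methods

## Scope and model

`mtgnet` implements the analysis core of a miRNA–TF–target-gene
co-regulatory study on a two-group transcriptome design: differential
expression of miRNA and mRNA counts, set-logic derivation of four
regulatory-pair classes from external prediction evidence, construction
of a typed directed regulatory network and a confidence-filtered PPI
network, topological key-node scoring, and exhaustive three-node motif
enumeration. External databases (miRNA target predictors, ChIP-evidence
TF-target catalogs, promoter-scanning TF predictors, PPI resources) are
represented as user-supplied tables; the package takes no network access
and performs no sequence analysis.

## Differential expression

Counts for feature *g* in sample *s* are modelled as negative binomial
with mean μ and variance μ + φμ², the parameterization shared by DESeq2
and edgeR. The test is a Wald test on the log2 fold change of
library-size-normalized group means:

- size factors are total counts scaled to mean 1 (a deliberate
  simplification relative to DESeq2's median-of-ratios; adequate when DE
  is composition-balanced, see Limitations);
- log2FC = log₂((m₂+½)/(m₁+½)) with pseudocount ½ to avoid infinities on
  zero counts;
- the dispersion is a single **common** value: the mean over features of
  per-feature method-of-moments estimates (s² − m)/m², themselves pooled
  across the two groups, floored at 1e−8. At n = 3 per group a purely
  per-feature moment estimate is so variable that the normal-reference
  Wald test rejects ~12–13% of null features at α = 0.05; sharing the
  dispersion across features removes the estimation noise and restores
  calibration (measured type-I ≈ 0.05–0.06 over 2,000 null features at
  φ = 0.1). The cost is an assumption of homogeneous dispersion across
  features — appropriate for the synthetic data this package validates
  against, and stated as a limitation for real data;
- Wald z = log2FC / SE with delta-method SE
  SE = (1/ln 2)·√(V₂/(m₂+½)² + V₁/(m₁+½)²), V_j = (m_j + φ̂m_j²)/n_j,
  and a two-sided normal p-value. A feature with zero SE and zero
  log2FC gets p = 1.

Calls use strict inequalities exactly as the thresholds are phrased:
`up` iff log2FC > 1 and P < 0.05, `down` iff log2FC < −1 and P < 0.05;
boundary values are `ns`. The low-expression filter retains a feature
iff its mean normalized value across **all** samples (per-group means
would be an alternative reading; all-samples is the documented default)
is ≥ 0.05 RPM (miRNA) or ≥ 1 TPM (mRNA) — a mean exactly at the cutoff
is retained. No multiple-testing correction is applied in DE calling
(the downstream set logic consumes raw-P calls); BH-adjusted values are
available in the enrichment module.

`ddct` implements relative quantification for qPCR validation:
2^−((Ct_target,treated − Ct_ref,treated) − (Ct_target,control − Ct_ref,control)).

## Regulatory pairs

All derivations are pure set operations, idempotent and invariant to
input duplication; provenance (supporting database names) accumulates
through merges.

- **DETFs** = DEGs ∩ TF catalog.
- **miRNA targets** from multi-database prediction tables, kept when
  supported by ≥ `min_db_support` distinct databases (default 1, i.e.
  union — the overlap the derivation emphasizes is with the DEG set, not
  among databases; configurable to 2 or 3).
- **TF targets** require a numeric evidence score ≥ 4.0; rows scoring
  lower or lacking a score are excluded (boundary kept).
- **TF→miRNA** evidence is a table of promoter binding hits filtered by
  strand-aware promoter windows around each miRNA TSS: [TSS−5000,
  TSS+1000] on +, [TSS−1000, TSS+5000] on −, 1-based inclusive, clipped
  at position 1. No score filter is applied to promoter hits.
- **Pair classes**: the regulator must be differentially expressed (DEM
  or DETF) and the target must lie in the class filter set (DEGs for
  miRNA-gene/TF-gene, DETFs for miRNA-TF, DEMs for TF-miRNA). Because a
  DETF is simultaneously a DEG, one predicted miRNA→TF relation
  legitimately yields both a miRNA-gene and a miRNA-TF pair.
- **Jointly regulated genes** = miRNA-target set ∩ TF-target set ∩ DEGs.

## Networks

The M-T-G network is a directed multigraph keyed by edge class (at most
one edge per (source, target, class)); node kinds are miRNA/TF/gene with
TF taking precedence over gene for dual-identity nodes, and any other
kind conflict is an error. Metrics and motif enumeration operate on the
collapsed simple digraph (who regulates whom), so a dual-class relation
counts once topologically. The PPI network keeps edges with confidence
≥ 0.7 (strictly lower removed) and drops isolated nodes.

## Key-node scoring

Directed metrics: total degree, outdegree, harmonic closeness
(Σ_u 1/d(v,u), well-defined on disconnected graphs), Brandes
betweenness over directed shortest paths (unnormalized), average
shortest path length over reachable nodes (absent when none are
reachable; negated before standardization since smaller is more
central), neighborhood connectivity (mean total degree over the union
of in- and out-neighbors), and motif occurrence. Each metric is
standardized within node kind using the **population** SD (the scored
pool is the full candidate population, not a sample); zero SD gives
z = 0, and the composite Z is the mean of the z-values present. Top-k
selection (10 TFs, 5 miRNAs) breaks ties lexicographically by node id.

PPI hub genes use MCC — Σ over maximal cliques containing the node of
(|C|−1)!, computed by exact Bron–Kerbosch enumeration and guarded by a
5,000-node limit; an isolated node scores 0 and a node with an
edge-free neighborhood scores its degree — and MNC, the size of the
largest connected component of the open neighborhood, together with
degree, unnormalized betweenness and harmonic closeness. Genes are
ranked by the mean of per-metric ranks (1 = best, ties averaged), top 7
selected, ties by id.

The published key-node tables carry Z-scores whose exact combination
rule was not specified by their source; the within-kind
standardize-orient-average rule above is this package's documented
reconstruction, and the packaged table fixtures are therefore used as
selection-test inputs, not as recomputation targets. Likewise the
fixture "occurrences" column is stored verbatim (its units for miRNAs
are not reconstructible).

## Motif enumeration

Exhaustive scan over kind-consistent ordered triples (m, t, g):

| kind | required edges |
|---|---|
| miRNA-FFL | m→t, m→g, t→g |
| TF-FFL | t→m, m→g, t→g |
| composite | m→t, t→m, m→g, t→g |

A triple satisfying the composite condition is reported as composite
only — FFL and composite lists are disjoint. A configuration flag
relaxes the composite definition to the bare mutual m⇄t pair plus at
least one gene-directed edge. Edge sign (miRNA edges as repression) is
annotation only and never affects membership. Output order is
deterministic (kind, then ids). Occurrence(v) = number of motif
instances containing v, satisfying Σ_v occ(v) = 3 × #motifs.

## Enrichment

Over-representation uses the upper hypergeometric tail
p = Σ_{j≥k} C(K,j)C(N−K,n−j)/C(N,n) via `scipy.stats.hypergeom`; the
universe defaults to all annotated genes, query genes outside it are
dropped with a warning, and terms are significant at raw P < 0.01 (the
stated cutoff; BH-adjusted values are reported alongside but do not
gate).

## Synthetic data generator

The generator emulates the study conditions: two groups of **3**
samples, baseline mean **500** counts, NB dispersion **φ = 0.1**,
planted |log2FC| = **2** on a configurable fraction of features with
random sign (defaults chosen as typical desk-scale values for a
small-animal cortex RNA-seq design; the source study reports no
effect-size or dispersion estimates, so these are defaults, not
claims). One integer seed drives everything through a documented
split: each stage uses `default_rng(SeedSequence([seed, stage_code]))`
with fixed stage codes, so outputs are byte-identical across reruns and
stages are decoupled.

Planted structure: a TF subset of the genes, ≥ 1 motif of each kind
(miRNA-FFL, TF-FFL, composite, up to 6 total) on disjoint
(miRNA, TF, non-TF gene) triples, plus background regulator→gene edges.
Background edges are constrained — each background gene receives edges
from only one regulator kind, and no background miRNA↔TF edges are
drawn — so the motif set of the true-edge graph is exactly the planted
list, which is what makes exact end-to-end recovery a meaningful
oracle. Evidence tables report each true edge per database with
probability `prediction_sensitivity` and false pairs (uniform over
non-edges, capped at 10× the true-edge count) with probability
`prediction_fpr`; true TF-target rows score uniform [4, 8] (always
passing the 4.0 filter), false ones uniform [0, 8]. True TF→miRNA
edges appear as promoter hits placed inside the miRNA's window; false
hits scatter within ±20 kb of the TSS so the window filter has real
work. PPI edges among planted motif genes form a clique with
confidence ≥ 0.7; background pairs draw from `ppi_confidence_range`.

What the generator does **not** emulate: read-level artifacts (GC/length
bias, mapping ambiguity), correlated features, heterogeneous per-feature
dispersions, database-specific biases, or indirect/chained regulation.
Passing the planted-recovery and calibration suites therefore
demonstrates correctness of the set logic, graph algorithms and test
statistics under the stated model — not robustness to real-data
violations of it.

## Validation design and problem sizes

- Graph metrics, MCC/MNC and motif enumeration are checked for exact
  agreement against independent brute-force oracles (Floyd–Warshall
  distances, DFS path enumeration, vertex-subset clique enumeration,
  union-find components, all-triples scan): exhaustively on every
  labeled digraph with ≤ 4 nodes, on 200 random 5-node digraphs, and on
  100 random 8–12-node typed graphs (full 5-node exhaustion — 2²⁰
  graphs — is beyond a sensible test budget; the sampled layer covers
  it).
- Planted recovery runs 20 seeds of the 50-gene/10-TF/8-miRNA noiseless
  configuration with every planted node DE and asserts 100%
  precision/recall on edges and motifs. Recovery conditions the
  pair/network/motif stages on the planted DE sets (the pipeline's
  `de_from_truth` oracle mode): with all features DE, total-count
  normalization absorbs part of the planted effect, so conditioning on
  estimated DE would measure DE power, not pair-logic correctness.
- DE calibration uses 2,000 null NB features and 500 signed ±2 effects
  among 2,500 features at n = 3/group, φ = 0.1. Effects are
  sign-balanced so that total-count size factors stay composition-
  neutral; an all-up design would confound the planted effect with the
  library size.

## Limitations

- The DE test is not DESeq2/edgeR: no shrinkage, no per-feature
  dispersion, no median-of-ratios normalization, no covariates. It
  preserves the NB model class and threshold semantics at desk scale;
  heterogeneous dispersions or composition-biased designs will degrade
  calibration and fold-change accuracy respectively.
- Exact clique enumeration limits MCC to moderate networks (guarded at
  5,000 nodes); no approximation is provided.
- Motif statistics are enumerative only — no null-model rewiring or
  enrichment Z against randomized networks.
- Coordinates are 1-based inclusive throughout; BED-style 0-based
  half-open inputs must be converted at the boundary.
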