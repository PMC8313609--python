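# Methods

## Problem setting

`psygset` compares diseases through their curated gene sets alone. A disease
is represented by the set of gene symbols associated with it in a
gene–disease association (GDA) table; no expression data enter the analysis.
The pipeline asks three questions: (i) which diseases are similar
(clustering on gene-set overlap); (ii) what characterises a cluster at each
level of biological organisation (overrepresentation of pathways, cell-type
markers, drug signatures and chromosomes, summarised by density indices);
and (iii) which level carries the similarity signal (partition concordance).

## Similarity and clustering

Similarity between diseases is the Jaccard index of their gene sets,
computed from integer intersection/union counts (exact; tested against
per-pair set arithmetic with zero tolerance). Two clustering routes operate
on the matrix:

* **Global route** — rows of the similarity matrix are feature vectors; PCA
  (full SVD, deterministic) column-centers and projects them, and k-means
  with 50 restarts and a fixed seed partitions the component scores. This is
  a reproducible surrogate for grouping diseases in the principal-component
  plane; the number of clusters is a parameter (default 3), not estimated.
* **Local route** — agglomerative clustering on distance 1 − J. Average
  linkage is the default (the common choice for similarity-derived
  distances); complete and Ward-on-distance are available. Dendrogram cuts
  use scipy's `cut_tree`, so cutting at k+1 always refines the cut at k, and
  cluster labels are renumbered by first appearance for determinism. The
  two-stage scheme — cut into branches, select a branch, re-cluster and cut
  into subgroups — is expressed in the pipeline config (`branch_k`,
  `select_branch`, `subgroup_k`); each stage is optional, since a cohort
  that is already focused needs no global narrowing.

## Overrepresentation

Each disease set (query, size n) is tested against every annotation set
(size K) over a background of N genes with the one-sided upper-tail
hypergeometric probability P(X ≥ k). This is the standard test for gene-set
overrepresentation; it is exact (scipy's survival function, validated
against rational tail sums and exhaustive draw enumeration). The drug level
is treated the same way — overlap between disease sets and drug signature
sets — deliberately ignoring signature direction, since curated GDA sets
carry no up/down information.

Multiple testing is controlled by Benjamini–Hochberg within each disease
across the annotations of one collection (each disease's profile is read on
its own); a single global family is available via `family="global"`. Pairs
with zero overlap carry p = 1 and belong to the BH family, but are not
emitted as rows — downstream code treats absence as non-significance, and
density values are invariant to whether zero-overlap rows are materialised.

The background defaults to the union of query and annotation universes; for
GDA data the recommended background is the full unfiltered gene universe of
the table (size filtering never shrinks it). Chromosome tests restrict the
background to genes with a chromosome assignment, because unmapped genes are
uninformative for chromosomal bias.

## Density index

For a theme T (a named group of annotations, via a many-to-one
annotation→theme map) over a disease set D at threshold q*:

    density(T, D) = #{(d, a) : d ∈ D, a ∈ T, q(d, a) < q*} / (|D| · |T|)

— the fill fraction of significant cells of the disease × theme-annotation
sub-matrix. It is 1 when every annotation of the theme is significant in
every disease, 0 when none is; a single annotation is the singleton-theme
special case (fraction of diseases significant). Merging themes yields the
annotation-count-weighted mean of the parts — an exact identity kept by
making theme membership single-valued. A weighted variant (mean over cells
of min(1, −log10 q / cap), cap 10) is available behind `method="weighted"`
for intensity-sensitive summaries; the binary form is the default and the
one all invariants are stated for. Flag thresholds for reporting
(0.5 pathways, 0.4 cell-types, 0.1 chromosomes) are presentation defaults
only and carry no inferential weight.

## Level attribution

To attribute inter-disease similarity to a level, diseases are embedded as
binary significance vectors over that level's annotations, clustered
agglomeratively on Jaccard distance between vectors, and cut at k (default:
the reference partition's cluster count, so comparisons run at matched
granularity). Diseases with no significant annotation cannot be embedded and
form one extra "unenriched" cluster rather than being dropped — dropping
would change the pair count C(n, 2) and invalidate cross-level comparison.

Agreement with the reference partition is the unadjusted Rand index
(fraction of disease pairs co-clustered in both or separated in both),
with the adjusted Rand index reported alongside for chance-corrected
context. Significance comes from a size-preserving label permutation of one
partition with the add-one estimator p = (1 + #{RI_perm ≥ RI_obs}) / (1 + B);
p is never exactly zero and is reproducible under a fixed seed. B defaults
to 10,000, resolving p-values down to ~1e-4. The estimator is calibrated:
for independent partitions the rejection rate at α = 0.05 sits within
binomial error of 0.05 (tested over 500 pairs at B = 199, where α(1+B) is an
integer so discreteness does not bias the level).

## Synthetic data

The generator emulates the pipeline's inputs with planted ground truth; it
is a fixture generator, not a model of any real GDA resource.

* **Gene universe and pools.** A universe of `gene_universe_size` symbols
  (default 2000) contains one shared pool (default 150 genes) and disjoint
  cluster-private pools (default 120 genes each).
* **Diseases.** Default 36 diseases in 4 clusters of 8/11/11/6 — the subgroup
  sizes of the psychiatric-cohort use case this package grew out of. Each
  disease has exactly `genes_per_disease` (80) distinct genes: a
  `core_fraction` (0.7) draw from its cluster pool, a `shared_fraction`
  (0.2) draw from the shared pool, the remainder uniform from unused
  universe genes, all without replacement. With core_fraction 1 and
  shared_fraction 0, between-cluster Jaccard is exactly 0 — the maximal
  separation used for exact-recovery tests.
* **Annotations.** A theme is n pathway sets sampled from one pool; pathway
  size defaults to 80% of the pool, giving pathways that overlap the pool
  heavily without duplicating it. Shared-pool themes are enriched in every
  disease (ubiquitous, the planted analogue of a process common to the whole
  cohort); cluster-pool themes only in their cluster.
* **Chromosomes.** Uniform assignment over `chromosome_count` (23)
  chromosomes; an optional bias sends one cluster's pool to one chromosome
  with probability w/(w + C − 1).
* **Drugs.** Signatures sampled from designated pools with a round-robin
  drug→mode-of-action map.
* **Determinism.** Every draw comes from a per-component, per-item
  substream of a single seed (numpy `SeedSequence` spawn keys), so outputs
  are byte-identical under a fixed seed and adding diseases, themes or drugs
  never perturbs earlier items.

What the generator does **not** emulate: GDA evidence scores, gene-symbol
aliasing, the heavy-tailed size distribution of real disease gene sets,
annotation hierarchies (GO parent/child redundancy), or connectivity-style
drug matching. Passing tests therefore demonstrate correctness of the
machinery and detectability of planted structure at realistic sizes — not
biological conclusions about any real cohort.

## Study conditions used by tests and the acceptance script

Replicated studies run at the default 36-disease/4-subgroup conditions:
ubiquitous-theme density (5 shared + 4×3 private pathways), chromosome bias
(cluster 0 → chromosome 5, weight 50) with a matched unbiased null, level
attribution (pool-mirroring level vs a label-permuted noise level,
B = 999), clustering degradation over shared_fraction ∈ {0, 0.3, 0.6, 0.9}
with core_fraction = 1 − shared_fraction, and permutation calibration over
500 independent partition pairs of 40 items in 4 labels. Replicate counts
(50–100) keep every study's Monte-Carlo error well below the margins the
assertions use.

## Known limitations

* The level-attribution null permutes labels of one partition only; it does
  not model uncertainty in the clustering itself.
* Binary significance vectors discard effect-size information at the
  embedding step (by design, matching the density index's binary reading).
* k for every cut is user-specified; no model-selection criterion is
  provided.
* Gene identity is exact string match; symbol aliasing must be resolved
  upstream.
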