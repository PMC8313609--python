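# psygset

Gene-set based comparison of diseases: which disorders resemble each other,
at which level of biological organisation, and how strongly.

Curated gene–disease association (GDA) resources such as DisGeNET attach a
signature gene set to each disease. Because these sets are independent of any
expression experiment, they allow many disorders — e.g. a cohort of
psychiatric diseases and their comorbidities — to be compared simultaneously
without cross-study normalisation. `psygset` implements that top-down
workflow as a library:

1. **Ingest & filter** — build one gene set per disease from a long-format
   GDA table, keeping sets within a size window; the hypergeometric
   background stays the unfiltered gene universe.
2. **Similarity & clustering** — pairwise Jaccard similarity
   J(A,B) = |A∩B| / |A∪B| between disease gene sets; global clusters via PCA
   on the similarity matrix plus k-means, subgroups via agglomerative
   clustering on 1 − J with dendrogram cuts (the two-stage
   branch-then-subgroup scheme).
3. **Overrepresentation profiling** — each disease set is tested against any
   annotation collection (pathways, cell-type markers, drug signatures,
   chromosomes) with the one-sided hypergeometric test
   P(X ≥ k), X ~ Hypergeom(N, K, n), Benjamini–Hochberg corrected per
   disease.
4. **Density index** — for a theme T (a group of annotations) over a disease
   set D, density = #significant (disease, annotation) cells / (|D| · |T|):
   near 1 for processes shared by all diseases, near 0 for private ones.
5. **Level attribution** — re-cluster the diseases from each level's binary
   significance profile and compare with the reference partition via the
   Rand index, with a size-preserving label-permutation null and the add-one
   estimator p = (1 + #{RI_perm ≥ RI_obs}) / (1 + B).

A synthetic-data module generates GDA tables with planted disease clusters,
annotation themes (ubiquitous or cluster-private), drug signatures with
modes of action, and chromosome maps with planted bias, so every stage can
be validated against known ground truth.

## Worked example

```python
import psygset as pg
from sklearn.metrics import adjusted_rand_score

spec = pg.SyntheticSpec(seed=7)           # 36 diseases, 4 planted subgroups
table, truth = pg.generate_gda(spec)
collection = pg.build_gene_sets(table, min_size=1, max_size=10**6)
matrix = pg.jaccard_matrix(collection)
subgroups = pg.cut_tree(pg.hierarchical_cluster(matrix), k=4)
print(adjusted_rand_score(truth.to_array(), subgroups.to_array(truth.labels)))
# 1.0  — the planted subgroups are recovered exactly
```

Profiling the same cohort at the pathway level
(`python examples/02_pathway_density.py`) prints

```
theme densities over all 36 diseases (flag *: density >= 0.5):
  shared_theme   0.983 *
  theme_c1       0.306
  theme_c2       0.306
  theme_c0       0.222
  theme_c3       0.167
```

The theme planted in the pool that every disease samples from is significant
in almost every disease (density 0.983, flagged at the 0.5 threshold),
whereas each subgroup-private theme reaches only its subgroup's share of the
cohort. `examples/04_level_attribution.py` then shows the concordance step:

```
  mirrored   RI=1.000 ARI=1.000 p=0.001 (null mean RI 0.632)
  noise      RI=0.644 ARI=0.033 p=0.218 (null mean RI 0.633)
```

The annotation level that mirrors the gene-set clusters reproduces the
reference partition exactly; a label-permuted noise level sits at the
permutation null. The remaining examples cover chromosome-bias detection and
the end-to-end pipeline (`psygset run --config config.yaml`), which writes
every stage artifact plus a checksummed manifest for byte-identical reruns.

## Command line

A thin CLI mirrors the library: `psygset simulate | ingest | similarity |
cluster | enrich | density | concordance | run | report` (see `--help` on
each subcommand).

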