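"""Attribute inter-disease similarity to the biological level that drives it.

Builds two annotation levels for the same cohort: one whose annotation sets
mirror the planted gene-set clusters (each subgroup's gene pool is an
annotation) and one 'noise' level in which the same enrichment profile is
assigned to randomly permuted diseases. Re-clusters the diseases from each
level's significance profile and compares the result with the reference
partition via the Rand index plus a permutation p-value.
"""
import numpy as np

import psygset as pg

spec = pg.SyntheticSpec(seed=7, core_fraction=1.0, shared_fraction=0.0)
table, truth = pg.generate_gda(spec)
collection = pg.build_gene_sets(table, min_size=1, max_size=10**6)

mirror = pg.GeneSetCollection(
    sets={f"pool{c}": frozenset(spec.cluster_pool(c)) for c in range(4)},
    universe=frozenset(spec.universe),
)
mirrored = pg.enrich(collection, mirror, background=frozenset(spec.universe))

rng = np.random.default_rng(1)
ids = list(collection.names)
relabel = dict(zip(ids, rng.permutation(ids)))
noise = mirrored.copy()
noise["disease_id"] = noise["disease_id"].map(relabel)
noise.attrs = dict(mirrored.attrs)

results, pairwise = pg.attribute_levels(
    truth, {"mirrored": mirrored, "noise": noise}, n_permutations=999, seed=0
)
print("level ranking by Rand-index concordance with the reference partition:")
for r in results:
    print(f"  {r.level:<10s} RI={r.rand_index:.3f} ARI={r.adjusted_rand:.3f} "
          f"p={r.p_value:.4g} (null mean RI {r.perm_mean:.3f})")
print()
print("The level that mirrors the gene-set clusters reproduces the reference")
print("partition exactly (RI=1, minimal permutation p); the label-permuted")
print("noise level is indistinguishable from the permutation null.")
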