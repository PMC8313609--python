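"""Synthetic gene–disease association data with planted structure.

The generator emulates the inputs of the full pipeline — a long-format GDA
table, annotation collections (pathways grouped into themes, drug signatures
with modes of action) and a gene→chromosome map — with known ground truth:

* diseases fall into planted clusters, each drawing a tunable fraction of its
  genes from a cluster-private pool;
* a universal ("shared") pool, sampled by every disease, creates a ubiquitous
  annotation theme analogous to a biological process affected across all
  diseases in a cohort;
* a chromosome bias can be planted for one cluster's pool.

Every output is deterministic given the spec's seed. Each disease draws from
its own random substream, so adding diseases never perturbs earlier ones.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .io import DiseaseGeneTable, GeneSetCollection
from .similarity import Partition


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-cluster GDA generator.

    ``core_fraction`` of each disease's genes come from its cluster-private
    pool, ``shared_fraction`` from the universal pool, and the remainder
    uniformly from the rest of the gene universe.
    """

    n_diseases: int = 36
    n_clusters: int = 4
    cluster_sizes: tuple[int, ...] = (8, 11, 11, 6)
    gene_universe_size: int = 2000
    core_pool_size: int = 120
    genes_per_disease: int = 80
    core_fraction: float = 0.7
    shared_pool_size: int = 150
    shared_fraction: float = 0.2
    chromosome_count: int = 23
    biased_chromosome: tuple[int, int, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "cluster_sizes", tuple(self.cluster_sizes))
        for name in ("n_diseases", "n_clusters", "gene_universe_size",
                     "core_pool_size", "genes_per_disease", "shared_pool_size",
                     "chromosome_count"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be a positive count")
        if len(self.cluster_sizes) != self.n_clusters:
            raise ValidationError("cluster_sizes length must equal n_clusters")
        if any(s < 1 for s in self.cluster_sizes):
            raise ValidationError("cluster_sizes entries must be positive")
        if sum(self.cluster_sizes) != self.n_diseases:
            raise ValidationError("cluster_sizes must sum to n_diseases")
        if not 0 <= self.core_fraction <= 1:
            raise ValidationError("core_fraction must lie in [0, 1]")
        if not 0 <= self.shared_fraction <= 1:
            raise ValidationError("shared_fraction must lie in [0, 1]")
        if self.core_fraction + self.shared_fraction > 1 + 1e-12:
            raise ValidationError("core_fraction + shared_fraction must not exceed 1")
        pools_total = self.n_clusters * self.core_pool_size + self.shared_pool_size
        if pools_total > self.gene_universe_size:
            raise ValidationError(
                "gene_universe_size too small for disjoint cluster pools plus "
                f"the shared pool ({pools_total} > {self.gene_universe_size})"
            )
        if self.genes_per_disease > self.gene_universe_size:
            raise ValidationError("genes_per_disease exceeds gene_universe_size")
        n_core, n_shared, _ = self._draw_counts()
        if n_core > self.core_pool_size:
            raise ValidationError("core_fraction × genes_per_disease exceeds core_pool_size")
        if n_shared > self.shared_pool_size:
            raise ValidationError("shared_fraction × genes_per_disease exceeds shared_pool_size")
        if self.biased_chromosome is not None:
            cluster, chrom, weight = self.biased_chromosome
            if not 0 <= cluster < self.n_clusters:
                raise ValidationError("biased_chromosome cluster id out of range")
            if not 0 <= chrom < self.chromosome_count:
                raise ValidationError("biased_chromosome chromosome id out of range")
            if weight < 1:
                raise ValidationError("biased_chromosome bias weight must be >= 1")

    def _draw_counts(self) -> tuple[int, int, int]:
        n_core = int(round(self.core_fraction * self.genes_per_disease))
        n_shared = int(round(self.shared_fraction * self.genes_per_disease))
        if n_core + n_shared > self.genes_per_disease:
            n_shared = self.genes_per_disease - n_core
        return n_core, n_shared, self.genes_per_disease - n_core - n_shared

    # --- deterministic universe layout -------------------------------------
    @property
    def universe(self) -> tuple[str, ...]:
        width = len(str(self.gene_universe_size))
        return tuple(f"G{i:0{width}d}" for i in range(self.gene_universe_size))

    @property
    def shared_pool(self) -> tuple[str, ...]:
        return self.universe[: self.shared_pool_size]

    def cluster_pool(self, cluster: int) -> tuple[str, ...]:
        if not 0 <= cluster < self.n_clusters:
            raise ValidationError(f"cluster id {cluster} out of range")
        start = self.shared_pool_size + cluster * self.core_pool_size
        return self.universe[start: start + self.core_pool_size]

    def pool(self, name: str | int) -> tuple[str, ...]:
        """Resolve a pool reference: 'shared' or a cluster index."""
        if name == "shared":
            return self.shared_pool
        if isinstance(name, int):
            return self.cluster_pool(name)
        raise ValidationError(f"unknown pool reference {name!r} (use 'shared' or a cluster id)")

    def disease_labels(self) -> list[tuple[str, int]]:
        """(disease id, planted cluster) pairs; ids are 'D<cluster>_<index>'."""
        out = []
        for cluster, size in enumerate(self.cluster_sizes):
            for j in range(size):
                out.append((f"D{cluster}_{j}", cluster))
        return out


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def generate_gda(spec: SyntheticSpec) -> tuple[DiseaseGeneTable, Partition]:
    """Generate the GDA table and the planted disease→cluster labels.

    Each disease's gene set has exactly ``genes_per_disease`` distinct genes,
    sampled without replacement: a core draw from its cluster pool, a shared
    draw from the universal pool, and a uniform remainder from unused
    universe genes.
    """
    n_core, n_shared, n_rest = spec._draw_counts()
    universe = np.array(spec.universe)
    records: list[tuple[str, str, str]] = []
    labels: list[str] = []
    codes: list[int] = []
    for idx, (disease_id, cluster) in enumerate(spec.disease_labels()):
        rng = _rng(spec.seed, 0, idx)
        chosen: list[str] = []
        chosen.extend(rng.choice(spec.cluster_pool(cluster), size=n_core, replace=False))
        chosen.extend(rng.choice(spec.shared_pool, size=n_shared, replace=False))
        if n_rest:
            taken = set(chosen)
            remaining = universe[[g not in taken for g in universe]]
            chosen.extend(rng.choice(remaining, size=n_rest, replace=False))
        for gene in chosen:
            records.append((disease_id, disease_id, str(gene)))
        labels.append(disease_id)
        codes.append(cluster)
    table = DiseaseGeneTable.from_records(records)
    return table, Partition.from_array(labels, codes)


@dataclass(frozen=True)
class ThemeSpec:
    """One annotation theme: ``n_pathways`` gene sets drawn from one pool.

    ``pool`` is 'shared' (→ a ubiquitous theme enriched in every disease) or
    a cluster index (→ a cluster-private theme). ``pathway_size`` defaults to
    80% of the pool, giving pathways that overlap heavily with the pool
    without being identical.
    """

    name: str
    pool: str | int
    n_pathways: int
    pathway_size: int | None = None


def generate_annotations(
    spec: SyntheticSpec, themes: Sequence[ThemeSpec]
) -> tuple[GeneSetCollection, dict[str, str]]:
    """Generate a pathway collection plus its pathway→theme map."""
    sets: dict[str, frozenset[str]] = {}
    theme_map: dict[str, str] = {}
    for t_idx, theme in enumerate(themes):
        pool = np.array(spec.pool(theme.pool))
        size = theme.pathway_size
        if size is None:
            size = max(1, int(round(0.8 * len(pool))))
        if size > len(pool):
            raise ValidationError(
                f"theme {theme.name!r}: pathway_size {size} exceeds pool size {len(pool)}"
            )
        for p_idx in range(theme.n_pathways):
            rng = _rng(spec.seed, 1, t_idx, p_idx)
            name = f"{theme.name}_p{p_idx}"
            if name in sets:
                raise ValidationError(f"duplicate pathway name {name!r}")
            sets[name] = frozenset(str(g) for g in rng.choice(pool, size=size, replace=False))
            theme_map[name] = theme.name
    return GeneSetCollection(sets=sets, universe=frozenset(spec.universe)), theme_map


def generate_chromosome_map(spec: SyntheticSpec) -> dict[str, str]:
    """Assign every universe gene to one chromosome ('chr1'..'chrC').

    Unbiased genes are assigned uniformly. If ``biased_chromosome`` is set to
    (cluster, chromosome, weight), genes of that cluster's pool land on that
    chromosome with probability weight/(weight + C − 1).
    """
    n_chrom = spec.chromosome_count
    chrom_names = [f"chr{i + 1}" for i in range(n_chrom)]
    rng = _rng(spec.seed, 2)
    assignment = rng.integers(0, n_chrom, size=spec.gene_universe_size)
    mapping = {gene: chrom_names[c] for gene, c in zip(spec.universe, assignment)}
    if spec.biased_chromosome is not None:
        cluster, chrom, weight = spec.biased_chromosome
        probs = np.full(n_chrom, 1.0)
        probs[chrom] = weight
        probs /= probs.sum()
        rng_bias = _rng(spec.seed, 2, 1)
        for gene in spec.cluster_pool(cluster):
            mapping[gene] = chrom_names[rng_bias.choice(n_chrom, p=probs)]
    return mapping


def generate_drug_signatures(
    spec: SyntheticSpec,
    n_drugs: int,
    moa_count: int,
    pool: str | int | Sequence[str | int] = "shared",
    signature_size: int | None = None,
) -> tuple[GeneSetCollection, dict[str, str]]:
    """Generate drug signature gene sets and a drug→mode-of-action map.

    ``pool`` designates the sampling pool for all drugs, or one pool per
    drug. Drugs are assigned round-robin to MOA labels, so every MOA is used
    and each drug has exactly one MOA.
    """
    if moa_count < 1:
        raise ValidationError("moa_count must be >= 1")
    if n_drugs < moa_count:
        raise ValidationError(f"n_drugs ({n_drugs}) must be >= moa_count ({moa_count})")
    if isinstance(pool, (str, int)):
        pools: list[str | int] = [pool] * n_drugs
    else:
        pools = list(pool)
        if len(pools) != n_drugs:
            raise ValidationError("per-drug pool list length must equal n_drugs")
    if signature_size is None:
        signature_size = spec.genes_per_disease
    sets: dict[str, frozenset[str]] = {}
    moa_map: dict[str, str] = {}
    for d_idx in range(n_drugs):
        members = np.array(spec.pool(pools[d_idx]))
        size = min(signature_size, len(members))
        rng = _rng(spec.seed, 3, d_idx)
        name = f"drug{d_idx}"
        sets[name] = frozenset(str(g) for g in rng.choice(members, size=size, replace=False))
        moa_map[name] = f"MOA{d_idx % moa_count}"
    return GeneSetCollection(sets=sets, universe=frozenset(spec.universe)), moa_map
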