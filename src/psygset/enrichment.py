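"""Hypergeometric overrepresentation analysis with BH false-discovery control.

Each disease gene set (query) is tested against every annotation set in a
collection — pathways, cell-type markers, drug signatures, or chromosomes —
with the one-sided upper-tail hypergeometric test: given a background of N
genes of which K carry the annotation, the probability of observing at least
k annotated genes in a query of size n drawn without replacement.

q-values are Benjamini–Hochberg adjusted. The correction family is, by
default, all annotations tested for one disease (each disease's profile is
interpreted on its own); a single global family across all (disease,
annotation) tests is available via ``family='global'``. Pairs with zero
overlap carry p = 1; they participate in the BH family but are not emitted
as rows, so downstream consumers treat absence as non-significance.
"""
from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import GeneSetCollection

logger = logging.getLogger(__name__)

#: Columns of an enrichment table.
ENRICHMENT_COLUMNS = [
    "disease_id", "annotation", "k", "n", "K", "N",
    "p_value", "q_value", "significant", "overlap_genes",
]


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= k).

    X counts annotated genes in a size-``n`` draw without replacement from a
    background of ``N`` genes containing ``K`` annotated ones.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValidationError(
            f"inconsistent counts: k={k}, n={n}, K={K}, N={N} "
            "(need 0 <= K <= N, 0 <= n <= N, 0 <= k <= min(n, K))"
        )
    if k == 0:
        return 1.0
    return float(min(1.0, hypergeom.sf(k - 1, N, K, n)))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (order-preserving)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    queries: GeneSetCollection,
    annotations: GeneSetCollection,
    background: Iterable[str] | None = None,
    q_threshold: float = 0.05,
    family: str = "per-disease",
) -> pd.DataFrame:
    """Overrepresentation of every annotation in every disease gene set.

    Genes outside the background are dropped (with a logged count) from both
    queries and annotations. Returns one row per (disease, annotation) pair
    with overlap k >= 1; see module docstring for the correction family.
    """
    if family not in ("per-disease", "global"):
        raise ValidationError(f"family must be 'per-disease' or 'global', got {family!r}")
    if background is None:
        background = queries.universe | annotations.universe
    background = frozenset(background)
    if not background:
        raise ValidationError("background universe is empty")

    genes = sorted(background)
    index = {g: i for i, g in enumerate(genes)}
    n_bg = len(genes)

    def incidence(collection: GeneSetCollection) -> tuple[list[str], np.ndarray, int]:
        names = collection.names
        mat = np.zeros((len(names), n_bg), dtype=np.int32)
        dropped = 0
        for row, name in enumerate(names):
            for g in collection.sets[name]:
                col = index.get(g)
                if col is None:
                    dropped += 1
                else:
                    mat[row, col] = 1
        return names, mat, dropped

    disease_ids, Q, q_dropped = incidence(queries)
    annot_names, A, a_dropped = incidence(annotations)
    if q_dropped or a_dropped:
        logger.info(
            "dropped genes outside background: %d from queries, %d from annotations",
            q_dropped, a_dropped,
        )

    overlap = Q @ A.T                      # (diseases × annotations) overlap counts
    n_query = Q.sum(axis=1)
    K_annot = A.sum(axis=1)
    # Vectorised exact tail: P(X >= k) = sf(k - 1)
    p = hypergeom.sf(overlap - 1, n_bg, K_annot[None, :], n_query[:, None])
    p = np.minimum(p, 1.0)
    p[overlap == 0] = 1.0

    if family == "per-disease":
        q = np.vstack([bh_adjust(row) for row in p])
    else:
        q = bh_adjust(p.ravel()).reshape(p.shape)

    rows = []
    gene_arr = np.array(genes)
    for i, j in zip(*np.nonzero(overlap)):
        members = gene_arr[(Q[i] & A[j]).astype(bool)]
        rows.append(
            (
                disease_ids[i], annot_names[j],
                int(overlap[i, j]), int(n_query[i]), int(K_annot[j]), n_bg,
                float(p[i, j]), float(q[i, j]), bool(q[i, j] < q_threshold),
                ";".join(sorted(members)),
            )
        )
    table = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)
    table.attrs["q_threshold"] = q_threshold
    table.attrs["family"] = family
    table.attrs["n_annotations_tested"] = len(annot_names)
    table.attrs["annotations"] = list(annot_names)
    table.attrs["diseases"] = list(disease_ids)
    return table


def chromosome_enrich(
    queries: GeneSetCollection,
    chromosome_map: Mapping[str, str],
    q_threshold: float = 0.05,
    family: str = "per-disease",
    background: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Chromosomal overrepresentation: each chromosome acts as an annotation set.

    The background (defaulting to the query collection's universe) is
    restricted to mapped genes; unmapped genes are uninformative for
    chromosomal bias and are dropped with a logged count.
    """
    if background is None:
        background = queries.universe
    mapped = frozenset(chromosome_map) & frozenset(background)
    n_unmapped = len(frozenset(background)) - len(mapped)
    if n_unmapped:
        logger.info("dropped %d background genes without a chromosome assignment", n_unmapped)
    if not mapped:
        raise ValidationError("no background gene has a chromosome assignment")
    by_chrom: dict[str, set[str]] = {}
    for gene in mapped:
        by_chrom.setdefault(chromosome_map[gene], set()).add(gene)
    chrom_sets = GeneSetCollection(
        sets={c: frozenset(g) for c, g in sorted(by_chrom.items())}, universe=mapped
    )
    restricted = GeneSetCollection(
        sets={d: s & mapped for d, s in queries.sets.items()}, universe=mapped
    )
    return enrich(restricted, chrom_sets, background=mapped,
                  q_threshold=q_threshold, family=family)


def drug_moa_summary(
    enrichment: pd.DataFrame,
    moa_map: Mapping[str, str],
    diseases: Sequence[str] | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Summarise a drug-signature enrichment table at the mode-of-action level.

    Returns (MOA frequency, per-drug density): the number of distinct
    significant drugs per MOA over the disease set, and for each drug the
    fraction of diseases in which its signature is significant.
    """
    if diseases is None:
        diseases = enrichment.attrs.get("diseases") or sorted(enrichment["disease_id"].unique())
    diseases = list(diseases)
    sig = enrichment[enrichment["significant"] & enrichment["disease_id"].isin(diseases)]
    missing = sorted(set(sig["annotation"]) - set(moa_map))
    if missing:
        raise ValidationError(f"significant drug(s) absent from the MOA map: {missing}")
    moa_freq = (
        sig.drop_duplicates("annotation")["annotation"].map(moa_map).value_counts()
    )
    moa_freq.name = "n_drugs"
    counts = Counter(sig.drop_duplicates(["disease_id", "annotation"])["annotation"])
    all_drugs = enrichment.attrs.get("annotations") or sorted(enrichment["annotation"].unique())
    density = pd.Series(
        {drug: counts.get(drug, 0) / len(diseases) for drug in all_drugs}, name="density"
    )
    return moa_freq, density


def significant_matrix(enrichment: pd.DataFrame, fill: float = 0.0) -> pd.DataFrame:
    """Diseases × annotations matrix of −log10(q) for significant pairs.

    Non-significant (or absent) pairs are ``fill`` — the heatmap-ready export
    in which colour intensity is proportional to −log10(q).
    """
    sig = enrichment[enrichment["significant"]]
    diseases = enrichment.attrs.get("diseases") or sorted(enrichment["disease_id"].unique())
    annotations = enrichment.attrs.get("annotations") or sorted(enrichment["annotation"].unique())
    mat = pd.DataFrame(fill, index=list(diseases), columns=list(annotations), dtype=float)
    for _, row in sig.iterrows():
        mat.loc[row["disease_id"], row["annotation"]] = -np.log10(row["q_value"])
    return mat


def write_enrichment_tsv(enrichment: pd.DataFrame, path) -> None:
    enrichment.to_csv(path, sep="\t", index=False)


def load_enrichment_tsv(path) -> pd.DataFrame:
    table = pd.read_csv(
        path, sep="\t",
        dtype={"disease_id": str, "annotation": str, "overlap_genes": str},
    )
    table["significant"] = table["significant"].astype(bool)
    table.attrs["diseases"] = list(dict.fromkeys(table["disease_id"]))
    table.attrs["annotations"] = list(dict.fromkeys(table["annotation"]))
    return table
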