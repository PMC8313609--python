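"""Disease–disease similarity and clustering.

Diseases are compared by the Jaccard index of their gene sets. The resulting
similarity matrix supports two clustering routes: a global one (PCA on the
matrix rows followed by k-means on the leading component scores) and a local
one (agglomerative clustering on 1 − Jaccard distances with dendrogram cuts),
mirroring the two-stage scheme in which a broad disease cluster is first
identified and then refined into branches and subgroups.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import ValidationError
from .io import GeneSetCollection

logger = logging.getLogger(__name__)

_LINKAGE_METHODS = {"average": "average", "complete": "complete", "ward-on-distance": "ward"}


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric disease × disease Jaccard matrix with unit diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("similarity matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValidationError("similarity matrix is not symmetric")
        if (v < 0).any() or (v > 1).any():
            raise ValidationError("similarity values must lie in [0, 1]")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="disease_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimilarityMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(labels=tuple(frame.index.astype(str)), values=frame.to_numpy(float))


@dataclass(frozen=True)
class Partition:
    """Assignment of items to cluster labels (small non-negative integers)."""

    labels: tuple[str, ...]
    assignment: Mapping[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        missing = [item for item in self.labels if item not in self.assignment]
        if missing:
            raise ValidationError(f"items without a cluster label: {missing[:5]}")
        object.__setattr__(
            self, "assignment", {item: int(self.assignment[item]) for item in self.labels}
        )

    @classmethod
    def from_array(cls, labels: Sequence[str], codes: Sequence[int]) -> "Partition":
        if len(labels) != len(codes):
            raise ValidationError("labels and codes differ in length")
        return cls(labels=tuple(labels), assignment=dict(zip(labels, map(int, codes))))

    def to_array(self, order: Sequence[str] | None = None) -> np.ndarray:
        order = self.labels if order is None else order
        return np.array([self.assignment[item] for item in order], dtype=int)

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, cluster: int) -> list[str]:
        return [item for item in self.labels if self.assignment[item] == cluster]

    def cluster_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for label in self.assignment.values():
            sizes[label] = sizes.get(label, 0) + 1
        return sizes

    def restrict(self, items: Sequence[str]) -> "Partition":
        return Partition(labels=tuple(items), assignment={i: self.assignment[i] for i in items})

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"disease_id": list(self.labels), "cluster": [self.assignment[i] for i in self.labels]}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Partition":
        frame = pd.read_csv(path, sep="\t", dtype={"disease_id": str, "cluster": int})
        return cls.from_array(list(frame["disease_id"]), list(frame["cluster"]))


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree over disease ids (scipy linkage encoding)."""

    labels: tuple[str, ...]
    linkage_matrix: np.ndarray
    method: str = "average"
    leaf_order: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        order = sch.leaves_list(self.linkage_matrix)
        object.__setattr__(self, "leaf_order", tuple(self.labels[i] for i in order))

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_newick(self) -> str:
        """Newick string with branch lengths = merge-height differences."""
        tree = sch.to_tree(self.linkage_matrix)

        def render(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        left = render(tree.left, tree.dist)
        right = render(tree.right, tree.dist)
        return f"({left},{right});"


def jaccard_matrix(collection: GeneSetCollection) -> SimilarityMatrix:
    """Pairwise Jaccard similarity J(A,B) = |A∩B| / |A∪B| between all gene sets.

    Computed with integer intersection/union counts, so results are exact.
    """
    if len(collection) < 2:
        raise ValidationError("need at least 2 gene sets to compare")
    for name, members in collection.sets.items():
        if not members:
            raise ValidationError(f"gene set {name!r} is empty")
    names = collection.names
    genes = sorted(frozenset().union(*collection.sets.values()))
    index = {g: i for i, g in enumerate(genes)}
    incidence = np.zeros((len(names), len(genes)), dtype=np.int64)
    for row, name in enumerate(names):
        cols = [index[g] for g in collection.sets[name]]
        incidence[row, cols] = 1
    inter = incidence @ incidence.T
    sizes = incidence.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    values = inter / union
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(labels=tuple(names), values=values)


def pca_cluster(
    matrix: SimilarityMatrix,
    n_components: int = 2,
    k: int = 3,
    seed: int = 0,
    n_init: int = 50,
) -> tuple[Partition, pd.DataFrame]:
    """Global clustering: PCA on similarity-matrix rows, k-means on the scores.

    Rows of the similarity matrix are the feature vectors (one disease's
    similarity profile against all diseases); PCA column-centers them and
    projects onto the top ``n_components`` axes; k-means with ``n_init``
    restarts and a fixed seed partitions the scores. Returns the partition
    and the per-disease principal-component scores.
    """
    n = len(matrix.labels)
    if not 2 <= n_components <= n:
        raise ValidationError(f"n_components must be in [2, {n}], got {n_components}")
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(matrix.values)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    codes = km.fit_predict(scores)
    codes = _relabel_by_first_appearance(codes)
    score_frame = pd.DataFrame(
        scores, index=list(matrix.labels),
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return Partition.from_array(matrix.labels, codes), score_frame


def hierarchical_cluster(matrix: SimilarityMatrix, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering on distance = 1 − Jaccard."""
    if linkage not in _LINKAGE_METHODS:
        raise ValidationError(
            f"linkage must be one of {sorted(_LINKAGE_METHODS)}, got {linkage!r}"
        )
    distance = 1.0 - matrix.values
    if not np.isfinite(distance).all():
        raise ValidationError("non-finite distances in similarity matrix")
    condensed = squareform(distance, checks=False)
    linkage_matrix = sch.linkage(condensed, method=_LINKAGE_METHODS[linkage])
    return Dendrogram(labels=matrix.labels, linkage_matrix=linkage_matrix, method=linkage)


def cut_tree(dendrogram: Dendrogram, k: int) -> Partition:
    """Cut the dendrogram into exactly ``k`` clusters.

    Cluster labels are renumbered by first appearance in input order, so the
    cut at k+1 refines the cut at k with stable numbering.
    """
    n = len(dendrogram.labels)
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    codes = sch.cut_tree(dendrogram.linkage_matrix, n_clusters=k).ravel()
    codes = _relabel_by_first_appearance(codes)
    return Partition.from_array(dendrogram.labels, codes)


def _relabel_by_first_appearance(codes: np.ndarray) -> np.ndarray:
    mapping: dict[int, int] = {}
    out = np.empty_like(codes)
    for i, code in enumerate(codes):
        if code not in mapping:
            mapping[code] = len(mapping)
        out[i] = mapping[code]
    return out
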