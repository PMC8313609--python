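"""Density indices: how widely an annotation theme is shared across diseases.

The density index of a theme over a disease set is the fill fraction of the
significant cells in the (disease × theme-annotation) sub-matrix:

    density = n_significant_pairs / (n_diseases × n_annotations)

A density near 1 marks a theme common to all diseases of the set; near 0, a
theme confined to a few. A single annotation is the singleton-theme special
case: the fraction of diseases in which it is significant. Rows absent from
the enrichment table (zero overlap) count as non-significant.

A weighted variant — the mean over cells of min(1, −log10(q)/cap) — is
available via ``method='weighted'``; the binary fill fraction is the default
and the form all invariants are stated for.
"""
from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .similarity import Partition

logger = logging.getLogger(__name__)

#: Columns of a density profile.
PROFILE_COLUMNS = [
    "theme", "disease_set", "density", "n_diseases", "n_annotations",
    "n_significant_pairs", "flagged",
]


def density_index(
    enrichment: pd.DataFrame,
    theme_map: Mapping[str, str],
    disease_set: Sequence[str],
    q_threshold: float = 0.05,
    disease_set_name: str = "all",
    method: str = "binary",
    weight_cap: float = 10.0,
) -> pd.DataFrame:
    """Per-theme density profile over ``disease_set``.

    ``theme_map`` (annotation → theme, many-to-one) must cover every
    annotation appearing in the enrichment table; the theme's annotation
    count is taken from the map, so untested annotations of a theme dilute
    its density only if they are listed in the map.
    """
    if method not in ("binary", "weighted"):
        raise ValidationError(f"method must be 'binary' or 'weighted', got {method!r}")
    diseases = list(dict.fromkeys(disease_set))
    if not diseases:
        raise ValidationError("disease_set is empty")
    uncovered = sorted(set(enrichment["annotation"]) - set(theme_map))
    if uncovered:
        raise ValidationError(f"annotations without a theme: {uncovered}")
    themes: dict[str, list[str]] = {}
    for annotation, theme in theme_map.items():
        themes.setdefault(theme, []).append(annotation)

    sub = enrichment[enrichment["disease_id"].isin(diseases)]
    sig = sub[sub["q_value"] < q_threshold]
    rows = []
    for theme, annotations in themes.items():
        if not annotations:
            raise ValidationError(f"theme {theme!r} has no annotations")
        cells = sig[sig["annotation"].isin(annotations)]
        cells = cells.drop_duplicates(["disease_id", "annotation"])
        n_pairs = len(diseases) * len(annotations)
        if method == "binary":
            density = len(cells) / n_pairs
        else:
            weights = np.minimum(1.0, -np.log10(cells["q_value"]) / weight_cap)
            density = float(weights.sum()) / n_pairs
        rows.append((theme, disease_set_name, density, len(diseases),
                     len(annotations), len(cells), False))
    profile = pd.DataFrame(rows, columns=PROFILE_COLUMNS)
    profile.attrs["q_threshold"] = q_threshold
    profile.attrs["method"] = method
    return profile


def single_annotation_density(
    enrichment: pd.DataFrame,
    annotation: str,
    disease_set: Sequence[str],
    q_threshold: float = 0.05,
    known_annotations: Sequence[str] | None = None,
) -> float:
    """Fraction of ``disease_set`` diseases in which ``annotation`` is significant.

    ``known_annotations`` (defaults to the annotations recorded on the
    enrichment table) guards against typos: an annotation outside it is an
    error, whereas a known annotation that is never significant has density 0.
    """
    if known_annotations is None:
        known_annotations = enrichment.attrs.get("annotations") or list(
            enrichment["annotation"].unique()
        )
    if annotation not in set(known_annotations):
        raise ValidationError(f"unknown annotation {annotation!r}")
    profile = density_index(
        enrichment[enrichment["annotation"] == annotation],
        {annotation: annotation},
        disease_set,
        q_threshold=q_threshold,
    )
    return float(profile["density"].iloc[0])


def flag_by_threshold(profile: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Flag profile rows with density >= threshold; records the threshold used."""
    if not 0 <= threshold <= 1:
        raise ValidationError(f"threshold must lie in [0, 1], got {threshold}")
    out = profile.copy()
    out["flagged"] = out["density"] >= threshold
    out.attrs = dict(profile.attrs)
    out.attrs["flag_threshold"] = threshold
    return out


def subgroup_profiles(
    enrichment: pd.DataFrame,
    theme_map: Mapping[str, str],
    partition: Partition,
    q_threshold: float = 0.05,
    method: str = "binary",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Density profiles per cluster plus an overall profile.

    Returns (profiles, correlation): a concatenated profile table with one
    block per cluster label (disease_set '<cluster>') plus the 'all' block,
    and the Pearson correlation matrix of theme-density vectors between
    subgroups.
    """
    diseases_in_table = set(enrichment["disease_id"])
    missing = sorted(diseases_in_table - set(partition.labels))
    if missing:
        raise ValidationError(f"diseases absent from the partition: {missing}")
    blocks = [
        density_index(enrichment, theme_map, list(partition.labels),
                      q_threshold=q_threshold, disease_set_name="all", method=method)
    ]
    by_cluster: dict[str, pd.Series] = {}
    for cluster in sorted(set(partition.assignment.values())):
        members = partition.members(cluster)
        block = density_index(enrichment, theme_map, members,
                              q_threshold=q_threshold,
                              disease_set_name=str(cluster), method=method)
        blocks.append(block)
        by_cluster[str(cluster)] = block.set_index("theme")["density"]
    profiles = pd.concat(blocks, ignore_index=True)
    profiles.attrs["q_threshold"] = q_threshold
    profiles.attrs["method"] = method
    corr = pd.DataFrame(by_cluster).corr()
    return profiles, corr


def plot_density_profile(profile: pd.DataFrame, path=None, ax=None):
    """Dot plot of theme densities (one panel per disease set), flags in red."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, max(2, 0.25 * profile["theme"].nunique())))
    themes = list(dict.fromkeys(profile["theme"]))
    y_pos = {t: i for i, t in enumerate(themes)}
    for _, row in profile.iterrows():
        color = "red" if row["flagged"] else "0.4"
        fill = color if row["density"] > 0 else "none"
        ax.scatter(row["density"], y_pos[row["theme"]],
                   facecolors=fill, edgecolors=color, s=30)
    ax.set_yticks(range(len(themes)), themes)
    ax.set_xlabel("density index")
    ax.set_xlim(-0.05, 1.05)
    if "flag_threshold" in profile.attrs:
        ax.axvline(profile.attrs["flag_threshold"], ls="--", lw=0.8, color="red")
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax
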