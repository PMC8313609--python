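"""Reading and writing of gene–disease association tables, GMT collections and maps.

The central inputs are a long-format gene–disease association (GDA) table in
the DisGeNET export style (one TSV row per association), annotation
collections in GMT format (pathways, cell-type markers, drug signatures) and
small two-column lookup maps (pathway→theme, drug→mode-of-action,
gene→chromosome).
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import EmptyResultError, FormatError

logger = logging.getLogger(__name__)

#: Default column names of a DisGeNET-style GDA export.
DEFAULT_DIALECT = {
    "disease_id": "diseaseId",
    "disease_name": "diseaseName",
    "gene_symbol": "geneSymbol",
}

_CANONICAL_COLUMNS = ["disease_id", "disease_name", "gene_symbol"]


@dataclass(frozen=True)
class DiseaseGeneTable:
    """Long-format table of gene–disease associations.

    One row per (disease, gene) pair; duplicates are collapsed on load.
    ``frame`` has the canonical columns ``disease_id``, ``disease_name``,
    ``gene_symbol``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _CANONICAL_COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"table lacks canonical columns: {missing}")
        for col in ("disease_id", "gene_symbol"):
            values = self.frame[col]
            if values.isna().any() or (values.astype(str).str.len() == 0).any():
                raise FormatError(f"column {col!r} contains empty values")

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str]]
    ) -> "DiseaseGeneTable":
        frame = pd.DataFrame(list(records), columns=_CANONICAL_COLUMNS)
        frame = frame.drop_duplicates(subset=["disease_id", "gene_symbol"])
        return cls(frame.reset_index(drop=True))

    @property
    def disease_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["disease_id"]))

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.frame["gene_symbol"])

    def gene_sets(self) -> dict[str, frozenset[str]]:
        """Per-disease gene sets, in first-appearance disease order."""
        grouped = self.frame.groupby("disease_id", sort=False)["gene_symbol"]
        return {did: frozenset(genes) for did, genes in grouped}

    def disease_names(self) -> dict[str, str]:
        sub = self.frame.drop_duplicates("disease_id")
        return dict(zip(sub["disease_id"], sub["disease_name"]))

    def __len__(self) -> int:
        return len(self.frame)

    def to_tsv(self, path: str | Path, dialect: Mapping[str, str] | None = None) -> None:
        dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
        out = self.frame.rename(
            columns={canon: dialect[canon] for canon in _CANONICAL_COLUMNS}
        )
        out.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets over a common universe of gene symbols.

    ``universe`` is the background against which overrepresentation is
    assessed; every member of every set must belong to it.
    """

    sets: Mapping[str, frozenset[str]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        universe = frozenset(self.universe)
        if not universe:
            universe = frozenset().union(*self.sets.values()) if self.sets else frozenset()
        for name, members in self.sets.items():
            extra = frozenset(members) - universe
            if extra:
                raise FormatError(
                    f"set {name!r} has members outside the universe: {sorted(extra)[:5]}"
                )
        object.__setattr__(self, "sets", {k: frozenset(v) for k, v in self.sets.items()})
        object.__setattr__(self, "universe", universe)

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def sizes(self) -> dict[str, int]:
        return {name: len(members) for name, members in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]


def load_gda(path: str | Path, dialect: Mapping[str, str] | None = None) -> DiseaseGeneTable:
    """Load a DisGeNET-style GDA TSV.

    ``dialect`` maps the canonical keys ``disease_id``, ``disease_name``,
    ``gene_symbol`` to the column names used in the file. Duplicate
    (disease, gene) rows are collapsed with a logged count.
    """
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty") from None
    if frame.empty:
        raise FormatError(f"{path}: file has a header but no rows")
    for canon in ("disease_id", "gene_symbol"):
        col = dialect[canon]
        if col not in frame.columns:
            raise FormatError(
                f"{path}: missing required column {col!r} (maps to {canon})"
            )
    name_col = dialect.get("disease_name")
    if name_col not in frame.columns:
        frame[name_col] = frame[dialect["disease_id"]]
    frame = frame.rename(
        columns={dialect[canon]: canon for canon in _CANONICAL_COLUMNS}
    )[_CANONICAL_COLUMNS]
    n_raw = len(frame)
    frame = frame.drop_duplicates(subset=["disease_id", "gene_symbol"]).reset_index(drop=True)
    n_dup = n_raw - len(frame)
    logger.info(
        "loaded %d GDA rows from %s (%d duplicate pairs collapsed)", len(frame), path, n_dup
    )
    return DiseaseGeneTable(frame)


def build_gene_sets(
    table: DiseaseGeneTable, min_size: int = 10, max_size: int = 1000
) -> GeneSetCollection:
    """Build one gene set per disease, keeping sets with size in [min_size, max_size].

    The universe is the union of genes in the *unfiltered* table: dropping
    small or large diseases must not shrink the hypergeometric background.
    """
    if not (1 <= min_size <= max_size):
        raise ValueError(f"require 1 <= min_size <= max_size, got {min_size}, {max_size}")
    all_sets = table.gene_sets()
    kept = {d: s for d, s in all_sets.items() if min_size <= len(s) <= max_size}
    n_dropped = len(all_sets) - len(kept)
    logger.info(
        "size filter [%d, %d]: kept %d of %d diseases (%d dropped)",
        min_size, max_size, len(kept), len(all_sets), n_dropped,
    )
    if not kept:
        raise EmptyResultError(
            f"no diseases survive the size filter [{min_size}, {max_size}]"
        )
    return GeneSetCollection(sets=kept, universe=table.genes)


def load_gmt(path: str | Path) -> GeneSetCollection:
    """Load a GMT file: per line, set name, description, then tab-separated members."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = frozenset(g for g in fields[2:] if g)
            if not members:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = members
    return GeneSetCollection(sets=sets)


def write_gmt(
    collection: GeneSetCollection, path: str | Path, descriptions: Mapping[str, str] | None = None
) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as handle:
        for name, members in collection.sets.items():
            desc = descriptions.get(name, "na")
            handle.write("\t".join([name, desc, *sorted(members)]) + "\n")


def load_two_column_map(path: str | Path, sep: str | None = None) -> dict[str, str]:
    """Load a two-column key→value map (CSV by .csv extension, else TSV).

    A key repeated with a conflicting value is an error; repeated identical
    rows are tolerated. A header is detected and skipped if its first field
    repeats nowhere as a key ambiguity cannot arise for 2-column maps, so the
    first row is treated as a header only when both fields are non-numeric and
    the file declares one via '#': rows starting with '#' are skipped.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    mapping: dict[str, str] = {}
    with open(path, newline="") as handle:
        for lineno, row in enumerate(csv.reader(handle, delimiter=sep), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].startswith("#"):
                continue
            if len(row) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected exactly 2 columns, got {len(row)}"
                )
            key, value = row[0].strip(), row[1].strip()
            if key in mapping and mapping[key] != value:
                raise FormatError(
                    f"{path}:{lineno}: duplicated key {key!r} with conflicting values "
                    f"({mapping[key]!r} vs {value!r})"
                )
            mapping[key] = value
    return mapping


def write_two_column_map(mapping: Mapping[str, str], path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter=sep)
        for key, value in mapping.items():
            writer.writerow([key, value])
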