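"""End-to-end orchestration: ingest → similarity → clustering → profiling → concordance.

A YAML config names the input files and parameters; ``run_pipeline`` executes
the stages in order, writing every intermediate artifact plus a manifest
(parameters, seed, SHA-256 checksums) into a run directory so that any stage
can be rerun standalone and a rerun with the same config reproduces
byte-identical outputs.

Stage order mirrors the top-down workflow: build size-filtered disease gene
sets, compare them with a Jaccard matrix, optionally pick a global cluster by
PCA + k-means, optionally refine it into branches by hierarchical clustering,
cut the selected branch into subgroups, profile the subgroup diseases at each
annotation level (pathways, cell-types, drugs, chromosomes), summarise with
density indices, and attribute inter-disease similarity to levels via Rand
index concordance.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import concordance as conc
from . import density as dens
from . import enrichment as enr
from . import io as gio
from . import similarity as sim
from .errors import PsygsetError, ValidationError

logger = logging.getLogger(__name__)

#: Default density flag thresholds per level (presentation defaults; all overridable).
DEFAULT_FLAG_THRESHOLDS = {"pathways": 0.5, "celltypes": 0.4, "drugs": 0.5, "chromosomes": 0.1}


class PipelineStageError(PsygsetError):
    """A stage failed; completed artifacts remain on disk for resumption."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Validated pipeline parameters; see module docstring for stage semantics."""

    gda: str
    pathways: str | None = None
    themes: str | None = None
    celltypes: str | None = None
    drugs: str | None = None
    drug_moa: str | None = None
    chromosomes: str | None = None
    background: str | None = None
    dialect: dict[str, str] | None = None
    min_size: int = 10
    max_size: int = 1000
    global_k: int | None = None
    n_components: int = 2
    select_cluster: int | str = "largest"
    branch_k: int | None = None
    select_branch: int | str = "largest"
    subgroup_k: int = 4
    linkage: str = "average"
    q_threshold: float = 0.05
    flag_thresholds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FLAG_THRESHOLDS)
    )
    n_permutations: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gda", "pathways", "themes", "celltypes", "drugs",
                     "drug_moa", "chromosomes", "background"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ValidationError(f"config path {name!r} does not exist: {path}")
        if not 0 < self.q_threshold <= 1:
            raise ValidationError("q_threshold must lie in (0, 1]")
        for level, thr in self.flag_thresholds.items():
            if not 0 <= thr <= 1:
                raise ValidationError(f"flag threshold for {level!r} must lie in [0, 1]")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if self.pathways is not None and self.themes is None:
            raise ValidationError("a theme map is required when pathways are given")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def _select(partition: sim.Partition, which: int | str) -> int:
    if which == "largest":
        sizes = partition.cluster_sizes()
        return max(sizes, key=lambda c: (sizes[c], -c))
    return int(which)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute all configured stages, returning the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def stage(name: str):
        class _Guard:
            def __enter__(self_inner):
                logger.info("stage %s", name)

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, PipelineStageError):
                    raise PipelineStageError(name, exc) from exc
        return _Guard()

    def save(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        artifacts[name] = path
        return path

    with stage("ingest"):
        table = gio.load_gda(config.gda, dialect=config.dialect)
        collection = gio.build_gene_sets(table, config.min_size, config.max_size)
        save("collection.gmt", lambda p: gio.write_gmt(collection, p))

    with stage("similarity"):
        matrix = sim.jaccard_matrix(collection)
        save("similarity.tsv", matrix.to_tsv)

    focus = matrix
    if config.global_k is not None:
        with stage("global_cluster"):
            global_part, scores = sim.pca_cluster(
                matrix, n_components=config.n_components,
                k=config.global_k, seed=config.seed,
            )
            save("global_partition.tsv", global_part.to_tsv)
            save("pc_scores.tsv", lambda p: scores.to_csv(p, sep="\t", index_label="disease_id"))
            chosen = _select(global_part, config.select_cluster)
            members = global_part.members(chosen)
            if len(members) < 2:
                raise ValidationError(f"selected global cluster {chosen} has < 2 diseases")
            idx = [matrix.labels.index(m) for m in members]
            focus = sim.SimilarityMatrix(
                labels=tuple(members), values=matrix.values[np.ix_(idx, idx)]
            )

    if config.branch_k is not None:
        with stage("branches"):
            dend = sim.hierarchical_cluster(focus, linkage=config.linkage)
            save("branch_dendrogram.nwk", lambda p: Path(p).write_text(dend.to_newick()))
            branch_part = sim.cut_tree(dend, config.branch_k)
            save("branch_partition.tsv", branch_part.to_tsv)
            chosen = _select(branch_part, config.select_branch)
            members = branch_part.members(chosen)
            if len(members) < 2:
                raise ValidationError(f"selected branch {chosen} has < 2 diseases")
            idx = [focus.labels.index(m) for m in members]
            focus = sim.SimilarityMatrix(
                labels=tuple(members), values=focus.values[np.ix_(idx, idx)]
            )

    with stage("subgroups"):
        dend = sim.hierarchical_cluster(focus, linkage=config.linkage)
        save("subgroup_dendrogram.nwk", lambda p: Path(p).write_text(dend.to_newick()))
        reference = sim.cut_tree(dend, config.subgroup_k)
        save("subgroup_partition.tsv", reference.to_tsv)

    focus_sets = gio.GeneSetCollection(
        sets={d: collection.sets[d] for d in focus.labels}, universe=collection.universe
    )

    level_tables: dict[str, pd.DataFrame] = {}
    theme_maps: dict[str, Mapping[str, str]] = {}
    with stage("enrichment"):
        background = None
        if config.background is not None:
            background = {
                line.strip()
                for line in Path(config.background).read_text().splitlines()
                if line.strip()
            }
        if config.pathways is not None:
            annotations = gio.load_gmt(config.pathways)
            level_tables["pathways"] = enr.enrich(
                focus_sets, annotations, background=background,
                q_threshold=config.q_threshold,
            )
            theme_maps["pathways"] = gio.load_two_column_map(config.themes)
        if config.celltypes is not None:
            markers = gio.load_gmt(config.celltypes)
            level_tables["celltypes"] = enr.enrich(
                focus_sets, markers, background=background,
                q_threshold=config.q_threshold,
            )
        if config.drugs is not None:
            signatures = gio.load_gmt(config.drugs)
            level_tables["drugs"] = enr.enrich(
                focus_sets, signatures, background=background,
                q_threshold=config.q_threshold,
            )
        if config.chromosomes is not None:
            chrom_map = gio.load_two_column_map(config.chromosomes)
            level_tables["chromosomes"] = enr.chromosome_enrich(
                focus_sets, chrom_map, q_threshold=config.q_threshold,
                background=background,
            )
        if not level_tables:
            raise ValidationError("no annotation level configured")
        for level, table_ in level_tables.items():
            save(f"enrichment_{level}.tsv", lambda p, t=table_: enr.write_enrichment_tsv(t, p))

    with stage("density"):
        for level, table_ in level_tables.items():
            theme_map = theme_maps.get(level)
            if theme_map is None:
                # one singleton theme per annotation (cell-types, drugs, chromosomes)
                names = table_.attrs.get("annotations", sorted(table_["annotation"].unique()))
                theme_map = {a: a for a in names}
            profiles, corr = dens.subgroup_profiles(
                table_, theme_map, reference, q_threshold=config.q_threshold
            )
            threshold = config.flag_thresholds.get(level, 0.5)
            profiles = dens.flag_by_threshold(profiles, threshold)
            save(f"density_{level}.tsv", lambda p, pr=profiles: pr.to_csv(p, sep="\t", index=False))
            save(f"density_corr_{level}.tsv",
                 lambda p, c=corr: c.to_csv(p, sep="\t", index_label="subgroup"))
        if config.drugs is not None and config.drug_moa is not None:
            moa_map = gio.load_two_column_map(config.drug_moa)
            moa_freq, drug_density = enr.drug_moa_summary(level_tables["drugs"], moa_map)
            save("moa_frequency.tsv",
                 lambda p: moa_freq.to_csv(p, sep="\t", index_label="moa"))
            save("drug_density.tsv",
                 lambda p: drug_density.to_csv(p, sep="\t", index_label="drug"))

    with stage("concordance"):
        usable: dict[str, pd.DataFrame] = {}
        for level, table_ in level_tables.items():
            sig = table_[table_["q_value"] < config.q_threshold]
            if sig["disease_id"].nunique() >= 2:
                usable[level] = table_
            else:
                logger.warning(
                    "level %s has fewer than 2 enriched diseases; excluded from concordance",
                    level,
                )
        results, pairwise = conc.attribute_levels(
            reference, usable, k=config.subgroup_k,
            n_permutations=config.n_permutations, seed=config.seed,
            q_threshold=config.q_threshold, linkage=config.linkage,
        )
        report = conc.concordance_report(results)
        save("concordance.tsv", lambda p: report.to_csv(p, sep="\t", index=False))
        save("concordance_pairwise.tsv",
             lambda p: pairwise.to_csv(p, sep="\t", index_label="level"))
        summary = {
            "levels": [dataclasses.asdict(r) for r in results],
            "pairwise": pairwise.to_dict(),
        }
        save("concordance.json",
             lambda p: Path(p).write_text(json.dumps(summary, indent=2, sort_keys=True)))

    with stage("manifest"):
        manifest = {
            "config": config.to_dict(),
            "seed": config.seed,
            "artifacts": {name: _sha256(path) for name, path in sorted(artifacts.items())},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return outdir


def make_report(run_dir: str | Path) -> Path:
    """Summarise a completed run into a plain-text report.

    Gathers the density profiles (with flags) for every level present plus
    the concordance table. Missing artifacts are an error naming them.
    """
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise ValidationError(f"incomplete run: missing {manifest_path.name}")
    manifest = json.loads(manifest_path.read_text())
    missing = [n for n in manifest["artifacts"] if not (run_dir / n).exists()]
    if missing:
        raise ValidationError(f"incomplete run: missing artifacts {missing}")

    lines = ["psygset run report", "=" * 60, ""]
    lines.append(f"seed: {manifest['seed']}")
    lines.append("")
    for name in sorted(manifest["artifacts"]):
        if name.startswith("density_") and not name.startswith("density_corr"):
            level = name[len("density_"):-len(".tsv")]
            profile = pd.read_csv(run_dir / name, sep="\t")
            lines.append(f"-- density profile: {level} --")
            overall = profile[profile["disease_set"] == "all"]
            for _, row in overall.sort_values("density", ascending=False).iterrows():
                flag = " *" if row["flagged"] else ""
                lines.append(f"  {row['theme']:<30s} {row['density']:.3f}{flag}")
            lines.append("")
    concordance_path = run_dir / "concordance.tsv"
    if concordance_path.exists():
        table = pd.read_csv(concordance_path, sep="\t")
        lines.append("-- level concordance with subgroup partition --")
        for _, row in table.iterrows():
            lines.append(
                f"  {row['level']:<14s} RI={row['rand_index']:.3f} "
                f"ARI={row['adjusted_rand']:.3f} p={row['p_value']:.4g}"
            )
        lines.append("")
    report_path = run_dir / "report.txt"
    report_path.write_text("\n".join(lines))
    return report_path
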