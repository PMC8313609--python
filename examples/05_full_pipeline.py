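"""Run the whole workflow end-to-end from files, the way the CLI does.

Writes synthetic inputs (GDA table, pathway GMT + theme map, drug signatures
with a mode-of-action map, chromosome map, background gene list) to a
directory, runs the configured pipeline, and prints the run report.
"""
import tempfile
from pathlib import Path

import psygset as pg
from psygset import io as gio
from psygset.pipeline import PipelineConfig, make_report, run_pipeline

workdir = Path(tempfile.mkdtemp(prefix="psygset_example_"))
spec = pg.SyntheticSpec(seed=7)
table, truth = pg.generate_gda(spec)
table.to_tsv(workdir / "gda.tsv")

themes = [pg.ThemeSpec("shared_theme", "shared", 5)] + [
    pg.ThemeSpec(f"theme_c{c}", c, 3) for c in range(4)
]
annotations, theme_map = pg.generate_annotations(spec, themes)
gio.write_gmt(annotations, workdir / "pathways.gmt")
gio.write_two_column_map(theme_map, workdir / "themes.csv")

drugs, moa_map = pg.generate_drug_signatures(spec, n_drugs=8, moa_count=4,
                                             pool=[0, 1, 2, 3] * 2)
gio.write_gmt(drugs, workdir / "drugs.gmt")
gio.write_two_column_map(moa_map, workdir / "drug_moa.csv")

biased = pg.SyntheticSpec(seed=7, biased_chromosome=(0, 4, 50.0))
gio.write_two_column_map(pg.generate_chromosome_map(biased), workdir / "chromosomes.tsv")
(workdir / "universe.txt").write_text("\n".join(spec.universe) + "\n")

config = PipelineConfig(
    gda=str(workdir / "gda.tsv"),
    pathways=str(workdir / "pathways.gmt"),
    themes=str(workdir / "themes.csv"),
    drugs=str(workdir / "drugs.gmt"),
    drug_moa=str(workdir / "drug_moa.csv"),
    chromosomes=str(workdir / "chromosomes.tsv"),
    background=str(workdir / "universe.txt"),
    min_size=1, max_size=10_000,
    subgroup_k=4, n_permutations=999, seed=0,
)
run_dir = run_pipeline(config, workdir / "run")
print(make_report(run_dir).read_text())
print(f"all artifacts under: {run_dir}")
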