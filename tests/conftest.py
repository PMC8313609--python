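import pytest

import psygset as pg


@pytest.fixture(scope="session")
def spec():
    """Default study conditions: 36 diseases in 4 planted subgroups."""
    return pg.SyntheticSpec(seed=7)


@pytest.fixture(scope="session")
def gda(spec):
    return pg.generate_gda(spec)


@pytest.fixture(scope="session")
def collection(gda):
    table, _ = gda
    return pg.build_gene_sets(table, min_size=1, max_size=10**6)


@pytest.fixture(scope="session")
def truth(gda):
    return gda[1]


@pytest.fixture(scope="session")
def theme_annotations(spec):
    """One ubiquitous (shared-pool) theme plus one private theme per cluster."""
    themes = [pg.ThemeSpec("shared_theme", "shared", 5)] + [
        pg.ThemeSpec(f"theme_c{c}", c, 3) for c in range(spec.n_clusters)
    ]
    return pg.generate_annotations(spec, themes)


@pytest.fixture(scope="session")
def pathway_enrichment(collection, theme_annotations, spec):
    annotations, _ = theme_annotations
    return pg.enrich(collection, annotations, background=frozenset(spec.universe))
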