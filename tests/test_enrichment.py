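import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import psygset as pg


def tail_fraction(k, n, K, N):
    """Independent exact oracle: rational tail sum over binomial coefficients."""
    total = comb(N, n)
    return sum(Fraction(comb(K, i) * comb(N - K, n - i), total)
               for i in range(k, min(n, K) + 1))


class TestHypergeomTail:
    def test_zero_overlap_gives_p_one_exactly(self):
        assert pg.hypergeom_tail(0, 10, 5, 100) == 1.0

    def test_small_worked_example(self):
        # C(2,2)·C(2,0)/C(4,2) = 1/6
        assert pg.hypergeom_tail(2, 2, 2, 4) == pytest.approx(1 / 6, abs=1e-12)

    def test_matches_rational_tail_oracle_on_random_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(300):
            N = int(rng.integers(1, 31))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(n, K) + 1))
            expected = float(tail_fraction(k, n, K, N))
            assert pg.hypergeom_tail(k, n, K, N) == pytest.approx(expected, abs=1e-12)

    def test_matches_exhaustive_draw_enumeration_on_tiny_instances(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            N = int(rng.integers(2, 11))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(n, K) + 1))
            annotated = set(range(K))
            hits = sum(
                1 for draw in itertools.combinations(range(N), n)
                if len(annotated & set(draw)) >= k
            )
            expected = hits / comb(N, n)
            assert pg.hypergeom_tail(k, n, K, N) == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_overlap(self):
        ps = [pg.hypergeom_tail(k, 20, 30, 100) for k in range(0, 21)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_inconsistent_counts_are_an_error(self):
        with pytest.raises(pg.ValidationError):
            pg.hypergeom_tail(5, 3, 10, 20)
        with pytest.raises(pg.ValidationError):
            pg.hypergeom_tail(1, 2, 30, 20)


def step_up_oracle(p):
    """Direct BH step-up: q_i = min_{j >= rank(i)} (m * p_(j) / j), capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestBhAdjust:
    def test_hand_evaluated_example(self):
        q = pg.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_and_tied_p_values(self):
        assert pg.bh_adjust([0.3]) == pytest.approx([0.3])
        assert pg.bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_empty_input_empty_output(self):
        assert len(pg.bh_adjust([])) == 0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=40))
    def test_matches_step_up_oracle_and_preserves_order(self, p):
        q = pg.bh_adjust(p)
        assert q == pytest.approx(step_up_oracle(p), abs=1e-12)
        order = np.argsort(p, kind="stable")
        assert (np.diff(np.asarray(q)[order]) >= -1e-12).all()
        assert ((q > 0) & (q <= 1)).all()

    def test_threshold_equivalence_with_step_up_rule(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            p = rng.uniform(1e-6, 1, size=rng.integers(1, 30))
            alpha = 0.05
            q = pg.bh_adjust(p)
            order = np.sort(p)
            below = np.nonzero(order <= alpha * np.arange(1, len(p) + 1) / len(p))[0]
            k = below[-1] + 1 if len(below) else 0
            rejected_by_rule = set(np.argsort(p, kind="stable")[:k])
            assert {i for i, qi in enumerate(q) if qi <= alpha} == rejected_by_rule


def make_collection(sets, universe=None):
    return pg.GeneSetCollection(
        sets={k: frozenset(v) for k, v in sets.items()},
        universe=frozenset(universe) if universe else frozenset(),
    )


class TestEnrich:
    def test_saturated_degenerate_case_gives_p_one(self):
        genes = {"g1", "g2", "g3"}
        table = pg.enrich(
            make_collection({"d": genes}), make_collection({"a": genes}), background=genes
        )
        assert table["p_value"].tolist() == [1.0]

    def test_planted_ubiquitous_pathway_significant_everywhere(self, spec):
        rich = pg.SyntheticSpec(
            seed=11, core_fraction=0.5, shared_fraction=0.5,
            shared_pool_size=100, genes_per_disease=80,
        )
        table, _ = pg.generate_gda(rich)
        collection = pg.build_gene_sets(table, 1, 10**6)
        annotations = make_collection(
            {"ubiq": set(rich.shared_pool)}, universe=rich.universe
        )
        result = pg.enrich(collection, annotations, background=frozenset(rich.universe))
        sig = result[result["annotation"] == "ubiq"]
        assert len(sig) == rich.n_diseases
        assert sig["significant"].all()

    def test_disjoint_annotation_emits_no_rows(self):
        universe = {"g1", "g2", "g3", "g4"}
        table = pg.enrich(
            make_collection({"d": {"g1", "g2"}}, universe),
            make_collection({"a": {"g3", "g4"}}, universe),
            background=universe,
        )
        assert table.empty

    def test_invariant_to_input_order(self, collection, theme_annotations, spec):
        annotations, _ = theme_annotations
        bg = frozenset(spec.universe)
        t1 = pg.enrich(collection, annotations, background=bg)
        rev_q = pg.GeneSetCollection(
            sets={n: collection[n] for n in reversed(collection.names)},
            universe=collection.universe,
        )
        rev_a = pg.GeneSetCollection(
            sets={n: annotations[n] for n in reversed(annotations.names)},
            universe=annotations.universe,
        )
        t2 = pg.enrich(rev_q, rev_a, background=bg)
        key = ["disease_id", "annotation"]
        merged = t1.merge(t2, on=key, suffixes=("_1", "_2"))
        assert len(merged) == len(t1) == len(t2)
        assert merged["p_value_1"].equals(merged["p_value_2"])
        assert merged["q_value_1"].equals(merged["q_value_2"])

    def test_k_zero_rows_participate_in_the_bh_family(self):
        """q-values use all annotations tested, not only emitted rows."""
        universe = {f"g{i}" for i in range(40)}
        query = make_collection({"d": {f"g{i}" for i in range(10)}}, universe)
        annotations = make_collection(
            {
                "hit": {f"g{i}" for i in range(10)},         # overlap 10
                "miss1": {f"g{i}" for i in range(20, 30)},   # overlap 0
                "miss2": {f"g{i}" for i in range(30, 40)},   # overlap 0
            },
            universe,
        )
        table = pg.enrich(query, annotations, background=universe)
        assert len(table) == 1
        p = table["p_value"].iloc[0]
        assert table["q_value"].iloc[0] == pytest.approx(min(1.0, 3 * p))

    def test_empty_background_is_an_error(self):
        with pytest.raises(pg.ValidationError, match="background"):
            pg.enrich(make_collection({"d": set()}), make_collection({"a": set()}),
                      background=frozenset())


class TestDrugMoaSummary:
    @staticmethod
    def drug_enrichment(spec, collection):
        drugs, moa = pg.generate_drug_signatures(spec, n_drugs=4, moa_count=2)
        table = pg.enrich(collection, drugs, background=frozenset(spec.universe))
        return table, moa

    def test_drug_significant_everywhere_has_density_one(self):
        spec = pg.SyntheticSpec(
            seed=5, core_fraction=0.4, shared_fraction=0.6,
            shared_pool_size=100, genes_per_disease=80,
        )
        table, _ = pg.generate_gda(spec)
        collection = pg.build_gene_sets(table, 1, 10**6)
        enr, moa = self.drug_enrichment(spec, collection)
        _, density = pg.drug_moa_summary(enr, moa)
        assert (density == 1.0).all()  # shared-pool drugs enrich in every disease

    def test_moa_frequency_counts_distinct_drugs(self):
        import pandas as pd
        table = pd.DataFrame(
            {
                "disease_id": ["d1", "d2", "d1"],
                "annotation": ["drugA", "drugA", "drugB"],
                "q_value": [0.01] * 3,
                "significant": [True] * 3,
            }
        )
        freq, density = pg.drug_moa_summary(
            table, {"drugA": "M1", "drugB": "M1"}, diseases=["d1", "d2"]
        )
        assert freq.to_dict() == {"M1": 2}
        assert density.to_dict() == {"drugA": 1.0, "drugB": 0.5}

    def test_missing_drug_in_moa_map_is_an_error(self, spec, collection):
        enr, moa = self.drug_enrichment(spec, collection)
        moa = dict(moa)
        dropped = enr.loc[enr["significant"], "annotation"].iloc[0]
        del moa[dropped]
        with pytest.raises(pg.ValidationError, match=dropped):
            pg.drug_moa_summary(enr, moa)


def test_significant_matrix_is_heatmap_ready(pathway_enrichment):
    mat = pg.significant_matrix(pathway_enrichment)
    sig = pathway_enrichment[pathway_enrichment["significant"]]
    assert (mat.to_numpy() >= 0).all()
    row = sig.iloc[0]
    assert mat.loc[row["disease_id"], row["annotation"]] == pytest.approx(
        -np.log10(row["q_value"])
    )
    assert float((mat.to_numpy() > 0).sum()) == len(sig)
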