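import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, rand_score

import psygset as pg
from psygset.similarity import Partition


def partition_of(assignment):
    return Partition(labels=tuple(assignment), assignment=assignment)


def brute_force_rand(p1, p2):
    """Independent oracle: double loop over all item pairs."""
    items = list(p1.labels)
    agree = 0
    for a, b in itertools.combinations(items, 2):
        same1 = p1.assignment[a] == p1.assignment[b]
        same2 = p2.assignment[a] == p2.assignment[b]
        agree += same1 == same2
    return agree / comb(len(items), 2)


class TestRandIndex:
    def test_identical_partitions_score_one(self):
        p = partition_of({"a": 0, "b": 0, "c": 1, "d": 2})
        assert pg.rand_index(p, p) == 1.0
        assert pg.adjusted_rand_index(p, p) == 1.0

    def test_worked_example_one_third(self):
        p1 = partition_of({"a": 0, "b": 0, "c": 1, "d": 1})
        p2 = partition_of({"a": 0, "b": 1, "c": 0, "d": 1})
        assert pg.rand_index(p1, p2) == pytest.approx(1 / 3)

    def test_matches_brute_force_and_sklearn_on_random_partitions(self):
        rng = np.random.default_rng(13)
        items = [f"i{j}" for j in range(8)]
        for _ in range(200):
            a = rng.integers(0, 4, size=8)
            b = rng.integers(0, 4, size=8)
            p1, p2 = Partition.from_array(items, a), Partition.from_array(items, b)
            ri = pg.rand_index(p1, p2)
            assert ri == pytest.approx(brute_force_rand(p1, p2), abs=1e-12)
            assert ri == pytest.approx(rand_score(a, b), abs=1e-12)
            assert pg.adjusted_rand_index(p1, p2) == pytest.approx(
                adjusted_rand_score(a, b), abs=1e-12
            )

    def test_symmetry_and_label_renaming_invariance(self):
        rng = np.random.default_rng(3)
        items = [f"i{j}" for j in range(10)]
        a = rng.integers(0, 3, size=10)
        b = rng.integers(0, 3, size=10)
        p1, p2 = Partition.from_array(items, a), Partition.from_array(items, b)
        renamed = Partition.from_array(items, 7 - b)  # bijective relabeling
        assert pg.rand_index(p1, p2) == pg.rand_index(p2, p1)
        assert pg.rand_index(p1, renamed) == pg.rand_index(p1, p2)

    def test_against_singletons_closed_form(self):
        rng = np.random.default_rng(6)
        items = [f"i{j}" for j in range(9)]
        codes = rng.integers(0, 3, size=9)
        p = Partition.from_array(items, codes)
        singles = Partition.from_array(items, range(9))
        separated = sum(
            1 for x, y in itertools.combinations(range(9), 2) if codes[x] != codes[y]
        )
        assert pg.rand_index(p, singles) == pytest.approx(separated / comb(9, 2))

    def test_mismatched_item_sets_error_lists_difference(self):
        p1 = partition_of({"a": 0, "b": 0})
        p2 = partition_of({"a": 0, "c": 0})
        with pytest.raises(pg.ValidationError, match="c"):
            pg.rand_index(p1, p2)


class TestPermutationTest:
    def test_identical_nontrivial_partitions_give_small_p(self):
        codes = [0] * 5 + [1] * 5 + [2] * 5
        p = Partition.from_array([f"i{j}" for j in range(15)], codes)
        result = pg.permutation_test(p, p, n_permutations=999, seed=0)
        assert result.rand_index == 1.0
        assert result.p_value < 0.02

    def test_single_cluster_partition_gives_p_one(self):
        p1 = partition_of({"a": 0, "b": 1, "c": 0, "d": 1})
        p2 = partition_of({"a": 0, "b": 0, "c": 0, "d": 0})
        result = pg.permutation_test(p1, p2, n_permutations=200, seed=0)
        assert result.p_value == 1.0
        assert result.perm_sd == pytest.approx(0.0, abs=1e-12)

    def test_p_value_never_zero_and_reproducible(self):
        rng = np.random.default_rng(1)
        items = [f"i{j}" for j in range(12)]
        p1 = Partition.from_array(items, rng.integers(0, 3, 12))
        p2 = Partition.from_array(items, rng.integers(0, 3, 12))
        r1 = pg.permutation_test(p1, p2, n_permutations=500, seed=9)
        r2 = pg.permutation_test(p1, p2, n_permutations=500, seed=9)
        assert r1.p_value > 0
        assert r1.p_value == r2.p_value
        assert r1.p_value == (1 + r1.n_greater_equal) / (1 + r1.n_permutations)


def significance_frame(matrix):
    """Binary disease×annotation matrix -> minimal enrichment-like frame."""
    rows = []
    for disease, row in matrix.iterrows():
        for annotation, hit in row.items():
            if hit:
                rows.append((disease, annotation, 0.001, True))
    frame = pd.DataFrame(rows, columns=["disease_id", "annotation", "q_value", "significant"])
    frame.attrs["diseases"] = list(matrix.index)
    frame.attrs["annotations"] = list(matrix.columns)
    return frame


class TestLevelPartition:
    def test_identical_significance_vectors_are_co_clustered(self):
        matrix = pd.DataFrame(
            [[1, 0], [1, 0], [0, 1], [0, 1]],
            index=["d1", "d2", "d3", "d4"], columns=["a1", "a2"],
        )
        part = pg.level_partition(significance_frame(matrix), k=2)
        assert part.assignment["d1"] == part.assignment["d2"]
        assert part.assignment["d3"] == part.assignment["d4"]
        assert part.assignment["d1"] != part.assignment["d3"]

    def test_unenriched_diseases_form_their_own_cluster(self):
        matrix = pd.DataFrame(
            [[1, 0], [1, 0], [0, 1], [0, 0], [0, 0]],
            index=[f"d{i}" for i in range(5)], columns=["a1", "a2"],
        )
        frame = significance_frame(matrix)
        part = pg.level_partition(frame, k=2, diseases=[f"d{i}" for i in range(5)])
        assert part.assignment["d3"] == part.assignment["d4"]
        assert part.assignment["d3"] not in {part.assignment["d0"], part.assignment["d2"]}
        assert set(part.labels) == {f"d{i}" for i in range(5)}  # nobody dropped

    def test_all_empty_enrichment_is_an_error(self):
        matrix = pd.DataFrame(
            [[0, 0], [0, 0]], index=["d1", "d2"], columns=["a1", "a2"]
        )
        with pytest.raises(pg.ValidationError):
            pg.level_partition(significance_frame(matrix), k=2, diseases=["d1", "d2"])

    def test_singleton_cut_is_deterministic(self):
        matrix = pd.DataFrame(
            np.eye(4, dtype=int), index=[f"d{i}" for i in range(4)],
            columns=[f"a{i}" for i in range(4)],
        )
        part = pg.level_partition(significance_frame(matrix), k=4)
        assert part.n_clusters == 4


class TestAttributeLevels:
    @staticmethod
    def mirrored_and_noise(spec, collection, truth, noise_seed):
        mirror = pg.GeneSetCollection(
            sets={f"pool{c}": frozenset(spec.cluster_pool(c)) for c in range(spec.n_clusters)},
            universe=frozenset(spec.universe),
        )
        mirrored = pg.enrich(collection, mirror, background=frozenset(spec.universe))
        rng = np.random.default_rng(noise_seed)
        ids = list(collection.names)
        relabel = dict(zip(ids, rng.permutation(ids)))
        noise = mirrored.copy()
        noise["disease_id"] = noise["disease_id"].map(relabel)
        noise.attrs = dict(mirrored.attrs)
        return mirrored, noise

    def test_mirrored_level_ranks_first_with_exact_p(self, spec, collection, truth):
        mirrored, noise = self.mirrored_and_noise(spec, collection, truth, noise_seed=2)
        results, pairwise = pg.attribute_levels(
            truth, {"mirror": mirrored, "noise": noise}, n_permutations=999, seed=5
        )
        assert results[0].level == "mirror"
        assert results[0].rand_index == 1.0
        assert results[0].p_value == pytest.approx(1 / 1000)

    def test_identical_levels_have_unit_pairwise_rand(self, spec, collection, truth):
        mirrored, _ = self.mirrored_and_noise(spec, collection, truth, noise_seed=2)
        twin = mirrored.copy()
        twin.attrs = dict(mirrored.attrs)
        _, pairwise = pg.attribute_levels(
            truth, {"m1": mirrored, "m2": twin}, n_permutations=99, seed=5
        )
        assert pairwise.loc["m1", "m2"] == 1.0

    def test_report_table_has_one_row_per_level(self, spec, collection, truth):
        mirrored, noise = self.mirrored_and_noise(spec, collection, truth, noise_seed=4)
        results, _ = pg.attribute_levels(
            truth, {"mirror": mirrored, "noise": noise}, n_permutations=99, seed=1
        )
        from psygset.concordance import concordance_report
        table = concordance_report(results)
        assert list(table["level"]) == [r.level for r in results]
        assert table["rand_index"].is_monotonic_decreasing
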