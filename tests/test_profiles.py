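"""Innervation-profile data model, statistics and clustering."""
import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster import hierarchy

from lnwire.errors import ConfigError, IntegrityError, SchemaError
from lnwire.glomeruli import CANONICAL_GLOMERULI, GlomerulusMap, default_map
from lnwire import profiles as prof
from lnwire import synthetic as synth

from conftest import make_collection


def test_canonical_map_has_55_unique_reference_names():
    m = default_map()
    assert len(m) == 55
    for name in ("DA1", "VA1d", "VA1v", "DA4m", "D", "DM6", "VL2a", "DL1",
                 "DM5", "DL3", "DL4", "DC3"):
        assert name in m
    with pytest.raises(SchemaError):
        GlomerulusMap(("DA1", "DA1"))


class TestIO:
    def test_round_trip_preserves_vectors_and_order(self, tmp_path):
        coll, _ = synth.gen_profiles(synth.CohortSpec(n_profiles=40, seed=3))
        path = tmp_path / "cohort.csv"
        coll.write(path)
        back = prof.read_profiles(path)
        np.testing.assert_array_equal(back.matrix, coll.matrix)
        assert list(back.meta.brain_id) == list(coll.meta.brain_id)

    def test_three_row_file_roundtrip(self, tmp_path, small_map):
        coll = make_collection(np.eye(3, 8, dtype=int), small_map)
        path = tmp_path / "t.tsv"
        coll.write(path)
        with pytest.warns(UserWarning):  # sparse toy profiles
            assert len(prof.read_profiles(path, small_map)) == 3

    def test_unknown_column_is_schema_error(self, tmp_path, small_map):
        coll = make_collection(np.eye(3, 8, dtype=int), small_map)
        df = coll.to_frame().rename(columns={"DM6": "XYZ9"})
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError):
            prof.read_profiles(path, small_map)

    def test_non_binary_cell_rejected(self, tmp_path, small_map):
        coll = make_collection(np.eye(3, 8, dtype=int), small_map)
        df = coll.to_frame()
        df.loc[0, "DA1"] = 2
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError):
            prof.read_profiles(path, small_map)

    def test_duplicate_brain_hemisphere_rejected(self, small_map):
        with pytest.raises(IntegrityError):
            make_collection(np.eye(2, 8, dtype=int), small_map,
                            brain_ids=["b0", "b0"], hemispheres=["L", "L"])

    def test_atypical_count_warns_not_errors(self, tmp_path):
        # an all-innervating neuron is outside the typical 6-24 range
        map = default_map()
        coll = make_collection(np.ones((1, 55), dtype=int), map)
        path = tmp_path / "t.csv"
        coll.write(path)
        with pytest.warns(UserWarning, match="typical"):
            prof.read_profiles(path)


class TestCounts:
    def test_innervation_count(self, make_coll):
        vec = np.zeros(55, dtype=int)
        vec[:12] = 1
        assert prof.innervation_count(vec) == 12
        assert prof.innervation_count(np.zeros(8, dtype=int)) == 0

    def test_cohort_mean_count_in_observed_range(self):
        # the paper-like frequency preset should give 6-24 innervated
        # glomeruli per neuron on average
        coll, _ = synth.gen_profiles(synth.CohortSpec(n_profiles=500,
                                                      seed=7))
        mean = coll.matrix.sum(axis=1).mean()
        assert 6 <= mean <= 24

    def test_mean_count_equals_sum_of_frequencies(self):
        # linearity: mean row-sum == sum of per-glomerulus frequencies
        coll, _ = synth.gen_profiles(synth.CohortSpec(n_profiles=200,
                                                      seed=9))
        freqs = prof.frequency_table(coll)
        mean_count = coll.matrix.sum(axis=1).mean()
        assert mean_count == pytest.approx(freqs.frequency.sum(), abs=1e-10)


class TestFrequencyTable:
    def test_simple_fraction(self, make_coll):
        mat = np.zeros((4, 8), dtype=int)
        mat[:3, 0] = 1  # DA1 innervated in 3 of 4
        freqs = prof.frequency_table(make_coll(mat))
        assert freqs.set_index("glomerulus").loc["DA1", "frequency"] == 0.75

    def test_full_innervation_frequency_one(self, make_coll):
        mat = np.zeros((5, 8), dtype=int)
        mat[:, 0] = 1
        freqs = prof.frequency_table(make_coll(mat))
        assert freqs.set_index("glomerulus").loc["DA1", "frequency"] == 1.0

    def test_invariant_to_row_order(self, make_coll):
        rng = np.random.default_rng(0)
        mat = rng.integers(0, 2, (20, 8))
        a = prof.frequency_table(make_coll(mat))
        b = prof.frequency_table(make_coll(mat[::-1]))
        pd.testing.assert_frame_equal(a, b)

    def test_bernoulli_recovery_within_three_se(self):
        p = 0.42
        spec = synth.CohortSpec(
            seed=21, groups=[synth.GroupSpec(n=2268,
                                             overrides={"VL2a": p})])
        coll, _ = synth.gen_profiles(spec)
        freqs = prof.frequency_table(coll).set_index("glomerulus")
        se = np.sqrt(p * (1 - p) / 2268)
        assert abs(freqs.loc["VL2a", "frequency"] - p) <= 3 * se

    def test_group_by_splits_counts(self, make_coll):
        mat = np.zeros((6, 8), dtype=int)
        mat[:3, 4] = 1
        coll = make_coll(mat, sex=["female"] * 3 + ["male"] * 3)
        freqs = prof.frequency_table(coll, group_by=["sex"])
        by = freqs.set_index(["group_label", "glomerulus"])
        assert by.loc[("female", "VL2a"), "frequency"] == 1.0
        assert by.loc[("male", "VL2a"), "frequency"] == 0.0


class TestDistinctPatterns:
    def test_multiplicities(self, make_coll):
        mat = np.vstack([np.ones((3, 8), int), np.zeros((1, 8), int)])
        mat[3, 0] = 1
        count, table = prof.distinct_patterns(make_coll(mat))
        assert count == 2
        assert table.multiplicity.sum() == 4

    def test_all_distinct(self, make_coll):
        count, _ = prof.distinct_patterns(make_coll(np.eye(8, dtype=int)))
        assert count == 8

    def test_agrees_with_set_of_tuples_oracle(self, small_map):
        rng = np.random.default_rng(12)
        mat = rng.integers(0, 2, (200, 8))
        count, table = prof.distinct_patterns(
            make_collection(mat, small_map))
        oracle = len({tuple(row) for row in mat})
        assert count == oracle
        assert table.multiplicity.sum() == 200

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(1, 40), st.integers(0, 10_000))
    def test_count_bounded_by_collection_size(self, n, seed):
        from conftest import SMALL_NAMES
        map = GlomerulusMap(SMALL_NAMES)
        mat = np.random.default_rng(seed).integers(0, 2, (n, 8))
        count, _ = prof.distinct_patterns(make_collection(mat, map))
        assert count <= n
        if len({tuple(r) for r in mat}) == n:
            assert count == n


class TestClassification:
    @pytest.mark.parametrize("freq,expected", [
        (1.0, "always"),    # always innervated
        (0.96, "high"),     # >95%
        (0.50, "variable"), # within the 10-84% band
        (0.10, "variable"),
        (0.84, "variable"),
        (0.87, "other"),    # the 84-95% gap
        (0.95, "other"),
        (0.05, "rare"),
        (0.0, "rare"),
    ])
    def test_default_classes(self, freq, expected):
        assert prof.classify_frequency(freq) == expected

    def test_overlapping_edges_rejected(self):
        with pytest.raises(ConfigError):
            prof.classify_frequency(0.5, {"rare_max": 0.9,
                                          "variable_max": 0.5})

    def test_every_glomerulus_classified(self):
        coll, _ = synth.gen_profiles(synth.CohortSpec(n_profiles=100,
                                                      seed=2))
        classes = prof.classify_glomeruli(prof.frequency_table(coll))
        assert set(classes) == set(coll.map.names)


def brute_force_complete_linkage(dist):
    """O(n^3) agglomeration oracle; returns (sorted merge heights,
    cophenetic distance matrix)."""
    n = dist.shape[0]
    clusters = {i: {i} for i in range(n)}
    coph = np.zeros((n, n))
    heights = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ai, a in enumerate(keys):
            for b in keys[ai + 1:]:
                d = max(dist[i, j] for i in clusters[a]
                        for j in clusters[b])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        clusters[a] |= clusters[b]
        del clusters[b]
    return sorted(heights), coph


class TestClustering:
    def test_identical_profiles_merge_at_zero(self, make_coll):
        mat = np.array([[1, 1, 0, 0, 1, 0, 0, 0]] * 2
                       + [[0, 0, 1, 1, 0, 1, 1, 1]])
        res = prof.cluster_profiles(make_coll(mat))
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_row_permutation_invariance(self, make_coll):
        rng = np.random.default_rng(5)
        mat = rng.integers(0, 2, (10, 8))
        mat[:, 0] = [1, 0] * 5  # guarantee variance
        perm = rng.permutation(10)
        res_a = prof.cluster_profiles(make_coll(mat))
        res_b = prof.cluster_profiles(make_coll(mat[perm]))
        from scipy.spatial.distance import squareform
        ca = squareform(hierarchy.cophenet(res_a.linkage))
        cb = squareform(hierarchy.cophenet(res_b.linkage))
        # row i of the permuted collection is original row perm[i]
        np.testing.assert_allclose(ca[np.ix_(perm, perm)], cb, atol=1e-12)

    def test_agrees_with_naive_agglomeration_oracle(self, make_coll):
        rng = np.random.default_rng(14)
        mat = rng.integers(0, 2, (6, 8))
        mat[:, 3] = [0, 1, 0, 1, 1, 0]  # ensure nonzero variance rows
        res = prof.cluster_profiles(make_coll(mat))
        dist = prof.correlation_distance_matrix(mat)
        heights, coph = brute_force_complete_linkage(dist)
        np.testing.assert_allclose(sorted(res.linkage[:, 2]), heights,
                                   atol=1e-12)
        from scipy.spatial.distance import squareform
        np.testing.assert_allclose(
            squareform(hierarchy.cophenet(res.linkage)), coph, atol=1e-12)

    def test_merge_heights_non_decreasing_and_distance_symmetric(self):
        coll, _ = synth.gen_profiles(synth.CohortSpec(n_profiles=30,
                                                      seed=8))
        dist = prof.correlation_distance_matrix(coll.matrix)
        np.testing.assert_allclose(dist, dist.T, atol=0)
        assert np.all(np.diag(dist) == 0)
        res = prof.cluster_profiles(coll)
        assert np.all(np.diff(res.linkage[:, 2]) >= -1e-12)

    def test_zero_variance_profile_gets_max_distance_with_warning(
            self, make_coll):
        mat = np.vstack([np.zeros((1, 8), int),
                         np.array([[1, 0, 1, 0, 1, 0, 1, 0],
                                   [0, 1, 0, 1, 0, 1, 0, 1]])])
        with pytest.warns(UserWarning, match="zero-variance"):
            dist = prof.correlation_distance_matrix(mat)
        assert dist[0, 1] == prof.MAX_CORR_DISTANCE
        assert dist[0, 0] == 0.0

    def test_newick_export_parses(self, make_coll):
        import skbio
        rng = np.random.default_rng(3)
        mat = rng.integers(0, 2, (5, 8))
        mat[:, 0] = [1, 0, 1, 0, 1]
        res = prof.cluster_profiles(make_coll(mat))
        tree = skbio.TreeNode.read(io.StringIO(res.to_newick()))
        # newick readers render underscores as spaces
        tips = sorted(t.name.replace(" ", "_") for t in tree.tips())
        assert tips == sorted(res.labels)

    def test_leaf_order_flag_minimizes_adjacent_distance(self, make_coll):
        rng = np.random.default_rng(6)
        mat = rng.integers(0, 2, (12, 8))
        mat[:, 0] = [1, 0] * 6
        coll = make_coll(mat)
        plain = prof.cluster_profiles(coll, optimize_leaf_order=False)
        opt = prof.cluster_profiles(coll, optimize_leaf_order=True)
        dist = prof.correlation_distance_matrix(mat)

        def path_cost(order):
            return sum(dist[a, b] for a, b in zip(order, order[1:]))

        assert path_cost(opt.leaf_order) <= path_cost(plain.leaf_order) \
            + 1e-12
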