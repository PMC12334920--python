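"""Brute-force KNN matching, the good-match filters, and the partition."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from twinmark.errors import DuplicateQueryIndex, InsufficientNeighbors, MetricMismatch
from twinmark.keypoints import DescriptorSet, pack_bits
from twinmark.matching import (
    FilterRule,
    Match,
    SingleNeighborPolicy,
    filter_good_matches,
    knn_match,
    match_pair,
    partition,
)


def naive_knn(a: np.ndarray, b: np.ndarray, k: int, metric: str):
    """Independent O(n^2) double-loop oracle with the same tie rule."""
    out = []
    for i in range(len(a)):
        dists = []
        for j in range(len(b)):
            if metric == "EUCLIDEAN":
                d = float(np.sqrt(np.sum((a[i] - b[j]) ** 2)))
            else:
                d = float(np.count_nonzero(a[i] != b[j]))
            dists.append((d, j))
        dists.sort()
        out.append(dists[: min(k, len(b))])
    return out


def _float_set(mat, kind="SIFT"):
    return DescriptorSet(kind=kind, values=np.asarray(mat, dtype=float))


def _orb_set(bits):
    return DescriptorSet(kind="ORB", values=pack_bits(bits))


class TestKnnMatch:
    def test_identical_sets_match_to_self_at_distance_zero(self, rng):
        vals = rng.standard_normal((20, 128))
        cands = knn_match(_float_set(vals), _float_set(vals), k=1)
        for i, lst in enumerate(cands):
            assert lst[0].index_b == i and lst[0].distance == 0.0

    def test_one_dimensional_example(self):
        # effectively 1-D values padded with zeros to the SURF width
        a = DescriptorSet(kind="SURF", values=np.pad([[0.0], [10.0]], ((0, 0), (0, 63))))
        b = DescriptorSet(kind="SURF", values=np.pad([[0.5], [9.0]], ((0, 0), (0, 63))))
        cands = knn_match(a, b, k=2)
        # |0-0.5|=0.5, |0-9|=9.0 ; |10-9|=1.0, |10-0.5|=9.5
        assert [(m.index_b, m.distance) for m in cands[0]] == [(0, 0.5), (1, 9.0)]
        assert [(m.index_b, m.distance) for m in cands[1]] == [(1, 1.0), (0, 9.5)]

    @pytest.mark.parametrize("metric", ["EUCLIDEAN", "HAMMING"])
    def test_equals_naive_oracle_on_random_instances(self, metric, rng):
        for _ in range(25):
            n_a, n_b = rng.integers(3, 40, size=2)
            k = int(rng.integers(1, 4))
            if metric == "EUCLIDEAN":
                a, b = rng.standard_normal((n_a, 64)), rng.standard_normal((n_b, 64))
                da, db = _float_set(a, "SURF"), _float_set(b, "SURF")
                oracle = naive_knn(a, b, k, metric)
            else:
                a = rng.integers(0, 2, size=(n_a, 256))
                b = rng.integers(0, 2, size=(n_b, 256))
                da, db = _orb_set(a), _orb_set(b)
                oracle = naive_knn(a.astype(np.uint8), b.astype(np.uint8), k, metric)
            got = knn_match(da, db, k=k)
            for lst, exp in zip(got, oracle):
                assert [(m.index_b) for m in lst] == [j for _, j in exp]
                np.testing.assert_allclose([m.distance for m in lst],
                                           [d for d, _ in exp], atol=1e-9)

    def test_ties_break_on_smaller_b_index(self):
        a = DescriptorSet(kind="SURF", values=np.zeros((1, 64)))
        b = DescriptorSet(kind="SURF", values=np.zeros((3, 64)))
        cands = knn_match(a, b, k=3)
        assert [m.index_b for m in cands[0]] == [0, 1, 2]

    def test_metric_mismatch_rejected(self, rng):
        f = _float_set(rng.standard_normal((4, 128)))
        o = _orb_set(rng.integers(0, 2, size=(4, 256)))
        with pytest.raises(MetricMismatch):
            knn_match(f, o, k=1)

    def test_short_lists_when_b_is_small(self):
        a = DescriptorSet(kind="SURF", values=np.zeros((2, 64)))
        b = DescriptorSet(kind="SURF", values=np.zeros((1, 64)))
        assert all(len(lst) == 1 for lst in knn_match(a, b, k=2))


def _cand(d1, d2):
    return [[Match(0, 0, d1), Match(0, 1, d2)]]


class TestFilterRules:
    def test_lowe_keeps_clear_winner(self):
        assert len(filter_good_matches(_cand(0.5, 8.5), ratio=0.7)) == 1

    def test_lowe_rejects_equal_distances(self):
        assert filter_good_matches(_cand(3.0, 3.0), ratio=0.7) == []

    def test_all_zero_self_matches_kept_under_every_rule(self):
        cands = [[Match(i, i, 0.0), Match(i, 1 - i, 0.0)] for i in range(2)]
        assert len(filter_good_matches(cands, FilterRule.LOWE_RATIO)) == 2
        assert len(filter_good_matches(cands, FilterRule.PAPER_LITERAL, n_b=2)) == 2
        assert len(filter_good_matches(cands, FilterRule.MIN_DIST_SCALE, ratio=1.0)) == 2

    def test_paper_literal_threshold_uses_descriptor_counts(self):
        cands = _cand(1.3, 1.4)
        # bound = 0.7 * min(1, 2) = 0.7 -> rejected; with n_b=10, bound 0.7*1
        assert filter_good_matches(cands, FilterRule.PAPER_LITERAL, n_b=2) == []
        kept = filter_good_matches(_cand(0.6, 0.65), FilterRule.PAPER_LITERAL, n_b=2)
        assert len(kept) == 1

    def test_min_dist_scale_keeps_within_scale_of_best(self):
        cands = [[Match(0, 0, 1.0)], [Match(1, 1, 1.9)], [Match(2, 0, 2.5)]]
        kept = filter_good_matches(cands, FilterRule.MIN_DIST_SCALE, ratio=2.0)
        assert [m.index_a for m in kept] == [0, 1]

    def test_single_neighbor_policies(self):
        cands = [[Match(0, 0, 1.0)]]
        assert len(filter_good_matches(cands)) == 1  # keep (default)
        assert filter_good_matches(
            cands, single_neighbor=SingleNeighborPolicy.DROP) == []
        with pytest.raises(InsufficientNeighbors):
            filter_good_matches(cands, single_neighbor=SingleNeighborPolicy.RAISE)

    def test_output_is_subset_of_best_neighbors_and_sorted(self, rng):
        vals_a = rng.standard_normal((30, 128))
        vals_b = rng.standard_normal((25, 128))
        cands = knn_match(_float_set(vals_a), _float_set(vals_b), k=2)
        good = filter_good_matches(cands, ratio=0.95)
        best = {(lst[0].index_a, lst[0].index_b) for lst in cands if lst}
        assert {(m.index_a, m.index_b) for m in good} <= best
        dists = [m.distance for m in good]
        assert dists == sorted(dists)

    @given(st.floats(0.05, 0.95), st.floats(0.05, 0.95), st.integers(0, 2 ** 31 - 1))
    def test_lowe_is_monotone_in_ratio(self, r1, r2, seed):
        rng = np.random.default_rng(seed)
        vals_a = rng.standard_normal((15, 128))
        vals_b = rng.standard_normal((15, 128))
        cands = knn_match(_float_set(vals_a), _float_set(vals_b), k=2)
        lo, hi = sorted([r1, r2])
        n_lo = len(filter_good_matches(cands, ratio=lo))
        n_hi = len(filter_good_matches(cands, ratio=hi))
        assert n_lo <= n_hi


class TestPartition:
    def test_counts_are_conserved(self):
        good = [Match(i, i, 0.1) for i in range(30)]
        res = partition(50, 50, good)
        assert len(res.matched_a) == 30 and len(res.mismatched_a) == 20
        assert res.matched_a | res.mismatched_a == frozenset(range(50))
        assert not (res.matched_a & res.mismatched_a)

    def test_zero_good_means_everything_mismatched(self):
        res = partition(10, 12, [])
        assert res.mismatched_a == frozenset(range(10))
        assert res.mismatched_b == frozenset(range(12))

    def test_full_match_means_no_mismatches(self):
        res = partition(5, 5, [Match(i, i, 0.0) for i in range(5)])
        assert res.mismatched_a == frozenset() and res.mismatched_b == frozenset()

    def test_duplicate_query_index_rejected(self):
        with pytest.raises(DuplicateQueryIndex):
            partition(5, 5, [Match(0, 1, 0.1), Match(0, 2, 0.2)])

    def test_many_to_one_b_matches_count_distinct_endpoints(self):
        good = [Match(0, 3, 0.1), Match(1, 3, 0.2)]
        res = partition(4, 5, good)
        assert res.matched_b == frozenset({3})
        assert len(res.matched_b) + len(res.mismatched_b) == 5

    @given(st.integers(1, 60), st.integers(1, 60), st.integers(0, 2 ** 31 - 1))
    def test_partition_conservation_property(self, n_a, n_b, seed):
        rng = np.random.default_rng(seed)
        n_good = int(rng.integers(0, min(n_a, n_b) + 1))
        a_idx = rng.choice(n_a, size=n_good, replace=False)
        b_idx = rng.choice(n_b, size=n_good, replace=True)
        good = [Match(int(i), int(j), float(rng.random())) for i, j in zip(a_idx, b_idx)]
        res = partition(n_a, n_b, good)
        assert len(res.matched_a) + len(res.mismatched_a) == n_a
        assert len(res.matched_b) + len(res.mismatched_b) == n_b


class TestMatchPair:
    def test_planted_correspondences_recovered_exactly_without_noise(self):
        from twinmark.synthetic import CohortSpec, synth_pair

        spec = CohortSpec(keypoints_per_image=50, match_fraction=0.6,
                          descriptor_noise_sigma=0.0, kinds=("SIFT", "ORB"))
        a, b, truth = synth_pair(spec, 0, 123)
        for kind in spec.kinds:
            res = match_pair(a[kind][1], b[kind][1])
            assert res.matched_a == truth.matched_a
            assert {m.index_a: m.index_b for m in res.good} == truth.correspondences

    def test_cross_check_removes_unreciprocated_matches(self, rng):
        vals_a = rng.standard_normal((20, 128))
        vals_b = np.vstack([vals_a[:10] + 1e-6, rng.standard_normal((10, 128))])
        plain = match_pair(_float_set(vals_a), _float_set(vals_b))
        checked = match_pair(_float_set(vals_a), _float_set(vals_b), use_cross_check=True)
        assert checked.matched_a <= plain.matched_a
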