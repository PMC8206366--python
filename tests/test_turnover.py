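"""Turnover statistics against brute-force oracles and constructed inputs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lvmcm.turnover as tno
from lvmcm.dynamics import CommunityTimeseries
from lvmcm.landscape import build_landscape


def make_ts(tensor):
    tensor = np.asarray(tensor, float)
    return CommunityTimeseries(
        tensor=tensor,
        times=np.arange(1.0, tensor.shape[2] + 1),
        species_ids=np.arange(tensor.shape[0]),
    )


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------


class TestBrayCurtis:
    def test_identical_vectors_score_zero(self):
        assert tno.bray_curtis([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_disjoint_supports_score_one(self):
        assert tno.bray_curtis([1.0, 0.0], [0.0, 3.0]) == 1.0

    def test_direct_formula(self):
        assert tno.bray_curtis([2.0, 1.0], [1.0, 1.0]) == pytest.approx(0.2)

    def test_both_zero_is_an_error_not_zero(self):
        with pytest.raises(ValueError):
            tno.bray_curtis([0.0, 0.0], [0.0, 0.0])
        with pytest.raises(ValueError):
            tno.bray_curtis([1.0], [-0.5])

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(0.0, 100.0), min_size=1, max_size=10),
        st.lists(st.floats(0.0, 100.0), min_size=1, max_size=10),
        st.floats(0.01, 100.0),
    )
    def test_bounded_symmetric_and_scale_invariant(self, u, v, c):
        n = min(len(u), len(v))
        u, v = np.array(u[:n]), np.array(v[:n])
        if u.sum() + v.sum() == 0:
            return
        bc = tno.bray_curtis(u, v)
        assert 0.0 <= bc <= 1.0
        assert bc == pytest.approx(tno.bray_curtis(v, u))
        assert bc == pytest.approx(tno.bray_curtis(c * u, c * v))


# ---------------------------------------------------------------------------
# temporal dissimilarity and clustering
# ---------------------------------------------------------------------------


def oracle_complete_linkage(D, cut):
    """Exhaustive O(n^3) agglomeration: merge the closest pair of clusters
    under the complete-linkage (maximum) distance until none is below cut."""
    clusters = [[i] for i in range(len(D))]
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                dist = max(D[i, j] for i in clusters[a] for j in clusters[b])
                if best is None or dist < best[0]:
                    best = (dist, a, b)
        if best[0] > cut:
            break
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return len(clusters)


class TestClustering:
    def test_fixed_point_series_is_one_cluster(self):
        ts = make_ts(np.tile(np.array([1.0, 2.0])[:, None, None], (1, 1, 40)))
        D = tno.temporal_dissimilarity(ts, 0, subsample_stride=1)
        assert D.max() < 1e-12
        assert tno.count_clusters(D) == 1

    def test_two_block_alternating_series(self):
        a, b = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        comp = np.stack([a if (t // 10) % 2 == 0 else b for t in range(40)], axis=1)
        ts = make_ts(comp[:, None, :].transpose(0, 1, 2))
        D = tno.temporal_dissimilarity(ts, 0, subsample_stride=1)
        assert tno.count_clusters(D) == 2
        # block structure: within-block zero, across-block one
        assert D[0, 5] == 0.0 and D[0, 15] == 1.0

    def test_two_perfect_blocks_cut(self):
        D = np.full((6, 6), 0.9)
        D[:3, :3] = 0.0
        D[3:, 3:] = 0.0
        assert tno.count_clusters(D) == 2

    @pytest.mark.parametrize("n", [6, 20, 50])
    def test_matches_exhaustive_agglomeration_oracle(self, n):
        rng = np.random.default_rng(n)
        X = rng.uniform(0.0, 1.0, size=(n, 4))
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(X, metric="braycurtis"))
        assert tno.count_clusters(D, 0.25) == oracle_complete_linkage(D, 0.25)
        assert tno.count_clusters(D, 0.6) == oracle_complete_linkage(D, 0.6)


class TestDetectTurnover:
    def test_fixed_point_not_flagged(self):
        ts = make_ts(np.tile(np.array([1.0, 0.5])[:, None, None], (1, 1, 30)))
        flag, mean_bc = tno.detect_turnover(ts, 0, subsample_stride=1)
        assert not flag and mean_bc < 1e-12

    def test_cycling_composition_flagged(self):
        from lvmcm.dynamics import may_leonard_fixture, simulate_isolated

        R, A = may_leonard_fixture()
        ts = simulate_isolated(R, A, np.array([0.5, 0.3, 0.2]), epsilon=1e-10,
                               duration=3000.0)
        flag, mean_bc = tno.detect_turnover(ts, 0)
        assert flag and mean_bc > 0.1


# ---------------------------------------------------------------------------
# occupancy and richness
# ---------------------------------------------------------------------------


class TestOccupancy:
    def test_always_present_scores_one_half_present_scores_half(self):
        tensor = np.zeros((2, 1, 10))
        tensor[0] = 1.0
        tensor[1, 0, :5] = 1.0
        occ = tno.temporal_occupancy(tno.presence_tensor(make_ts(tensor)))
        lookup = dict(zip(occ.species, occ.occupancy))
        assert lookup[0] == 1.0 and lookup[1] == 0.5

    def test_never_present_excluded(self):
        tensor = np.zeros((2, 1, 10))
        tensor[0] = 1.0
        occ = tno.temporal_occupancy(tno.presence_tensor(make_ts(tensor)))
        assert set(occ.species) == {0}

    def test_bimodality_checks_on_constructed_distributions(self):
        rng = np.random.default_rng(5)
        bimodal = np.concatenate([rng.uniform(0, 0.05, 40), rng.uniform(0.97, 1.0, 60),
                                  rng.uniform(0.3, 0.7, 10)])
        uniform = rng.uniform(0, 1, 200)
        unimodal = np.clip(rng.normal(0.5, 0.1, 200), 0, 1)
        assert tno.is_bimodal(bimodal)
        assert tno.has_occupancy_dip(bimodal)
        assert not tno.is_bimodal(unimodal)
        assert not tno.has_occupancy_dip(unimodal)
        assert not tno.has_occupancy_dip(uniform)

    def test_richness_hand_count(self):
        tensor = np.zeros((3, 2, 2))
        tensor[0, 0, 0] = 1.0
        tensor[1, 0, 0] = 1.0
        tensor[2, 1, 1] = 1.0
        P = tno.presence_tensor(make_ts(tensor))
        np.testing.assert_array_equal(
            tno.richness_timeseries(P), [[2, 0], [0, 1]]
        )

    def test_empty_tensor_gives_zero_richness(self):
        P = tno.presence_tensor(make_ts(np.zeros((2, 2, 3))))
        np.testing.assert_array_equal(tno.richness_timeseries(P), 0)


class TestNeighbourhoodRichness:
    def test_isolated_patch_equals_local_richness(self):
        ls = build_landscape(1, seed=0)
        B = np.array([[1.0], [0.0], [1.0]])
        np.testing.assert_array_equal(tno.neighbourhood_richness(B, ls), [2])

    def test_three_patch_line_union_by_hand(self, collinear3):
        B = np.array(
            [
                [1.0, 0.0, 0.0],
                [0.0, 1.0, 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        # ends see themselves + centre (2 species); centre sees all 3
        np.testing.assert_array_equal(
            tno.neighbourhood_richness(B, collinear3), [2, 3, 2]
        )


# ---------------------------------------------------------------------------
# species-time-area relation
# ---------------------------------------------------------------------------


def oracle_star_table(P, coords, area_windows, time_windows):
    """Exhaustive union counts over every focal patch and window start."""
    S, N, T = P.shape
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
    table = np.zeros((len(area_windows), len(time_windows)))
    for ai, dA in enumerate(area_windows):
        for ti, dT in enumerate(time_windows):
            vals = []
            for x in range(N):
                patches = sorted(range(N), key=lambda y: (d[x, y], y))[:dA]
                for t0 in range(T - dT + 1):
                    present = P[:, patches, t0 : t0 + dT]
                    vals.append(int(present.any(axis=(1, 2)).sum()))
            table[ai, ti] = np.mean(vals)
    return table


class TestStar:
    def test_full_window_recovers_regional_richness(self):
        rng = np.random.default_rng(2)
        P = rng.random((5, 4, 8)) > 0.6
        coords = rng.uniform(0, 2, size=(4, 2))
        res = tno.star(P, coords, area_windows=[1, 2, 4], time_windows=[1, 8])
        regional = P.any(axis=(1, 2)).sum()
        assert res.table[-1, -1] == pytest.approx(regional)

    def test_toy_tensor_matches_exhaustive_union_oracle(self):
        rng = np.random.default_rng(3)
        P = rng.random((6, 5, 12)) > 0.5
        coords = rng.uniform(0, 3, size=(5, 2))
        aw, tw = [1, 2, 4], [1, 5, 10]
        res = tno.star(P, coords, area_windows=aw, time_windows=tw)
        np.testing.assert_allclose(res.table, oracle_star_table(P, coords, aw, tw))

    def test_monotone_in_both_windows(self):
        rng = np.random.default_rng(4)
        P = rng.random((8, 6, 20)) > 0.7
        coords = rng.uniform(0, 3, size=(6, 2))
        res = tno.star(P, coords, area_windows=[1, 2, 4], time_windows=[1, 5, 10])
        assert np.all(np.diff(res.table, axis=0) >= -1e-12)
        assert np.all(np.diff(res.table, axis=1) >= -1e-12)

    def test_rejects_oversized_windows(self):
        P = np.ones((2, 2, 5), dtype=bool)
        coords = np.zeros((2, 2))
        with pytest.raises(ValueError):
            tno.star(P, coords, area_windows=[4], time_windows=[1])
        with pytest.raises(ValueError):
            tno.star(P, coords, area_windows=[1], time_windows=[10])


# ---------------------------------------------------------------------------
# beta diversity and abundance structure
# ---------------------------------------------------------------------------


class TestBetaDiversities:
    def test_identical_patches_have_zero_spatial_turnover(self):
        snapshot = np.tile(np.array([1.0, 2.0])[:, None], (1, 4))
        beta_s, _ = tno.beta_diversities(snapshot=snapshot)
        assert beta_s == pytest.approx(0.0, abs=1e-12)

    def test_fixed_point_run_has_negligible_temporal_turnover(self):
        ts = make_ts(np.tile(np.array([[1.0, 0.3], [0.2, 0.9]])[:, :, None], (1, 1, 30)))
        _, beta_t = tno.beta_diversities(timeseries=ts, subsample_stride=1)
        assert beta_t < 1e-6


class TestAbundanceStructure:
    def test_constant_composition_gives_identical_ranks(self):
        ts = make_ts(np.tile(np.array([3.0, 1.0, 2.0])[:, None, None], (1, 1, 10)))
        vectors, dist = tno.abundance_structure(ts, 0, [0, 5, 9])
        np.testing.assert_array_equal(vectors[0], [3.0, 2.0, 1.0])
        for v in vectors[1:]:
            np.testing.assert_array_equal(v, vectors[0])
        assert dist == 0.0

    def test_hand_ranked_toy_input(self):
        tensor = np.zeros((3, 1, 2))
        tensor[:, 0, 0] = [0.5, 2.0, 1.0]
        tensor[:, 0, 1] = [1.0, 0.1, 3.0]
        ts = make_ts(tensor)
        vectors, _ = tno.abundance_structure(ts, 0, [0, 1])
        np.testing.assert_array_equal(vectors[0], [2.0, 1.0, 0.5])
        np.testing.assert_array_equal(vectors[1], [3.0, 1.0, 0.1])
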