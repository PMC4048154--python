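import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from connclust import (
    AdjacencyMatrix,
    LinkCountMap,
    MaskedGrid,
    extract_clusters,
    link_count_map,
    max_statistics,
    paired_t_matrix,
    threshold_to_adjacency,
)

from _oracles import bfs_clusters, paired_t_scalar


# ---------------------------------------------------------------------------
# paired t matrix


def test_identical_conditions_yield_zero_t(grid2d, rng):
    mats = [np.clip((m + m.T) / 2, -1, 1) for m in
            [rng.uniform(-1, 1, (8, 8)) for _ in range(4)]]
    for m in mats:
        np.fill_diagonal(m, 1.0)
    tm = paired_t_matrix(mats, mats)
    off = ~np.eye(8, dtype=bool)
    assert np.all(tm.values[off] == 0.0)
    assert tm.dof == 3


def test_all_flips_negate_t(paired_matrices):
    mats_a, mats_b = paired_matrices(5, 6, seed=3)
    t_plus = paired_t_matrix(mats_a, mats_b).values
    t_minus = paired_t_matrix(mats_a, mats_b, flips=-np.ones(5)).values
    off = ~np.eye(6, dtype=bool)
    np.testing.assert_allclose(t_minus[off], -t_plus[off], atol=1e-12)


def test_matches_scalar_paired_t_oracle(paired_matrices):
    mats_a, mats_b = paired_matrices(4, 5, seed=9)
    tm = paired_t_matrix(mats_a, mats_b).values
    for i in range(5):
        for j in range(i + 1, 5):
            a = [m[i, j] for m in mats_a]
            b = [m[i, j] for m in mats_b]
            assert tm[i, j] == pytest.approx(paired_t_scalar(a, b), abs=1e-12)


def test_paired_t_errors(paired_matrices):
    mats_a, mats_b = paired_matrices(2, 4, seed=1)
    with pytest.raises(ValueError, match="2 subjects"):
        paired_t_matrix(mats_a[:1], mats_b[:1])
    with pytest.raises(ValueError, match="differ"):
        paired_t_matrix(mats_a, [m[:3, :3] for m in mats_b])


# ---------------------------------------------------------------------------
# thresholding and link counts


def test_subthreshold_matrix_gives_no_links(paired_matrices):
    mats_a, mats_b = paired_matrices(4, 5, seed=2)
    tm = paired_t_matrix(mats_a, mats_b)
    t0 = np.nanmax(np.abs(tm.values)) + 1.0
    for sign in ("positive", "negative"):
        adj = threshold_to_adjacency(tm, t0, sign)
        assert adj.values.sum() == 0


def test_single_suprathreshold_pair_counts_twice(paired_matrices):
    mats_a, mats_b = paired_matrices(4, 6, seed=5)
    tm = paired_t_matrix(mats_a, mats_b)
    iu, ju = np.triu_indices(6, k=1)
    order = np.argsort(tm.values[iu, ju])[::-1]
    top = order[0]
    second = tm.values[iu[order[1]], ju[order[1]]]
    t0 = (tm.values[iu[top], ju[top]] + second) / 2
    adj = threshold_to_adjacency(tm, t0, "positive")
    assert adj.values.sum() == 2  # symmetric pair
    assert adj.values[iu[top], ju[top]] == 1
    grid = MaskedGrid(np.ones((2, 3), bool))
    lcm = link_count_map(adj, grid)
    assert lcm.counts.sum() == 2
    assert sorted(lcm.counts)[-2:] == [1, 1]


def test_threshold_matches_elementwise_oracle(rng):
    vals = rng.standard_normal((20, 20)) * 2
    vals = (vals + vals.T) / 2
    tm = paired_t_matrix(  # only used for its container; overwrite values
        [np.eye(20)] * 2, [np.eye(20) * 0.5] * 2
    )
    tm.values = vals.copy()
    np.fill_diagonal(tm.values, np.nan)
    adj = threshold_to_adjacency(tm, 2.0, "positive")
    for i in range(20):
        for j in range(20):
            expect = 0 if i == j else int(vals[i, j] > 2.0)
            assert adj.values[i, j] == expect
    neg = threshold_to_adjacency(tm, 2.0, "negative")
    for i in range(20):
        for j in range(20):
            expect = 0 if i == j else int(vals[i, j] < -2.0)
            assert neg.values[i, j] == expect
    with pytest.raises(ValueError):
        threshold_to_adjacency(tm, -1.0, "positive")


def test_link_counts_are_row_sums(rng, grid2d):
    n = grid2d.n_voxels
    raw = rng.random((n, n)) < 0.1
    adj_vals = np.triu(raw, 1)
    adj_vals = (adj_vals + adj_vals.T).astype(np.uint8)
    adj = AdjacencyMatrix(adj_vals, threshold_value=2.0, sign="positive")
    lcm = link_count_map(adj, grid2d)
    np.testing.assert_array_equal(lcm.counts, adj_vals.sum(axis=1))
    assert lcm.counts.sum() % 2 == 0  # every link counted at both endpoints


# ---------------------------------------------------------------------------
# cluster extraction


def _lcm_from_counts(counts_img, sign="positive"):
    grid = MaskedGrid(np.ones(counts_img.shape, bool))
    return LinkCountMap(counts_img.ravel(), grid, sign=sign)


def test_single_voxel_cluster():
    counts = np.zeros((3, 3), dtype=int)
    counts[1, 1] = 3
    clusters = extract_clusters(_lcm_from_counts(counts))
    assert len(clusters) == 1
    assert clusters[0].css_extent == 1
    assert clusters[0].cms_mass == 3


def test_corner_contact_does_not_join_3d_clusters():
    counts = np.zeros((2, 2, 2), dtype=int)
    counts[0, 0, 0] = 1
    counts[1, 1, 1] = 1  # shares only a corner with the first voxel
    grid = MaskedGrid(np.ones((2, 2, 2), bool))
    clusters = extract_clusters(LinkCountMap(counts.ravel(), grid))
    assert [c.css_extent for c in clusters] == [1, 1]


def test_edge_contact_joins_3d_clusters():
    counts = np.zeros((2, 2, 2), dtype=int)
    counts[0, 0, 0] = 1
    counts[1, 1, 0] = 1  # shares an edge
    grid = MaskedGrid(np.ones((2, 2, 2), bool))
    clusters = extract_clusters(LinkCountMap(counts.ravel(), grid))
    assert [c.css_extent for c in clusters] == [2]


def test_matches_bfs_oracle_on_random_3d_maps(rng):
    grid = MaskedGrid(np.ones((8, 8, 8), bool))
    for _ in range(10):
        binary = rng.random((8, 8, 8)) < 0.25
        counts = binary.astype(int) * rng.integers(1, 5, (8, 8, 8))
        clusters = extract_clusters(LinkCountMap(counts.ravel(), grid))
        expected = bfs_clusters(binary)
        got = [set(map(tuple, c.member_coords)) for c in clusters]
        assert sorted(map(sorted, got)) == sorted(map(sorted, expected))


def test_compact_cluster_with_scattered_partners_extents_five_and_eight():
    """A compact 5-voxel cluster holding 8 link endpoints: CSS 5, CMS 8.

    Eight links connect a contiguous block of five voxels to eight isolated
    voxels elsewhere; the largest cluster by extent has five voxels and by
    mass eight link endpoints.
    """
    grid = MaskedGrid(np.ones((5, 9), bool))
    n = grid.n_voxels
    block = [grid.index_of((2, c)) for c in range(5)]  # contiguous row of 5
    partners = [grid.index_of(c) for c in
                [(0, 0), (0, 2), (0, 4), (0, 6), (0, 8), (4, 1), (4, 4), (4, 7)]]
    links = list(zip([block[0], block[0], block[1], block[1], block[2],
                      block[2], block[3], block[4]], partners))
    adj = np.zeros((n, n), dtype=np.uint8)
    for u, v in links:
        adj[u, v] = adj[v, u] = 1
    lcm = link_count_map(AdjacencyMatrix(adj, 2.0, "positive"), grid)
    max_css, max_cms = max_statistics(lcm)
    assert (max_css, max_cms) == (5, 8)


def test_max_statistics_reduces_extract_clusters(rng):
    grid = MaskedGrid(np.ones((6, 6), bool))
    counts = (rng.random((6, 6)) < 0.4) * rng.integers(1, 6, (6, 6))
    lcm = LinkCountMap(counts.ravel(), grid)
    clusters = extract_clusters(lcm)
    max_css, max_cms = max_statistics(lcm)
    if clusters:
        assert max_css == max(c.css_extent for c in clusters)
        assert max_cms == max(c.cms_mass for c in clusters)
    else:
        assert (max_css, max_cms) == (0, 0)
    # per-cluster invariants
    for c in clusters:
        assert c.cms_mass >= c.css_extent
    # mass conservation: no link mass lost or invented by clustering
    assert sum(c.cms_mass for c in clusters) == counts.sum()


def test_empty_map_yields_no_clusters(grid2d):
    lcm = LinkCountMap(np.zeros(grid2d.n_voxels, int), grid2d)
    assert extract_clusters(lcm) == []
    assert max_statistics(lcm) == (0, 0)


def test_once_per_link_mass_mode():
    # two voxels linked to each other and each to one far voxel:
    # endpoint mass = 4 for the pair cluster, link mass = 3
    grid = MaskedGrid(np.ones((1, 7), bool))
    adj = np.zeros((7, 7), dtype=np.uint8)
    for u, v in [(0, 1), (0, 3), (1, 5)]:
        adj[u, v] = adj[v, u] = 1
    amat = AdjacencyMatrix(adj, 2.0, "positive")
    lcm = link_count_map(amat, grid)
    clusters = extract_clusters(lcm, adjacency=amat, mass_mode="endpoint")
    pair = max(clusters, key=lambda c: c.css_extent)
    assert pair.cms_mass == 4
    clusters = extract_clusters(lcm, adjacency=amat, mass_mode="link")
    pair = max(clusters, key=lambda c: c.css_extent)
    assert pair.cms_mass == 3


def test_negating_differences_swaps_sign_clusters(paired_matrices, grid2d):
    mats_a, mats_b = paired_matrices(5, grid2d.n_voxels, seed=17)
    t0 = 2.0
    tm_ab = paired_t_matrix(mats_a, mats_b)
    tm_ba = paired_t_matrix(mats_b, mats_a)
    for s1, s2 in (("positive", "negative"), ("negative", "positive")):
        lcm1 = link_count_map(threshold_to_adjacency(tm_ab, t0, s1), grid2d)
        lcm2 = link_count_map(threshold_to_adjacency(tm_ba, t0, s2), grid2d)
        np.testing.assert_array_equal(lcm1.counts, lcm2.counts)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_cluster_partition_properties(seed):
    """Clusters partition the linked voxels; members all hold >= 1 link."""
    local = np.random.default_rng(seed)
    grid = MaskedGrid(np.ones((5, 5), bool))
    counts = (local.random((5, 5)) < 0.4) * local.integers(1, 4, (5, 5))
    lcm = LinkCountMap(counts.ravel(), grid)
    clusters = extract_clusters(lcm)
    all_members = np.concatenate(
        [c.member_indices for c in clusters]
    ) if clusters else np.array([], dtype=int)
    assert len(all_members) == len(set(all_members.tolist()))
    assert set(all_members.tolist()) == set(np.flatnonzero(counts.ravel()).tolist())
    for c in clusters:
        assert np.all(counts.ravel()[c.member_indices] >= 1)
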