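import numpy as np
import pytest

from connclust import (
    MaskedGrid,
    MaxStatDistribution,
    cluster_null_distributions,
    elementwise_maxt_test,
    enumerate_flips,
    fwe_pvalue,
    null_distribution_cluster,
    pearson_connectivity,
)

from _oracles import max_cluster_stats_straightline, signflip_pvalue_scalar


# ---------------------------------------------------------------------------
# flip enumeration


def test_full_enumeration_two_subjects():
    scheme = enumerate_flips(2, "full")
    rows = {tuple(r) for r in scheme.flips.tolist()}
    assert rows == {(1, 1), (1, -1), (-1, 1), (-1, -1)}
    assert tuple(scheme.flips[0]) == (1, 1)  # identity first


def test_subset_is_deterministic_and_contains_identity():
    a = enumerate_flips(5, "subset", n_permutations=8, seed=42)
    b = enumerate_flips(5, "subset", n_permutations=8, seed=42)
    np.testing.assert_array_equal(a.flips, b.flips)
    assert tuple(a.flips[0]) == (1,) * 5
    assert len({tuple(r) for r in a.flips.tolist()}) == 8


def test_subset_larger_than_universe_fails():
    with pytest.raises(ValueError):
        enumerate_flips(3, "subset", n_permutations=9, seed=0)


# ---------------------------------------------------------------------------
# cluster null distributions


def _paired_scans(n, n_vox, T, seed):
    rng = np.random.default_rng(seed)
    mats_a = [pearson_connectivity(rng.standard_normal((n_vox, T))).values
              for _ in range(n)]
    mats_b = [pearson_connectivity(rng.standard_normal((n_vox, T))).values
              for _ in range(n)]
    return mats_a, mats_b


def test_perfect_null_gives_all_zero_distribution():
    mats, _ = _paired_scans(3, 4, 12, seed=0)
    grid = MaskedGrid(np.ones((2, 2), bool))
    scheme = enumerate_flips(3, "full")
    dist = null_distribution_cluster(mats, mats, 2.0, "css", scheme, grid)
    assert np.all(dist.values == 0)


def test_matches_straightline_recomputation_over_all_flips():
    mats_a, mats_b = _paired_scans(3, 4, 15, seed=7)
    mask = np.ones((2, 2), bool)
    grid = MaskedGrid(mask)
    scheme = enumerate_flips(3, "full")
    t0 = 1.5
    dists = cluster_null_distributions(mats_a, mats_b, t0, scheme, grid)
    for p in range(scheme.n_permutations):
        css, cms = max_cluster_stats_straightline(
            mats_a, mats_b, scheme.flips[p], t0, mask
        )
        assert dists["css"].values[p] == css
        assert dists["cms"].values[p] == cms


def test_negative_threshold_distribution_equals_positive():
    mats_a, mats_b = _paired_scans(5, 9, 20, seed=3)
    grid = MaskedGrid(np.ones((3, 3), bool))
    scheme = enumerate_flips(5, "full")
    pos = cluster_null_distributions(mats_a, mats_b, 2.5, scheme, grid,
                                     sign="positive")
    neg = cluster_null_distributions(mats_a, mats_b, 2.5, scheme, grid,
                                     sign="negative")
    for kind in ("css", "cms"):
        np.testing.assert_array_equal(np.sort(pos[kind].values),
                                      np.sort(neg[kind].values))


def test_half_enumeration_reproduces_full_distribution():
    """One member of each {f, -f} pair, at both signs, gives the full null."""
    mats_a, mats_b = _paired_scans(4, 9, 18, seed=11)
    grid = MaskedGrid(np.ones((3, 3), bool))
    scheme = enumerate_flips(4, "full")
    full = cluster_null_distributions(mats_a, mats_b, 2.0, scheme, grid)
    # half set: keep the labelling where subject 0 is unflipped
    half_rows = scheme.flips[scheme.flips[:, 0] == 1]
    half = enumerate_flips(4, "full")
    half.flips = half_rows
    pos = cluster_null_distributions(mats_a, mats_b, 2.0, half, grid,
                                     sign="positive")
    neg = cluster_null_distributions(mats_a, mats_b, 2.0, half, grid,
                                     sign="negative")
    for kind in ("css", "cms"):
        combined = np.concatenate([pos[kind].values, neg[kind].values])
        np.testing.assert_array_equal(np.sort(combined),
                                      np.sort(full[kind].values))


# ---------------------------------------------------------------------------
# p-values


def test_extreme_observation_p_is_one_over_permutations():
    values = np.zeros(4096)
    values[0] = 50  # identity is the largest
    dist = MaxStatDistribution("css", values)
    assert fwe_pvalue(50, dist) == pytest.approx(1 / 4096)
    assert fwe_pvalue(50, dist, "two") == pytest.approx(2 / 4096)


def test_minimum_observation_p_is_one(rng):
    values = rng.integers(5, 50, size=200)
    dist = MaxStatDistribution("css", values)
    assert fwe_pvalue(values.min(), dist) == 1.0


def test_pvalue_matches_count_oracle(rng):
    values = rng.integers(0, 30, size=100)
    dist = MaxStatDistribution("css", values)
    for obs in range(0, 35, 3):
        expect = np.count_nonzero(values >= obs) / 100
        assert fwe_pvalue(obs, dist) == pytest.approx(expect)
    # monotonicity: non-increasing in the observed statistic
    ps = [fwe_pvalue(o, dist) for o in range(0, 35)]
    assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))


def test_validity_floor_with_identity_included():
    mats_a, mats_b = _paired_scans(4, 4, 10, seed=5)
    grid = MaskedGrid(np.ones((2, 2), bool))
    scheme = enumerate_flips(4, "full")
    dist = null_distribution_cluster(mats_a, mats_b, 1.0, "css", scheme, grid)
    # identity value is in the distribution, so p >= 1/P always
    assert fwe_pvalue(dist.values[0], dist) >= 1 / scheme.n_permutations


# ---------------------------------------------------------------------------
# element-wise max/min t test


def test_min_t_distribution_mirrors_max_t():
    mats_a, mats_b = _paired_scans(5, 6, 14, seed=21)
    scheme = enumerate_flips(5, "full")
    max_d, min_d, _ = elementwise_maxt_test(mats_a, mats_b, scheme)
    np.testing.assert_array_equal(np.sort(min_d.values),
                                  -np.sort(max_d.values)[::-1])


def test_single_element_reduces_to_textbook_signflip_test():
    rng = np.random.default_rng(31)
    n = 8
    a = rng.normal(0.3, 1.0, n)
    b = rng.normal(0.0, 1.0, n)
    # two-voxel matrices with the paired values in the off-diagonal element
    mats_a = [np.array([[1.0, x], [x, 1.0]]) for x in a]
    mats_b = [np.array([[1.0, x], [x, 1.0]]) for x in b]
    scheme = enumerate_flips(n, "full")
    max_d, min_d, sig = elementwise_maxt_test(mats_a, mats_b, scheme)
    p_package = (np.count_nonzero(max_d.values >= max_d.values[0])
                 / scheme.n_permutations)
    assert p_package == pytest.approx(signflip_pvalue_scalar(a, b))


def test_flagged_elements_respect_alpha_tails():
    mats_a, mats_b = _paired_scans(6, 8, 25, seed=2)
    scheme = enumerate_flips(6, "full")
    alpha = 0.2
    max_d, min_d, sig = elementwise_maxt_test(mats_a, mats_b, scheme, alpha)
    assert sig.shape == (8, 8)
    assert not sig.diagonal().any()
    np.testing.assert_array_equal(sig, sig.T)
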