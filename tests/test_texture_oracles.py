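"""Texture matrices against exhaustive-enumeration oracles on toy volumes.

The oracles below recompute every grey-level matrix by explicit Python
loops over voxels, neighbours and connected regions, independent of the
vectorised implementations.
"""

import numpy as np
import pytest

from artomics import texture as tx


def tiny_pattern(seed, shape=(5, 5, 4), n_levels=3):
    rng = np.random.default_rng(seed)
    levels = rng.integers(1, n_levels + 1, size=shape)
    mask = rng.random(shape) < 0.8
    mask[2, 2, 2] = True
    levels = np.where(mask, levels, 0)
    return levels.astype(np.int64), mask


def checkerboard(shape=(4, 4, 1)):
    idx = np.indices(shape).sum(axis=0)
    levels = (idx % 2 + 1).astype(np.int64)
    return levels, np.ones(shape, dtype=bool)


ALL_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def inside(p, shape):
    return all(0 <= c < s for c, s in zip(p, shape))


def oracle_glcm(levels, mask, ng):
    """Direction-averaged symmetric normalised GLCM by voxel-pair loops."""
    mats = []
    for d in tx.DIRECTIONS_13:
        P = np.zeros((ng, ng))
        for p in np.argwhere(mask):
            q = tuple(p + d)
            if inside(q, mask.shape) and mask[q]:
                i, j = levels[tuple(p)], levels[q]
                P[i - 1, j - 1] += 1
                P[j - 1, i - 1] += 1
        if P.sum():
            mats.append(P / P.sum())
    return np.mean(mats, axis=0)


def oracle_glrlm(levels, mask, ng):
    """Run-length matrix by walking every line in all 13 directions."""
    runs = []
    for d in tx.DIRECTIONS_13:
        seen = set()
        for p in map(tuple, np.argwhere(mask)):
            prev = tuple(np.subtract(p, d))
            if inside(prev, mask.shape) and mask[prev] and levels[prev] == levels[p]:
                continue  # not a run head
            length = 1
            cur = p
            while True:
                nxt = tuple(np.add(cur, d))
                if inside(nxt, mask.shape) and mask[nxt] and levels[nxt] == levels[p]:
                    length += 1
                    cur = nxt
                else:
                    break
            runs.append((d, levels[p], length))
    max_len = max(r[2] for r in runs)
    P = np.zeros((ng, max_len))
    for _, lev, length in runs:
        P[lev - 1, length - 1] += 1
    return P


def oracle_glszm(levels, mask, ng):
    """Size-zone matrix by breadth-first search over 26-connected zones."""
    visited = np.zeros(mask.shape, dtype=bool)
    zones = []
    for p in map(tuple, np.argwhere(mask)):
        if visited[p]:
            continue
        g = levels[p]
        stack, size = [p], 0
        visited[p] = True
        while stack:
            cur = stack.pop()
            size += 1
            for d in ALL_26:
                q = tuple(np.add(cur, d))
                if (
                    inside(q, mask.shape)
                    and mask[q]
                    and not visited[q]
                    and levels[q] == g
                ):
                    visited[q] = True
                    stack.append(q)
        zones.append((g, size))
    max_size = max(s for _, s in zones)
    P = np.zeros((ng, max_size))
    for g, s in zones:
        P[g - 1, s - 1] += 1
    return P


def oracle_gldm(levels, mask, ng):
    """Dependence matrix: 1 + equal-level in-mask 26-neighbours per voxel."""
    deps = []
    for p in map(tuple, np.argwhere(mask)):
        dep = 1
        for d in ALL_26:
            q = tuple(np.add(p, d))
            if inside(q, mask.shape) and mask[q] and levels[q] == levels[p]:
                dep += 1
        deps.append((levels[p], dep))
    max_dep = max(d for _, d in deps)
    P = np.zeros((ng, max_dep))
    for g, d in deps:
        P[g - 1, d - 1] += 1
    return P


def oracle_ngtdm(levels, mask, ng):
    """n_i and s_i by explicit neighbourhood averaging."""
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    for p in map(tuple, np.argwhere(mask)):
        nb = [
            levels[tuple(np.add(p, d))]
            for d in ALL_26
            if inside(tuple(np.add(p, d)), mask.shape) and mask[tuple(np.add(p, d))]
        ]
        g = levels[p]
        n_i[g - 1] += 1
        if nb:
            s_i[g - 1] += abs(g - np.mean(nb))
    return n_i, s_i


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_glcm_matrix_matches_pair_enumeration(seed):
    levels, mask = tiny_pattern(seed)
    ng = int(levels.max())
    np.testing.assert_allclose(
        tx.glcm_matrix(levels, mask, ng), oracle_glcm(levels, mask, ng), atol=1e-12
    )


def test_glcm_contrast_on_checkerboard():
    levels, mask = checkerboard()
    ng = 2
    P = tx.glcm_matrix(levels, mask, ng)
    feats = tx.glcm_features(P)
    Po = oracle_glcm(levels, mask, ng)
    contrast_oracle = sum(
        (i - j) ** 2 * Po[i - 1, j - 1] for i in (1, 2) for j in (1, 2)
    )
    assert feats["Contrast"] == pytest.approx(contrast_oracle, abs=1e-12)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_glrlm_matrix_matches_run_enumeration(seed):
    levels, mask = tiny_pattern(seed, shape=(6, 6, 6))
    ng = int(levels.max())
    fast = tx.glrlm_matrix(levels, mask, ng)
    slow = oracle_glrlm(levels, mask, ng)
    np.testing.assert_array_equal(fast, slow)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_glszm_matrix_matches_flood_fill(seed):
    levels, mask = tiny_pattern(seed, shape=(6, 6, 6))
    ng = int(levels.max())
    np.testing.assert_array_equal(
        tx.glszm_matrix(levels, mask, ng), oracle_glszm(levels, mask, ng)
    )


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_gldm_matrix_matches_neighbour_counts(seed):
    levels, mask = tiny_pattern(seed, shape=(6, 6, 6))
    ng = int(levels.max())
    np.testing.assert_array_equal(
        tx.gldm_matrix(levels, mask, ng), oracle_gldm(levels, mask, ng)
    )


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_ngtdm_table_matches_neighbourhood_loops(seed):
    levels, mask = tiny_pattern(seed, shape=(6, 6, 6))
    ng = int(levels.max())
    n_i, s_i = tx.ngtdm_table(levels, mask, ng)
    n_o, s_o = oracle_ngtdm(levels, mask, ng)
    np.testing.assert_array_equal(n_i, n_o)
    np.testing.assert_allclose(s_i, s_o, atol=1e-10)


def test_discretize_conventions():
    x = np.array([0.0, 24.9, 25.0, 100.0])
    np.testing.assert_array_equal(tx.discretize(x, bin_width=25), [1, 1, 2, 5])
    y = np.array([0.0, 0.5, 1.0])
    np.testing.assert_array_equal(tx.discretize(y, n_bins=4), [1, 2, 4])
    np.testing.assert_array_equal(tx.discretize(np.ones(3), n_bins=4), [1, 1, 1])


def test_first_order_constant_voi():
    vals = np.full(27, 7.0)
    levels = tx.discretize(vals, bin_width=25)
    f = tx.first_order_features(vals, levels)
    assert f["Mean"] == 7.0
    assert f["Variance"] == 0.0
    assert f["Skewness"] == 0.0 and f["Kurtosis"] == 0.0  # documented fallback
    assert f["Uniformity"] == 1.0


def test_degenerate_texture_fallbacks_are_finite():
    """A constant VOI yields the documented fallbacks, never NaN."""
    vals = np.ones((4, 4, 4))
    feats = tx.intensity_features(vals, np.ones((4, 4, 4), bool), bin_width=25)
    assert all(np.isfinite(v) for v in feats.values())
    assert feats["ngtdm_Coarseness"] == tx.COARSENESS_MAX
    assert feats["glcm_Contrast"] == 0.0
    assert feats["glcm_Correlation"] == 1.0


@pytest.mark.parametrize("seed", [11, 12])
def test_all_features_finite_on_random_vois(seed):
    rng = np.random.default_rng(seed)
    vals = rng.normal(size=(8, 8, 8))
    mask = rng.random((8, 8, 8)) < 0.6
    if mask.sum() < 8:
        mask[:2, :2, :2] = True
    feats = tx.intensity_features(vals, mask, n_bins=16)
    assert len(feats) == 93
    assert all(np.isfinite(v) for v in feats.values())


def test_small_voi_rejected():
    with pytest.raises(ValueError, match="too small"):
        tx.intensity_features(np.ones((2, 2, 2)), np.zeros((2, 2, 2), bool), n_bins=4)
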