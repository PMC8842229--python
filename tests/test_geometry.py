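"""Geometric primitives against brute-force oracles."""

import numpy as np
import pytest

from artomics.datamodel import Role, VOIMask
from artomics.geometry import (
    assign_parotid_laterality,
    dilate,
    min_distances_to_surface,
    surface_mask,
    surface_voxels,
)

from conftest import random_blob_mask


def brute_force_surface(mask: np.ndarray) -> np.ndarray:
    """Voxels with at least one six-connected background neighbour."""
    out = np.zeros_like(mask)
    for p in np.argwhere(mask):
        for d in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
            q = p + d
            if np.any(q < 0) or np.any(q >= mask.shape) or not mask[tuple(q)]:
                out[tuple(p)] = True
                break
    return out


def brute_force_min_distances(src: VOIMask, tgt: VOIMask) -> np.ndarray:
    surf = np.argwhere(brute_force_surface(tgt.values)) * np.asarray(tgt.spacing)
    pts = np.argwhere(src.values) * np.asarray(src.spacing)
    d = np.sqrt(((pts[:, None, :] - surf[None, :, :]) ** 2).sum(-1))
    return d.min(axis=1)


def test_single_voxel_surface_is_its_center():
    m = np.zeros((5, 5, 5), dtype=bool)
    m[2, 3, 1] = True
    pts = surface_voxels(VOIMask(m, (1.0, 2.0, 3.0), Role.GTVNP))
    np.testing.assert_allclose(pts, [[2.0, 6.0, 3.0]])


def test_cube_surface_count():
    m = np.zeros((9, 9, 9), dtype=bool)
    m[2:7, 2:7, 2:7] = True
    surf = surface_mask(VOIMask(m, (1, 1, 1), Role.GTVNP))
    assert surf.sum() == 5**3 - 3**3  # 98


def test_surface_translation_equivariance():
    rng = np.random.default_rng(3)
    m = random_blob_mask(rng, shape=(12, 12, 12), max_voxels=200)
    # clear the boundary so the roll is a pure translation (no wrap-around)
    interior = np.zeros_like(m.values)
    interior[1:-3, 1:-3, 1:-2] = m.values[1:-3, 1:-3, 1:-2]
    m = VOIMask(interior, m.spacing, m.role)
    shifted = np.roll(m.values, (1, 2, 1), axis=(0, 1, 2))
    a = surface_voxels(m)
    b = surface_voxels(VOIMask(shifted, m.spacing, m.role))
    shift_mm = np.array([1, 2, 1]) * np.asarray(m.spacing)
    np.testing.assert_allclose(
        sorted(map(tuple, a + shift_mm)), sorted(map(tuple, b)), atol=1e-12
    )


def test_min_distance_trivial_cases():
    a = np.zeros((8, 8, 8), dtype=bool)
    b = np.zeros((8, 8, 8), dtype=bool)
    a[1, 1, 1] = True
    b[6, 1, 1] = True
    src = VOIMask(a, (1, 1, 1), Role.PG_LEFT)
    tgt = VOIMask(b, (1, 1, 1), Role.GTVNP)
    np.testing.assert_allclose(min_distances_to_surface(src, tgt), [5.0])
    # coincident voxel: distance zero
    np.testing.assert_allclose(min_distances_to_surface(tgt, tgt), [0.0])


@pytest.mark.parametrize("seed", range(12))
def test_min_distance_matches_pairwise_oracle(seed):
    rng = np.random.default_rng(seed)
    src = random_blob_mask(rng, role=Role.PG_LEFT)
    tgt = random_blob_mask(rng, role=Role.GTVNP)
    fast = np.sort(min_distances_to_surface(src, tgt))
    slow = np.sort(brute_force_min_distances(src, tgt))
    np.testing.assert_allclose(fast, slow, atol=1e-9)


def _parotid_scene(ipsi_left: bool):
    grid = (40, 24, 16)
    gtv = np.zeros(grid, dtype=bool)
    gtv[18:23, 10:14, 6:10] = True
    near = np.zeros(grid, dtype=bool)
    near[10:14, 10:14, 6:10] = True  # ~5 voxels from GTV surface
    far = np.zeros(grid, dtype=bool)
    far[2:6, 10:14, 6:10] = True
    left, right = (near, far) if ipsi_left else (far, near)
    sp = (2.0, 2.0, 2.0)
    return (
        VOIMask(left, sp, Role.PG_LEFT),
        VOIMask(right, sp, Role.PG_RIGHT),
        VOIMask(gtv, sp, Role.GTVNP),
    )


def test_laterality_follows_median_distance():
    left, right, gtv = _parotid_scene(ipsi_left=True)
    assert assign_parotid_laterality(left, right, gtv) == (Role.PG_LEFT, Role.PG_RIGHT)
    left, right, gtv = _parotid_scene(ipsi_left=False)
    assert assign_parotid_laterality(left, right, gtv) == (Role.PG_RIGHT, Role.PG_LEFT)


def test_laterality_tie_resolves_left():
    grid = (31, 11, 11)
    gtv = np.zeros(grid, dtype=bool)
    gtv[14:17, 4:7, 4:7] = True
    pg = np.zeros(grid, dtype=bool)
    pg[2:5, 4:7, 4:7] = True
    sp = (1.0, 1.0, 1.0)
    left = VOIMask(pg, sp, Role.PG_LEFT)
    right = VOIMask(pg[::-1].copy(), sp, Role.PG_RIGHT)  # exact mirror
    assert assign_parotid_laterality(left, right, VOIMask(gtv, sp, Role.GTVNP)) == (
        Role.PG_LEFT,
        Role.PG_RIGHT,
    )


def test_laterality_mirror_equivariance():
    # mirror-symmetric parotids with a laterally displaced tumour: the
    # mirror image of the scene must swap the assignment
    grid = (40, 24, 16)
    sp = (2.0, 2.0, 2.0)
    pg_l = np.zeros(grid, dtype=bool)
    pg_l[2:6, 10:14, 6:10] = True
    pg_r = np.zeros(grid, dtype=bool)
    pg_r[34:38, 10:14, 6:10] = True  # exact mirror position of pg_l
    gtv = np.zeros(grid, dtype=bool)
    gtv[24:29, 10:14, 6:10] = True  # displaced towards the right parotid
    def assign_by_anatomical_side(pg_a, pg_b, tumour):
        """Label the parotids by centroid (smaller x = left), then assign."""
        ca = np.argwhere(pg_a)[:, 0].mean()
        cb = np.argwhere(pg_b)[:, 0].mean()
        left, right = (pg_a, pg_b) if ca < cb else (pg_b, pg_a)
        return assign_parotid_laterality(
            VOIMask(left, sp, Role.PG_LEFT),
            VOIMask(right, sp, Role.PG_RIGHT),
            VOIMask(tumour, sp, Role.GTVNP),
        )

    before = assign_by_anatomical_side(pg_l, pg_r, gtv)
    after = assign_by_anatomical_side(
        pg_l[::-1].copy(), pg_r[::-1].copy(), gtv[::-1].copy()
    )
    assert before == (Role.PG_RIGHT, Role.PG_LEFT)
    assert after == (Role.PG_LEFT, Role.PG_RIGHT)


def test_dilate_zero_radius_is_identity():
    rng = np.random.default_rng(5)
    m = random_blob_mask(rng)
    np.testing.assert_array_equal(dilate(m, 0.0).values, m.values)


def test_dilate_single_voxel_counts_lattice_points():
    m = np.zeros((9, 9, 9), dtype=bool)
    m[4, 4, 4] = True
    mask = VOIMask(m, (1, 1, 1), Role.GTVN)
    # lattice points within Euclidean distance 2.5 of the origin
    r = np.arange(-3, 4)
    X, Y, Z = np.meshgrid(r, r, r, indexing="ij")
    expected = int(((X**2 + Y**2 + Z**2) <= 2.5**2).sum())
    assert expected == 81
    assert dilate(mask, 2.5).count() == expected


def test_dilate_monotone_in_radius():
    rng = np.random.default_rng(9)
    m = random_blob_mask(rng, shape=(12, 12, 12), max_voxels=100)
    small = dilate(m, 1.5).values
    large = dilate(m, 3.5).values
    assert np.all(large[small])
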