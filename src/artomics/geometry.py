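"""Geometric primitives on voxel masks.

Distances are Euclidean, voxel-centre to voxel-centre, in physical mm
(anisotropic spacing respected).  "Surface" voxels are mask voxels with at
least one six-connected background neighbour; voxels on the grid boundary
count as surface.  All exact nearest-distance queries are answered with
the exact Euclidean distance transform (:func:`scipy.ndimage.distance_transform_edt`),
which returns, for every voxel, the distance to the nearest feature voxel
centre — identical to the brute-force all-pairs minimum.
"""

from __future__ import annotations

import logging
from typing import Tuple

import numpy as np
from scipy import ndimage

from .datamodel import Role, VOIMask

log = logging.getLogger(__name__)


def surface_mask(mask: VOIMask) -> np.ndarray:
    """Boolean grid of surface voxels (six-connectivity convention)."""
    mask.require_nonempty()
    m = mask.values
    eroded = ndimage.binary_erosion(
        m, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return m & ~eroded


def surface_voxels(mask: VOIMask, origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)) -> np.ndarray:
    """Physical coordinates (mm) of surface-voxel centres, shape (n, 3)."""
    surf = surface_mask(mask)
    idx = np.argwhere(surf).astype(np.float64)
    return idx * np.asarray(mask.spacing) + np.asarray(origin)


def _distance_to_voxels(target: np.ndarray, spacing) -> np.ndarray:
    """Distance (mm) from every grid voxel to the nearest True voxel of target."""
    if not target.any():
        raise ValueError("empty target voxel set")
    return ndimage.distance_transform_edt(~target, sampling=spacing)


def min_distances_to_surface(source: VOIMask, target: VOIMask) -> np.ndarray:
    """For every voxel of ``source``, min distance (mm) to ``target``'s surface.

    Source voxels are all mask voxels ("volume", not surface); the target
    side uses surface voxels only.
    """
    source.require_nonempty()
    dist = _distance_to_voxels(surface_mask(target), source.spacing)
    return dist[source.values]


def signed_distance_to_surface(grid_mask: np.ndarray, target: VOIMask) -> np.ndarray:
    """Signed distance (mm) to ``target``'s surface for every grid voxel.

    Magnitude is the distance to the nearest surface-voxel centre; the sign
    is negative for voxels inside ``target`` (surface voxels themselves are
    inside, at distance 0).
    """
    dist = _distance_to_voxels(surface_mask(target), target.spacing)
    signed = np.where(target.values, -dist, dist)
    return signed


def median_surface_distance(voi: VOIMask, reference: VOIMask) -> float:
    """Median over ``voi`` voxels of min distance to ``reference``'s surface.

    Even-length medians are the mean of the two central values.
    """
    return float(np.median(min_distances_to_surface(voi, reference)))


def assign_parotid_laterality(
    pg_left: VOIMask, pg_right: VOIMask, gtvnp: VOIMask
) -> Tuple[Role, Role]:
    """Ipsi/contra-lateral parotid assignment relative to the primary tumour.

    For each parotid the median, over all its voxels, of the minimum
    distance to the GTVnp surface is computed; the parotid with the smaller
    median is the ipsilateral one.  An exact tie (possible only in
    artificial mirror-symmetric scenes) resolves to the left parotid with a
    logged warning.

    Returns ``(ipsi_side, contra_side)`` as ``Role.PG_LEFT``/``PG_RIGHT``.
    """
    med_left = median_surface_distance(pg_left, gtvnp)
    med_right = median_surface_distance(pg_right, gtvnp)
    if med_left == med_right:
        log.warning(
            "parotid laterality tie (median distance %.3f mm both sides); "
            "resolving to left",
            med_left,
        )
        return Role.PG_LEFT, Role.PG_RIGHT
    if med_left < med_right:
        return Role.PG_LEFT, Role.PG_RIGHT
    return Role.PG_RIGHT, Role.PG_LEFT


def dilate(mask: VOIMask, radius_mm: float) -> VOIMask:
    """Physical dilation: all voxels within ``radius_mm`` of the mask."""
    if radius_mm < 0:
        raise ValueError("radius must be >= 0")
    if radius_mm == 0 or not mask.values.any():
        return VOIMask(mask.values.copy(), mask.spacing, mask.role)
    dist = ndimage.distance_transform_edt(~mask.values, sampling=mask.spacing)
    return VOIMask(dist <= radius_mm, mask.spacing, mask.role)
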