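"""Contouromics (C): inter-organ geometry features from OVH and POV.

The overlap-volume histogram (OVH) of a VOI pair (A, B) is the cumulative
distribution, over A's voxels, of the signed Euclidean distance to B's
surface (negative inside B, so overlapping structures are representable).
Its scalar features are the distances at volume fractions 0%, 5%, ..., 100%
(21 quantiles; 0% is the minimum signed distance, 100% the maximum).

The projection-overlap-volume (POV) at an axial angle theta is the
fraction of A's voxels lying inside the one-sided shadow of B cast along
the in-plane unit direction (cos theta, sin theta, 0): a voxel of A is in
the shadow iff some voxel of B lies behind it (same slice, lateral offset
within half a voxel) along -theta.  Twelve angles at 30 degree steps are
used, giving 21 + 12 = 33 features per pair and 132 over the four pairs

    PTVn_low_dose-SC, GTVnp-IpsiPG, GTVnp-ContraPG, GTVnp-SC

(the first-listed VOI of a pair is A).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .datamodel import (
    FeatureColumn,
    FeatureTable,
    PatientRecord,
    Role,
    VOIMask,
)
from .geometry import signed_distance_to_surface

#: the four (A, B) VOI pairs of the contouromics catalogue
CONTOUROMICS_PAIRS: Tuple[Tuple[Role, Role], ...] = (
    (Role.PTVN_LOW, Role.SC),
    (Role.GTVNP, Role.IPSI_PG),
    (Role.GTVNP, Role.CONTRA_PG),
    (Role.GTVNP, Role.SC),
)

OVH_FRACTIONS = tuple(np.linspace(0.0, 1.0, 21))
POV_ANGLES_DEG = tuple(range(0, 360, 30))
N_PER_PAIR = len(OVH_FRACTIONS) + len(POV_ANGLES_DEG)  # 33


@dataclass
class OVH:
    """Cumulative signed-distance distribution of A relative to B."""

    distances_mm: np.ndarray  # sorted signed distances, one per A voxel
    def __post_init__(self) -> None:
        self.distances_mm = np.sort(np.asarray(self.distances_mm, dtype=np.float64))

    def fraction_at(self, t: float) -> float:
        """OVH(t): fraction of A's voxels with signed distance <= t."""
        return float(np.searchsorted(self.distances_mm, t, side="right")) / len(
            self.distances_mm
        )

    def distance_at_fraction(self, q: float) -> float:
        """Inverse OVH: the signed distance at cumulative volume fraction q.

        q = 0 returns the minimum distance, q = 1 the maximum; in between
        the distance of the ceil(q*N)-th smallest A voxel (a distance an
        actual voxel attains).
        """
        n = len(self.distances_mm)
        k = int(np.ceil(q * n))
        return float(self.distances_mm[max(k, 1) - 1])


def compute_ovh(voi_a: VOIMask, voi_b: VOIMask) -> OVH:
    """Signed distances from every voxel of A to B's surface."""
    voi_a.require_nonempty()
    voi_b.require_nonempty()
    if voi_a.shape != voi_b.shape or not np.allclose(voi_a.spacing, voi_b.spacing):
        raise ValueError("OVH requires masks on a shared grid")
    signed = signed_distance_to_surface(voi_a.values, voi_b)
    return OVH(signed[voi_a.values])


def ovh_scalars(ovh: OVH) -> Dict[str, float]:
    """Distances (mm) at volume fractions 0%, 5%, ..., 100%."""
    return {
        f"OVH{round(q * 100):d}pct": ovh.distance_at_fraction(q)
        for q in OVH_FRACTIONS
    }


def compute_pov(voi_a: VOIMask, voi_b: VOIMask, angle_deg: float) -> float:
    """Fraction of A inside the one-sided axial shadow of B at ``angle_deg``."""
    voi_a.require_nonempty()
    voi_b.require_nonempty()
    if voi_a.shape != voi_b.shape or not np.allclose(voi_a.spacing, voi_b.spacing):
        raise ValueError("POV requires masks on a shared grid")
    theta = np.deg2rad(angle_deg)
    direction = np.array([np.cos(theta), np.sin(theta)])
    sx, sy, _ = voi_a.spacing
    lateral_tol = max(sx, sy) / 2.0
    perp = np.array([-direction[1], direction[0]])

    a_idx = np.argwhere(voi_a.values)
    b_idx = np.argwhere(voi_b.values)
    a_xy = a_idx[:, :2] * np.array([sx, sy])
    b_xy = b_idx[:, :2] * np.array([sx, sy])
    a_s, a_t = a_xy @ direction, a_xy @ perp
    b_s, b_t = b_xy @ direction, b_xy @ perp

    hit = np.zeros(len(a_idx), dtype=bool)
    # same-slice matching only: the projection direction has no z component
    for z in np.unique(a_idx[:, 2]):
        sel_a = a_idx[:, 2] == z
        sel_b = b_idx[:, 2] == z
        if not sel_b.any():
            continue
        dt = np.abs(a_t[sel_a][:, None] - b_t[sel_b][None, :]) <= lateral_tol + 1e-12
        behind = b_s[sel_b][None, :] <= a_s[sel_a][:, None] + 1e-12
        hit[np.flatnonzero(sel_a)] = (dt & behind).any(axis=1)
    return float(hit.mean())


def pair_features(voi_a: VOIMask, voi_b: VOIMask) -> Dict[str, float]:
    """The 33 contouromic features of one ordered VOI pair."""
    out = ovh_scalars(compute_ovh(voi_a, voi_b))
    for ang in POV_ANGLES_DEG:
        out[f"POV{ang:d}deg"] = compute_pov(voi_a, voi_b, ang)
    assert len(out) == N_PER_PAIR
    return out


def assemble_contouromics(cohort: Sequence[PatientRecord]) -> FeatureTable:
    """Family-C table: 33 features x 4 VOI pairs = 132 columns."""
    columns: List[FeatureColumn] = []
    rows = []
    for rec in cohort:
        values: List[float] = []
        cols: List[FeatureColumn] = []
        for role_a, role_b in CONTOUROMICS_PAIRS:
            try:
                feats = pair_features(rec.structures[role_a], rec.structures[role_b])
            except Exception as exc:  # pragma: no cover
                raise RuntimeError(
                    f"contouromics failed for patient {rec.patient_id}, "
                    f"{role_a.value}-{role_b.value}: {exc}"
                ) from exc
            voi = f"{role_a.value}-{role_b.value}"
            for name, v in feats.items():
                cols.append(FeatureColumn("C", voi, name))
                values.append(v)
        if not columns:
            columns = cols
        rows.append(values)
    return FeatureTable(np.array(rows), columns, [r.patient_id for r in cohort])
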