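"""Dosiomics (D): DVH scalars, spatial dose gradients, and dose-map texture.

Per VOI the catalogue is 201 features:

* 102 DVH scalars — Dmax, Dmin, Dmean plus D_x% for x = 1..99, where
  D_x% is the minimum dose received by the hottest x% of the VOI volume
  (hottest-fraction convention with upper-value interpolation on the
  sorted in-VOI dose vector);
* 6 gradient features — mean and standard deviation over VOI voxels of
  the central-difference dose gradient component (Gy/mm) along each
  imaging axis;
* 93 texture features — the shared intensity catalogue applied to the
  dose map restricted to the VOI (original image only, fixed 1 Gy bins).

Across the eight analysis VOIs this yields 1,608 columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from .datamodel import (
    ANALYSIS_ROLES,
    FeatureColumn,
    FeatureTable,
    ImageVolume,
    Modality,
    PatientRecord,
    VOIMask,
)
from .radiomics import ExtractionConfig, crop_to_mask
from .texture import intensity_features

DVH_PERCENTS = tuple(range(1, 100))  # D1% .. D99%
N_DVH_FEATURES = 3 + len(DVH_PERCENTS)  # 102
N_GRADIENT_FEATURES = 6
N_PER_VOI = N_DVH_FEATURES + N_GRADIENT_FEATURES + 93  # 201


@dataclass
class CumulativeDVH:
    """Cumulative dose-volume histogram of one VOI.

    ``fraction[k]`` is the fraction of VOI volume receiving at least
    ``dose_gy[k]``; it is 1 at zero dose, non-increasing, and 0 beyond the
    maximum dose.  All voxels are weighted equally.
    """

    dose_gy: np.ndarray
    fraction: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.dose_gy) <= 0):
            raise ValueError("dose grid must be strictly ascending")
        if np.any(np.diff(self.fraction) > 1e-12):
            raise ValueError("cumulative DVH must be non-increasing")


def compute_dvh(dose: ImageVolume, mask: VOIMask, bin_gy: float = 0.1) -> CumulativeDVH:
    """Cumulative DVH over in-VOI doses on a regular dose grid."""
    if dose.modality is not Modality.DOSE:
        raise ValueError("compute_dvh expects a DOSE volume")
    if bin_gy <= 0:
        raise ValueError("bin_gy must be positive")
    mask.require_nonempty().check_aligned(dose)
    d = dose.values[mask.values]
    grid = np.arange(0.0, d.max() + 2 * bin_gy, bin_gy)
    # fraction of voxels with dose >= t, via one sorted search
    ds = np.sort(d)
    frac = 1.0 - np.searchsorted(ds, grid, side="left") / d.size
    return CumulativeDVH(grid, frac)


def dvh_scalars(dose: ImageVolume, mask: VOIMask) -> Dict[str, float]:
    """Dmax, Dmin, Dmean and D_1% .. D_99% from the raw in-VOI doses.

    The three summary doses are exact (no binning); D_x% takes the
    sorted-descending dose vector and returns element ``ceil(x% * N) - 1``
    (upper-value interpolation: the reported dose is one actually received
    by a voxel, conservatively the coldest voxel inside the hottest x%).
    """
    mask.require_nonempty().check_aligned(dose)
    d = dose.values[mask.values]
    desc = np.sort(d)[::-1]
    n = d.size
    out = {
        "Dmax": float(d.max()),
        "Dmin": float(d.min()),
        "Dmean": float(d.mean()),
    }
    for x in DVH_PERCENTS:
        k = int(np.ceil(x / 100.0 * n))
        out[f"D{x}pct"] = float(desc[max(k, 1) - 1])
    return out


def gradient_features(dose: ImageVolume, mask: VOIMask) -> Dict[str, float]:
    """Mean/SD over VOI voxels of the per-axis dose gradient (Gy/mm).

    Gradients are central differences in the interior with one-sided
    differences at the grid boundary (``numpy.gradient`` convention).
    Masks with fewer than 2 voxels of extent on any axis are degenerate.
    """
    mask.require_nonempty().check_aligned(dose)
    idx = np.argwhere(mask.values)
    extent = idx.max(axis=0) - idx.min(axis=0) + 1
    if np.any(extent < 2):
        raise ValueError(
            f"mask {mask.role.value} has degenerate extent {tuple(extent)}"
        )
    grads = np.gradient(dose.values, *dose.spacing)
    out = {}
    for axis, name in enumerate("xyz"):
        g = grads[axis][mask.values]
        out[f"Gradient{name.upper()}Mean"] = float(g.mean())
        out[f"Gradient{name.upper()}Std"] = float(g.std())
    return out


def dose_texture_features(
    dose: ImageVolume, mask: VOIMask, config: ExtractionConfig
) -> Dict[str, float]:
    """The 93-feature intensity catalogue on the dose map (1 Gy bins)."""
    mask.require_nonempty().check_aligned(dose)
    values, mvals = crop_to_mask(dose.values, mask.values, 1)
    return intensity_features(values, mvals, bin_width=config.dose_bin_width)


def voi_dosiomics(
    dose: ImageVolume, mask: VOIMask, config: ExtractionConfig
) -> Dict[str, float]:
    """All 201 dosiomic features of one VOI."""
    out: Dict[str, float] = {}
    out.update(dvh_scalars(dose, mask))
    out.update(gradient_features(dose, mask))
    out.update(dose_texture_features(dose, mask, config))
    assert len(out) == N_PER_VOI
    return out


def assemble_dosiomics(
    cohort: Sequence[PatientRecord], config: ExtractionConfig
) -> FeatureTable:
    """Family-D table: 201 features x 8 VOIs = 1,608 columns."""
    columns: List[FeatureColumn] = []
    rows = []
    for rec in cohort:
        dose = rec.images[Modality.DOSE]
        values: List[float] = []
        cols: List[FeatureColumn] = []
        for role in ANALYSIS_ROLES:
            try:
                feats = voi_dosiomics(dose, rec.structures[role], config)
            except Exception as exc:  # pragma: no cover
                raise RuntimeError(
                    f"dosiomics failed for patient {rec.patient_id}, "
                    f"{role.value}: {exc}"
                ) from exc
            for name, v in feats.items():
                cols.append(FeatureColumn("D", role.value, name))
                values.append(v)
        if not columns:
            columns = cols
        rows.append(values)
    return FeatureTable(np.array(rows), columns, [r.patient_id for r in cohort])
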