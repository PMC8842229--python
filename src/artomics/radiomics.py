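"""Radiomics (R) and morphology (M) feature extraction.

Image preprocessing follows common standardisation practice for texture
analysis: resampling to an isotropic grid (trilinear for intensities,
nearest-neighbour for masks), z-score normalisation of MR intensities over
the body region, and grey-level discretisation with a fixed bin width for
CT-like images and a fixed bin count for MR-like images.

The filter bank yields 12 response images per volume: the original, the
Laplacian-of-Gaussian at three physical kernel widths, and the eight
sub-bands (HHH ... LLL) of a single-level stationary wavelet transform
with a Coiflet-1 kernel.  Combined with the 93-feature intensity catalogue
this gives 1,116 features per (modality, VOI) pair; radiomics covers the
ten modality-VOI pairs

    CT:  GTVnp, GTVn, IpsiPG, ContraPG
    T1:  GTVnp, IpsiPG, ContraPG
    T2:  GTVnp, IpsiPG, ContraPG

for 11,160 columns.  Morphology is 14 shape descriptors of each of the
four tumour/parotid VOIs (56 columns).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pywt
from scipy import ndimage
from skimage.measure import marching_cubes, mesh_surface_area

from .datamodel import (
    FeatureColumn,
    FeatureTable,
    ImageVolume,
    Modality,
    PatientRecord,
    Role,
    VOIMask,
)
from .texture import N_INTENSITY_FEATURES, intensity_features

#: Table-1 modality-VOI source map for radiomics
RADIOMICS_SOURCES: Tuple[Tuple[Modality, Role], ...] = (
    (Modality.CT, Role.GTVNP),
    (Modality.CT, Role.GTVN),
    (Modality.CT, Role.IPSI_PG),
    (Modality.CT, Role.CONTRA_PG),
    (Modality.T1, Role.GTVNP),
    (Modality.T1, Role.IPSI_PG),
    (Modality.T1, Role.CONTRA_PG),
    (Modality.T2, Role.GTVNP),
    (Modality.T2, Role.IPSI_PG),
    (Modality.T2, Role.CONTRA_PG),
)

#: VOIs entering the morphology family
MORPHOLOGY_VOIS: Tuple[Role, ...] = (
    Role.GTVNP,
    Role.GTVN,
    Role.IPSI_PG,
    Role.CONTRA_PG,
)

WAVELET_SUBBANDS = ("HHH", "HHL", "HLH", "HLL", "LHH", "LHL", "LLH", "LLL")


@dataclass
class ExtractionConfig:
    """Tunable extraction parameters (the catalogue itself is fixed).

    ``resample_spacing`` is the isotropic grid (mm) images and masks are
    resampled to before filtering; the default of 2 mm matches the
    synthetic cohort's native grid so desk-scale runs skip interpolation.
    """

    resample_spacing: float = 2.0
    ct_bin_width: float = 25.0
    mr_bins: int = 64
    dose_bin_width: float = 1.0
    log_sigmas_mm: Tuple[float, ...] = (1.0, 3.0, 6.0)
    wavelet: str = "coif1"
    crop_margin_voxels: int = 8

    def discretization_kwargs(self, modality: Modality) -> Dict[str, object]:
        if modality is Modality.CT:
            return {"bin_width": self.ct_bin_width}
        if modality is Modality.DOSE:
            return {"bin_width": self.dose_bin_width}
        return {"n_bins": self.mr_bins}


def resample_isotropic(
    volume: ImageVolume, mask: VOIMask, target_mm: float
) -> Tuple[ImageVolume, VOIMask]:
    """Resample to an isotropic grid; trilinear intensity, nearest mask."""
    zoom = [s / target_mm for s in volume.spacing]
    if np.allclose(zoom, 1.0):
        return volume, mask
    values = ndimage.zoom(volume.values, zoom, order=1, mode="nearest")
    mvals = ndimage.zoom(mask.values.astype(np.uint8), zoom, order=0, mode="nearest")
    new_mask = VOIMask(mvals > 0, (target_mm,) * 3, mask.role)
    if not new_mask.values.any():
        raise ValueError(f"mask {mask.role.value} vanished after resampling")
    return (
        ImageVolume(values, (target_mm,) * 3, volume.origin, volume.modality),
        new_mask,
    )


def normalize_mr(values: np.ndarray) -> np.ndarray:
    """Z-score normalisation over the body region.

    The body is taken as all voxels strictly above the volume minimum
    (the background of a co-registered head scan is a constant floor).
    """
    body = values > values.min()
    if not body.any():
        raise ValueError("cannot normalize a constant-intensity volume")
    mu = values[body].mean()
    sd = values[body].std()
    if sd == 0:
        raise ValueError("zero intensity variance in body region")
    return (values - mu) / sd


def preprocess(
    volume: ImageVolume, mask: VOIMask, config: ExtractionConfig
) -> Tuple[ImageVolume, VOIMask]:
    """Resample to isotropic spacing; z-score MR intensities.

    CT and dose are left in native units (HU / Gy).
    """
    volume, mask = resample_isotropic(volume, mask, config.resample_spacing)
    if volume.modality in (Modality.T1, Modality.T2):
        volume = ImageVolume(
            normalize_mr(volume.values), volume.spacing, volume.origin, volume.modality
        )
    return volume, mask


def crop_to_mask(
    values: np.ndarray, mask: np.ndarray, margin: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Crop both arrays to the mask bounding box plus a filter margin."""
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + margin, mask.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return values[sl], mask[sl]


def _swt_subbands(values: np.ndarray, wavelet: str) -> Dict[str, np.ndarray]:
    """Single-level 3D stationary wavelet sub-bands, labelled H/L per axis.

    Axis lengths are padded (symmetric) to even before the transform and
    cropped back after.  Low-pass retains the kernel's sqrt(2)-per-axis
    gain (the convention is documented, not normalised away).
    """
    pad = [(0, s % 2) for s in values.shape]
    padded = np.pad(values, pad, mode="symmetric")
    coeffs = pywt.swtn(padded, wavelet, level=1)[0]
    out = {}
    for key, arr in coeffs.items():
        label = "".join("H" if c == "d" else "L" for c in key)
        out[label] = arr[tuple(slice(0, s) for s in values.shape)]
    return out


def filter_bank(
    values: np.ndarray, spacing_mm: float, config: ExtractionConfig
) -> List[Tuple[str, np.ndarray]]:
    """The 12 response images: original, LoG x3, wavelet x8."""
    out: List[Tuple[str, np.ndarray]] = [("original", values)]
    for sigma in config.log_sigmas_mm:
        # Gaussian smoothing followed by the exact 7-point discrete
        # Laplacian (1/mm^2): annihilates constants exactly, which the
        # sampled-kernel gaussian_laplace does not at sub-voxel sigma
        smooth = ndimage.gaussian_filter(values, sigma=sigma / spacing_mm)
        log_img = ndimage.laplace(smooth) / spacing_mm**2
        out.append((f"log-sigma-{sigma:g}mm", log_img))
    sub = _swt_subbands(values, config.wavelet)
    for label in WAVELET_SUBBANDS:
        out.append((f"wavelet-{label}", sub[label]))
    return out


def extract_intensity_features(
    volume: ImageVolume, mask: VOIMask, config: ExtractionConfig
) -> Dict[str, float]:
    """All 1,116 (12 filter images x 93) features for one volume-VOI pair."""
    vol, msk = preprocess(volume, mask, config)
    msk.require_nonempty()
    values, mvals = crop_to_mask(vol.values, msk.values, config.crop_margin_voxels)
    kwargs = config.discretization_kwargs(volume.modality)
    out: Dict[str, float] = {}
    for fname, fvals in filter_bank(values, config.resample_spacing, config):
        for feat, v in intensity_features(fvals, mvals, **kwargs).items():
            out[f"{fname}_{feat}"] = v
    assert len(out) == 12 * N_INTENSITY_FEATURES
    return out


# ---------------------------------------------------------------------------
# morphology

MORPHOLOGY_FEATURES = (
    "Elongation",
    "Flatness",
    "LeastAxisLength",
    "MajorAxisLength",
    "MinorAxisLength",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "Maximum2DDiameterSlice",
    "Maximum3DDiameter",
    "MeshVolume",
    "Sphericity",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "VoxelVolume",
)


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    v0, v1, v2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    return abs(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum()) / 6.0


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 400:
        try:
            from scipy.spatial import ConvexHull

            points = points[ConvexHull(points, qhull_options="QJ").vertices]
        except Exception:
            pass
    d2 = np.sum((points[:, None, :] - points[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def morphology_features(mask: VOIMask) -> Dict[str, float]:
    """The 14 shape descriptors of one VOI mask (physical mm units).

    Principal axis lengths follow the 4*sqrt(eigenvalue) convention on the
    covariance of voxel-centre coordinates; maximum 2D diameters are the
    largest in-plane surface-voxel distances with the plane fixed along
    the x (column), y (row) and z (slice) axis respectively.  Single-voxel
    masks have degenerate axes and are rejected.
    """
    mask.require_nonempty()
    m = mask.values
    spacing = np.asarray(mask.spacing)
    n = int(m.sum())
    if n < 2:
        raise ValueError("morphology is degenerate for a single-voxel mask")
    coords = np.argwhere(m) * spacing

    cov = np.cov(coords, rowvar=False)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eig = np.clip(eig, 0.0, None)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()
    elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0
    flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 1.0

    # a lightly smoothed indicator yields a far less jagged iso-surface
    # than the raw binary (staircase meshes overestimate surface area)
    padded = np.pad(m, 2).astype(np.float64)
    from scipy import ndimage

    soft = ndimage.gaussian_filter(padded, sigma=0.8)
    if soft.max() <= 0.5:  # very thin structure: fall back to the binary
        soft = padded
    verts, faces, _, _ = marching_cubes(soft, level=0.5, spacing=tuple(spacing))
    area = float(mesh_surface_area(verts, faces))
    volume = float(_mesh_volume(verts, faces))
    sphericity = (36.0 * np.pi * volume**2) ** (1.0 / 3.0) / area

    from .geometry import surface_mask

    surf = np.argwhere(surface_mask(mask)) * spacing
    max3d = _max_pairwise(surf)
    diam2d = {}
    for axis, name in ((0, "Column"), (1, "Row"), (2, "Slice")):
        best = 0.0
        other = [a for a in range(3) if a != axis]
        for v in np.unique(surf[:, axis]):
            pts = surf[surf[:, axis] == v][:, other]
            best = max(best, _max_pairwise(pts))
        diam2d[name] = best

    return {
        "Elongation": elongation,
        "Flatness": flatness,
        "LeastAxisLength": least,
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "Maximum2DDiameterColumn": diam2d["Column"],
        "Maximum2DDiameterRow": diam2d["Row"],
        "Maximum2DDiameterSlice": diam2d["Slice"],
        "Maximum3DDiameter": max3d,
        "MeshVolume": volume,
        "Sphericity": float(sphericity),
        "SurfaceArea": area,
        "SurfaceVolumeRatio": area / volume,
        "VoxelVolume": float(n * np.prod(spacing)),
    }


# ---------------------------------------------------------------------------
# cohort assembly


def assemble_radiomics(
    cohort: Sequence[PatientRecord], config: ExtractionConfig
) -> FeatureTable:
    """Family-R table: the ten Table-1 modality-VOI pairs per patient."""
    columns: List[FeatureColumn] = []
    rows = []
    for rec in cohort:
        values: List[float] = []
        cols: List[FeatureColumn] = []
        for modality, role in RADIOMICS_SOURCES:
            volume = rec.images[modality]
            mask = rec.structures[role]
            try:
                feats = extract_intensity_features(volume, mask, config)
            except Exception as exc:  # pragma: no cover - explicit failure path
                raise RuntimeError(
                    f"radiomics failed for patient {rec.patient_id}, "
                    f"{modality.value}-{role.value}: {exc}"
                ) from exc
            voi = f"{modality.value}-{role.value}"
            for name, v in feats.items():
                cols.append(FeatureColumn("R", voi, name))
                values.append(v)
        if not columns:
            columns = cols
        rows.append(values)
    return FeatureTable(np.array(rows), columns, [r.patient_id for r in cohort])


def assemble_morphology(cohort: Sequence[PatientRecord]) -> FeatureTable:
    """Family-M table: 14 shape features x 4 VOIs = 56 columns."""
    columns: List[FeatureColumn] = []
    rows = []
    for rec in cohort:
        values: List[float] = []
        cols: List[FeatureColumn] = []
        for role in MORPHOLOGY_VOIS:
            try:
                feats = morphology_features(rec.structures[role])
            except Exception as exc:  # pragma: no cover
                raise RuntimeError(
                    f"morphology failed for patient {rec.patient_id}, "
                    f"{role.value}: {exc}"
                ) from exc
            for name in MORPHOLOGY_FEATURES:
                cols.append(FeatureColumn("M", role.value, name))
                values.append(feats[name])
        if not columns:
            columns = cols
        rows.append(values)
    return FeatureTable(np.array(rows), columns, [r.patient_id for r in cohort])
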