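"""NIfTI and CSV plumbing for volumes, masks, cohorts and feature tables.

NIfTI-1 is the on-disk format for all 3D data (via nibabel); cohort
manifests and feature tables are plain CSV.  Feature-table round-trips are
lossless to better than 1e-10 relative (values printed with 17 significant
digits).
"""

from __future__ import annotations

import os
from typing import Dict, Union

import nibabel as nib
import numpy as np
import pandas as pd

from .datamodel import (
    CohortRow,
    CohortTable,
    FeatureTable,
    ImageVolume,
    Modality,
    Role,
    VOIMask,
    parse_column_key,
)

PathLike = Union[str, os.PathLike]

#: manifest columns for the per-channel volumes
CHANNEL_COLUMNS = ("ct", "t1", "t2", "dose")


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def write_volume(volume: ImageVolume, path: PathLike) -> None:
    img = nib.Nifti1Image(volume.values.astype(np.float64), _affine(volume.spacing, volume.origin))
    img.header.set_zooms(volume.spacing)
    nib.save(img, os.fspath(path))


def read_volume(path: PathLike, modality: Modality = Modality.CT) -> ImageVolume:
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D image in {path}, got {data.ndim}D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return ImageVolume(np.asarray(data, dtype=np.float64), spacing, origin, modality)


def write_mask(mask: VOIMask, path: PathLike) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), _affine(mask.spacing, (0, 0, 0)))
    img.header.set_zooms(mask.spacing)
    nib.save(img, os.fspath(path))


def read_mask(path: PathLike, reference: ImageVolume, role: Role) -> VOIMask:
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D mask in {path}, got {data.ndim}D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    mask = VOIMask(data > 0, spacing, role)
    mask.check_aligned(reference)
    mask.require_nonempty()
    return mask


def write_feature_table(table: FeatureTable, path: PathLike) -> None:
    df = table.to_frame()
    df.index.name = "patient_id"
    df.to_csv(os.fspath(path), float_format="%.17g")


def read_feature_table(path: PathLike) -> FeatureTable:
    df = pd.read_csv(os.fspath(path), index_col=0)
    columns = [parse_column_key(k) for k in df.columns]
    return FeatureTable(df.to_numpy(dtype=np.float64), columns, [str(i) for i in df.index])


def write_patient(record, directory: PathLike) -> Dict[str, str]:
    """Write one patient's volumes and masks as NIfTI; returns manifest paths."""
    from .datamodel import Modality, PatientRecord  # noqa: F811

    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    pid = record.patient_id
    paths: Dict[str, str] = {}
    channel_of = {
        Modality.CT: "ct", Modality.T1: "t1", Modality.T2: "t2", Modality.DOSE: "dose",
    }
    for modality, volume in record.images.items():
        fname = f"{pid}_{channel_of[modality]}.nii.gz"
        write_volume(volume, os.path.join(directory, fname))
        paths[channel_of[modality]] = fname
    for role, mask in record.structures.masks.items():
        fname = f"{pid}_mask_{role.value}.nii.gz"
        write_mask(mask, os.path.join(directory, fname))
        paths[f"mask_{role.value}"] = fname
    return paths


def load_patient(row: CohortRow, base_dir: PathLike):
    """Reconstruct a PatientRecord from a cohort-manifest row."""
    from .datamodel import Modality, PatientRecord, StructureSet

    base = os.fspath(base_dir)
    modality_of = {
        "ct": Modality.CT, "t1": Modality.T1, "t2": Modality.T2, "dose": Modality.DOSE,
    }
    images = {}
    for channel, modality in modality_of.items():
        if channel not in row.paths:
            raise ValueError(f"manifest row {row.patient_id} missing channel {channel}")
        images[modality] = read_volume(os.path.join(base, row.paths[channel]), modality)
    masks = {}
    reference = images[Modality.CT]
    for key, rel in row.paths.items():
        if not key.startswith("mask_"):
            continue
        role = Role(key[len("mask_"):])
        masks[role] = read_mask(os.path.join(base, rel), reference, role)
    return PatientRecord(
        row.patient_id, row.label, images, StructureSet(masks, row.patient_id)
    )


def write_cohort(records, directory: PathLike) -> CohortTable:
    """Write a whole cohort plus its ``cohort.csv`` manifest."""
    rows = []
    for record in records:
        paths = write_patient(record, directory)
        rows.append(CohortRow(record.patient_id, record.label, paths))
    table = CohortTable(rows)
    write_cohort_table(table, os.path.join(os.fspath(directory), "cohort.csv"))
    return table


def load_cohort(manifest_path: PathLike):
    """Load all patients of a manifest; returns (records, CohortTable)."""
    table = read_cohort_table(manifest_path)
    base = os.path.dirname(os.fspath(manifest_path))
    return [load_patient(row, base) for row in table.rows], table


def write_cohort_table(cohort: CohortTable, path: PathLike) -> None:
    records = []
    for row in cohort.rows:
        rec: Dict[str, object] = {"patient_id": row.patient_id, "label": row.label}
        rec.update(row.paths)
        records.append(rec)
    pd.DataFrame(records).to_csv(os.fspath(path), index=False)


def read_cohort_table(path: PathLike) -> CohortTable:
    df = pd.read_csv(os.fspath(path), dtype={"patient_id": str})
    rows = []
    for _, r in df.iterrows():
        paths = {
            k: str(v)
            for k, v in r.items()
            if k not in ("patient_id", "label") and pd.notna(v)
        }
        rows.append(CohortRow(str(r["patient_id"]), int(r["label"]), paths))
    return CohortTable(rows)
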