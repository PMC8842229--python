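"""Shared in-memory containers for the multi-omics pipeline.

All 3D arrays are indexed ``(x, y, z)`` with per-axis voxel spacing in
millimetres; every geometric computation downstream works in physical mm
derived from ``spacing``.  Masks are voxel-centre based: a voxel belongs to
a volume of interest (VOI) iff its stored label is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd


class Modality(str, Enum):
    CT = "CT"
    T1 = "T1"
    T2 = "T2"
    DOSE = "DOSE"


class Role(str, Enum):
    """Anatomical roles of the eight analysis VOIs (plus raw parotid sides).

    ``PG_LEFT``/``PG_RIGHT`` are the as-delineated parotids; laterality
    resolution maps them onto ``IPSI_PG``/``CONTRA_PG`` relative to the
    primary tumour (GTVnp).
    """

    GTVNP = "GTVnp"
    GTVN = "GTVn"
    IPSI_PG = "IpsiPG"
    CONTRA_PG = "ContraPG"
    BS = "BS"
    SC = "SC"
    PTVN_HIGH = "PTVn_high_dose"
    PTVN_LOW = "PTVn_low_dose"
    PG_LEFT = "PG_left"
    PG_RIGHT = "PG_right"


#: the eight roles every resolved structure set must contain
ANALYSIS_ROLES: Tuple[Role, ...] = (
    Role.GTVNP,
    Role.GTVN,
    Role.IPSI_PG,
    Role.CONTRA_PG,
    Role.BS,
    Role.SC,
    Role.PTVN_HIGH,
    Role.PTVN_LOW,
)


@dataclass
class ImageVolume:
    """A 3D scalar grid with physical geometry and a modality tag."""

    values: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: Modality = Modality.CT

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.values.ndim}D")
        if any(n < 2 for n in self.values.shape):
            raise ValueError("volume must have >= 2 voxels along every axis")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three strictly positive values")
        self.origin = tuple(float(o) for o in self.origin)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        if self.modality is Modality.DOSE and self.values.min() < 0:
            raise ValueError("dose values must be non-negative (Gy)")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class VOIMask:
    """Binary mask on the grid of a reference :class:`ImageVolume`."""

    values: np.ndarray
    spacing: Tuple[float, float, float]
    role: Role

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values) > 0
        if self.values.ndim != 3:
            raise ValueError("mask must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def count(self) -> int:
        return int(self.values.sum())

    def require_nonempty(self) -> "VOIMask":
        if not self.values.any():
            raise ValueError(f"empty VOI for role {self.role.value}")
        return self

    def check_aligned(self, reference: ImageVolume) -> "VOIMask":
        if self.shape != reference.shape:
            raise ValueError(
                f"mask grid {self.shape} does not match reference {reference.shape}"
            )
        if not np.allclose(self.spacing, reference.spacing):
            raise ValueError(
                f"mask spacing {self.spacing} does not match reference "
                f"{reference.spacing}"
            )
        return self


@dataclass
class StructureSet:
    """Named VOI masks for one patient, all on a shared grid."""

    masks: Dict[Role, VOIMask]
    patient_id: str = ""

    def __getitem__(self, role: Role) -> VOIMask:
        return self.masks[role]

    def __contains__(self, role: Role) -> bool:
        return role in self.masks

    def require_analysis_roles(self) -> "StructureSet":
        missing = [r.value for r in ANALYSIS_ROLES if r not in self.masks]
        if missing:
            raise ValueError(f"structure set missing roles: {missing}")
        return self


@dataclass
class PatientRecord:
    """One patient's volumes (CT/T1/T2/dose) and structure set, in memory."""

    patient_id: str
    label: int
    images: Dict[Modality, ImageVolume]
    structures: StructureSet

    def __post_init__(self) -> None:
        shapes = {m: v.shape for m, v in self.images.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel grids differ: {shapes}")


@dataclass
class CohortRow:
    patient_id: str
    label: int
    paths: Dict[str, str] = field(default_factory=dict)


@dataclass
class CohortTable:
    """Patient manifest: binary ART label plus on-disk file paths."""

    rows: List[CohortRow]

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("patient_ids must be unique")
        for r in self.rows:
            if r.label not in (0, 1):
                raise ValueError(f"label must be 0 or 1, got {r.label!r}")

    @property
    def patient_ids(self) -> List[str]:
        return [r.patient_id for r in self.rows]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.rows], dtype=int)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class FeatureColumn:
    """Metadata of one feature column: omics family, source VOI, name."""

    family: str  # one of R, M, D, C
    voi: str  # VOI name or "A-B" VOI pair
    name: str

    @property
    def key(self) -> str:
        return f"{self.family}:{self.voi}:{self.name}"


class FeatureTable:
    """Patients x features matrix with per-column family/VOI/name tags."""

    def __init__(
        self,
        matrix: np.ndarray,
        columns: Sequence[FeatureColumn],
        patient_ids: Sequence[str],
    ) -> None:
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.ndim != 2:
            raise ValueError("feature matrix must be 2D (patients x features)")
        if matrix.shape != (len(patient_ids), len(columns)):
            raise ValueError("matrix shape does not match ids/columns")
        keys = [c.key for c in columns]
        if len(set(keys)) != len(keys):
            dup = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate feature column keys: {dup[:5]}")
        if not np.all(np.isfinite(matrix)):
            bad = [keys[j] for j in np.where(~np.isfinite(matrix).all(axis=0))[0]]
            raise ValueError(f"non-finite feature values in columns {bad[:5]}")
        self.matrix = matrix
        self.columns = list(columns)
        self.patient_ids = list(patient_ids)

    @property
    def keys(self) -> List[str]:
        return [c.key for c in self.columns]

    @property
    def n_features(self) -> int:
        return len(self.columns)

    def family(self) -> str:
        fams = {c.family for c in self.columns}
        return fams.pop() if len(fams) == 1 else "+".join(sorted(fams))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.patient_ids, columns=self.keys)

    def select(self, keys: Sequence[str]) -> "FeatureTable":
        index = {k: j for j, k in enumerate(self.keys)}
        cols = [index[k] for k in keys]
        return FeatureTable(
            self.matrix[:, cols], [self.columns[j] for j in cols], self.patient_ids
        )

    @staticmethod
    def concat(tables: Sequence["FeatureTable"]) -> "FeatureTable":
        ids = tables[0].patient_ids
        for t in tables[1:]:
            if t.patient_ids != ids:
                raise ValueError("cannot concat tables with different patients")
        matrix = np.hstack([t.matrix for t in tables])
        columns = [c for t in tables for c in t.columns]
        return FeatureTable(matrix, columns, ids)


def parse_column_key(key: str) -> FeatureColumn:
    parts = key.split(":", 2)
    if len(parts) != 3:
        raise ValueError(f"malformed feature column key {key!r}")
    return FeatureColumn(*parts)
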