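"""Shared fixtures: small synthetic cohorts and random mask factories."""

from __future__ import annotations

import numpy as np
import pytest

from artomics.datamodel import Role, VOIMask
from artomics.radiomics import ExtractionConfig
from artomics.synthetic import SyntheticConfig, generate_cohort, resolve_laterality


@pytest.fixture(scope="session")
def extraction_config() -> ExtractionConfig:
    return ExtractionConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """Twelve resolved patients with default planted effects (seed 7)."""
    records, table = generate_cohort(SyntheticConfig(n_patients=12, seed=7))
    return [resolve_laterality(r) for r in records], table


def random_blob_mask(
    rng: np.random.Generator,
    shape=(14, 12, 10),
    spacing=(1.0, 1.5, 2.0),
    max_voxels: int = 500,
    role: Role = Role.GTVNP,
) -> VOIMask:
    """A random connected-ish blob with at most ``max_voxels`` voxels."""
    center = rng.uniform(2, np.maximum(np.array(shape) - 3, 2.5))
    radii = rng.uniform(1.5, 4.0, size=3)
    x, y, z = np.ogrid[: shape[0], : shape[1], : shape[2]]
    blob = (
        ((x - center[0]) / radii[0]) ** 2
        + ((y - center[1]) / radii[1]) ** 2
        + ((z - center[2]) / radii[2]) ** 2
    ) <= 1.0
    noise = rng.random(shape) < 0.05
    mask = blob | noise
    if mask.sum() > max_voxels:
        idx = np.argwhere(mask)
        keep = rng.choice(len(idx), size=max_voxels, replace=False)
        out = np.zeros(shape, dtype=bool)
        out[tuple(idx[keep].T)] = True
        mask = out
    if not mask.any():
        mask[tuple(np.round(center).astype(int))] = True
    return VOIMask(mask, spacing, role)
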