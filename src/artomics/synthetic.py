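"""Synthetic NPC cohort generator with plantable per-channel signal.

The generator emulates the statistical structure the analysis assumes: a
cohort of head-and-neck patients with three image channels (CT-like,
T1-like, T2-like), a 3D dose map, eight organ masks, and a binary
adaptive-radiotherapy (ART) label at ~26% prevalence.  Anatomy is
topological rather than realistic: ellipsoidal tumour volumes and parotids,
tubular brainstem/spinal cord, and nodal planning target volumes obtained
by physically dilating the nodal tumour volume by 3 mm and 8 mm.

Outcome-linked signal is planted through four patient-level standardised
latents, one per omics family, so each maps to exactly one feature
catalogue and the planted ordering is auditable:

* ``texture_d`` — the variance of the correlated intensity noise inside
  GTVnp, GTVn and both parotids (all three image channels share one
  latent), picked up by first-order/texture radiomics;
* ``dose_d``    — the mean dose of the ipsilateral parotid, picked up by
  DVH dosiomics;
* ``morph_d``   — the log-volume of GTVnp (all between-patient volume
  variation flows through this latent), picked up by morphology;
* ``contour_d`` — the GTVnp-to-spinal-cord distance, picked up by
  contouromics (OVH).

A latent with planted effect d is drawn N(d, 1) for label-1 patients and
N(0, 1) otherwise, so the Bayes-optimal AUC of the planted statistic is
Phi(d / sqrt(2)).  The defaults (2.0, 1.2, 0.5, 0.15) imply Bayes AUCs of
about 0.92, 0.80, 0.64 and 0.54, bracketing the qualitative single-omics
ordering R > D > M > C the full pipeline must recover.

Determinism: one random stream per patient derived from
``(seed, patient_index)``; identical seed and config give identical
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
from scipy import ndimage

from .datamodel import (
    CohortRow,
    CohortTable,
    ImageVolume,
    Modality,
    PatientRecord,
    Role,
    StructureSet,
    VOIMask,
)
from .geometry import assign_parotid_laterality, dilate, min_distances_to_surface

DEFAULT_EFFECTS = {
    "texture_d": 2.0,
    "dose_d": 1.2,
    "morph_d": 0.5,
    "contour_d": 0.15,
}

#: noise-variance latent mapping: v = VAR_MEAN + VAR_SCALE * u, clipped
VAR_MEAN = 400.0
VAR_SCALE = 160.0
VAR_MIN = 25.0
#: ipsilateral parotid dose latent mapping (Gy); the baseline sits above
#: the typical PTV spillover so the planted mean is rarely clipped
PG_DOSE_MEAN = 35.0
PG_DOSE_SCALE = 8.0
#: GTVnp log-volume scale per latent unit.  Deliberately small in physical
#: terms (4% volume SD ~ 0.2 mm radius SD): morphology reads the volume
#: almost noiselessly, while inter-organ distance features see the radius
#: change only at the voxelisation-noise level, keeping the morphology
#: channel out of the contouromics catalogue.
LOGVOL_SCALE = 0.04
#: GTVnp anterior shift (voxels) per contour-latent unit
CONTOUR_SHIFT_VOX = 1.0


@dataclass
class SyntheticConfig:
    """Cohort-level generation parameters (the study conditions)."""

    n_patients: int = 135
    prevalence: float = 35.0 / 135.0
    grid: Tuple[int, int, int] = (64, 64, 48)
    spacing: Tuple[float, float, float] = (2.0, 2.0, 2.0)
    effect_sizes: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 10:
            raise ValueError("n_patients must be >= 10")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if any(n < 32 for n in self.grid):
            raise ValueError("grid too small to place all organs (< 32 voxels)")
        effects = dict(DEFAULT_EFFECTS)
        effects.update(self.effect_sizes)
        if any(v < 0 for v in effects.values()):
            raise ValueError("effect sizes must be >= 0")
        self.effect_sizes = effects


@dataclass
class PatientLatents:
    """The four standardised per-patient signal latents."""

    texture: float
    dose: float
    morph: float
    contour: float


def _ellipsoid(grid, center, radii_vox) -> np.ndarray:
    coords = np.ogrid[: grid[0], : grid[1], : grid[2]]
    acc = np.zeros(grid, dtype=np.float64)
    for c, ctr, r in zip(coords, center, radii_vox):
        acc = acc + ((c - ctr) / r) ** 2
    return acc <= 1.0


def _tube(grid, center_xy, radius_vox, z_lo, z_hi) -> np.ndarray:
    x, y, z = np.ogrid[: grid[0], : grid[1], : grid[2]]
    disk = ((x - center_xy[0]) ** 2 + (y - center_xy[1]) ** 2) <= radius_vox**2
    return disk & (z >= z_lo) & (z <= z_hi)


def generate_anatomy(
    rng: np.random.Generator, config: SyntheticConfig, latents: PatientLatents
) -> StructureSet:
    """One patient's eight organ masks (parotids as left/right, unresolved).

    Anatomy: GTVnp near the posterior midline, GTVn lateral-inferior,
    lateral parotids, posterior midline brainstem with the spinal cord as
    its inferior continuation, nodal PTVs by 3/8 mm dilation of GTVn.
    Organ positions and sizes carry per-patient jitter; the GTVnp volume
    and its distance to the spinal cord are driven by the morphology and
    contour latents.
    """
    grid = config.grid
    spacing = config.spacing
    cx = (grid[0] - 1) / 2.0

    jitter = lambda s: float(rng.uniform(-s, s))  # noqa: E731
    lateral = float(rng.choice([-2.0, 2.0]))

    # independent positional jitter dominates the (tiny) radius variation
    # in every inter-organ distance, so contour features carry only the
    # planted contour latent plus geometric noise
    sc_y = grid[1] * 0.72 + jitter(0.75)
    sc = _tube(grid, (cx + jitter(0.5), sc_y), 2.2, 0, int(grid[2] * 0.62))
    bs = _tube(
        grid,
        (cx + jitter(0.5), sc_y - 2.0),
        3.2,
        int(grid[2] * 0.58),
        int(grid[2] * 0.95),
    )

    # GTVnp: volume through the morphology latent, SC distance through the
    # contour latent; no other volume jitter so the planted effects are clean
    scale = np.exp(LOGVOL_SCALE * latents.morph / 3.0)
    gtvnp_y = grid[1] * 0.56 - CONTOUR_SHIFT_VOX * latents.contour
    gtvnp = _ellipsoid(
        grid,
        (cx + lateral / 2.0, gtvnp_y, grid[2] * 0.62),
        (6.0 * scale, 5.0 * scale, 4.5 * scale),
    )

    pg_dx = grid[0] * 0.30 + jitter(1.25)
    pg_y = grid[1] * 0.56 + jitter(1.25)
    pg_z = grid[2] * 0.56 + jitter(1.0)
    pg_r = (4.0, 5.0, 6.0)
    szj = float(rng.normal(1.0, 0.05))
    pg_left = _ellipsoid(grid, (cx - pg_dx, pg_y, pg_z), tuple(r * szj for r in pg_r))
    szj = float(rng.normal(1.0, 0.05))
    pg_right = _ellipsoid(grid, (cx + pg_dx, pg_y, pg_z), tuple(r * szj for r in pg_r))

    side = np.sign(lateral)
    szj = float(rng.normal(1.0, 0.08))
    gtvn = _ellipsoid(
        grid,
        (cx + side * 6.0 + jitter(1.0), grid[1] * 0.5 + jitter(1.0), grid[2] * 0.33 + jitter(1.0)),
        (4.0 * szj, 4.0 * szj, 5.0 * szj),
    )

    masks = {
        Role.GTVNP: VOIMask(gtvnp, spacing, Role.GTVNP),
        Role.GTVN: VOIMask(gtvn, spacing, Role.GTVN),
        Role.PG_LEFT: VOIMask(pg_left, spacing, Role.PG_LEFT),
        Role.PG_RIGHT: VOIMask(pg_right, spacing, Role.PG_RIGHT),
        Role.BS: VOIMask(bs, spacing, Role.BS),
        Role.SC: VOIMask(sc, spacing, Role.SC),
    }
    masks[Role.PTVN_HIGH] = VOIMask(
        dilate(masks[Role.GTVN], 3.0).values, spacing, Role.PTVN_HIGH
    )
    masks[Role.PTVN_LOW] = VOIMask(
        dilate(masks[Role.GTVN], 8.0).values, spacing, Role.PTVN_LOW
    )
    for role, m in masks.items():
        if not m.values.any():
            raise ValueError(f"organ placement produced an empty {role.value} mask")
    return StructureSet(masks)


def _body_mask(grid) -> np.ndarray:
    return _ellipsoid(
        grid,
        ((grid[0] - 1) / 2.0, (grid[1] - 1) / 2.0, (grid[2] - 1) / 2.0),
        (grid[0] * 0.47, grid[1] * 0.47, grid[2] * 0.48),
    )


def _correlated_noise(rng, grid, sigma_vox: float = 0.8) -> np.ndarray:
    """Smoothed white noise, empirically normalised to unit variance."""
    white = rng.standard_normal(grid)
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox)
    return smooth / smooth.std()


#: base tissue intensities per modality: (background, body, GTVnp, GTVn, PG, BS/SC)
TISSUE_BASES = {
    Modality.CT: (-1000.0, 40.0, 60.0, 55.0, 30.0, 35.0),
    Modality.T1: (0.0, 200.0, 260.0, 250.0, 150.0, 180.0),
    Modality.T2: (0.0, 150.0, 230.0, 220.0, 190.0, 160.0),
}


def render_images(
    structures: StructureSet,
    config: SyntheticConfig,
    latents: PatientLatents,
    rng: np.random.Generator,
) -> Dict[Modality, ImageVolume]:
    """CT/T1/T2 channels: piecewise tissue bases plus correlated noise.

    Inside the four signal VOIs (GTVnp, GTVn, both parotids) the noise
    standard deviation is sqrt(v_p) with the patient's variance latent
    v_p = 400 + 160 * u_p (clipped at 25); elsewhere it is ``noise_sd``.
    Voxels outside the body ellipsoid keep the constant background value.
    """
    grid = config.grid
    body = _body_mask(grid)
    v_p = max(VAR_MEAN + VAR_SCALE * latents.texture, VAR_MIN)
    signal_voi = (
        structures[Role.GTVNP].values
        | structures[Role.GTVN].values
        | structures[Role.PG_LEFT].values
        | structures[Role.PG_RIGHT].values
    )
    amplitude = np.where(signal_voi, np.sqrt(v_p), config.noise_sd)
    out = {}
    for modality, (bg, b_body, b_np, b_n, b_pg, b_cord) in TISSUE_BASES.items():
        base = np.full(grid, bg)
        base[body] = b_body
        base[structures[Role.PG_LEFT].values] = b_pg
        base[structures[Role.PG_RIGHT].values] = b_pg
        base[structures[Role.BS].values] = b_cord
        base[structures[Role.SC].values] = b_cord
        base[structures[Role.GTVN].values] = b_n
        base[structures[Role.GTVNP].values] = b_np
        noise = _correlated_noise(rng, grid)
        values = np.where(body, base + amplitude * noise, bg)
        out[modality] = ImageVolume(values, config.spacing, modality=modality)
    return out


def _gaussian_blob(grid, spacing, center_vox, sigma_mm) -> np.ndarray:
    coords = np.ogrid[: grid[0], : grid[1], : grid[2]]
    acc = np.zeros(grid, dtype=np.float64)
    for c, ctr, s, sp in zip(coords, center_vox, sigma_mm, spacing):
        acc = acc + ((c - ctr) * sp / s) ** 2
    return np.exp(-0.5 * acc)


def render_dose(
    structures: StructureSet,
    config: SyntheticConfig,
    latents: PatientLatents,
    rng: np.random.Generator,
) -> ImageVolume:
    """Dose map: PTV-centred Gaussian blobs with a smooth penumbra.

    The high-dose blob is scaled for a mean of ~70 Gy inside
    PTVn_high_dose and the low-dose blob for ~60 Gy inside PTVn_low_dose;
    an additional parotid-directed component gives the ipsilateral parotid
    a mean dose of 25 + 8 * w_p Gy through the dose latent w_p.  The map
    is non-negative everywhere by construction.
    """
    grid, spacing = config.grid, config.spacing

    def centroid(role):
        return np.argwhere(structures[role].values).mean(axis=0)

    def extent_mm(role):
        idx = np.argwhere(structures[role].values)
        return (idx.max(axis=0) - idx.min(axis=0) + 1) * np.asarray(spacing)

    high, low = structures[Role.PTVN_HIGH], structures[Role.PTVN_LOW]
    g_low = _gaussian_blob(grid, spacing, centroid(Role.PTVN_LOW), extent_mm(Role.PTVN_LOW) / 1.6)
    a_low = 55.0 / g_low[low.values].mean()
    dose = a_low * g_low
    g_high = _gaussian_blob(grid, spacing, centroid(Role.PTVN_HIGH), extent_mm(Role.PTVN_HIGH) / 1.4)
    a_high = max(70.0 - dose[high.values].mean(), 0.0) / g_high[high.values].mean()
    dose = dose + a_high * g_high

    ipsi_side, contra_side = assign_parotid_laterality(
        structures[Role.PG_LEFT], structures[Role.PG_RIGHT], structures[Role.GTVNP]
    )
    # contralateral first: the ipsilateral component is added last so its
    # in-parotid mean matches the planted target exactly (up to clipping)
    pg_dose = (
        (contra_side, max(12.0 + 4.0 * rng.standard_normal(), 0.0)),
        (ipsi_side, max(PG_DOSE_MEAN + PG_DOSE_SCALE * latents.dose, 0.0)),
    )
    for side, target_mean in pg_dose:
        pg = structures[side]
        blob = _gaussian_blob(grid, spacing, centroid(side), extent_mm(side) / 1.2)
        spill = dose[pg.values].mean()
        amp = max(target_mean - spill, 0.0) / blob[pg.values].mean()
        dose = dose + amp * blob

    return ImageVolume(np.clip(dose, 0.0, None), spacing, modality=Modality.DOSE)


def _draw_latents(rng, effects, label: int) -> PatientLatents:
    shift = float(label)
    return PatientLatents(
        texture=float(rng.normal(effects["texture_d"] * shift, 1.0)),
        dose=float(rng.normal(effects["dose_d"] * shift, 1.0)),
        morph=float(rng.normal(effects["morph_d"] * shift, 1.0)),
        contour=float(rng.normal(effects["contour_d"] * shift, 1.0)),
    )


def generate_patient(config: SyntheticConfig, index: int, label: int) -> PatientRecord:
    """Generate one patient deterministically from (seed, index)."""
    rng = np.random.default_rng([config.seed, index])
    latents = _draw_latents(rng, config.effect_sizes, label)
    structures = generate_anatomy(rng, config, latents)
    images = render_images(structures, config, latents, rng)
    images[Modality.DOSE] = render_dose(structures, config, latents, rng)
    pid = f"P{index:04d}"
    structures.patient_id = pid
    return PatientRecord(pid, label, images, structures)


def draw_labels(config: SyntheticConfig) -> np.ndarray:
    rng = np.random.default_rng([config.seed, 10**6])
    return (rng.random(config.n_patients) < config.prevalence).astype(int)


def generate_cohort(config: SyntheticConfig) -> Tuple[List[PatientRecord], CohortTable]:
    """The full cohort plus its manifest (no files written)."""
    labels = draw_labels(config)
    records = [generate_patient(config, i, int(labels[i])) for i in range(config.n_patients)]
    table = CohortTable(
        [CohortRow(r.patient_id, r.label, {}) for r in records]
    )
    return records, table


def resolve_laterality(record: PatientRecord) -> PatientRecord:
    """Map PG_left/PG_right onto IpsiPG/ContraPG relative to GTVnp."""
    s = record.structures
    ipsi_side, contra_side = assign_parotid_laterality(
        s[Role.PG_LEFT], s[Role.PG_RIGHT], s[Role.GTVNP]
    )
    masks = dict(s.masks)
    masks[Role.IPSI_PG] = VOIMask(s[ipsi_side].values, s[ipsi_side].spacing, Role.IPSI_PG)
    masks[Role.CONTRA_PG] = VOIMask(
        s[contra_side].values, s[contra_side].spacing, Role.CONTRA_PG
    )
    record.structures = StructureSet(masks, s.patient_id)
    record.structures.require_analysis_roles()
    return record


# ---------------------------------------------------------------------------
# signal audit


def planted_statistics(record: PatientRecord) -> Dict[str, float]:
    """The four per-patient statistics the latents are planted on."""
    s = record.structures
    ct = record.images[Modality.CT]
    gtvnp = s[Role.GTVNP]
    dose = record.images[Modality.DOSE]
    if Role.IPSI_PG in s:
        ipsi = s[Role.IPSI_PG]
    else:
        side, _ = assign_parotid_laterality(s[Role.PG_LEFT], s[Role.PG_RIGHT], gtvnp)
        ipsi = s[side]
    return {
        "texture": float(ct.values[gtvnp.values].var()),
        "dose": float(dose.values[ipsi.values].mean()),
        "morph": float(np.log(gtvnp.count() * np.prod(gtvnp.spacing))),
        "contour": float(np.median(min_distances_to_surface(gtvnp, s[Role.SC]))),
    }


def cohens_d(x0: np.ndarray, x1: np.ndarray) -> float:
    """Standardised mean difference with the pooled (n-1) SD."""
    n0, n1 = len(x0), len(x1)
    if min(n0, n1) < 2:
        raise ValueError("need >= 2 samples per class")
    pooled = np.sqrt(
        ((n0 - 1) * np.var(x0, ddof=1) + (n1 - 1) * np.var(x1, ddof=1)) / (n0 + n1 - 2)
    )
    if pooled == 0:
        return 0.0
    return float((x1.mean() - x0.mean()) / pooled)


def signal_audit(cohort: List[PatientRecord]):
    """Realised Cohen's d and implied Bayes AUC per planted channel.

    Returns a DataFrame with one row per channel; the implied AUC is
    Phi(d / sqrt(2)), the Bayes-optimal AUC of a unit-variance two-class
    normal shift of size d.
    """
    import pandas as pd
    from scipy.stats import norm

    labels_list, stats = [], []
    for r in cohort:  # single pass so a patient generator can be streamed
        labels_list.append(r.label)
        stats.append(planted_statistics(r))
    labels = np.array(labels_list)
    if len(np.unique(labels)) < 2:
        raise ValueError("signal audit needs both classes in the cohort")
    rows = []
    for channel in ("texture", "dose", "morph", "contour"):
        x = np.array([s[channel] for s in stats])
        d = cohens_d(x[labels == 0], x[labels == 1])
        rows.append(
            {
                "channel": channel,
                "cohens_d": d,
                "bayes_auc": float(norm.cdf(abs(d) / np.sqrt(2))),
            }
        )
    return pd.DataFrame(rows).set_index("channel")
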