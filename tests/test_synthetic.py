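"""Cohort generator: determinism, anatomy topology, planted-signal audit."""

import numpy as np
import pytest

from artomics.datamodel import Modality, Role
from artomics.geometry import assign_parotid_laterality
from artomics.synthetic import (
    SyntheticConfig,
    cohens_d,
    draw_labels,
    generate_cohort,
    generate_patient,
    planted_statistics,
    signal_audit,
)


def test_config_validation():
    with pytest.raises(ValueError, match="n_patients"):
        SyntheticConfig(n_patients=5)
    with pytest.raises(ValueError, match="prevalence"):
        SyntheticConfig(prevalence=1.5)
    with pytest.raises(ValueError, match="grid too small"):
        SyntheticConfig(grid=(20, 64, 48))
    with pytest.raises(ValueError, match="effect"):
        SyntheticConfig(effect_sizes={"texture_d": -1.0})


def test_labels_reproducible_and_in_binomial_range():
    config = SyntheticConfig(n_patients=135, seed=11)
    l1, l2 = draw_labels(config), draw_labels(config)
    np.testing.assert_array_equal(l1, l2)
    assert 20 <= l1.sum() <= 50  # +/- 3 SD around 35


def test_patient_bitwise_deterministic():
    config = SyntheticConfig(n_patients=10, grid=(40, 40, 36), seed=21)
    a = generate_patient(config, 3, 1)
    b = generate_patient(config, 3, 1)
    for mod in a.images:
        np.testing.assert_array_equal(a.images[mod].values, b.images[mod].values)
    for role in a.structures.masks:
        np.testing.assert_array_equal(
            a.structures[role].values, b.structures[role].values
        )


@pytest.fixture(scope="module")
def patient():
    return generate_patient(SyntheticConfig(n_patients=10, seed=2), 0, 1)


def test_ptv_strict_nesting(patient):
    s = patient.structures
    gtvn = s[Role.GTVN].values
    high = s[Role.PTVN_HIGH].values
    low = s[Role.PTVN_LOW].values
    assert np.all(high[gtvn]) and high.sum() > gtvn.sum()
    assert np.all(low[high]) and low.sum() > high.sum()


def test_parotids_disjoint(patient):
    s = patient.structures
    assert not np.any(s[Role.PG_LEFT].values & s[Role.PG_RIGHT].values)


def test_all_eight_roles_present_and_nonempty(patient):
    s = patient.structures
    roles = {Role.GTVNP, Role.GTVN, Role.PG_LEFT, Role.PG_RIGHT, Role.BS,
             Role.SC, Role.PTVN_HIGH, Role.PTVN_LOW}
    for role in roles:
        assert s[role].count() > 0


def test_dose_nonnegative_and_calibrated():
    config = SyntheticConfig(n_patients=20, seed=31)
    labels = draw_labels(config)
    means = []
    for i in range(20):
        rec = generate_patient(config, i, int(labels[i]))
        dose = rec.images[Modality.DOSE].values
        assert dose.min() >= 0.0
        high = rec.structures[Role.PTVN_HIGH].values
        means.append(dose[high].mean())
    assert all(63.0 <= m <= 77.0 for m in means)


def test_background_constant_outside_body(patient):
    from artomics.synthetic import _body_mask

    body = _body_mask(patient.images[Modality.CT].shape)
    for mod, bg in ((Modality.CT, -1000.0), (Modality.T1, 0.0), (Modality.T2, 0.0)):
        outside = patient.images[mod].values[~body]
        assert np.all(outside == bg)


def test_grid_mirror_swaps_parotid_proximity():
    """Left-right mirroring of the whole scene flips which anatomical side
    is nearer the primary tumour."""
    config = SyntheticConfig(n_patients=10, seed=5)
    rec = generate_patient(config, 1, 0)
    s = rec.structures
    flip = lambda m: m.values[::-1].copy()  # noqa: E731
    from artomics.datamodel import VOIMask

    before, _ = assign_parotid_laterality(s[Role.PG_LEFT], s[Role.PG_RIGHT], s[Role.GTVNP])
    # mirroring maps the left-side anatomy onto the right side: relabel
    left2 = VOIMask(flip(s[Role.PG_RIGHT]), s[Role.PG_RIGHT].spacing, Role.PG_LEFT)
    right2 = VOIMask(flip(s[Role.PG_LEFT]), s[Role.PG_LEFT].spacing, Role.PG_RIGHT)
    gtv2 = VOIMask(flip(s[Role.GTVNP]), s[Role.GTVNP].spacing, Role.GTVNP)
    after, _ = assign_parotid_laterality(left2, right2, gtv2)
    swap = {Role.PG_LEFT: Role.PG_RIGHT, Role.PG_RIGHT: Role.PG_LEFT}
    assert after == swap[before]


def test_cohort_generation_contract():
    config = SyntheticConfig(n_patients=12, grid=(40, 40, 36), seed=13)
    records, table = generate_cohort(config)
    assert len(records) == 12 and len(table) == 12
    assert table.patient_ids == [r.patient_id for r in records]
    assert set(table.labels) <= {0, 1}


def test_audit_deterministic_given_cohort(small_cohort):
    records, _ = small_cohort
    a1 = signal_audit(records)
    a2 = signal_audit(records)
    assert a1.equals(a2)


def test_audit_rejects_single_class():
    config = SyntheticConfig(n_patients=10, grid=(40, 40, 36), seed=2)
    records = [generate_patient(config, i, 0) for i in range(10)]
    with pytest.raises(ValueError, match="both classes"):
        signal_audit(records)


def stream_stats(config, n):
    labels = draw_labels(config)[:n]
    stats = [planted_statistics(generate_patient(config, i, int(labels[i])))
             for i in range(n)]
    return labels, stats


def channel_d(labels, stats, channel):
    x = np.array([s[channel] for s in stats])
    return cohens_d(x[labels == 0], x[labels == 1])


def test_zero_effects_audit_near_null():
    config = SyntheticConfig(
        n_patients=135, seed=17,
        effect_sizes={k: 0.0 for k in ("texture_d", "dose_d", "morph_d", "contour_d")},
    )
    labels, stats = stream_stats(config, 135)
    for channel in ("texture", "dose", "morph", "contour"):
        assert abs(channel_d(labels, stats, channel)) < 0.25


def test_default_effects_recover_planted_ordering():
    """Realised effect sizes reproduce texture > dose > morph > contour and
    the texture channel lands near its planted standardised difference."""
    config = SyntheticConfig(n_patients=200, seed=23)
    labels, stats = stream_stats(config, 200)
    d = {c: channel_d(labels, stats, c) for c in ("texture", "dose", "morph", "contour")}
    assert d["texture"] > d["dose"] > d["morph"] > d["contour"]
    # planted 2.0, attenuated only by the variance-estimator noise
    assert 1.55 <= d["texture"] <= 2.45
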