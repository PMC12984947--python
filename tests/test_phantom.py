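"""Phantom generator: composition ledgers, determinism, closure properties."""

import dataclasses

import numpy as np
import pytest

import fivol
from fivol.phantom import COHORT_PRESETS, PhantomError


def _measure(spec):
    volume, roi, truth = fivol.generate_phantom(spec)
    labels = fivol.segment_tissues(volume, roi)
    return fivol.compute_volumes(labels), truth


@pytest.mark.parametrize("pattern", ["dispersed", "clustered"])
def test_noiseless_closure_is_exact(pattern):
    """Without noise or partial volume, segment->volumes recovers the
    generator's voxel composition exactly."""
    spec = fivol.PhantomSpec(
        target_ftmp=1.0, seed=2, shape=(40, 40, 10), fat_pattern=pattern
    )
    res, truth = _measure(spec)
    assert res.fat_voxels == truth.fat_voxels
    assert res.muscle_voxels == truth.muscle_voxels
    assert res.unclassified_voxels == 0
    assert res.ftmp == pytest.approx(truth.true_ftmp, abs=1e-9)


def test_zero_target_gives_zero_fat():
    res, truth = _measure(fivol.PhantomSpec(target_ftmp=0.0, seed=1))
    assert truth.fat_voxels == 0
    assert res.fat_volume == 0.0
    assert res.ftmp == 0.0


def test_unreachable_target_reports_maximum():
    spec = fivol.PhantomSpec(target_ftmp=1e9, seed=0, shape=(8, 8, 4))
    with pytest.raises(PhantomError, match="max achievable"):
        fivol.generate_phantom(spec)


def test_determinism_same_seed_bit_identical():
    spec = fivol.PhantomSpec(
        target_ftmp=2.5, seed=42, partial_volume_width=1, noise_sd=100.0,
        fat_pattern="clustered",
    )
    v1, r1, t1 = fivol.generate_phantom(spec)
    v2, r2, t2 = fivol.generate_phantom(spec)
    np.testing.assert_array_equal(v1.data, v2.data)
    np.testing.assert_array_equal(r1.mask, r2.mask)
    assert t1 == t2


def test_partial_volume_creates_gray_zone_and_underestimation():
    """Enabling boundary mixing adds unclassified volume and never raises
    measured FTMP above the noiseless value — the partial-volume
    underestimation mechanism."""
    for seed in range(5):
        base = fivol.PhantomSpec(
            target_ftmp=3.0, seed=seed, shape=(40, 40, 10), fat_pattern="clustered"
        )
        mixed = dataclasses.replace(base, partial_volume_width=1)
        res0, truth0 = _measure(base)
        res1, truth1 = _measure(mixed)
        assert truth1.mixed_voxels > 0
        assert res1.unclassified_voxels > 0
        assert res0.unclassified_voxels == 0
        assert res1.ftmp <= res0.ftmp
        # the mixed ledger bounds the voxels that can leave their class
        lost_fat = truth1.fat_voxels - res1.fat_voxels
        assert 0 < lost_fat <= truth1.mixed_voxels


def test_noisy_recovery_within_tolerance():
    errors = []
    for seed in range(5):
        spec = fivol.PhantomSpec(
            target_ftmp=2.0, seed=seed, shape=(40, 40, 10), noise_sd=150.0
        )
        res, truth = _measure(spec)
        errors.append(abs(res.ftmp - truth.true_ftmp))
    assert np.mean(errors) < 0.2


def test_intensities_stay_in_class_ranges():
    spec = fivol.PhantomSpec(target_ftmp=5.0, seed=3, shape=(30, 30, 8))
    volume, roi, _ = fivol.generate_phantom(spec)
    inside = volume.data[roi.mask]
    assert ((inside >= 1002) & (inside <= 3448) | (inside >= 3600) & (inside <= 9652)).all()
    assert (volume.data[~roi.mask] == 0).all()


def test_normal_intensity_model_available():
    spec = fivol.PhantomSpec(
        target_ftmp=2.0, seed=3, shape=(30, 30, 8), intensity_model="normal"
    )
    res, truth = _measure(spec)
    assert res.ftmp == pytest.approx(truth.true_ftmp, abs=1e-9)


def test_cohort_presets_and_reproducibility():
    single = fivol.generate_cohort("control", 1, seed=9)
    again = fivol.generate_cohort("control", 1, seed=9)
    assert single[0][0] == again[0][0]
    assert single[0][1].specimen_id == again[0][1].specimen_id

    six = fivol.generate_cohort("control", 6, seed=1)
    mean_t = np.mean([s.target_ftmp for s, _ in six])
    assert 0.0 <= mean_t < 1.5  # near the 0.5 preset at n=6


@pytest.mark.parametrize("preset", list(COHORT_PRESETS))
def test_cohort_large_n_matches_generating_mean(preset):
    """Law-of-large-numbers check on the FTMP draws (truncation at 0
    shifts the mean up slightly, so allow that bias plus 2 SE)."""
    mean, sd = COHORT_PRESETS[preset]["ftmp"]
    n = 200
    specs = fivol.generate_cohort(preset, n, seed=17)
    sample_mean = np.mean([s.target_ftmp for s, _ in specs])
    trunc_bias = 0.12 if preset == "control" else 0.02
    assert abs(sample_mean - mean) < 2 * sd / np.sqrt(n) + trunc_bias


def test_cohort_weight_tracks_volume():
    pairs = fivol.generate_cohort("repair", 20, seed=3)
    vols = [s.roi_semiaxes[0] for s, _ in pairs]
    weights = [r.muscle_weight_g for _, r in pairs]
    rho = fivol.spearman(vols, weights)
    assert rho.rho > 0.8


def test_section_zero_truth_has_no_red():
    image, mask = fivol.generate_section(truth_fraction=0.0, seed=5)
    assert mask.sum() == 0
    assert fivol.fat_fraction_hsb(image).fat_fraction == 0.0


def test_section_determinism():
    a, ma = fivol.generate_section(truth_fraction=5.0, seed=11)
    b, mb = fivol.generate_section(truth_fraction=5.0, seed=11)
    np.testing.assert_array_equal(a.pixels, b.pixels)
    np.testing.assert_array_equal(ma, mb)


def test_section_truth_hits_target_within_half_point():
    for truth in (1.0, 5.0, 12.0):
        _, mask = fivol.generate_section(truth_fraction=truth, shape=(128, 128), seed=2)
        assert 100.0 * mask.mean() == pytest.approx(truth, abs=0.5)


def test_section_infeasible_fraction_rejected():
    with pytest.raises(PhantomError):
        fivol.generate_section(truth_fraction=60.0, seed=0)


def test_intensity_sample_fixture_structure():
    samples = fivol.generate_intensity_samples(seed=4)
    values = {
        "muscle": [s.value for s in samples if s.label == "muscle"],
        "fat": [s.value for s in samples if s.label == "fat"],
    }
    assert len(samples) == 90
    assert len(values["muscle"]) == 45 and len(values["fat"]) == 45
    assert min(values["muscle"]) == 1002 and max(values["muscle"]) == 3448
    assert min(values["fat"]) == 3600 and max(values["fat"]) == 9652
    assert len({s.specimen_id for s in samples}) == 18
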