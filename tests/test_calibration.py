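"""ROC cutoff calibration against an exhaustive-candidate oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

import fivol
from fivol.calibration import CalibrationError, IntensitySample, _candidate_cutoffs


def _samples(muscle, fat):
    return [IntensitySample(v, "muscle") for v in muscle] + [
        IntensitySample(v, "fat") for v in fat
    ]


def brute_force_best_j(muscle, fat):
    """Independent oracle: evaluate J at every midpoint/sentinel candidate."""
    muscle = np.asarray(muscle, float)
    fat = np.asarray(fat, float)
    distinct = sorted(set(muscle) | set(fat))
    candidates = [distinct[0] - 1.0]
    for a, b in zip(distinct, distinct[1:]):
        candidates.append((a + b) / 2.0)
    candidates.append(distinct[-1] + 1.0)
    best = -np.inf
    for t in candidates:
        sens = np.mean(fat >= t)
        spec = np.mean(muscle < t)
        best = max(best, sens + spec - 1.0)
    return best, candidates


def j_at(muscle, fat, t):
    muscle = np.asarray(muscle, float)
    fat = np.asarray(fat, float)
    return float(np.mean(fat >= t) + np.mean(muscle < t) - 1.0)


def test_sample_intensities_reads_untransformed_values(small_volume):
    small_volume.data[2, 3, 1] = 3448.0
    small_volume.data[4, 1, 2] = 9652.0
    samples = fivol.sample_intensities(
        small_volume, [(2, 3, 1), (4, 1, 2)], ["muscle", "fat"]
    )
    assert samples[0] == IntensitySample(3448.0, "muscle")
    assert samples[1] == IntensitySample(9652.0, "fat")


@pytest.mark.parametrize("point", [(-1, 0, 0), (8, 0, 0), (0, 6, 0)])
def test_out_of_bounds_points_rejected(small_volume, point):
    with pytest.raises(CalibrationError):
        fivol.sample_intensities(small_volume, [point], ["muscle"])


def test_label_length_mismatch_rejected(small_volume):
    with pytest.raises(CalibrationError):
        fivol.sample_intensities(small_volume, [(0, 0, 0)], ["muscle", "fat"])


def test_two_point_symmetry():
    result = fivol.calibrate_cutoff(_samples([10], [20]))
    assert result.cutoff == 15
    assert result.sensitivity == 1.0 and result.specificity == 1.0


def test_reference_fixture_perfect_separation():
    """90 labelled probes spanning the observed tissue ranges calibrate to a
    perfectly separating cutoff at the gap midpoint."""
    samples = fivol.generate_intensity_samples(seed=0)
    result = fivol.calibrate_cutoff(samples)
    assert result.n_samples == 90
    assert result.sensitivity == 1.0 and result.specificity == 1.0
    assert 3448 < result.cutoff < 3600
    assert result.cutoff == 3524.0  # midpoint of the separating gap
    assert result.gap == (3448.0, 3600.0)


def test_matches_exhaustive_oracle_on_overlapping_classes(rng):
    muscle = [1, 2, 3, 4]
    fat = [3, 4, 5, 6]
    result = fivol.calibrate_cutoff(_samples(muscle, fat))
    best_j, _ = brute_force_best_j(muscle, fat)
    assert result.youden_j == pytest.approx(best_j)
    assert j_at(muscle, fat, result.cutoff) == pytest.approx(best_j)

    for _ in range(60):
        n_m = int(rng.integers(1, 26))
        n_f = int(rng.integers(1, 26))
        muscle = rng.integers(0, 30, n_m).tolist()
        fat = rng.integers(0, 30, n_f).tolist()
        result = fivol.calibrate_cutoff(_samples(muscle, fat))
        best_j, _ = brute_force_best_j(muscle, fat)
        assert result.youden_j == pytest.approx(best_j)
        assert j_at(muscle, fat, result.cutoff) == pytest.approx(best_j)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    muscle=hst.lists(hst.integers(0, 1000), min_size=1, max_size=25),
    gap=hst.integers(1, 500),
    fat_offsets=hst.lists(hst.integers(0, 1000), min_size=1, max_size=25),
)
def test_separable_classes_give_perfect_cutoff(muscle, gap, fat_offsets):
    """Whenever max(muscle) < min(fat), sensitivity = specificity = 1 and
    the cutoff lies strictly inside the gap."""
    lo = max(muscle) + gap
    fat = [lo + o for o in fat_offsets]
    result = fivol.calibrate_cutoff(_samples(muscle, fat))
    assert result.sensitivity == 1.0 and result.specificity == 1.0
    assert max(muscle) < result.cutoff <= min(fat)
    assert result.cutoff == pytest.approx((max(muscle) + min(fat)) / 2.0)


def test_label_swap_antisymmetry_on_separable_input():
    muscle = [100.0, 220.0, 300.0]
    fat = [500.0, 640.0]
    fwd = fivol.calibrate_cutoff(_samples(muscle, fat))
    mirrored = fivol.calibrate_cutoff(_samples([-v for v in fat], [-v for v in muscle]))
    assert mirrored.cutoff == pytest.approx(-fwd.cutoff)


def test_duplicate_sample_keeps_candidate_set():
    muscle = [1.0, 2.0, 5.0]
    fat = [4.0, 8.0]
    base = fivol.calibrate_cutoff(_samples(muscle, fat))
    dup = fivol.calibrate_cutoff(_samples(muscle + [2.0], fat))
    assert [p[0] for p in base.roc_points] == [p[0] for p in dup.roc_points]


def test_candidates_are_midpoints_plus_sentinels():
    cands = _candidate_cutoffs(np.array([1.0, 3.0, 3.0, 7.0]))
    np.testing.assert_array_equal(cands, [0.0, 2.0, 5.0, 8.0])


def test_single_class_input_rejected():
    with pytest.raises(CalibrationError):
        fivol.calibrate_cutoff(_samples([1, 2], []))


def test_identical_values_flagged_inseparable():
    result = fivol.calibrate_cutoff(_samples([5.0, 5.0], [5.0, 5.0]))
    assert result.inseparable_flag
    assert result.youden_j == pytest.approx(0.0)


def test_samples_csv_roundtrip(tmp_path):
    samples = fivol.generate_intensity_samples(seed=3)
    path = tmp_path / "samples.csv"
    fivol.calibration.write_samples_csv(samples, path)
    back = fivol.calibration.read_samples_csv(path)
    assert back == samples
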