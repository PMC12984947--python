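"""Threshold-paint segmentation against a voxelwise brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

import fivol
from fivol.core import EmptyRoiError, MaskMismatchError
from fivol.segmentation import BACKGROUND, FAT, MUSCLE, UNCLASSIFIED

from conftest import random_volume_and_roi


def oracle_labels(volume, roi, policy):
    """Independent per-voxel rule evaluation by triple loop."""
    lo, hi = policy.muscle_window
    out = np.empty(volume.shape, dtype=int)
    for i in range(volume.shape[0]):
        for j in range(volume.shape[1]):
            for k in range(volume.shape[2]):
                if not roi.mask[i, j, k]:
                    out[i, j, k] = BACKGROUND
                elif lo <= volume.data[i, j, k] <= hi:
                    out[i, j, k] = MUSCLE
                elif volume.data[i, j, k] >= policy.fat_floor:
                    out[i, j, k] = FAT
                else:
                    out[i, j, k] = UNCLASSIFIED
    return out


def test_default_policy_windows():
    policy = fivol.default_policy()
    assert policy.muscle_window == (1000.0, 3500.0)
    assert policy.fat_floor == 3600.0
    lo, hi = policy.gray_zone
    assert lo < 3550 < hi


def test_window_boundaries_and_mask_constraint():
    data = np.zeros((2, 2, 1))
    data[0, 0, 0] = 3448.0  # inside muscle window
    data[0, 1, 0] = 3600.0  # at the fat floor
    data[1, 0, 0] = 5000.0  # bright but outside ROI
    data[1, 1, 0] = 3550.0  # gray zone
    roi = np.ones((2, 2, 1), dtype=bool)
    roi[1, 0, 0] = False
    labels = fivol.segment_tissues(
        fivol.ImageVolume(data, (1, 1, 1)), fivol.RoiMask(roi)
    )
    assert labels.labels[0, 0, 0] == MUSCLE
    assert labels.labels[0, 1, 0] == FAT
    assert labels.labels[1, 0, 0] == BACKGROUND
    assert labels.labels[1, 1, 0] == UNCLASSIFIED


def test_matches_voxelwise_oracle_small_handset():
    rng = np.random.default_rng(11)
    data = rng.choice([500.0, 1000.0, 2500.0, 3500.0, 3550.0, 3600.0, 9000.0], size=(3, 3, 3))
    roi = rng.random((3, 3, 3)) < 0.7
    roi[0, 0, 0] = True
    volume = fivol.ImageVolume(data, (1, 1, 1))
    mask = fivol.RoiMask(roi)
    policy = fivol.default_policy()
    labels = fivol.segment_tissues(volume, mask, policy)
    np.testing.assert_array_equal(labels.labels, oracle_labels(volume, mask, policy))


def test_matches_voxelwise_oracle_randomized(rng):
    for _ in range(10):
        volume, roi = random_volume_and_roi(rng, shape=(10, 8, 6))
        policy = fivol.default_policy()
        labels = fivol.segment_tissues(volume, roi, policy)
        np.testing.assert_array_equal(labels.labels, oracle_labels(volume, roi, policy))


def test_partition_of_roi(rng):
    volume, roi = random_volume_and_roi(rng)
    labels = fivol.segment_tissues(volume, roi)
    inside = labels.labels[roi.mask]
    assert (inside != BACKGROUND).all()
    assert (labels.labels[~roi.mask] == BACKGROUND).all()
    n = labels.count(MUSCLE) + labels.count(FAT) + labels.count(UNCLASSIFIED)
    assert n == roi.foreground_count


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    floor_bump=hst.floats(0, 5000, allow_nan=False),
    widen=hst.floats(0, 99, allow_nan=False),
    seed=hst.integers(0, 100),
)
def test_threshold_monotonicity(floor_bump, widen, seed):
    """Raising the fat floor never adds fat voxels; widening the muscle
    window never removes muscle voxels."""
    volume, roi = random_volume_and_roi(np.random.default_rng(seed), shape=(8, 8, 4))
    base = fivol.ThresholdPolicy(muscle_window=(1000.0, 3500.0), fat_floor=3600.0)
    raised = fivol.ThresholdPolicy(muscle_window=(1000.0, 3500.0), fat_floor=3600.0 + floor_bump)
    widened = fivol.ThresholdPolicy(
        muscle_window=(1000.0 - widen, 3500.0 + widen), fat_floor=3600.0
    )
    n_fat_base = fivol.segment_tissues(volume, roi, base).count(FAT)
    n_fat_raised = fivol.segment_tissues(volume, roi, raised).count(FAT)
    assert n_fat_raised <= n_fat_base
    n_muscle_base = fivol.segment_tissues(volume, roi, base).count(MUSCLE)
    n_muscle_widened = fivol.segment_tissues(volume, roi, widened).count(MUSCLE)
    assert n_muscle_widened >= n_muscle_base


def test_deterministic_and_spacing_independent(rng):
    volume, roi = random_volume_and_roi(rng, shape=(6, 6, 3))
    a = fivol.segment_tissues(volume, roi)
    b = fivol.segment_tissues(volume, roi)
    np.testing.assert_array_equal(a.labels, b.labels)
    rescaled = fivol.ImageVolume(volume.data, spacing=(9.0, 9.0, 9.0))
    c = fivol.segment_tissues(rescaled, roi)
    np.testing.assert_array_equal(a.labels, c.labels)


def test_empty_roi_and_mismatch_errors(small_volume):
    with pytest.raises(EmptyRoiError):
        fivol.segment_tissues(small_volume, fivol.RoiMask(np.zeros(small_volume.shape)))
    with pytest.raises(MaskMismatchError):
        fivol.segment_tissues(small_volume, fivol.RoiMask(np.ones((1, 1, 1))))


def test_invalid_policy_rejected():
    with pytest.raises(ValueError):
        fivol.ThresholdPolicy(muscle_window=(1000.0, 3700.0), fat_floor=3600.0)


def test_label_map_roundtrip(tmp_path, rng):
    volume, roi = random_volume_and_roi(rng, shape=(6, 5, 4))
    labels = fivol.segment_tissues(volume, roi)
    path = tmp_path / "labels.nii.gz"
    fivol.segmentation.save_label_map(labels, path)
    back = fivol.segmentation.load_label_map(path)
    np.testing.assert_array_equal(back.labels, labels.labels)
    assert back.policy == labels.policy
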