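"""Eye segmentation, frame synchronization, and behavior labeling."""

import dataclasses
import math

import numpy as np
import pytest
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from vtapipe.eyeblink import (
    EyeConfig,
    EyeTrace,
    detect_lightoff_frames,
    extract_eye_area,
    label_lick_trials,
    normalize_and_label_blinks,
    synchronize_frame_times,
)
from vtapipe.synthetic import TrialRecord


def _eye_frame(r_radius=36, c_radius=44, specks=()):
    img = np.full((120, 160), 250, dtype=np.uint8)
    rr, cc = draw_ellipse(60, 80, r_radius, c_radius, shape=img.shape)
    img[rr, cc] = 60
    for row, col, radius in specks:
        sr, sc = draw_disk((row, col), radius, shape=img.shape)
        img[sr, sc] = 80
    return img, len(rr)


def test_uniform_bright_frame_has_no_eye():
    area, ecc = extract_eye_area(np.full((120, 160), 255, dtype=np.uint8))
    assert area == 0 and math.isnan(ecc)


def test_ellipse_area_recovered_within_two_percent():
    img, true_area = _eye_frame()
    area, ecc = extract_eye_area(img)
    assert abs(area - true_area) / true_area < 0.02
    assert 0 < ecc < 1


def test_small_specks_do_not_change_area():
    clean, _ = _eye_frame()
    specked, _ = _eye_frame(specks=((10, 12, 5), (10, 148, 6), (108, 16, 5)))
    assert extract_eye_area(clean)[0] == extract_eye_area(specked)[0]


def test_circle_has_near_zero_eccentricity():
    img = np.full((120, 160), 250, dtype=np.uint8)
    rr, cc = draw_disk((60, 80), 30, shape=img.shape)
    img[rr, cc] = 60
    _, ecc = extract_eye_area(img)
    assert ecc < 0.2


def test_non_grayscale_frame_rejected():
    with pytest.raises(ValueError, match="8-bit"):
        extract_eye_area(np.zeros((10, 10), dtype=np.float64))
    with pytest.raises(ValueError, match="single-channel"):
        extract_eye_area(np.zeros((10, 10, 3), dtype=np.uint8))


def test_eye_config_validation():
    with pytest.raises(ValueError):
        EyeConfig(intensity_threshold=0)
    with pytest.raises(ValueError):
        EyeConfig(blink_threshold=1.5)


# --------------------------------------------------------- light-off detection

def test_flat_intensity_series_has_no_events():
    assert detect_lightoff_frames(np.full(500, 240.0)) == []


def test_isolated_dips_detected():
    x = np.full(400, 240.0)
    x[120] = 60.0
    x[240] = 55.0
    assert detect_lightoff_frames(x) == [120, 240]


def test_two_frame_dip_collapses_to_one_event():
    x = np.full(400, 240.0)
    x[120:122] = 60.0
    assert detect_lightoff_frames(x) == [120]


def test_too_few_frames_rejected():
    with pytest.raises(ValueError):
        detect_lightoff_frames(np.asarray([240.0, 60.0]))


# ------------------------------------------------------------ synchronization

def test_linear_interpolation_between_anchors():
    times = synchronize_frame_times([100, 220], [10.0, 12.0], 400)
    assert times[160] == pytest.approx(11.0)
    assert times[100] == pytest.approx(10.0)   # anchor fidelity
    assert times[40] == pytest.approx(9.0)     # extrapolation before first anchor
    assert times[280] == pytest.approx(13.0)   # extrapolation after last anchor


def test_synchronization_input_validation():
    with pytest.raises(ValueError, match="equally many"):
        synchronize_frame_times([100, 200], [1.0], 300)
    with pytest.raises(ValueError, match="two"):
        synchronize_frame_times([100], [1.0], 300)
    with pytest.raises(ValueError, match="increasing"):
        synchronize_frame_times([200, 100], [1.0, 2.0], 300)


# -------------------------------------------------------------- blink labels

def _trace_with_delay_area(delay_norm_area: float):
    """600 frames at 60 Hz; one odor trial at t=2 s; delay area as requested."""
    n = 600
    times = np.arange(n) / 60.0
    areas = np.full(n, 1000.0)
    delay = (times >= 3.0) & (times < 4.0)
    areas[delay] = delay_norm_area * 1000.0
    trace = EyeTrace(
        raw_area=areas, eccentricity=np.full(n, 0.5),
        mean_intensity=np.full(n, 240.0), frame_times=times,
    )
    trial = TrialRecord(0, "C", "airpuff", 2.0, 3.0, 4.0, 1.0)
    return trace, [trial]


@pytest.mark.parametrize(
    "delay_area, expected_blink",
    [(0.3, True), (0.7, False), (0.5, False)],  # exactly 0.5 is no-blink
)
def test_blink_labels_threshold(delay_area, expected_blink):
    trace, trials = _trace_with_delay_area(delay_area)
    labels = normalize_and_label_blinks(trace, trials)
    row = labels.iloc[0]
    assert row["delay_mean_area"] == pytest.approx(delay_area, abs=0.01)
    assert bool(row["blink"]) is expected_blink


def test_trial_without_frames_left_unlabeled():
    trace, _ = _trace_with_delay_area(0.3)
    far_trial = TrialRecord(1, "C", "airpuff", 100.0, 101.0, 102.0, 1.0)
    with pytest.warns(UserWarning, match="unlabeled"):
        labels = normalize_and_label_blinks(trace, [far_trial])
    assert labels.iloc[0]["blink"] is None


def test_normalized_area_rarely_exceeds_one():
    trace, trials = _trace_with_delay_area(0.3)
    normalize_and_label_blinks(trace, trials)
    norm = trace.normalized_area
    assert np.mean(norm <= 1.0) >= 0.99


# ---------------------------------------------------------------- lick labels

@pytest.mark.parametrize("n_licks, expected", [(4, True), (2, False), (3, True)])
def test_lick_labels_threshold(n_licks, expected):
    trial = TrialRecord(0, "A", "water", 2.0, 3.0, 4.0, 1.0)
    licks = np.linspace(3.05, 3.95, n_licks)
    labels = label_lick_trials(licks, [trial])
    assert bool(labels.iloc[0]["lick"]) is expected
    assert labels.iloc[0]["delay_lick_rate"] == pytest.approx(n_licks)
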