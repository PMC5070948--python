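"""Eye-area quantification from behavioral video and trial labeling.

The eye is segmented from each 8-bit grayscale frame by intensity
thresholding (the infrared-lit face background is nearly saturated, the
eye dark), small-component removal, morphological opening, and hole
filling; the area of the largest remaining component is the eye area.
Frames are synchronized to the recording clock through brief infrared-
light-off events delivered 2 s after every US, which appear as troughs
in the mean frame intensity.  Trials are then labeled as blink /
no-blink by the normalized eye area during the CS-US delay, and lick /
no-lick by the delay lick rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import label as label_components
from skimage.measure import regionprops
from skimage.morphology import disk, opening, remove_small_holes, remove_small_objects

from .synthetic.tasks import TrialRecord


@dataclass(frozen=True)
class EyeConfig:
    intensity_threshold: int = 234   # 8-bit level separating eye from background
    min_patch: int = 500             # smaller foreground components are deleted
    opening_radius: int = 2          # px, disk structuring element
    hole_fill_max: int = 500         # enclosed background holes up to this size are filled
    norm_percentile: float = 99.0    # session normalizer: this percentile of eye areas
    blink_threshold: float = 0.5     # normalized delay-mean area below this = blink
    delay_window: tuple[float, float] = (1.0, 2.0)  # s from odor onset
    lick_threshold: float = 3.0      # licks/s in the delay; >= this = lick trial

    def __post_init__(self) -> None:
        if not 0 < self.intensity_threshold < 255:
            raise ValueError("intensity_threshold must lie strictly within (0, 255)")
        if not 0.0 < self.blink_threshold < 1.0:
            raise ValueError("blink_threshold must lie in (0, 1)")


@dataclass
class EyeTrace:
    """Per-frame eye measurements, with times filled in after synchronization."""

    raw_area: np.ndarray            # px
    eccentricity: np.ndarray        # NaN where no eye component was found
    mean_intensity: np.ndarray      # per-frame mean pixel intensity
    frame_times: np.ndarray | None = None
    normalized_area: np.ndarray | None = None
    lightoff_frames: np.ndarray | None = None

    def valid_mask(self) -> np.ndarray:
        """Frames usable for area analysis (excludes infrared-off frames)."""
        mask = np.ones(len(self.raw_area), dtype=bool)
        if self.lightoff_frames is not None:
            mask[np.asarray(self.lightoff_frames, dtype=int)] = False
            # the off period can span two frames; drop the successor too
            succ = np.asarray(self.lightoff_frames, dtype=int) + 1
            mask[succ[succ < len(mask)]] = False
        return mask


def extract_eye_area(frame: np.ndarray, config: EyeConfig | None = None) -> tuple[int, float]:
    """Eye area (px) and eccentricity of the largest dark component.

    Steps: binarize (intensity below threshold = foreground), delete
    foreground components smaller than ``min_patch``, morphological
    opening with a disk, fill enclosed holes smaller than
    ``hole_fill_max``, then measure the largest connected component.
    Returns ``(0, nan)`` when nothing survives cleanup.
    """
    config = config or EyeConfig()
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("frame must be a single-channel image")
    if frame.dtype != np.uint8:
        raise ValueError("frame must be 8-bit grayscale")
    binary = frame < config.intensity_threshold
    # components strictly smaller than min_patch are deleted (kept at >= min_patch)
    binary = remove_small_objects(binary, max_size=config.min_patch - 1, connectivity=2)
    if config.opening_radius > 0:
        binary = opening(binary, footprint=disk(config.opening_radius))
    binary = remove_small_holes(binary, max_size=config.hole_fill_max - 1)
    labels = label_components(binary, connectivity=2)
    if labels.max() == 0:
        return 0, float("nan")
    regions = regionprops(labels)
    largest = max(regions, key=lambda r: r.area)
    return int(largest.area), float(largest.eccentricity)


def measure_eye_trace(frames: np.ndarray, config: EyeConfig | None = None) -> EyeTrace:
    """Run eye-area extraction over an image stack (n_frames, h, w)."""
    config = config or EyeConfig()
    n = len(frames)
    area = np.zeros(n)
    ecc = np.full(n, np.nan)
    mean_int = np.zeros(n)
    for i in range(n):
        mean_int[i] = frames[i].mean()
        area[i], ecc[i] = extract_eye_area(frames[i], config)
    trace = EyeTrace(raw_area=area, eccentricity=ecc, mean_intensity=mean_int)
    trace.lightoff_frames = np.asarray(detect_lightoff_frames(mean_int), dtype=int)
    return trace


def detect_lightoff_frames(
    mean_frame_intensities: np.ndarray, threshold: float | None = None
) -> list[int]:
    """Frame indices of infrared-off events (troughs of mean intensity).

    The default trough threshold is the midpoint between the session
    median and minimum intensity.  Consecutive dark frames (the off
    period can span up to two frames at 60 Hz) collapse to one event at
    the run's first frame.
    """
    x = np.asarray(mean_frame_intensities, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 frames")
    if threshold is None:
        threshold = 0.5 * (np.median(x) + x.min())
    below = x < threshold
    if not below.any():
        return []
    idx = np.flatnonzero(below)
    run_starts = idx[np.concatenate([[True], np.diff(idx) > 1])]
    return run_starts.tolist()


def synchronize_frame_times(
    event_frames: np.ndarray,
    event_timestamps: np.ndarray,
    n_frames: int,
) -> np.ndarray:
    """Interpolate a time for every frame from (frame index, timestamp) anchors.

    Piecewise-linear between bracketing anchors; frames outside the
    anchor span are extrapolated from the nearest two anchors.
    """
    f = np.asarray(event_frames, dtype=float)
    t = np.asarray(event_timestamps, dtype=float)
    if f.size != t.size:
        raise ValueError("need equally many event frames and timestamps")
    if f.size < 2:
        raise ValueError("need at least two synchronization anchors")
    if np.any(np.diff(f) <= 0) or np.any(np.diff(t) <= 0):
        raise ValueError("anchors must be strictly increasing")
    frames = np.arange(n_frames, dtype=float)
    times = np.interp(frames, f, t)
    lo = frames < f[0]
    hi = frames > f[-1]
    slope_lo = (t[1] - t[0]) / (f[1] - f[0])
    slope_hi = (t[-1] - t[-2]) / (f[-1] - f[-2])
    times[lo] = t[0] + (frames[lo] - f[0]) * slope_lo
    times[hi] = t[-1] + (frames[hi] - f[-1]) * slope_hi
    return times


def normalize_areas(trace: EyeTrace, config: EyeConfig | None = None) -> np.ndarray:
    """Normalize raw areas by the session's high-percentile (near-maximum) area.

    Infrared-off frames are excluded from the normalizer.  Values
    slightly above 1 are possible and are not clipped.
    """
    config = config or EyeConfig()
    valid = trace.valid_mask()
    if not valid.any():
        raise ValueError("no valid frames to normalize against")
    denom = np.percentile(trace.raw_area[valid], config.norm_percentile)
    if denom <= 0:
        raise ValueError("session has no measurable eye area")
    norm = trace.raw_area / denom
    trace.normalized_area = norm
    return norm


def normalize_and_label_blinks(
    trace: EyeTrace,
    trials: list[TrialRecord],
    config: EyeConfig | None = None,
) -> pd.DataFrame:
    """Per-trial delay-window mean normalized area and blink label.

    Every odor trial gets a row; air-puff analyses downstream select the
    air-puff-predicting trials.  A delay mean below ``blink_threshold``
    labels the trial a blink; a mean exactly at the threshold is
    no-blink.  Trials with no frames in the delay window are left
    unlabeled (NaN) with a warning.
    """
    config = config or EyeConfig()
    if trace.frame_times is None:
        raise ValueError("trace must be synchronized first (frame_times missing)")
    norm = trace.normalized_area
    if norm is None:
        norm = normalize_areas(trace, config)
    valid = trace.valid_mask()
    rows = []
    for trial in trials:
        if not trial.has_odor:
            continue
        lo = trial.odor_onset + config.delay_window[0]
        hi = trial.odor_onset + config.delay_window[1]
        mask = (trace.frame_times >= lo) & (trace.frame_times < hi) & valid
        if not mask.any():
            warnings.warn(f"trial {trial.trial_index}: no frames in delay window, unlabeled")
            rows.append((trial.trial_index, trial.odor, np.nan, None))
            continue
        mean_area = float(norm[mask].mean())
        rows.append((trial.trial_index, trial.odor, mean_area,
                     bool(mean_area < config.blink_threshold)))
    return pd.DataFrame(rows, columns=["trial_index", "odor", "delay_mean_area", "blink"])


def label_lick_trials(
    lick_times: np.ndarray,
    trials: list[TrialRecord],
    config: EyeConfig | None = None,
) -> pd.DataFrame:
    """Per-trial delay lick rate and lick / no-lick label (rate >= threshold)."""
    config = config or EyeConfig()
    licks = np.asarray(lick_times, dtype=float)
    rows = []
    for trial in trials:
        if not trial.has_odor:
            continue
        lo = trial.odor_onset + config.delay_window[0]
        hi = trial.odor_onset + config.delay_window[1]
        rate = float(np.sum((licks >= lo) & (licks < hi)) / (hi - lo))
        rows.append((trial.trial_index, trial.odor, rate, bool(rate >= config.lick_threshold)))
    return pd.DataFrame(rows, columns=["trial_index", "odor", "delay_lick_rate", "lick"])
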