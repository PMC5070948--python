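"""Synthetic behavioral eye video with known ground truth.

Frames emulate an infrared view of the mouse's right eye: a bright
saturated face background, the eye as a dark filled ellipse, occasional
small dark specks elsewhere in the frame, and brief global darkenings
(infrared light source off) 2 s after every US onset, which downstream
code uses to synchronize frame indices with event timestamps.

On air-puff-predicting trials with blink intent, the ellipse area ramps
down during the CS-US delay to well below half its open value and
recovers after the US.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .tasks import TaskSpec, TrialRecord, session_end_time


@dataclass(frozen=True)
class BlinkParams:
    """Blink behavior and rendering geometry of the synthetic eye."""

    blink_prob: float = 0.48          # fraction of air-puff CS trials with a blink
    closed_fraction: float = 0.25     # eye area during a blink, relative to open
    ramp_start: float = 0.5           # s from odor onset: blink begins
    ramp_end: float = 1.0             # s from odor onset: blink fully developed
    reopen_start: float = 0.3         # s after US: eye starts reopening
    reopen_end: float = 0.8           # s after US: eye fully open
    open_radii: tuple[int, int] = (36, 44)   # (row, col) semi-axes, px
    frame_shape: tuple[int, int] = (120, 160)
    eye_intensity: float = 60.0
    background_intensity: float = 250.0
    speck_rate: float = 1.0           # mean specks per frame (all < 500 px)
    lightoff_scale: float = 0.25      # global intensity scale on infrared-off frames

    def __post_init__(self) -> None:
        if not 0.0 <= self.blink_prob <= 1.0:
            raise ValueError("blink_prob must lie in [0, 1]")
        if not 0.0 < self.closed_fraction < 0.5:
            raise ValueError("closed_fraction must lie in (0, 0.5) so blinks cross threshold")


@dataclass
class EyeVideoGroundTruth:
    """Per-frame and per-trial ground truth stored with a synthetic video."""

    frame_times: np.ndarray            # true time of each frame (s)
    true_area: np.ndarray              # rendered eye-ellipse pixel count per frame
    open_area: float                   # rendered open-eye pixel count
    true_eccentricity: float           # analytic eccentricity of the open ellipse
    blink_intent: dict[int, bool]      # trial_index -> blink intent (air-puff CS trials)
    lightoff_frames: list[int]         # first frame of each infrared-off event
    frame_rate: float = 60.0


def _area_scale(t: float, trial: TrialRecord, p: BlinkParams) -> float:
    """Relative eye area at time t on a blink trial (1 = fully open)."""
    on = trial.odor_onset
    us = trial.us_onset
    if t < on + p.ramp_start or t > us + p.reopen_end:
        return 1.0
    if t < on + p.ramp_end:
        frac = (t - on - p.ramp_start) / (p.ramp_end - p.ramp_start)
        return 1.0 + frac * (p.closed_fraction - 1.0)
    if t <= us + p.reopen_start:
        return p.closed_fraction
    frac = (t - us - p.reopen_start) / (p.reopen_end - p.reopen_start)
    return p.closed_fraction + frac * (1.0 - p.closed_fraction)


def synthesize_eye_video(
    trials: list[TrialRecord],
    spec: TaskSpec,
    blink_params: BlinkParams | None = None,
    frame_rate: float = 60.0,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, EyeVideoGroundTruth]:
    """Render the session's eye video as an 8-bit grayscale image stack.

    Returns ``(frames, ground_truth)`` where ``frames`` has shape
    (n_frames, height, width) and dtype uint8.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    p = blink_params or BlinkParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    t_end = session_end_time(trials)
    n_frames = int(np.ceil(t_end * frame_rate)) + 1
    frame_times = np.arange(n_frames) / frame_rate
    h, w = p.frame_shape
    center = (h // 2, w // 2)
    r_open, c_open = p.open_radii
    ecc = np.sqrt(1.0 - (min(r_open, c_open) / max(r_open, c_open)) ** 2)

    # blink intent on air-puff-predicting CS trials
    blink_intent: dict[int, bool] = {}
    blink_trials: list[TrialRecord] = []
    for trial in trials:
        if trial.has_odor and spec.odor_outcomes[trial.odor][1] > 0:
            intent = bool(rng.random() < p.blink_prob)
            blink_intent[trial.trial_index] = intent
            if intent:
                blink_trials.append(trial)

    # infrared-off events: 1-2 consecutive frames at us_onset + 2 s
    lightoff_frames: list[int] = []
    lightoff_all: set[int] = set()
    for trial in trials:
        k = int(round((trial.us_onset + 2.0) * frame_rate))
        if k >= n_frames:
            continue
        lightoff_frames.append(k)
        run = {k} if rng.random() < 0.5 else {k, min(k + 1, n_frames - 1)}
        lightoff_all |= run

    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    true_area = np.zeros(n_frames)
    open_mask_area = None

    for i, t in enumerate(frame_times):
        scale = 1.0
        for trial in blink_trials:
            if trial.odor_onset - 0.5 <= t <= trial.us_onset + 2.0:
                scale = min(scale, _area_scale(t, trial, p))
        img = p.background_intensity + 2.0 * rng.standard_normal((h, w))
        ax = np.sqrt(scale)
        rr, cc = draw_ellipse(center[0], center[1], r_open * ax, c_open * ax, shape=(h, w))
        img[rr, cc] = p.eye_intensity + 3.0 * rng.standard_normal(len(rr))
        true_area[i] = len(rr)
        if open_mask_area is None and scale == 1.0:
            open_mask_area = float(len(rr))
        # dark specks, each well below the minimum-patch size
        for _ in range(rng.poisson(p.speck_rate)):
            radius = rng.integers(3, 7)
            row = rng.integers(radius, h - radius)
            col = rng.integers(radius, w - radius)
            # keep specks clear of the eye so they stay separate components
            if (abs(row - center[0]) < r_open + radius + 4
                    and abs(col - center[1]) < c_open + radius + 4):
                continue
            sr, sc = draw_disk((row, col), radius, shape=(h, w))
            img[sr, sc] = 80.0
        if i in lightoff_all:
            img *= p.lightoff_scale
        frames[i] = np.clip(img, 0, 255).astype(np.uint8)

    truth = EyeVideoGroundTruth(
        frame_times=frame_times,
        true_area=true_area,
        open_area=float(open_mask_area if open_mask_area is not None else len(rr)),
        true_eccentricity=float(ecc),
        blink_intent=blink_intent,
        lightoff_frames=lightoff_frames,
        frame_rate=frame_rate,
    )
    return frames, truth
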