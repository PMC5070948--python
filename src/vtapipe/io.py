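"""Session bundles on disk: simulation output and analysis input.

A session directory holds plain-text tables sharing one clock:

* ``trials.csv`` — trial_index, odor, outcome, odor_onset_s,
  odor_offset_s, us_onset_s, iti_before_s (odor columns NaN on no-odor
  free-outcome trials)
* ``spikes.csv`` — unit_id, time_s (sorted within unit)
* ``light_pulses.csv`` — time_s, frequency_hz
* ``licks.csv`` — time_s
* ``waveforms.csv`` — unit_id, kind (spontaneous|evoked), channel,
  sample, value: per-unit mean waveforms from the stimulation block
* ``ground_truth.json`` — generator parameters and provenance (seed,
  package version)
* ``eye/frame_%06d.png`` + ``eye_truth.json`` — optional video media
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import __version__
from .optotagging import mean_waveforms
from .synthetic import (
    LightProtocol,
    NeuronModelParams,
    SpikeTrain,
    TaskSpec,
    TrialRecord,
    build_light_protocol,
    build_task_spec,
    cs_value,
    generate_trial_sequence,
    sample_neuron_params,
    session_end_time,
    simulate_dopamine_session,
    simulate_licks,
    simulate_light_tagging,
    synthesize_eye_video,
)
from .synthetic.tasks import LOW_REWARD_CONTEXT
from .synthetic.video import EyeVideoGroundTruth

def _float_repr(value) -> str:
    """Shortest decimal representation that round-trips a float64."""
    return repr(float(value))


TRIAL_COLUMNS = [
    "trial_index", "odor", "outcome",
    "odor_onset_s", "odor_offset_s", "us_onset_s", "iti_before_s",
]


@dataclass
class SessionBundle:
    """Everything recorded (or simulated) in one session."""

    task: TaskSpec
    trials: list[TrialRecord]
    units: dict[str, SpikeTrain]
    protocol: LightProtocol
    licks: np.ndarray
    waveform_means: dict[str, tuple[np.ndarray | None, np.ndarray | None]]
    ground_truth: dict
    seed: int
    eye_frames: np.ndarray | None = None
    eye_truth: EyeVideoGroundTruth | None = None


def simulate_session(
    task: str = "mixed_prediction",
    n_trials: int = 400,
    n_tagged: int = 6,
    n_untagged: int = 3,
    seed: int = 0,
    with_video: bool = False,
    trains_per_frequency: int = 5,
    neuron_params: NeuronModelParams | None = None,
    task_overrides: dict | None = None,
) -> SessionBundle:
    """Generate a complete synthetic session with known ground truth.

    One master seed fans out into independent substreams for the trial
    sequence, each unit, the licks and the video, so components can be
    regenerated independently.  Tagged units follow the value-coding
    dopamine model with the context (low/high reward) implied by the
    task; untagged units fire at baseline only.  When ``neuron_params``
    is given it is used for every tagged unit instead of per-neuron
    sampled parameters.
    """
    spec = build_task_spec(task)
    if task_overrides:
        from dataclasses import replace

        spec = replace(spec, **task_overrides)
    context = "low" if task in LOW_REWARD_CONTEXT else "high"
    ss = np.random.SeedSequence(seed)
    keys = ["trials", "licks", "video"] + [f"unit{i}" for i in range(n_tagged + n_untagged)]
    rngs = {k: np.random.default_rng(s) for k, s in zip(keys, ss.spawn(len(keys)))}

    trials = generate_trial_sequence(spec, n_trials, rngs["trials"])
    t_beh_end = session_end_time(trials)
    protocol = build_light_protocol(
        start=t_beh_end + 8.0, trains_per_frequency=trains_per_frequency
    )

    units: dict[str, SpikeTrain] = {}
    waveform_means: dict[str, tuple[np.ndarray | None, np.ndarray | None]] = {}
    unit_truth: dict[str, dict] = {}
    for i in range(n_tagged + n_untagged):
        tagged = i < n_tagged
        uid = f"dan{i:02d}" if tagged else f"unt{i - n_tagged:02d}"
        rng = rngs[f"unit{i}"]
        if tagged:
            params = neuron_params or sample_neuron_params(rng, context)
        else:
            params = NeuronModelParams(
                baseline_rate=float(rng.uniform(5.0, 10.0)), value_gain=0.0
            )
        behavior = simulate_dopamine_session(
            params, trials, spec, rng, t_end=t_beh_end, unit_id=uid
        )
        tag_block = simulate_light_tagging(
            params, tagged, protocol, rng, pad=8.0, unit_id=uid
        )
        spont, evoked = mean_waveforms(tag_block, protocol)
        units[uid] = SpikeTrain(
            np.concatenate([behavior.times, tag_block.times]), unit_id=uid
        )
        waveform_means[uid] = (spont, evoked)
        unit_truth[uid] = {
            "tagged": tagged,
            "baseline_rate": params.baseline_rate,
            "value_gain": params.value_gain,
            "water_value": params.water_value,
            "airpuff_value": params.airpuff_value,
            "context_excitation": params.context_excitation,
            "aversive_cs_masking": params.aversive_cs_masking,
        }

    licks = simulate_licks(trials, spec, rngs["licks"])

    eye_frames = None
    eye_truth = None
    if with_video:
        eye_frames, eye_truth = synthesize_eye_video(trials, spec, seed=rngs["video"])

    sample_params = NeuronModelParams()
    ground_truth = {
        "task": task,
        "context": context,
        "seed": seed,
        "package_version": __version__,
        "n_trials": n_trials,
        "pulse_duration": protocol.pulse_duration,
        "units": unit_truth,
        "cs_values": {
            odor: cs_value(spec, odor, sample_params.water_value, sample_params.airpuff_value)
            for odor in spec.odors
        },
    }
    return SessionBundle(
        task=spec, trials=trials, units=units, protocol=protocol, licks=licks,
        waveform_means=waveform_means, ground_truth=ground_truth, seed=seed,
        eye_frames=eye_frames, eye_truth=eye_truth,
    )


def _trials_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (t.trial_index, t.odor, t.outcome, t.odor_onset, t.odor_offset,
             t.us_onset, t.iti_before)
            for t in trials
        ],
        columns=TRIAL_COLUMNS,
    )


def write_session(bundle: SessionBundle, path: str | Path) -> Path:
    """Write a session bundle to a directory of plain-text files."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    _trials_frame(bundle.trials).to_csv(path / "trials.csv", index=False, float_format=_float_repr)

    spike_rows = []
    for uid in sorted(bundle.units):
        for t in bundle.units[uid].times:
            spike_rows.append((uid, t))
    pd.DataFrame(spike_rows, columns=["unit_id", "time_s"]).to_csv(
        path / "spikes.csv", index=False, float_format=_float_repr
    )

    pd.DataFrame(
        {
            "time_s": bundle.protocol.pulse_onsets,
            "frequency_hz": bundle.protocol.pulse_frequencies,
        }
    ).to_csv(path / "light_pulses.csv", index=False, float_format=_float_repr)

    pd.DataFrame({"time_s": bundle.licks}).to_csv(
        path / "licks.csv", index=False, float_format=_float_repr
    )

    wf_rows = []
    for uid in sorted(bundle.waveform_means):
        spont, evoked = bundle.waveform_means[uid]
        for kind, wf in (("spontaneous", spont), ("evoked", evoked)):
            if wf is None:
                continue
            for ch in range(wf.shape[0]):
                for s in range(wf.shape[1]):
                    wf_rows.append((uid, kind, ch, s, wf[ch, s]))
    pd.DataFrame(
        wf_rows, columns=["unit_id", "kind", "channel", "sample", "value"]
    ).to_csv(path / "waveforms.csv", index=False, float_format=_float_repr)

    with open(path / "ground_truth.json", "w") as fh:
        json.dump(bundle.ground_truth, fh, indent=1, sort_keys=True)

    if bundle.eye_frames is not None:
        eye_dir = path / "eye"
        eye_dir.mkdir(exist_ok=True)
        for i, frame in enumerate(bundle.eye_frames):
            iio.imwrite(eye_dir / f"frame_{i:06d}.png", frame)
        truth = bundle.eye_truth
        if truth is not None:
            with open(path / "eye_truth.json", "w") as fh:
                json.dump(
                    {
                        "frame_rate": truth.frame_rate,
                        "open_area": truth.open_area,
                        "true_eccentricity": truth.true_eccentricity,
                        "true_area": truth.true_area.tolist(),
                        "frame_times": truth.frame_times.tolist(),
                        "blink_intent": {str(k): v for k, v in truth.blink_intent.items()},
                        "lightoff_frames": truth.lightoff_frames,
                    },
                    fh, indent=1, sort_keys=True,
                )
    return path


def _require_columns(df: pd.DataFrame, columns: list[str], filename: str) -> None:
    for col in columns:
        if col not in df.columns:
            raise ValueError(f"{filename}: missing required column {col!r}")


def read_session(path: str | Path) -> SessionBundle:
    """Read and validate a session bundle from a directory.

    Raises a ``ValueError`` naming the offending file/column/row for
    schema violations (missing columns, unsorted timestamps).
    """
    path = Path(path)
    for fname in ("trials.csv", "spikes.csv", "light_pulses.csv", "licks.csv"):
        if not (path / fname).exists():
            raise FileNotFoundError(f"session at {path} is missing required file {fname}")

    trials_df = pd.read_csv(path / "trials.csv", float_precision="round_trip")
    _require_columns(trials_df, TRIAL_COLUMNS, "trials.csv")
    us = trials_df["us_onset_s"].to_numpy()
    bad = np.flatnonzero(np.diff(us) <= 0)
    if bad.size:
        raise ValueError(f"trials.csv: non-monotone us_onset_s at row {int(bad[0]) + 1}")
    trials = [
        TrialRecord(
            int(r.trial_index), str(r.odor), str(r.outcome),
            float(r.odor_onset_s), float(r.odor_offset_s),
            float(r.us_onset_s), float(r.iti_before_s),
        )
        for r in trials_df.itertuples()
    ]

    spikes_df = pd.read_csv(path / "spikes.csv", float_precision="round_trip")
    _require_columns(spikes_df, ["unit_id", "time_s"], "spikes.csv")
    units: dict[str, SpikeTrain] = {}
    for uid, grp in spikes_df.groupby("unit_id", sort=True):
        times = grp["time_s"].to_numpy()
        bad = np.flatnonzero(np.diff(times) < 0)
        if bad.size:
            row = grp.index[int(bad[0]) + 1]
            raise ValueError(f"spikes.csv: unsorted spike times for unit {uid} at row {row}")
        units[str(uid)] = SpikeTrain(times, unit_id=str(uid))

    pulses_df = pd.read_csv(path / "light_pulses.csv", float_precision="round_trip")
    _require_columns(pulses_df, ["time_s", "frequency_hz"], "light_pulses.csv")

    gt_path = path / "ground_truth.json"
    ground_truth = json.loads(gt_path.read_text()) if gt_path.exists() else {}
    pulse_duration = float(ground_truth.get("pulse_duration", 0.005))
    protocol = LightProtocol(
        pulses_df["time_s"].to_numpy(),
        pulses_df["frequency_hz"].to_numpy(),
        pulse_duration=pulse_duration,
    )

    licks_df = pd.read_csv(path / "licks.csv", float_precision="round_trip")
    _require_columns(licks_df, ["time_s"], "licks.csv")
    licks = licks_df["time_s"].to_numpy()

    waveform_means: dict[str, tuple[np.ndarray | None, np.ndarray | None]] = {}
    wf_path = path / "waveforms.csv"
    if wf_path.exists():
        wf_df = pd.read_csv(wf_path, float_precision="round_trip")
        _require_columns(wf_df, ["unit_id", "kind", "channel", "sample", "value"], "waveforms.csv")
        for uid, grp in wf_df.groupby("unit_id", sort=True):
            means: dict[str, np.ndarray] = {}
            for kind, kgrp in grp.groupby("kind"):
                n_ch = int(kgrp["channel"].max()) + 1
                n_s = int(kgrp["sample"].max()) + 1
                wf = np.zeros((n_ch, n_s))
                wf[kgrp["channel"].to_numpy(), kgrp["sample"].to_numpy()] = (
                    kgrp["value"].to_numpy()
                )
                means[str(kind)] = wf
            waveform_means[str(uid)] = (means.get("spontaneous"), means.get("evoked"))

    task_name = ground_truth.get("task")
    task = build_task_spec(task_name) if task_name else build_task_spec("mixed_prediction")

    eye_frames = None
    eye_truth = None
    eye_dir = path / "eye"
    if eye_dir.is_dir():
        frame_files = sorted(eye_dir.glob("frame_*.png"))
        if frame_files:
            eye_frames = np.stack([iio.imread(f) for f in frame_files])
        truth_path = path / "eye_truth.json"
        if truth_path.exists():
            raw = json.loads(truth_path.read_text())
            eye_truth = EyeVideoGroundTruth(
                frame_times=np.asarray(raw["frame_times"]),
                true_area=np.asarray(raw["true_area"]),
                open_area=float(raw["open_area"]),
                true_eccentricity=float(raw["true_eccentricity"]),
                blink_intent={int(k): bool(v) for k, v in raw["blink_intent"].items()},
                lightoff_frames=[int(v) for v in raw["lightoff_frames"]],
                frame_rate=float(raw["frame_rate"]),
            )

    return SessionBundle(
        task=task, trials=trials, units=units, protocol=protocol, licks=licks,
        waveform_means=waveform_means, ground_truth=ground_truth,
        seed=int(ground_truth.get("seed", 0)),
        eye_frames=eye_frames, eye_truth=eye_truth,
    )
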