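"""End-to-end validation runs: ground-truth recovery on synthetic sessions.

Each function here regenerates its own inputs with the package's
synthetic module and measures how well the analysis chain recovers the
known ground truth: chi-square reproduction from published census
counts, auROC agreement with the exhaustive pairwise definition,
calibration and power of the spike-latency test, eye-pipeline accuracy,
value/prediction-error parameter recovery in low reward contexts, the
context effect on the inhibition census, and byte-level determinism of
the session/report writers.
"""

from __future__ import annotations

import filecmp
import tempfile
import warnings
from dataclasses import replace
from pathlib import Path

import numpy as np

from .eyeblink import (
    EyeConfig,
    detect_lightoff_frames,
    extract_eye_area,
    measure_eye_trace,
    normalize_and_label_blinks,
    synchronize_frame_times,
)
from .io import simulate_session, write_session
from .optotagging import salt_test
from .pipeline import run_full_analysis, write_report
from .population import (
    classify_cs_value_coding,
    context_contingency_test,
    inhibition_census,
)
from .spike_metrics import AnalysisWindows, auroc, baseline_rate, epoch_response
from .synthetic import (
    AIRPUFF,
    NOTHING,
    WATER,
    NeuronModelParams,
    build_light_protocol,
    build_task_spec,
    generate_trial_sequence,
    sample_neuron_params,
    simulate_dopamine_session,
    simulate_light_tagging,
    synthesize_eye_video,
)

# Census counts reported for the low vs high reward probability tasks:
# neurons inhibited by the air-puff CS relative to baseline (12 of 12 low,
# 11 of 17 high) and, in the late CS window, relative to the nothing CS
# (9 of 12 low i.e. 75%, 6 of 17 high i.e. 35%).
CENSUS_COUNTS_VS_BASELINE = ((12, 12), (11, 17))
CENSUS_COUNTS_LATE_VS_NOTHING = ((6, 17), (9, 12))


def chi_square_reproduction() -> dict[str, float]:
    """Chi-square statistics recomputed from the published census counts."""
    (k1, n1), (k2, n2) = CENSUS_COUNTS_VS_BASELINE
    chi_baseline, p_baseline = context_contingency_test(k1, n1, k2, n2)
    (k1, n1), (k2, n2) = CENSUS_COUNTS_LATE_VS_NOTHING
    chi_late, p_late = context_contingency_test(k1, n1, k2, n2)
    return {
        "chi2_census_vs_baseline": chi_baseline,
        "p_census_vs_baseline": p_baseline,
        "chi2_census_late_vs_nothing": chi_late,
        "p_census_late_vs_nothing": p_late,
    }


def auroc_pairwise_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Exhaustive-pairwise definition: P(a > b) + 0.5 P(a = b)."""
    greater = half = 0.0
    for x in a:
        for y in b:
            if x > y:
                greater += 1.0
            elif x == y:
                half += 0.5
    return (greater + half) / (len(a) * len(b))


def auroc_oracle_agreement(n_cases: int = 200, seed: int = 0) -> dict[str, float]:
    """Exact agreement of the rank-based auROC with the pairwise oracle.

    Random small integer-valued samples (n <= 12 per side) guarantee ties.
    """
    rng = np.random.default_rng(seed)
    exact = 0
    for _ in range(n_cases):
        na, nb = rng.integers(1, 13, size=2)
        a = rng.integers(0, 6, size=na).astype(float)
        b = rng.integers(0, 6, size=nb).astype(float)
        if auroc(a, b) == auroc_pairwise_oracle(a, b):
            exact += 1
    return {"n_cases": n_cases, "n_exact": exact, "fraction_exact": exact / n_cases}


def salt_calibration(
    n_null: int = 200, n_locked: int = 20, seed: int = 0
) -> dict[str, float]:
    """False-positive rate on null units and power on latency-locked units.

    Null units are homogeneous Poisson with no light coupling; locked
    units fire one spike per pulse at 4 +/- 0.5 ms.
    """
    rng = np.random.default_rng(seed)
    protocol = build_light_protocol(trains_per_frequency=5)
    null_ps = []
    for _ in range(n_null):
        unit = simulate_light_tagging(
            NeuronModelParams(baseline_rate=8.0), tagged=False, protocol=protocol, seed=rng
        )
        null_ps.append(salt_test(unit, protocol, seed=rng).p_value)
    locked_ps = []
    all_freq_sure = {f: 1.0 for f in (1, 2, 5, 10, 20, 50)}
    for _ in range(n_locked):
        unit = simulate_light_tagging(
            NeuronModelParams(baseline_rate=8.0), tagged=True, protocol=protocol,
            seed=rng, evoked_prob=all_freq_sure,
        )
        locked_ps.append(salt_test(unit, protocol, seed=rng).p_value)
    null_ps = np.asarray(null_ps)
    return {
        "null_fraction_p_below_05": float((null_ps < 0.05).mean()),
        "n_null_units": n_null,
        "locked_max_p": float(max(locked_ps)),
        "n_locked_units": n_locked,
    }


def eye_pipeline_recovery(seed: int = 0, n_trials: int = 30) -> dict[str, float]:
    """Ground-truth recovery of the eye pipeline on a synthetic video."""
    rng = np.random.default_rng(seed)
    spec = replace(build_task_spec("high_reward_probability"), iti_mean=2.0)
    trials = generate_trial_sequence(spec, n_trials, rng)
    frames, truth = synthesize_eye_video(trials, spec, seed=rng)
    trace = measure_eye_trace(frames)

    valid = trace.valid_mask() & (truth.true_area > 0)
    area_err = np.abs(trace.raw_area[valid] - truth.true_area[valid]) / truth.true_area[valid]

    # speck invariance: a clean ellipse frame vs the same frame plus
    # three sub-threshold specks
    from skimage.draw import disk as draw_disk
    from skimage.draw import ellipse as draw_ellipse

    clean = np.full((120, 160), 250, dtype=np.uint8)
    rr, cc = draw_ellipse(60, 80, 36, 44, shape=clean.shape)
    clean[rr, cc] = 60
    specked = clean.copy()
    for row, col in ((10, 12), (10, 148), (108, 16)):
        sr, sc = draw_disk((row, col), 5, shape=clean.shape)
        specked[sr, sc] = 80
    area_clean, _ = extract_eye_area(clean)
    area_specked, _ = extract_eye_area(specked)

    detected = detect_lightoff_frames(trace.mean_intensity)
    us_times = np.asarray([t.us_onset + 2.0 for t in trials])
    frame_times = synchronize_frame_times(
        np.asarray(detected, dtype=float), us_times[: len(detected)], len(frames)
    )
    idx = np.arange(len(frames))
    interior = (idx >= detected[0]) & (idx <= detected[-1])
    sync_err = np.abs(frame_times - truth.frame_times)[interior].max()

    trace.frame_times = frame_times
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        labels = normalize_and_label_blinks(trace, trials)
    lab = labels.set_index("trial_index")["blink"]
    airpuff_trials = [
        t for t in trials if t.has_odor and spec.odor_outcomes[t.odor][1] > 0
    ]
    matches = sum(
        bool(lab[t.trial_index]) == truth.blink_intent[t.trial_index]
        for t in airpuff_trials
        if t.trial_index in lab.index and lab[t.trial_index] is not None
    )
    return {
        "max_area_relative_error": float(area_err.max()),
        "speck_area_change_px": float(abs(area_specked - area_clean)),
        "blink_label_accuracy": matches / len(airpuff_trials),
        "n_airpuff_trials": len(airpuff_trials),
        "max_frame_time_error_s": float(sync_err),
    }


def vpe_parameter_recovery(
    seed: int = 0, n_neurons: int = 50, n_trials: int = 400
) -> dict[str, float]:
    """Sign/classification recovery for simulated low-context VPE neurons.

    Neurons are split between the two low-reward-context tasks (the
    mixed-prediction and low-reward-probability designs), mirroring how
    the low-context population pools both datasets.
    """
    rng = np.random.default_rng(seed)
    windows = AnalysisWindows()
    mono = water_sign = airpuff_sign = omission_sign = 0
    n_mono = n_water = n_airpuff = n_omission = 0
    tasks = ["mixed_prediction"] * (n_neurons // 2) + ["low_reward_probability"] * (
        n_neurons - n_neurons // 2
    )
    for task in tasks:
        spec = build_task_spec(task)
        trials = generate_trial_sequence(spec, n_trials, rng)
        params = sample_neuron_params(rng, "low")
        spikes = simulate_dopamine_session(params, trials, spec, rng)
        base_aligns = np.asarray(
            [t.odor_onset if t.has_odor else t.us_onset - 2.0 for t in trials]
        )
        base = baseline_rate(spikes, base_aligns, windows.baseline)

        def cs(odor):
            onsets = np.asarray([t.odor_onset for t in trials if t.odor == odor])
            return epoch_response(spikes, onsets, windows.cs, base).subtracted

        cls = classify_cs_value_coding(
            {"A": cs("A"), "B": cs("B"), "C": cs("C")}, order=("A", "B", "C")
        )
        n_mono += 1
        mono += cls.monotonic

        def us(select, window):
            aligns = np.asarray([t.us_onset for t in trials if select(t)])
            if aligns.size < 2:
                return None
            return epoch_response(spikes, aligns, window, base).subtracted

        pw = us(lambda t: t.odor == "A" and t.outcome == WATER, windows.us)
        uw = us(lambda t: not t.has_odor and t.outcome == WATER, windows.us)
        pa = us(lambda t: t.odor == "C" and t.outcome == AIRPUFF, windows.us)
        ua = us(lambda t: not t.has_odor and t.outcome == AIRPUFF, windows.us)
        om = us(lambda t: t.odor == "C" and t.outcome == NOTHING, windows.omission)
        no = us(lambda t: t.odor == "B", windows.omission)
        if pw is not None and uw is not None:
            n_water += 1
            water_sign += uw.mean() > pw.mean()
        if pa is not None and ua is not None:
            n_airpuff += 1
            airpuff_sign += pa.mean() > ua.mean()
        if om is not None and no is not None:
            n_omission += 1
            omission_sign += om.mean() > no.mean()
    return {
        "n_neurons": n_neurons,
        "fraction_monotonic": mono / n_mono,
        "fraction_water_pe_sign": water_sign / n_water,
        "fraction_airpuff_pe_sign": airpuff_sign / n_airpuff,
        "fraction_omission_above_nothing": omission_sign / n_omission,
    }


def context_effect_recovery(
    seed: int = 0, n_per_context: int = 30, n_trials: int = 272
) -> dict[str, float]:
    """Air-puff-CS vs nothing-CS census in low vs high reward contexts.

    In the high reward context the short-latency excitation masks the
    aversive CS value signal, so fewer neurons distinguish the air-puff
    CS from the nothing CS; the chi-square direction should match the
    published low > high contrast.
    """
    rng = np.random.default_rng(seed)
    windows = AnalysisWindows()
    counts = {}
    for task, context in (
        ("low_reward_probability", "low"),
        ("high_reward_probability", "high"),
    ):
        spec = build_task_spec(task)
        airpuff_cs, nothing_cs = [], []
        for _ in range(n_per_context):
            trials = generate_trial_sequence(spec, n_trials, rng)
            params = sample_neuron_params(rng, context)
            spikes = simulate_dopamine_session(params, trials, spec, rng)
            base_aligns = np.asarray(
                [t.odor_onset if t.has_odor else t.us_onset - 2.0 for t in trials]
            )
            base = baseline_rate(spikes, base_aligns, windows.baseline)
            for odor, store in (("C", airpuff_cs), ("B", nothing_cs)):
                onsets = np.asarray([t.odor_onset for t in trials if t.odor == odor])
                store.append(epoch_response(spikes, onsets, windows.cs, base).subtracted)
        census = inhibition_census(airpuff_cs, nothing_cs, criterion="vs_nothing")
        counts[context] = (census.n_flagged, census.n_neurons)
    chi2, p = context_contingency_test(*counts["low"], *counts["high"])
    return {
        "low_context_flagged": counts["low"][0],
        "high_context_flagged": counts["high"][0],
        "n_per_context": n_per_context,
        "chi2": chi2,
        "p": p,
        "direction_low_exceeds_high": float(counts["low"][0] > counts["high"][0]),
    }


def _dirs_identical(a: Path, b: Path) -> bool:
    files_a = sorted(p.relative_to(a) for p in a.rglob("*") if p.is_file())
    files_b = sorted(p.relative_to(b) for p in b.rglob("*") if p.is_file())
    if files_a != files_b:
        return False
    return all(filecmp.cmp(a / f, b / f, shallow=False) for f in files_a)


def determinism_check(seed: int = 0) -> dict[str, float]:
    """Identical seeds must give byte-identical session bundles and reports."""
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        bundles = []
        for name in ("run1", "run2"):
            bundle = simulate_session(
                task="low_reward_probability", n_trials=60, n_tagged=2, n_untagged=1,
                seed=seed, trains_per_frequency=2,
            )
            write_session(bundle, tmp / f"session_{name}")
            report = run_full_analysis(bundle, seed=seed)
            write_report(report, tmp / f"report_{name}")
            bundles.append(bundle)
        sessions_equal = _dirs_identical(tmp / "session_run1", tmp / "session_run2")
        reports_equal = _dirs_identical(tmp / "report_run1", tmp / "report_run2")
    return {
        "sessions_byte_identical": float(sessions_equal),
        "reports_byte_identical": float(reports_equal),
    }
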