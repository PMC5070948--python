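"""Full-session analysis: tagging -> responses -> population statistics.

``run_full_analysis`` sequences, for one session bundle: optogenetic
identification of every unit, trial-aligned epoch responses of the
identified dopamine neurons, monotonic value-coding classification,
prediction-error and omission contrasts, inhibition censuses, and
behavior (blink / lick) splits when the corresponding media are present.
Every statistical test performed is logged with its family, n,
statistic and p-value; Bonferroni-adjusted p-values are added within
each declared family of planned comparisons.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .eyeblink import (
    EyeConfig,
    label_lick_trials,
    measure_eye_trace,
    normalize_and_label_blinks,
    synchronize_frame_times,
)
from .io import SessionBundle
from .optotagging import decide_identification, light_response_profile, salt_test, waveform_correlation
from .population import (
    behavior_split_contrast,
    bonferroni,
    classify_cs_value_coding,
    inhibition_census,
    omission_contrast,
    population_auroc_test,
    prediction_error_contrast,
)
from .spike_metrics import AnalysisWindows, baseline_rate, epoch_response
from .synthetic.tasks import AIRPUFF, NOTHING, WATER, TaskSpec, TrialRecord


@dataclass
class AnalysisReport:
    """Machine-readable result tables for one session."""

    tagging: pd.DataFrame
    cs_responses: pd.DataFrame
    classification: pd.DataFrame
    contrasts: pd.DataFrame
    population: pd.DataFrame
    census: pd.DataFrame
    behavior: pd.DataFrame
    test_log: pd.DataFrame
    summary: dict


def _role_odors(spec: TaskSpec) -> dict[str, str | None]:
    """Map functional roles (reward / nothing / airpuff / mixed CS) to odors."""
    reward = nothing = airpuff = mixed = None
    for odor, (p_w, p_a, p_n) in spec.odor_outcomes.items():
        if p_w > 0 and p_a > 0:
            mixed = odor
        elif p_w > 0:
            reward = odor
        elif p_a > 0:
            airpuff = odor
        elif p_n == 1.0:
            nothing = odor
    return {"reward": reward, "nothing": nothing, "airpuff": airpuff, "mixed": mixed}


def _odor_onsets(trials: list[TrialRecord], odor: str) -> np.ndarray:
    return np.asarray([t.odor_onset for t in trials if t.odor == odor])


def _baseline_aligns(trials: list[TrialRecord]) -> np.ndarray:
    """Baseline alignment times pooled over all trial types.

    No-odor trials use a virtual onset 2 s before the US so every trial
    contributes a pre-stimulus window.
    """
    return np.asarray(
        [t.odor_onset if t.has_odor else t.us_onset - 2.0 for t in trials]
    )


def run_full_analysis(
    bundle: SessionBundle,
    windows: AnalysisWindows | None = None,
    eye_config: EyeConfig | None = None,
    seed: int = 0,
) -> AnalysisReport:
    """Run the complete analysis chain on one session bundle."""
    windows = windows or AnalysisWindows()
    eye_config = eye_config or EyeConfig()
    spec = bundle.task
    trials = bundle.trials
    roles = _role_odors(spec)
    log_rows: list[dict] = []

    def log(family: str, test: str, n: int, statistic: float, p: float) -> None:
        log_rows.append(
            {"family": family, "test": test, "n": n, "statistic": statistic, "p": p}
        )

    # ------------------------------------------------------------------ tagging
    ss = np.random.SeedSequence(seed)
    unit_ids = sorted(bundle.units)
    salt_seeds = dict(zip(unit_ids, ss.spawn(len(unit_ids))))
    tagging_rows = []
    identified: list[str] = []
    for uid in unit_ids:
        spikes = bundle.units[uid]
        result = salt_test(spikes, bundle.protocol, seed=np.random.default_rng(salt_seeds[uid]))
        spont, evoked = bundle.waveform_means.get(uid, (None, None))
        if spont is None or evoked is None:
            wf_r = float("nan")
            decision = False
        else:
            wf_r = waveform_correlation(spont, evoked)
            decision = decide_identification(result.p_value, wf_r).identified
        profile = light_response_profile(spikes, bundle.protocol)
        row = {
            "unit_id": uid,
            "salt_p": result.p_value,
            "waveform_r": wf_r,
            "identified": decision,
            "latency_mean_ms": profile.latency_mean * 1e3,
            "latency_sd_ms": profile.latency_sd * 1e3,
        }
        for freq, prob in sorted(profile.evoked_probability.items()):
            row[f"p_evoked_{freq:g}hz"] = prob
        tagging_rows.append(row)
        log("tagging", "salt", result.n_pulses_used, result.test_statistic, result.p_value)
        if decision:
            identified.append(uid)
    tagging = pd.DataFrame(tagging_rows)

    if not identified:
        warnings.warn("no identified dopamine neurons; analysis sections are empty")

    # -------------------------------------------------- epoch responses per unit
    baselines: dict[str, float] = {}
    cs_resp: dict[str, dict[str, np.ndarray]] = {}
    cs_rows = []
    baseline_aligns = _baseline_aligns(trials)
    for uid in identified:
        spikes = bundle.units[uid]
        base = baseline_rate(spikes, baseline_aligns, windows.baseline)
        baselines[uid] = base
        cs_resp[uid] = {}
        for odor in spec.odors:
            onsets = _odor_onsets(trials, odor)
            if onsets.size == 0:
                continue
            resp = epoch_response(spikes, onsets, windows.cs, base)
            cs_resp[uid][odor] = resp.subtracted
            cs_rows.append(
                {
                    "unit_id": uid, "odor": odor, "n_trials": onsets.size,
                    "baseline_hz": base,
                    "mean_rate_hz": float(resp.rates.mean()),
                    "mean_subtracted_hz": float(resp.subtracted.mean()),
                }
            )
    cs_responses = pd.DataFrame(cs_rows)

    # --------------------------------------------------------- classification
    class_rows = []
    comparison_sets = []
    if roles["reward"] and roles["nothing"] and roles["airpuff"]:
        comparison_sets.append(
            ("reward-nothing-airpuff", (roles["reward"], roles["nothing"], roles["airpuff"]))
        )
    if roles["reward"] and roles["mixed"] and roles["airpuff"]:
        comparison_sets.append(
            ("reward-mixed-airpuff", (roles["reward"], roles["mixed"], roles["airpuff"]))
        )
    for uid in identified:
        for name, keys in comparison_sets:
            if not all(k in cs_resp[uid] and cs_resp[uid][k].size >= 2 for k in keys):
                continue
            cls = classify_cs_value_coding({k: cs_resp[uid][k] for k in keys}, order=keys)
            class_rows.append(
                {
                    "unit_id": uid, "comparison": name,
                    "anova_p": cls.anova_p, "modulated": cls.modulated,
                    "pairwise_p": cls.pairwise_p, "monotonic": cls.monotonic,
                }
            )
            log("classification", f"anova:{name}", sum(cs_resp[uid][k].size for k in keys),
                float("nan"), cls.anova_p)
    classification = pd.DataFrame(class_rows)

    # ------------------------------------------------------------- contrasts
    def us_responses(uid: str, subset: list[TrialRecord], window) -> np.ndarray:
        aligns = np.asarray([t.us_onset for t in subset])
        if aligns.size == 0:
            return np.empty(0)
        return epoch_response(bundle.units[uid], aligns, window, baselines[uid]).subtracted

    # predicted outcomes come from the pure single-outcome predictor odors;
    # the mixed-outcome odor predicts an intermediate value and would
    # confound the prediction-error contrast
    predicted_water = [t for t in trials if t.odor == roles["reward"] and t.outcome == WATER]
    unpredicted_water = [t for t in trials if not t.has_odor and t.outcome == WATER]
    predicted_airpuff = [t for t in trials if t.odor == roles["airpuff"] and t.outcome == AIRPUFF]
    unpredicted_airpuff = [t for t in trials if not t.has_odor and t.outcome == AIRPUFF]
    omission_trials = [
        t for t in trials if t.odor == roles["airpuff"] and t.outcome == NOTHING
    ]
    nothing_trials = [t for t in trials if t.odor == roles["nothing"]]

    contrast_rows = []
    aurocs: dict[str, list[float]] = {"water_pe": [], "airpuff_pe": [], "omission": []}
    for uid in identified:
        specs = [
            ("water_pe", predicted_water, unpredicted_water, windows.us, True),
            ("airpuff_pe", predicted_airpuff, unpredicted_airpuff, windows.us, True),
            ("omission", omission_trials, nothing_trials, windows.omission, False),
        ]
        for name, group_a, group_b, window, is_pe in specs:
            if len(group_a) < 2 or len(group_b) < 2:
                continue
            ra = us_responses(uid, group_a, window)
            rb = us_responses(uid, group_b, window)
            if is_pe:
                res = prediction_error_contrast(predicted=ra, unpredicted=rb)
            else:
                res = omission_contrast(omission_trials=ra, nothing_trials=rb)
            aurocs[name].append(res.auroc)
            contrast_rows.append(
                {
                    "unit_id": uid, "contrast": name,
                    "mean_difference_hz": res.mean_difference, "auroc": res.auroc,
                    "test": res.test_name, "statistic": res.statistic, "p": res.p_value,
                    "n_a": res.n_a, "n_b": res.n_b,
                }
            )
            log(f"contrast:{name}", res.test_name, res.n_a + res.n_b,
                res.statistic, res.p_value)
    contrasts = pd.DataFrame(contrast_rows)

    pop_rows = []
    family_ps = []
    for name in ("water_pe", "airpuff_pe", "omission"):
        vals = np.asarray(aurocs[name])
        if vals.size < 2:
            continue
        mean_auroc, t_stat, p = population_auroc_test(vals)
        pop_rows.append(
            {
                "contrast": name, "n_neurons": vals.size,
                "mean_auroc": mean_auroc, "t": t_stat, "p": p,
            }
        )
        family_ps.append(p)
        log("population_auroc", "one-sample t vs 0.5", vals.size, t_stat, p)
    population = pd.DataFrame(pop_rows)
    if not population.empty:
        population["p_bonferroni"] = bonferroni(family_ps)

    # ---------------------------------------------------------------- census
    census_rows = []
    if identified and roles["airpuff"]:
        airpuff_cs = [cs_resp[uid].get(roles["airpuff"], np.empty(0)) for uid in identified]
        res = inhibition_census(airpuff_cs, criterion="vs_baseline")
        census_rows.append(
            {"criterion": "vs_baseline", "n_neurons": res.n_neurons, "n_flagged": res.n_flagged}
        )
        if roles["nothing"]:
            nothing_cs = [cs_resp[uid].get(roles["nothing"], np.empty(0)) for uid in identified]
            res = inhibition_census(airpuff_cs, nothing_cs, criterion="vs_nothing")
            census_rows.append(
                {"criterion": "vs_nothing", "n_neurons": res.n_neurons, "n_flagged": res.n_flagged}
            )
    census = pd.DataFrame(census_rows)

    # -------------------------------------------------------------- behavior
    behavior_rows = []
    blink_labels = None
    if bundle.eye_frames is not None and identified:
        trace = measure_eye_trace(bundle.eye_frames, eye_config)
        us_times = np.asarray([t.us_onset + 2.0 for t in trials])
        event_frames = np.asarray(trace.lightoff_frames, dtype=float)
        anchors = us_times[: len(event_frames)]
        if 2 <= len(event_frames) <= len(us_times):
            trace.frame_times = synchronize_frame_times(
                event_frames, anchors, len(trace.raw_area)
            )
            blink_labels = normalize_and_label_blinks(trace, trials, eye_config)

    if blink_labels is not None and roles["airpuff"]:
        split = _behavior_split(
            bundle, identified, trials, roles["airpuff"], blink_labels,
            label_col="blink", windows=windows, baselines=baselines,
        )
        if split is not None:
            behavior_rows.append(split | {"split": "blink"})
            log("behavior:blink", split["test"], split["n_neurons"],
                split["statistic"], split["p"])

    if identified and roles["reward"] and len(bundle.licks):
        lick_labels = label_lick_trials(bundle.licks, trials, eye_config)
        split = _behavior_split(
            bundle, identified, trials, roles["reward"], lick_labels,
            label_col="lick", windows=windows, baselines=baselines,
        )
        if split is not None:
            behavior_rows.append(split | {"split": "lick"})
            log("behavior:lick", split["test"], split["n_neurons"],
                split["statistic"], split["p"])
    behavior = pd.DataFrame(behavior_rows)

    test_log = pd.DataFrame(log_rows)
    summary = {
        "n_units": len(unit_ids),
        "n_identified": len(identified),
        "identified": identified,
        "n_trials": len(trials),
        "task": spec.name,
    }
    return AnalysisReport(
        tagging=tagging, cs_responses=cs_responses, classification=classification,
        contrasts=contrasts, population=population, census=census,
        behavior=behavior, test_log=test_log, summary=summary,
    )


def _behavior_split(
    bundle: SessionBundle,
    identified: list[str],
    trials: list[TrialRecord],
    odor: str,
    labels: pd.DataFrame,
    label_col: str,
    windows: AnalysisWindows,
    baselines: dict[str, float],
) -> dict | None:
    """Per-neuron CS responses on ``odor`` trials split by a behavior label."""
    lab = labels.set_index("trial_index")[label_col]
    subset = [
        t for t in trials
        if t.odor == odor and t.trial_index in lab.index and lab[t.trial_index] is not None
        and not (isinstance(lab[t.trial_index], float) and np.isnan(lab[t.trial_index]))
    ]
    if len(subset) < 4:
        return None
    onsets = np.asarray([t.odor_onset for t in subset])
    trial_labels = np.asarray([bool(lab[t.trial_index]) for t in subset])
    responses = []
    for uid in identified:
        resp = epoch_response(bundle.units[uid], onsets, windows.cs, baselines[uid])
        responses.append(resp.subtracted)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = behavior_split_contrast(
                responses, [trial_labels] * len(responses)
            )
    except ValueError:
        return None
    return {
        "n_neurons": result.n_neurons,
        "mean_true": float(result.means_true.mean()),
        "mean_false": float(result.means_false.mean()),
        "test": result.paired.test_name,
        "statistic": result.paired.statistic,
        "p": result.paired.p_value,
        "one_sample_p_true": result.one_sample_true[1],
        "one_sample_p_false": result.one_sample_false[1],
    }


def write_report(report: AnalysisReport, path: str | Path) -> Path:
    """Write the report tables to a directory (deterministic byte output)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name in ("tagging", "cs_responses", "classification", "contrasts",
                 "population", "census", "behavior", "test_log"):
        getattr(report, name).to_csv(path / f"{name}.csv", index=False)
    with open(path / "summary.json", "w") as fh:
        json.dump(report.summary, fh, indent=1, sort_keys=True)
    return path
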