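"""Task presets, trial sequences, and integrated CS value."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.stats import chisquare

from vtapipe.synthetic import (
    TASK_PRESETS,
    TaskSpec,
    build_task_spec,
    cs_value,
    generate_trial_sequence,
)


@pytest.mark.parametrize(
    "task, odor, probs",
    [
        ("mixed_prediction", "A", (0.25, 0.0, 0.75)),
        ("mixed_prediction", "B", (0.0, 0.0, 1.0)),
        ("mixed_prediction", "C", (0.0, 0.75, 0.25)),
        ("mixed_prediction", "D", (0.25, 0.75, 0.0)),
        ("low_reward_probability", "A", (0.20, 0.0, 0.80)),
        ("low_reward_probability", "C", (0.0, 0.90, 0.10)),
        ("high_reward_probability", "A", (0.90, 0.0, 0.10)),
        ("high_reward_probability_2", "C", (0.0, 0.80, 0.20)),
    ],
)
def test_preset_outcome_probabilities(task, odor, probs):
    spec = build_task_spec(task)
    assert spec.odor_outcomes[odor] == pytest.approx(probs)


def test_preset_free_outcome_fractions():
    for spec in TASK_PRESETS.values():
        assert spec.no_odor_fraction == pytest.approx(
            spec.free_reward_fraction + spec.free_airpuff_fraction
        )
        assert math.isclose(sum(spec.trial_type_fractions().values()), 1.0)


def test_unknown_task_rejected():
    with pytest.raises(ValueError, match="unknown task"):
        build_task_spec("foo")


def test_invalid_task_spec_rejected():
    with pytest.raises(ValueError, match="sum to 1"):
        TaskSpec(
            name="bad", odor_outcomes={"A": (0.5, 0.2, 0.2)},
            no_odor_fraction=0.0, free_reward_fraction=0.0, free_airpuff_fraction=0.0,
        )


@pytest.mark.parametrize(
    "task, odor, v_w, v_a, expected",
    [
        ("mixed_prediction", "B", 1.0, -0.3, 0.0),
        ("mixed_prediction", "D", 1.0, -0.3, 0.025),
        ("mixed_prediction", "C", 1.0, -0.3, -0.225),
        ("low_reward_probability", "A", 1.0, -0.3, 0.2),
    ],
)
def test_cs_value_integrates_both_valences(task, odor, v_w, v_a, expected):
    spec = build_task_spec(task)
    assert cs_value(spec, odor, v_w, v_a) == pytest.approx(expected)


def test_cs_value_unknown_odor():
    spec = build_task_spec("low_reward_probability")
    with pytest.raises(ValueError, match="odor"):
        cs_value(spec, "D", 1.0, -0.3)


def test_empty_sequence():
    assert generate_trial_sequence(build_task_spec("mixed_prediction"), 0, seed=0) == []


def test_trial_type_frequencies_match_design():
    """Empirical trial-type rates converge to the design fractions."""
    spec = build_task_spec("mixed_prediction")
    n = 10_000
    trials = generate_trial_sequence(spec, n, seed=42)
    fractions = spec.trial_type_fractions()
    counts = {}
    for t in trials:
        key = t.odor if t.has_odor else f"free_{t.outcome}"
        counts[key] = counts.get(key, 0) + 1
    labels = list(fractions)
    observed = np.asarray([counts.get(k, 0) for k in labels], dtype=float)
    expected = np.asarray([fractions[k] * n for k in labels])
    for obs, exp, frac in zip(observed, expected, fractions.values()):
        se = math.sqrt(n * frac * (1 - frac))
        assert abs(obs - exp) <= 3 * se
    assert chisquare(observed, expected).pvalue > 0.01


def test_outcomes_follow_per_odor_probabilities():
    spec = build_task_spec("mixed_prediction")
    trials = generate_trial_sequence(spec, 10_000, seed=7)
    d_trials = [t for t in trials if t.odor == "D"]
    p_water = np.mean([t.outcome == "water" for t in d_trials])
    se = math.sqrt(0.25 * 0.75 / len(d_trials))
    assert abs(p_water - 0.25) <= 3 * se


def test_iti_truncation_and_monotone_timestamps():
    spec = dataclasses.replace(build_task_spec("mixed_prediction"), iti_mean=8.0)
    trials = generate_trial_sequence(spec, 2000, seed=3)
    itis = np.asarray([t.iti_before for t in trials])
    assert itis.max() <= 15.0
    us = np.asarray([t.us_onset for t in trials])
    assert np.all(np.diff(us) > 0)


def test_trial_timing_invariants():
    spec = build_task_spec("mixed_prediction")
    for t in generate_trial_sequence(spec, 200, seed=1):
        if t.has_odor:
            assert t.odor_offset - t.odor_onset == pytest.approx(spec.odor_duration)
            assert t.us_onset - t.odor_onset == pytest.approx(
                spec.odor_duration + spec.delay_duration
            )


def test_sequence_reproducible_given_seed():
    spec = build_task_spec("low_reward_probability")
    a = generate_trial_sequence(spec, 300, seed=9)
    b = generate_trial_sequence(spec, 300, seed=9)
    assert a == b
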