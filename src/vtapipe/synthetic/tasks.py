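"""Odor-conditioning task designs and trial-sequence generation.

A session is a sequence of trials.  On most trials a 1-s odor (the
conditioned stimulus, CS) is followed by a 1-s delay and an outcome
(the unconditioned stimulus, US): a drop of water, an air puff to the
eye, or nothing.  A small fraction of trials carry no odor and deliver
a free (unpredicted) water or air-puff outcome.  Inter-trial intervals
are exponential with a hard truncation so that the hazard of the next
trial start is flat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

ODOR_NONE = "none"
WATER = "water"
AIRPUFF = "airpuff"
NOTHING = "nothing"
OUTCOMES = (WATER, AIRPUFF, NOTHING)

#: trial-type labels for the two kinds of uncued (free-outcome) trials
FREE_WATER = "free_water"
FREE_AIRPUFF = "free_airpuff"


@dataclass(frozen=True)
class TaskSpec:
    """One task condition: per-odor outcome probabilities and timing.

    ``odor_outcomes`` maps an odor label to ``(P(water), P(airpuff),
    P(nothing))``.  ``no_odor_fraction`` is the fraction of all trials
    with no CS; those trials deliver a free water or free air-puff
    outcome (the two sub-fractions must add up to ``no_odor_fraction``).
    Remaining trials are split equally among the listed odors.
    """

    name: str
    odor_outcomes: dict[str, tuple[float, float, float]]
    no_odor_fraction: float
    free_reward_fraction: float
    free_airpuff_fraction: float
    odor_duration: float = 1.0
    delay_duration: float = 1.0
    iti_mean: float = 3.0
    iti_truncation: float = 15.0

    def __post_init__(self) -> None:
        if not self.odor_outcomes:
            raise ValueError("task needs at least one odor")
        for odor, probs in self.odor_outcomes.items():
            if len(probs) != 3:
                raise ValueError(f"odor {odor!r}: need (P(water), P(airpuff), P(nothing))")
            if any(p < 0 or p > 1 for p in probs):
                raise ValueError(f"odor {odor!r}: probabilities must lie in [0, 1]")
            if not math.isclose(sum(probs), 1.0, abs_tol=1e-9):
                raise ValueError(f"odor {odor!r}: outcome probabilities must sum to 1")
        for name in ("no_odor_fraction", "free_reward_fraction", "free_airpuff_fraction"):
            v = getattr(self, name)
            if v < 0 or v > 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not math.isclose(
            self.no_odor_fraction,
            self.free_reward_fraction + self.free_airpuff_fraction,
            abs_tol=1e-9,
        ):
            raise ValueError("no_odor_fraction must equal free_reward + free_airpuff fraction")
        if self.odor_duration <= 0 or self.delay_duration <= 0:
            raise ValueError("odor and delay durations must be positive")
        if self.iti_mean <= 0 or self.iti_truncation <= 0:
            raise ValueError("ITI parameters must be positive")

    @property
    def odors(self) -> tuple[str, ...]:
        return tuple(self.odor_outcomes)

    def trial_type_fractions(self) -> dict[str, float]:
        """Fraction of trials of each type (odors split the CS mass equally)."""
        cs_fraction = 1.0 - self.no_odor_fraction
        per_odor = cs_fraction / len(self.odor_outcomes)
        fractions = {odor: per_odor for odor in self.odor_outcomes}
        fractions[FREE_WATER] = self.free_reward_fraction
        fractions[FREE_AIRPUFF] = self.free_airpuff_fraction
        return fractions


# Task presets.  Outcome probability columns are (water, airpuff, nothing);
# no-odor trial fractions are 4% (mixed), 12% (high/low reward probability)
# and 13% (high reward probability 2), split into free water per the task
# summary's free-reward column, remainder free air puff.
TASK_PRESETS: dict[str, TaskSpec] = {
    "mixed_prediction": TaskSpec(
        name="mixed_prediction",
        odor_outcomes={
            "A": (0.25, 0.0, 0.75),
            "B": (0.0, 0.0, 1.0),
            "C": (0.0, 0.75, 0.25),
            "D": (0.25, 0.75, 0.0),
        },
        no_odor_fraction=0.04,
        free_reward_fraction=0.02,
        free_airpuff_fraction=0.02,
    ),
    "low_reward_probability": TaskSpec(
        name="low_reward_probability",
        odor_outcomes={
            "A": (0.20, 0.0, 0.80),
            "B": (0.0, 0.0, 1.0),
            "C": (0.0, 0.90, 0.10),
        },
        no_odor_fraction=0.12,
        free_reward_fraction=0.06,
        free_airpuff_fraction=0.06,
    ),
    "high_reward_probability": TaskSpec(
        name="high_reward_probability",
        odor_outcomes={
            "A": (0.90, 0.0, 0.10),
            "B": (0.0, 0.0, 1.0),
            "C": (0.0, 0.90, 0.10),
        },
        no_odor_fraction=0.12,
        free_reward_fraction=0.06,
        free_airpuff_fraction=0.06,
    ),
    "high_reward_probability_2": TaskSpec(
        name="high_reward_probability_2",
        odor_outcomes={
            "A": (0.90, 0.0, 0.10),
            "B": (0.0, 0.0, 1.0),
            "C": (0.0, 0.80, 0.20),
        },
        no_odor_fraction=0.13,
        free_reward_fraction=0.07,
        free_airpuff_fraction=0.06,
    ),
}

#: tasks whose session-wide reward frequency is low; the short-latency
#: context excitation is absent there and present in high reward contexts
LOW_REWARD_CONTEXT = ("mixed_prediction", "low_reward_probability")
HIGH_REWARD_CONTEXT = ("high_reward_probability", "high_reward_probability_2")


def build_task_spec(name: str) -> TaskSpec:
    """Return the preset task condition with the given name."""
    try:
        return TASK_PRESETS[name]
    except KeyError:
        known = ", ".join(sorted(TASK_PRESETS))
        raise ValueError(f"unknown task {name!r}; known tasks: {known}") from None


def cs_value(spec: TaskSpec, odor: str, water_value: float, airpuff_value: float) -> float:
    """Integrated value predicted by an odor: P(water)*v_w + P(airpuff)*v_a.

    Reward and aversion are combined on a single value axis; an odor
    predicting nothing has value 0.
    """
    if odor not in spec.odor_outcomes:
        raise ValueError(f"odor {odor!r} is not part of task {spec.name!r}")
    p_water, p_airpuff, _ = spec.odor_outcomes[odor]
    return p_water * water_value + p_airpuff * airpuff_value


@dataclass(frozen=True)
class TrialRecord:
    """One trial: odor label, realized outcome, and event timestamps (s).

    For no-odor (free outcome) trials ``odor`` is ``"none"`` and the odor
    timestamps are NaN; the outcome is still delivered at ``us_onset``.
    """

    trial_index: int
    odor: str
    outcome: str
    odor_onset: float
    odor_offset: float
    us_onset: float
    iti_before: float

    @property
    def has_odor(self) -> bool:
        return self.odor != ODOR_NONE


def _draw_truncated_iti(rng: np.random.Generator, mean: float, truncation: float) -> float:
    """Exponential ITI, redrawn while above the truncation (flat hazard below it)."""
    while True:
        iti = rng.exponential(mean)
        if iti <= truncation:
            return iti


def generate_trial_sequence(
    spec: TaskSpec,
    n_trials: int,
    seed: int | np.random.Generator = 0,
    post_outcome: float = 1.0,
) -> list[TrialRecord]:
    """Draw a pseudorandomly interleaved trial sequence for one session.

    Trial types are sampled i.i.d. from the task's trial-type fractions,
    outcomes from the per-odor outcome probabilities, and inter-trial
    intervals from the truncated exponential.  ``post_outcome`` is the
    time reserved after each US before the next ITI starts.
    """
    if n_trials < 0:
        raise ValueError("n_trials must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fractions = spec.trial_type_fractions()
    labels = list(fractions)
    probs = np.asarray([fractions[k] for k in labels], dtype=float)
    probs = probs / probs.sum()
    types = rng.choice(len(labels), size=n_trials, p=probs)

    trials: list[TrialRecord] = []
    t = 0.0
    for i, ty in enumerate(types):
        label = labels[ty]
        iti = _draw_truncated_iti(rng, spec.iti_mean, spec.iti_truncation)
        if label == FREE_WATER or label == FREE_AIRPUFF:
            us_onset = t + iti
            outcome = WATER if label == FREE_WATER else AIRPUFF
            trials.append(
                TrialRecord(i, ODOR_NONE, outcome, math.nan, math.nan, us_onset, iti)
            )
            t = us_onset + post_outcome
        else:
            odor_onset = t + iti
            odor_offset = odor_onset + spec.odor_duration
            us_onset = odor_onset + spec.odor_duration + spec.delay_duration
            outcome = rng.choice(OUTCOMES, p=np.asarray(spec.odor_outcomes[label]))
            trials.append(
                TrialRecord(i, label, str(outcome), odor_onset, odor_offset, us_onset, iti)
            )
            t = us_onset + post_outcome
    return trials


def session_end_time(trials: list[TrialRecord], pad: float = 3.0) -> float:
    """End of the behavioral recording: last US plus a pad."""
    if not trials:
        return 0.0
    return max(tr.us_onset for tr in trials) + pad
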