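"""Spike-train simulation for value-coding dopamine neurons.

The model is a steady-state inhomogeneous Poisson process.  Around each
trial the instantaneous rate is the tonic baseline plus three boxcar
contributions:

* a context-dependent short-latency excitation at CS onset (present in
  high reward contexts, absent in low ones),
* a CS value term proportional to the integrated value predicted by the
  odor (reward and aversion on one axis),
* a US prediction-error term proportional to the realized outcome value
  minus the predicted value, so that predicted outcomes evoke smaller
  responses than unpredicted ones and omission of a predicted outcome
  flips the response sign.

Negative contributions suppress the rate, floored at zero.  In high
reward contexts the short-latency excitation also masks (attenuates) the
negative-value CS term: the excitation observed in the data is not a
constant added on top of intact value coding, it degrades the value
signal for aversive cues.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .tasks import AIRPUFF, NOTHING, WATER, TaskSpec, TrialRecord, cs_value, session_end_time


@dataclass(frozen=True)
class Kernel:
    """A boxcar response kernel: unit height over [onset, onset+duration)."""

    onset: float
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("kernel duration must be positive")
        if self.onset < 0:
            raise ValueError("kernel onset must be >= 0")


@dataclass(frozen=True)
class NeuronModelParams:
    """Parameters of one simulated dopamine neuron.

    ``value_gain`` converts value units into firing rate (Hz per unit
    value).  ``water_value``/``airpuff_value`` set the outcome values on
    the common axis; the air puff is mildly aversive so its magnitude is
    far below the water value.  ``context_excitation`` is the amplitude
    (Hz) of the short-latency CS excitation (0 in low reward contexts)
    and ``aversive_cs_masking`` in [0, 1] is the fraction of the
    negative-value CS term it masks.
    """

    baseline_rate: float = 6.0
    value_gain: float = 40.0
    water_value: float = 1.0
    airpuff_value: float = -0.125
    context_excitation: float = 0.0
    aversive_cs_masking: float = 0.0
    omission_gain: float = 1.0
    early_kernel: Kernel = field(default_factory=lambda: Kernel(0.0, 0.15))
    cs_kernel: Kernel = field(default_factory=lambda: Kernel(0.05, 0.35))
    us_kernel: Kernel = field(default_factory=lambda: Kernel(0.0, 0.30))
    rate_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be > 0")
        if self.water_value <= 0:
            raise ValueError("water_value must be > 0")
        if self.airpuff_value >= 0:
            raise ValueError("airpuff_value must be < 0")
        if not 0.0 <= self.aversive_cs_masking <= 1.0:
            raise ValueError("aversive_cs_masking must lie in [0, 1]")
        if self.rate_floor < 0:
            raise ValueError("rate_floor must be >= 0")

    def outcome_value(self, outcome: str) -> float:
        if outcome == WATER:
            return self.water_value
        if outcome == AIRPUFF:
            return self.airpuff_value
        if outcome == NOTHING:
            return 0.0
        raise ValueError(f"unknown outcome {outcome!r}")


#: high-reward-context defaults for the two context parameters
CONTEXT_EXCITATION_HIGH = 8.0
AVERSIVE_CS_MASKING_HIGH = 0.8


def params_for_context(context: str, **overrides) -> NeuronModelParams:
    """Default neuron parameters for a ``"low"`` or ``"high"`` reward context."""
    if context == "low":
        base = NeuronModelParams()
    elif context == "high":
        base = NeuronModelParams(
            context_excitation=CONTEXT_EXCITATION_HIGH,
            aversive_cs_masking=AVERSIVE_CS_MASKING_HIGH,
        )
    else:
        raise ValueError("context must be 'low' or 'high'")
    return replace(base, **overrides) if overrides else base


def sample_neuron_params(
    rng: np.random.Generator, context: str = "low"
) -> NeuronModelParams:
    """Draw per-neuron parameter variability around the context defaults.

    Baseline rates span the tonic range typical of dopamine neurons and
    the value gain varies so that response functions are scaled versions
    of one another across neurons.
    """
    base = params_for_context(context)
    return replace(
        base,
        baseline_rate=float(rng.uniform(5.0, 8.0)),
        value_gain=float(base.value_gain * rng.uniform(0.8, 1.2)),
    )


@dataclass
class SpikeTrain:
    """Spike timestamps (s) of one unit, optionally with waveform snippets.

    ``waveforms`` has shape (n_spikes, n_channels, n_samples) aligned
    with ``times``.
    """

    times: np.ndarray
    unit_id: str = ""
    waveforms: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("spike times must be a 1-D array")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("spike times must be sorted ascending")
        if self.waveforms is not None and len(self.waveforms) != len(self.times):
            raise ValueError("one waveform snippet per spike required")

    def __len__(self) -> int:
        return len(self.times)


def _sample_piecewise_poisson(
    breaks: np.ndarray, rates: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Sample an inhomogeneous Poisson process with piecewise-constant rate."""
    times = []
    for lo, hi, rate in zip(breaks[:-1], breaks[1:], rates):
        if rate <= 0 or hi <= lo:
            continue
        n = rng.poisson(rate * (hi - lo))
        if n:
            times.append(rng.uniform(lo, hi, size=n))
    if not times:
        return np.empty(0)
    return np.sort(np.concatenate(times))


def _trial_boxes(
    params: NeuronModelParams, trial: TrialRecord, spec: TaskSpec
) -> list[tuple[float, float, float]]:
    """(start, stop, rate delta) boxes contributed by one trial."""
    boxes: list[tuple[float, float, float]] = []
    if trial.has_odor:
        value = cs_value(spec, trial.odor, params.water_value, params.airpuff_value)
        if params.context_excitation != 0.0:
            k = params.early_kernel
            boxes.append(
                (trial.odor_onset + k.onset,
                 trial.odor_onset + k.onset + k.duration,
                 params.context_excitation)
            )
        effective = value if value >= 0 else value * (1.0 - params.aversive_cs_masking)
        if effective != 0.0:
            k = params.cs_kernel
            boxes.append(
                (trial.odor_onset + k.onset,
                 trial.odor_onset + k.onset + k.duration,
                 params.value_gain * effective)
            )
    else:
        value = 0.0
    prediction_error = params.outcome_value(trial.outcome) - value
    if trial.outcome == NOTHING and value != 0.0:
        prediction_error *= params.omission_gain
    if prediction_error != 0.0:
        k = params.us_kernel
        boxes.append(
            (trial.us_onset + k.onset,
             trial.us_onset + k.onset + k.duration,
             params.value_gain * prediction_error)
        )
    return boxes


def simulate_dopamine_session(
    params: NeuronModelParams,
    trials: list[TrialRecord],
    spec: TaskSpec,
    seed: int | np.random.Generator = 0,
    t_start: float = 0.0,
    t_end: float | None = None,
    unit_id: str = "",
) -> SpikeTrain:
    """Simulate one unit's spikes over a session of trials.

    The rate is assembled as a piecewise-constant function (baseline plus
    trial boxes, floored at ``rate_floor``) and sampled exactly segment by
    segment, so the result is reproducible given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if t_end is None:
        t_end = session_end_time(trials)
    if t_end < t_start:
        raise ValueError("t_end must be >= t_start")

    deltas: list[tuple[float, float]] = []
    for trial in trials:
        for lo, hi, amp in _trial_boxes(params, trial, spec):
            deltas.append((lo, amp))
            deltas.append((hi, -amp))
    edges = np.unique(
        np.concatenate([[t_start, t_end], [t for t, _ in deltas]])
    ) if deltas else np.asarray([t_start, t_end], dtype=float)
    edges = edges[(edges >= t_start) & (edges <= t_end)]
    if edges[0] != t_start:
        edges = np.concatenate([[t_start], edges])
    if edges[-1] != t_end:
        edges = np.concatenate([edges, [t_end]])

    rates = np.full(len(edges) - 1, params.baseline_rate)
    # a box [lo, hi) covers the segments whose left edge falls inside it
    for trial in trials:
        for lo, hi, amp in _trial_boxes(params, trial, spec):
            mask = (edges[:-1] >= lo - 1e-12) & (edges[:-1] < hi - 1e-12)
            rates[mask] += amp
    rates = np.maximum(rates, params.rate_floor)
    return SpikeTrain(_sample_piecewise_poisson(edges, rates, rng), unit_id=unit_id)


# ---------------------------------------------------------------------------
# optogenetic tagging simulation
# ---------------------------------------------------------------------------

DEFAULT_FREQUENCIES = (1, 2, 5, 10, 20, 50)

#: probability that a light pulse evokes a spike, by stimulation frequency;
#: non-increasing with frequency (channelrhodopsin spike fidelity drops at
#: high stimulation rates)
DEFAULT_EVOKED_PROB = {1: 0.95, 2: 0.92, 5: 0.85, 10: 0.75, 20: 0.55, 50: 0.35}


@dataclass(frozen=True)
class LightProtocol:
    """Light-pulse stimulation protocol: trains of brief pulses.

    ``pulse_onsets`` and ``pulse_frequencies`` are aligned per-pulse
    arrays (onset time in s, train frequency label in Hz).
    """

    pulse_onsets: np.ndarray
    pulse_frequencies: np.ndarray
    pulse_duration: float = 0.005
    pulses_per_train: int = 10

    def __post_init__(self) -> None:
        onsets = np.asarray(self.pulse_onsets, dtype=float)
        freqs = np.asarray(self.pulse_frequencies, dtype=float)
        object.__setattr__(self, "pulse_onsets", onsets)
        object.__setattr__(self, "pulse_frequencies", freqs)
        if onsets.shape != freqs.shape:
            raise ValueError("one frequency label per pulse required")
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("pulse onsets must be strictly increasing")
        if self.pulse_duration <= 0:
            raise ValueError("pulse_duration must be positive")

    @property
    def frequencies(self) -> np.ndarray:
        return np.unique(self.pulse_frequencies)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.pulse_onsets[0]), float(self.pulse_onsets[-1])


def build_light_protocol(
    frequencies: tuple[int, ...] = DEFAULT_FREQUENCIES,
    trains_per_frequency: int = 5,
    pulses_per_train: int = 10,
    pulse_duration: float = 0.005,
    inter_train_interval: float = 3.0,
    start: float = 0.0,
) -> LightProtocol:
    """Build trains of ``pulses_per_train`` pulses at each frequency.

    Within a train the inter-pulse interval is 1/frequency; trains are
    separated by ``inter_train_interval`` of darkness.
    """
    onsets: list[float] = []
    labels: list[float] = []
    t = start
    for freq in frequencies:
        period = 1.0 / freq
        for _ in range(trains_per_frequency):
            train = t + np.arange(pulses_per_train) * period
            onsets.extend(train)
            labels.extend([freq] * pulses_per_train)
            t = train[-1] + period + inter_train_interval
    return LightProtocol(
        np.asarray(onsets), np.asarray(labels),
        pulse_duration=pulse_duration, pulses_per_train=pulses_per_train,
    )


def make_waveform_template(
    rng: np.random.Generator, n_channels: int = 4, n_samples: int = 32
) -> np.ndarray:
    """A smooth biphasic extracellular waveform with per-channel amplitudes."""
    t = np.linspace(-1.5, 3.0, n_samples)
    shape = -np.exp(-(t ** 2)) + 0.45 * np.exp(-((t - 1.4) ** 2) / 1.2)
    amplitudes = rng.uniform(0.3, 1.0, size=n_channels)
    return amplitudes[:, None] * shape[None, :]


def _light_artifact(n_channels: int, n_samples: int) -> np.ndarray:
    """A photoelectric-artifact transient contaminating evoked snippets."""
    t = np.arange(n_samples, dtype=float)
    artifact = 3.0 * np.exp(-t / 3.0)
    return np.tile(artifact, (n_channels, 1))


def simulate_light_tagging(
    params: NeuronModelParams,
    tagged: bool,
    protocol: LightProtocol,
    seed: int | np.random.Generator = 0,
    evoked_prob: dict[int, float] | None = None,
    latency_mean: float = 0.004,
    latency_sd: float = 0.0005,
    light_artifact: bool = False,
    pad: float = 3.0,
    unit_id: str = "",
) -> SpikeTrain:
    """Simulate a unit's spikes during the light-stimulation block.

    Tagged units fire at most one evoked spike per pulse with a
    frequency-dependent probability and a truncated-Gaussian latency, on
    top of their baseline Poisson firing.  Untagged units only fire at
    baseline.  Every spike carries a waveform snippet drawn from the
    unit's template; with ``light_artifact`` the evoked snippets are
    contaminated by a stimulation transient (for negative controls).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = dict(DEFAULT_EVOKED_PROB if evoked_prob is None else evoked_prob)
    t0, t1 = protocol.span
    t0, t1 = t0 - pad, t1 + pad

    baseline = _sample_piecewise_poisson(
        np.asarray([t0, t1]), np.asarray([params.baseline_rate]), rng
    )
    evoked = np.empty(0)
    if tagged:
        p = np.asarray([probs.get(int(f), min(probs.values())) for f in protocol.pulse_frequencies])
        fires = rng.random(len(p)) < p
        if latency_sd > 0:
            lat = rng.normal(latency_mean, latency_sd, size=int(fires.sum()))
            while np.any(lat < 0):  # truncate at zero
                bad = lat < 0
                lat[bad] = rng.normal(latency_mean, latency_sd, size=int(bad.sum()))
        else:
            lat = np.full(int(fires.sum()), latency_mean)
        evoked = protocol.pulse_onsets[fires] + lat

    times = np.sort(np.concatenate([baseline, evoked]))
    is_evoked = np.isin(times, evoked)

    template = make_waveform_template(rng)
    n_ch, n_s = template.shape
    waveforms = (
        template[None, :, :]
        * (1.0 + 0.05 * rng.standard_normal(len(times)))[:, None, None]
        + 0.02 * rng.standard_normal((len(times), n_ch, n_s))
    )
    if light_artifact:
        waveforms[is_evoked] += _light_artifact(n_ch, n_s)[None, :, :]
    return SpikeTrain(times, unit_id=unit_id, waveforms=waveforms)


# ---------------------------------------------------------------------------
# licking behavior
# ---------------------------------------------------------------------------

def simulate_licks(
    trials: list[TrialRecord],
    spec: TaskSpec,
    seed: int | np.random.Generator = 0,
    anticipatory_rate: float = 8.0,
    baseline_rate: float = 0.2,
    consummatory_rate: float = 8.0,
    anticipation_prob_high: float = 0.98,
    anticipation_prob_low: float = 0.7,
) -> np.ndarray:
    """Lick timestamps: anticipatory licking in the delay of reward trials
    plus consummatory licking after water delivery.

    Odors with high reward probability (>= 0.5) elicit anticipatory
    licking on nearly every trial; low-probability reward odors on a
    smaller fraction of trials.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_end = session_end_time(trials)
    licks = [_sample_piecewise_poisson(np.asarray([0.0, t_end]), np.asarray([baseline_rate]), rng)]
    for trial in trials:
        if trial.has_odor:
            p_water = spec.odor_outcomes[trial.odor][0]
            if p_water > 0:
                p_ant = anticipation_prob_high if p_water >= 0.5 else anticipation_prob_low
                if rng.random() < p_ant:
                    lo = trial.odor_onset + spec.odor_duration
                    hi = trial.us_onset
                    licks.append(
                        _sample_piecewise_poisson(
                            np.asarray([lo, hi]), np.asarray([anticipatory_rate]), rng
                        )
                    )
        if trial.outcome == WATER:
            licks.append(
                _sample_piecewise_poisson(
                    np.asarray([trial.us_onset, trial.us_onset + 1.5]),
                    np.asarray([consummatory_rate]),
                    rng,
                )
            )
    return np.sort(np.concatenate(licks))
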