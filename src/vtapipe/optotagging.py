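"""Optogenetic identification of dopamine neurons from light responses.

A unit counts as an identified dopamine neuron when (1) a stimulus-
associated spike-latency test (SALT) shows that light pulses change its
spike timing at p < 0.001, and (2) the Pearson correlation between its
mean spontaneous and mean light-evoked waveforms exceeds 0.9 (ruling out
light-artifact contamination of the sorted cluster).

The latency test compares the distribution of first-spike latencies
after light pulses with latency distributions collected in baseline
(no-light) segments of the same length, using a symmetric
Jensen-Shannon divergence between latency histograms.  Significance is
a Monte-Carlo rank: the test statistic (median divergence between the
pulse histogram and a set of reference baseline histograms) is ranked
within the null distribution of the same statistic computed for
baseline-resampled pseudo-pulse histograms.  A pseudo-count keeps the
p-value strictly positive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .synthetic.neurons import LightProtocol, SpikeTrain

SALT_P_THRESHOLD = 1e-3
WAVEFORM_R_THRESHOLD = 0.9


@dataclass(frozen=True)
class SaltResult:
    """Outcome of the spike-latency test for one unit."""

    p_value: float
    test_window: float
    n_pulses_used: int
    baseline_segments: int
    test_statistic: float
    null_median: float
    null_q95: float
    degenerate: bool = False


@dataclass(frozen=True)
class TagDecision:
    salt_p: float
    waveform_r: float
    identified: bool


@dataclass(frozen=True)
class LightResponseProfile:
    """Per-frequency evoked-spike probability and pooled latency statistics."""

    evoked_probability: dict[float, float]
    n_pulses: dict[float, int]
    latency_mean: float
    latency_sd: float


def _pulse_onsets(pulses: LightProtocol | np.ndarray) -> np.ndarray:
    if isinstance(pulses, LightProtocol):
        return pulses.pulse_onsets
    return np.asarray(pulses, dtype=float)


def first_spike_latencies(
    spike_times: np.ndarray, starts: np.ndarray, window: float
) -> np.ndarray:
    """Latency of the first spike in (start, start + window] per start; NaN if none."""
    spike_times = np.asarray(spike_times, dtype=float)
    starts = np.asarray(starts, dtype=float)
    idx = np.searchsorted(spike_times, starts, side="right")
    latencies = np.full(len(starts), np.nan)
    valid = idx < len(spike_times)
    cand = spike_times[idx[valid]] - starts[valid]
    cand[cand > window] = np.nan
    latencies[valid] = cand
    return latencies


def latency_histogram(latencies: np.ndarray, window: float, bin_width: float) -> np.ndarray:
    """Counts per latency bin plus a trailing explicit "no spike" category."""
    n_bins = int(round(window / bin_width))
    edges = np.linspace(0.0, window, n_bins + 1)
    finite = latencies[np.isfinite(latencies)]
    counts, _ = np.histogram(finite, bins=edges)
    return np.concatenate([counts, [len(latencies) - len(finite)]]).astype(float)


def baseline_epochs_from_pulses(
    pulses: LightProtocol | np.ndarray,
    pre_pad: float = 5.0,
    guard: float = 0.1,
) -> list[tuple[float, float]]:
    """No-light epochs around a pulse protocol: the stretch before the first
    pulse and every inter-pulse gap longer than the guard period."""
    onsets = _pulse_onsets(pulses)
    epochs: list[tuple[float, float]] = [(onsets[0] - pre_pad, onsets[0])]
    gaps = np.diff(onsets)
    for onset, gap in zip(onsets[:-1], gaps):
        if gap > 2 * guard:
            epochs.append((onset + guard, onset + gap))
    return epochs


def tile_baseline_segments(
    epochs: list[tuple[float, float]], window: float
) -> np.ndarray:
    """Start times of consecutive ``window``-long segments tiling the epochs."""
    starts: list[np.ndarray] = []
    for lo, hi in epochs:
        n = int(math.floor((hi - lo) / window))
        if n > 0:
            starts.append(lo + np.arange(n) * window)
    if not starts:
        return np.empty(0)
    return np.concatenate(starts)


def _jensen_shannon(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """JS divergence between rows of ``p`` (2-D) and a single distribution ``q``."""
    p = np.atleast_2d(p)
    m = 0.5 * (p + q)
    with np.errstate(divide="ignore", invalid="ignore"):
        kl_pm = np.where(p > 0, p * np.log(p / m), 0.0).sum(axis=1)
        kl_qm = np.where(q > 0, q * np.log(q / m), 0.0).sum(axis=1)
    return 0.5 * (kl_pm + kl_qm)


def salt_test(
    spikes: SpikeTrain | np.ndarray,
    pulses: LightProtocol | np.ndarray,
    test_window: float = 0.010,
    baseline_epochs: list[tuple[float, float]] | None = None,
    latency_bin: float = 0.001,
    seed: int | np.random.Generator = 0,
    n_reference: int = 8,
    n_null: int = 1999,
    min_baseline_segments: int = 100,
) -> SaltResult:
    """Stimulus-associated spike-latency test, pooled over all pulses.

    Pulses from every stimulation frequency are pooled.  Baseline epochs
    default to the no-light stretches of the protocol itself.  The null
    distribution is generated by multinomial resampling of the pooled
    baseline latency distribution, seeded for reproducibility.
    """
    spike_times = spikes.times if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)
    onsets = _pulse_onsets(pulses)
    if len(onsets) < 1:
        raise ValueError("need at least one light pulse")
    if baseline_epochs is None:
        baseline_epochs = baseline_epochs_from_pulses(pulses)
    for lo, hi in baseline_epochs:
        in_pulse = (onsets >= lo) & (onsets < hi)
        if np.any(in_pulse):
            raise ValueError("baseline epochs must not overlap light pulses")

    segment_starts = tile_baseline_segments(baseline_epochs, test_window)
    n_segments = len(segment_starts)
    if n_segments < min_baseline_segments:
        raise ValueError(
            f"only {n_segments} baseline segments available; "
            f"need at least {min_baseline_segments}"
        )

    n_pulses = len(onsets)
    if len(spike_times) == 0:
        return SaltResult(
            p_value=1.0, test_window=test_window, n_pulses_used=n_pulses,
            baseline_segments=n_segments, test_statistic=0.0,
            null_median=0.0, null_q95=0.0, degenerate=True,
        )

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    test_counts = latency_histogram(
        first_spike_latencies(spike_times, onsets, test_window), test_window, latency_bin
    )
    pool_counts = latency_histogram(
        first_spike_latencies(spike_times, segment_starts, test_window),
        test_window, latency_bin,
    )
    test_hist = test_counts / test_counts.sum()
    pool_prob = pool_counts / pool_counts.sum()

    refs = rng.multinomial(n_pulses, pool_prob, size=n_reference) / n_pulses
    nulls = rng.multinomial(n_pulses, pool_prob, size=n_null) / n_pulses

    test_divs = np.asarray([_jensen_shannon(test_hist, r)[0] for r in refs])
    null_divs = np.column_stack([_jensen_shannon(nulls, r) for r in refs])
    test_stat = float(np.median(test_divs))
    null_stats = np.median(null_divs, axis=1)
    p = (1.0 + float(np.sum(null_stats >= test_stat))) / (1.0 + n_null)

    return SaltResult(
        p_value=p, test_window=test_window, n_pulses_used=n_pulses,
        baseline_segments=n_segments, test_statistic=test_stat,
        null_median=float(np.median(null_stats)),
        null_q95=float(np.quantile(null_stats, 0.95)),
    )


def salt_test_per_frequency(
    spikes: SpikeTrain, protocol: LightProtocol, **kwargs
) -> dict[float, SaltResult]:
    """SALT run separately on each stimulation frequency's pulses."""
    baseline = baseline_epochs_from_pulses(protocol)
    out: dict[float, SaltResult] = {}
    for freq in protocol.frequencies:
        onsets = protocol.pulse_onsets[protocol.pulse_frequencies == freq]
        out[float(freq)] = salt_test(spikes, onsets, baseline_epochs=baseline, **kwargs)
    return out


def waveform_correlation(
    spontaneous_mean: np.ndarray, evoked_mean: np.ndarray
) -> float:
    """Pearson correlation of two multi-channel mean waveforms (concatenated)."""
    a = np.asarray(spontaneous_mean, dtype=float).ravel()
    b = np.asarray(evoked_mean, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("waveforms must have identical channel and sample counts")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("waveform correlation undefined for zero-variance waveform")
    return float(np.corrcoef(a, b)[0, 1])


def mean_waveforms(
    spikes: SpikeTrain,
    pulses: LightProtocol | np.ndarray,
    evoked_window: float = 0.010,
    spontaneous_gap: float = 0.5,
) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Mean spontaneous and light-evoked waveform of a unit.

    Evoked spikes fall within ``evoked_window`` of a pulse onset;
    spontaneous spikes are at least ``spontaneous_gap`` from every pulse.
    Returns ``None`` for a category with no spikes.
    """
    if spikes.waveforms is None:
        raise ValueError("spike train carries no waveform snippets")
    onsets = _pulse_onsets(pulses)
    times = spikes.times
    idx = np.searchsorted(onsets, times, side="right")
    prev = np.where(idx > 0, times - onsets[np.maximum(idx - 1, 0)], np.inf)
    nxt = np.where(idx < len(onsets), onsets[np.minimum(idx, len(onsets) - 1)] - times, np.inf)
    evoked_mask = (prev > 0) & (prev <= evoked_window)
    spont_mask = (prev >= spontaneous_gap) & (nxt >= spontaneous_gap)
    evoked = spikes.waveforms[evoked_mask].mean(axis=0) if evoked_mask.any() else None
    spont = spikes.waveforms[spont_mask].mean(axis=0) if spont_mask.any() else None
    return spont, evoked


def decide_identification(
    salt_p: float,
    waveform_r: float,
    p_threshold: float = SALT_P_THRESHOLD,
    r_threshold: float = WAVEFORM_R_THRESHOLD,
) -> TagDecision:
    """Identified iff salt_p < threshold AND waveform_r > threshold (both strict)."""
    if not (math.isfinite(salt_p) and math.isfinite(waveform_r)):
        raise ValueError("salt_p and waveform_r must be finite")
    return TagDecision(
        salt_p=salt_p,
        waveform_r=waveform_r,
        identified=bool(salt_p < p_threshold and waveform_r > r_threshold),
    )


def light_response_profile(
    spikes: SpikeTrain | np.ndarray,
    protocol: LightProtocol,
    window: float = 0.010,
) -> LightResponseProfile:
    """Evoked-spike probability per stimulation frequency plus latency stats.

    Probability is the fraction of pulses followed by at least one spike
    within the window; latency mean and SD pool first spikes over all
    frequencies.
    """
    spike_times = spikes.times if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)
    probs: dict[float, float] = {}
    n_pulses: dict[float, int] = {}
    all_latencies: list[np.ndarray] = []
    for freq in protocol.frequencies:
        onsets = protocol.pulse_onsets[protocol.pulse_frequencies == freq]
        if len(onsets) == 0:
            warnings.warn(f"no pulses at {freq} Hz; frequency omitted")
            continue
        lat = first_spike_latencies(spike_times, onsets, window)
        probs[float(freq)] = float(np.mean(np.isfinite(lat)))
        n_pulses[float(freq)] = len(onsets)
        all_latencies.append(lat[np.isfinite(lat)])
    pooled = np.concatenate(all_latencies) if all_latencies else np.empty(0)
    latency_mean = float(np.mean(pooled)) if len(pooled) else float("nan")
    latency_sd = float(np.std(pooled)) if len(pooled) else float("nan")
    return LightResponseProfile(
        evoked_probability=probs, n_pulses=n_pulses,
        latency_mean=latency_mean, latency_sd=latency_sd,
    )
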