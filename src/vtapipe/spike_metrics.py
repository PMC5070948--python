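"""Trial-aligned firing-rate estimation and discrimination statistics.

Conventions: all analysis windows are half-open ``[t0, t1)`` in seconds
relative to an alignment event; a spike exactly at ``t0`` counts, one
exactly at ``t1`` does not.  PSTHs use 1-ms bins and spike-density
functions a centered 100-ms box filter; CS responses use 0-1000 ms (or
200-1000 ms) from odor onset, US responses 0-600 ms from US onset,
omission/nothing outcomes 0-1000 ms, and the per-neuron baseline the
-1000-0 ms window before odor onset pooled over all trial types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .synthetic.neurons import SpikeTrain

Window = tuple[float, float]


@dataclass(frozen=True)
class AnalysisWindows:
    psth_bin: float = 0.001
    density_box: float = 0.100
    cs: Window = (0.0, 1.0)
    cs_late: Window = (0.2, 1.0)
    us: Window = (0.0, 0.6)
    omission: Window = (0.0, 1.0)
    baseline: Window = (-1.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("cs", "cs_late", "us", "omission", "baseline"):
            lo, hi = getattr(self, name)
            if hi <= lo:
                raise ValueError(f"window {name} must have positive length")
        if not (self.cs[0] <= self.cs_late[0] and self.cs_late[1] <= self.cs[1]):
            raise ValueError("cs_late must be contained in cs")
        if self.psth_bin <= 0 or self.density_box < self.psth_bin:
            raise ValueError("need 0 < psth_bin <= density_box")


@dataclass
class PSTH:
    """Binned trial-aligned spike counts and the corresponding rate."""

    bin_edges: np.ndarray   # relative to alignment, length n_bins + 1
    counts: np.ndarray      # summed over alignments
    rate: np.ndarray        # Hz: counts / (n_align * bin)
    n_align: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class EpochResponse:
    """Per-trial firing rates in one window, with the neuron's baseline."""

    rates: np.ndarray          # Hz, one per trial
    baseline: float            # Hz, pooled across all trial types
    window: Window

    @property
    def subtracted(self) -> np.ndarray:
        return self.rates - self.baseline


def _times(spikes: SpikeTrain | np.ndarray) -> np.ndarray:
    return spikes.times if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)


def window_counts(
    spikes: SpikeTrain | np.ndarray, align_times: np.ndarray, window: Window
) -> np.ndarray:
    """Spike count in [align + t0, align + t1) for each alignment."""
    times = _times(spikes)
    align = np.asarray(align_times, dtype=float)
    lo = np.searchsorted(times, align + window[0], side="left")
    hi = np.searchsorted(times, align + window[1], side="left")
    return (hi - lo).astype(int)


def compute_psth(
    spikes: SpikeTrain | np.ndarray,
    align_times: np.ndarray,
    window: Window = (-1.0, 3.0),
    bin_width: float = 0.001,
) -> PSTH:
    """Peristimulus time histogram over the given alignments."""
    align = np.asarray(align_times, dtype=float)
    if align.size == 0:
        raise ValueError("need at least one alignment time")
    length = window[1] - window[0]
    n_bins = round(length / bin_width)
    if not np.isclose(n_bins * bin_width, length, rtol=1e-9, atol=1e-12):
        raise ValueError("bin width must divide the window length")
    times = _times(spikes)
    edges = window[0] + np.arange(n_bins + 1) * bin_width
    counts = np.zeros(n_bins)
    for a in align:
        lo = np.searchsorted(times, a + window[0], side="left")
        hi = np.searchsorted(times, a + window[1], side="left")
        rel = times[lo:hi] - a
        idx = np.floor((rel - window[0]) / bin_width).astype(int)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        np.add.at(counts, idx, 1)
    rate = counts / (len(align) * bin_width)
    return PSTH(bin_edges=edges, counts=counts, rate=rate, n_align=len(align))


def smooth_density(
    rate: np.ndarray, bin_width: float = 0.001, box: float = 0.100
) -> np.ndarray:
    """Centered moving-average (box-filter) spike-density estimate.

    Edges use the truncated window renormalized by actual coverage, so a
    constant input stays constant.
    """
    if box < bin_width:
        raise ValueError("box must be at least one bin wide")
    w = int(round(box / bin_width))
    rate = np.asarray(rate, dtype=float)
    kernel = np.ones(w)
    num = np.convolve(rate, kernel, mode="same")
    den = np.convolve(np.ones_like(rate), kernel, mode="same")
    return num / den


def baseline_rate(
    spikes: SpikeTrain | np.ndarray,
    align_times: np.ndarray,
    window: Window = (-1.0, 0.0),
) -> float:
    """Pooled baseline firing rate across all provided trials (Hz)."""
    align = np.asarray(align_times, dtype=float)
    if align.size == 0:
        raise ValueError("need at least one trial for the baseline")
    counts = window_counts(spikes, align, window)
    return float(counts.sum() / (len(align) * (window[1] - window[0])))


def epoch_response(
    spikes: SpikeTrain | np.ndarray,
    align_times: np.ndarray,
    window: Window,
    baseline: float = 0.0,
) -> EpochResponse:
    """Per-trial firing rates in a half-open window around each alignment."""
    align = np.asarray(align_times, dtype=float)
    if align.size == 0:
        raise ValueError("need at least one trial")
    counts = window_counts(spikes, align, window)
    rates = counts / (window[1] - window[0])
    return EpochResponse(rates=rates, baseline=float(baseline), window=window)


def auroc(responses_a: np.ndarray, responses_b: np.ndarray) -> float:
    """Area under the ROC curve for discriminating two sets of responses.

    Equals P(a > b) + 0.5 P(a = b) over all cross-pairs; 0.5 means the
    conditions are indistinguishable, above 0.5 means condition ``a``
    tends to exceed condition ``b``.  Computed from midranks (exactly the
    Mann-Whitney U statistic divided by n_a * n_b).
    """
    a = np.asarray(responses_a, dtype=float)
    b = np.asarray(responses_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    ranks = rankdata(np.concatenate([a, b]))
    u = ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0
    return float(u / (a.size * b.size))
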