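"""PSTH construction, box-filter density, epoch rates, and auROC."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from vtapipe.spike_metrics import (
    AnalysisWindows,
    auroc,
    baseline_rate,
    compute_psth,
    epoch_response,
    smooth_density,
)


def test_analysis_windows_defaults():
    w = AnalysisWindows()
    assert w.psth_bin == 0.001 and w.density_box == 0.1
    assert w.cs == (0.0, 1.0) and w.cs_late == (0.2, 1.0)
    assert w.us == (0.0, 0.6) and w.omission == (0.0, 1.0)
    assert w.baseline == (-1.0, 0.0)
    with pytest.raises(ValueError):
        AnalysisWindows(cs_late=(0.2, 1.5))


def test_psth_single_spike_lands_in_first_bin():
    psth = compute_psth(np.asarray([10.0005]), np.asarray([10.0]), window=(0.0, 1.0))
    assert psth.counts[0] == 1
    assert psth.counts[1:].sum() == 0


def test_psth_no_spikes_all_zero():
    psth = compute_psth(np.empty(0), np.asarray([5.0]), window=(0.0, 1.0))
    assert psth.counts.sum() == 0


def test_psth_rate_normalization():
    """100 alignments, one spike each in the first 1-ms bin -> 1000 Hz there."""
    aligns = np.arange(100) * 10.0
    spikes = aligns + 0.0004
    psth = compute_psth(np.sort(spikes), aligns, window=(0.0, 1.0))
    assert psth.rate[0] == pytest.approx(1000.0)


def test_psth_conserves_spike_count(rng):
    spikes = np.sort(rng.uniform(0, 100, size=500))
    aligns = np.asarray([20.0, 50.0, 80.0])
    window = (-1.0, 2.0)
    psth = compute_psth(spikes, aligns, window=window)
    direct = sum(
        np.sum((spikes >= a + window[0]) & (spikes < a + window[1])) for a in aligns
    )
    assert psth.counts.sum() == direct


def test_psth_requires_alignments_and_divisible_bin():
    with pytest.raises(ValueError, match="alignment"):
        compute_psth(np.asarray([1.0]), np.empty(0))
    with pytest.raises(ValueError, match="divide"):
        compute_psth(np.asarray([1.0]), np.asarray([0.0]), window=(0.0, 1.0), bin_width=0.0003)


def test_smoothing_preserves_constants():
    out = smooth_density(np.full(500, 10.0))
    assert np.allclose(out, 10.0)


def test_smoothing_single_spike_density():
    """One spike, one alignment, 1-ms bins: 10 Hz over the 100 covered bins."""
    psth = compute_psth(np.asarray([0.5]), np.asarray([0.0]), window=(0.0, 1.0))
    sm = smooth_density(psth.rate)
    covered = sm[sm > 0]
    assert len(covered) == 100
    assert np.allclose(covered, 10.0)


def test_smoothing_conserves_mass_for_interior_support(rng):
    rate = np.zeros(1000)
    rate[300:700] = rng.uniform(0, 50, size=400)
    sm = smooth_density(rate)
    assert sm.sum() == pytest.approx(rate.sum())


def test_smoothing_shift_equivariance(rng):
    spikes = np.sort(rng.uniform(10, 20, size=200))
    aligns = np.asarray([12.0, 15.0])
    shift = 123.456
    a = smooth_density(compute_psth(spikes, aligns, (0.0, 2.0)).rate)
    b = smooth_density(compute_psth(spikes + shift, aligns + shift, (0.0, 2.0)).rate)
    assert np.allclose(a, b)


def test_epoch_response_rate_and_half_open_window():
    resp = epoch_response(np.asarray([10.1, 10.2]), np.asarray([10.0]), (0.0, 0.6))
    assert resp.rates[0] == pytest.approx(2 / 0.6)
    # spike exactly at the right edge is excluded, at the left edge included
    edge = epoch_response(np.asarray([10.0, 10.6]), np.asarray([10.0]), (0.0, 0.6))
    assert edge.rates[0] == pytest.approx(1 / 0.6)


def test_epoch_response_requires_trials():
    with pytest.raises(ValueError, match="trial"):
        epoch_response(np.asarray([1.0]), np.empty(0), (0.0, 1.0))


def test_stationary_unit_has_zero_mean_subtracted_response(rng):
    """A homogeneous Poisson unit's baseline-subtracted response is ~0."""
    rate, t_end = 8.0, 4000.0
    n = rng.poisson(rate * t_end)
    spikes = np.sort(rng.uniform(0, t_end, size=n))
    aligns = np.arange(500) * 7.0 + 2.0
    base = baseline_rate(spikes, aligns, (-1.0, 0.0))
    resp = epoch_response(spikes, aligns, (0.0, 1.0), base)
    se = np.sqrt(2 * rate / len(aligns))  # two windows contribute noise
    assert abs(resp.subtracted.mean()) <= 3 * se


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ([1.0, 2.0, 5.0], [1.0, 2.0, 5.0], 0.5),
        ([2.0, 3.0], [0.0, 1.0], 1.0),
        ([1.0, 2.0, 3.0], [2.0, 3.0, 4.0], 2.0 / 9.0),
    ],
)
def test_auroc_examples(a, b, expected):
    assert auroc(np.asarray(a), np.asarray(b)) == pytest.approx(expected)


def test_auroc_complement_symmetry(rng):
    for _ in range(50):
        a = rng.integers(0, 5, size=rng.integers(1, 10)).astype(float)
        b = rng.integers(0, 5, size=rng.integers(1, 10)).astype(float)
        assert auroc(a, b) + auroc(b, a) == pytest.approx(1.0)


def test_auroc_equals_mann_whitney_u(rng):
    """auROC equals U / (n_a * n_b) on random tied samples."""
    for _ in range(200):
        a = rng.integers(0, 4, size=rng.integers(2, 12)).astype(float)
        b = rng.integers(0, 4, size=rng.integers(2, 12)).astype(float)
        u = mannwhitneyu(a, b, alternative="two-sided").statistic
        assert auroc(a, b) == pytest.approx(u / (len(a) * len(b)))


def test_auroc_rejects_empty():
    with pytest.raises(ValueError):
        auroc(np.empty(0), np.asarray([1.0]))
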