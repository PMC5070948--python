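"""Spike-latency test, waveform correlation, and the identification rule."""

import numpy as np
import pytest

from vtapipe.optotagging import (
    baseline_epochs_from_pulses,
    decide_identification,
    salt_test,
    waveform_correlation,
)
from vtapipe.synthetic import (
    NeuronModelParams,
    SpikeTrain,
    build_light_protocol,
    simulate_light_tagging,
)

SURE = {f: 1.0 for f in (1, 2, 5, 10, 20, 50)}


@pytest.fixture(scope="module")
def protocol():
    return build_light_protocol(trains_per_frequency=5)


def test_latency_locked_unit_is_highly_significant(protocol):
    """A unit spiking at 4 ms after every pulse and silent otherwise."""
    spikes = SpikeTrain(protocol.pulse_onsets + 0.004)
    result = salt_test(spikes, protocol, seed=0)
    assert result.p_value < 0.001
    assert not result.degenerate


def test_zero_spike_unit_is_degenerate(protocol):
    result = salt_test(SpikeTrain(np.empty(0)), protocol, seed=0)
    assert result.p_value == 1.0
    assert result.degenerate


def test_p_value_strictly_positive(protocol):
    spikes = SpikeTrain(protocol.pulse_onsets + 0.004)
    assert salt_test(spikes, protocol, seed=0).p_value > 0.0


def test_too_few_baseline_segments_rejected(protocol):
    spikes = SpikeTrain(protocol.pulse_onsets + 0.004)
    with pytest.raises(ValueError, match="baseline segments"):
        salt_test(spikes, protocol, seed=0, baseline_epochs=[(-(0.5), 0.0)])


def test_baseline_overlapping_pulses_rejected(protocol):
    spikes = SpikeTrain(protocol.pulse_onsets + 0.004)
    t0 = float(protocol.pulse_onsets[0])
    with pytest.raises(ValueError, match="overlap"):
        salt_test(spikes, protocol, seed=0, baseline_epochs=[(t0 - 1.0, t0 + 5.0)])


def test_salt_power_monotone_in_evoked_probability(protocol):
    """Power is non-decreasing along a 3-point grid of evoked probability."""
    medians = []
    for prob in (0.05, 0.3, 1.0):
        ps = []
        for seed in range(5):
            unit = simulate_light_tagging(
                NeuronModelParams(baseline_rate=8.0), tagged=True, protocol=protocol,
                seed=seed, evoked_prob={f: prob for f in (1, 2, 5, 10, 20, 50)},
            )
            ps.append(salt_test(unit, protocol, seed=seed).p_value)
        medians.append(np.median(ps))
    assert medians[0] >= medians[1] >= medians[2]


def test_reproducible_given_seed(protocol):
    unit = simulate_light_tagging(
        NeuronModelParams(baseline_rate=8.0), tagged=False, protocol=protocol, seed=9
    )
    assert salt_test(unit, protocol, seed=4).p_value == salt_test(unit, protocol, seed=4).p_value


def test_baseline_epochs_avoid_pulses(protocol):
    for lo, hi in baseline_epochs_from_pulses(protocol):
        assert not np.any((protocol.pulse_onsets >= lo) & (protocol.pulse_onsets < hi))


def test_waveform_correlation_identity_scale_inversion(rng):
    wf = rng.standard_normal((4, 32))
    assert waveform_correlation(wf, wf) == pytest.approx(1.0)
    assert waveform_correlation(wf, 0.5 * wf) == pytest.approx(1.0)
    assert waveform_correlation(wf, -wf) == pytest.approx(-1.0)


def test_waveform_correlation_errors(rng):
    wf = rng.standard_normal((4, 32))
    with pytest.raises(ValueError, match="zero-variance"):
        waveform_correlation(wf, np.zeros_like(wf))
    with pytest.raises(ValueError, match="identical"):
        waveform_correlation(wf, wf[:, :16])


@pytest.mark.parametrize(
    "salt_p, wf_r, expected",
    [
        (0.0005, 0.95, True),
        (0.01, 0.95, False),
        (0.001, 0.95, False),   # boundary is strict
        (0.0005, 0.9, False),   # boundary is strict
        (0.0005, 0.85, False),
    ],
)
def test_identification_criterion(salt_p, wf_r, expected):
    assert decide_identification(salt_p, wf_r).identified is expected


def test_identification_monotone():
    """Decreasing p or increasing r never flips identified -> not identified."""
    grid_p = [1e-5, 1e-4, 5e-4, 1e-3, 1e-2]
    grid_r = [0.5, 0.85, 0.9, 0.95, 0.999]
    for i, p in enumerate(grid_p):
        for j, r in enumerate(grid_r):
            if decide_identification(p, r).identified:
                for p2 in grid_p[: i + 1]:
                    for r2 in grid_r[j:]:
                        assert decide_identification(p2, r2).identified


def test_identification_rejects_non_finite():
    with pytest.raises(ValueError):
        decide_identification(float("nan"), 0.95)
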