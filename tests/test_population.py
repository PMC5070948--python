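"""Population analyses: value coding, contrasts, censuses, contingency tests."""

import warnings

import numpy as np
import pytest
from scipy.stats import chi2_contingency, ttest_1samp, ttest_ind

from vtapipe.population import (
    behavior_split_contrast,
    bonferroni,
    classify_cs_value_coding,
    context_contingency_test,
    inhibition_census,
    omission_contrast,
    population_auroc_test,
    prediction_error_contrast,
    response_correlation,
    two_condition_contrast,
)


# ------------------------------------------------------------- classification

def test_classification_separated_means_are_monotonic(rng):
    resp = {
        "reward": 3.0 + 0.1 * rng.standard_normal(40),
        "middle": 0.5 + 0.1 * rng.standard_normal(40),
        "airpuff": -1.0 + 0.1 * rng.standard_normal(40),
    }
    cls = classify_cs_value_coding(resp)
    assert cls.modulated and cls.monotonic


def test_classification_identical_groups_not_modulated(rng):
    x = rng.standard_normal(30)
    cls = classify_cs_value_coding({"a": x, "b": x.copy(), "c": x.copy()})
    assert not cls.modulated and not cls.monotonic


def test_classification_middle_not_intermediate(rng):
    resp = {
        "reward": 3.0 + 0.1 * rng.standard_normal(40),
        "middle": -1.0 + 0.1 * rng.standard_normal(40),
        "airpuff": 0.5 + 0.1 * rng.standard_normal(40),
    }
    cls = classify_cs_value_coding(resp)
    assert cls.modulated and not cls.monotonic


def test_classification_missing_odor_rejected(rng):
    with pytest.raises(ValueError, match="missing odor"):
        classify_cs_value_coding(
            {"a": rng.standard_normal(5), "b": rng.standard_normal(5)},
            order=("a", "b", "c"),
        )


def test_classification_invariant_to_constant_shift(rng):
    resp = {
        "r": 2.0 + rng.standard_normal(30),
        "m": 0.0 + rng.standard_normal(30),
        "a": -2.0 + rng.standard_normal(30),
    }
    shifted = {k: v + 7.5 for k, v in resp.items()}
    assert classify_cs_value_coding(resp).monotonic == classify_cs_value_coding(shifted).monotonic


# ------------------------------------------------------------------ contrasts

def test_identical_distributions_are_indistinguishable(rng):
    x = rng.standard_normal(50)
    res = two_condition_contrast(x, x.copy())
    assert res.mean_difference == pytest.approx(0.0)
    assert res.auroc == pytest.approx(0.5)


def test_prediction_error_contrast_direction(rng):
    predicted = 1.0 + rng.standard_normal(60)
    unpredicted = 3.0 + rng.standard_normal(60)
    res = prediction_error_contrast(predicted, unpredicted)
    assert res.mean_difference > 0 and res.auroc > 0.5 and res.p_value < 0.01


def test_omission_contrast_rejects_single_trial(rng):
    with pytest.raises(ValueError):
        omission_contrast(np.asarray([1.0]), rng.standard_normal(10))


def test_normality_gate_switches_to_nonparametric():
    local = np.random.default_rng(0)
    heavy = np.concatenate([local.standard_normal(60), [60.0, 80.0, 95.0]])
    res = two_condition_contrast(heavy, local.standard_normal(60) + 0.5)
    assert res.test_name == "mann-whitney u"
    gauss = two_condition_contrast(local.standard_normal(60), local.standard_normal(60))
    assert gauss.test_name == "unpaired t"


def test_population_auroc_against_half(rng):
    mean, t, p = population_auroc_test(0.6 + 0.05 * rng.standard_normal(30))
    assert mean > 0.5 and p < 0.001


# ---------------------------------------------------------------- correlation

def test_correlation_exact_lines():
    x = np.linspace(0, 1, 20)
    r, p, slope, intercept = response_correlation(x, 2 * x + 1)
    assert r == pytest.approx(1.0) and slope == pytest.approx(2.0)
    r, _, _, _ = response_correlation(x, -x)
    assert r == pytest.approx(-1.0)


def test_correlation_constant_input_rejected():
    with pytest.raises(ValueError, match="constant"):
        response_correlation(np.ones(10), np.arange(10.0))


def test_correlation_null_distribution(rng):
    """Independent normals at n=38: |r| < 0.32 in about 95% of repeats."""
    inside = 0
    for _ in range(1000):
        r, *_ = response_correlation(rng.standard_normal(38), rng.standard_normal(38))
        inside += abs(r) < 0.32
    assert 0.92 <= inside / 1000 <= 0.975


# --------------------------------------------------------------------- census

def test_census_strong_suppression_flags_all(rng):
    neurons = [-2.0 + 0.2 * rng.standard_normal(80) for _ in range(12)]
    res = inhibition_census(neurons, criterion="vs_baseline")
    assert res.n_flagged == res.n_neurons == 12


def test_census_null_flag_rate_near_one_sided_alpha(rng):
    """Unsuppressed neurons are flagged at ~2.5% (two-sided p, one-sided sign)."""
    neurons = [rng.standard_normal(80) for _ in range(200)]
    res = inhibition_census(neurons, criterion="vs_baseline")
    rate = res.n_flagged / res.n_neurons
    se = np.sqrt(0.025 * 0.975 / 200)
    assert abs(rate - 0.025) <= 3 * se


def test_census_matches_per_neuron_recount(rng):
    airpuff = [rng.standard_normal(40) - rng.uniform(0, 1.5) for _ in range(25)]
    nothing = [rng.standard_normal(40) for _ in range(25)]
    res = inhibition_census(airpuff, nothing, criterion="vs_nothing")
    manual = 0
    for x, y in zip(airpuff, nothing):
        p = ttest_ind(x, y).pvalue
        manual += (x.mean() < y.mean()) and (p < 0.05)
    assert res.n_flagged == manual


def test_census_excludes_undersampled_neuron(rng):
    neurons = [rng.standard_normal(40), np.asarray([1.0])]
    with pytest.warns(UserWarning, match="excluded"):
        res = inhibition_census(neurons, criterion="vs_baseline")
    assert res.n_neurons == 1


# -------------------------------------------------------------- chi-square

def test_contingency_reproduces_published_values():
    chi2, p = context_contingency_test(12, 12, 11, 17)
    assert round(chi2, 2) == 5.34 and round(p, 2) == 0.02
    chi2, p = context_contingency_test(6, 17, 9, 12)
    assert round(chi2, 2) == 4.44 and round(p, 2) == 0.04


def test_contingency_zero_for_equal_proportions():
    chi2, p = context_contingency_test(5, 10, 5, 10)
    assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)


def test_contingency_symmetries():
    base = context_contingency_test(11, 17, 12, 12)[0]
    assert context_contingency_test(12, 12, 11, 17)[0] == pytest.approx(base)
    # swapping flagged/unflagged columns leaves the statistic unchanged
    assert context_contingency_test(6, 17, 0, 12)[0] == pytest.approx(
        context_contingency_test(11, 17, 12, 12)[0]
    )


def test_contingency_matches_scipy_oracle():
    for table in ((12, 12, 11, 17), (6, 17, 9, 12), (3, 30, 14, 25)):
        k1, n1, k2, n2 = table
        chi2, p = context_contingency_test(k1, n1, k2, n2)
        ref = chi2_contingency(
            [[k1, n1 - k1], [k2, n2 - k2]], correction=False
        )
        assert chi2 == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


def test_contingency_zero_margin_rejected():
    with pytest.raises(ValueError, match="margin"):
        context_contingency_test(0, 10, 0, 12)


# ----------------------------------------------------------- behavior splits

def test_behavior_split_detects_constructed_effect(rng):
    responses, labels = [], []
    for _ in range(20):
        lab = rng.random(40) < 0.5
        resp = rng.standard_normal(40) - 1.0 * lab  # 1 Hz lower on blink trials
        responses.append(resp)
        labels.append(lab)
    res = behavior_split_contrast(responses, labels)
    assert res.paired.mean_difference < 0 and res.paired.p_value < 0.05


def test_behavior_split_shuffled_labels_is_calibrated(rng):
    """Rejection rate under shuffled labels stays near the nominal level."""
    rejections = 0
    n_shuffles = 200
    responses = [rng.standard_normal(40) for _ in range(15)]
    for _ in range(n_shuffles):
        labels = [rng.permutation(np.repeat([True, False], 20)) for _ in range(15)]
        res = behavior_split_contrast(responses, labels)
        rejections += res.paired.p_value < 0.05
    assert 0.005 <= rejections / n_shuffles <= 0.12


def test_behavior_split_excludes_single_class_neuron(rng):
    responses = [rng.standard_normal(20) for _ in range(3)]
    labels = [
        rng.random(20) < 0.5,
        rng.random(20) < 0.5,
        np.ones(20, dtype=bool),  # only one class: excluded
    ]
    with pytest.warns(UserWarning, match="excluded"):
        res = behavior_split_contrast(responses, labels)
    assert res.n_neurons == 2


def test_bonferroni_adjustment():
    assert bonferroni([0.01, 0.04, 0.5]) == [0.03, 0.12, 1.0]
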