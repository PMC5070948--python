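"""Neuron- and population-level analyses of conditioned responses.

Covers monotonic value-coding classification of CS responses, prediction-
error contrasts for delivered and omitted outcomes, response correlations
across neurons, censuses of significantly inhibited neurons, contingency
tests between task contexts, and behavior-split (blink / lick) contrasts.

Test selection follows a normality gate: a Lilliefors-type Kolmogorov-
Smirnov normality check decides between the parametric test (t) and its
nonparametric fallback (Mann-Whitney U unpaired, Wilcoxon signed-rank
paired).  Two-sided p-values are reported throughout; census flags add a
one-sided direction requirement (the flagged response must actually be
lower) because they count inhibited neurons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .spike_metrics import auroc

NORMALITY_ALPHA = 0.05
_MIN_N_FOR_NORMALITY_TEST = 8


def _is_normal(x: np.ndarray, alpha: float = NORMALITY_ALPHA) -> bool:
    """Lilliefors KS normality check; tiny samples default to parametric."""
    x = np.asarray(x, dtype=float)
    if x.size < _MIN_N_FOR_NORMALITY_TEST or np.ptp(x) == 0:
        return True
    from statsmodels.stats.diagnostic import kstest_normal

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = kstest_normal(x)
    return bool(p >= alpha)


@dataclass(frozen=True)
class ContrastResult:
    """A two-condition comparison of per-trial (or per-neuron) responses."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    mean_difference: float      # mean_a - mean_b
    auroc: float                # P(a > b) + 0.5 P(a = b)
    test_name: str
    statistic: float
    p_value: float
    paired: bool = False


@dataclass(frozen=True)
class CodingClassification:
    anova_p: float
    modulated: bool             # CS responses significantly modulated by odor
    pairwise_p: float           # reward CS vs air-puff CS
    monotonic: bool             # all three monotonicity criteria hold


@dataclass(frozen=True)
class CensusResult:
    n_neurons: int
    n_flagged: int
    criterion: str
    p_values: tuple[float, ...]
    flags: tuple[bool, ...]


@dataclass(frozen=True)
class BehaviorSplitResult:
    """Per-neuron class means and the population comparison between classes."""

    n_neurons: int
    means_true: np.ndarray       # per-neuron mean response on label-true trials
    means_false: np.ndarray
    paired: ContrastResult       # population-level true vs false comparison
    one_sample_true: tuple[float, float]    # (t, p) of true-class means vs 0
    one_sample_false: tuple[float, float]


def two_condition_contrast(
    responses_a: np.ndarray,
    responses_b: np.ndarray,
    label_a: str = "a",
    label_b: str = "b",
    paired: bool = False,
) -> ContrastResult:
    """Compare two response samples with the normality-gated test."""
    a = np.asarray(responses_a, dtype=float)
    b = np.asarray(responses_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two observations per condition")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison needs equal sample sizes")
        diff = a - b
        if np.ptp(diff) == 0 and diff[0] == 0:
            name, stat, p = "degenerate", 0.0, 1.0
        elif _is_normal(diff):
            res = stats.ttest_rel(a, b)
            name, stat, p = "paired t", float(res.statistic), float(res.pvalue)
        else:
            res = stats.wilcoxon(a, b)
            name, stat, p = "wilcoxon", float(res.statistic), float(res.pvalue)
    else:
        if np.ptp(np.concatenate([a, b])) == 0:
            name, stat, p = "degenerate", 0.0, 1.0
        elif _is_normal(a) and _is_normal(b):
            res = stats.ttest_ind(a, b)
            name, stat, p = "unpaired t", float(res.statistic), float(res.pvalue)
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            name, stat, p = "mann-whitney u", float(res.statistic), float(res.pvalue)
    return ContrastResult(
        label_a=label_a, label_b=label_b, n_a=a.size, n_b=b.size,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        mean_difference=float(a.mean() - b.mean()),
        auroc=auroc(a, b), test_name=name, statistic=stat, p_value=p,
        paired=paired,
    )


def classify_cs_value_coding(
    per_odor_responses: Mapping[str, np.ndarray],
    order: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> CodingClassification:
    """Monotonic value-coding classification of CS responses.

    ``order`` names the three odors as (reward-predicting, middle,
    air-puff-predicting); defaults to the mapping's insertion order.  A
    neuron is monotonic when (1) one-way ANOVA across the three odors is
    significant, (2) the reward-CS response significantly exceeds the
    air-puff-CS response (unpaired t), and (3) the middle odor's mean
    response is intermediate between the two.
    """
    keys = tuple(order) if order is not None else tuple(per_odor_responses)
    if len(keys) != 3:
        raise ValueError("exactly three odors are compared")
    missing = [k for k in keys if k not in per_odor_responses]
    if missing:
        raise ValueError(f"missing odor(s): {', '.join(map(str, missing))}")
    groups = [np.asarray(per_odor_responses[k], dtype=float) for k in keys]
    if any(g.size < 2 for g in groups):
        raise ValueError("need at least two trials per odor")
    reward, middle, airpuff = groups

    if np.ptp(np.concatenate(groups)) == 0:
        anova_p = 1.0
    else:
        anova_p = float(stats.f_oneway(*groups).pvalue)
    modulated = bool(anova_p < alpha)

    if np.ptp(np.concatenate([reward, airpuff])) == 0:
        pairwise_p = 1.0
    else:
        pairwise_p = float(stats.ttest_ind(reward, airpuff).pvalue)
    larger = reward.mean() > airpuff.mean()
    intermediate = airpuff.mean() < middle.mean() < reward.mean()
    monotonic = bool(modulated and pairwise_p < alpha and larger and intermediate)
    return CodingClassification(
        anova_p=anova_p, modulated=modulated,
        pairwise_p=pairwise_p, monotonic=monotonic,
    )


def prediction_error_contrast(
    predicted: np.ndarray, unpredicted: np.ndarray
) -> ContrastResult:
    """US responses to unpredicted vs predicted outcomes (baseline-subtracted).

    auROC above 0.5 means the unpredicted response exceeds the predicted
    one, the signature of prediction-error coding.
    """
    return two_condition_contrast(
        unpredicted, predicted, label_a="unpredicted", label_b="predicted"
    )


def omission_contrast(
    omission_trials: np.ndarray, nothing_trials: np.ndarray
) -> ContrastResult:
    """Outcome-period responses on omission trials vs nothing trials."""
    return two_condition_contrast(
        omission_trials, nothing_trials, label_a="omission", label_b="nothing"
    )


def population_auroc_test(aurocs: np.ndarray) -> tuple[float, float, float]:
    """One-sample t test of per-neuron auROC values against 0.5.

    Returns (mean auROC, t statistic, two-sided p).
    """
    a = np.asarray(aurocs, dtype=float)
    if a.size < 2:
        raise ValueError("need at least two neurons")
    res = stats.ttest_1samp(a, 0.5)
    return float(a.mean()), float(res.statistic), float(res.pvalue)


def response_correlation(
    x: np.ndarray, y: np.ndarray
) -> tuple[float, float, float, float]:
    """Pearson correlation of two per-neuron response vectors.

    Returns (r, two-sided p, slope, intercept of the best-fit line).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with at least 3 neurons")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return float(r), float(p), float(fit.slope), float(fit.intercept)


def inhibition_census(
    airpuff_responses: Sequence[np.ndarray],
    nothing_responses: Sequence[np.ndarray] | None = None,
    criterion: str = "vs_baseline",
    alpha: float = 0.05,
) -> CensusResult:
    """Count neurons significantly inhibited by the air-puff-predicting CS.

    ``vs_baseline``: per neuron, one-sample t test of baseline-subtracted
    air-puff-CS responses against zero; flagged if the mean is negative
    and p < alpha.  ``vs_nothing``: per neuron, two-sample t test of
    air-puff-CS vs nothing-CS responses; flagged if the air-puff mean is
    lower and p < alpha.  Neurons with fewer than two trials in a needed
    condition are excluded with a warning.
    """
    if criterion not in ("vs_baseline", "vs_nothing"):
        raise ValueError("criterion must be 'vs_baseline' or 'vs_nothing'")
    if criterion == "vs_nothing":
        if nothing_responses is None or len(nothing_responses) != len(airpuff_responses):
            raise ValueError("vs_nothing needs one nothing-CS sample per neuron")
    p_values: list[float] = []
    flags: list[bool] = []
    for i, resp in enumerate(airpuff_responses):
        x = np.asarray(resp, dtype=float)
        if x.size < 2:
            warnings.warn(f"neuron {i}: fewer than 2 trials, excluded from census")
            continue
        if criterion == "vs_baseline":
            if np.ptp(x) == 0:
                p = 1.0 if x[0] == 0 else 0.0
                stat_mean_low = x[0] < 0
            else:
                p = float(stats.ttest_1samp(x, 0.0).pvalue)
                stat_mean_low = x.mean() < 0
        else:
            y = np.asarray(nothing_responses[i], dtype=float)
            if y.size < 2:
                warnings.warn(f"neuron {i}: fewer than 2 nothing trials, excluded")
                continue
            if np.ptp(np.concatenate([x, y])) == 0:
                p = 1.0
                stat_mean_low = False
            else:
                p = float(stats.ttest_ind(x, y).pvalue)
                stat_mean_low = x.mean() < y.mean()
        p_values.append(p)
        flags.append(bool(stat_mean_low and p < alpha))
    return CensusResult(
        n_neurons=len(p_values), n_flagged=int(sum(flags)), criterion=criterion,
        p_values=tuple(p_values), flags=tuple(flags),
    )


def context_contingency_test(
    k1: int, n1: int, k2: int, n2: int
) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table.

    Compares the proportion k1/n1 with k2/n2 (e.g. fractions of inhibited
    neurons in two reward contexts).  Returns (chi-square, p).
    """
    for k, n in ((k1, n1), (k2, n2)):
        if not 0 <= k <= n:
            raise ValueError("counts must satisfy 0 <= k <= n")
    observed = np.asarray([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    row = observed.sum(axis=1)
    col = observed.sum(axis=0)
    total = observed.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("chi-square undefined with a zero margin")
    expected = np.outer(row, col) / total
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def behavior_split_contrast(
    per_neuron_responses: Sequence[np.ndarray],
    per_neuron_labels: Sequence[np.ndarray],
    label_true: str = "blink",
    label_false: str = "no-blink",
    min_trials: int = 2,
) -> BehaviorSplitResult:
    """Split each neuron's trials by a behavior label and compare classes.

    Neurons lacking ``min_trials`` trials in either class are excluded
    with a warning.  The population comparison pairs each neuron's two
    class means; one-sample t tests of each class's means against zero
    are also reported.
    """
    means_t: list[float] = []
    means_f: list[float] = []
    for i, (resp, lab) in enumerate(zip(per_neuron_responses, per_neuron_labels)):
        resp = np.asarray(resp, dtype=float)
        lab = np.asarray(lab, dtype=bool)
        if resp.shape != lab.shape:
            raise ValueError(f"neuron {i}: one label per trial required")
        if lab.sum() < min_trials or (~lab).sum() < min_trials:
            warnings.warn(f"neuron {i}: a behavior class has too few trials, excluded")
            continue
        means_t.append(float(resp[lab].mean()))
        means_f.append(float(resp[~lab].mean()))
    if len(means_t) < 2:
        raise ValueError("need at least two neurons with both behavior classes")
    mt = np.asarray(means_t)
    mf = np.asarray(means_f)
    paired = two_condition_contrast(mt, mf, label_a=label_true, label_b=label_false, paired=True)
    t_t = stats.ttest_1samp(mt, 0.0)
    t_f = stats.ttest_1samp(mf, 0.0)
    return BehaviorSplitResult(
        n_neurons=len(mt), means_true=mt, means_false=mf, paired=paired,
        one_sample_true=(float(t_t.statistic), float(t_t.pvalue)),
        one_sample_false=(float(t_f.statistic), float(t_f.pvalue)),
    )


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Bonferroni-adjusted p-values for a family of planned comparisons."""
    m = len(p_values)
    return [min(1.0, float(p) * m) for p in p_values]
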