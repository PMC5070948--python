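# Methods

This note documents the models, numerical choices, and deliberate design
decisions behind `vtapipe`, and what the synthetic-data tests do and do
not establish about real recordings.

## Task designs and trial generation

Four task presets encode the conditioning designs analyzed by the
pipeline. Per-odor outcome probabilities (water, air puff, nothing):

| task | A | B | C | D | no-odor | free water | free air puff |
|---|---|---|---|---|---|---|---|
| mixed_prediction | 25/0/75 | 0/0/100 | 0/75/25 | 25/75/0 | 4% | 2% | 2% |
| low_reward_probability | 20/0/80 | 0/0/100 | 0/90/10 | — | 12% | 6% | 6% |
| high_reward_probability | 90/0/10 | 0/0/100 | 0/90/10 | — | 12% | 6% | 6% |
| high_reward_probability_2 | 90/0/10 | 0/0/100 | 0/80/20 | — | 13% | 7% | 6% |

Every trial is odor (1 s) → delay (1 s) → outcome; no-odor trials
deliver a free (unpredicted) water or air-puff outcome with no cue. The
exact allocation of trials across odors is not published; CS trials are
split **equally** among the task's odors. Under this split the overall
rewarded-trial percentage does not exactly match any of the published
summary percentages (which are themselves mutually inconsistent at the
1–2% level); no attempt is made to force it. Inter-trial intervals are
exponential (default mean 3 s — a typical head-fixed conditioning pace;
the published designs state only the distribution family) with draws
above 15 s rejected and redrawn, preserving a flat hazard below the
truncation.

## The dopamine-neuron model

A simulated unit is an inhomogeneous Poisson process, sampled exactly on
the piecewise-constant rate function

r(t) = max(rate_floor, b + c·k_early + g·V_eff·k_CS + g·(v_out − V)·k_US)

with boxcar kernels k_early = [0, 150) ms and k_CS = [50, 400) ms from
CS onset, k_US = [0, 300) ms from US onset (all configurable). V is the
integrated value of the odor, V = P(water)·v_w + P(airpuff)·v_a; v_out
is the realized outcome's value (0 for nothing, so omission of a
predicted outcome yields a sign-flipped response, scaled by
`omission_gain`). This is a steady-state phenomenological stand-in: no
biophysics, no learning across trials.

Defaults: baseline b = 6 Hz (tonic dopamine range; per-neuron sampled
5–8 Hz), value gain g = 40 Hz per value unit (per-neuron ±20%), v_w = 1,
v_a = −0.125. The small |v_a|/v_w ratio reflects that a mild air puff
carries far less negative value than water carries positive value — the
very asymmetry that motivates using 75–90% air-puff probabilities
against 20–25% water probabilities to balance the two valences. Two
constraints fixed these magnitudes *a priori*:

* **Floor linearity.** The deepest instantaneous inhibition, g·|v_a| =
  5 Hz, stays below baseline. If it exceeded baseline, the rate floor
  would clip predicted and unpredicted air-puff responses to the same
  value and destroy the prediction-error ordering the model is supposed
  to carry.
* **Power at realistic session sizes.** At 272–400 trials per session
  (the published range), per-neuron sign recovery of the water and
  air-puff prediction-error contrasts has >95% analytic power under
  Poisson count noise with these gains.

**Context dependence.** In high reward contexts the model adds a
short-latency excitation c (default 8 Hz over 0–150 ms) to every CS
*and* masks the negative-value CS term: V_eff = V for V ≥ 0, V·(1 −
masking) otherwise, masking = 0.8 in high contexts and 0 in low ones.
The masking term is deliberate: a purely additive excitation cancels out
of any air-puff-CS vs nothing-CS comparison (it raises both by the same
amount), so it cannot reproduce the observed context effect in which
fewer neurons distinguish the two cues in high reward contexts. The
biological observation is precisely that the excitation does *not* ride
on top of intact value coding but degrades it, and the model encodes
that as attenuation.

The generator does **not** couple blink intent to neural parameters, so
passing tests show the behavior-split machinery works on labeled data,
not that the simulation reproduces the blink/no-blink firing difference.
Other real-data features deliberately absent: drift and nonstationarity,
sub-Poisson/bursty spike statistics, correlated noise across trials,
imperfect spike sorting, and learning dynamics. Passing parameter-
recovery tests therefore validates the *analysis chain*, not the realism
of dopamine firing per se.

## Optogenetic identification

A unit is an identified dopamine neuron iff SALT p < 0.001 **and**
spontaneous-vs-evoked waveform Pearson correlation > 0.9, both strict,
pooling light pulses over all stimulation frequencies (1–50 Hz).

The latency test collects, for every pulse, the first-spike latency in
(0, 10 ms] binned at 1 ms with an explicit "no spike" category.
Baseline epochs (the no-light stretches of the stimulation block) are
tiled into 10-ms segments and pooled into a baseline latency
distribution. Monte-Carlo machinery, seeded for reproducibility:

* 8 reference histograms and 1999 null pseudo-test histograms are drawn
  as multinomial samples of `n_pulses` segments from the pooled baseline
  distribution;
* the statistic is the median Jensen–Shannon divergence between a
  histogram and the references;
* p = (1 + #{null ≥ observed}) / (1 + 1999), so p ≥ 0.0005 > 0 always,
  and the smallest attainable p (0.0005) is below the 0.001 criterion.

On 200 simulated null units the false-positive rate at p < 0.05 is
0.03–0.065 across seeds (the bootstrap approximation is close to exact:
pseudo-tests resample a finite segment pool rather than the true
process, a ~n_pulses/n_segments ≈ 7% variance distortion). A unit with
zero spikes returns p = 1 with a degenerate flag; fewer than 100
baseline segments is an error.

Evoked waveforms average spikes within 10 ms of a pulse; spontaneous
waveforms average spikes ≥ 500 ms from every pulse. The generator can
contaminate evoked snippets with a photoelectric artifact to exercise
the waveform-correlation rejection path.

## Response metrics

All windows are half-open [t0, t1): a spike at t0 counts, at t1 does
not. PSTHs use 1-ms bins; the spike-density function is a centered
100-ms box filter whose edges renormalize by actual coverage (constants
are preserved). The per-neuron baseline pools the [−1000, 0) ms window
over **all** trial types; no-odor trials contribute a virtual onset 2 s
before their US. auROC is computed from midranks (identical to the
Mann–Whitney U statistic divided by n_a·n_b, and exactly equal to
P(a>b) + 0.5·P(a=b)); baseline subtraction is a per-neuron constant and
cannot change it. Convention: auROC > 0.5 means the first argument's
responses are larger.

## Population statistics

* **Normality gate.** Each comparison first applies a Lilliefors
  Kolmogorov–Smirnov normality check at α = 0.05 and falls back to
  Mann–Whitney U (unpaired) or Wilcoxon signed-rank (paired) when
  normality is rejected; samples under n = 8 use the parametric test
  (KS-type tests are uninformative there). All p-values are two-sided.
* **Monotonic value coding** requires (1) one-way ANOVA across the three
  odors p < 0.05, (2) reward CS > air-puff CS by unpaired t at p < 0.05,
  (3) the middle odor's mean strictly between the two. The monotonic
  flag is invariant to adding a constant to all responses.
* **Prediction-error contrasts** compare predicted outcomes (delivered
  by the *pure* single-outcome predictor odor) with free outcomes in the
  US window; omission uses the 0–1000 ms outcome window against trials
  of the nothing odor. Population inference is a one-sample t of
  per-neuron auROC against 0.5, Bonferroni-corrected within the declared
  family of planned contrasts.
* **Inhibition censuses** flag a neuron when its air-puff-CS response is
  significantly below zero (vs-baseline, one-sample t) or below the
  nothing-CS response (vs-nothing, two-sample t), with the one-sided
  direction requirement added because the census counts *inhibited*
  neurons; the two-sided p is retained, so null units are flagged at
  ≈ 2.5%.
* **Context contingency** is the Pearson chi-square on the 2×2 table of
  flagged/unflagged counts in two contexts, 1 df, **no** continuity
  correction — only the uncorrected statistic reproduces χ² = 5.34 from
  the counts 12/12 vs 11/17 (and 4.44 from 6/17 vs 9/12).
* Statistics include all neurons; no outlier exclusion is performed
  anywhere (outliers affect only published box-plot display, not the
  statistics).

## Eye-blink pipeline

Segmentation per frame: binarize (intensity < 234 on the 8-bit scale;
the infrared-lit face is near-saturated), delete connected components
smaller than 500 px (8-connectivity), morphological opening with a
2-px disk, fill enclosed holes smaller than 500 px, then take the
largest component's area and second-moment-ellipse eccentricity.
Eccentricity is computed and stored but drives no downstream decision.
The threshold and structuring element are per-session configurable; no
automatic threshold search is attempted.

Synchronization: infrared-off events (< 25 ms, so one to two frames at
60 Hz) occur 2 s after every US and appear as troughs of mean frame
intensity; the trough threshold is the midpoint between the session
median and minimum intensity, and consecutive dark frames collapse to
the run's first frame. Frame times are piecewise-linear interpolations
between (event frame, event timestamp) anchors. Within the anchor span
the error is bounded by the anchor quantization (< half the 60-Hz frame
period, 1/120 s). Frames outside the span are extrapolated from the
nearest two anchors, where quantization error is slope-amplified; no
analysis window uses those frames, and the stated error bound applies
to the span.

Blink labeling: areas are normalized by the session's 99th-percentile
area (infrared-off frames excluded from the normalizer; values slightly
above 1 are kept unclipped), and an air-puff trial is a blink trial when
the mean normalized area in the [1, 2) s delay window is **strictly
below** 0.5 — a tie labels no-blink. Lick trials are delay lick rate
≥ 3 licks/s, inclusive.

## Determinism and I/O

One master seed fans out via seed-sequence spawning into independent
substreams (trial sequence, each unit, licks, video, per-unit SALT
Monte-Carlo), so identical seeds give identical sessions and any
component can be regenerated independently. Session CSVs are written
with shortest-round-trip float representations and read back with
round-trip parsing; write → read → write is byte-identical, and analysis
reports are byte-identical across repeated runs.

## Validation problem sizes

The acceptance runs use: 200 null + 20 locked units for SALT
calibration (300 pulses each, 5 trains per frequency); 50 low-context
neurons at 400 trials/session for parameter recovery, split between the
mixed-prediction and low-reward-probability tasks (mirroring how the two
low-context datasets are pooled in the analyses they exercise); 30
neurons per context at 272 trials for the context census; a 30-trial
video session at 60 Hz for the eye pipeline. These sizes sit inside the
published per-session ranges while keeping the whole validation suite
around a minute of CPU time.

## Known limitations

* The simulator is stationary; it cannot exercise learning-related or
  satiety-related analyses.
* Blink intent is independent of neural parameters (see above).
* The SALT null is a bootstrap of a finite baseline pool; its p-values
  are approximately, not exactly, uniform under the null.
* The equal-per-odor trial split is an assumption; published overall
  reward percentages cannot all be reproduced simultaneously under any
  split.
* Eye segmentation assumes a near-saturated background and a single
  dark eye region; it has no provision for grooming artifacts or
  whisker occlusion beyond the small-component filter.
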