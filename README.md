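# vtapipe

Simulation and analysis of optogenetically identified dopamine-neuron
recordings in classical conditioning.

## The problem

In odor-conditioning experiments, midbrain dopamine neurons are recorded
while a mouse learns that odor cues (conditioned stimuli, CS) predict
water, an air puff to the eye, or nothing (the unconditioned stimulus,
US, delivered 2 s after CS onset). The analysis chain that turns such a
recording into scientific claims has many coupled stages:

1. **Optogenetic identification** — is a sorted unit a dopamine neuron?
   Decided from light-pulse trains (10 × 5-ms pulses at 1–50 Hz): a
   stimulus-associated spike-latency test (SALT) must give p < 0.001 and
   the spontaneous-vs-evoked waveform correlation must exceed 0.9.
2. **Trial-aligned response metrics** — 1-ms PSTHs, 100-ms box-filter
   spike density, epoch firing rates (CS 0–1000 ms or 200–1000 ms, US
   0–600 ms, omission 0–1000 ms, baseline −1000–0 ms), and trial-by-trial
   auROC discrimination between conditions.
3. **Population analyses** — monotonic value coding of CS responses
   (water > nothing > air puff), value-prediction-error (VPE) contrasts
   (predicted vs unpredicted outcomes; omission vs nothing), censuses of
   significantly inhibited neurons, chi-square contingency tests between
   reward contexts, and splits by trial-by-trial behavior (anticipatory
   eye blinks and licks).
4. **Eye-blink video quantification** — segmenting the eye area from
   infrared video by intensity thresholding and morphology, synchronizing
   frames to the recording clock via brief infrared-off events 2 s after
   every US, and labeling blink/no-blink trials from the normalized eye
   area in the CS–US delay.

Because raw recordings of this kind are rarely shareable, `vtapipe`
pairs the full analysis chain with a **synthetic session generator**
with known ground truth: task designs with per-odor outcome
probabilities, exponential inter-trial intervals truncated at 15 s,
tonic-plus-phasic dopamine spike trains whose CS response follows the
integrated value V(odor) = P(water)·v_w + P(airpuff)·v_a and whose US
response follows the prediction error (outcome value − V), light-locked
spiking for tagged units, lick trains, and rendered eye video with
blinks and infrared-off frames. Every stage of the pipeline is tested
against this ground truth.

The central model for a simulated dopamine neuron is an inhomogeneous
Poisson process with rate

```
r(t) = max(0,  b  +  c·k_early(t − t_CS)  +  g·V·k_CS(t − t_CS)
              +  g·(v_outcome − V)·k_US(t − t_US))
```

where `b` is the tonic baseline, `g` the value gain (Hz per value unit),
`c` a short-latency excitation present only in high-reward contexts, and
the `k` are boxcar kernels. In high-reward contexts the excitation also
masks (attenuates) the negative-value CS term, degrading aversive value
coding — the context effect the population analyses are designed to
detect.

## Worked example

Simulate a 400-trial mixed-prediction session (Odor A → 25% water,
B → nothing, C → 75% air puff, D → 25% water / 75% air puff) with six
dopamine and three untagged units, then analyze it:

```
vtapipe simulate --task mixed_prediction --n-trials 400 --seed 7 --out demo_session
vtapipe analyze --session demo_session --seed 1 --out demo_report
vtapipe report --analysis demo_report
```

which prints (abridged):

```
== tagging ==
unit_id  salt_p  waveform_r  identified  latency_mean_ms  p_evoked_1hz  p_evoked_50hz
  dan00  0.0005    0.999971        True         3.986924          0.96           0.50
  dan01  0.0005    0.999993        True         3.975747          1.00           0.42
  ...
  unt00  0.6965    0.999939       False         4.856737          0.06           0.08

== population ==
  contrast  n_neurons  mean_auroc         t        p  p_bonferroni
  water_pe          6    0.737795  6.299827 0.001483      0.004448
airpuff_pe          6    0.335417 -5.425268 0.002883      0.008648
  omission          6    0.636511  9.880682 0.000181      0.000543

== census ==
  criterion  n_neurons  n_flagged
vs_baseline          6          6
 vs_nothing          6          6
```

Reading the output: all six simulated dopamine units pass the
identification criterion (SALT p = 0.0005 < 0.001, waveform correlation
≈ 1) while the untagged units do not; their evoked-spike probability
falls from ~0.96 at 1 Hz to ~0.5 at 50 Hz with ~4-ms latencies. The
population auROC for water is above 0.5 (unpredicted water excites more
than predicted water), for air puff below 0.5 (unpredicted air puff
inhibits more deeply than predicted), and for omission above 0.5
(omitted air puff raises firing relative to nothing trials) — the three
signatures of value-prediction-error coding. All six neurons are flagged
as significantly inhibited by the air-puff CS, as expected in a
low-reward context.

The same steps are available as library calls (`vtapipe.io.simulate_session`,
`vtapipe.pipeline.run_full_analysis`); see the module docstrings.

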