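# mupulse

Analysis pipeline for the EEG and psychophysical signatures of
*subthreshold* (imperceptible) electrical finger-nerve stimulation,
driven entirely by synthetic data with known ground truth.

Weak somatosensory pulses that never reach awareness still modulate the
sensorimotor **mu rhythm** — the Rolandic oscillation with alpha
(~10 Hz) and beta (~20 Hz) spectral peaks recorded over central
electrodes (C4 for left-hand stimulation).  Single subthreshold pulses
transiently *increase* mu power (event-related synchronization, ERS)
when the preceding trial was also a single pulse, while brief 7 Hz
pulse trains (eight pulses, 1 s) produce a prolonged power *decrease*
(event-related desynchronization, ERD) that outlasts the train and
biases the response to the following trial (hysteresis).  In parallel,
near-threshold target detection shifts when targets are paired with
subthreshold stimulation.  Because the underlying human recordings are
not available, every stage of the analysis is verified against a
forward model that injects these effects with known parameters.

## What the package computes

For per-subject condition maps `P(f, t)` of Morlet-wavelet power
(5 cycles, 4–30 Hz in 1 Hz steps) normalized to the pre-stimulus
baseline `B̄(f)` (−200…0 ms) as relative change `(P − B̄)/B̄`, the
group-level statistic is the **cluster-based permutation test**: a
pointwise paired *t*-map across subjects is thresholded at two-tailed
*p* < 0.05, supra-threshold points form 4-connected clusters scored by
their signed *t*-sum, and each observed cluster is referred to the
permutation null of the maximum |t-sum| obtained by exchanging the two
conditions (sign-flipping each subject's difference) with probability ½
over 1000 iterations; family-wise-error *p*-values use
`(1 + count)/(1 + n_iter)`.

Around that core: a 32-channel forward simulator (mu, occipital alpha,
blinks, evoked P60, 1/f noise), zero-phase Butterworth filtering
(1–45 Hz, order 3), downsampling to 500 Hz, ICA with operational
selection of Rolandic components (central topography, alpha+beta
spectral peaks above the 1/f fit, post-suprathreshold ERD),
back-projection, SEP averaging with the P60 window test (55–65 ms vs
baseline, paired *t*), and the psychophysical arm: staircase/constant-
stimuli thresholds, 5 × 32-trial blocks with 16 catch trials, and
detection-rate comparisons reported as relative change
`(rate_paired − rate_control)/rate_control`.

## Worked example

```python
from mupulse.pipeline import run_contrast_recovery, run_behavior_experiment
from mupulse.params import SubjectParams

res = run_contrast_recovery(n_subjects=40, trials_per_cond=60, seed=42)
c = res["train_vs_baseline"].clusters[0]
print(f"train ERD cluster: t-sum {c.t_sum:+.1f}, p_FWE = {c.p:.4f}")

st = run_behavior_experiment(
    "A2", seed=0,
    params=SubjectParams(effect_shift={"single_60ms": 0.065}))
print(f"detection change {st.mean_relative_change:+.2%}, "
      f"t({st.df}) = {st.t:.2f}, p = {st.p:.4f}")
```

prints (seed 42 / seed 0):

```
train ERD cluster: t-sum -12987.5, p_FWE = 0.0010
detection change +8.78%, t(20) = 6.25, p = 0.0000
```

The train-vs-baseline contrast finds the injected negative (ERD)
cluster with the smallest p-value the 1000-iteration null can resolve,
and the behavioral experiment recovers a positive detection-rate change
of the injected order (+6.5 % in expectation; single cohorts scatter
around it).

The numbered scripts under `analysis/` run the same stages as a
narrative: paradigm generation, preprocessing/component selection, SEP
and P60 statistics, the cluster contrasts, statistical calibration, and
the six detection experiments.  They write their tables under
`results/`.

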