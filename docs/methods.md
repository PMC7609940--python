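# Methods

This note documents the generative model, the analysis operational
definitions, the numerical choices, and what the synthetic-data tests
do and do not establish about real recordings.

## Forward model

A recording is a linear mixture of four sources through fixed Gaussian
scalp topographies on a schematic 2-D projection of the 32-channel
extended 10–20 montage (no volume-conduction physics; the topographies
exist so that topography-based selection criteria are testable):

* **Central mu source** (peak at C4, spread 0.35 scalp units): a sum of
  an alpha oscillation (default 10 Hz, amplitude `mu_base_amp` = 4 µV)
  and a beta oscillation (20 Hz, 0.6× alpha), each with random phase
  and a slowly wandering envelope (low-passed noise below 0.1 Hz,
  ±25 %).  Event-dependent modulation is expressed as **power gains**:
  a gain *g(t)* multiplies the oscillation amplitude by √(1+*g*), so a
  baseline-normalized power map recovers *g* directly.
* **Occipital alpha** (peak near Oz, 10.5 Hz, 6 µV): the distractor
  rhythm the Rolandic selection has to reject.
* **Blinks**: Poisson-timed (0.2 Hz) frontopolar transients, 80 µV,
  ~250 ms wide — the target of ocular-component flagging.
* **Evoked P60**: a Gaussian positivity (FWHM 10 ms, peak 0.4 µV) 60 ms
  after every subthreshold pulse, including each of the eight intra-train
  pulses.  Suprathreshold pulses evoke a 10× biphasic response plus an
  imposed alpha+beta ERD (gain −0.4 over 0.1–0.6 s) so that the third
  Rolandic criterion is testable.
* **Noise**: per-channel white + 1/f-amplitude noise, equal power,
  total SD `noise_sd` = 5 µV.

### Event-dependent gains

* Single pulse with single-pulse history (SaS): ERS, gain +0.3 over
  0.15–0.35 s (alpha band).
* Pulse train: ERD, gain −0.3 over 0.1–2.0 s from train onset (i.e.
  lasting ~1 s beyond the 1 s train), with an additional brief beta ERD
  (half amplitude) during the train, and an exponential tail
  (τ = `hysteresis_decay` = 2 s) decaying into subsequent trials.
* Single pulse with train history (SaT): the ERS is absent, and the
  pulse *re-induces* an ERD over 0.1–0.5 s with amplitude
  `erd_gain·exp(−Δt/τ)`, Δt being the gap since the preceding train's
  end.  This is the implemented reading of the hysteresis phenomenology
  (synchronization absent after trains; a single pulse re-triggers
  desynchronization); a model in which the SaT trials carried only the
  passively decaying residual ERD leaves the residual in the SaT
  baseline as well, and baseline normalization then cancels most of the
  SaS-vs-SaT contrast — inconsistent with the phenomenon the contrast
  is meant to detect.

Timing values follow the reported phenomenology; the gain magnitudes
(±0.3) are generator parameters, not literature claims, chosen to give
single-trial SNR at which 40 subjects × 60 trials/condition detect the
effects reliably but not trivially.

### Reduced single-channel protocol

Repeated calibration analyses (type-I error, recovery rates) need
hundreds of multi-subject experiments; running the 32-channel forward
model plus ICA for each would be pointless numerical overhead, because
those analyses operate on the C4 time course after component selection.
`simulate_epochs` therefore draws labelled C4 epochs directly from the
same gain model (mu + evoked + noise, no artifacts, no mixing), at
250–500 Hz depending on the highest analysed frequency.  The full path
(simulate → filter → resample → ICA → selection → back-projection →
epoch → TFR → cluster test) is exercised end-to-end in the pipeline
tests at small size.  What the reduced protocol does **not** test:
imperfect artifact removal, component splitting, volume conduction —
all limitations shared with any forward model this simple.

## Analysis definitions

* **Filter**: third-order Butterworth band-pass 1–45 Hz, applied
  forward-backward (zero phase, so the P60 latency is not shifted; the
  effective magnitude response is squared).  Downsampling to 500 Hz by
  polyphase resampling; event times are kept in seconds.
* **ICA**: pluggable; default fixed-point FastICA (deterministic per
  seed).  Component count defaults to 16 in the pipeline (the simulated
  source space is low-rank; full rank is configurable).
* **Ocular flag**: frontally dominant topography (mean |weight| over
  the frontopolar+frontal rows > 2× elsewhere) AND sub-4 Hz power >
  3× alpha-band power.
* **Rolandic selection** (ocular components ineligible): (1) the
  component's peak-|weight| channel lies over the central region
  (C3/Cz/C4 and the FC/CP neighbours); (2) local spectral maxima in
  7–14 Hz and 15–29 Hz above a log-log linear 1/f fit, with the alpha
  excess > 0.5 (relative to the fit) and the beta excess > 20 % of the
  alpha excess; (3) mean 8–13 Hz Hilbert power in 0.1–0.6 s after
  suprathreshold pulses at least 10 % below the −0.2–0 s baseline.
  All thresholds are keyword-exposed.  Selection is monotone in the
  thresholds.  Because the generator injects a *single* mu source,
  "selected count = injected count" bookkeeping is not meaningful here;
  the tests assert the operational contract (mu selected, occipital
  rejected) instead.
* **SEP / P60**: epochs −200…2400 ms; per-epoch baseline subtraction
  (−200…0 ms) before averaging; P60 statistic = paired two-tailed *t*
  across subjects of the 55–65 ms window mean against the baseline mean
  (or a pre-component reference window).  Zero-variance differences are
  flagged degenerate rather than returned as ±∞ blindly.
* **TFR**: complex Morlet wavelets, n_cycles = 5, σ_t = 5/(2πf),
  unit energy, truncated at ±3σ_t; FFT convolution scaled by 1/rate so
  power matches the continuous-time closed forms.  Samples within one
  wavelet half-support of an epoch edge are masked invalid per
  frequency, and all statistics respect the mask — consequently epochs
  used for TFR are cut wider than the analysis window (e.g. −0.9…3.0 s
  for the train contrast) so the −200…0 ms baseline is valid at 4 Hz.
  Power maps are decimated to 20 ms steps (power at ≤30 Hz with
  5-cycle resolution varies slowly).  Baseline normalization is
  relative change (P − B̄)/B̄ with B̄ from the trial-averaged map
  (per-trial baselines amplify single-trial noise; switchable).
* **Cluster permutation**: cluster-forming threshold two-tailed
  p < 0.05 at the group df; 4-connected components per sign; null
  statistic = max |t-sum| over clusters of both signs per iteration;
  whole-map sign flip per subject (the pointwise-swap reading of the
  exchange is a documented variant, not a silent default); FWE p =
  (1 + #{null ≥ observed})/(1 + n_iter), with ties counted within a
  1e-9 relative tolerance so the identity assignment always counts.
  The a-priori window for the SaS-vs-SaT contrast is 0.1–0.4 s ×
  8–20 Hz (the value itself is this package's choice and is recorded in
  the result parameters); the train-vs-baseline window is 0.1–2 s ×
  4–30 Hz.
* **Behavior**: absolute threshold by ascending constant stimuli in
  0.1 mA steps (majority over 5 repeats), subthreshold intensity =
  0.85× threshold; 50 % point by a 1-up-1-down staircase with
  step-halving at reversals (floor 0.01 mA, estimate = mean of the last
  8 reversal intensities); five target intensities linearly spaced over
  0.90–1.10× the 50 % point.  Blocks: 5 intensities × 32 trials
  (16 paired at the design delay, 16 control) + 16 catch trials,
  shuffled.  A block with >1 catch-trial response is discarded
  (block-level, mirroring the reported per-block handling; subject-level
  discard is switchable).  Rates are pooled over the five intensities;
  the group test is a paired two-tailed *t* on the per-subject rates and
  the effect is reported as (rate_paired − rate_control)/rate_control.

## Problem sizes and calibration results

The repeated-simulation analyses use: 200 null experiments of
20 subjects (two pseudo-conditions of 30 effect-free trials, 4–30 Hz ×
0–0.5 s, 300 iterations) for type-I calibration; 50 runs of 40 subjects
× 60 trials/condition with 1000 iterations for ERS/ERD cluster
recovery; 50 repeats of 40 subjects × 360 trials for P60 power (and 50
with zero amplitude for its null); 1000 cohorts of 21 subjects for the
behavioral estimator.  These sizes are the package's documented
operating points; all are recomputed from scratch by the test suite and
`scripts/acceptance.py`, and no number stated here is asserted anywhere
without being recomputed.

Two quantitative subtleties worth knowing:

* The *relative* power change recovered from C4 underestimates the
  injected source-level gain when unmodulated broadband noise
  contributes to the band power (the measured change is diluted by
  roughly the mu-to-total band-power ratio).  Quantitative gain
  recovery is therefore asserted at mu-dominant SNR (noise 2 µV);
  at the default 5 µV the diluted value is ~−0.24 for an injected
  −0.30, while cluster detection is unaffected.
* The ratio estimator (rate_paired − rate_control)/rate_control is
  slightly biased upward at finite trial counts (Jensen); with 480
  control trials per subject the bias is well inside the ±0.01
  acceptance band around the injected +0.065.

## Known limitations

Fixed topographies and instantaneous mixing (no realistic volume
conduction), one mu source per hemisphere, no EMG or line noise, no
eye-tracking, reaction times modelled as constant + jitter only,
detection modelled as a stationary logistic observer without lapses,
sensitivity/criterion (SDT) decomposition out of scope by design.
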