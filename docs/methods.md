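# Methods

This note documents the models, parameter choices and numerical decisions
behind `screamsleep`, and what the synthetic-data validation does and does
not establish about real recordings.

## The analysis model

The pipeline quantifies auditory responses in polysomnographic EEG along
three complementary axes:

1. **Oscillatory power.** Continuous EEG is convolved with complex Morlet
   wavelets on a 1–30 Hz grid (1 Hz steps).  Wavelet time resolution is
   parameterized directly by the Gaussian envelope's full width at half
   maximum, decreasing linearly from 1 s at 1 Hz (one cycle) to 0.33 s at
   30 Hz (~10 cycles).  Power is `10·ln(|z|²)` — a natural-log "decibel";
   the conventional `10·log10` is available via `db_log10` and differs only
   by the constant ln 10 — baseline-corrected per trial, channel and
   frequency by the mean over −0.5–0 s, and averaged within the canonical
   sleep-research bands: delta 1–4, theta 4–8, sigma 12–15 Hz (inclusive
   integer bins, so theta = {4,5,6,7,8}).
2. **Phase consistency.** Inter-trial phase coherence is the resultant
   length of unit phasors across trials, ITPC(f,t) = |Σₖ e^{iφₖ(f,t)}|/N,
   computed per participant and condition (a first-order statistic), then
   corrected by the mean ITPC over −1–0 s.  Under random phases its
   expectation is √(π/4N), which the tests verify; the baseline subtraction
   removes exactly this trial-count-dependent floor.
3. **Feature dependence.** At each time point, frequency and electrode,
   single-trial power is regressed on the z-scored stimulus feature
   (roughness or pitch; sample SD, n−1).  The OLS slope (β, dB per SD) is
   the participant's first-order statistic.

Channels are averaged *after* the per-channel first-order computation.
Second-order inference uses cluster-based sign-flip permutation across
participants: point-wise paired two-tailed t-tests at α = 0.05, clusters as
runs of consecutive supra-threshold points of one sign, cluster score =
sum of t values, and a null distribution of the maximal |cluster| score
over random per-participant sign flips of the paired differences
(5000 permutations by default; p = (1 + #{null ≥ |obs|})/(1 + N)).
Power analyses are tested in 0–2 s post-onset, ERP/ITPC analyses in 0–1 s.
Effect sizes are Cohen's d = µ/s over cluster-averaged participant values.
Non-significant clusters are reported with their p rather than suppressed.

### Numerical choices

* Wavelet kernels are unit-energy; only baseline-relative dB quantities are
  interpreted, which makes the normalization immaterial.
* Convolution is evaluated in the frequency domain: each kernel's transfer
  function is an analytic real Gaussian (exactly zero phase lag).  Because
  the band is narrow, the decimated output (−2..3 s epochs at 50 Hz, factor
  10) is synthesized directly by folding the product spectrum onto the
  decimated grid — identical to convolve-then-subsample to ~1e-6 relative
  (verified against direct time-domain convolution) and an order of
  magnitude faster.  The analytic wavelet output is band-limited well below
  the 50 Hz complex bandwidth, so no extra anti-alias filter is needed.
* Trials whose epoch, padded by one kernel FWHM, touches the recording
  edges are flagged invalid, not silently truncated.
* Cluster permutation p-values use the +1 correction and a 1e-9 relative
  tolerance when comparing observed scores against the null, so the
  identity permutation always counts (without it, last-ulp differences
  between two algebraically equal computations can drop exact ties).
* Zero-variance, zero-mean paired differences (e.g. a condition compared
  with itself) yield t = 0 and no clusters; zero variance with nonzero
  mean is an error.
* The dB transform floors |z|² at the smallest positive float; with real
  or synthetic EEG noise this floor is never reached in practice.
* Regression betas are computed on *uncorrected* dB power: an OLS slope is
  invariant in expectation to per-trial constant offsets, and the
  single-trial baseline estimate (0.5 s of noise-dominated pre-stimulus
  power) would only add variance — ln of a noise-dominated power
  coefficient has an SD of ~12.8 dB regardless of scale, and at spindle
  frequencies the wavelet's ~0.7 s FWHM leaves roughly one independent
  baseline sample.  Condition-mean power contrasts, where the baseline is
  definitional, keep it.
* Filters are second-order-section Butterworth designs; `order` counts
  poles per band edge (the convention of clinical EEG reports), and
  zero-phase filtering applies the filter forward and backward, doubling
  the effective order.  Stability is checked from the section poles.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with every injected parameter recorded as ground truth.

**Stimuli** are sine-ramped amplitude-modulated harmonic complexes (750 ms,
100 ms quarter-sine ramps, common RMS), not recorded voices: the analysis
consumes only roughness and pitch scalars, and synthetic clips give full
control of both.  Scream/neutral pairs share a carrier F0 drawn log-normally
(median ≈ 620 Hz, clipped to 300–1400 Hz — high, variable pitch with the
heavy right tail typical of screamed vocalizations, kept inside the F0
estimator's 40–1500 Hz search range).  Screams carry AM at 40–110 Hz with
depth 0.6–0.95; neutral clips modulate at 3–10 Hz (prosody-like) with depth
0.1–0.3, leaving the 30–150 Hz roughness band empty.  The AM rate is kept
below 0.18·F0: rough vocalizations modulate slower than their pitch, and
faster deep AM would make the clip's period — hence its pitch — genuinely
ambiguous.  Roughness ground truth is taken from the package's own MPS
estimator applied to the rendered clip (closing the loop), not from the
AM depth.

**Sessions** follow the stimulation protocol structure: blocks of 22
stimuli with uniform 5–11 s jitter after each offset, wake blocks first,
then NREM blocks after a single N1 transition epoch, over a repeating
N2/N2/N2/N3/N3 scoring-epoch cycle.  The EEG background is unit-variance
1/f^α Gaussian noise (α = 1 by default, flattened below 0.5 Hz) scaled to
15 µV per channel.  Spontaneous oscillations are Poisson events per
scoring epoch: spindles (12–15 Hz, ~1 s, ~15 µV; 3/min in N2, 1.5/min in
N3) and slow waves (one 0.6–1.1 Hz cycle; 40 µV at 3/min in N2, 75 µV at
8/min in N3).  These densities are literature-plausible defaults — the
analysis places no constraint on background sleep EEG — and configurable.

**Injected responses** per stimulus, by the stage at onset:

* wake — an N1-P2-N2 evoked-potential kernel (8 µV) and a phase-locked
  theta burst;
* N2/N3 — the theta burst (×1.3 amplitude; phase locking ×0.6), an evoked
  delta wave (one 1 Hz cycle from 0.2 s, 40 µV), and a non-phase-locked
  sigma burst (13.5 Hz under a plateau envelope 0.6–1.4 s with 0.2 s
  cosine ramps).

The theta burst's phase is von Mises with κ = κ₀ + g·z (κ₀ = 1, g = 0.8
per SD of roughness), so its noise-free ITPC is the Bessel ratio
I₁(κ)/I₀(κ), which the tests verify against the generator's recorded
phases.  Sigma and delta amplitudes scale as exp(g·z/20) with g in
(10·ln)-dB per SD — exactly the linear-in-z dB model the regression fits —
with default g = 1 dB/SD for both.  The sigma burst's 28 µV base amplitude
(top of the physiological spindle range) makes it dominate background
sigma power in its latency window, so the injected dB slope is, to within
a few percent, the slope of the recorded signal; weaker bursts would
attenuate every slope estimate by the background fraction.  All response
topographies are dipolar and zero-mean across the montage (scalp fields
referenced to the common average sum to zero), so common-average
re-referencing leaves them unchanged; channel magnitudes stay ≥ ~0.5 so
every channel carries signal.

**What the generator does not emulate:** realistic vocal-tract acoustics,
EOG/EMG physiology (placeholder channels), non-stationary background
(stage transitions change only the oscillation events, not the 1/f floor),
K-complexes as distinct from generic slow waves, micro-arousals beyond
optional spike artifacts, and between-participant heterogeneity of effect
sizes (all participants share the configured gains; only noise differs).
Passing tests therefore demonstrate that the *pipeline* is correct and
well-calibrated under the assumed signal model — not that real data will
show these effects, nor that the printed roughness scale of any particular
deposited stimulus set is reproduced (the roughness a.u. depends on
spectrogram and normalization choices that differ across implementations;
only gain-invariance, orderings and monotonicity are contractual).

## Validation studies and problem sizes

`tests/test_acceptance.py` and `scripts/acceptance.py` run the same
studies; sizes are chosen so a full run stays within minutes on one CPU:

* **Type-I error.** 500 null simulations of 15 participants × 50 time
  points of AR(1) noise (φ = 0.8, 0–1 s at 50 Hz), 1000 permutations each;
  the family-wise rate of any p < 0.05 cluster must fall in the 95%
  binomial interval [0.031, 0.072] around the nominal 0.05.
* **Exhaustive agreement.** For n = 5 participants the Monte-Carlo p is
  compared with the exact 2⁵-pattern sign-flip enumeration (within 0.02).
* **Slope recovery.** Twenty single-participant NREM sessions of ~200
  trials with an injected sigma slope of 0.2 dB/SD; the mean recovered
  band-averaged β over the burst plateau (0.7–1.3 s) must lie within
  ±0.05 of truth, and within ±0.02 of zero when the injected slope is 0.
* **Detection calibration.** Twenty datasets of 15 participants × ~44 NREM
  trials at generator defaults; the screams-vs-neutral theta-ITPC cluster
  (0–1 s) and sigma-power cluster (0–2 s) must each be detected in ≥ 90%
  of datasets, and in ≤ 10% when all effect gains are zero.  The reduced
  trial count per dataset (the study protocol yields several hundred per
  night) raises sampling noise; the default effect gains are set so the
  generated screams-vs-neutral sigma difference (~1 dB) sits at the upper
  end of the range such experiments report, keeping the reduced datasets
  adequately powered.

## Design choices where the design was open

* Visual artifact rejection and micro-arousal exclusion are replaced by
  deterministic thresholds (±300 µV absolute, 1 µV flatness), with a
  participant-level QC failure below 100 clean trials.  Thresholds are
  config parameters and reported in QC output.
* Sleep-stage epochs are half-open intervals [k·20, (k+1)·20) s; N1
  onsets are excluded (neither wake nor consolidated NREM); pre- and
  post-sleep wake trials are pooled.
* Roughness and pitch enter separate simple regressions by default (the
  stimulus design makes them nearly orthogonal); joint two-regressor OLS
  is available (`feature2=`).
* Point-wise tests are two-tailed with a max-|cluster| null spanning both
  signs — the conservative standard when positive and negative clusters
  are both of interest.
* ITPC baseline subtraction is applied per channel and frequency before
  channel averaging.
* The MPS spectrogram uses short 10 ms Hann windows at a 640 Hz frame rate
  (long windows would low-pass the envelope and erase the roughness band),
  log-amplitude compression with a gain-invariant relative floor, and
  normalization by total modulation power, making roughness a relative,
  gain-invariant log measure.
* The user interface is the library plus the numbered scripts under
  `analysis/`; no console entry point is installed.

## Known limitations

* The cluster test controls family-wise error per contrast; no correction
  across the contrast manifest is applied (matching standard practice of
  reporting each contrast separately).
* Slope estimates carry a small attenuation bias (background power
  fraction in the analysis window); with default generator settings it is
  ~5–10% of the injected slope.
* EDF output quantizes to 16 bits over each channel's observed range;
  round-trips are exact only to that quantization.
* The YIN-style F0 estimator assumes quasi-harmonic input; for deeply
  amplitude-modulated sounds it includes a subharmonic-disambiguation step,
  but clips whose AM rate approaches their F0 remain intrinsically
  ambiguous (the generator avoids that regime by construction).
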