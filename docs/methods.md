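# Methods

This note documents the models, algorithms and numerical choices behind
`betafeedback`: a simulation and analysis package for closed-loop
neurofeedback experiments that target subthalamic (STN) beta bursts recorded
from externalized DBS electrodes in Parkinson's disease.

## The online loop

The neurofeedback signal is the average power of a patient-specific 5 Hz beta
band `[f−2, f+2]` (center `f` between 13 and 30 Hz) in the selected bipolar
STN LFP channel, recomputed every 250 ms over the trailing 500 ms of signal:
mean subtraction, a zero-phase 4th-order 5–85 Hz Butterworth band pass, an
untapered FFT power spectrum (2 Hz bin spacing for a 500 ms window), and the
mean of the bins whose centers fall inside the band.  During each session's
30 s rest period the same update runs on windows fully contained in the rest
segment — `floor((30 − 0.5)/0.25) + 1 = 119` updates — and the burst
threshold `T` is their 75th percentile (linear interpolation between order
statistics).  By construction, resting beta power exceeds `T` one quarter of
the time.

During a feedback phase of duration `D ∈ [4, 8]` s there are `D/0.25`
updates (16–32), each computed on the trailing 500 ms so the loop is causal.
The ball drops one step whenever an update exceeds `T`; the step is
`y0 / ceil(0.25 · n_updates)`, so crossing on exactly a quarter of the
updates — the resting expectation — parks the ball at the bottom at phase
end.  The ball's height is floored at 0 and x advances uniformly.  Counting
conventions (fully-contained windows for calibration, trailing windows for
feedback) reconcile the 119-update calibration count with the 16–32 update
feedback counts.

## Offline spectral analysis

Signals are band-passed 0.5–100 Hz and notch-filtered 48–52 Hz (zero-phase
4th-order Butterworth, applied forward–backward).  Time–frequency maps use
continuous complex Morlet wavelets on a 1–95 Hz grid with 1 Hz resolution
and cycle counts linear from 4 (at 1 Hz) to 8 (at 95 Hz).  Wavelets are the
standard zero-mean L2-normalized Morlets (constructed with MNE); the
convolution itself is a batched FFT implementation, verified in the test
suite to match `mne.time_frequency.tfr_array_morlet` to machine precision —
the batching is what keeps a 21-hemisphere study on one CPU tractable.
Wavelets span ±5 temporal standard deviations, so the 1 Hz wavelet needs
≈6.4 s of signal; per-trial maps are therefore computed on a padded context
(3.4 s before the feedback phase to 0.3 s after the cue) and windowed
afterwards, which also keeps the 2 s pre-cue carry-over window free of edge
bias for all bands ≥3 Hz.

Power is normalized per frequency as percent change against the mean power
over the experiment's rest period, `(P − P_rest)/P_rest × 100`.  Band powers
are means over the band's integer-frequency bins and the analysis window:
the patient beta band, alpha 8–12 Hz, theta/tremor 3–7 Hz, broad gamma
55–95 Hz, and the `Beta−8`/`Beta+8` control bands obtained by shifting the
beta band by ∓8 Hz on the integer grid.  (Non-integer control-band centers
cannot be represented on a 1 Hz grid; the integer shift is used throughout.)
Inputs to the mixed models use `10·log10` of raw (unnormalized) band power,
in dB.

### Burst quantification

The beta envelope is the Morlet magnitude averaged over the five band bins,
smoothed with a 200 ms moving average — the smoothing that standard
beta-burst analyses apply before thresholding.  Without it, within-burst
interference dips fragment supra-threshold runs and roughly triple the
apparent burst rate.  The offline threshold is the 75th percentile of the
smoothed rest-period envelope, recalibrated per session like its online
counterpart.  A burst is a maximal contiguous supra-threshold run; runs
truncated by the analysis window are counted at their truncated length
(unbiased accumulated time is prioritized over unbiased durations).
Reported metrics: accumulated supra-threshold time (% of window), mean run
duration (undefined when no run; reported as missing), runs per second, and
a duration histogram with a ≤400 ms / >400 ms split — long bursts are the
ones most consistently suppressed by training.

### Connectivity

From the complex maps of the STN LFP and the ipsilateral motor-cortex EEG,
per frequency over the `n` time points of the first 4 s of the feedback
phase:

* phase synchrony index `PSI = |n⁻¹ Σ_t exp(i(φ_lfp(t) − φ_eeg(t)))|`,
* coherence `Coh = |n⁻¹ Σ_t m_lfp m_eeg e^{iΔφ}|² / [(n⁻¹ Σ m_lfp²)(n⁻¹ Σ m_eeg²)]`,

both averaged over the band bins afterwards.  Both lie in [0, 1], equal 1
for identical signals, and are invariant to per-channel positive rescaling.
Because the phase is that of the total signal, in-band background noise
attenuates PSI below the generator's coupling parameter; recovery of PSI = 1
is exact only as in-band SNR grows (this is a property of the estimator on
real data too, not an artifact of the simulation).

## Behavior

Reaction time: the pinch force is low-pass filtered at 20 Hz (zero-phase
4th order), epoched −1 to +3 s around the Go cue; the onset threshold is the
mean + 3 SD of the 500 ms pre-cue force, and the RT is the first post-cue
crossing sustained ≥100 ms.  No qualifying crossing within 2 s is a miss.
Trials are excluded when missed, faster than 200 ms (anticipation), or
artifact-flagged; exclusion records exactly one reason and is idempotent.
Tremor is the 3–7 Hz band power of each accelerometer axis (4th-order
zero-phase band pass, mean square), averaged across the three axes and
expressed as percent change versus the rest reference — the same convention
as the LFP normalization.  EMG amplitude is the mean rectified signal after
a 20 Hz high pass.

## Statistics

Condition contrasts at the hemisphere level use a paired t-test when an
Anderson–Darling test (5 % level) does not reject normality of the paired
differences, otherwise a Wilcoxon signed-rank test; Bonferroni correction
multiplies p by the family size.  Correlations are Pearson.

Reaction times are right-skewed, so RT models are generalized linear mixed
models with an inverse-Gaussian response and identity link: fixed slopes
shared across hemispheres, a random intercept per hemisphere.  No installed
package fits this model, so the package maximizes the marginal likelihood
directly, integrating the random intercept with a per-group Laplace
approximation (inner Newton steps on the group mode with expected-information
curvature; outer Nelder–Mead then BFGS on fixed effects, log dispersion and
log random-intercept SD).  Standard errors come from the numerical Hessian
(pseudo-inverse when a variance component sits on the boundary); p-values
are Wald.  Estimation is plain ML — not REML — so AIC comparisons across
fixed-effect structures are valid.  R² is the squared correlation between
conditionally fitted (fixed + predicted random intercept) and observed
responses.  The gaussian-response branch (tremor, carry-over and day models;
their responses are already normalized percent changes) delegates to
`statsmodels` MixedLM with ML.  Cross-checks in the test suite: the
inverse-Gaussian branch against `statsmodels` GLM (inverse Gaussian,
identity) when the group variance is zero, and parameter recovery on data
simulated from the model.

The model registry covers the RT family (condition, pre-cue beta/gamma/alpha
LFP power, pre-cue burst metrics, EEG beta/alpha, and their combinations),
the tremor model (condition + beta + theta), carry-over models (2 s pre-cue
measures against feedback-phase measures and against condition), and two-day
learning models (condition-difference of ball height / beta / accumulated
burst duration against day).

The beta-matched control selects 75 % of the smaller condition group by
greedy nearest-neighbour matching on normalized beta power without
replacement, asserts the matched means differ by <0.1 pooled SD (a failed
balance check raises a diagnostic error rather than silently reporting an
unbalanced contrast), and re-tests RT, gamma and tremor on the matched
subgroups.

## The synthetic-data generator

Each hemisphere-session is built at 2048 Hz from:

* **LFP** — unit-RMS 1/f background (spectral exponent 1, flattened below
  0.5 Hz) plus a white floor (0.15); a narrowband beta carrier (unit-modulus
  phase dynamics, 1.3 Hz linewidth) with amplitude
  `beta_level · (AM(t) + E(t))`, where AM is a slow lognormal-like
  modulation (τ = 0.7 s, depth 0.25) of the continuous beta and `E` is the
  burst envelope; broadband 55–95 Hz gamma; and a theta oscillation at 5 Hz
  with a slowly drifting envelope.
* **Bursts** — a renewal process: exponential gaps measured from burst end
  (so bursts never overlap), with mean gap set to give the configured burst
  rate; gamma-distributed durations; lognormal per-burst plateau amplitudes
  (σ = 0.3) times `beta_burst_gain = 5`; raised-cosine 50 ms on/off ramps to
  avoid spectral splatter.
* **EEG** — its own 1/f background and alpha, plus a beta component whose
  phase equals the LFP carrier phase plus a slow offset process whose
  circular spread is chosen so the time-averaged phasor magnitude equals the
  configured coupling (wrapped-normal: σ² = −2 ln ψ); its amplitude partly
  tracks the LFP bursts.
* **Accelerometer** — three axes with fixed loadings; the tremor-band
  oscillation amplitude is `tremor_coeff_theta` times the LFP theta
  envelope, so STN theta power and measured tremor co-vary.
* **Force** — near-zero baseline noise; each pinch is a raised-cosine rise
  over 150 ms to a unit plateau starting at the trial's latent reaction
  time (the sharp, noise-free onset makes the mean + 3 SD rule well-defined).
* **Reaction times** — inverse-Gaussian draws (shape λ = 20 s) with mean
  `0.511 − 0.0154·[Training] + 0.0061·(β_dB − β̄) − 0.0085·(γ_dB − γ̄)` s,
  using the trial's latent pre-cue beta and gamma power; the slope and
  condition-effect defaults are taken from the empirical RT models, so the
  simulated study reproduces the reported effect directions and approximate
  magnitudes.

Condition presets: the "No Training" feedback phase uses the
passively-observed burst statistics (0.531 bursts/s, 377.2 ms mean duration,
SD 0.2 s); "Training" uses the volitionally suppressed statistics
(0.446 bursts/s, 319.6 ms, SD 0.18 s) with raised gamma (×1.12 amplitude)
and raised theta/tremor drive (×1.35).  **Rest is busier than the task**
(0.61 bursts/s, 0.41 s): engaged observation already lowers beta relative
to rest, which is what makes the task-phase accumulated supra-threshold time
(~21 %) sit below the rest-calibrated 25 %, as observed empirically.  The
rest preset, the beta-to-background ratio and the burst gain were calibrated
once, before the test expectations were frozen, so that the offline
quantifier run on the "No Training" preset reproduces that condition's
published burst statistics; they are study conditions, not per-run tuning
knobs.

Everything is driven by one `numpy` Generator seeded from the config, so a
(config, seed) pair reproduces sessions, trial tables and figures
bit-identically.

### What the generator does not emulate

Common-average-referencing hardware, realistic EMG bursting, stimulation
artifacts, non-stationary electrode drift, volume conduction, and true
neural dynamics (the burst process is phenomenological).  Passing recovery
tests therefore shows that the pipeline measures what the generator encodes
under realistic spectra and SNR — not that the biological claims hold; on
real recordings, artifact rejection and channel selection quality will
dominate in ways the simulation cannot probe.

## Problem sizes

Desk-scale defaults keep every experiment on one CPU: the cohort study
simulates 21 hemispheres × 1 session × (10 + 10) trials; burst-statistics
recovery uses 1,600 four-second epochs across 800 session-style calibrations;
threshold-exceedance checks use 10,000 held-out updates against 100
independent 119-update calibrations; the test suite runs reduced versions of
the same experiments at 512 Hz.  The analysis windows are the first 4 s of
each feedback phase and the 2 s pre-cue carry-over window.

## Known limitations

* The online path assumes drift-free amplifier gain within a session;
  between-session drift is handled, as in the experimental protocol, by
  recalibrating `T` each session.
* The inverse-Gaussian Laplace fit can sit on a variance boundary when the
  true random-intercept variance is ~0; estimates remain valid but the
  corresponding SE is reported from a pseudo-inverse.
* `Beta±8` control bands use integer-grid shifts, so their centers differ
  by up to 0.5 Hz from non-integer conventions.
* With `coupling_psi = 1`, estimated PSI saturates near 0.8 at realistic
  in-band SNR (noise-phase attenuation); the estimator, not the generator,
  sets this ceiling.
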