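# Methods

This note records the models, estimators, numerical choices and known
limitations behind `sdsephys`, in the order the pipeline applies them.

## Synthetic data model

The generator is the pipeline's data source and its test oracle: every
injected feature is recorded in a ground-truth object.

**LFP/EEG sessions.** A session is `background + Σ components + artifacts`.
The background is 1/f^α noise (α = 1 by default) produced by spectral
shaping of white noise and scaled to a target SD in mV. Each oscillatory
component is either a pure sinusoid (bandwidth 0, peak amplitude in mV) or
band-limited Gaussian noise (RMS amplitude in mV) confined to
`center ± bandwidth/2`. Drug effects are multiplicative amplitude gains per
component, applied as a step at the drug time — no pharmacokinetic ramp is
modeled because none is specified for the study design being emulated.
Artifact epochs add a square 5-mV-scale deflection to the signal channel
and/or multiply the EMG noise SD, so the amplitude and movement masks can
be exercised independently. Defaults follow the emulated design: 60-min
sessions, drug at 30 min, LFP at 2 kHz or EEG at 400 Hz, theta and beta
components over the 1/f floor.

**Patch-clamp traces.** A trace is
`holding baseline + Gaussian noise + Poisson sIPSC train + tonic steps`,
with every GABAergic term (events, baseline tonic, drug tonic shift)
zeroed after bicuculline onset. Events are difference-of-exponential
kernels (rise 1 ms, decay τ = 10 ms by default, rise chosen 10× faster
than decay), inward (negative), with log-free amplitude jitter
(CV 0.3, floored at 5% of the mean). The config field `baseline_tonic_pA`
carries the pre-drug tonic current; it is required for a nonzero
"pretonic" measurement, since that quantity is defined as the
bicuculline-induced shift from the pre-drug baseline. Defaults: 360-s
recordings at 10 kHz (40 kHz available), drug at 60 s, bicuculline at
300 s, −10 pA baseline tonic, −15 pA drug shift, 1.3× amplitude and τ
gains on post-drug events.

**Behavior cohorts.** Each mouse draws a latent depression state with
probability `p_depressed` (default 0.7 — a typical susceptible fraction
for this paradigm; the emulated study reports none). dSIT1 is
`sit_base_s` (80 s of the 150-s trial) plus noise; depressed mice have
dSIT2/dSIT3 reduced by `depression_drop_frac` (0.5), resilient mice drift
up by 20%. All SIT times are clipped to [0, 150] s. Depressed mice are
assigned round-robin to arms; post-drug SIT times add the per-arm, per-day
treatment effect (+40 s for allopregnanolone from day 1, 0 for vehicle and
diazepam) with measurement noise SD 15 s, matching the arm size (13) and
noise scale of the emulated design. With noise, the classifier's
false-positive and false-negative rates nearly cancel, so the classified
fraction tracks `p_depressed` to within binomial error; with zero noise
the match is exact.

What the generator does **not** emulate: non-stationary behavioral states
(sleep/wake), electrode drift, line noise, seasonal/circadian structure,
correlated multi-channel noise, IPSC rise-time variability, and
pharmacokinetic onset/washout. Passing tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
every artifact of real recordings.

## Artifact masks and the inclusion rule

Bins are half-open 1-s intervals `[t, t+1)`. "Exceeds 2 mV" is read as the
maximum **absolute** amplitude in the bin strictly above threshold
(artifacts are taken as symmetric). The EMG is high-passed with a
4th-order zero-phase Butterworth at 100 Hz (only the cutoff is prescribed;
the order and zero-phase application are this package's choice), RMS is
computed per bin, and the threshold is the mean + 1 SD over **all** bins
of the session (population SD). Ties never exclude: both rules use strict
inequality, as does the < 10% inclusion rule.

The inclusion gate is applied to the amplitude mask. The rmsEMG rule by
construction flags the upper tail of the rms distribution (~16% of bins
for stationary EMG), so gating on the union would reject every recording;
movement bins are instead repaired by interpolation like amplitude bins.

Interpolation acts on **per-bin series** (normalized band power), not raw
samples: exclusion is defined per bin, and sample-level interpolation
would distort spectra. Excluded bins are filled linearly between the
nearest included neighbors; leading/trailing gaps take the nearest
included value (linear interpolation is undefined with one neighbor).
Values inside excluded bins can influence results only through nothing at
all — the series is overwritten before any summary.

## Spectral estimation

Each 1-s bin gets a periodogram at 1-Hz resolution with a Hann taper and
amplitude correction ('spectrum' scaling: a tone of amplitude A yields
A²/2 at its bin); a rectangular window is available and makes the per-bin
power sum equal the time-domain mean square (Parseval). Band edges are
half-open (theta [6, 12), beta [15, 30)) so no frequency is double-counted.
Normalization divides per-bin band power by total power over 1–100 Hz by
default — DC and the line-noise-dominated high end are excluded, and the
exact range is configurable because only "total power" is prescribed. The
pre window is [drug − 15 min, drug); the post window [drug + 15 min,
drug + 30 min).

Normalized ratios are scale-invariant but compress multiplicative band
effects: a gain g on a band that contributes a non-negligible share of
total power raises the denominator too, so the normalized post/pre ratio
is below g². `raw_band_power` exposes the unnormalized per-bin band power
for effect-recovery checks; the injected √2 amplitude gain is recovered as
a raw-power ratio of 2.0 within simulation error.

## Tonic current

Epoch means (10 ms every 100 ms, tiled from t = 0, epoch centers as
timestamps) are histogrammed with Freedman–Diaconis bins (fallback to 8
bins for degenerate spreads) and fit with a Gaussian by nonlinear least
squares, initialized at the sample mean/SD. A constant sample
short-circuits to (value, 0) without fitting. Fit goodness is the R² of
the histogram fit; below 0.8 a `GaussianFitWarning` is emitted (bimodal
holding currents fall well under this; clean Gaussian windows of ≥ 300
epochs sit well above it). Tonic current is `μ_blocked − μ_condition`,
reported positive for inhibitory current; the estimator depends only on
differences and is exactly translation-invariant. The "pretonic" window is
the 30 s immediately before drug onset and the "posttonic" window the last
30 s before bicuculline, both paired against the 30 s after bicuculline;
window placement is configurable since the emulated procedure does not pin
the pre-drug window. IPSC-containing epochs are not removed before
fitting — the Gaussian fit to the histogram mode is robust to the skewed
event tail (with 2 Hz events the bias is < 0.5 pA at default settings).

## sIPSC detection and kinetics

The trace is low-passed at 1 kHz (4th-order zero-phase Butterworth, when
the sampling rate allows) and baseline-subtracted with a chunked running
median (100-ms chunks, linearly interpolated), which tracks tonic steps
while ignoring sparse events. Detection uses a sliding-template
(Clements–Bekkers) criterion: a peak-normalized difference-of-exponentials
template with a 5-ms flat pre-onset pad is least-squares fit (scale +
offset) at every offset, and candidates require the t-like criterion
`scale/SE(scale) > 4`. A bare 3×SD threshold crossing cannot meet a
0.05-Hz false-positive budget — level-crossing theory puts the noise
upcrossing rate at ~0.6% of the filtered bandwidth, i.e. of order 1/s —
so the template criterion does the noise rejection, and two amplitude
rules prune the candidates: the fitted scale and the peak's rise above the
local pre-onset baseline (median of the preceding 3 ms) must both exceed
3× the MAD-based robust noise SD. The local-rise rule removes "echo"
detections riding a preceding event's decay; the flat template pad makes
the criterion rise-sensitive in the first place. Minimum inter-event
interval is 5 ms.

Decay fitting: single exponential from the measured peak over a window of
5× an initial τ guess (from the 63%-decay crossing), truncated at the next
event onset, with τ bounded in [0.1 ms, 1 s]. Failed fits keep the event
with τ = NaN and are excluded from mean τ. At the reference condition
(amplitude 5× noise SD, 1 Hz, τ = 10 ms) recall and precision are ≥ 0.96
and fitted τ is within 3% of truth; fully blocked segments yield no
detections at default settings.

## Statistics

Thin wrappers with explicit contracts: paired and unpaired t (Welch by
default — equal variances are not assumed; the classic pooled test is an
option), Tukey's HSD via Tukey–Kramer q statistics against the
studentized-range distribution (cross-checked against an independent HSD
implementation in the tests), Sidak's closed form `1 − (1−p)^m`, and
Dunnett's many-to-one test via the multivariate-t distribution with a
fixed quasi-Monte-Carlo stream (adjusted p reproducible and accurate to
~10⁻³). Identical paired samples return t = 0, p = 1 by convention; a
constant nonzero difference is an error (t undefined). All tests are
two-sided at α = 0.05. Under their global nulls at 10,000 replicates,
each test's type-I (or family-wise) error calibrates to 0.04–0.06. For
SIT time courses with two arms the Sidak family is the set of post-drug
days; with three or more arms Tukey is applied per day (whether days form
one family is ambiguous in the emulated design; both modes are reachable
through the API).

## Pipeline, determinism and problem sizes

`RunConfig` drives a full simulated study. Sub-seeds derive from
`SeedSequence((seed, stage, subject))`, so disabling one stage never
changes another's outputs and identical seeds give byte-identical result
tables (the manifest stores the config, its hash, and library versions —
no timestamps). Default study sizes keep a full run near a minute while
matching the emulated arm structure: 3 arms × 7 mice (EEG-rate sessions,
60 min at 400 Hz), 6 cells per arm (360-s traces at 10 kHz), and a 39-mouse
behavioral cohort; the acceptance script scales some replicate counts
(e.g. 10 tonic-recovery seeds) similarly. LFP-rate (2 kHz) sessions are a
config change.

## Known limitations

- EDF output is 16-bit; round trips are exact only to the per-channel
  quantization step. Metadata (markers, roles, subject fields) travels in
  a JSON sidecar, not in EDF header extensions.
- The Clements–Bekkers template uses fixed default kinetics (rise 1 ms,
  τ 10 ms); detection degrades gracefully for moderate mismatch (the 1.3×
  post-drug τ gain is handled) but strongly different kinetics warrant a
  re-tuned template.
- Overlapping events closer than ~5 ms merge into one detection.
- The behavioral generator emits zone-time summaries directly; video
  tracking, interaction-zone geometry and locomotor trajectories are out
  of scope.
- No coherence, phase–amplitude coupling, sleep staging or source
  localization; no receptor-kinetics pharmacology.
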