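# Methods

## Signal model and scope

`egmkit` treats a recording as a fixed-rate matrix of unipolar electrogram
channels (millivolts, typically 64 channels × 60 s at 1 kHz). All analysis
assumes the ventricular far field has been removed — either upstream or by
the package's average-template QRS subtraction — and that what remains is
quasi-periodic atrial activity with a cycle length T in the 100–400 ms
range. Times are seconds, indices 0-based, analysis intervals half-open
`[start, end)`.

## Preprocessing

* **EQI front end** (mandatory for the EQI branch): 4th-order Butterworth
  high-pass at 2.5 Hz, low-pass at 30 Hz, and band-stop 55–65 Hz (60 Hz
  regions; `notch=(45, 55)` for 50 Hz grids). All stages run zero-phase
  via forward–backward second-order sections, so deflection timing is
  preserved; the effective magnitude response is the square of the
  single-pass design. Edge transients from the forward–backward pass are
  handled by excluding 0.5 s (`edge_trim_s`) at each end from EQI
  intervals.
* **Spectral branch input**: the QRS-subtracted, mean-removed signal
  *without* the 2.5–30 Hz band-pass. The band-pass is attached to the EQI
  definition only; since the spectral branch is already restricted to
  0–20 Hz and demeaned per Welch segment, band-passing it first is nearly
  a no-op. `IndexConfig(spectral_use_eqi_band=True)` runs the other
  reading.
* **QRS subtraction**: per channel, windows of −100…+150 ms around
  externally supplied R-peak times are demeaned, averaged into a template,
  and the template subtracted at each window. Peaks whose windows overlap
  the previous one are skipped with a warning; at least 3 usable windows
  are required. Averaging N windows leaves the incoherent atrial
  contribution attenuated ≈ 1/√N in the template, which is why the
  procedure is close to idempotent. R-peak *detection* is out of scope; a
  simple threshold detector is provided as a convenience only.

## Spectral indices

Welch PSD: Hamming window, 4 s segments, 50% overlap, per-segment mean
removal (no slope detrend), one-sided, truncated to [0, 20] Hz. At the
defaults the bin spacing is 0.25 Hz and a 60 s record averages 29
segments. DF is the arg-max bin at or above `f_min_hz = 1.0` — the search
floor guards against residual low-frequency leakage and sits far below
fibrillatory rates (~5 Hz); ties break toward the lowest frequency. The
full [0, 20] band is kept for the SPI sums.

SPI boundary conventions are fixed: bin retention is strict
(`power > α·P_DF`), DF-window membership closed (`|f − DF| ≤ Δf`). The DF
bin always belongs to both sums, so SPI ∈ (0, 1], and SPI is
non-decreasing in Δf at fixed α. The `prop_one` patient aggregation counts
channels with SPI ≥ 1 − 10⁻¹², i.e. all above-threshold power inside the
window up to float noise — exact float equality would be
implementation-fragile.

The grid search sweeps α ∈ {0.02, 0.04, …, 0.50} and Δf ∈ {0.4, 0.8, …,
12.0} Hz by default, computing per-patient aggregated SPI and the
Term/NonTerm AUC per cell with the orientation fixed at lower-SPI ⇒ Term.
Orientation is declared a priori per index (EQI higher ⇒ Term, SPI and ADF
lower ⇒ Term) and never auto-flipped: flipping post hoc would bias every
reported AUC upward. Arg-max ties break toward the smallest α, then the
smallest Δf.

## EQI

Pipeline per channel: front-end filter → period estimate → dv/dt by first
difference × fs (the 30 Hz low-pass already bounds derivative noise; no
further smoothing) → consecutive intervals of width T starting at
`edge_trim_s + start_offset_s` → per-interval Q → channel EQI = mean Q.
The trailing partial interval is discarded; a trimmed 60 s record at
T = 200 ms yields 295 intervals.

**Period estimation.** The signal is smoothed by a zero-phase 4th-order
low-pass at 20 Hz, its biased autocorrelation (FFT-based, normalized to
the zero-lag value) is scanned for peaks with prominence ≥ 0.08, and T is
the lag of the *highest-valued* qualifying peak inside [0.10, 0.40] s.
Two numerical choices deserve note:

* *Highest value, not first qualifying peak.* The biased ACF decays with
  lag, so the fundamental-period peak is the tallest in-band peak (value
  ≈ 0.3–1.0). Cross-terms between signal components — e.g. between the
  activation spike and a slower repolarization wave, or between the two
  deflections of a fractionated pair — produce genuine ACF peaks at lags
  like CL − delay that *precede* the fundamental with values ≈ 0.1–0.5.
  A first-qualifying-peak rule locks onto them; the tallest-peak rule does
  not, while the [0.10, 0.40] s physiologic band still excludes harmonics
  and sub-harmonics.
* *Prominence floor 0.08.* The sample ACF of 20 Hz-low-passed white noise
  fluctuates with SD ≈ 1/√n_eff ≈ 0.02 at 60 s, producing spurious peaks
  with prominences up to ~0.07 (occasionally more). 0.08 (≈ 4 SD) rejects
  aperiodic channels while admitting every regime of the synthetic suite
  (minimum observed true-peak prominence 0.10). The floor is a threshold
  on a noisy statistic: extreme noise can still slip through, and a very
  degraded channel can fail. Channels that fail period estimation are
  excluded from the patient mean and reported, not imputed.

**Per-interval Q.** Local maxima are samples strictly greater than both
neighbors (plateaus count once); γ collects the *positive* ones, with one
occurrence of the global maximum β removed. β itself is the segment's
global maximum even when attained at a boundary sample. Q = (β − mean γ)/β;
Q = 1 when no other positive maximum exists; an interval with β ≤ 0 has no
identifiable activation and scores Q = 0 with a `no_activation` flag. The
mean (not the sum) of the γ values is the correct normalization — a raw
sum could push Q negative, contradicting its 0–1 range.

Because Q uses the *mean* of the γ values, many tiny spurious maxima pull
Q toward 1, not 0. This matters when feeding the pipeline signals with
substantial energy above the 30 Hz low-pass: the filter ringing creates
small positive dv/dt maxima that dilute mean(γ). The analytic test
fixtures therefore use deflections of σ = 15 ms (spectral content
essentially inside the pass-band) so that "one deflection ⇒ Q = 1" and
"two equal deflections ⇒ Q = 0" hold to machine precision.

## Cohort statistics

AUC is computed from the empirical ROC by trapezoidal integration
(sklearn `roc_curve`, all thresholds kept), which equals the two-sample
concordance probability with ties at one half; a Mann–Whitney rank form is
used inside resampling loops. The bootstrap CI is percentile, 10 000
replicates, *stratified by class* — plain resampling at 17/25 patients
occasionally drops a class entirely. Leave-k-out sensitivity removes k = 5
random patients per iteration (5 000 iterations), redrawing removal sets
that empty a class, and reports median and quartiles. Outlier removal is
per group: ±3 SD for groups passing Shapiro–Wilk at 0.05, else 1.5 IQR
fences. The t-test defaults to the Welch (unequal-variance) flavor; the
rank-sum test uses exact enumeration for tie-free groups of ≤ 10 and the
tie/continuity-corrected normal approximation otherwise. The logistic
adjustment check fits label ~ index + one covariate by maximum likelihood
and reports the Wald p of the index term, flagging perfect separation
instead of reporting an untrustworthy p.

## Synthetic electrograms

Each channel is a renewal-process train of activation complexes plus
noise:

* **Beat times**: i.i.d. per-beat cycle lengths N(CL, (cv·CL)²), gaps
  floored at twice the deflection width; default CL 200 ms.
* **Activation complex**: a derivative-of-Gaussian biphasic deflection
  (default σ 4 ms, 1 mV, negative lobe leading — one sharp dv/dt
  extremum), plus a slower opposite-polarity Gaussian "recovery" lobe
  (default 0.3 × amplitude, σ 40 ms, 40 ms delay). The recovery lobe is
  what puts the spectral peak at the activation rate: a bare
  derivative-of-Gaussian has a *rising* spectral envelope (peak at
  1/2πσ ≈ 40 Hz), which would place the DF at the top of the 0–20 Hz
  band instead of at 1/CL. Its amplitude is set so that the DF tracks
  1/CL while the 2nd–4th harmonics of a regular train stay above the
  α = 0.18 retention threshold over CL 182–218 ms.
* **Degradations**: per-beat amplitude jitter, extra "fractionated"
  deflections at uniform random offsets, white noise, 60 Hz mains, and an
  optional wider/slower far-field train (σ 25 ms, 70 bpm) for exercising
  QRS subtraction.

Cohort templates: the organized (Term) phenotype uses cl_jitter_cv 0.005,
no fractionation, 0.03 mV noise; the disorganized (NonTerm) phenotype
cl_jitter_cv 0.10, two extra deflections at 80% amplitude, 0.08 mV noise;
64 channels, 17 vs 25 patients, 5% between-patient parameter spread.
Under renewal dynamics, timing drift is *cumulative* — per-beat CV 0.01
already decoheres harmonics within a 4 s spectral window, and CV 0.15
smears even the fundamental outside DF ± 3.6 Hz. The template CVs are
therefore chosen to reproduce the two regimes the indices are designed to
separate (harmonic-rich narrow-peak vs broad-single-peak), not to match a
clinical per-beat CV numerically; a rate-stabilized driver in real tissue
maintains coherence at larger per-beat variability than an unanchored
renewal process does.

What the generator does *not* emulate: spatial correlation between
channels (channels are independent draws), wavefront propagation and
electrode geometry, amplitude heterogeneity across the atrium,
non-stationary rhythm changes within a recording, and realistic QRST
morphology. Passing cohort tests therefore demonstrate that the pipeline
recovers the intended ordering under controlled conditions with large
effect sizes — synthetic cohorts separate at AUC ≈ 1.0, whereas clinical
cohorts report ≈ 0.85 — and say nothing about clinical effect sizes or
about spatially structured confounders.

## Problem sizes in the test suite

The randomized range/robustness suite uses 100 channels of 60 s; the
cohort-ordering test runs 10 seeded cohorts of 42 patients × 16 channels
× 60 s with 1 000-replicate bootstrap CIs. A null AUC at 17/25 patients
has Monte-Carlo SD ≈ 0.09, so the ADF's non-discrimination is asserted on
the mean AUC across the 10 cohorts (SD ≈ 0.03) rather than per cohort,
where individual null AUCs scatter well beyond ±0.15.

## Known limitations

* EDF support is read via `mne` and written by a minimal built-in writer:
  16-bit quantization, integer sampling rates only, recordings padded to
  whole seconds. CSV is the lossless interchange format.
* The period estimator returns a single global T per channel; rhythms
  whose cycle length drifts substantially within a recording are averaged
  over, and intervals gradually desynchronize from activations (the EQI's
  start-time insensitivity bounds but does not remove this effect).
* `remove_outliers`' normality selector (Shapiro–Wilk at 0.05) is a
  convention; near the threshold the two rules can disagree on which
  points to drop.
* The logistic adjustment check is a single-covariate screen, not a
  multivariable model.
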