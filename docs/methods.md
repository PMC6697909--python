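# Methods

This note documents the models, conventions and numerical choices behind
`crackletrack`, and what the synthetic-data tests do and do not establish
about real recordings.

## Recording model and conventions

Audio is single-channel PCM WAV; integer samples are rescaled to
[−1, 1). Times are seconds, sample indices 0-based, and **all intervals
are half-open `[start, end)`**, so a phase boundary sample belongs to the
following phase. Breath phases come from the paced-breathing protocol
(default 8 breaths, 2 s inspiration + 2 s expiration, starting at t = 0)
or from annotation CSVs; no automatic phase segmentation from audio is
attempted, because envelope-based segmentation would add an unvalidated
stage ahead of every timing feature. Multichannel files are rejected by
default (`first_channel` and `split` policies available): the protocol
records one site per file and silent downmixing would corrupt features.
Absolute calibration (a 94 dB / 1 kHz reference) is metadata only — every
reported feature except the raw deflection amplitudes is invariant to
positive rescaling, and amplitudes enter the analysis only as the ratios
A2/A1 and A3/A1.

## Band limiting

Breath sounds are band-limited to 100–2000 Hz with a 4th-order
Butterworth filter applied forward–backward (`sosfiltfilt`). Zero-phase
filtering is essential: group delay would bias every onset-timing
feature. The filter family and order are not dictated by any measurement
standard; Butterworth order 4 was chosen for a flat passband (passband
tones preserved within 5%) with ≥ 20 dB attenuation at 50 Hz after the
double pass. Note that zero-phase filtering is acausal: a strong
transient acquires a low-frequency pre-ring *ahead* of its physical
onset, which constrains how onsets may be localized (below).

## Crackle model

The synthetic crackle is an exponentially damped sinusoid

    s(t) = A · polarity · sin(2π f₀ t) · e^(−t/τ),  t ≥ 0

the simplest waveform with the classical deflection anatomy and
closed-form metrology: zero crossings at k/(2f₀), hence IDW = 1/(2f₀),
2CD = 2/f₀, and deflection peaks at tan(2π f₀ t) = 2π f₀ τ, giving
A2/A1 = e^(−1/(2 f₀ τ)) analytically. Generated supports run to 16 τ so
the truncation step is ~e^(−16) of the peak and cannot register as a
transient. Fine-crackle morphology corresponds to f₀ ≈ 200–800 Hz and
τ ≈ 2–10 ms (2CD 2.5–10 ms).

## Breath-noise fixture and SNR

Synthetic breath sound is white noise band-limited to 100–1000 Hz with a
half-sine amplitude envelope per phase, expiration at 40% of the
inspiratory gain. This emulates the spectral tilt and periodicity of
vesicular sound; it does **not** emulate heart sounds, ambient noise,
friction artifacts, or breath-to-breath variability, so detector
performance on the fixture is an upper bound for real recordings.

**SNR definition.** `snr_db` is the ratio of the *mean crackle power* to
the *breath-noise power*, both measured over the 20 ms window starting at
the crackle onset. (A peak-power definition was considered and rejected:
for a τ = 5 ms crackle inside the noise band, peak-power 10 dB puts even
the optimal matched-filter deflection √(2E/N₀) near 4.7 — an operating
point where no detector can reach 90% recall and precision. The
window-power definition is the standard energy SNR and makes the
detector's validated operating range meaningful.) Crackle amplitudes are
scaled per event against the local noise power, so the difficulty knob is
uniform across the envelope.

## Crackle detection

Detection must find a ~5 ms oscillatory transient whose frequency lies
*inside* the breath-noise band. Pointwise energy operators (squared
amplitude, Teager energy) cannot do this reliably: at a 2 ms smoothing
scale the noise energy statistic has only ~3–4 effective degrees of
freedom (2 ms × ~900 Hz bandwidth), so its tail overlaps the crackle
response at any threshold — measured directly during design. The
detector therefore uses the structure of the target:

1. **Envelope normalization** — divide by a robust local scale
   (1.4826 × rolling 50 ms median of |x|, floored at 1% of global RMS),
   so the breath envelope cannot modulate the false-alarm rate. The
   rolling median is evaluated on a strided grid (hop = window/4) and
   interpolated, which is ~300× cheaper than a dense rolling median and
   differs from it negligibly at the envelope time scale.
2. **Matched-template bank** — correlate with unit-norm damped sinusoids
   on a grid of f₀ ∈ {250…900} Hz (geometric, 8 points) × τ ∈ {3, 6, 10} ms,
   truncated at 15 ms for time resolution. Damped sinusoids decorrelate
   slowly in f₀, so the coarse grid loses little matched gain. The
   statistic is z = |c| / (1.4826 · MAD(c)) per template, maximized over
   the bank and smoothed over 2 ms.
3. **Threshold** — z > 10 (default `threshold_k`). The correlation of
   the normalized noise is Gaussian-tailed; its per-segment maximum
   measures 7–8, while SNR-10 crackles peak at ≥ 12.8, so 10 sits in the
   measured gap. Detection is additionally gated where the local
   envelope scale falls below 10% of the segment's 90th-percentile scale
   (no SNR is defined where the breath sound is essentially off).
4. **Onset** — suprathreshold runs separated by less than the 5 ms
   refractory period are consolidated; each run contributes one onset:
   the baseline (zero) crossing of the waveform **nearest** the run's
   correlation peak (the matched peak sits at the template start, i.e.
   the onset, which is itself a baseline crossing). "Last crossing
   before the peak" was rejected because the zero-phase filter pre-ring
   suppresses baseline crossings for several ms ahead of strong
   transients and biases onsets early. Exact-zero samples count as
   crossings only where the signal actually leaves zero, so silence
   cannot flood the candidate set.

Validated operating range: on the seeded fixture (20 crackles, f₀ 300–700
Hz, τ 3–8 ms) the detector achieves recall = precision = 1.0 at
SNR 10 dB with onsets within ~1.3 ms of truth; performance degrades
below ~8 dB as the crackle z approaches the noise maximum. The detector
is deterministic given its inputs and translation-equivariant to within
one sample.

## Waveform metrology

From a given onset, zero crossings are located with sub-sample linear
interpolation inside a 25 ms analysis window; deflection k lies between
crossings k−1 and k (the onset is crossing 0). IDW is the width of
deflection 1, 2CD the time from onset to the end of deflection 4, LDW the
maximum width among deflections 1–4, A1–A3 the peak magnitudes of
deflections 1–3. Events with fewer than four crossings before the
segment or window end are flagged unmeasurable and excluded (counted in
the extraction log). On noise-free damped sinusoids the measured IDW and
2CD sit within two sample periods (45 µs at 44.1 kHz) of the analytic
values. `is_fine` applies the 2CD < 10 ms rule to the *measured* 2CD.

Patient aggregation pools both recording sites (maximizing events per
patient; site-stratified output remains available through the per-event
tables), divides the fine-crackle count by the number of inspirations
analyzed, and labels patient onset timing by the tercile (equal thirds of
the inspiratory phase) of the mean first-fine-crackle relative onset per
inspiration; `modal` and `earliest` rules are provided as non-default
alternatives, as is counting all crackles rather than fine only.

## Spectral percentiles

Welch-averaged modified periodograms: Hann window, 4096 samples
(~93 ms, ~10.8 Hz resolution at 44.1 kHz), 50% overlap, truncated to
100–2000 Hz. Fq is the smallest grid frequency whose cumulative bin
power reaches q × total power (right-continuous step rule, no
interpolation — deterministic and oracle-testable; a linear-interpolation
variant is available). Spectra of all inspiratory segments from both
sites are averaged *before* extracting percentiles, matching the
"total signal power" reading at the patient level; per-segment
percentiles can be computed from individual spectra. Percentile
frequencies are invariant to positive rescaling, and band power matches
band-limited signal variance within windowing loss (~10%).

## Synthetic cohorts

Per-patient features are drawn from lognormals calibrated by quartile
matching to the published honeycombing (n = 24) vs non-honeycombing
(n = 47) group summaries: μ = ln(median), σ = ln(q3/q1)/(2 z₀.₇₅).
Printed quartile triples are generally not log-symmetric, so a
two-parameter lognormal reproduces the median exactly and the IQR ratio
exactly, but not both quartiles individually — the calibration is
documented as median + IQR-ratio matching. Where rounding collapses a
printed q1 onto the median (LDW in the non-honeycombing group), σ is
calibrated from the upper half alone. Patient counts per inspiration are
kept continuous: they are averages over 16 inspirations, and the
discrimination cutoff itself (≈13–15 per phase) is non-integer.

Onset terciles are categorical draws from the published per-group counts
(20/4/0 and 12/27/8). Continuous features share a one-factor latent
**disease-severity** copula (loading 0.7; signed so severity raises
counts and frequencies and shortens 2CD/LDW), with an extra common
factor among F50/F95/F99 bringing their pairwise rank correlation to
~0.75. Without this dependence the cohort would be jointly
quasi-separable at n = 71 — unrealistic for clinical data and degenerate
for multivariate regression. Marginals remain exactly the calibrated
lognormals. Even so, strongly separated draws can still reach
quasi-separation; the logistic fit then reports `converged=False` rather
than silent estimates.

The cohort generator emulates marginal locations/spreads, category
frequencies and a plausible dependence structure. It does not emulate
measurement error in the acoustic pipeline, site effects, missing data
patterns, or covariate confounding; cohort-level test results validate
the statistical chain, not clinical effect sizes.

## Statistical chain

- Quartiles by linear interpolation of order statistics; percentages
  rounded half-up to one decimal.
- Mann–Whitney U (U counts pairs x > y): exact null distribution for
  tie-free samples with n_x·n_y ≤ 400, otherwise normal approximation
  with tie and continuity corrections.
- Pearson chi-squared without continuity correction (Yates available).
- **Gwet's AC1** for inter-rater agreement: AC1 = (p_a − p_e)/(1 − p_e)
  with p_a the mean pairwise observed agreement per item and
  p_e = Σ_c π_c(1−π_c)/(C−1); unlike kappa, p_e stays bounded away from 1
  under extreme prevalence. Multi-rater formula by default; variance by
  the standard item-level linearization, 95% Wald CI truncated at 1.
- Logistic regression by maximum likelihood (Newton; BFGS fallback when
  the Hessian is singular under quasi-separation, with the fit flagged
  non-converged when |β| indicates separation). Odds ratios are
  unit-scaled: OR = exp(β·u), 95% CI = exp((β ± 1.96·se)·u), e.g. u = 5
  crackles or 100 Hz. Wald (not profile) intervals, matching the
  OR/CI arithmetic conventional in clinical tables. Complete-case
  handling per model with n_used reported; no imputation; no
  multiple-testing correction (exploratory feature screen — noted as a
  limitation).
- Model building: candidates significant at p < 0.05 univariately enter;
  within any cluster of retained continuous variables with
  |Spearman ρ| > 0.7, only the designated representative is kept
  (F99 for the frequency cluster; otherwise the smallest univariate p).
  Forced-in terms (LDW, age by default) reproduce the conventional
  adjusted-model shape regardless of screening.
- ROC over all distinct-score thresholds (positive call: score ≥ t);
  AUC by the trapezoid rule along the ROC path (exact for the empirical
  staircase; AUC·n₁·n₀ equals the Mann–Whitney concordance count on
  tie-free data). The reported cutoff minimizes the Euclidean distance
  to (0, 1), ties broken toward higher specificity, and is placed at the
  midpoint between the adjacent distinct scores realizing the optimum.
  Dichotomization uses the ≥ convention. Percentile-bootstrap AUC CIs
  resample patients.

## Pipeline determinism and problem sizes

A fully specified config plus seed determines every output byte;
manifests carry SHA-256 checksums and the reporter only formats numbers
already present in the results bundle. Child seeds are derived from the
master seed via `numpy` seed sequences. Default problem sizes — a
71-patient cohort, two audio patients × two sites × eight breaths at
44.1 kHz for the fixture set, 500–1000 replicates for the oracle and
identity checks — keep a full synthesize → extract → analyze → report
cycle and the whole test suite in the tens of seconds on one CPU while
leaving Monte-Carlo error well below the tested tolerances.

## Known limitations

- The detector's operating range is validated on the package's own
  noise fixture; real recordings add heart sounds and artifacts that
  would require retuning `threshold_k` and possibly the template bank.
- The onset-timing label depends on a patient-level aggregation rule the
  measurement literature leaves open; three rules are implemented and
  the default (mean first-crackle onset) is the simplest reproducible
  choice, not a validated standard.
- Cohort AUCs from the quartile-calibrated generator (~0.8–0.95) are
  properties of the synthetic distributions, not estimates of clinical
  performance.
- Exact logistic regression and penalized (Firth) fits are out of scope;
  separated fits are flagged, not rescued.
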