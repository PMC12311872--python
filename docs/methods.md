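# Methods

`circamark` computes a 26-marker panel of sleep and circadian rhythm
biomarkers from minute-level wearable data (heart rate in bpm, step counts
in steps/min, device-logged sleep episodes) and provides the cohort-level
statistics and feature-importance machinery used to relate the panel to a
binary phenotype such as metabolic syndrome.  This note documents the
models, the defaults and why they were chosen, the synthetic cohort the
tests run on, and the package's known limitations.

## Preprocessing and wear-time eligibility

Device exports are regridded to a strict one-minute grid and trimmed to
whole midnight-to-midnight days (partial first/last days carry systematic
phase bias into the daily profile, so they are dropped rather than padded).
Heart-rate samples that are absent or zero-coded are flagged as missing and
repaired by linear interpolation between the nearest valid neighbours;
leading/trailing runs take the nearest valid value.  Linear interpolation is
deliberate: spline repair overshoots across long nonwear gaps.  The missing
mask is preserved so downstream code can audit repaired spans.  Step gaps
are *not* treated as nonwear — zero steps at rest are genuine data — so
nonwear detection rests on the heart-rate channel alone.

A participant is wear-eligible when the record contains at least five
calendar-consecutive weekdays (a weekend breaks the run) and no calendar day
has more than 360 missing minutes.  Calendar days, not sliding 24-h windows,
keep the rule simple and deterministic.

## Sleep markers

For each night (window 18:00–12:00 next day) the longest episode is the main
sleep; naps are discarded.  MST is the clock midpoint of the main episode in
minutes after midnight; TST its duration in minutes.  Means and SDs are
taken across nights, with MST averaged **circularly** on the 24-h circle so
that 23:50 and 00:10 average to midnight.  The panel reports MST_Mean,
MST_SD, TST_Mean, TST_SD.  Only main sleep enters the summaries; the
device's sleep log is trusted as-is (no re-scoring from heart rate or
steps, from which sleep efficiency cannot be estimated).

## Cosinor markers

The single-component cosinor model Y(t) = M + A·cos(2πt/τ + φ) with τ fixed
at 1440 min is fitted by ordinary least squares through the linear
reparameterisation Y = M + β·cos(ωt) + γ·sin(ωt), pooling the whole
multi-day record.  Reported markers: MESOR M, amplitude A = √(β²+γ²),
acrophase as the clock time of the fitted peak in decimal hours (the
convention that puts heart-rate acrophase near 15 h), and the circadian
quotient CQ = A/M.  A constant series has A = 0 and an undefined acrophase,
reported as missing; CQ is missing when M ≤ 0.

## Nonparametric markers

L5/M10 are the minimum/maximum mean over all contiguous 300-/600-minute
windows of the 1440-point average daily profile, with windows wrapping past
midnight; ties resolve to the earliest window start.  RA = (M10−L5)/(M10+L5)
(missing when both are zero).  A per-day-then-average mode exists but the
profile mode is the default used for the panel.

IV and IS are computed on hourly bins (the conventional actigraphy choice;
minute-resolution first differences would be dominated by measurement noise
and inflate IV far beyond the ~0.5–1.2 range typical of hourly analyses):

    IV = N·Σ_{t≥2}(Y_t − Y_{t−1})² / [(N−1)·Σ(Y_t − Ȳ)²]
    IS = N·Σ_h(x̄_h − x̄)² / [S·Σ_i(x_i − x̄)²],  S = 24

Both are missing for constant series.  White hourly noise gives IV ≈ 2;
identical repeated days give IS = 1.  Heart-rate markers use the
interpolated series; step markers use raw counts.

## CCE: continuous wavelet circadian-rhythm energy

The novel band-energy markers use an analytic Morlet wavelet
ψ(t) = π^(−1/4)·e^(iω₀t)·e^(−t²/2) with ω₀ = 6.  Scales map to Fourier
periods by a = (ω₀+√(2+ω₀²))/(4π)·λ.  The signal is z-scored, transformed
over 80 log-spaced central periods from 20 to 1500 min (the coarsest grid
of this span keeping ≥3 points inside each marker band), and the energy at
each period is Σ_b |W(a,b)|².  Coefficients carry the L1 scale
normalisation (W = (1/a)∫x·ψ*((t−b)/a)dt), which weights a sinusoid of
fixed amplitude equally at every period; with the profile normalised to
unit total, band values are dimensionless fractions of signal energy on the
~0.03 scale.  The markers are the summed energy at grid periods inside
69–80 min (CCE_MF), 900–1100 min (CCE_LF), and their ratio, computed on
heart rate for the panel (step-count profiles remain available for band
scans).

Implementation: the transform is evaluated in the Fourier domain with
periodic boundary handling, and the time-summed energy follows from
Parseval's identity without materialising the spectrogram, which makes the
per-participant cost a handful of FFTs.  An optional cone-of-influence mode
drops coefficients within √2·a samples of the record edges for sensitivity
checks; the default includes them.  The test suite cross-checks the
coefficients against PyWavelets' complex-Morlet CWT (identical mother
wavelet for `cmor2.0-C` with C = ω₀/2π).

Two resolution caveats follow from the Morlet log-period bandwidth
(≈ 1/ω₀ = 0.167): (1) the circadian peak leaks a floor of energy into the
900–1100 min band, so CCE_LF sits above the pure 1000-min component energy;
(2) grid points within one bandwidth of an injected 70-min component
respond near-identically, so the location of a band-scan significance
minimum is reproducible only to about one grid step.  Localization claims
are therefore asserted to one-grid-step tolerance.

## CARE: singular-spectrum circadian activity rhythm energy

The comparator marker embeds the (mean-removed) step-count series in a
Hankel trajectory matrix (window 1440 min), takes the 20 leading singular
triples, reconstructs each component by diagonal averaging, estimates its
dominant period from the FFT peak of the reconstruction, and reports the
fraction of retained energy (squared singular values) in components with
dominant period strictly below 1440 min.  Components are treated
individually (no eigentriple pairing).  This is a reimplementation from the
method's published description, not a reference implementation; window
length, component count and the threshold are configurable.

The SVD exploits Hankel structure: matrix–vector products are FFT
correlations, so a seeded randomised range finder (oversampling 10, two
power iterations) computes the truncated SVD in O(k·N log N).  Small inputs
fall back to a dense exact SVD.  The internal seed is fixed — marker
extraction is fully deterministic.

## Cohort statistics and importance ranking

Group comparison reports per-marker means, SDs, a two-sided Welch t test
(pooled-variance toggle available) and the Wilcoxon rank-sum test, dropping
missing values marker-wise.  Raw p-values are primary, matching the common
presentation of such panels; a Benjamini–Hochberg column is emitted
alongside for honest multiple-testing reporting.

Importance ranking treats the model as a pluggable backend behind one
contract — `fit(X, y)`, then `global_importance()`:

- `tree_shap`: an XGBoost classifier (binary logistic, default boosting
  parameters, fixed seed) attributed with XGBoost's built-in exact TreeSHAP
  (`pred_contribs`); importance is the mean absolute contribution.
- `additive_boosting`: a boosted generalised additive model — gradient
  boosted trees constrained to single-feature splits — scored by seeded
  permutation importance (log-loss, 10 repeats).
- `attention_tabular`: interface placeholder for an attention-based tabular
  network; this package declares no deep-learning stack, so requesting it
  raises an explicit "backend missing" error rather than silently falling
  back.

Missing marker values are median-filled for model fitting only (statistical
tests stay complete-case).  Covariates (age, sex, BMI) can be appended as
features to reproduce the with/without-confounder contrast; no
residualisation is attempted.

`undersample_stability` refits the backend on `repeats` (default 5)
without-replacement subsamples of the majority group matched to the
minority size and counts per-marker top-k appearances — a robustness check
for imbalanced cohorts.  All randomness derives from the caller's seed.

## Synthetic cohort generator

Every stage is testable without private cohort data via a generator that
emulates five weekdays (Monday–Friday) of minute-level data per
participant:

- **Heart rate** = MESOR + circadian cosine + 70-min and 1000-min cosines
  with participant-random phases + nocturnal elevation while asleep + AR(1)
  noise (φ = 0.8, stationary SD 3 bpm).  Nonwear appears as zero-coded
  bursts (Poisson count, geometric lengths, 2% of minutes by default).
- **Steps** = 0 during sleep; awake, Poisson counts with a mid-afternoon
  activity hump, a two-state bout chain, and a day-level lognormal rate
  multiplier expressing day-to-day irregularity.
- **Sleep** = one episode per night with midpoint ~ N(MST, mst_sd) and
  duration ~ N(TST, tst_sd).

Group effects are injected **mechanistically** (component amplitudes, MESOR
shift, nocturnal elevation, activity rate and its day-to-day CV), never by
perturbing markers directly, so marker recovery is a genuine end-to-end
test.  Default group *means* (MESOR 71.89 vs 75.05 bpm, amplitude 11.66 vs
11.22 bpm, acrophase ~15 h, MST ≈ 207.6/207.1 min, TST ≈ 414.9/410.7 min)
follow the published cohort tables.  The ultradian amplitudes (3.0 vs 2.4
bpm at 70 min; 1.5 vs 1.9 bpm at 1000 min) were calibrated once, against the
published band-energy magnitudes (~0.029 vs ~0.024 mid-frequency fraction),
by noise-free component decomposition.  Between-participant spreads
(mesor SD 4.5 bpm, acrophase SD 1.2 h, amplitude CV 0.15) are the
generator's own calibration: they are set so the published
significant/nonsignificant split is detectable with high probability at the
reference size of 88 cases / 184 controls, which is the study condition the
acceptance checks prescribe.  Consequently the simulated between-person
marker SDs are somewhat tighter than the observed cohort's (which include
behavioural and physiological variance the generator does not model).

What the generator does **not** emulate: heart-rate variability
microstructure, activity-HR coupling, weekend behaviour, device-specific
artefacts other than zero-coded gaps, daytime naps, and covariate-marker
correlations.  Passing tests therefore demonstrate that the pipeline
recovers known injected structure of the stated form — not that the markers
behave identically on real cohort data.

## Numerical choices and degenerate inputs

- Cosinor: `numpy.linalg.lstsq`; amplitudes below 1e−9 of the signal scale
  count as zero (acrophase undefined).
- L5/M10 window ties: earliest start wins.
- Constant series: IV/IS/CCE/CARE are missing (never silently zero); the
  marker vector records the reason per marker.
- CWT: periodic (circular) boundary handling; a period grid exceeding half
  the record length is an error.
- SSA: strictly-less-than-1440-min threshold, so a pure 24-h rhythm scores
  CARE ≈ 0.
- All pipeline stages are bit-deterministic given config and seed.

## Problem sizes used by the test and acceptance runs

Cohort-scale checks run the full pipeline at the reference size 88/184
(significance-pattern replication over 20 seeded cohorts), 40/80 for the
isolated-attenuation and importance checks, and 15/15 × 100 simulations for
type-I calibration — sizes chosen so each check has the statistical
resolution it needs while the whole suite stays desk-scale.

## Known limitations

- CCE_LF magnitudes carry circadian spectral leakage under this
  normalisation; comparisons are meaningful within a fixed configuration,
  and the published low-frequency/ratio magnitudes are matched in direction
  and order of magnitude only.
- The `attention_tabular` backend is declared but not provided.
- CARE's published algorithm is under-specified; this reimplementation
  makes its free choices explicit rather than claiming reference fidelity.
- Band-scan localization is resolution-limited to roughly one grid step
  (Morlet bandwidth), as described above.
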