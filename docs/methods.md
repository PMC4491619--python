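# Methods

This note documents the models, estimators, numerical choices, and known
limitations behind `alphamark`. It describes *how* each quantity is
computed and why the defaults are what they are; every number quoted here
is produced by the package's own tests or scripts.

## Preprocessing

Recordings are multichannel matrices in microvolts with 10–20 channel
labels. The chain is:

* **Common-average reference.** Each scalp channel minus the
  instantaneous mean over all scalp channels. EOG channels, when present
  in a file, are excluded from the average and from all analyses (they
  exist only to document eye movements). The operation is idempotent and
  reference-agnostic: no attempt is made to simulate or undo a
  linked-mastoid original reference.
* **Epoching.** Consecutive, non-overlapping epochs of 2 s (500 samples
  at 250 Hz); the trailing partial epoch is discarded, so a recording of
  duration `T` yields exactly `floor(T/2)` epochs — 150 for a clean
  5-minute recording.
* **Artifact rejection.** Expert visual rejection is not reproducible, so
  an automated two-threshold rule stands in: an epoch is dropped when any
  channel exceeds 100 µV absolute amplitude or a 50 µV sample-to-sample
  step. Both thresholds are conventional clinical screening values and
  are config-exposed; rejection is monotone (tightening a threshold never
  recovers an epoch) and never modifies data. No software band-pass is
  re-applied by default — synthetic data are generated in-band — but the
  thresholds and epoching operate identically on real files read from
  EDF or the CSV matrix format.

## Spectra, anchors, and individualized bands

The PSD is the Welch estimate over the kept epochs: per epoch a
Hanning-windowed, mean-detrended periodogram with density scaling, then
the unweighted average across epochs, restricted to 2–45 Hz. With 2-s
epochs the native grid spacing is 1/2 s = 0.5 Hz; the grid is therefore
the 87 bins 2.0, 2.5, …, 45.0 Hz. Epochs are the segments — there is no
overlap, matching the consecutive-epoch design. Because all band powers
are *relative*, the PSD scaling constant cancels everywhere; consistency,
not the constant, is what the tests assert.

Anchors are detected on the unweighted electrode-averaged spectrum:

* **IAF** — argmax of power in the closed extended alpha range
  [5, 14] Hz. Ties break toward the lower frequency (deterministic;
  measure-zero with noise).
* **TF** — argmin of power in `[3 Hz, IAF)`. The published rule says only
  "minimum power in the alpha range"; the 3 Hz floor keeps the search
  clear of the delta roll-off while allowing early transitions, and ties
  break toward the higher frequency, the bin nearest the alpha rise. A
  monotone spectrum returns the floor — documented boundary behavior.

Bands follow the anchor rules (delta `[TF−4, TF−2)` through alpha3
`[IAF, IAF+2)`, with the alpha1/alpha2 split at the midpoint of TF–IAF).
Three numerical choices matter:

* Bin membership uses the *exact real-valued* half-open interval
  `lo ≤ f < hi`. A midpoint such as 8.25 Hz (TF 6.5, IAF 10.0) simply
  partitions the grid bins without rounding, so no bin is ever counted in
  two bands; the top band closes at 45 Hz so the last bin is not
  orphaned.
* The upper-band edges beta1/beta2 end at 19.2 and 32.4 Hz by default.
  These are fixed absolute values chosen to match the conventional group
  means; whether they should instead be individualized has no published
  construction rule, so both are supported via config and neither is
  claimed as canonical.
* A TF below 6 Hz pushes the delta band below the 2 Hz grid; the lower
  edge is clipped to 2 Hz with a warning. At TF = 4 Hz delta collapses to
  a zero-width band and band powers raise an explicit empty-band error
  rather than silently returning NaN.

Relative power divides each channel's bins by that channel's mean power
over the grid (so the relative spectrum averages to exactly 1), band
power is the mean relative power over a band's bins averaged across
channels, and the two ratios are alpha3/alpha2 and theta/gamma. With the
shared per-channel normalizer the ratio is identical whether computed
from relative or absolute power; relative is used. All band powers and
ratios are exactly invariant to rescaling the recording.

## Coherence

Magnitude-squared coherence per pair: cross- and autospectra are averaged
across the *same* kept epochs (Hanning windows, identical to the PSD
segmentation) before forming `|S_xy|²/(S_xx S_yy)` — the Welch coherence
estimator, which is meaningful only with segment averaging (a single
segment gives identically 1, so two kept epochs are the minimum). Values
are clipped to [0, 1] against floating-point excursions. Band summaries
reuse the band-membership rule above; the per-band value is the mean over
bins (peak-per-band is an alternative no published analysis pins down).

Coherence is computed on common-average-referenced data, like the power
pipeline. The common reference introduces a known shared-signal coupling
floor across channels — the volume-conduction caveat inherent to scalp
coherence — which is documented rather than corrected. No bias correction
is applied to the estimator; instead the finite-epoch bias floor
(≈ 1/L for L epochs of independent noise) is characterized empirically in
the test suite against a Monte-Carlo oracle.

The pair sets are fixed: left intrahemispheric {F3–T3, T3–P3, F3–P3},
right intrahemispheric {F4–T4, T4–P4, F4–P4}, interhemispheric
{F3–F4, T3–T4, P3–P4}.

## Cohort statistics

* **Stratification.** Fixed cutoffs (default) classify a ratio `r` as low
  for `r < 1.0`, middle for `1.0 ≤ r < 1.17`, high for `r ≥ 1.17`. The
  conventional printed cutoffs leave (1.16, 1.17) unassigned; the
  half-open convention closes that gap with minimal deviation and makes
  classification total. Empirical tertiles (linear-interpolation 1/3 and
  2/3 quantiles) are available as an alternative mode.
* **Mixed ANOVA.** Group is between-subject; band × pair is the full
  within grid. Each subject's cell matrix is double-centered across both
  within factors, projecting onto the interaction space; the
  group × band × pair F is the ratio of the between-group dispersion of
  those interaction scores, df `(g−1)(f−1)(p−1)`, to the pooled
  within-group residual, df `(N−g)(f−1)(p−1)`. Greenhouse–Geisser epsilon
  is the Box index of the pooled within-group covariance projected onto
  an orthonormal (Helmert ⊗ Helmert) interaction contrast basis, clipped
  to `[1/d, 1]`; the corrected p is always reported alongside the
  uncorrected one, and Mauchly's W (with its chi-square approximation) is
  reported but never used to gate the correction. When the pooled df are
  too small for the covariance to be full-rank, Mauchly is reported as
  NaN. The implementation is cross-checked against an independently coded
  nested-least-squares oracle (agreement 1e-10) and against R's
  `aov` with `Error(subject/(band*pair))`.
* **Post hoc contrasts.** Stepwise multiple-range procedures are poorly
  specified for three-way cell structures and statistically disfavored;
  plain pairwise Welch t contrasts on subject means are provided instead,
  explicitly uncorrected for multiplicity (the column is named
  accordingly). This is a deliberate deviation from older practice.
* **Correlations and W scores.** Pearson r with the two-sided t-transform
  p. W scores standardize a measure against an age regression fitted on
  controls: `(value − (a + b·age)) / SD(residuals)`. The residual SD uses
  ddof = 1, so the control sample's own W scores have mean 0 and SD
  exactly 1 by construction.

## The synthetic cohort generator

Each channel is a sum of band-passed white-noise oscillators over a
1/f^β background; all filters are 4th-order Butterworth band-passes and
each component is scaled *analytically* — via the filter's integrated
frequency response, not the realized sample variance — to its requested
RMS, so the expected one-sided PSD of a subject is known in closed form.
Components per subject, anchored on the intended TF and IAF:

| component  | band (Hz)            | default RMS (µV) |
|------------|----------------------|------------------|
| theta      | [TF−2, TF−1]         | 2.0              |
| low alpha  | [TF+0.5, IAF]        | 4.0              |
| high alpha | [IAF, IAF+2]         | 4.0              |
| alpha peak | [IAF−0.5, IAF+0.5]   | 3.0              |
| background | 1/f^β, β = 1.5       | 12.0             |

The theta oscillator sits in the lower half of the theta band and the
low-alpha oscillator starts half a bin above TF, leaving a
background-floored notch between theta activity and the alpha rise; since
the 1/f background declines with frequency, the spectral minimum lands in
that notch rather than below theta, which keeps the transition frequency
well-defined even when coupling sources add theta power. Narrow
Butterworth oscillators were chosen over pure sinusoids because pure
tones have no spectral width and make the transition trough degenerate.
The background exponent β = 1.5 and 12 µV RMS give eyes-closed-like
low-frequency dominance with a clearly dominant alpha peak (the package's
own choice of a comfortable-recovery regime: no SNR is published for
recordings of this kind, and these defaults are documented, not claimed
realistic).

**Ground truth is the analytic spectrum.** The true IAF/TF of a subject
are the argmax/argmin of the closed-form electrode-averaged spectrum on
the analysis grid under exactly the detector rules — TF is a property of
the spectrum, not a free dial, and the truth table records these realized
values. Per-channel gains drawn from [0.9, 1.1] add realistic amplitude
topography without touching any relative quantity.

**Cohorts.** For each subject a target alpha3/alpha2 ratio is drawn from
the inner 80 % of its group's range (defaults: low 0.77–0.98, middle
1.00–1.16, high 1.17–1.52, sizes 18/38/18), the intended IAF from
N(10.9, 0.8) clipped to [9, 12.5] and TF ≈ IAF − 4. A single knob scales
the high-alpha oscillator up and the low-alpha oscillator down until the
*analytic* ratio hits the target (brentq, with candidates discarded if
they destabilize the analytic anchors), then the realized recording is
verified with the default measurement pipeline; subjects falling outside
their range are redrawn (bounded retries, fully deterministic from the
master seed) and an infeasible group raises a generation error naming it.
Covariates (age, sex, education, MMSE) are drawn per group from published
summary distributions and carry no EEG dependence unless configured —
groups are covariate-matched by construction, so null correlations are
the expected result.

**Coupling.** A shared band-limited source (default: 2 Hz wide, centered
at 5.9 Hz, 3 µV RMS) is added to one channel in full and to its partner
scaled by a mixing coefficient in [0, 1]. For the two-channel test
generator the expected coherence is closed-form,
`mix²·Ps² / ((Ps+Pn)(mix²·Ps+Pn))`, and measured coherence is
non-decreasing in the mixing coefficient.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: artifact morphology (only a square-burst
injector exists, to exercise rejection), non-stationarity and
drowsiness-related alpha drift, volume-conducted broadband source
mixtures (channels are independent except for explicit coupling),
reactive alpha (eyes-open blocking), or any dependence of EEG on the
demographic covariates.

## Problem sizes and runtimes

Simulation-backed checks use sizes chosen for quick desk iteration:
anchor-recovery sweeps use 30–60-s recordings; the tertile-recovery
experiment runs 50 master seeds × one subject per group at 60 s; coupling
monotonicity averages 20 seeds per mixing value at 40 s; the analysis
scripts simulate the full 74-subject cohort at 120 s per subject; and the
IAF-detection reproduction uses the full 300-s, 19-channel subject. The
acceptance script completes in well under a minute.

## Known limitations

* The transition-frequency detector assumes a visible theta/alpha trough;
  flat or monotone spectra return the search floor by construction.
* A detected TF ≤ 4 Hz produces an empty delta band and a hard error —
  deliberate, since the band rule itself is undefined there.
* The ANOVA denominator df depends on the subject count entering each
  pair-set table; only the numerator df is structurally fixed at
  `(g−1)(f−1)(p−1)`.
* Whether the within "frequency" factor should carry all 8 bands is an
  inference from df arithmetic in the conventional design; the
  implementation accepts any ≥ 2-level within grid.
* EDF output uses 16-bit quantization over each channel's observed range;
  round-trips are exact only to that resolution (tested).
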