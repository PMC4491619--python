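# alphamark

Individually anchored EEG frequency bands, the **alpha3/alpha2 power
ratio**, and linear spectral coherence for resting-state cohorts — with a
synthetic-EEG generator that provides recoverable ground truth for every
stage.

## The problem

In mild cognitive impairment (MCI), a relative increase of upper-alpha
over lower-alpha power in the eyes-closed resting EEG has been proposed
as a marker of incipient Alzheimer-type degeneration. Measuring it
requires *individualized* frequency bands: canonical fixed bands blur the
alpha peak, which shifts from subject to subject. This package implements
that analysis chain for researchers working with 10–20-montage resting
recordings:

1. **Preprocessing** — common-average re-reference, consecutive 2-s
   epochs, threshold-based artifact rejection.
2. **Spectra and anchors** — Welch power spectral density (Hanning
   windows, 0.5 Hz resolution, 2–45 Hz). On the electrode-averaged
   spectrum two anchors are located: the individual alpha frequency
   (IAF), the power maximum in 5–14 Hz, and the theta/alpha transition
   frequency (TF), the power minimum between the theta and alpha bumps.
3. **Individualized bands** — delta `[TF−4, TF−2)`, theta `[TF−2, TF)`,
   alpha1 `[TF, mid)`, alpha2 `[mid, IAF)`, alpha3 `[IAF, IAF+2)` with
   `mid = (TF+IAF)/2`; fixed upper edges for beta1/beta2/gamma
   (19.2 / 32.4 / 45 Hz by default). Relative band power is the mean,
   over a band's bins, of power normalized by the channel's 2–45 Hz mean;
   the biomarker is the ratio `alpha3 / alpha2`.
4. **Coherence** — magnitude-squared coherence
   `|S_xy|² / (S_xx S_yy)` from epoch-averaged cross- and autospectra,
   summarized per band over the fronto-temporal, temporo-parietal and
   fronto-parietal intrahemispheric pairs and the F3–F4 / T3–T4 / P3–P4
   interhemispheric pairs.
5. **Cohort statistics** — tertile stratification of the ratio (fixed
   cutoffs 1.0 / 1.17 or empirical tertiles), three-way mixed ANOVA
   (group × band × pair) with Greenhouse–Geisser correction and Mauchly's
   test, Pearson correlations, and age-corrected W scores against a
   control-sample regression.

Because clinical recordings of this kind are rarely shareable, the
`synth` module generates whole cohorts of resting-state-like EEG
(narrow-band stochastic oscillators over a 1/f^β background) whose IAF,
TF, band-power ratio, and pairwise coupling are known by construction —
every downstream stage is tested against that ground truth.

## Worked example

```python
from alphamark import (SubjectSpec, generate_subject,
                       common_average_reference, segment_epochs,
                       reject_artifacts, welch_psd, grand_average_spectrum,
                       detect_iaf, detect_tf, AnchorFrequencies,
                       build_band_scheme, relative_power, band_powers)

rec = generate_subject(SubjectSpec(iaf_true=10.9, seed=1))   # 5-min, 19 ch
es = reject_artifacts(segment_epochs(common_average_reference(rec)))
ps = welch_psd(es)
avg = grand_average_spectrum(ps)
iaf = detect_iaf(avg)
tf = detect_tf(avg, iaf)
scheme = build_band_scheme(AnchorFrequencies(tf=tf, iaf=iaf))
bp = band_powers(relative_power(ps), scheme)
print(f"epochs kept: {es.n_kept}/{es.n_epochs}")
print(f"TF {tf:g} Hz, IAF {iaf:g} Hz")
print(f"alpha2 band {scheme['alpha2']}, alpha3 band {scheme['alpha3']}")
print(f"alpha3/alpha2 = {bp.alpha3_alpha2:.3f}")
```

prints

```
epochs kept: 150/150
TF 6.5 Hz, IAF 11 Hz
alpha2 band (8.75, 11.0), alpha3 band (11.0, 13.0)
alpha3/alpha2 = 1.521
```

150 epochs is the bookkeeping expected for a clean 5-min recording; the
alpha peak placed at 10.9 Hz is detected at 11.0 Hz, the nearest bin of
the 0.5 Hz grid; and the band edges follow from the detected anchors. The
ratio lands well above the 1.17 cutoff, i.e. this simulated subject would
stratify into the high-risk tertile.

## Cohort analyses

The `analysis/` scripts run the full study-shaped analysis on a simulated
74-subject cohort (18 low / 38 middle / 18 high tertile targets):

```sh
python analysis/01_simulate_cohort.py   # recordings + ground truth
python analysis/02_spectral_bands.py    # anchors, bands, ratios, summary
python analysis/03_coherence.py         # pair coherence + coupling experiment
python analysis/04_cohort_stats.py      # mixed ANOVAs, correlations, W scores
```

Tables land in `results/`. The same chain is available as a one-command
pipeline: `alphamark run --config cfg.yaml` (see `alphamark --help` for
the per-stage subcommands).

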