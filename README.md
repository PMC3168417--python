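# nirscreen

Two-stage FT-NIR screening of plant cell-wall composition, built for
forward-genetic screens where thousands of leaves must be triaged with a
single near-infrared scan each.

Near-infrared spectra (~4000–12000 cm⁻¹) of intact leaves carry broad,
overlapping overtone bands with no interpretable peaks, so both stages are
multivariate:

1. **Spectral outlier screen.** Within each growth batch, spectra are
   cropped to 3800–9000 cm⁻¹, Savitzky–Golay smoothed (25 points),
   baseline-corrected, area-normalized, mean-centered and compressed by
   PCA. A randomly chosen leaf, scanned five times, defines a batch
   reference set; every other leaf's Mahalanobis distance

   d² = (u − ū_ref)ᵀ S⁻¹ (u − ū_ref)

   is computed in the space of the first 4 principal-component scores
   (the number of score variables must stay strictly below the number of
   reference scans, or S is singular). The top 5% are shortlisted; the
   procedure repeats with five random references, and leaves present in
   every shortlist are **consensus outliers** — candidates for wet-lab
   composition assay.

2. **Per-sugar PLS calibration.** Confirmed candidates plus references,
   with measured monosaccharide mol% (HPAEC-style), train one
   single-response NIPALS PLS regression per sugar (Ara 8, Gal 7, Glc 11,
   Xyl 10 latent components), validated by seeded 10-fold
   cross-validation (RMSEP per fold, pooled predicted-vs-measured R²).
   Predictions for the whole population are screened against per-sugar
   thresholds of four standard deviations of the reference relative
   variability (μ ± 4σ, ≈99.99% band): a sample is flagged when any major
   sugar's relative percent difference from its batch baseline reaches
   the threshold (e.g. Gal: 4 × 8.5% = 34.0%).

A fully seeded synthetic-data module generates leaf populations — basis
spectra with sugar-characteristic bands, batch gain and baseline effects,
line (sibling) structure, replicate reference scans and planted
composition outliers with recorded ground truth — so every stage is
testable without instrument data.

## Worked example

`python examples/01_screen_a_batch.py` builds a 370-leaf batch with three
planted 6σ composition outliers and screens it:

```
batch of 370 leaves, planted outliers:
  0065-3: Gal shifted +98%
  0035-4: Gal shifted +119%
  0025-3: Ara shifted +60%

shortlist size per iteration: 19
consensus outliers (present in all 5 shortlists):
  0025-3 (5/5 shortlists) <- planted
  0035-4 (5/5 shortlists) <- planted
  0065-3 (5/5 shortlists) <- planted
```

Each shortlist holds ceil(0.05 × 369) = 19 leaves; the consensus set is
their intersection across the five reference iterations, here exactly the
three planted outliers. `examples/02_calibrate_pls.py` then calibrates
the sugar models on a simulated 206-sample set:

```
per-sugar calibration (10-fold CV):
  Ara: 8 components, RMSEP 0.183 mol%, R^2 0.986
  Gal: 7 components, RMSEP 0.144 mol%, R^2 0.985
  Glc: 11 components, RMSEP 0.201 mol%, R^2 0.989
  Xyl: 10 components, RMSEP 0.229 mol%, R^2 0.989
pooled R^2 over 824 held-out pairs: 0.9998
```

`examples/03_flag_sugar_outliers.py` applies the 4σ thresholds, and
`examples/04_full_pipeline.py` (or the `nirscreen` CLI) chains
simulate → preprocess → screen → calibrate → predict → flag → report with
byte-identical artifacts for a fixed seed.

## Layout

```
src/nirscreen/
  spectra.py       containers + wide-CSV / JCAMP-DX I/O
  preprocess.py    crop, smooth, baseline, area-normalize, center
  chemometrics.py  PCA compression, Mahalanobis distance
  screen.py        iterative consensus screen
  pls.py           NIPALS PLS, K-fold CV, calibration reports
  composition.py   mol% tables, 4σ thresholds, flagging, rates
  synthsim.py      synthetic populations with ground truth
  pipeline.py      staged workflow with seeded determinism
  cli.py           thin click interface (`nirscreen ...`)
```

See `docs/methods.md` for the model assumptions, parameter choices and
what the synthetic populations do and do not demonstrate.
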