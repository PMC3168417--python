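# Methods

## The screening problem

A forward-genetic screen grows mutagenized plant lines in batches (here:
50 lines × 8 sibling leaves ≈ 400 leaves per batch), scans each leaf once
by FT-NIR, and must decide which few leaves deserve a destructive,
slow composition assay. Cell-wall monosaccharide composition (mol% of
Fuc, Rha, Ara, Gal, Glc, Xyl, GlcA, GalA in the TFA-hydrolysable matrix
fraction) is the phenotype of interest; the four abundant "major" sugars
Ara, Gal, Glc and Xyl are the decision variables, the minors being too
noisy to act on. The package implements the two triage stages —
reference-relative spectral outlier detection, then calibrated
composition prediction — plus the simulator used to validate them.

## Preprocessing

Order: crop → smooth → baseline → area-normalize → mean-center.

- **Crop** to a closed interval, default [3800, 9000] cm⁻¹, keeping
  exactly the grid points inside it (closedness fixed so channel counts
  are reproducible).
- **Smoothing** is Savitzky–Golay with a 25-point window. The window is
  the only externally fixed parameter; the polynomial order (default 2)
  is a configuration choice, as instrument software rarely documents its
  smoother. Edges use the fitted polynomial on the truncated window.
- **Baseline**: the default *rubberband* correction subtracts, per
  spectrum, the lower convex hull of the (wavenumber, absorbance) points
  (monotone-chain hull, linear interpolation between vertices), which
  removes offsets and broad curvature and leaves a non-negative spectrum
  touching zero at hull vertices. A two-point *linear* correction is the
  alternative. Both are deterministic and parameter-free.
- **Area normalization** divides each spectrum by its trapezoidal
  integral over the grid (trapezoid, not channel sum, so non-uniform
  grids integrate consistently). It removes optical-path/amount scale;
  consequently only relative spectral shape carries information, which
  matches the compositional (mol%) response.
- **Mean centering** is fit on a designated set and stored in a
  `CenteringModel`; held-out spectra are centered with the training mean,
  never their own, to avoid leakage. The PLS models center internally,
  so the regression path applies the first four steps only.

All steps are row-local except centering and append their parameters to
the set's processing log.

## PCA and Mahalanobis screening

PCA is computed by SVD of the centered matrix (stable for channels ≫
samples); scores are U·s, explained variance s²/(n−1). The screen
compresses each batch to its first 4 score dimensions — about 90–95% of
batch variance in both real leaf data and the simulator.

A screening iteration takes one randomly chosen leaf with 5 replicate
scans (scanned at different spots, so the reference captures within-leaf
variability), builds the reference mean and unbiased covariance of its
scores, and ranks all other leaves by Mahalanobis distance. The hard
constraint that score dimensions must be strictly fewer than reference
observations is enforced (4 < 5). Shortlist = top ceil(5% × eligible),
ties broken by sample id. Five iterations with distinct references; the
consensus set is the leaves present in *every* shortlist (`min_hits`
configurable; the default is the strictest reading, which matches the
low candidate counts such a screen reports).

**Covariance stabilization.** A 4×4 covariance estimated from 5 scans has
4 degrees of freedom; its smallest eigenvalue is near-degenerate with
high probability, and the classical inverse then amplifies an arbitrary
direction by 10²–10⁴. In simulation this made shortlist membership
flip between iterations for genuinely extreme samples. The bare
`mahalanobis_distance` keeps the classical estimator (with a numerical
ridge λ = 1e-8·tr(S)/p only when the condition number exceeds 1e12), but
accepts a `shrinkage` argument blending S toward its scaled identity
(tr(S)/p)·I. The screen defaults to the Ledoit–Wolf data-driven
intensity, which is large exactly when the estimate is noise-dominated
(n ≈ p) and vanishes for well-determined references. Rankings are then
stable across iterations while remaining covariance-scaled. Fixed
intensities (0 = classical, 1 = spherical) are available.

Distances are reported on the d (square-root) scale; rankings are
identical on d².

## PLS calibration

One single-response NIPALS PLS model per sugar, regressing preprocessed
spectra on mol%: weights maximize covariance with the response residual,
X and y are deflated per component, and the regression vector
b = Wᵀ(PWᵀ)⁻¹q reproduces the component-wise prediction. Component
counts per sugar (Ara 8, Gal 7, Glc 11, Xyl 10) are fixed defaults, not
auto-selected; the cross-validation report exposes RMSEP so users can
tune them manually. With as many components as rank(X), PLS prediction
equals least squares (tested); fewer components regularize.

Seeded K-fold cross-validation (default K = 10, simple random partition)
refits the model — including its centering — on each training split.
Reported: per-fold RMSEP, per-sugar R², and the pooled predicted-vs-
measured R² over all (sugar, sample) held-out pairs, computed as the
squared Pearson correlation of the pooled scatter (a regression-R²
variant is reported alongside). The pooled figure is dominated by
between-sugar abundance differences and is therefore always flattering;
the per-sugar values are the diagnostic ones.

Negative predicted mol% is reported with a warning, never clipped:
clipping would silently bias the percent differences computed from
predictions.

## Thresholds and flagging

Reference leaves define per-sugar relative variability: each reference's
relative percent deviation from its batch reference mean is computed, and
μ ± σ are the mean and unbiased standard deviation of the **absolute**
deviations pooled across batches (batches with fewer than two references
contribute nothing). Flagging thresholds are k·σ with k = 4 (≈99.99%
band under normality). The shipped defaults for rice leaves are
μ ± σ = 3.3 ± 2.3 (Ara), 12.5 ± 8.5 (Gal), 14.2 ± 9.2 (Glc), 4.8 ± 3.0
(Xyl) percent, with ready-made thresholds {Ara 9.1, Gal 34.0, Glc 36.6,
Xyl 12.1}; note that only the Gal threshold is exactly 4× the rounded σ —
the others were evidently derived from unrounded values upstream, so the
shipped threshold set is kept verbatim rather than recomputed.

Percent differences use the batch baseline appropriate to the path:
reference-sample means for confirming screen candidates, batch means of
*predicted* values for the model path. Comparison at the threshold is
closed (|Δ| ≥ t flags). Two candidate sets (screen consensus, model
flags) are combined by plain set union/intersection bookkeeping, and
validation rates are reported as rounded integer percent of
confirmed/analyzed with full precision retained internally.

## Synthetic populations

The simulator emulates what the method needs from real data, with every
quantity recorded as ground truth:

- **Spectra.** Each sugar has a basis spectrum of six Gaussian bands
  (centers 4000–9000 cm⁻¹, widths 50–300 cm⁻¹); one band per sugar lies
  in a sugar-specific subwindow — the characteristic feature that makes
  NIR quantification of individual components chemically possible at
  all. Pairwise basis correlations are kept below 0.95. A leaf's
  absorbance is the composition-weighted mixture times a batch gain,
  plus a sloped baseline and white noise (σ = 0.002 absorbance).
- **Composition.** Per-sugar lognormal variation around a batch-shifted
  base (typical rice-leaf mol%: Ara 12, Gal 6, Glc 28, Xyl 44 plus
  minors), with per-sugar CVs chosen so the four major sugars have
  comparable absolute mol% spreads (Ara 9%, Gal 15%, Glc 4.2%, Xyl
  2.7%); Gal's CV is capped by requiring that a −6σ shift keep mol%
  positive. Sibling leaves of a line share 75% of the log-variance (a
  genotype-plus-microenvironment line effect), so extreme natural
  variation arrives clustered in lines, as in a real batch of 50 lines.
  Rows are renormalized to 100 mol% (closed composition). An optional
  latent-factor co-regulation across sugars exists but defaults off: it
  places natural variation on the same axes as single-sugar lesions and
  thus destroys the very contrast the screen exploits.
- **Bounded normality.** Normal biological variation is bounded by
  construction: per-sugar deviations are clipped at 2σ and the joint
  standardized deviation radius at 2.6. The generator's semantics are a
  planted-truth design — "normal" samples are definitionally inside the
  bound, and anything beyond is an explicitly planted, labeled outlier.
  This gives the population/outlier dichotomy a ground truth against
  which sensitivity can be measured at all.
- **Planted outliers.** A chosen fraction (or exact count) of leaves get
  one major sugar displaced by k population standard deviations
  (default k = 6, versus the k = 4 flagging rule — a controlled
  true-positive margin). The displacement is solved on the
  post-renormalization scale — closure claws back up to half of a naive
  shift on abundant sugars — and lands at least kσ beyond both the batch
  base and the leaf's own draw, so a "6σ outlier" genuinely lies ≥6σ
  outside the population wherever its own draw started. The recorded
  relative shift is always ≥ k·CV·100 percent.
- **Scans.** Every scan samples one leaf location; tissue heterogeneity
  is a per-scan composition jitter at 15% of the population CV.
  Designated reference leaves receive five scans (fresh jitter, baseline
  and noise on the same leaf composition), mirroring the replicate-scan
  reference protocol. Replicate rows carry a `#s<k>` suffix on the
  sample id.

**What passing tests show — and don't.** The simulator provides linear
mixtures with smooth baselines, Gaussian noise, and bounded, labeled
variation. Real leaf spectra add water bands, scattering, developmental
gradients, and outliers for reasons other than matrix-sugar composition
(lignin, starch, cellulose), and real populations have no bound on
natural variation. Sensitivity and calibration figures obtained here
therefore validate the *implementation and its statistical machinery*
under the stated generative assumptions; they are upper bounds, not
forecasts, for instrument data — consistent with the modest wet-lab
validation rates such screens report in practice.

## Problem sizes and numerical choices

Simulated studies use one 370-leaf batch (74 lines × 5 leaves) for the
screen sensitivity checks and 100–206-sample calibration sets for the
regression checks, with 10–20 seeded replicates — sizes at which the
Monte-Carlo properties are stable while a full test run stays fast.
Tie-breaks (shortlists, consensus ordering) are by ascending sample id;
area = trapezoidal integral; crop interval closed; covariance unbiased
(n−1); all randomness flows from explicit integer seeds through
`numpy.random.default_rng`, and the staged pipeline derives per-stage
substream seeds from one global seed, making full runs byte-identical.

## Known limitations

- JCAMP-DX support covers single-spectrum AFFN (X++(Y..Y)) tables only
  (no SQZ/DIF compression, no multi-block files).
- No scatter correction (SNV/MSC) or derivative spectra; the modeled
  workflow uses none.
- Grids must match exactly for sets to be combined; resampling is out of
  scope by design (silent interpolation corrupts chemometrics).
- Component counts per sugar are fixed, not selected by RMSEP
  minimization.
- The consensus screen's sensitivity depends on the reference leaf being
  reasonably typical; an atypical random reference can suppress true
  outliers in its iteration, which the all-iterations consensus only
  partly absorbs. This is a property of the protocol, visible in
  simulation, not an implementation artifact.
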