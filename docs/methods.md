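# Methods

This note documents the models, parameter choices and numerical decisions
behind `ricehsi`, and what the synthetic experiments do and do not show
about real data.

## The synthetic experiment generator

The generator (`ricehsi.synth`) emulates a controlled-environment rice
phenotyping study: 23 accessions (15 *indica*, 8 *tropical japonica*),
two nitrogen fertigation levels (N1 high, N2 low), two replicates per
accession×treatment cell with one cell at three replicates (94 occupied
pots), four imaging weeks (6, 9, 10, 13), and destructive leaf traits
measured around week 9, with SLA/C/N unavailable for six plants (88
complete nitrogen samples).

### Latent physiology

Each plant×week state carries three latents, each 1.0 on average:

- **chlorophyll** — treatment effect ±0.25 (N1 high), accession random
  effect sd 0.08, plant residual sd 0.07, a slight downward drift with
  age, and an attenuated treatment gap (×0.45) at week 13;
- **water** — same random effects; under N1 at week 13 it drops by 0.35
  (late-season water stress of the larger, high-N canopies), which is what
  makes the final week the hardest to classify and the source of the
  cross-week degradation pattern;
- **structure** — treatment effect ±0.15 (denser high-N canopies), a
  small growth trend.

### Spectra

Reflectance is a smooth plant-like curve, not a radiative-transfer model:
a visible baseline with a green bump attenuated multiplicatively by
Gaussian chlorophyll-absorption bands (495, 655 nm); a logistic Red-Edge
ramp (width 13 nm) whose inflection sits at 702 nm + 20 nm per unit
chlorophyll, so the mean N1−N2 Red-Edge shift is the configured 10 nm; a
NIR plateau at 40% + 8 per unit structure; and a decaying SWIR baseline
carved by water troughs at 1450/1940 nm (depth growing with the water
latent) plus a fixed dry-matter feature near 2300 nm.  The default grid is
2 nm VNIR + 5 nm SWIR with a half-open junction at 1000 nm → 601 bands,
keeping wavelength-selection sizes (300–700) in their intended regime.

Raw scans are constructed so that white/dark calibration inverts exactly:
`plant = dark + gain·(R + ε)/100` with a wavelength-dependent lamp gain.
The noise ε has per-band sd `spectral_noise_sd` (default 1.0% reflectance
per scan) and is **spectrally correlated**: 70% of its variance is a
circularly-smoothed component (Gaussian kernel, ~10 bands) and 30% white.
Real canopy scans do not carry independent noise per band — illumination
geometry and plant pose perturb whole spectral regions together — and the
effective noise dimensionality matters downstream: selection procedures
can exploit independent noise dimensions, so unrealistically white noise
makes null traits spuriously "predictable" (see *Known limitations*).

### Traits

Leaf N (%) = 1.0 + 1.2·chlorophyll + 0.3·1[N1] + noise (sd 0.13).  The
0.3 offset is luxury uptake: heavily fertigated plants accumulate leaf N
beyond what pigment levels track, making the N–chlorophyll mapping
treatment-dependent.  This is what breaks cross-treatment transfer — a
purely spectral treatment shift would not, because a linear model on a
global monotone chlorophyll→N mapping extrapolates across treatments.
C (%) is 40 ± 0.5 independent of everything, so C:N = C/N is strongly
anti-correlated with N (≈ −0.96 in samples) and C itself is genuinely
unpredictable from spectra.  gsw is log-normal and E = 1.6·gsw exactly
(log-transforms correlate 1.0).  Quantum yields, SLA components, Vcmax
and biomass couple to the latents with noise chosen so the sample
correlations match the magnitudes a real study reports (corr(N, pQY) ≈
0.5, corr(N, mQY) ≈ 0.4, corr(SLA, N) ≈ 0.5); final biomass couples to
water/structure only.

The noise scales were anchored once to the reported performance of the
real analysis this pipeline re-implements (validation R² ≈ 0.8 for N) and
then frozen; the resulting analytic ceiling for N prediction is

    R²max = s / (s + σ²),  s = (1.2·0.5 + 0.3)²/4 + 1.2²·(0.08² + 0.07²)

= 0.928 with defaults (`analytic_r2_ceiling`).

### What the generator does not emulate

Pixel-level imagery, plant/background segmentation, camera spectral
response, temporal dynamics finer than weekly, and radiative-transfer
realism (PROSPECT/SAIL-class models).  Passing tests show the *pipeline*
is correct and that the *phenomena* (Red-Edge treatment signal, transfer
asymmetry, sample-size effects) follow from the stated couplings — not
that real rice data will reach the same numbers.

## Analysis decisions

- **Calibration QC**: reflectance outside [0, 100]% under noise is
  retained (clipping would bias means); a QC report flags rows with >1%
  of bands outside [−5, 105]%.
- **"Normalized" traits** (normFB, normpQY, normmQY) are min–max scaled
  to [0, 1] (configurable to z-scores); logs are natural.
- **Correlation significance** is a per-pair two-sided t-test at α = 0.01
  with no multiplicity correction, computed after mean imputation.
- **Trait PCA** standardizes columns (correlation-matrix PCA);
  **clustering** standardizes before Euclidean distance (mixed units make
  raw distances meaningless) and uses average linkage; scipy's ordering
  makes results deterministic for a given input order.
- **Spectral PCA** is covariance-based (centered, unscaled) on
  accession-mean spectra; `W_SVM` pools the top-10 |loading| wavelengths
  of the minimal leading components strictly exceeding 90% cumulative
  variance ("top loadings" read as absolute values; the top-k is a
  parameter, so the 20–30-loading variant used for visual summaries is
  available).
- **RReliefF** follows the regression Relief estimator with expRank
  weighting: k = 70 neighbors (capped at n−1), σ = 20, Manhattan distance
  on min–max-scaled attributes, m = 100·n sampled instances with
  replacement.  Because neighborhoods are deterministic given the data,
  per-instance contributions are computed once and the m draws only weight
  them — numerically identical to the literal loop (tested against one).
- **SVM protocol**: features standardized on the training week and the
  same transform applied to evaluation weeks; 23-fold stratified CV
  (accession-grouped folding available — the fold count plausibly maps to
  the 23 accessions); accuracy is pooled held-out proportion correct; the
  fine grid spans ±0.5 in the exponent at step 0.1, widened to ±2 and
  clipped when the rough optimum sits on a lattice boundary; fine
  parameters adopted only on strict improvement.  Grid-point ties resolve
  to the smallest exponents.  Note the best-of-grid CV accuracy is
  optimistically biased (selection over ~340 grid points); under permuted
  labels it centers near 0.55–0.6 rather than 0.5, and same-week
  train/evaluate entries of the cross-week matrix are optimistic for the
  same reason.
- **PLSR** centers predictors and response, no scaling (reflectances
  share units).  Coefficients for all component counts come from one
  NIPALS pass via the recursion r_h = w_h − Σ_{j<h}(p_jᵀw_h)·r_j, which
  makes leave-one-out selection O(n) fits.  The component search is
  capped at min(20, n−1, p); LOO RMSEP ties (including numerically exact
  fits) resolve to the smallest count; a 0-component optimum is returned
  as a first-class "not fittable" result, never an exception.  NIPALS
  stops early if the residual weight norm underflows (rank exhaustion).
- **Jackknife intervals** use the normal approximation with the
  (n−1)/n jackknife variance factor.  They quantify model uncertainty in
  the predicted values (coverage of the noise-free truth ≈ 95% in
  simulation), not prediction intervals for noisy measurements.
- **Splits** take floor(0.8·stratum) per treatment stratum — pinned by
  the 78 → 62 calibration correspondence.
- **Wavelength scoring uses calibration rows only** (no leakage of
  validation responses; verified by a permutation test).  The ranking is,
  however, computed once before the LOO component search, exactly as in
  the protocol being re-implemented — see limitations.
- **Seeding**: every stochastic operation takes an explicit seed; the
  pipeline splits one global seed into per-stage streams by hashing
  stable stage names, so toggling a stage never changes another stage's
  draws.

## Problem sizes

The test suite and the acceptance script run the full default design (94
plants, 601 bands, 4 weeks, 3 scans/week).  Repeated-seed properties use
20 generator seeds; the hyperparameter study reports its two headline
cells at 30–50 iterations and the full 50-cell grid at 10 iterations
(the full 100-iteration grid is a parameter away).

## Known limitations

- Scoring wavelengths on calibration data *outside* the LOO loop leaks
  selection into component choice; with many effectively independent
  predictors this can make pure-noise traits appear fittable.  The
  pipeline reproduces the protocol faithfully and relies on realistic
  spectral noise correlation to keep the effect small; a fully nested
  selection would remove it at ~n× the cost.
- The best-of-grid SVM accuracy is an optimistic estimator (above).
- The generator's analytic ceiling assumes the spectra identify the
  latents perfectly; finite spectral noise keeps realized validation R²
  slightly below it.
- C:N inherits essentially all of its signal from N (C is near-constant),
  so its models mirror N's rather than adding independent information —
  which is itself one of the phenomena worth knowing about.
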