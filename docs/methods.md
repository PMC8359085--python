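# Methods

## The quantity being modelled

Hepatocellular carcinoma (HCC) progressively replaces portal-venous blood
supply with newly formed arterial supply ("arterialization"). On a
three-phase contrast-enhanced CT study the arterial enhancement fraction

    AEF = (CTa − CTu) / (CTp − CTu)

— arterial-phase enhancement over portal-phase enhancement, computed per
voxel from the unenhanced (CTu), arterial (CTa) and portal (CTp) CT numbers
— approximates the arterial share of tissue perfusion. Because
arterialization is multifocal, a lesion's response to transarterial
chemoembolization (TACE) is associated not just with its mean AEF but with
the *spatial heterogeneity* of its AEF map. `aeftex` quantifies that
heterogeneity with 32 texture features of the lesion ROI and feeds them
into logistic response-prediction models.

### Validity handling

The AEF denominator CTp − CTu can be zero or negative (noise,
non-enhancing tissue). Voxels with CTp − CTu ≤ ε are flagged invalid and
excluded from every downstream statistic — never zero-filled, which would
fabricate gray levels. Defaults: ε = 1 HU (rejects division-by-noise while
keeping genuinely portal-enhancing tissue) and a clip window of [0, 4]
(clinical lesion AEF summaries sit around 0.1–2; negative AEF, i.e.
arterial de-enhancement, clips to 0). Both are parameters of
`compute_aef_map` and of the CLI.

### Phase alignment

`align_phases` is an integer rigid translation found by exhaustive search
(mean-squared difference on the overlapping region, window ±`max_shift`
voxels per axis), applied circularly. It warns when the optimum sits on the
window boundary. This is deliberately *not* a deformable registration: the
synthetic phantoms are rigid, and the alignment utility exists to exercise
the pipeline contract, not to correct real breathing motion.

## The 32 texture features

Texture is computed in 2-D on the ROI's largest axial plane (ties broken
toward the lower plane index), matching how such ROIs are delineated in
practice — on one plane, along the tumor outline. Four families:

* **IBS (11)** — order statistics and moments of the raw (unquantized)
  valid AEF values: MinIntensity, MaxIntensity, MedianIntensity, MeanValue,
  StdDeviation (population), Variance, VolumeCount (valid in-plane pixel
  count), VoxelValueSum, Range, MeanDeviation (mean |x − mean|),
  RelativeDeviation (sd/mean; 0 when the mean is 0).
* **IBH (5)** — Skewness and Kurtosis (standardized third/fourth moments,
  kurtosis with the Fisher −3 convention), plus Uniformity = Σpᵢ² and
  Entropy = −Σpᵢ log₂ pᵢ over a 256-bin min–max histogram, and
  Energy = Σpᵢ² over the Ng-level discretization. Energy and Uniformity are
  the same functional at different binning — they differ numerically but
  are strongly redundant, which is why a |ρ| ≥ 0.9 filter typically keeps
  only one of them.
* **GLCM (6)** — Haralick features of the symmetric co-occurrence matrix at
  unit distance, averaged over the four 2-D directions
  {(0,1), (1,0), (1,1), (1,−1)}: Inertia (contrast), Correlation,
  InverseDifferenceMoment, ClusterShade, ClusterProminence, and
  HaralickCorrelation. HaralickCorrelation follows the ITK convention where
  the centring and normalisation terms are the mean and variance of the
  *marginal probability vector entries* (not of the level values); this is
  what produces its characteristic ~10⁶ magnitude and distinguishes it from
  the [−1, 1] Correlation.
* **GLRLM (10)** — the classical Galloway run-length statistics and their
  gray-level extensions, per direction and then averaged: runs are maximal
  same-level sequences of in-ROI pixels; out-of-ROI (or invalid) pixels
  break runs. Each direction conserves pixels: Σ r(g, l)·l equals the ROI
  pixel count.

Quantization for the matrix features is uniform min–max binning of the
ROI's valid values into Ng levels (level Ng at the maximum; a constant ROI
maps to level 1). Defaults Ng = 64 and 256 histogram bins were chosen so
the default feature magnitudes match clinical AEF texture reports (Entropy
≈ 6–7 bits needs >2⁷ bins; HighGreyLevelRunEmphasis of order Ng²
≈ 2–4×10³ implies Ng ≈ 64). The source tool's discretization is
unpublished, so these remain configurable (`TextureConfig`).

Degenerate conventions (all explicit and tested, chosen so no input yields
non-finite features): constant or single-pixel ROI → Skewness = Kurtosis
= 0, Entropy 0, Uniformity 1; constant plane → Correlation =
HaralickCorrelation = 1, Inertia = 0, InverseDifferenceMoment = 1; a plane
with no co-occurring pixel pair in any direction falls back to the same
homogeneous-plane values.

Tumor area is in-plane pixel count × pixel area, reported in cm².

## Synthetic phantoms and cohorts

No patient data ships with the package; the generator produces
study-shaped inputs.

* **Phantom**: a (16, 64, 64) grid at (3, 0.8, 0.8) mm — a desk-scale
  abdominal CT geometry — with portal-dominant background
  (50/62/95 HU across phases). Lesions are *physical* spheres: the radius
  is given in in-plane voxels and the through-plane semi-axis is shrunk by
  the plane/pixel anisotropy (3/0.8), because an index-space sphere of
  clinical size cannot fit a 16-plane grid. Inside a lesion, a fraction of
  voxels ("arterialized patches") takes a strong arterial gain
  (default 70 HU) and the rest a weak one (25 HU) over a uniform portal
  gain (60 HU), so the noise-free AEF is two-valued: 25/60 ≈ 0.42 and
  70/60 ≈ 1.17, bracketing clinical lesion values. Patches are realized by
  thresholding a Gaussian-smoothed white-noise field at the exact sample
  quantile of the requested fraction; `cluster_scale` (the smoothing sigma,
  in voxels) sets patch granularity. HU noise is additive Gaussian,
  independent across phases, default sd 4 HU.
* **Heterogeneity knob**: the arterialized fraction. Note the response of
  Entropy/Energy/InverseDifferenceMoment is non-monotone with a peak at
  fraction 0.5 (two-component mixing entropy); scenarios meant to have a
  monotone "more heterogeneous" direction keep group means at or below 0.5.
* **Cohort**: two labelled groups (`Improved`/`Un-improved`, sizes 22/23,
  or `Un-worsened`/`Worsened`, 31/14 — the clinical splits). The positive
  group's lesion-parameter means are offset by `group_effect` (default:
  arterialized fraction +0.25, i.e. responders are more heterogeneous — the
  direction observed clinically: lower Energy, higher Entropy in
  responders). Subjects jitter around their group mean: arterialized
  fraction sd `subject_frac_sd` (default 0.15), cluster scale ×
  lognormal(sd 0.15), radius × N(1, 0.08). The default dispersion makes
  the groups overlap substantially, so a default cohort yields moderate
  univariate significance (p ~ 10⁻⁴) and an imperfect model (AUC ≈ 0.85),
  rather than trivially separable data. Subject i draws all randomness from
  a generator seeded `seed + i` (keep seeds below 2³¹ − n), so cohorts are
  bit-reproducible and single subjects can be regenerated.

What the generator does **not** emulate: liver anatomy, vessels, lipiodol
deposits, breathing motion, scanner spectra, partial-volume effects, or any
quantitative lesion-level AEF spatial statistics from the clinical cohort
(none were published). Passing tests therefore demonstrate correctness of
the computational pipeline and the qualitative direction of the
heterogeneity→response association under this generative model — not
clinical performance of the published models on real patients.

## Statistics and modeling

* **Univariate comparisons** mirror standard clinical-table practice: each
  feature is screened per group with a one-sample Kolmogorov–Smirnov test
  against N(sample mean, sample sd) — the plain KS test, without the
  Lilliefors estimated-parameter correction, a deliberate and documented
  simplification. Both groups normal (α = 0.05, n ≥ 5) → pooled-variance t
  test; otherwise Mann-Whitney U with mid-ranks, exact enumeration when
  min(n) ≤ 10 with no ties, tie-corrected normal approximation otherwise.
  Rank means are always reported. 2×k tables: chi-squared without
  continuity correction when all expected counts ≥ 5, Fisher's exact test
  for small-expected 2×2. All p two-tailed; no multiplicity correction (the
  clinical table applies none).
* **Standardization** is z-scoring with the sample (n−1) sd; the per-column
  mean/sd record travels with the model so new subjects score on the
  training scale.
* **Redundancy filter**: greedy Spearman elimination — repeatedly take the
  remaining pair with the largest |ρ| ≥ 0.9 and drop the member with the
  weaker univariate Mann-Whitney association; exact ties keep the
  alphabetically first name. Result is order-independent for distinct
  association strengths. The filter is rank-based, so filtering before or
  after standardization is equivalent; we standardize first.
* **LASSO selection**: L1-penalized logistic regression over a 40-point
  log-spaced penalty grid descending from the smallest λ that zeroes all
  coefficients; λ chosen to minimize mean held-out binomial deviance over
  stratified 5-fold cross-validation (the min rule, not 1-SE; ties prefer
  the sparser λ); fold assignment is fixed by the seed. Nonzero
  coefficients of the full-data refit at the chosen λ are the selection.
* **Final model**: unpenalized maximum-likelihood logistic fit with Wald z
  and two-tailed p per term. Perfect separation is reported as a warning on
  the returned model (coefficients at the iteration cap) rather than an
  error — small radiomics cohorts separate easily, and the published Model
  A itself shows the signature of near-separation (intercept z ≈ 0,
  p = 1.000).
* **Published models**: the two fixed-coefficient models ship as versioned
  JSON resources — model A (Improved outcome, 9 terms, intercept −7.1555)
  and model B (Un-worsened outcome, 4 terms, intercept 3.1287). They expect
  *standardized* feature inputs and are applied as
  lp = intercept + Σ βᵢxᵢ, p = 1/(1+e^(−lp)). Where the printed formula and
  the coefficient table disagree in the last digit
  (LongRunHighGreyLevelEmphasis in model A), the table value −12.0604 is
  used.

## Evaluation

* **ROC**: trapezoidal AUC over all distinct thresholds — identical to the
  normalized Mann-Whitney statistic U/(n₀n₁) with mid-rank ties, an
  identity the tests exploit as a cross-check. Operating point: maximal
  Youden J, ties toward the lower cutoff; predicted-positive means
  score ≥ cutoff (closed on the left, making net-benefit curves
  bit-reproducible). The cutoff rule is recorded in the report metadata
  because the clinical source does not name its rule.
* **Calibration**: equal-frequency reliability bins (default 10) plus a
  logistic recalibration of the outcome on logit(p̂); slope 1, intercept 0
  is perfect calibration. Constant-probability input degenerates to a
  single bin with slope 1 by convention.
* **Decision curves**: net benefit NB(pt) = TP/n − (FP/n)·pt/(1−pt) on the
  grid 0.01…0.99 (step 0.01), against treat-all
  (prevalence − (1−prevalence)·pt/(1−pt)) and treat-none (≡ 0). A perfect
  classifier's NB equals prevalence at every threshold — an analytic
  identity used as a test.

## Problem sizes in the shipped test suite

Monte-Carlo checks run at sizes chosen to keep the default suite around a
minute: cohort-level type-I error uses 120 replicate 6+6 cohorts on
32×32×10 grids; the entropy-separation check 20 replicate 8+8 cohorts; the
direction-of-effect acceptance check 40 replicate 30+30 cohorts on
48×48×10 grids with a strong standardized effect (fraction shift +0.40,
subject sd 0.06); LASSO recovery 100 seeded replicates at n = 200; null
type-I error for the continuous comparison 1000 replicates at n = 20+20.
These sizes are package choices and are trivially editable in the tests.

## Known limitations

* 2-D, single-plane, four-direction texture only; no 3-D texture, no
  filtered (wavelet/LoG) features, no feature families beyond the frozen 32.
* The source tool's discretization, direction set and feature definitions
  are unpublished; Range/MeanDeviation/RelativeDeviation use literal
  readings of their names, and Energy-vs-Uniformity is a binning
  distinction only.
* The rigid integer alignment is a pipeline surrogate, not motion
  correction.
* Published-model coefficients are applied to *this package's* standardized
  features; because the original feature implementation is proprietary and
  its cohort restricted, absolute probabilities from models A/B on
  synthetic data have no clinical meaning — only the worked-example
  arithmetic (intercepts, slopes, affinity) is checkable, and it is.
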