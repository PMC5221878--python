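# Methods

This note records the models, conventions and numerical choices behind
`qctlung`, and what the synthetic data can and cannot establish.

## Image model and coordinates

A CT slice is a 2-D float matrix of Hounsfield units with per-axis pixel
spacing in mm (anisotropic spacing supported throughout; the phantom
defaults to isotropic 0.7 mm, a typical thorax-CT in-plane resolution).
Pixels are addressed `(row, col)`, 0-based, and geometry refers to pixel
centers. Integer storage conventions (DICOM rescale slope/intercept) are
resolved at the I/O boundary; internally HU are floating point because
phantom generation and smoothing produce non-integer values. Display
windowing is the standard linear clamp: HU at `level ± width/2` map to
0/1.

## Segmentation

Region growing is defined exactly: the 8-connected component, containing
the seed, of the set of pixels with HU inside `[lower, upper]`. The
interval is either given explicitly or derived as the 3×3
seed-neighbourhood median ± a half-width (default 350 HU). Both the
half-width and the connectivity are parameters rather than fixed truths:
interactive wand-style tools vary in both, and 8-connectivity was chosen
because 4-connectivity fragments thin lobulations. Note the consequence of
the default half-width: seeded in a solid core, the interval `[~40−350,
~40+350]` excludes ground-glass at ≈ −450 HU, so sub-solid tumors need a
wider interval (e.g. −600 to 200 HU, the range used in the examples).

Manual separation of vessels/bronchus/chest wall is represented by
exclusion masks applied as set difference followed by restriction to the
seed's connected component. Interior holes are *not* auto-filled: air
bronchograms are excluded from the measured ROI by convention, and a
`fill_holes` operation exists only as an explicit opt-in. Thin- and
thick-slice ROIs of the same tumor are compared by Dice overlap
(`juxtapose_check`); a failing check signals re-delineation, mirroring the
juxtaposition step of the interactive protocol.

## The ten features

* **Area**: pixel count × pixel area (mm²).
* **Perimeter**: length of the traced *outer* crack boundary with the
  classic ImageJ wand weighting — 0.948 per unit edge and 1.340 per
  counted corner pair, with consecutive unit sides counting only every
  other vertex as a corner. Naive crack-edge counting overestimates a
  digital circle's perimeter by ~27% (4/π); with this weighting, digital
  disks of radius 10–80 px measure within 2% of 2πr, while axis-aligned
  squares deviate by ≈ 5% (the weighting is calibrated for smooth
  anatomical outlines, not rectilinear ones). The corner scan is anchored
  at a side longer than one unit, making the measurement exactly invariant
  under 90° rotation and mirroring. Interior holes never contribute.
* **Feret diameter**: maximum pairwise distance between boundary-pixel
  centers, computed on the convex hull (provably equal to brute-force
  all-pairs).
* **Mean attenuation**: arithmetic mean HU over the ROI.
* **Circularity**: `4πA/P²`, clipped at 1.0 (the tracer can overshoot by
  <1% on near-perfect disks).
* **Ellipse-derived shape**: the second-central-moment ellipse of the
  pixel centers, rescaled so its area equals the ROI area. Under that
  area-preserving convention `roundness = 4A/(π·major²)` is identically
  `1/aspect_ratio`, which is the consistency the printed worked examples
  obey (aspect 1.15 ↔ roundness 0.87) and a property test enforces to
  ±0.01.
* **Skewness / kurtosis**: population-normalised standardized moments,
  `mean(z³)` and `mean(z⁴) − 3` (excess). No small-sample bias correction
  is applied: ROI pixel counts are in the hundreds-to-thousands and the
  plain-expectation definition is the one the formulas state.
* **Entropy**: `−Σ pᵢ log₂ pᵢ` over fixed-width bins spanning the observed
  ROI range. Base 2 and 1-HU bins are defaults (consistent with reported
  magnitudes around 6.7–7.1 bits for tumor ROIs) but both are parameters,
  because entropy is not comparable across binning conventions; absolute
  entropy values should not be compared between software without aligning
  them.

### Reporting precision

`reporting.printed_round` reproduces chained printed precision: half-up
rounding at one extra decimal, then at the target. Derived quantities in
figure legends typically pass through such an intermediate precision
(e.g. a circularity of 0.5649 printed as 0.565 → 0.57), so consistency
checks against printed values use this chain rather than single-stage
rounding.

## Phantom generator

The nodule scene is a star-convex region `r(θ) = r₀·g(θ)` on a uniform
−800 HU lung background: `g ≡ 1` for disks, the polar ellipse radius for
ellipses, and `1 + Σₖ aₖcos(kθ+φₖ)` (k = 2…5, amplitudes ∝ 1/√k, drawn
from the seed) for lobulated shapes. `r₀` is normalised by numeric
quadrature of `∫g²dθ` so the enclosed area matches the target; pixels are
inside if their centers are, so the rasterized area differs from target
by at most about one boundary row. Part-solid composition renders the
outer `ggo_fraction` of area at −450 HU around a solid 40 HU core scaled
to `√(1−f)`; an optional air-bronchogram hole is set to −950 HU and
excluded from the ground-truth mask.

The paired reconstruction is emulated, not physically simulated: the
sharp/thin image is scene + Gaussian noise (default SD 35 HU), the
smooth/thick image is the scene blurred with a σ = 1.5 px Gaussian plus
weaker noise (default SD 10 HU). No protocol publishes its noise
magnitudes; these defaults give the qualitative contrast that matters to
the analysis (thin = sharp but noisy, thick = smooth), and only that
contrast — not sinogram physics, beam hardening, dose, or
scanner-to-scanner variability — is represented. Consequently the phantom
validates geometry and the *direction* of thickness effects, not absolute
texture values on real scanners.

## Cohort simulation

Per patient, tumor area is lognormal (mean 287, SD 280 mm², the pooled
cohort moments) and mean attenuation normal (−154 ± 215 HU, clipped to
physical range); these two drive recurrence through
`logit P = β₀ + ln(1.002)·area + ln(1.005)·attenuation`, with β₀
root-found (per draw) so expected prevalence is 25/194 ≈ 0.129. Diameter,
perimeter and circularity are derived from area (circle-equivalent
diameter inflated by a half-normal irregularity factor; perimeter from a
drawn circularity), so the size features carry realistic mutual
correlation; aspect/roundness obey the reciprocal identity; skewness,
kurtosis and entropy are drawn from the observed marginal moments but
independently of outcome and of each other — the simulation does not
encode texture–outcome or texture–attenuation dependence, so null results
for those features in the simulated cohort are by construction, not
evidence.

Event times are descriptive only (recurrences uniform on 0.5–2.6 years,
censoring uniform on 2–3 years): they give the Cox cross-check the same
risk ordering as the logistic model but are not a hazard-faithful disease
model.

Thick-slice copies of each feature come from the variance-components
identity `ICC = σ²_between/(σ²_between + σ²_noise)`: given a target ICC
ρ, additive noise with variance `σ²_between(1−ρ)/ρ` is applied per
feature. The default target profile follows the observed agreement
ordering (size/attenuation ≈ 0.95–0.99; shape ≈ 0.71–0.81;
skewness/kurtosis ≈ 0.53–0.60; entropy 0.85). Because the noise scale is
a cohort-level quantity, this operation takes the cohort feature table,
not a single patient's vector.

## Statistics

* **ICC**: two-way random effects, absolute agreement, single measures
  (ICC(A,1), via pingouin), the defensible variant when the "raters" are
  two measurement systems; consistency (ICC(C,1)) is available by flag
  since the two differ in the third decimal when means shift between
  reconstructions. Bands: ≤0.20 poor, ≤0.40 fair, ≤0.60 moderate, ≤0.80
  substantial, else excellent.
* **Logistic regression**: maximum likelihood (statsmodels), odds ratios
  reported per explicit scale unit (`exp(coef·scale)`) with Wald 95% CIs —
  reported effect scales (per mm², per HU, per 10 HU) vary between tables
  in this literature, so the scale is a column of the result, never
  implicit. Complete separation raises with a diagnostic rather than
  returning an unbounded estimate.
* **Forward conditional selection**: entry by the Rao score test of each
  candidate given the current model (p < 0.05 to enter, smallest p
  first); after each entry, included terms are re-tested and removed when
  their likelihood-ratio p exceeds 0.10. The removal test is an exact LR
  refit rather than the "conditional" one-step approximation some
  legacy software uses to avoid refits — with modern fitting cost the
  exact test is strictly preferable and agrees asymptotically. The full
  entry/removal trace is returned and is deterministic for a given
  cohort.
* **ROC/C-index**: AUC by the concordance rule (ties half), equal to the
  trapezoidal area; variance by DeLong's structural components via
  midranks; CI clipped to [0,1]. The C-index of a fitted model uses its
  in-sample linear predictor — apparent performance, flagged as such in
  the result notes, since the design has no validation split.
* **Group tests**: Student t (equal variances) for continuous, Pearson
  chi-square without continuity correction for categorical; Fisher's
  exact on sparse 2×2 tables by the expected-cell<5 rule, with an
  override because published tables do not apply the switch uniformly.
* **Cox**: lifelines partial likelihood with Efron ties, HR with Wald CI.

## Problem sizes in the test suite

Oracle-equivalence checks (region growing vs exhaustive flood fill, Feret
vs all-pairs, AUC vs concordant-pair counting) run on grids ≤ 128×128,
masks ≤ 64×64 and cohorts ≤ 50 — sizes where the brute-force reference is
exact and instant. Statistical calibration checks use 100–200 simulated
cohorts of n = 500–2000, enough for the binomial/CI tolerances asserted
(e.g. ≥90% CI coverage of the generating odds ratios, ICC within ±0.02 of
a 0.98 target at n = 500).

## Known limitations

* Single representative axial slice by design; no 3-D segmentation or
  volumetric features.
* The phantom's lung background is uniform; no vasculature, pleural
  contact or motion artefacts, so exclusion-mask handling is exercised
  only on synthetic geometry.
* First-order histogram features only; no co-occurrence/run-length
  texture families.
* Entropy magnitudes depend on binning and are not portable across
  software conventions.
* The simulated cohort encodes outcome dependence only through area and
  attenuation; it cannot validate texture-based prognostic claims.
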