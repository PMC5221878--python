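# qctlung

Quantitative CT analysis of surgically resected lung adenocarcinoma, built
as a tested, reusable pipeline. The scientific question it serves: do
preoperative quantitative CT features of the tumor — measured on a single
representative axial slice — predict post-resection recurrence, and how
stable are those features across reconstruction thickness (1-mm
high-frequency vs 5-mm standard kernel)?

The pipeline covers four stages, each usable on its own:

1. **Segmentation** — semi-automatic tumor delineation: a seed click inside
   the tumor under the lung window (width 1500 HU / level −700 HU), then
   attenuation-based region growing (8-connected, fixed HU interval around
   the seed-neighbourhood median), with scripted exclusion masks standing in
   for the manual separation of vessels, bronchus, chest wall and air
   bronchograms.
2. **Features** — the ten per-tumor quantities:
   Feret diameter (mm), perimeter of the traced outer boundary (mm), area
   (mm²), mean attenuation (HU), circularity `4πA/P²`, aspect ratio
   `major/minor` of the area-preserving moment ellipse, roundness
   `4A/(π·major²)`, and first-order histogram skewness `E[((X−μ)/σ)³]`,
   excess kurtosis `E[((X−μ)/σ)⁴] − 3` and entropy `−Σ pᵢ log₂ pᵢ` over
   1-HU bins.
3. **Agreement** — thin- vs thick-slice comparability per feature by the
   intraclass correlation coefficient (two-way random effects, absolute
   agreement, single measures), interpreted on the conventional bands
   (≤0.20 poor … 0.81–1.00 excellent).
4. **Recurrence modelling** — univariate logistic regression per feature,
   a multivariable model built by forward conditional selection (score test
   to enter at p < 0.05, likelihood-ratio re-check to remove at p > 0.10),
   the apparent C-index (AUC with a DeLong-type CI) of the fitted risk
   score, and a univariate Cox model as a cross-check.

Because no clinical images ship with the package, a **phantom module**
generates the study conditions synthetically: nodules of controllable area,
shape (disk / ellipse / lobulated), solid and ground-glass composition on a
−800 HU lung background, rendered as a paired reconstruction (sharp, noisy
thin slice vs blurred, cleaner thick slice) with a ground-truth mask; and a
simulated cohort whose recurrence follows a logistic model in tumor area
and mean attenuation (odds ratios 1.002 per mm² and 1.005 per HU, ~13%
prevalence at n = 194 by default).

## Worked example

```python
import qctlung as q

# a part-solid lobulated nodule, reconstructed sharp/1-mm and smooth/5-mm
spec = q.NodulePhantomSpec(shape="lobulated", target_area_mm2=420.0,
                           ggo_fraction=0.3, seed=9)
sharp, smooth, truth = q.generate_nodule_pair(spec)

# grow over the full sub-solid attenuation range; the narrower default
# interval from q.bounds_from_seed() would capture only the solid core
roi = q.region_grow(sharp, truth.seed, -600.0, 200.0)
fv = q.extract_features(sharp, roi)
print({k: round(float(v), 2) for k, v in fv.as_dict().items()})
```

prints (seed 9):

```
{'diameter_mm': 27.26, 'perimeter_mm': 78.98, 'area_mm2': 419.44,
 'mean_attenuation_hu': -105.48, 'circularity': 0.84, 'aspect_ratio': 1.3,
 'roundness': 0.77, 'skewness': -0.86, 'kurtosis': -1.14,
 'entropy_bits': 7.74}
```

— a 27 mm part-solid tumor whose mean attenuation (−105 HU) reflects its
30% ground-glass component, moderately non-circular (0.84) from the
lobulated margin. On the cohort side:

```python
cohort = q.simulate_cohort(q.CohortSimSpec(n=2000, seed=3))
model = q.forward_conditional_logistic(
    cohort, ["diameter_mm_1mm", "perimeter_mm_1mm",
             "area_mm2_1mm", "mean_attenuation_hu_1mm"])
print(model.extras["selected"])
# ['mean_attenuation_hu_1mm', 'area_mm2_1mm']
print(model.table[["term", "estimate", "lo", "hi"]].round(4))
#                       term  estimate      lo      hi
# 0                Intercept   -2.1742 -2.3955 -1.9529
# 1  mean_attenuation_hu_1mm    1.0048  1.0039  1.0058
# 2             area_mm2_1mm    1.0021  1.0016  1.0026
```

The selection recovers area and mean attenuation as the independent
predictors with odds ratios at their generating values (1.002/mm² and
1.005/HU); the apparent C-index of the fitted score,
`q.roc_cindex(model.extras["linear_predictor"], cohort["recurrence"])`,
is 0.755 on this cohort.

The same flow is scriptable end to end:

```bash
qctlung run --seed 5 --out run/        # phantom → segment → features → stats
qctlung phantom cohort --n 500 --seed 7 --out cohort.csv
qctlung stats --cohort cohort.csv --out results/
```

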