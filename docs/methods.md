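# Methods

## The generative model behind the synthetic cohorts

The cohort generator emulates a cross-sectional comparative study: for
each species, `n_individuals` animals are drawn with one age each,
uniform over `age_range` (real zoo cohorts are opportunistic, with no
stated sampling design, so a flat prior over the observed range is the
least-committal choice). For an individual of age *a*, each of its cells
is "damaged" with probability

```
p(a) = clip(p0 + r·a, 0, 1)
```

where `p0` is the baseline damaged fraction and `r` the true damage rate
per year. Clipping, rather than a logistic link, is the simplest model
consistent with the linear trends the analysis fits. Per-cell γH2AX
intensity is a two-component lognormal mixture — lognormal because
fluorescence is non-negative with multiplicative noise, two components
because the positivity rule presumes a damaged and an undamaged
population. Defaults put the components at log-means 4.0 and 5.5 (log-sd
0.3 each), i.e. ≈5 log-sd of separation, so misclassification by a
mid-gap threshold is negligible. Per-cell telomere fluorescence is
lognormal with log-mean declining linearly in age
(`telomere_log_mean_at_birth − telomere_decline_per_year·a`, defaults
8.0 and 0.01/yr, log-sd 0.5) — values chosen once as plausible for
high-throughput Q-FISH-style data.

`datasets.study_cohort_configs()` carries the study-design defaults: the
reported per-species cohort sizes and age ranges (9 dolphins aged
8.6–50.1 yr, 15 goats 0.85–10.1 yr, 8 reindeer 1.44–10.5 yr, 15 flamingos
0.79–50.1 yr, 6 vultures 8.06–21.4 yr, 3 sea turtles 8.35–43.7 yr) with
the published γH2AX rates as generative truth. The per-individual cell
count for the damage assay was never reported; the default of 5,000 cells
is an ordinary high-content-screening well yield and is configurable.

Randomness: one master seed; per-individual and per-field substreams are
`numpy` generators seeded with the `(seed, index)` pair, so any subset of
the outputs is reproducible regardless of generation order.

## Synthetic images

2D fields place non-overlapping, randomly oriented filled ellipses
(rejection sampling on bounding circles, bounded attempts) on a constant
background; the damage channel inside nucleus *i* is
`background + assigned_intensity_i`, so the measurement stage can be
validated to machine precision when blur and noise are off. Optics are a
Gaussian PSF followed by Poisson shot noise with one global gain. 3D
stacks add telomere and 53BP1 foci as Gaussian blobs (σ = 0.8 voxel)
whose placement uses the Euclidean distance transform of each nucleus:
"interior" spots sit ≥ rim_margin + 2 voxels from the boundary,
deliberate edge spots sit inside the rim band, constructed TIF pairs
share a voxel across channels, and all same-channel spots keep ≥ 7 voxels
of separation so detected integration spheres (radius 3) do not swallow a
neighbour's tails. Ground truth records every centroid, the rendered blob
sum, and colocalization/rim flags. What the generator does **not**
emulate: plate/batch effects, autofocus failure, anisotropic PSFs,
overlapping or touching nuclei, and realistic chromatin texture — so
passing image tests demonstrate correctness of the measurement code on
idealised fields, not segmentation robustness on real microscopy.

## Measurement

Nucleus segmentation is global Otsu thresholding of the nuclear channel,
full-connectivity connected components, minimum-area and optional
border-exclusion filters, relabelled contiguously. This is a documented
stand-in for the proprietary high-content-screening software used with
real data, validated only against synthetic ground truth. Pan-nuclear
damage intensity is the **mean** (not sum) over the nucleus mask with no
background subtraction, making the statistic independent of nucleus area.
Foci are local maxima above an absolute threshold within nucleus masks,
merged below 2 voxels; spot intensity integrates a 3-voxel-radius sphere.
A spot is "near rim" when its peak lies within `rim_margin` (default 2)
voxels of the nucleus boundary. A TIF is a same-nucleus telomere×53BP1
pair within `max_distance` (default 2) voxels after rim-flagged 53BP1
spots are removed; matching is greedy nearest-first and one-to-one with
coordinate tie-breaks, so results are invariant to input order. The
headline per-individual statistic (% of cells with ≥1 TIF) is insensitive
to the matching scheme. Per-cell telomere fluorescence is the **sum** of
telomere spot intensities (nuclei without spots get 0 and a flag); the
sum-vs-mean choice is undocumented in the protocol this emulates, and sum
was chosen as the natural total-telomere-content proxy. Coordinates are
0-based `(z, y, x)` voxel indices; distances assume isotropic voxels.

## Scoring

Percentiles interpolate linearly between closest order statistics
(`h = (p/100)(n−1)`), which is bit-reproducible and makes an even-sized
tie-free reference exactly 50% positive against its own median.
Inequalities are strict in both rules ("higher than" for damage, "below"
for shortness); ties score negative/not-short. The reference sample is
the youngest individual of each species (a single animal, overridable per
species); thresholds are computed once and reused for every individual of
that species.

**Attenuation caveat.** If the reference animal's true damaged fraction
`p_ref` is not exactly 0.5, the median threshold falls inside one mixture
component and the scored slope is attenuated by roughly
`1 − |p_ref − 0.5| / max(p_ref, 1 − p_ref)` even with perfectly separated
components. With `p0 = 0.5` and a youngest animal of age ~1–2 years this
is a few percent of the slope. Consequently, confidence-interval coverage
of the *true* rate is checked on the ground-truth damaged fraction, while
the scored route is validated for monotonicity (rank correlation with
age) and end-to-end sign.

## Rate and cross-species estimation

Per-species rates are unweighted OLS of percentage on age — plain
trendline arithmetic, with slope SE and 95% CI (t distribution, n−2 df)
added as diagnostics that are reported but never used to filter. R² with
zero response variance is carried as an explicit undefined flag. The
power-law trendline is OLS of ln y on ln x with R² reported on the
log-log scale (the spreadsheet power-trendline convention); an R² of the
back-transformed curve on the original scale is attached as a clearly
labelled diagnostic. The multivariate lifespan model is standard OLS
(statsmodels) with per-coefficient t tests and an overall F test;
rank-deficient designs raise an error naming the collinear predictors.
Species with missing traits are dropped per fit, never imputed; very
long-lived reptile outliers (the sea turtle entry) are excluded from
cross-species fits by default and re-included by flag. The very-old
cutoff is strictly greater than 0.7 × maximum lifespan; ties count as not
old.

## Problem sizes and numerical choices

The test suite and acceptance checks run at desk scale chosen to keep the
statistics sharp: threshold self-consistency uses 10,000/10,001 cells;
parameter-recovery coverage uses 100 replicates of 15 individuals ×
10,000 cells for three true rates (0.1/0.5/1.2 %/yr over ages 0–20);
image checks use 20-nucleus 2D fields and 6-nucleus 3D stacks; oracle
equivalence uses 100 random instances per estimator at 10⁻⁶ tolerance.
Degenerate inputs (blank images, constant predictors, single-age cohorts,
empty spot lists) raise explicit errors or flagged results rather than
NaNs.

## Known limitations

No phylogenetic comparative correction is applied (rates are treated as
independent species points); segmentation is not robust to touching
nuclei; telomere fluorescence is never calibrated to kilobases; the
bundled species-traits table is illustrative, not measured data; and the
published per-species slopes shipped in `datasets` are fixture inputs for
downstream analyses, not quantities recomputed from raw data.
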