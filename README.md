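# damagerates

Comparative biologists have observed that the *rate* at which leukocytes
accumulate DNA damage with age — not the damage level itself — tracks how
long a species lives. `damagerates` is a Python package for running that
style of cross-sectional, cross-species analysis end to end, from per-cell
fluorescence measurements to lifespan allometry, with a synthetic-data
generator that provides full ground truth for every stage.

## What it computes

Per cell, the readouts are the pan-nuclear γH2AX immunofluorescence
intensity (a DNA double-strand-break marker) and the total telomere-probe
fluorescence (an HT Q-FISH-style telomere-length proxy). Per individual
(one age each — the design is cross-sectional):

* **% γH2AX-positive cells** — cells whose pan-nuclear intensity is
  strictly above the 50th percentile of a young reference sample of the
  same species;
* **% short telomeres** — cells whose telomere fluorescence is strictly
  below the 25th percentile of the young reference sample;
* **% cells with ≥1 TIF** — telomere-dysfunction-induced foci, counted in
  3D confocal-like stacks as one-to-one colocalization of telomere and
  53BP1 spots within 2 voxels, after excluding 53BP1 staining at the very
  edge of nuclei.

Per species, the **rate of increase** of a percentage with age is the OLS
slope *b* of

```
pct_i = a + b · age_i + ε_i        (one point per individual)
```

reported with intercept, R², standard error and 95% CI. Across species,
the rates are regressed on species traits (maximum/average lifespan, body
weight, heart rate) with linear trendlines *y = m·x + c*, power-law
trendlines *y = a·x^b* (OLS of ln y on ln x, R² on the log-log scale), a
rate-vs-rate correlation, and a multivariate linear model predicting
lifespan from both rates (t and F tests). A "very old individual"
abundance metric counts sampled ages strictly above 70% of the species'
maximum lifespan.

## Worked example

```python
import pandas as pd
from damagerates import (SpeciesSimConfig, generate_cohort,
                         compute_reference_thresholds, summarize_individuals,
                         fit_rate)

cfg = SpeciesSimConfig(species_name="goat", baseline_positive_fraction=0.5,
                       true_damage_rate=0.00668, n_individuals=15,
                       age_range=(0.85, 10.1), cells_per_individual=5000)
cohort = generate_cohort(cfg, seed=1)
thresholds = compute_reference_thresholds(cohort)
summary = summarize_individuals(cohort, thresholds)
fit = fit_rate(summary["age"], summary["pct_gh2ax_positive"],
               species="goat", statistic="gh2ax_positivity")
print(fit.summary())
```

prints

```
Rate fit: goat / gh2ax_positivity
  n individuals : 15
  slope         : 0.5812 %/yr (SE 0.0820, 95% CI [0.4041, 0.7584])
  intercept     : 49.7373 %
  R^2           : 0.7944
```

The simulated goats gain damaged cells at a true rate of 0.668 % per year
from a baseline of 50 %; the fitted slope of 0.581 %/yr sits close to that
rate (percentile-threshold scoring mildly attenuates the slope whenever
the reference animal is not exactly half positive — see
`docs/methods.md`), and the intercept sits at the ~50 % baseline that the
young-reference median threshold enforces by construction.

The full chain — simulate cohorts (optionally with rendered image
fields), quantify, score, fit per-species rates, and regress them on a
species-traits table — runs from a single YAML config:

```bash
damage-rates run-all --config config.yaml --seed 1 --outdir results/
```

and writes `cohort.csv`, `individual_summaries.csv`, `species_rates.csv`,
`cross_species.json`, `old_abundance.csv` and a checksummed run manifest.
An illustrative species-traits table (not measured data) ships at
`damagerates.cross_species.example_traits_path()`.

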