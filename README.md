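# corneaquant

Automated quantification of corneal stromal damage in H&E-stained
histology sections.

Corneal melting (keratomalacia) and its treatment by riboflavin/UV-A
phototherapy are assessed histologically: damaged stroma shows fissures —
bright, unstained gaps between collagen lamellae — while healthy stroma
stains uniformly dark. Counting tens of thousands of fissures by hand is
not feasible, and hard detection is confounded by staining variability
and partial-volume effects. `corneaquant` implements the alternative:
a regional *brightness* statistic measured on an anatomically meaningful
grid, compared across experimental populations with a multi-aspect
permutation battery. It is aimed at researchers analyzing digitized
cornea sections (JPEG2000/TIFF/PNG) from organ-culture or animal
studies, and ships a synthetic-section generator so the entire pipeline
is testable without slide scans.

## Method

1. **Segmentation** — the green channel `I_g` of the RGB section is
   thresholded with Otsu's method (tissue = low class), cleaned
   morphologically, and the largest connected component is the cornea
   band.
2. **Centerline** — a third-order polynomial fitted to the mask (after
   PCA pre-rotation) initializes the medial axis; each sampled point is
   moved to the midpoint of the two boundary crossings along the local
   normal; a cubic smoothing spline resampled at equal arc length gives
   the final centerline.
3. **ROI grid** — the band is split into 4 depth layers (boundaries
   parallel to the axis, layer 1 anterior) × 6 radial frames
   (perpendicular to the axis): 24 regions of interest R_ij with areas
   A_ij.
4. **Brightness** — per ROI,

       b_ij = (1 / A_ij) · Σ_{(r,c) ∈ R_ij} I_g(r, c),

   the mean green intensity: high values indicate stromal laxity, low
   values compactness. Being an average, it responds continuously to
   partial damage with no detection threshold.
5. **Statistics** — a fixed-effects multi-way ANOVA (population, layer,
   frame + two-way interactions); one-sided two-sample *permutation*
   tests for each population pair on two distributional aspects —
   location (difference of means) and scatter (difference of variances
   of mean-centered values) — with exact enumeration for small samples;
   Bonferroni–Holm–Shaffer step-down adjustment (multipliers {3,1,1}
   for three populations); Tukey HSD post-hoc; a dominance-counting
   ranking (rank = 1 + number of populations significantly larger); and
   per-ROI p-value heat maps localizing where two populations differ.

## Worked example

```python
import pandas as pd
from corneaquant import (PipelineConfig, default_cohort_spec,
                         generate_cohort, multiway_anova,
                         pairwise_population_tests, process_section)

sections = generate_cohort(default_cohort_spec(n_per_group=10, seed=2))
cfg = PipelineConfig()
table = pd.concat([process_section(s.image, cfg, metadata=s.metadata)[0]
                   for s in sections], ignore_index=True)
anova = multiway_anova(table)
battery = pairwise_population_tests(table, n_permutations=4999, seed=2)
print(battery["rankings"]["location"].ranks)
```

On the default synthetic cohort (10 corneas × 4 slides per population)
this prints the location ranking

```
{'healthy': 2, 'injured': 1, 'treated': 2}
```

meaning injured corneas rank first (brightest — most damage) while
healthy and treated tie below: phototherapy restores a healthy-like
mean brightness. The accompanying battery reports injured > healthy in
location with adjusted p = 0.0006, treated vs healthy location
nonsignificant (p ≈ 0.78 / 0.22 for the two directions), and
treated > healthy in *scatter* with adjusted p = 0.0006 — the treated
population is healthy-like on average but more heterogeneous. The ANOVA
finds a strong depth-layer effect (central layers 2–3 brighter than the
outer layers, p < 0.001) and no radial-frame effect.

The narrative scripts in `examples/` run each capability end to end
(generation, segmentation + centerline, ROI brightness, statistics,
full pipeline); each prints the numbers it computes and a line on what
they mean. A thin CLI mirrors the stages:

```bash
corneaquant simulate --out cohort/ --n-per-group 10 --seed 2
corneaquant run --images cohort/ --metadata cohort/metadata.csv --out results/
corneaquant fluence --irradiance 30 --exposure 3   # -> 5.4 J/cm^2
```

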