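# Methods

This note documents the models, numerical choices and limitations of
`corneaquant`, in the order the pipeline runs.

## The brightness model

The damage proxy is the mean green-channel intensity over each region of
interest, `b_ij = (1/A_ij) Σ I_g`. The green channel is used exclusively
because it carries the strongest eosin contrast in H&E material; red and
blue are ignored everywhere. Brightness is reported on the native 0–255
grey scale with no cross-slide normalization; consequently, comparisons
are only meaningful within a consistently stained and scanned batch —
a real limitation for multi-center material. Reported summaries are
rounded to two decimals; CV = 100·SD/mean (percent), IQR = q75 − q25,
SD uses ddof = 1.

## Segmentation

Otsu's threshold is computed on the fixed 256-bin histogram of the
(rounded) green values; pixels ≤ t form the low class, and among ties the
smallest maximizer of the between-class variance is returned, making the
threshold reproducible bit-for-bit. Tissue is the *low* class — H&E
tissue is darker than the slide background, and bright pixels inside
tissue are exactly the damage signal being measured, so they must not
decide polarity. Cleanup: objects and holes smaller than
`min_object_area` (default 0.1 % of the image) are removed/filled,
followed by closing with a disk of radius 5 px and another hole fill,
then the largest 8-connected component is kept. Hole filling matters:
bright fissures would otherwise punch holes through the band and corrupt
the centerline, whereas damage is quantified by brightness, not by mask
topology. All parameters are exposed in `PipelineConfig`.

## Centerline

The initial estimate is a least-squares cubic y(x) fitted to all mask
pixels after rotating the principal (PCA) axis horizontal, which makes
the procedure independent of slide orientation; a near-isotropic mask
(eigenvalue ratio ≤ 1.05) is rejected as orientation-ambiguous.
Refinement samples 200 points over the axis range (2 % end inset) and
replaces each by the midpoint of the two mask-boundary crossings along
the local normal; the mask is bilinearly interpolated and scanned in
0.25 px steps, with the crossing localized sub-pixel at the 0.5 level.
Points whose normal fails on either side, exceeds 2.5× the median
one-sided distance, or whose total crossing span falls below 0.85× the
median thickness are dropped — the latter rule removes points whose
normal escapes through the band's end caps, the dominant failure mode.
A cubic smoothing spline (chord-length parameterized, residual budget
0.25·n ≈ 0.5 px noise per point) is then resampled at exactly equal
arc-length steps; when a mask is supplied, dense samples outside it are
trimmed first so every returned point lies inside the band.

One refinement pass is the default (an iteration count is exposed).
On synthetic arcs the end-to-end RMS error against the analytic medial
axis is ≲ 0.7 px for sagitta ratios up to 0.7; beyond ≈ 0.8 (a nearly
semicircular band, outside the range of real sections) the cubic
initialization biases the normals and accuracy degrades.

## ROI grid

Each mask pixel is assigned to its nearest centerline point (k-d tree;
ties resolve to the lower index, hence the lower frame). The point's
arc length selects one of 6 equal frames; pixels exactly on a frame
boundary join the lower frame. The pixel's signed normal offset, divided
by the local half-thickness on its side (measured by the same normal
scan), gives a normalized depth u ∈ [−1, +1]; 4 equal intervals of u
form the layers, boundary pixels joining the more anterior layer.
Equal normalized quarters and equal arc-length sextiles are design
choices: anatomy (epithelium/Bowman vs stroma vs endothelium) does not
dictate exact boundaries, and the equal-split rule is the simplest
reproducible reading. Which side is anterior must be stated ("left" or
"right" of the centerline's travel direction); without it the grid is
built with "left" assumed and flagged `orientation_verified=False`
rather than guessing from image content.

## Statistics

*ANOVA.* A fixed-effects OLS with sum-coded factors (population, frame,
layer) and all two-way interactions, Type-III F tests. Interactions with
empty cells are dropped with a notice. The study design has replicate
slides per cornea, so records are not fully independent; a cornea
blocking factor is available but absorbs the population effect (corneas
are nested in populations) and defaults to off. The permutation battery,
not the ANOVA, is the primary inference tool.

*Permutation tests.* Location: difference of raw means, pooled
re-randomization. Scatter: each sample is centered at its own mean and
the pooled residuals are permuted, comparing variances (ddof = 1) — the
standard permutation-on-residuals scheme for spread. One-sided
p = (1 + #{T* ≥ T}) / (B + 1) with B = 4999 by default and the seed
recorded in the result; for pooled n ≤ 12 all C(n, n_a) splits are
enumerated and the p-value is exact. Ties at the observed statistic are
counted as ≥ using a relative 1e-9 tolerance. The permutation unit is
the brightness record; exchangeability across serial slides of one
cornea is an assumption, flagged in the output header, and cornea-level
aggregation (`aggregate="cornea"`) is provided as the conservative
alternative.

*Multiplicity.* Step-down Holm with Shaffer's S1 logical-constraint
multipliers when the family is all pairwise comparisons of k groups
(for k = 3: {3, 1, 1} — once the smallest p is rejected, at most one of
the remaining equalities can hold). Per aspect, each unordered pair
enters the family through its supported direction (the smaller one-sided
p); the opposite direction is reported raw. Since both one-sided
alternatives are examined jointly, a two-sided claim at level α should
be read against α/2.

*Ranking.* Dominance counting: rank(k) = 1 + #{h : adjusted
p(h > k) ≤ α}; ties share ranks. No tie-break by observed statistic is
applied by default — a ranking difference that the tests cannot support
is not reported. Note that with this rule a population can only be
ranked *below* another when the tests separate them; scatter rankings in
which a nonsignificant pair is nonetheless ordered (as appears in some
published multi-aspect analyses with unpublished appendix algorithms)
cannot arise here by construction.

*Heat map.* Location and scatter tests run independently in each of the
24 cells for one population pair, with per-cell seeds spawned from the
run seed; cells with fewer than 2 records per group are flagged, never
silently dropped. Under the null the expected number of significant
cells at α = 0.05 is 1.2 per aspect.

## Synthetic sections

The generator draws a circular-arc band (sagitta ratio `band_curvature`,
0 = straight) of uniform thickness on a bright background, so mask,
medial axis and layer geometry are known analytically. The green value
inside tissue is base intensity + per-layer gain + fissures + staining
field + pixel noise, clipped to [0, 255]; red/blue are affine pink-tint
maps of green. Fissures are bright filled ellipses (uniform orientation,
axes 1.5–4.5 px, centers uniform over tissue, expected count
`fissure_density` per 1000 tissue pixels). Staining heterogeneity is a
stationary Gaussian field (blurred white noise, correlation length 4 px,
SD 10 grey levels): stationarity guarantees it cannot masquerade as a
layer or frame effect. Defaults place healthy tissue near 150 grey
levels against a 230 background with central layers (+10) brighter than
the outer ones, echoing the layered compactness of real stroma.

A cohort draws, per population: a mean offset, a fissure-density
multiplier, and a variance multiplier m that scales every stochastic
component's variance while preserving the mean — cornea intercept and
staining SDs grow by √m, and the fissure population trades count for
size (density/m, axes ×√m): fewer but larger residual gaps, a
heterogeneous treatment response. The default three-arm preset is
10 corneas × 4 serial slides per population (the replicate-slide design
of organ-culture studies; ~960 ROI records per population), injured
= +4 grey offset with 1.3× fissures (measured total elevation ≈ +5
grey levels over healthy), treated = variance multiplier 1.5 with no
mean offset. Between-cornea intercept SD is 0.35 grey levels.

What the generator does *not* emulate: nuclei and cell rendering,
epithelium/endothelium microanatomy, stain batch effects, scanner
vignetting, large between-animal variability, or non-elliptical fissure
shapes. Passing tests therefore demonstrate the pipeline's correctness
and calibration on controlled band-shaped material, not robustness to
every artifact of real slides. Pixel units are used throughout; no
micron calibration is assumed.

## Problem sizes and determinism

Synthetic sections are 360 × 480 px with an 81 px band — large enough
for 24 well-populated ROIs (~1.5 k px each), small enough that the full
default cohort (120 sections) processes in well under a minute. Null
calibration suites use 1000–2000 replicates; the permutation default is
4999 resamples. All randomness flows from explicit seeds
(`numpy.random.default_rng`; child seeds via `SeedSequence`), and
identical configuration + seed reproduces every CSV byte-for-byte.

## Known limitations

- Single-band assumption: folded, torn or multi-fragment sections end up
  as the largest component only; branched bands are out of scope.
- Record-level permutation is mildly anticonservative under strong
  within-cornea correlation; use cornea aggregation when that is a
  concern.
- The fixed-effects ANOVA inherits the same correlation caveat; its
  interaction tests especially should be read descriptively.
- Brightness depends on staining/scanning consistency; no normalization
  is applied by design.
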