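# Methods

## Segmentation model

The pipeline assumes a calibrated 2-D multichannel image (pixel size in
µm/px is required; there is no safe default for unknown scanners, and the
shipped reference value of 0.65 µm/px corresponds to a typical 10×
slide scan) with a nuclear channel, a glucagon channel, an insulin channel,
and optionally one marker channel. Staining is treated as approximately
two-level per channel — background/autofluorescence versus specific
signal — which is what makes per-channel Otsu thresholding appropriate.

Operator sequence per section:

1. **Preprocessing.** Grayscale closing with a disc of radius 2 px on the
   hormone channels bridges sub-cellular unstained gaps so adjacent
   hormone-positive cells merge into territories; a mean filter with a disc
   of radius 1 px suppresses shot noise. The mean radius is deliberately
   the smallest possible: every pixel of blur creates a ramp at each signal
   edge, and because Otsu places its threshold inside that ramp, larger
   radii systematically dilate the masks by ~1 px — negligible for large
   compartments, but a first-order error for thin ones such as the
   bihormonal interface. Radii are expressed in pixels because the
   structuring element lives on the pixel grid; at a different
   magnification the config should be adjusted accordingly.
2. **Thresholding.** Otsu per channel per section (recorded in the run
   report), overridable by fixed per-channel values. Per-section rather
   than cohort-global thresholds are used; this follows the usual practice
   of per-image auto-thresholding and is flagged here because section-wise
   staining variation then cannot bias a whole cohort coherently.
3. **Islet assembly.** Connected components (8-connectivity) of the
   binary-closed union of the two hormone masks; the closing decides
   *connectivity only* — labels are kept only on hormone-positive pixels,
   so closing never adds islet area. Components with hormone-positive area
   < 1000 µm² (strict) are removed as non-specific staining. Retaining
   the area on hormone pixels (not the closed hull) is what makes the
   partition identity below exact.
4. **Compartmentalisation.** Within the islet footprint:
   bihormonal = glucagon ∧ insulin, alpha-only = glucagon ∧ ¬insulin,
   beta-only = insulin ∧ ¬glucagon. By construction
   `|alpha_only| + |beta_only| + |bihormonal| = |islet footprint|`
   for every input — this holds as an identity, not a tolerance.
5. **Tissue and exocrine.** The all-channel sum projection of a slide image
   is trimodal (bare glass, tissue autofluorescence, bright staining). A
   two-class Otsu threshold on the raw projection can land in the
   tissue/stain valley and silently discard dim exocrine tissue — observed
   on sections with enlarged islets, where the tissue footprint collapsed
   threefold. The projection is therefore log-compressed (stabilising the
   bright class, whose raw-intensity spread otherwise dominates the
   histogram) and split with a three-class multi-Otsu; tissue is everything
   above the lowest (glass/tissue) threshold, hole-filled, and unioned with
   the hormone masks so tissue ⊇ islets always. Exocrine = tissue minus
   the islet footprint.

## Nuclei

Foreground by threshold, Euclidean distance transform smoothed with a
Gaussian of σ = 0.5 px, watershed seeded at h-maxima with h = 1 px.
σ = 0.5 matters: heavier smoothing flattens the distance peaks of small
(~4 µm radius) nuclei below the h-maxima height and silently drops them.
The size filter removes objects with equivalent diameter > 10 µm
(interpreted as a *diameter*, the natural reading of a length in µm; the
equivalent-diameter convention `2·√(area/π)` is used because the watershed
fragments are roughly convex). Compartment assignment is by centroid
membership — cheap, deterministic, and order-independent; pixel-majority
assignment would differ only for nuclei straddling a boundary.

## Morphometric definitions

* fractional area: `100 · area_c / reference`, with the reference either
  the whole tissue footprint (default) or the exocrine area. Both modes
  exist because the two conventions are both in circulation; tissue is the
  default as the one used for headline percentages. Since
  exocrine ⊂ tissue, the exocrine-normalised value is always ≥ the
  tissue-normalised one.
* mean area per islet: total compartment area / islet count; NaN (never 0)
  for sections without islets.
* islet density: islets per mm² of tissue. Under a pure size effect
  (islets grow, count constant) this is invariant between groups, which is
  the diagnostic separating hypertrophy/hyperplasia of islets from
  neogenesis.
* islet diameter: maximum Feret diameter — the largest pairwise distance
  between pixel centres of the islet, computed exactly via the convex
  hull. A single-pixel object has diameter 0 by convention.
* estimated cell size: compartment area / nuclei count in that compartment;
  NaN when no nuclei. This is a 2-D section estimate, not a stereological
  cell volume.
* normalized nuclei count: compartment nuclei as % of all islet nuclei.
* α-positive islet fraction: % of islets with any alpha-positive
  (alpha-only ∪ bihormonal) pixel; a minimum-area variant is exposed for
  stricter calls since no threshold is canonical.
* marker metrics: the marker channel is mean-filtered and thresholded;
  per compartment the marker-positive area, its % of the compartment area,
  and an intensity `Σ raw marker intensity over the compartment /
  compartment area in mm²` (AU/mm²) are reported. Intensity integrates the
  *raw* channel over the whole compartment — the only reading consistent
  with the AU/mm² unit — so it is insensitive to the marker threshold.

## Group statistics

`compare_groups` routes to a pooled-variance two-sided t-test when both
groups pass Shapiro-Wilk at α = 0.05 (requiring n ≥ 3 and non-constant
data) and to the two-sided Mann-Whitney U test otherwise; scipy computes
the exact Mann-Whitney null for small tie-free samples and the midrank
normal approximation otherwise. `ttest_from_summary` reconstructs the
pooled test from printed `mean ± SEM, n`: for equal group sizes
`t = (m₁−m₂)/√(sem₁²+sem₂²)` with df = n₁+n₂−2 *is* the pooled t-test, so
published p-values are recomputable from printed summaries alone — the
pooled (not Welch) form is used because it is the one that reproduces the
published values. No multiplicity correction is applied across morphometric
metrics; each comparison carries its own two-sided p and an α = 0.05 flag.
Fisher's exact test sums hypergeometric probabilities of all tables with
the observed margins no more probable than the observed table (scipy);
an all-zero table returns p = 1.

## Differential protein abundance

Intensities are log2-transformed (non-positive raw values treated as
missing) and proteins with any missing value in either compared group are
dropped — strict per-group completeness, no imputation. The moderated
statistic is `d = (mean_a − mean_b)/(s + s0)` with `s` the pooled
two-sample standard error; s0 (default 0.01) damps proteins whose tiny
variance would otherwise produce large t-statistics at negligible fold
change. At s0 = 0, d is exactly the pooled t statistic.

The FDR is estimated by label permutation: the samples of the two compared
groups are reassigned (all distinct assignments when there are at most
`n_permutations` of them — logged when that happens — otherwise
`n_permutations` = 250 seeded draws), d is recomputed for every protein
under every assignment, and for each observed |d| cutoff

```
q = median over permutations of #{null |d*| ≥ cutoff} / #{observed |d| ≥ cutoff}
```

clipped to [0, 1] and made monotone non-increasing in |d| by a cumulative
maximum down the ranking. The permutation subsets are drawn for the
lexicographically first group name, which makes the null ensemble — and
hence every q — invariant under swapping the two group labels, while d and
log2FC simply change sign. For the −log10 FDR used in volcano tables, q is
floored at `1/(P · n_proteins)` so proteins never exceeded by any permuted
statistic plot at a large finite height; the up/down/ns class boundary is
strict (q exactly at the threshold is ns). The estimator is validated by
simulation (null matrices: at most a few discoveries in 1000 proteins;
spike-ins at log2FC = 2, within-group sd 0.3: full sensitivity at ≤ 0.2%
null discoveries) rather than by claimed bit-compatibility with any
particular proteomics package, whose exact permutation scheme is not
public.

## Colocalisation

Intensity-weighted Manders coefficients:
`M1 = Σ A over pixels with A > t_A and B > t_B / Σ A over pixels with A > t_A`,
M2 with the roles swapped. Thresholds gate the masks only — no background
subtraction — and default to per-channel Otsu; a constant channel gets
threshold 0 with a warning. M1 is therefore "the proportion of channel A's
suprathreshold signal lying within channel B's suprathreshold mask", which
is how the usual directional prose ("overlap of A over B") is mapped onto a
formula here. Scatter samples are uniform without-replacement subsamples
with a fixed seed. Multiplying a channel and its threshold by the same
positive constant leaves both coefficients unchanged.

## Synthetic data

`generate_section` renders what the estimators need to be tested against,
not photorealism:

* **Tissue**: a rectangle inset from the canvas; bare glass outside. The
  nuclear channel carries tissue autofluorescence (background 40 AU over
  glass 0) so a projection threshold can recover the footprint; the
  quenched hormone/marker channels have a flat background everywhere.
* **Islets**: lobulated blobs (a central disc plus four overlapping
  satellites) placed with at least two islet radii of clearance; too many
  islets for the canvas raises `PackingError` rather than silently
  truncating. Default: 3 islets of radius 52–57 µm on a 1120 µm field at
  2 µm/px, calibrated so a control section has ≈1.6% islet fractional area
  and ≈6250 µm² mean islet area — the published control operating point.
* **Territories**: each blob's innermost ~25% (by boundary distance) is a
  hormone-negative core standing in for non-endocrine islet tissue; the
  shell is split into contiguous angular sectors ordered
  bihormonal | alpha | bihormonal | beta with exact pixel quotas
  (largest-remainder apportionment). The bihormonal wedges buffer alpha
  from beta on purpose: where alpha and beta territories touch, the blur
  ramps of the two thresholded masks overlap in a ~1 px band that is pure
  segmentation artefact, and for a compartment as thin as the bihormonal
  sliver that artefact dominates the truth. With the buffer layout the
  glucagon and insulin masks can only intersect on genuinely bihormonal
  pixels. Default shares of the blob: alpha 0.05, beta 0.70, bihormonal
  0.05. The bihormonal share is deliberately larger than the ~2% of islet
  area seen in control tissue: the residual ±1 px boundary band is an
  absolute error, and a ~360 µm² sliver could never be recovered to the 5%
  relative tolerance the validation demands of every compartment.
* **Marker**: the central 22% (control default) of each alpha sector,
  matching the published control GLP-1-positive fraction of α-cell area.
* **Nuclei**: 4 µm-radius discs on a jittered grid at 5 nuclei/1000 µm²
  with a hard minimum spacing of 2.5 nucleus radii, so rendered nuclei
  never touch and ground-truth counts are unambiguous; parameter
  combinations that cannot satisfy the spacing raise at construction.
* **Noise**: white Gaussian noise (default sd 8 AU against a 160 AU
  signal step) plus a shared low-frequency autofluorescence field (half the
  white-noise amplitude, confined to tissue), synthesised on a coarse grid
  and upsampled. Ground truth is always measured on the noise-free masks.

`generate_cohort` draws a control and a "pregnant" group. Effect
multipliers are per-metric area folds: the islet multiplier scales the
squared islet radius, and each compartment's share of the blob moves by its
own fold relative to the islet fold; compartment multipliers left
unspecified follow the islet multiplier, so a bare islet×1.9 cohort scales
islets without changing their composition. Between-donor variability is a
single mean-preserving log-normal size factor per donor with the requested
CV (default 0.25); a single factor — rather than independent per-metric
factors — keeps every area metric's between-donor CV at exactly the
requested value instead of a compounded one. Marker fraction and intensity
draw their own donor factors. With all multipliers at 1 the groups are
exchangeable by construction.

The default multipliers (islet 1.9, alpha 4.3, beta 1.9, bihormonal 5.4,
marker area 2.39, marker intensity 1.33) are the published pregnancy fold
changes. They are mutually inconsistent with the identity
islet = alpha + beta + bihormonal: the share-weighted average of the
compartment folds implies an islet fold of ~2.3, not 1.9. The generator
prioritises the compartment folds; its realised islet fold under the full
default multipliers is therefore ~2.3–2.4 (visible in the README example),
while a cohort specifying only the islet multiplier realises that fold
exactly.

What the generator does **not** emulate — and hence what passing tests do
not show about real tissue: optics (no PSF, no depth effects, no chromatic
shift), staining chemistry (no antibody gradients, no edge artefacts,
uniform two-level signal), biological texture (islets are not sectored
wedges; real bihormonal signal may be resolution-limited overlap of
juxtaposed cells rather than true co-expression), nucleus morphology
(uniform discs, no clumping), and section-to-section registration issues.
Recovery results on this generator validate the estimators' correctness,
not the biological accuracy of any particular threshold on real
micrographs.

`generate_protein_matrix` draws protein baselines from
N(24, 2²) on the log2 scale (log-normal intensities), adds within-group
noise of sd 0.3 (a typical label-free replicate CV), shifts the first
`n_true_effects` proteins by the effect size in the pregnant group, and
censors completely at random at the requested rate. Missingness is MCAR by
design — intensity-dependent censoring, the harder real-world case, is out
of scope because the completeness filter drops affected rows either way.

## Numerical conventions

* Areas are pixel counts × pixel_size²; masks share one row-major grid with
  the origin top-left; the < 1000 µm² size filter removes strictly smaller
  objects (area = 1000 µm² is retained).
* Undefined ratios (mean area with 0 islets, cell size with 0 nuclei,
  normalized counts with 0 islet nuclei, Manders with no suprathreshold
  signal) are NaN, never 0 or ∞; zero denominators that indicate broken
  input (fractional area of an empty reference, islet density of empty
  tissue) raise instead.
* Degenerate statistics: a constant raster has no Otsu threshold (empty
  mask, warning); two zero-variance equal-mean samples give t = 0, p = 1,
  and unequal means give the p → 0 limit; zero variance in both groups with
  s0 = 0 raises.
* Ties in territory quotas and marker selection are broken
  lexicographically by (depth/distance, row, column), so generation is
  bit-reproducible; every random stage consumes a `numpy` generator seeded
  from explicit integers, and each cohort donor derives its stream from
  (cohort seed, group index, donor index) so single donors can be
  regenerated in isolation.

## Validation problem sizes

The shipped validation uses 560×560 px sections at 2 µm/px with 3 islets
(about 5900 nuclei per section), 100 random sections for the partition
invariant, 5 noise-free sections for ground-truth recovery, 20 null and one
spiked 1000 × (6 vs 6) matrices for FDR calibration, 100 replicate 7+7
cohorts for power at the published effect sizes, and 200 replicate cohorts
for islet fold-change recovery. These sizes give the Monte-Carlo estimates
comfortable margins around their pass criteria while keeping the whole
suite around five minutes on one CPU.

## Known limitations

* Marker quantification by Otsu is biased upward for very small positive
  regions (the threshold lands in the blur ramp because the positive class
  is a negligible histogram mass); with marker regions as small as the
  synthetic defaults (~200 µm² per islet) the positive area can be
  overestimated severalfold. Fixed thresholds avoid this and are used in
  the validation; on real data, marker thresholds should be checked
  visually per batch.
* Tissue segmentation under noise is accurate to ~5–10%, not exact: the
  glass/tissue contrast is the smallest step in the image.
* Watershed parameters (σ = 0.5 px, h = 1 px) are tuned for nuclei a few
  pixels across; strongly different magnifications need rescaled
  parameters.
* The Mann-Whitney route reports no effect-size estimate beyond the group
  summaries; donor-level covariate adjustment (age, BMI) is out of scope.
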