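# Methods

This note documents the models, defaults and numerical choices behind
`tamspatial`, and what the synthetic cohorts do and do not establish about
real tissue data.

## Cell phenotyping

Cells arrive with six per-marker mean intensities. The gate is a
fixed-priority decision list (first match wins):

1. AE1AE3 ≥ positivity → **Tumor**
2. CD68 < positivity → **Other**
3. CD163+ and CD206+ → **CD68+CD163+CD206+**
4. CD163+ → **CD68++CD163+** if CD68 ≥ high else **CD68+CD163+**
5. CD206+ → **CD68+CD206++** if CD206 ≥ high else **CD68+CD206+**
6. IRF8+ → **CD68+IRF8+**
7. otherwise → **CD68+**

Design choices worth making explicit:

* **Scavenger/mannose positivity outranks IRF8.** The five M2-like labels
  are defined purely by CD163/CD206 status; IRF8 only splits the
  double-negative branch. This yields exactly seven macrophage labels and a
  total partition (every cell gets exactly one label).
* **"++" is a second absolute threshold**, estimated per cohort, rather
  than a relative comparison between neighbouring cells — an absolute
  cutoff is reproducible and auditable.
* **Thresholds are cohort-wide** (all patients pooled), mirroring the use
  of a single trained classifier across a study.

Threshold estimation (`estimate_thresholds`) offers two transparent rules:
a two-component Gaussian mixture on log1p intensity per marker (positivity
at the equal-posterior crossing, high thresholds at the upper component's
mean) with a percentile fallback on degenerate fits, and a plain percentile
rule (positivity 70th, high 90th). The log1p transform reflects the strong
right skew of staining intensities. A caveat the robustness checks make
visible: when a marker is genuinely trimodal (negative / positive / high,
as CD68 is here), a two-component fit pools the two positive modes, and its
upper-component mean is a poor "++" cutoff; the synthetic generator's
`true_gating()` (log-midpoints of the generating components) is therefore
the reference configuration for recovery measurements, and the
mixture-based estimate should be reviewed against the marker histogram in
real cohorts.

Exposure normalization divides each marker intensity by its per-cell
exposure time when requested; thresholds always refer to one declared
intensity scale.

## Nearest-cell distance analysis

For a reference population and a target population within one image, each
reference cell is paired with the closest target cell by Euclidean
nucleus-to-nucleus distance (k-d tree; exhaustive-scan equivalent, with
self-pairing excluded when a cell appears in both sets). Distances are
never computed across images: coordinates live in per-tile frames and
tiles are assumed non-overlapping.

* **Median distance** per patient × ROI uses the midpoint convention for
  even counts.
* **Effective percentage** bins the per-cell nearest distances into
  half-open `[k·w, (k+1)·w)` bins (default w = 10 µm — no boundary rule is
  canonical, and half-open bins avoid double counting); fractions are
  relative to the total reference count, so bins partition the reference
  set as the range grows.
* **Effective density** counts reference cells whose nearest target lies
  within the contact radius (default 10 µm nucleus-to-nucleus, an
  estimated direct-contact distance; the criterion is inclusive, reading
  "within a radius" as ≤) divided by tissue area. The identity
  `effective_density = cumulative effective percentage × reference density`
  holds exactly and is verified numerically.
* **Densities** are counts pooled over a stratum's images divided by the
  summed analyzed-image area (mm²). Compartment-stratified rows are
  normalized by the same total imaged area, because per-compartment mask
  areas are not recoverable from a cell table; compartment densities are
  therefore comparable within an image set but are not per-compartment
  tissue concentrations.
* Under complete spatial randomness the cumulative effective percentage
  follows 1 − exp(−λπr²); the test fixture pads the target window by a
  guard band so the infinite-plane law applies without edge bias.

## Interface gradients

The tumor-nest/stroma interface is point zero of a signed axis: a cell's
signed distance is the distance to the nearest nucleus of the opposite
compartment, positive inside the nest. This nucleus-based proxy replaces
the segmentation-mask boundary distance (masks are not part of the input
contract); it overestimates the true boundary distance by roughly half the
local cell spacing and converges to it as density grows. Signed distances
are computed on an image's full cell complement *before* any balanced
sampling, so sampling balances representation, not geometry.

Profiles bin cells (optionally one population) by signed distance
(default 10 µm bins, matching the distance-analysis increment), report the
per-bin mean intensity with either a 95% t-interval or a seeded percentile
bootstrap (1000 resamples), and suppress bins with fewer than two cells.
Compartment-balanced sampling draws an equal number of cells per side per
patient (default 500) without replacement; patients lacking the quota are
either excluded (strict mode) or the cohort-wide quota drops to the
minimum available.

Quadrant classification calls a side positive when its cell-weighted mean
intensity strictly exceeds the threshold (a mean exactly at threshold is
negative): tumor-side positive → I, stroma positive → II, stroma
negative → III, tumor negative → IV. Thresholds for the macrophage
markers are taken as reference-class means (tumor cells and non-macrophage
"Other" cells) computed on the analyzed cohort.

Half-rise localization (`estimate_half_rise`) fits a cell-weighted
isotonic (monotone non-decreasing) curve to the profile and interpolates
where it crosses midway between its extreme levels. The isotonic fit is
essential: sparse far-stroma bins are noisy, and a raw first-crossing rule
produces spurious early detections. When pooling populations for a
gradient readout, only populations sharing the same base intensity level
should be pooled — mixing levels lets composition drift across distance
masquerade as an intensity gradient.

## Cohort statistics

* **PDL1 subsampling cohorts** pool an equal number of cells per patient
  (default 10⁴, all ROIs, all cell types; default five independent seeded
  cohorts) so tissue-rich patients do not dominate. Patients below the
  quota are sampled with replacement and flagged. Positivity is strict
  (> cohort mean); the positive fraction of a right-skewed intensity
  distribution is therefore below one half. Patient-level PDL1-high calls
  require at least one *macrophage* in the cohort's top percentile
  (default 1%); flagged tumor cells never qualify a patient.
* **Environmental gene signatures**: per gene, Spearman correlation
  between expression and a population's per-patient density (one ROI,
  default core). The signature keeps genes at p < 0.05 and the refined
  signature at p < 0.001 — raw p-values, as stated for the study design;
  BH-FDR is reported per gene but does not drive membership. P-values use
  the t-approximation for n > 9 and the exact permutation distribution for
  n ≤ 9 (valid for tie-free data); with n ≤ 6 samples even a perfect
  correlation cannot reach p < 0.001 (the permutation floor is 2/6! ≈
  0.0028), so refined signatures require larger cohorts by construction.
* **Signature scores** are means of per-gene z-scored expression; samples
  split at the cohort median (strictly above → high). A deterministic
  average-linkage, correlation-distance hierarchical clustering is
  available as the alternative heat-map grouping.
* **Survival**: Kaplan–Meier product-limit estimates with the Mantel–Cox
  log-rank test (two-group comparisons only: upper vs lower density
  tercile, or above vs below a signature median). Terciles: upper strictly
  above the 2/3 quantile, lower at or below the 1/3 quantile; heavy ties
  can empty a group, which is reported with a warning rather than
  repaired.
* **Robustness**: subsample stability repeatedly draws equal-size cell
  subsets of a population and correlates (Pearson) the subsample's mean
  marker vector with the bulk vector; the k-means sweep clusters z-scored
  log1p marker vectors (10 restarts, seeded) and reports inertia,
  silhouette and the adjusted Rand index against the gate at k = 7.

## Synthetic cohort generator

The generator is the package's only data source for tests and emulates the
statistical structure the analyses assume:

* **Geometry.** One image tile per ROI per patient: a 2×2 microscope stamp
  (1338 × 1000 µm) for core/edge/normal and a 1×1 stamp (669 × 500 µm) for
  the margin. Tumor nests are unions of random discs (mean count
  2 per mm²; lognormal radii, 150 µm mean, 0.3 log-SD), giving a tortuous,
  measurable interface; the compartment label comes directly from the disc
  mask. Adjacent-normal tiles have no nests and no tumor cells.
* **Placement.** Tumor cells are a homogeneous Poisson process thinned to
  the nest mask (so counts are Poisson with mean rate × nest area). Each
  macrophage population draws a Poisson count (rate × tile area; defaults
  30–80 cells/mm² per population, ~700 "Other" cells/mm², 1500 tumor
  cells/mm² of nest — free parameters chosen for realistic per-tile cell
  totals) and places each cell at a target distance from the nearest tumor
  cell drawn from a Gamma kernel (shape 2) with a population-specific
  median: 12 µm for CD68+IRF8+ up to 26 µm for the triple-positive
  population, injecting the proximal/distal ordering as ground truth. The
  target distance is drawn once per cell and held fixed during rejection
  sampling — resampling it per retry would bias realized distances small.
* **Intensities.** Lognormal per marker per phenotype; negative components
  at log-location 0, positive at 2, "++" at 3.8 with log-scale 0.3
  (≥ 6σ separation, making the gate recoverable but not trivial).
  Interface gradients multiply intensity by
  `1 + (fold−1)·expit((s + onset)/ramp)` — half-rise exactly `onset` µm
  before the interface, plateau `fold` inside the nest. Defaults: a
  twofold CD68 increase with 25 µm onset on the CD163+ and IRF8+
  populations, and nest-side PDL1 up-regulation (fold 2, onset 10 µm) on
  all macrophages. The gradient covariate is the same signed
  nearest-opposite-nucleus distance the analysis measures, so recovery
  tests probe the profiling machinery rather than the mask-vs-nucleus
  proxy gap. Note the deliberate tension: the CD68 gradient doubles some
  CD68+ cells' intensities, partially violating the mixture-separation
  premise of the gate — gating-recovery figures are therefore quoted on a
  gradient-free configuration, and with gradients enabled accuracy drops
  by about half a percentage point.
* **Expression.** Linked genes are normal scores of the designated
  population's density ranks plus Gaussian noise with
  σ = noise_scale · sqrt(1/r² − 1), r = 2·sin(π·ρ_target/6), which makes
  the expected Spearman correlation equal the target (default 0.8) for
  bivariate-normal scores; noise_scale 0 gives ρ = 1 exactly. Unlinked
  genes are independent noise. Defaults: 2000 genes, 50 linked per
  population.
* **Survival.** Exponential event times with hazard
  baseline · exp(coef · z(density)) (defaults 0.02/month and −0.6 per SD
  of CD68++CD163+ core density, i.e. protective high density) and
  independent exponential censoring calibrated to the configured
  per-patient censoring probability (default 0.2).
* **Reproducibility.** One `SeedSequence` stream per patient, spawned into
  placement / intensity / expression / survival children; identical config
  and seed give byte-identical tables.

What passing tests on these cohorts show — and what they do not: the
analyses provably recover planted spatial orderings, gradients, gene
linkages and survival effects under the generator's assumptions
(independent lognormal markers, disc-union nests, Poisson placement,
exponential survival). Real tissue violates most of these in degree —
correlated marker noise, segmentation errors, irregular nest shapes,
inter-patient batch effects — so green tests certify the correctness of
the machinery, not the biological validity of any particular cohort's
readout.

## Problem sizes and numerical choices

Test and acceptance runs use compact study sizes chosen by the package:
3–34 patients per check, one or two core tiles per patient, 100–200
replicate simulations for calibration claims, 2000-gene expression
matrices at n = 34 samples, and 200-tile Monte Carlo for the spatial
closed form. Tolerances follow the quantity: exact equality for oracle
equivalences and the BH hand check, 1e-9 for the effective-density
identity, 3 standard errors for Monte Carlo means, and ±1 bin for
gradient localization. Ties in nearest-neighbour queries are broken
arbitrarily (only the distance is consumed downstream); constant vectors
yield missing correlations rather than errors; M1:M2 ratios report 0/0 and
0/positive as 0 and positive/0 as +inf.

## Known limitations

* The nucleus-based interface distance is a biased proxy for the
  mask-boundary distance at low cell density.
* Compartment-stratified densities share the stratum's total imaged area
  (see above).
* The two-component mixture threshold estimator underestimates the "++"
  cutoff on trimodal markers.
* The exact Spearman permutation p assumes tie-free data; ties at n ≤ 9
  fall back to an approximate tail.
* The generator samples subtype-like metadata uniformly and models no
  staining chemistry, pixel noise or segmentation error.
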