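# Methods

This note documents the models, conventions and numerical choices behind
`metpet`, what the synthetic-data generator does and does not emulate, and the
known limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. SUV conversion and tumor delineation

Activity volumes (Bq/mL) are converted voxelwise to standardized uptake
values, SUV = activity × body weight (g) / injected dose (Bq). The reference
value is the arithmetic mean SUV over all voxels whose **centers** fall inside
a 10 mm-diameter sphere on normal contralateral tissue (center-in-sphere is
the simplest unambiguous rasterization; the sphere must lie fully inside the
grid). The tumor boundary is delineated at **1.3 × reference SUVmean**, with
these conventions:

- The comparison is **inclusive** (SUV ≥ threshold): a voxel exactly at
  threshold belongs to the tumor. The alternative (strict >) is
  indistinguishable on continuous data and would make worked integer examples
  ambiguous.
- Among all supra-threshold voxels, the mask is the single **26-connected
  component containing the candidates' global SUV maximum**. Clinical practice
  selects the avid area by physician review; the hottest-component rule is the
  reproducible automated proxy, and an optional `search_region` bounding box
  stands in for manual review when several avid regions exist.
- Coordinates are 0-based voxel indices; physical geometry enters only via the
  per-axis voxel spacing (axis-aligned grids; no affine/orientation handling —
  phantoms are generated axis-aligned, and NIfTI input is assumed already
  resampled that way).

Metrics: SUVmax and SUVmean over the mask; TNR = SUVmax / reference;
MTV = voxel count × voxel volume in mL (mm³/1000); TLMU = MTV × SUVmean.
Masks below 27 voxels are refused for texture analysis and masks below 64
voxels carry a warning: a 64-level co-occurrence analysis of a region smaller
than one voxel per level is numerically meaningless.

## 2. Gray-level quantization

Within the analysis region, q(x) = 1 + ⌊G·(SUV(x) − min)/(max − min)⌋ clamped
to G, with min/max taken over the region and G = 64 by default. Both
endpoints are guaranteed: the minimum maps to level 1 and the maximum to
level G; a constant region maps entirely to level 1. Because the mapping
depends only on the intensity ranks within the min–max range, **multiplying
the input by any positive constant leaves the quantized image — and hence all
36 features — unchanged**, and a *consistent* rescaling of activity and
injected dose leaves even the SUV volume itself unchanged (bit-exactly so
when the factor is a power of two; to 1 ulp otherwise).

## 3. The 36-feature battery

Exactly 36 features, frozen in `texture.FEATURE_NAMES`:

| family | count | members |
|---|---|---|
| histogram | 4 | skewness, kurtosis, entropy, energy |
| GLCM | 7 | homogeneity, energy, contrast, correlation, entropy, dissimilarity, variance |
| GLRLM | 11 | SRE, LRE, LGRE, HGRE, SRLGE, SRHGE, LRLGE, LRHGE, GLNUr, RLNU, RP |
| NGLDM | 3 | coarseness, contrast, busyness |
| GLZLM | 11 | SZE, LZE, LGZE, HGZE, SZLGE, SZHGE, LZLGE, LZHGE, GLNUz, ZLNU, ZP |

Shared conventions:

- **13-direction aggregation.** GLCM and GLRLM accumulate all 13 unique 3D
  neighbor offsets into **one** matrix (not 13 per-direction matrices with
  averaged features). The 13 offsets plus their negatives cover the full
  26-neighborhood, and the set is closed under axis permutations and flips, so
  aggregated features are *exactly* invariant under those symmetries (asserted
  bit-for-bit in the tests).
- **Offsets are in voxel units** regardless of physical spacing — the common
  radiomics convention. With anisotropic voxels the "diagonal" directions mix
  physical scales; the phantoms here are isotropic (2 mm).
- **Region boundary.** Pairs, runs, zones and neighborhoods never cross the
  region boundary: runs and zones truncate there, and out-of-region neighbors
  are excluded from co-occurrence and dependence counts.
- **Entropies are base 2** (bits): a uniform histogram over 64 levels then has
  entropy exactly 6, a convenient fixed point for tests.
- The GLCM is symmetrized (each ordered pair counted both ways) and normalized
  to sum 1; correlation uses the shared marginal mean/variance and is defined
  as 0 when the marginal variance is 0. RP divides the run count by
  (region voxels × number of directions), so RP ∈ (0,1] holds under
  aggregation; ZP divides the zone count by the region voxel count.
- NGLDM is the 3D 26-neighborhood gray-level difference statistic: for each
  region voxel with at least one in-region neighbor, A(x) is the mean neighbor
  level; with nᵢ, sᵢ = Σ|i−A| per level and pᵢ = nᵢ/N,
  coarseness = 1/Σpᵢsᵢ, contrast = [Σᵢⱼ pᵢpⱼ(i−j)²/(Nᵍ(Nᵍ−1))]·[Σsᵢ/N],
  busyness = Σpᵢsᵢ / Σᵢⱼ|i·pᵢ − j·pⱼ| (sums over occupied levels). Degenerate
  denominators (constant region, one occupied level) return 0 by convention.
- Zero-variance degenerate cases: histogram skewness/kurtosis are 0 on a
  constant region; single-voxel regions raise rather than emitting degenerate
  matrices.
- **Order-canonical accumulation.** Histogram moments are computed from the
  level histogram (fixed level order), and NGLDM neighbor sums use sorted
  accumulation, so results are bit-identical under any spatial rearrangement
  of the voxels — float reductions in visit order would differ in the last ulp.

**The texture region vs. the metric mask.** The delineation mask itself is
purely supra-threshold. For texture, `extract_all` analyzes the hole-filled
interior of that boundary by default (`fill_boundary_holes=True`): internal
low-uptake cavities — necrotic foci falling below 1.3× reference — are part
of the tumor's interior texture, and excluding them would blind LGRE to
exactly the "many small low-accumulation segments" it is meant to detect.
MTV/TLMU/TNR always come from the supra-threshold mask.

The 36-name roster reconstructs the classical PET-texture battery
(histogram 4 + GLCM 7 + GLRLM 11 + NGLDM 3 + GLZLM 11); the GLCM auxiliary
member (variance) completes the family count. Absolute feature values are
convention-dependent (quantization rule, symmetrization, entropy base,
aggregation), so cross-software numerical identity is not expected — notably,
GLCM correlation as defined here is bounded by 1, while some clinical software
reports values above 1 under a different normalization. The shipped clinical
cutoff defaults (0.088 for LGRE, 1.074 for correlation) are replication
constants on that other scale and will generally need re-deriving (e.g. cohort
medians) for data quantized by this package.

## 4. Feature reduction

Features are clustered agglomeratively on d(f,g) = 1 − |Pearson r(f,g)|
across subjects, average linkage by default, tree cut at k clusters (default
k = 6). |r| is the right redundancy measure for de-duplication: a feature and
its negation or any affine rescaling are distance 0. "Explains its cluster
best" is operationalized as the **highest mean squared correlation with the
other cluster members** (singletons represent themselves; ties break
lexicographically by feature name, so the reduction is deterministic). This
operationalization is isolated in `select_representatives` so alternatives
(first principal-component loading, medoid) can be swapped without touching
the clustering. k is a config parameter: the default mirrors the typical
6-of-36 reduction but nothing in the method selects k automatically.

## 5. Survival analysis

Records are rows with time (months, > 0), event flag (all-cause death),
clinical covariates and feature values. Estimation is delegated to lifelines:

- Kaplan–Meier product-limit per group; k-group log-rank with k−1 df.
- Cox proportional hazards with **Efron's tie handling** (the lifelines
  implementation; verified in tests against a hand-written Efron partial
  likelihood maximized by grid search to 1e-4). Wald 95% CIs exp(β ± 1.96·SE);
  model likelihood-ratio χ² against the null model.
- Hard errors on constant covariates, rank-deficient (collinear) designs and
  non-convergence; monotone likelihood (perfect separation) surfaces either as
  a convergence error or a clearly divergent coefficient with a huge SE.
- `dichotomize` splits at feature < cutoff vs ≥ cutoff; an empty group warns
  and the log-rank test then refuses the single remaining group.
- The univariate screen fits one single-covariate model per candidate. Sex and
  genetic status are handled categorically; a genetic-status level with zero
  events makes the HR non-estimable (monotone likelihood), and that row is
  flagged NA with the across-levels log-rank p reported instead — the standard
  presentation for such covariates. WHO grade enters ordinal-numerically
  (II=2, III=3, IV=4); genetic status as indicators against a configurable
  reference level (default: mutant with codeletion, the best-prognosis group).
- Texture features enter on their raw scale by default (HRs are then "per
  unit" and can be enormous for features spanning ~0.05–0.12);
  `standardize_covariates=True` gives per-SD HRs.
- α = 0.05 two-sided throughout, with **no multiple-testing correction** — a
  deliberate mirror of common practice in small clinical series, and a caveat:
  a 12-candidate screen at α = 0.05 expects ~0.6 false positives.

## 6. The synthetic generator

What it emulates: an elliptical "head" of near-unit-SUV background with
additive Gaussian noise (SD 0.05) and zero activity outside; an ellipsoidal
tumor (defaults: 18–24 mm semi-axes, uptake 2.2–4.2× background, matching a
typical MET-avid glioma with TNR ≈ 3); intratumoral heterogeneity as the sum
of two controllable mechanisms:

- a **Gaussian random field** — white noise convolved with an isotropic
  Gaussian kernel of σ = `field_corr_length` (mm), renormalized to unit
  variance, scaled by `field_sd` (default 0.25 × background) — the single
  interpretable length scale for voxel-to-voxel smoothness, which drives GLCM
  correlation;
- **necrotic foci** — up to a few disjoint spheres (defaults 2.5–4 mm radius,
  uptake 0.3–0.8× background, i.e. below the delineation threshold) placed by
  rejection sampling fully inside the ellipsoid eroded by the focus radius,
  pairwise separated by 2·radius plus one voxel so they stay 26-disconnected;
  at most 1000 retries per focus, then a placement error naming the focus.
  These drive LGRE.

The contralateral reference region is the tumor center mirrored across the
midline; the geometry defaults keep that sphere inside the head and far from
the tumor, so the reference is guaranteed noise-only background.

Cohorts sample per-subject phantom parameters uniformly from ranges and draw
survival from a proportional-hazards model: log hazard = β_necrosis ×
(n_foci / max n_foci) + β_corr × (corr length / max corr length), exponential
times at rate `baseline_hazard`·exp(log hazard) (default 0.02/month ≈ a
median OS of a few years at baseline), administrative censoring at
`max_followup` (60 months) plus, with probability `censor_rate` (0.3), an
earlier uniform censoring time. Clinical covariates (age ~ N(55,13) clipped,
43% male, WHO grade 17/40/43% with grade-conditional genetic status) match a
mixed surgical glioma series marginally but **carry no hazard**, making them
pure-noise adjusters for confounding checks. All randomness flows from one
root seed through fixed named substreams (background, field, foci, params,
clinical, survival, censoring), so each component is independently
reproducible. `generate_cohort` returns truth records with the per-subject
phantom spec embedded; volumes render lazily and reproducibly on demand.

What it does **not** emulate — and therefore what passing tests do not show
about real data: scanner physics (attenuation, scatter, partial volume,
reconstruction filters and their texture artifacts), anatomical background
structure (gray/white matter contrast, ventricles), irregular or infiltrative
tumor margins, necrosis geometries other than spheres, inter-scanner
harmonization, and any realistic joint distribution of clinical covariates
with imaging. Parameter-recovery results here certify the *statistical
machinery*, not clinical effect sizes.

## 7. Pipeline and problem sizes

One JSON/YAML config drives simulate → segment → texture → select → survival;
unknown keys are rejected by name, all values range-checked, and the defaults
encode the reference settings (1.3× threshold, 10 mm ROI, G = 64, k = 6,
clinical cutoff constants). Units are fixed pipeline-wide: mm, mL, months,
Bq, g. Each stage reads/writes only declared files under the run directory,
and the manifest records config, version, warnings and SHA-256 hashes of all
data artifacts; a re-run with the same config and seed reproduces the hashes.

Test and acceptance problem sizes are chosen so the full suite runs in
minutes on one CPU: 48³ phantoms (≈ 2–4 × 10³ tumor voxels) for Monte-Carlo
texture checks with 20 seeds per condition; 6³ grids with G ≤ 4 (200
replicates) for brute-force oracle equivalence; n = 500 × 50 replicates for
Cox recovery; a 36-subject rendered cohort for the end-to-end texture→hazard
sign check. The same statistical statements hold at larger n with tighter
Monte-Carlo error; the small sizes are a deliberate compute/precision
trade-off, not a methodological limit.

## 8. Known limitations

- Single-lesion analysis only (hottest component); no multi-focal handling.
- No IBSI-certification harness; conventions are documented here instead, and
  absolute feature values are not comparable across radiomics software.
- No proportional-hazards diagnostics, time-varying covariates, Firth
  correction, or progression-free survival.
- No DICOM ingestion or MR coregistration; reference-ROI placement is by
  explicit coordinates.
- Cutpoint choice for KM dichotomization is an input, not an optimization;
  data-driven cutpoint searches inflate type-I error and are deliberately out
  of scope.
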