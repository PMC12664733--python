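# Methods

## Scope and data model

`spatialtme` analyzes per-cell object tables from two dual-stain IHC
panels acquired on consecutive 4-µm sections of the same tumor block:
CCR8/FOXP3 (regulatory T cells) and GZMB/CD8 (cytotoxic T cells). A cell
is a point in slide coordinates (µm) with binary marker calls; geometry is
orientation-agnostic (no assumption that y grows downward) because only
relative positions matter. Phenotypes partition each panel: FOXP3+ cells
are Tregs, split by CCR8; CD8+ cells are cytotoxic T cells, split by
granzyme B; everything else — including CCR8+FOXP3− cells, for which CCR8
positivity carries no defined meaning here — is OTHER. Tumor regions are
simple GeoJSON polygons delineated upstream; cells exactly on the polygon
boundary count as inside (a closed test keeps counting deterministic and
consistent with area-inclusive densities). Stromal versus intra-tumoral
compartmentalization is out of scope.

## Whole-tumor-area metrics

Densities are in-region phenotype counts divided by the annotated area in
mm²; percentages and ratios are undefined (NaN, never 0) when their
denominator count is zero, and undefined values propagate — a case with no
CCR8+ Tregs simply drops out of any split on the CD8/CCR8+Treg ratio.
Ratios are computed from densities, which is identical to count ratios
since both panels share the region. Median splits label values strictly
above the cohort median HIGH and the rest LOW; the tie rule is recorded in
the output metadata. With an even number of distinct values this gives
balanced groups. Stage-wise metric comparisons use two-sided Mann-Whitney
tests with no multiplicity adjustment, matching common practice for
descriptive cohort tables; pairs with under two cases per stage are
skipped.

## Hotspot ROIs

Candidate 500×500 µm windows are anchored on a lattice of pitch
window/5 = 100 µm spanning the tumor bounding box. Windows are half-open
([x0, x0+500) × [y0, y0+500)), which makes window counts identical to
block sums of 100-µm bins and lets a brute-force search serve as an exact
oracle. Selection is greedy: the highest-count window wins rank 1 (ties
broken by smaller x0, then y0), all overlapping candidates are discarded,
and the process repeats to k = 5. Requiring non-overlap reads "five most
enriched areas" as five distinct areas; a continuous slide position search
would add nondeterminism without changing counts materially at this
window size. ROIs transfer to the paired section through a rigid
transform, identity by default — consecutive 4-µm sections are treated as
co-registered; a measured rotation/translation can be supplied. The
top-case correlation analysis ranks cases by mean hotspot CCR8+ Treg
density (a `rank_by="wta"` switch uses whole-tumor density instead, since
either reading of "highest accumulation" is defensible), keeps the top 40,
and fits ordinary least squares of hotspot CCR8+ Treg density against CD8
density and against %GzmB+ in CD8.

## Distance analysis

Nearest-neighbor distances and annulus censuses run over all in-region
cells (the whole-tumor protocol). Annuli are half-open, [10i, 10(i+1)) µm
to 100 µm: a target at exactly 10.0 µm falls in the second bin, and a
nearest neighbor at exactly 100 µm is a valid distance that contributes
to no annulus. No edge correction is applied at the tumor boundary;
instead each index cell's boundary distance is exported so users can
filter boundary-proximal cells. Profiles can be pooled across all Tregs
of a cohort or kept per case; the pooled Mann-Whitney comparison treats
cells as exchangeable units, which overstates precision when cases are
heterogeneous — both modes are exposed and neither is claimed canonical.
Distance to the invasion front is the shortest Euclidean distance to the
annotated polyline, summarized per phenotype by median and IQR.

## Statistical tests

* Mann-Whitney U: exact null when the combined sample is ≤ 20 without
  ties, otherwise the tie-corrected normal approximation; two-sided.
* Fisher's exact test: classical two-sided rule (sum of hypergeometric
  probabilities not exceeding the observed table's).
* Pearson chi-square without continuity correction. Both categorical
  tests are reported side by side in composition tables: at n = 80 their
  p-values differ enough (e.g. 0.019 vs 0.034 on the same 2×2 table)
  that silently choosing one would be misleading.
* Kaplan-Meier product-limit estimation; five-year survival is the step
  function read at 60 months. Log-rank for two-group comparison. Cox
  proportional hazards with Efron tie handling and Wald 95% CIs on the
  log hazard ratio; monotone likelihood (complete separation) is flagged
  as non-convergence with no HR reported. α = 0.05, two-sided,
  unadjusted throughout.

All of these delegate to scipy/lifelines; the package's own contribution
is the spatial machinery and the generator, and tests verify the
delegated routes against independent enumerations, hand tabulations and
grid searches.

## Synthetic tissue and cohort generator

The generator encodes each qualitative structure the analysis is meant to
detect as an explicit parameter (defaults in parentheses):

* Tumor region: 4,000×4,000 µm square (16 mm²); the bottom edge is the
  invasion front. A mid-sized resection-specimen tumor cross-section.
* Tregs: homogeneous Poisson, λ_treg = 150/mm²; CCR8 positivity
  p = 0.35, multiplied by (1 + g), g = 1.5, within w = 500 µm of the
  front (clipped to [0,1]) — front accumulation as a step enrichment.
* CD8 candidates: Poisson, λ_cd8 = 300/mm², thinned near CCR8+ Tregs:
  retention 1 − s·exp(−d/τ) with s = 1, τ = 20 µm, d the distance to the
  nearest CCR8+ Treg. Thinning bookkeeping (candidates = retained +
  removed) is emitted per case.
* GzmB positivity: logistic(a − b·ρ) with a = 0.5, b = 0.25, ρ the CCR8+
  Treg count within 100 µm — local suppression of effector state,
  independent of the exclusion knob.
* Paired section: the CD8/GZMB panel observes the same cells with
  isotropic Gaussian jitter σ = 15 µm (an independent-resampling check is
  in the test suite via σ = 0 versus σ = 30 comparisons).
* Cohort: per-case lognormal intensity multipliers (sd 0.4) and a
  logit-normal CCR8 fraction (sd 0.5) create between-case spread;
  clinicopathological covariates (stage, sex, histology, invasion flags,
  chemotherapy) are drawn independently of everything else, so
  composition-table tests are null by construction.
* Survival: exponential RFS with hazard h0·exp(β·risk), h0 = 0.004 per
  month, risk = −z where z is the cohort-standardized log CD8/CCR8+Treg
  density ratio, administratively censored at 60 months. β = 1 by
  default; the sign convention makes positive β penalize low-ratio cases,
  the direction observed clinically. h0 yields roughly an 80% five-year
  recurrence-free fraction, in the range seen in resected cohorts.

Intensities are realistic for T-cell infiltrates in gastric tumors
(10²–10³ cells/mm²) and give ~2,400 Tregs and ~4,800 CD8 candidates per
default case. Determinism: a per-case substream is derived from the
config seed and a CRC-32 of the case id; identical (config, seed) give
bit-identical outputs. `generate_cohort(spatial=False)` is a count-level
fast path drawing per-case counts without positions, used for survival
simulation studies where geometry is irrelevant; spatial mechanisms do
not act there, and it is never used to validate spatial claims.

What the generator does not emulate: cell morphology and staining
intensity, stromal architecture, irregular tumor outlines, spatially
correlated clustering beyond the front band, marker mis-classification,
and section-to-section cell loss. Passing recovery tests therefore shows
the pipeline detects these mechanisms when present with realistic
abundances — not that real tissue contains them.

## Validation studies and problem sizes

Simulation studies (module `spatialtme.studies`) run the full
generator→analysis path:

* Null calibration: with s = g = b = 0 and β = 0, the CCR8+/CCR8−
  distance comparison and the median-split log-rank test each reject at
  5% ± 4% over 200 simulated datasets.
* Effect recovery at defaults: longer NN distances from CCR8+ than
  CCR8− Tregs, shorter front distances for CCR8+ Tregs, a negative
  hotspot %GzmB slope (80-case cohorts, top 40), and a lower LOW-ratio
  KM curve at 60 months — each in ≥ 95 of 100 seeds.
* Cox CI coverage: 500 count-level cohorts of 200 cases at β = 1;
  Wald 95% CI coverage lands in 93–97%. Measured coverage is ≈ 94.4%,
  the mild anticonservativeness expected of Wald intervals at ~50 events
  per cohort.

These sizes keep the default validation suite to a few minutes on one
CPU while leaving Monte-Carlo noise well inside the stated bands.

## Known limitations and flagged inconsistencies

* Hotspot anchors are lattice-quantized; a window straddling two anchors
  can in principle beat the lattice optimum by a few cells.
* The pooled distance comparison ignores case-level clustering (see
  above); per-case medians are exported for hierarchy-aware analyses.
* Published cohort tables of this design can be internally inconsistent;
  one known example reports histology counts of 17/23 vs 29/11 across
  ratio groups (i.e. 42.5%/57.5% by column arithmetic in one group)
  while printing 47.5%/52.5%, and its narrative assigns the 47.5%
  differentiation rate to the opposite column. The composition-table
  code always derives percentages from counts; it does not attempt to
  reconcile such source discrepancies.
* No stromal/epithelial compartmentalization, no deformable section
  registration, no second-order spatial statistics (Ripley's K,
  cross-PCF) — the census and nearest-neighbor summaries are the
  analysis targets.
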