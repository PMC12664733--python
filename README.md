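# spatialtme

Spatial immune-microenvironment profiling of tumor tissue from digital
pathology cell exports.

Tumor-infiltrating regulatory T cells (Tregs, FOXP3+) suppress antitumor
immunity, and the CCR8+ subset marks highly suppressive, tumor-resident
activated Tregs. `spatialtme` implements a complete, testable pipeline for
quantifying the spatial relationship between CCR8+ Tregs and cytotoxic
CD8+ T cells (and their granzyme-B effector state) from paired dual-stain
immunohistochemistry panels on consecutive sections — CCR8/FOXP3 and
GZMB/CD8 — together with the survival analyses that link these spatial
summaries to patient outcome. It is aimed at translational
immuno-oncology groups analyzing per-cell object tables exported by image
analysis platforms (HALO-style CSVs), with tumor regions annotated as
GeoJSON polygons.

## What it computes

For each case, with tumor area $A$ (mm²) from the pathologist annotation:

* **Whole-tumor-area (WTA) metrics** — densities (cells/mm²) of Tregs
  (FOXP3+), CCR8+ Tregs (CCR8+FOXP3+), CD8+ T cells, and GzmB+CD8+
  T cells; the percentages %CCR8+ in Tregs and %GzmB+ in CD8+; and the
  ratios CD8/Treg and CD8/CCR8+Treg. Cohorts are dichotomized at the
  median of any metric (HIGH: value > median; LOW: value ≤ median).
* **Hotspot ROIs** — the five non-overlapping 500×500 µm windows with
  the highest CCR8+ Treg counts (greedy selection over a 100 µm anchor
  lattice), transferred to the paired GZMB/CD8 section, with per-ROI
  densities and, over the top-n most infiltrated cases, OLS regressions
  of hotspot CCR8+ Treg density against CD8 density and %GzmB+ in CD8.
* **Distance analysis** — from every CCR8+ and CCR8− Treg, the
  Euclidean nearest-neighbor distance to CD8+ (or GzmB+CD8+) cells and a
  census of targets in half-open 10-µm annuli out to 100 µm, compared by
  Mann-Whitney U; plus per-cell distance to the annotated invasion front.
* **Survival** — Kaplan-Meier recurrence-free survival per median-split
  group, log-rank tests, univariable Cox hazard ratios (Efron ties) with
  Wald 95% CIs, and clinicopathological composition tables with
  chi-square/Fisher/Mann-Whitney tests.
* **Synthetic ground truth** — a generator of paired-section tissues and
  clinical cohorts in which front enrichment of CCR8+ Tregs, local CD8
  exclusion, GzmB suppression and the ratio–hazard link are explicit,
  switchable parameters, so every stage can be validated without patient
  data (see `docs/methods.md`).

## Worked example

```python
from spatialtme import CohortSpatialModel, SyntheticConfig, generate_cohort

cohort = generate_cohort(SyntheticConfig(seed=42, n_cases=12))
results = CohortSpatialModel(cohort.cells, cohort.regions,
                             cohort.clinical, top_n=10).fit()
print(results.summary())
```

prints (abridged):

```
Spatial immune-microenvironment cohort analysis
================================================
cases: 12   hotspot window: 500 um, k = 5

Nearest CD8+ T cell distance (pooled):
  median from CCR8+ Tregs   35.5 um
  median from CCR8- Tregs   30.7 um
  Mann-Whitney p = 8.2e-122

Hotspot correlations (top 10 cases):
  CCR8+ Treg density vs cd8_density: slope -0.4488, r = -0.634, p = 0.0489 (n = 10)
  CCR8+ Treg density vs pct_gzmb_in_cd8: slope -0.1319, r = -0.983, p = 3.38e-07 (n = 10)

Distance to invasion front (median um):
  TREG_CCR8NEG     2187.0
  TREG_CCR8POS     1659.3

RFS split on ratio_cd8_over_ccr8treg:
  5-year RFS high  83.3% (n=6) vs low  33.3% (n=6), log-rank p = 0.0542
  Cox HR (low vs high) 6.73 [0.73, 61.96]
```

Reading it: CD8+ T cells are farther from CCR8+ than CCR8− Tregs (local
exclusion), hotspots dense in CCR8+ Tregs show a lower granzyme-B-positive
fraction among their CD8+ T cells (negative slope), CCR8+ Tregs sit closer
to the invasion front, and cases with a low CD8/CCR8+Treg ratio recur
sooner — each the direct readout of a generator mechanism that the
pipeline recovers.

The same stages are available from the shell:

```sh
spatialtme simulate --out-dir data/ --seed 7
spatialtme wta --cells-treg data/cells_ccr8_foxp3.csv \
    --cells-cd8 data/cells_cd8_gzmb.csv --regions data/regions \
    --out wta_metrics.csv
spatialtme survival --clinical data/clinical.csv --metrics wta_metrics.csv \
    --split ratio_cd8_over_ccr8treg --out survival_report.json
```

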