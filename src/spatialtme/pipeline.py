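"""End-to-end cohort analysis as a model/results pair.

:class:`CohortSpatialModel` bundles the inputs of the full analysis —
classified cell tables for both panels, tumor-region annotations and an
optional clinical table — and its :meth:`~CohortSpatialModel.fit` runs
every stage: whole-tumor-area metrics and median splits, hotspot ROI
profiling with the top-case correlations, Treg→CD8 distance profiling,
invasion-front distances, and survival stratification. The returned
:class:`CohortSpatialResults` carries the per-stage tables and a
:meth:`~CohortSpatialResults.summary` report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import distance as _dist
from . import hotspot as _hot
from . import survival as _surv
from . import wta as _wta
from .exceptions import UsageError
from .io_tables import (Panel, RegionAnnotation, read_cell_table,
                        read_clinical_table, read_region_annotation,
                        classify_phenotypes)

SPLIT_VARIABLES = ("treg_density", "ccr8_treg_density", "cd8_density",
                   "gzmb_cd8_density", "pct_ccr8_in_treg",
                   "ratio_cd8_over_treg", "ratio_cd8_over_ccr8treg")


class CohortSpatialModel:
    """Spatial immune-microenvironment analysis of a cohort.

    Parameters
    ----------
    cells : pandas.DataFrame
        Phenotype-classified cells of both panels for all cases.
    regions : mapping of case_id -> RegionAnnotation
    clinical : pandas.DataFrame, optional
        Per-case outcome table (case_id, rfs_months, event, covariates).
    window_um, k_hotspots, top_n, bin_um, max_um, rank_by
        Analysis parameters: hotspot window side and count, number of
        top cases entering the ROI correlations, annulus bin width and
        census radius, and how the top cases are ranked
        (``"hotspot"`` or ``"wta"``).
    """

    def __init__(self, cells: pd.DataFrame,
                 regions: Mapping[str, RegionAnnotation],
                 clinical: pd.DataFrame | None = None, *,
                 window_um: float = 500.0, k_hotspots: int = 5,
                 top_n: int = 40, bin_um: float = 10.0, max_um: float = 100.0,
                 rank_by: str = "hotspot", pool_distances: bool = True):
        if "phenotype" not in cells.columns:
            parts = [classify_phenotypes(g)
                     for _, g in cells.groupby("panel", sort=False)]
            cells = pd.concat(parts, ignore_index=True)
        self.cells = cells
        self.regions = dict(regions)
        self.clinical = clinical
        self.window_um = window_um
        self.k_hotspots = k_hotspots
        self.top_n = top_n
        self.bin_um = bin_um
        self.max_um = max_um
        self.rank_by = rank_by
        self.pool_distances = pool_distances

    @classmethod
    def from_files(cls, cells_treg_csv, cells_cd8_csv, region_paths: Mapping[str, str],
                   clinical_csv=None, **kwargs) -> "CohortSpatialModel":
        """Build the model from CSV/GeoJSON files on disk."""
        tf = classify_phenotypes(read_cell_table(cells_treg_csv, Panel.CCR8_FOXP3))
        cg = classify_phenotypes(read_cell_table(cells_cd8_csv, Panel.CD8_GZMB))
        regions = {cid: read_region_annotation(p) for cid, p in region_paths.items()}
        clinical = read_clinical_table(clinical_csv) if clinical_csv else None
        return cls(pd.concat([tf, cg], ignore_index=True), regions, clinical,
                   **kwargs)

    def _case_panels(self, case_id):
        if not hasattr(self, "_panel_groups"):
            self._panel_groups = dict(iter(
                self.cells.groupby(["case_id", "panel"], sort=False)))
        empty = self.cells.iloc[:0]
        return (self._panel_groups.get((case_id, Panel.CCR8_FOXP3.value), empty),
                self._panel_groups.get((case_id, Panel.CD8_GZMB.value), empty))

    def fit(self) -> "CohortSpatialResults":
        """Run every analysis stage and collect the results."""
        if not self.regions:
            raise UsageError("no region annotations supplied")
        wta = _wta.wta_metrics_table(self.cells, self.regions)

        splits = {}
        for var in SPLIT_VARIABLES:
            try:
                splits[var] = _wta.median_split(wta[var])
            except UsageError:
                continue

        roi_tables, nn_pos, nn_neg, front_frames = [], [], [], []
        case_medians = []
        for case_id, region in self.regions.items():
            tf, cg = self._case_panels(case_id)
            rois = _hot.select_hotspots(tf, region, self.window_um,
                                        self.k_hotspots)
            if rois:
                roi_tables.append(_hot.roi_metrics(rois, tf, cg))
            profiles = _dist.treg_cd8_profiles(tf, cg, bin_um=self.bin_um,
                                               max_um=self.max_um, region=region)
            pos = profiles.get("TREG_CCR8POS")
            neg = profiles.get("TREG_CCR8NEG")
            if pos is not None:
                nn_pos.append(pos.nn_distances)
            if neg is not None:
                nn_neg.append(neg.nn_distances)
            if pos is not None and neg is not None:
                case_medians.append({"case_id": case_id,
                                     "median_nn_ccr8pos": pos.median_nn,
                                     "median_nn_ccr8neg": neg.median_nn})
            if region.invasion_front is not None and len(tf):
                inreg = tf[region.contains(tf["x_um"].to_numpy(),
                                           tf["y_um"].to_numpy())]
                fd = _dist.distance_to_front(inreg, region.invasion_front)
                if fd is not None:
                    front_frames.append(fd)

        rois = (pd.concat(roi_tables, ignore_index=True) if roi_tables
                else pd.DataFrame())
        roi_summary = _hot.case_roi_summary(rois) if len(rois) else pd.DataFrame()
        regressions = None
        if len(roi_summary) >= 3:
            regressions = _hot.roi_correlation(roi_summary, top_n=self.top_n,
                                               rank_by=self.rank_by,
                                               wta_metrics=wta)

        distance_comparison = None
        if nn_pos and nn_neg and self.pool_distances:
            a = _dist.DistanceProfile("TREG_CCR8POS", "CD8T_ANY",
                                      np.concatenate(nn_pos), np.array([]),
                                      np.empty((0, 0)))
            b = _dist.DistanceProfile("TREG_CCR8NEG", "CD8T_ANY",
                                      np.concatenate(nn_neg), np.array([]),
                                      np.empty((0, 0)))
            distance_comparison = _dist.compare_profiles(a, b)

        front_summary = None
        if front_frames:
            front_summary = _dist.front_distance_summary(
                pd.concat(front_frames, ignore_index=True))

        survival = {}
        if self.clinical is not None:
            for var, labels in splits.items():
                try:
                    survival[var] = _surv.km_split_analysis(self.clinical, labels)
                except UsageError:
                    continue

        return CohortSpatialResults(
            model=self, wta=wta, splits=splits, rois=rois,
            roi_case_summary=roi_summary, regressions=regressions,
            distance_comparison=distance_comparison,
            per_case_nn_medians=pd.DataFrame(case_medians),
            front_summary=front_summary, survival=survival)


@dataclass
class CohortSpatialResults:
    """Fitted results of :class:`CohortSpatialModel`."""

    model: CohortSpatialModel
    wta: pd.DataFrame
    splits: dict
    rois: pd.DataFrame
    roi_case_summary: pd.DataFrame
    regressions: dict | None
    distance_comparison: object | None
    per_case_nn_medians: pd.DataFrame
    front_summary: pd.DataFrame | None
    survival: dict = field(default_factory=dict)

    def summary(self) -> str:
        """Human-readable multi-stage report."""
        lines = ["Spatial immune-microenvironment cohort analysis",
                 "=" * 48,
                 f"cases: {len(self.wta)}   "
                 f"hotspot window: {self.model.window_um:.0f} um, "
                 f"k = {self.model.k_hotspots}"]
        lines.append("\nWhole-tumor-area metrics (cohort medians):")
        med = self.wta.median(numeric_only=True)
        for k, v in med.items():
            lines.append(f"  {k:<28s} {v:10.2f}")
        if self.distance_comparison is not None:
            dc = self.distance_comparison
            lines.append("\nNearest CD8+ T cell distance (pooled):")
            lines.append(f"  median from CCR8+ Tregs {dc.median_a:6.1f} um")
            lines.append(f"  median from CCR8- Tregs {dc.median_b:6.1f} um")
            lines.append(f"  Mann-Whitney p = {dc.p:.3g}")
        if self.regressions:
            lines.append(f"\nHotspot correlations (top {self.model.top_n} cases):")
            for name, reg in self.regressions.items():
                lines.append(f"  CCR8+ Treg density vs {name}: "
                             f"slope {reg.slope:+.4g}, r = {reg.r:+.3f}, "
                             f"p = {reg.p:.3g} (n = {reg.n})")
        if self.front_summary is not None:
            lines.append("\nDistance to invasion front (median um):")
            for pheno, row in self.front_summary.iterrows():
                lines.append(f"  {pheno:<14s} {row['median_um']:8.1f}")
        for var, res in self.survival.items():
            lr = res["logrank"]
            lines.append(f"\nRFS split on {var}:")
            lines.append(f"  5-year RFS high {res['rfs60_high']:5.1f}% "
                         f"(n={res['n_high']}) vs low {res['rfs60_low']:5.1f}% "
                         f"(n={res['n_low']}), log-rank p = {lr.p:.3g}")
            cox = res["cox_low_vs_high"]
            if cox.converged:
                lines.append(f"  Cox HR (low vs high) {cox.hr:.2f} "
                             f"[{cox.ci_low:.2f}, {cox.ci_high:.2f}]")
        return "\n".join(lines)
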