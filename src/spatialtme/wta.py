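"""Whole-tumor-area (WTA) metrics and median-split cohort grouping.

The WTA protocol quantifies immune infiltration over the entire annotated
tumor region of a section. Six per-case metrics are computed from the two
panels:

* ``treg_density`` — FOXP3+ cells / mm²
* ``ccr8_treg_density`` — CCR8+FOXP3+ cells / mm²
* ``cd8_density`` — CD8+ cells / mm²
* ``gzmb_cd8_density`` — GZMB+CD8+ cells / mm²
* ``pct_ccr8_in_treg`` — 100 · CCR8+FOXP3+ / FOXP3+ (undefined without Tregs)
* ``pct_gzmb_in_cd8`` — 100 · GZMB+CD8+ / CD8+ (undefined without CD8 cells)

plus two ratio statistics, ``ratio_cd8_over_treg`` and
``ratio_cd8_over_ccr8treg``, computed from the densities (equivalently the
counts, since both panels share the tumor region). Undefined quantities are
reported as NaN, never as zero, and propagate as missing into splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import DegenerateSplitError, UsageError
from .io_tables import Phenotype, RegionAnnotation
from .survival import TestResult, mann_whitney_test

WTA_METRIC_COLUMNS = (
    "treg_density", "ccr8_treg_density", "cd8_density", "gzmb_cd8_density",
    "pct_ccr8_in_treg", "pct_gzmb_in_cd8",
    "ratio_cd8_over_treg", "ratio_cd8_over_ccr8treg",
)


@dataclass
class WtaMetrics:
    """The six whole-tumor-area metrics plus the two ratios for one case."""

    case_id: str
    treg_density: float
    ccr8_treg_density: float
    cd8_density: float
    gzmb_cd8_density: float
    pct_ccr8_in_treg: float
    pct_gzmb_in_cd8: float
    ratio_cd8_over_treg: float
    ratio_cd8_over_ccr8treg: float

    def as_dict(self) -> dict:
        return asdict(self)


def _phenotype_counts(cells: pd.DataFrame, region: RegionAnnotation) -> dict[str, int]:
    if len(cells) == 0:
        return {}
    inside = region.contains(cells["x_um"].to_numpy(), cells["y_um"].to_numpy())
    sub = cells.loc[inside]
    return sub["phenotype"].value_counts().to_dict()


def compute_wta_metrics(cells_treg_panel: pd.DataFrame,
                        cells_cd8_panel: pd.DataFrame,
                        region: RegionAnnotation,
                        case_id: str | None = None) -> WtaMetrics:
    """Compute the WTA metrics for one case.

    Parameters
    ----------
    cells_treg_panel, cells_cd8_panel : pandas.DataFrame
        Phenotype-classified cell tables (see
        :func:`spatialtme.io_tables.classify_phenotypes`) for the CCR8/FOXP3
        and CD8/GZMB panels of the case. Cells outside the tumor region are
        excluded before counting; boundary cells count as inside.
    region : RegionAnnotation
        Tumor annotation whose area (mm²) is the density denominator.

    Raises
    ------
    UsageError
        If the region area is not positive.
    """
    area = region.area_mm2
    if not area > 0:
        raise UsageError("tumor region area must be positive")
    if case_id is None:
        for df in (cells_treg_panel, cells_cd8_panel):
            if len(df):
                case_id = str(df["case_id"].iloc[0])
                break
    tf = _phenotype_counts(cells_treg_panel, region)
    cg = _phenotype_counts(cells_cd8_panel, region)
    n_ccr8_treg = tf.get(Phenotype.TREG_CCR8POS.value, 0)
    n_treg = n_ccr8_treg + tf.get(Phenotype.TREG_CCR8NEG.value, 0)
    n_gzmb_cd8 = cg.get(Phenotype.CD8T_GZMBPOS.value, 0)
    n_cd8 = n_gzmb_cd8 + cg.get(Phenotype.CD8T_GZMBNEG.value, 0)

    treg_density = n_treg / area
    ccr8_treg_density = n_ccr8_treg / area
    cd8_density = n_cd8 / area
    gzmb_cd8_density = n_gzmb_cd8 / area
    return WtaMetrics(
        case_id=case_id,
        treg_density=treg_density,
        ccr8_treg_density=ccr8_treg_density,
        cd8_density=cd8_density,
        gzmb_cd8_density=gzmb_cd8_density,
        pct_ccr8_in_treg=100.0 * n_ccr8_treg / n_treg if n_treg else np.nan,
        pct_gzmb_in_cd8=100.0 * n_gzmb_cd8 / n_cd8 if n_cd8 else np.nan,
        ratio_cd8_over_treg=cd8_density / treg_density if n_treg else np.nan,
        ratio_cd8_over_ccr8treg=(cd8_density / ccr8_treg_density
                                 if n_ccr8_treg else np.nan),
    )


def wta_metrics_table(cells: pd.DataFrame,
                      regions: Mapping[str, RegionAnnotation]) -> pd.DataFrame:
    """Per-case WTA metrics for a cohort.

    `cells` holds both panels (classified); `regions` maps case_id to its
    tumor annotation. Returns one row per case present in `regions`.
    """
    from .io_tables import Panel
    rows = []
    for case_id, region in regions.items():
        sub = cells[cells["case_id"] == case_id]
        tf = sub[sub["panel"] == Panel.CCR8_FOXP3.value]
        cg = sub[sub["panel"] == Panel.CD8_GZMB.value]
        rows.append(compute_wta_metrics(tf, cg, region, case_id=case_id).as_dict())
    return pd.DataFrame(rows).set_index("case_id")


def median_split(values: Mapping[str, float] | pd.Series) -> pd.Series:
    """Dichotomize cases at the cohort median: > median → HIGH, ≤ → LOW.

    Missing (NaN) values are excluded; those cases receive no label. With an
    even number of distinct values the split is balanced (the median falls
    between the two middle order statistics). Values tied at the median go
    LOW — a deterministic rule recorded in the returned Series' attrs.

    Raises
    ------
    UsageError
        Fewer than 2 non-missing values.
    DegenerateSplitError
        All non-missing values identical.
    """
    s = pd.Series(values, dtype=float).dropna()
    if len(s) < 2:
        raise UsageError("median split needs at least 2 non-missing values")
    if s.nunique() == 1:
        raise DegenerateSplitError("all values identical; cannot split at median")
    med = float(np.median(s.to_numpy()))
    labels = pd.Series(np.where(s.to_numpy() > med, "HIGH", "LOW"), index=s.index)
    labels.attrs["median"] = med
    labels.attrs["tie_rule"] = "values equal to the median are labeled LOW"
    return labels


def stage_compare(metrics: pd.DataFrame,
                  stages: Mapping[str, str] | pd.Series,
                  metric_columns: tuple[str, ...] = WTA_METRIC_COLUMNS,
                  ) -> pd.DataFrame:
    """Pairwise Mann-Whitney comparison of each metric across tumor stages.

    No multiplicity adjustment is applied; each stage pair is tested
    marginally at the two-sided level. Pairs where either stage has fewer
    than 2 cases with a non-missing metric are skipped with a warning.

    Returns a DataFrame with columns ``metric, stage_a, stage_b, n_a, n_b,
    statistic, p``.
    """
    stages = pd.Series(stages)
    rows = []
    stage_levels = sorted(stages.dropna().unique())
    for metric in metric_columns:
        vals = metrics[metric]
        for a, b in combinations(stage_levels, 2):
            xa = vals[stages.index[stages == a].intersection(vals.index)].dropna()
            xb = vals[stages.index[stages == b].intersection(vals.index)].dropna()
            if len(xa) < 2 or len(xb) < 2:
                warnings.warn(f"stage pair ({a}, {b}) skipped for {metric}: "
                              "fewer than 2 cases per stage")
                continue
            res: TestResult = mann_whitney_test(xa.to_numpy(), xb.to_numpy())
            rows.append({"metric": metric, "stage_a": a, "stage_b": b,
                         "n_a": len(xa), "n_b": len(xb),
                         "statistic": res.statistic, "p": res.p})
    return pd.DataFrame(rows)
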