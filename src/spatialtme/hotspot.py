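"""Density grids, 500×500 µm hotspot ROIs, paired-section transfer, and the
top-case correlation analysis.

The ROI protocol emulates a density-heatmap workflow: candidate 500×500 µm
windows are anchored on a lattice of pitch window/5 (100 µm by default) over
the tumor bounding box, scored by the number of in-region CCR8+ Tregs they
contain, and the five best pairwise non-overlapping windows are picked
greedily. Window membership is half-open, [x0, x0+side) × [y0, y0+side),
so lattice bin sums reproduce window counts exactly. Selected ROIs are
transferred to the paired CD8/GZMB section (identity transform by default,
since consecutive 4-µm sections are near-identical in geometry; an optional
rigid transform covers registered slides) and per-ROI densities are
computed over the fixed 0.25 mm² window area.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely.geometry import Polygon

from .exceptions import UsageError
from .io_tables import Phenotype, RegionAnnotation


@dataclass
class DensityGrid:
    """Per-bin in-region phenotype counts on a regular grid.

    ``counts[i, j]`` is the number of cells with
    x ∈ [origin_x + i·bin_um, origin_x + (i+1)·bin_um) and y likewise
    (x-index first). Cells exactly on the grid's upper boundary are folded
    into the last bin so that the grid conserves the in-region total.
    """

    case_id: str | None
    origin: tuple[float, float]
    bin_um: float
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class HotspotROI:
    """One selected 500×500 µm hotspot window."""

    case_id: str | None
    rank: int
    x0: float
    y0: float
    side_um: float
    count: int

    @property
    def area_mm2(self) -> float:
        return self.side_um ** 2 / 1e6

    def contains(self, x_um, y_um) -> np.ndarray:
        """Half-open window membership test."""
        x = np.asarray(x_um, float)
        y = np.asarray(y_um, float)
        return ((x >= self.x0) & (x < self.x0 + self.side_um)
                & (y >= self.y0) & (y < self.y0 + self.side_um))


@dataclass
class RigidTransform:
    """Rotation (radians, about the origin) followed by translation, µm."""

    theta: float = 0.0
    dx: float = 0.0
    dy: float = 0.0

    def apply(self, x, y):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        c, s = math.cos(self.theta), math.sin(self.theta)
        return c * x - s * y + self.dx, s * x + c * y + self.dy


@dataclass
class RegressionResult:
    """Ordinary least-squares line fit with Pearson correlation."""

    slope: float
    intercept: float
    r: float
    p: float
    n: int


def _select_phenotype(cells: pd.DataFrame, phenotype) -> pd.DataFrame:
    if phenotype is None:
        return cells
    value = phenotype.value if isinstance(phenotype, Phenotype) else str(phenotype)
    return cells[cells["phenotype"] == value]


def build_density_grid(cells: pd.DataFrame, region: RegionAnnotation,
                       bin_um: float,
                       phenotype: Phenotype | str | None = None) -> DensityGrid:
    """Bin in-region cells of one phenotype onto a regular grid.

    The grid origin is the region bounding-box minimum; the extent covers
    the full bounding box. A region smaller than one bin yields a single-bin
    grid with a warning.
    """
    if not bin_um > 0:
        raise UsageError("bin_um must be positive")
    sub = _select_phenotype(cells, phenotype)
    xmin, ymin, xmax, ymax = region.bounds
    nx = max(1, math.ceil((xmax - xmin) / bin_um))
    ny = max(1, math.ceil((ymax - ymin) / bin_um))
    if (xmax - xmin) < bin_um or (ymax - ymin) < bin_um:
        warnings.warn("region smaller than one bin; returning a single-bin grid")
    counts = np.zeros((nx, ny), dtype=np.int64)
    if len(sub):
        x = sub["x_um"].to_numpy(float)
        y = sub["y_um"].to_numpy(float)
        inside = region.contains(x, y)
        x, y = x[inside], y[inside]
        ix = np.minimum((np.floor((x - xmin) / bin_um)).astype(int), nx - 1)
        iy = np.minimum((np.floor((y - ymin) / bin_um)).astype(int), ny - 1)
        np.add.at(counts, (ix, iy), 1)
    case_id = str(cells["case_id"].iloc[0]) if len(cells) else None
    return DensityGrid(case_id=case_id, origin=(xmin, ymin), bin_um=bin_um,
                       counts=counts)


def _anchor_lattice(lo: float, hi: float, window: float, pitch: float) -> np.ndarray:
    n = int(math.floor((hi - lo - window) / pitch + 1e-9)) + 1
    return lo + pitch * np.arange(max(n, 1))


def select_hotspots(cells: pd.DataFrame, region: RegionAnnotation,
                    window_um: float = 500.0, k: int = 5,
                    phenotype: Phenotype | str = Phenotype.TREG_CCR8POS,
                    ) -> list[HotspotROI]:
    """Greedy selection of the k highest-count non-overlapping windows.

    Candidate anchors lie on a lattice of pitch ``window_um / 5`` spanning
    the region bounding box. Each round picks the remaining candidate with
    the maximal in-region count of the target phenotype (ties broken by
    smaller x0, then y0) and discards all candidates overlapping it. Fewer
    than k ROIs are returned only when no non-overlapping candidate with a
    positive count remains.

    Raises
    ------
    UsageError
        Region bounding box smaller than one window.
    """
    xmin, ymin, xmax, ymax = region.bounds
    if (xmax - xmin) < window_um or (ymax - ymin) < window_um:
        raise UsageError("region bounding box smaller than one hotspot window")
    pitch = window_um / 5.0
    xs = _anchor_lattice(xmin, xmax, window_um, pitch)
    ys = _anchor_lattice(ymin, ymax, window_um, pitch)

    sub = _select_phenotype(cells, phenotype)
    case_id = str(cells["case_id"].iloc[0]) if len(cells) else None
    if len(sub) == 0:
        warnings.warn("no cells of the hotspot phenotype in the region")
        return []
    x = sub["x_um"].to_numpy(float)
    y = sub["y_um"].to_numpy(float)
    inside = region.contains(x, y)
    x, y = x[inside], y[inside]
    if x.size == 0:
        warnings.warn("no in-region cells of the hotspot phenotype")
        return []

    # window count matrix via membership outer product: counts[i, j] =
    # #cells with x in [xs[i], xs[i]+w) and y in [ys[j], ys[j]+w)
    in_x = ((x[None, :] >= xs[:, None]) & (x[None, :] < xs[:, None] + window_um))
    in_y = ((y[None, :] >= ys[:, None]) & (y[None, :] < ys[:, None] + window_um))
    counts = in_x.astype(np.float64) @ in_y.astype(np.float64).T
    counts = np.round(counts).astype(np.int64)

    available = np.ones_like(counts, dtype=bool)
    rois: list[HotspotROI] = []
    for rank in range(1, k + 1):
        masked = np.where(available, counts, -1)
        best = masked.max()
        if best <= 0:
            break
        # lexicographic tie-break on (x0, y0): first index in row-major order
        i, j = np.argwhere(masked == best)[0]
        rois.append(HotspotROI(case_id=case_id, rank=rank,
                               x0=float(xs[i]), y0=float(ys[j]),
                               side_um=float(window_um), count=int(best)))
        overlap_x = np.abs(xs - xs[i]) < window_um
        overlap_y = np.abs(ys - ys[j]) < window_um
        available[np.ix_(overlap_x, overlap_y)] = False
    return rois


def transfer_roi(roi: HotspotROI, transform: RigidTransform | None = None) -> Polygon:
    """Map a hotspot window into the paired-section frame.

    With the default identity transform the footprint is the original
    window. Under a general rigid transform the footprint is the
    transformed (possibly rotated) square polygon; counting inside it is
    boundary-inclusive.
    """
    if transform is None:
        transform = RigidTransform()
    cx = [roi.x0, roi.x0 + roi.side_um, roi.x0 + roi.side_um, roi.x0]
    cy = [roi.y0, roi.y0, roi.y0 + roi.side_um, roi.y0 + roi.side_um]
    tx, ty = transform.apply(np.array(cx), np.array(cy))
    return Polygon(zip(tx, ty))


def count_in_window(cells: pd.DataFrame, footprint: Polygon,
                    phenotype: Phenotype | str | None = None) -> int:
    """Boundary-inclusive count of cells of a phenotype inside a footprint."""
    sub = _select_phenotype(cells, phenotype)
    if len(sub) == 0:
        return 0
    pts = shapely.points(sub["x_um"].to_numpy(float), sub["y_um"].to_numpy(float))
    return int(shapely.covers(footprint, pts).sum())


def roi_metrics(rois: list[HotspotROI], cells_treg_panel: pd.DataFrame,
                cells_cd8_panel: pd.DataFrame,
                transform: RigidTransform | None = None) -> pd.DataFrame:
    """Per-ROI densities on both panels plus the granzyme-B percentage.

    The CCR8+ Treg count comes from the selecting panel inside the original
    window; CD8-panel counts come from the transferred footprint on the
    paired section. An ROI whose transferred footprint contains no CD8-panel
    cells yields NaN for ``pct_gzmb_in_cd8``.
    """
    identity = transform is None or (transform.theta == 0.0
                                     and transform.dx == 0.0
                                     and transform.dy == 0.0)
    cx = cells_cd8_panel["x_um"].to_numpy(float)
    cy = cells_cd8_panel["y_um"].to_numpy(float)
    pheno = cells_cd8_panel["phenotype"].to_numpy() if len(cells_cd8_panel) else np.array([])
    rows = []
    for roi in rois:
        if identity:
            # axis-aligned closed window: equivalent to shapely covers()
            inside = ((cx >= roi.x0) & (cx <= roi.x0 + roi.side_um)
                      & (cy >= roi.y0) & (cy <= roi.y0 + roi.side_um))
            n_cd8_gzmb = int((inside & (pheno == Phenotype.CD8T_GZMBPOS.value)).sum())
            n_cd8 = n_cd8_gzmb + int(
                (inside & (pheno == Phenotype.CD8T_GZMBNEG.value)).sum())
        else:
            foot = transfer_roi(roi, transform)
            n_cd8_gzmb = count_in_window(cells_cd8_panel, foot,
                                         Phenotype.CD8T_GZMBPOS)
            n_cd8 = n_cd8_gzmb + count_in_window(cells_cd8_panel, foot,
                                                 Phenotype.CD8T_GZMBNEG)
        area = roi.area_mm2
        rows.append({
            "case_id": roi.case_id, "rank": roi.rank,
            "x0": roi.x0, "y0": roi.y0, "side_um": roi.side_um,
            "ccr8_treg_count": roi.count,
            "ccr8_treg_density": roi.count / area,
            "cd8_count": n_cd8,
            "cd8_density": n_cd8 / area,
            "gzmb_cd8_count": n_cd8_gzmb,
            "gzmb_cd8_density": n_cd8_gzmb / area,
            "pct_gzmb_in_cd8": 100.0 * n_cd8_gzmb / n_cd8 if n_cd8 else np.nan,
        })
    return pd.DataFrame(rows)


def case_roi_summary(roi_table: pd.DataFrame) -> pd.DataFrame:
    """Per-case means over the selected ROIs (NaN-aware for percentages)."""
    return roi_table.groupby("case_id").agg(
        n_rois=("rank", "size"),
        mean_ccr8_treg_density=("ccr8_treg_density", "mean"),
        mean_cd8_density=("cd8_density", "mean"),
        mean_pct_gzmb_in_cd8=("pct_gzmb_in_cd8", "mean"),
    )


def linear_regression(x, y) -> RegressionResult:
    """OLS line fit with Pearson r and its two-sided p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise UsageError("regression requires at least 3 usable points")
    res = stats.linregress(x, y)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r=float(res.rvalue), p=float(res.pvalue), n=int(x.size))


def roi_correlation(case_summary: pd.DataFrame, top_n: int = 40,
                    rank_by: str = "hotspot",
                    wta_metrics: pd.DataFrame | None = None,
                    ) -> dict[str, RegressionResult]:
    """Correlation analysis over the cases with highest CCR8+ Treg burden.

    Cases are ranked by mean hotspot CCR8+ Treg density (``rank_by =
    "hotspot"``, the default) or by whole-tumor-area CCR8+ Treg density
    (``rank_by = "wta"``, requires `wta_metrics`); the `top_n` retained
    cases enter two regressions against mean hotspot CCR8+ Treg density:
    mean CD8 density, and mean %GzmB+ in CD8.
    """
    df = case_summary.dropna(subset=["mean_ccr8_treg_density"])
    if rank_by == "hotspot":
        ranked = df.sort_values("mean_ccr8_treg_density", ascending=False)
    elif rank_by == "wta":
        if wta_metrics is None:
            raise UsageError("rank_by='wta' requires the WTA metrics table")
        order = wta_metrics["ccr8_treg_density"].reindex(df.index)
        ranked = df.loc[order.sort_values(ascending=False).index]
    else:
        raise UsageError(f"unknown rank_by {rank_by!r}")
    if len(ranked) < top_n:
        warnings.warn(f"only {len(ranked)} usable cases; top_n={top_n} truncated")
    top = ranked.head(top_n)
    x = top["mean_ccr8_treg_density"]
    return {
        "cd8_density": linear_regression(x, top["mean_cd8_density"]),
        "pct_gzmb_in_cd8": linear_regression(x, top["mean_pct_gzmb_in_cd8"]),
    }
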