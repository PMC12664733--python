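"""Nearest-neighbor and annulus-census distance analysis.

From each index cell (CCR8+ or CCR8− Treg) the Euclidean distance to the
nearest target cell (CD8+ or GzmB+CD8+ T cell) is measured, and target
cells are counted in concentric half-open 10-µm annuli [0,10), …, [90,100)
µm. Distances are computed over all in-region cells (the whole-tumor-area
protocol) with no edge correction at the tumor boundary; each index cell's
distance to the boundary is exported so users can filter if desired.

Nearest-neighbor and radius queries use a k-d tree
(:class:`scipy.spatial.cKDTree`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import LineString

from .exceptions import UsageError
from .io_tables import Phenotype, RegionAnnotation
from .survival import TestResult, mann_whitney_test


@dataclass
class DistanceProfile:
    """Distance census from one index phenotype to one target phenotype.

    ``annulus_counts`` is the mean number of target cells per index cell in
    each 10-µm annulus; ``annulus_matrix`` keeps the per-index-cell counts.
    A nearest neighbor at exactly ``max_um`` is a valid NN distance but
    contributes to no annulus (half-open binning).
    """

    index_class: str
    target_class: str
    nn_distances: np.ndarray
    annulus_counts: np.ndarray
    annulus_matrix: np.ndarray
    bin_um: float = 10.0
    max_um: float = 100.0
    boundary_distances: np.ndarray | None = field(default=None, repr=False)

    @property
    def median_nn(self) -> float:
        return float(np.median(self.nn_distances))

    @property
    def n_index(self) -> int:
        return int(self.nn_distances.size)


@dataclass
class ProfileComparison:
    """Mann-Whitney comparison of two NN-distance samples."""

    median_a: float
    median_b: float
    statistic: float
    p: float


def _as_xy(cells) -> np.ndarray:
    if isinstance(cells, pd.DataFrame):
        return cells[["x_um", "y_um"]].to_numpy(float)
    return np.asarray(cells, float).reshape(-1, 2)


def nn_distances(index_cells, target_cells, target_name: str = "target") -> np.ndarray:
    """Euclidean distance from each index cell to its nearest target cell.

    Output order follows the index input order. The index and target sets
    must be phenotype-disjoint (a cell is never its own target); coincident
    positions of different phenotypes legitimately yield 0.
    """
    idx = _as_xy(index_cells)
    tgt = _as_xy(target_cells)
    if tgt.shape[0] == 0:
        raise UsageError(f"no {target_name} cells: nearest-neighbor distances "
                         "are undefined")
    if idx.shape[0] == 0:
        return np.empty(0)
    d, _ = cKDTree(tgt).query(idx, k=1)
    return np.asarray(d, float)


def annulus_census(index_cells, target_cells, bin_um: float = 10.0,
                   max_um: float = 100.0) -> tuple[np.ndarray, np.ndarray]:
    """Count target cells per half-open annulus around each index cell.

    Returns ``(mean_counts, matrix)`` where ``matrix[i, b]`` is the number
    of target cells at distance [b·bin_um, (b+1)·bin_um) from index cell i
    and ``mean_counts`` is the per-bin mean over index cells. A target at
    exactly a bin edge falls in the upper bin; one at exactly ``max_um``
    is excluded.
    """
    if max_um <= 0:
        raise UsageError("max_um must be positive")
    nbins_f = max_um / bin_um
    if abs(nbins_f - round(nbins_f)) > 1e-9:
        raise UsageError("bin_um must divide max_um")
    nbins = int(round(nbins_f))
    idx = _as_xy(index_cells)
    tgt = _as_xy(target_cells)
    matrix = np.zeros((idx.shape[0], nbins), dtype=np.int64)
    if idx.shape[0] and tgt.shape[0]:
        tree = cKDTree(tgt)
        neighbours = tree.query_ball_point(idx, r=max_um)
        for i, nb in enumerate(neighbours):
            if not nb:
                continue
            d = np.linalg.norm(tgt[nb] - idx[i], axis=1)
            d = d[d < max_um]  # half-open outer boundary
            b = np.floor(d / bin_um).astype(int)
            np.add.at(matrix[i], b, 1)
    mean_counts = (matrix.mean(axis=0) if matrix.shape[0]
                   else np.zeros(nbins))
    return mean_counts, matrix


def compute_distance_profile(cells_index, cells_target,
                             index_class: str = "", target_class: str = "",
                             bin_um: float = 10.0, max_um: float = 100.0,
                             region: RegionAnnotation | None = None,
                             ) -> DistanceProfile:
    """Assemble the full NN + annulus profile for one index/target pair.

    When a region is given, its boundary distance per index cell is
    attached (for optional boundary-proximity filtering downstream).
    """
    nn = nn_distances(cells_index, cells_target, target_name=target_class or "target")
    mean_counts, matrix = annulus_census(cells_index, cells_target, bin_um, max_um)
    boundary = None
    if region is not None:
        idx = _as_xy(cells_index)
        pts = shapely.points(idx[:, 0], idx[:, 1])
        boundary = shapely.distance(pts, region._union.boundary)
    return DistanceProfile(index_class=index_class, target_class=target_class,
                           nn_distances=nn, annulus_counts=mean_counts,
                           annulus_matrix=matrix, bin_um=bin_um, max_um=max_um,
                           boundary_distances=boundary)


def distance_to_front(cells: pd.DataFrame, front: LineString | None,
                      ) -> pd.DataFrame | None:
    """Shortest distance from each classified cell to the invasion front.

    Returns the input with a ``front_dist_um`` column, or None (with a
    notice) when no front is annotated.

    Raises
    ------
    UsageError
        Degenerate (zero-length) front polyline.
    """
    if front is None:
        import warnings
        warnings.warn("no invasion-front annotation; distance-to-front skipped")
        return None
    if front.length == 0:
        raise UsageError("invasion front polyline is degenerate")
    out = cells.copy()
    pts = shapely.points(out["x_um"].to_numpy(float), out["y_um"].to_numpy(float))
    out["front_dist_um"] = shapely.distance(pts, front)
    return out


def front_distance_summary(cells_with_dist: pd.DataFrame) -> pd.DataFrame:
    """Median and IQR of front distance per phenotype class."""
    def _summ(s):
        q1, med, q3 = np.percentile(s, [25, 50, 75])
        return pd.Series({"n": len(s), "median_um": med, "q1_um": q1, "q3_um": q3})
    return (cells_with_dist.groupby("phenotype")["front_dist_um"]
            .apply(_summ).unstack())


def compare_profiles(a: DistanceProfile, b: DistanceProfile) -> ProfileComparison:
    """Two-sided Mann-Whitney comparison of two NN-distance samples.

    Exact for combined n ≤ 20 without ties, otherwise the tie-corrected
    normal approximation.
    """
    if a.nn_distances.size == 0 or b.nn_distances.size == 0:
        raise UsageError("both profiles must have non-empty NN distance lists")
    res: TestResult = mann_whitney_test(a.nn_distances, b.nn_distances)
    return ProfileComparison(median_a=a.median_nn, median_b=b.median_nn,
                             statistic=res.statistic, p=res.p)


def treg_cd8_profiles(cells_treg_panel: pd.DataFrame,
                      cells_cd8_panel: pd.DataFrame,
                      target: str | Phenotype = "CD8T_ANY",
                      bin_um: float = 10.0, max_um: float = 100.0,
                      region: RegionAnnotation | None = None,
                      ) -> dict[str, DistanceProfile]:
    """Profiles from CCR8+ and CCR8− Tregs to CD8 targets for one case.

    ``target`` may be ``"CD8T_ANY"`` (all CD8+ cells) or a specific
    phenotype such as ``CD8T_GZMBPOS``. Cells are restricted to the tumor
    region when one is given.
    """
    tf, cg = cells_treg_panel, cells_cd8_panel
    if region is not None:
        tf = tf[region.contains(tf["x_um"].to_numpy(), tf["y_um"].to_numpy())]
        cg = cg[region.contains(cg["x_um"].to_numpy(), cg["y_um"].to_numpy())]
    tname = target.value if isinstance(target, Phenotype) else str(target)
    if tname == "CD8T_ANY":
        tgt = cg[cg["phenotype"].isin([Phenotype.CD8T_GZMBPOS.value,
                                       Phenotype.CD8T_GZMBNEG.value])]
    else:
        tgt = cg[cg["phenotype"] == tname]
    out = {}
    for cls in (Phenotype.TREG_CCR8POS, Phenotype.TREG_CCR8NEG):
        idx = tf[tf["phenotype"] == cls.value]
        if len(idx) == 0:
            continue
        out[cls.value] = compute_distance_profile(
            idx, tgt, index_class=cls.value, target_class=tname,
            bin_um=bin_um, max_um=max_um, region=region)
    return out
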