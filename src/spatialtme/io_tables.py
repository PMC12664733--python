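"""Reading, writing and phenotyping of cell-object, region and clinical tables.

Cell-object tables emulate the per-cell export of a digital-pathology image
analysis platform: one CSV row per detected cell with case id, stain panel,
x/y position in micrometres, and binary marker calls. Two dual-stain panels
are supported: CCR8/FOXP3 (regulatory T cells) and CD8/GZMB (cytotoxic
T cells), acquired on consecutive tissue sections.

Tumor-region annotations are GeoJSON feature collections in slide (µm)
coordinates: one or more Polygon features with ``role = "tumor"`` and an
optional LineString with ``role = "invasion_front"``.

The canonical in-memory container for cells is a :class:`pandas.DataFrame`
with columns ``case_id, panel, x_um, y_um`` plus the panel's two marker
columns as booleans; :func:`classify_phenotypes` appends a ``phenotype``
column.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Polygon, shape as geo_shape, mapping as geo_mapping

from .exceptions import FormatError, GeometryError, UsageError, ValidationError


class Panel(str, enum.Enum):
    """Dual-stain panel identity."""

    CCR8_FOXP3 = "CCR8_FOXP3"
    CD8_GZMB = "CD8_GZMB"


#: Marker columns required by each panel, in canonical column order.
PANEL_MARKERS: dict[Panel, tuple[str, str]] = {
    Panel.CCR8_FOXP3: ("CCR8", "FOXP3"),
    Panel.CD8_GZMB: ("CD8", "GZMB"),
}


class Phenotype(str, enum.Enum):
    """Mutually exclusive phenotype classes derived from marker calls.

    Treg classes require FOXP3 positivity; CCR8 on a FOXP3-negative cell
    does not define a phenotype of interest and is classed OTHER. CD8 T cell
    classes require CD8 positivity, subdivided by granzyme B.
    """

    TREG_CCR8POS = "TREG_CCR8POS"
    TREG_CCR8NEG = "TREG_CCR8NEG"
    CD8T_GZMBPOS = "CD8T_GZMBPOS"
    CD8T_GZMBNEG = "CD8T_GZMBNEG"
    OTHER = "OTHER"


CELL_BASE_COLUMNS = ("case_id", "panel", "x_um", "y_um")


def _coerce_panel(panel: Panel | str) -> Panel:
    try:
        return Panel(panel)
    except ValueError:
        raise UsageError(f"unknown panel {panel!r}; expected one of "
                         f"{[p.value for p in Panel]}") from None


def read_cell_table(path, panel: Panel | str) -> pd.DataFrame:
    """Read a cell-object CSV for one stain panel.

    Parameters
    ----------
    path : str or path-like
        CSV with header ``case_id, x_um, y_um`` plus the panel's two marker
        columns holding 0/1 calls. A ``panel`` column is optional; if present
        it must agree with `panel`.
    panel : Panel or str
        Which dual-stain panel the file belongs to.

    Returns
    -------
    pandas.DataFrame
        One row per cell in file order; marker columns converted to bool.

    Raises
    ------
    FormatError
        If a required column is missing (the message names it).
    ValidationError
        If a marker value is not 0/1 or a coordinate is not finite
        (the message gives the 1-based data row number).
    """
    panel = _coerce_panel(panel)
    df = pd.read_csv(path)
    markers = PANEL_MARKERS[panel]
    for col in ("case_id", "x_um", "y_um", *markers):
        if col not in df.columns:
            raise FormatError(f"cell table {path} is missing required column {col!r}")
    if "panel" in df.columns:
        bad = df.index[df["panel"].astype(str) != panel.value]
        if len(bad):
            raise ValidationError(
                f"row {bad[0] + 1}: panel {df.loc[bad[0], 'panel']!r} does not "
                f"match declared panel {panel.value!r}")
    else:
        df["panel"] = panel.value

    xy = df[["x_um", "y_um"]].to_numpy(dtype=float)
    finite = np.isfinite(xy).all(axis=1)
    if not finite.all():
        row = int(np.flatnonzero(~finite)[0])
        raise ValidationError(f"row {row + 1}: non-finite coordinate")
    for col in markers:
        vals = df[col].to_numpy()
        ok = np.isin(vals, (0, 1, False, True))
        if not ok.all():
            row = int(np.flatnonzero(~ok)[0])
            raise ValidationError(
                f"row {row + 1}: marker {col!r} value {vals[row]!r} is not 0/1")
        df[col] = df[col].astype(bool)
    return df[[*CELL_BASE_COLUMNS, *markers]]


def write_cell_table(df: pd.DataFrame, path) -> None:
    """Write a cell table in the canonical CSV dialect (0/1 markers)."""
    out = df.copy()
    for col in out.columns:
        if out[col].dtype == bool:
            out[col] = out[col].astype(int)
    out.to_csv(path, index=False)


def classify_phenotypes(cells: pd.DataFrame) -> pd.DataFrame:
    """Append a ``phenotype`` column derived from the marker calls.

    All rows must belong to a single panel. The classes partition the
    input: every cell receives exactly one phenotype.

    Raises
    ------
    UsageError
        If the table mixes panels.
    """
    panels = cells["panel"].unique()
    if len(panels) > 1:
        raise UsageError(f"mixed panels in one table: {sorted(panels)}")
    out = cells.copy()
    if len(cells) == 0:
        out["phenotype"] = pd.Series([], dtype=str)
        return out
    panel = _coerce_panel(panels[0])
    if panel is Panel.CCR8_FOXP3:
        pos, neg = Phenotype.TREG_CCR8POS, Phenotype.TREG_CCR8NEG
        lineage, sub = out["FOXP3"].to_numpy(bool), out["CCR8"].to_numpy(bool)
    else:
        pos, neg = Phenotype.CD8T_GZMBPOS, Phenotype.CD8T_GZMBNEG
        lineage, sub = out["CD8"].to_numpy(bool), out["GZMB"].to_numpy(bool)
    pheno = np.where(lineage, np.where(sub, pos.value, neg.value), Phenotype.OTHER.value)
    out["phenotype"] = pheno
    return out


@dataclass
class RegionAnnotation:
    """Pathologist-delineated tumor region for one case.

    Attributes
    ----------
    case_id : str or None
    tumor_polygons : list of shapely.Polygon
        Simple polygons in µm coordinates.
    invasion_front : shapely.LineString or None
        The advancing tumor boundary, when annotated.
    """

    tumor_polygons: list[Polygon]
    invasion_front: LineString | None = None
    case_id: str | None = None
    _union: shapely.Geometry = field(init=False, repr=False, default=None)

    def __post_init__(self):
        if not self.tumor_polygons:
            raise FormatError("region annotation has no tumor polygon")
        for poly in self.tumor_polygons:
            if not poly.is_valid:
                raise GeometryError("self-intersecting or invalid tumor polygon")
        self._union = shapely.union_all(self.tumor_polygons)
        if self.area_mm2 <= 0:
            raise GeometryError("tumor region has non-positive area")

    @property
    def area_mm2(self) -> float:
        """Tumor area in mm² (polygon area in µm² / 10⁶)."""
        return sum(p.area for p in self.tumor_polygons) / 1e6

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the tumor region, µm."""
        return self._union.bounds

    def contains(self, x_um, y_um) -> np.ndarray:
        """Boundary-inclusive point-in-region test (vectorized).

        Cells exactly on the tumor-polygon boundary count as inside.
        """
        pts = shapely.points(np.asarray(x_um, float), np.asarray(y_um, float))
        return shapely.covers(self._union, pts)


def read_region_annotation(path) -> RegionAnnotation:
    """Read a GeoJSON tumor annotation (µm coordinates).

    Expects ≥1 Polygon feature with property ``role = "tumor"`` and an
    optional LineString with ``role = "invasion_front"``.
    """
    with open(path) as fh:
        doc = json.load(fh)
    polys: list[Polygon] = []
    front = None
    case_id = None
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        role = props.get("role")
        geom = geo_shape(feat["geometry"])
        case_id = props.get("case_id", case_id)
        if role == "tumor":
            if geom.geom_type == "MultiPolygon":
                polys.extend(geom.geoms)
            elif geom.geom_type == "Polygon":
                polys.append(geom)
            else:
                raise FormatError(f"tumor feature has geometry {geom.geom_type}, "
                                  "expected Polygon")
            if not polys[-1].is_valid:
                raise GeometryError(f"self-intersecting tumor polygon in {path}")
        elif role == "invasion_front":
            if geom.geom_type != "LineString":
                raise FormatError("invasion_front feature must be a LineString")
            front = geom
    if not polys:
        raise FormatError(f"no feature with role='tumor' in {path}")
    return RegionAnnotation(tumor_polygons=polys, invasion_front=front, case_id=case_id)


def write_region_annotation(region: RegionAnnotation, path) -> None:
    """Write a :class:`RegionAnnotation` as GeoJSON (µm coordinates)."""
    feats = []
    for poly in region.tumor_polygons:
        feats.append({"type": "Feature",
                      "properties": {"role": "tumor", "case_id": region.case_id},
                      "geometry": geo_mapping(poly)})
    if region.invasion_front is not None:
        feats.append({"type": "Feature",
                      "properties": {"role": "invasion_front", "case_id": region.case_id},
                      "geometry": geo_mapping(region.invasion_front)})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_clinical_table(path) -> pd.DataFrame:
    """Read a per-case clinical CSV (case_id, rfs_months, event, covariates).

    ``rfs_months`` must be ≥ 0 and ``event`` must be 0/1.
    """
    df = pd.read_csv(path)
    for col in ("case_id", "rfs_months", "event"):
        if col not in df.columns:
            raise FormatError(f"clinical table {path} is missing column {col!r}")
    if (df["rfs_months"].to_numpy(float) < 0).any():
        row = int(np.flatnonzero(df["rfs_months"].to_numpy(float) < 0)[0])
        raise ValidationError(f"row {row + 1}: negative rfs_months")
    ev = df["event"].to_numpy()
    if not np.isin(ev, (0, 1, False, True)).all():
        row = int(np.flatnonzero(~np.isin(ev, (0, 1, False, True)))[0])
        raise ValidationError(f"row {row + 1}: event value {ev[row]!r} is not 0/1")
    df["event"] = df["event"].astype(bool)
    return df
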