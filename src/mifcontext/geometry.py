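"""Invasive-margin / tumor-center compartments, analysis fields, densities.

The invasive margin (IM) is the band of fixed total width (default 1 mm)
spanning the tumor–stroma interface: the interface polyline dilated by
width/2 on each side with flat (non-extending) end caps.  The tumor center
(TC) is the tumor polygon minus that band.  Cell densities are measured
inside up to five 1 mm² analysis fields per compartment, mirroring
field-based digital pathology workflows: counts are pooled over the union
of field∩region intersections and divided by its area.

All coordinates are micrometres; areas are reported in mm²; densities in
cells/mm².  The y axis follows the image convention (increases downward).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Polygon, box
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

UM2_PER_MM2 = 1e6

__all__ = [
    "CompartmentGeometry", "FieldROI", "build_im_band", "derive_regions",
    "assign_regions", "select_fields", "compute_densities", "pool_regions",
]


@dataclass
class CompartmentGeometry:
    """Tumor polygon, interface polyline and the derived IM/TC compartments."""

    tumor_polygon: BaseGeometry
    interface: LineString
    im_band: BaseGeometry
    tc_polygon: BaseGeometry
    im_width_um: float = 1000.0
    tissue_polygon: BaseGeometry | None = None

    def region_polygon(self, region: str) -> BaseGeometry:
        if region == "IM":
            return self.im_band
        if region == "TC":
            return self.tc_polygon
        raise ValueError(f"unknown region {region!r} (expected 'IM' or 'TC')")


@dataclass
class FieldROI:
    """A square analysis window clipped to its compartment."""

    region: str
    origin: tuple[float, float]          # lower-x, lower-y corner, μm
    side_um: float
    analysis_polygon: BaseGeometry       # field ∩ region
    sample_id: str = ""

    @property
    def polygon(self) -> Polygon:
        x, y = self.origin
        return box(x, y, x + self.side_um, y + self.side_um)

    @property
    def analyzed_area_mm2(self) -> float:
        return self.analysis_polygon.area / UM2_PER_MM2


def build_im_band(interface: LineString, width_um: float) -> BaseGeometry:
    """Dilate the interface polyline into the invasive-margin band.

    The band has total perpendicular width ``width_um`` (width/2 on each
    side) and flat end caps, so a straight interface of length L yields an
    L × width rectangle and the margin never extends beyond the delineated
    interface ends.
    """
    if width_um <= 0:
        raise ValueError(f"IM band width must be positive, got {width_um}")
    if interface is None or interface.length <= 0 or len(interface.coords) < 2:
        raise ValueError("interface polyline must have >= 2 vertices and positive length")
    return interface.buffer(width_um / 2.0, cap_style="flat")


def derive_regions(tumor_polygon: BaseGeometry, interface: LineString,
                   width_um: float = 1000.0,
                   tissue_polygon: BaseGeometry | None = None,
                   ) -> CompartmentGeometry:
    """Split tissue into the IM band and the TC remainder.

    IM = the full band around the interface (it straddles the interface, so
    part of it lies on the stromal side); TC = tumor polygon minus the band.
    An empty TC (band covers the whole tumor) is allowed with a warning.
    """
    band = build_im_band(interface, width_um)
    if tissue_polygon is not None:
        band = band.intersection(tissue_polygon)
    tc = tumor_polygon.difference(band)
    if tc.is_empty or tc.area == 0:
        warnings.warn("IM band covers the entire tumor polygon; TC is empty")
    return CompartmentGeometry(
        tumor_polygon=tumor_polygon, interface=interface, im_band=band,
        tc_polygon=tc, im_width_um=float(width_um),
        tissue_polygon=tissue_polygon)


def assign_regions(cells: pd.DataFrame, geometry: CompartmentGeometry) -> pd.DataFrame:
    """Label every cell IM, TC or outside.

    The IM band takes precedence over the tumor polygon and is closed: a
    cell at exactly width/2 from the interface is IM.  Remaining cells
    inside the tumor polygon are TC; everything else is outside.
    """
    cells = cells.copy()
    pts = shapely.points(cells["x_um"].to_numpy(float),
                         cells["y_um"].to_numpy(float))
    band = geometry.im_band
    tumor = geometry.tumor_polygon
    shapely.prepare(band)
    shapely.prepare(tumor)
    in_im = shapely.covers(band, pts)
    in_tumor = shapely.covers(tumor, pts)
    region = np.where(in_im, "IM", np.where(in_tumor, "TC", "outside"))
    cells["region"] = region
    return cells


def select_fields(geometry: CompartmentGeometry, region: str,
                  n_max: int = 5, side_um: float = 1000.0,
                  seed: int = 0, sample_id: str = "") -> list[FieldROI]:
    """Place up to ``n_max`` non-overlapping square analysis fields in a
    compartment.

    Candidate fields on a regular grid (stride = side, hence automatically
    non-overlapping) are ranked by their overlap area with the compartment
    and picked greedily; ties are broken by a seeded shuffle, making manual
    "representative field" selection reproducible.  Only candidates whose
    center lies in the compartment qualify.  If no grid candidate qualifies
    (compartment smaller than one field) a single field centered on the
    compartment is returned, clipped, with a warning.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if side_um <= 0:
        raise ValueError("field side must be positive")
    poly = geometry.region_polygon(region)
    if poly.is_empty:
        raise ValueError(f"region {region} polygon is empty")
    shapely.prepare(poly)

    minx, miny, maxx, maxy = poly.bounds
    xs = np.arange(minx, maxx, side_um)
    ys = np.arange(miny, maxy, side_um)
    cand = []
    for x in xs:
        for y in ys:
            cx, cy = x + side_um / 2, y + side_um / 2
            if not shapely.covers(poly, shapely.points(cx, cy)):
                continue
            clip = box(x, y, x + side_um, y + side_um).intersection(poly)
            if clip.is_empty or clip.area == 0:
                continue
            cand.append(((x, y), clip))
    if not cand:
        warnings.warn(f"region {region} smaller than one {side_um} μm field; "
                      "returning a single clipped field")
        c = poly.centroid
        x, y = c.x - side_um / 2, c.y - side_um / 2
        clip = box(x, y, x + side_um, y + side_um).intersection(poly)
        return [FieldROI(region, (x, y), side_um, clip, sample_id)]

    rng = np.random.default_rng(seed)
    tie = rng.permutation(len(cand))
    order = sorted(range(len(cand)), key=lambda i: (-cand[i][1].area, tie[i]))
    out = []
    for i in order[:n_max]:
        (x, y), clip = cand[i]
        out.append(FieldROI(region, (x, y), side_um, clip, sample_id))
    return out


def _analysis_union(fields: list[FieldROI]) -> BaseGeometry:
    return unary_union([f.analysis_polygon for f in fields])


def _cells_in(cells: pd.DataFrame, geom: BaseGeometry) -> np.ndarray:
    if len(cells) == 0:
        return np.zeros(0, dtype=bool)
    pts = shapely.points(cells["x_um"].to_numpy(float),
                         cells["y_um"].to_numpy(float))
    shapely.prepare(geom)
    return shapely.covers(geom, pts)


def compute_densities(cells: pd.DataFrame, fields: list[FieldROI],
                      phenotypes: list[str | tuple[str, str]],
                      ) -> pd.DataFrame:
    """Per-(sample, region, phenotype) cell densities over the analyzed area.

    ``phenotypes`` entries are labels or (label, panel) pairs; with a panel,
    only cells of that staining panel are counted (CD3 on P1 and P3 are
    different sections).  Counts are pooled over the union of the region's
    field∩region polygons; density = n / pooled area (mm²).  Regions with
    zero analyzed area are suppressed with a warning.
    """
    from .io import has_phenotype  # local import: io imports geometry types

    recs = []
    for sample_id, sub in cells.groupby("sample_id", sort=True):
        for region in ("TC", "IM"):
            ffs = [f for f in fields
                   if f.region == region and f.sample_id in ("", sample_id)]
            if not ffs:
                continue
            union = _analysis_union(ffs)
            area = union.area / UM2_PER_MM2
            if area == 0:
                warnings.warn(f"{sample_id}/{region}: zero analyzed area; "
                              "density record suppressed")
                continue
            inside = _cells_in(sub, union)
            for entry in phenotypes:
                phen, panel = entry if isinstance(entry, tuple) else (entry, None)
                mask = has_phenotype(sub, phen).to_numpy() & inside
                if panel is not None:
                    mask &= (sub["panel"] == panel).to_numpy()
                n = int(mask.sum())
                recs.append({"sample_id": sample_id, "region": region,
                             "phenotype": phen, "panel": panel or "",
                             "n_cells": n, "area_mm2": area,
                             "density": n / area})
    return pd.DataFrame(recs, columns=["sample_id", "region", "phenotype",
                                       "panel", "n_cells", "area_mm2",
                                       "density"])


def pool_regions(densities: pd.DataFrame) -> pd.DataFrame:
    """Whole-tissue densities: pool counts and areas across IM and TC."""
    grouped = densities.groupby(["sample_id", "phenotype", "panel"],
                                as_index=False).agg(
        n_cells=("n_cells", "sum"))
    # areas are repeated per phenotype within a (sample, region); sum unique
    areas = (densities.drop_duplicates(["sample_id", "region"])
             .groupby("sample_id")["area_mm2"].sum().rename("area_mm2"))
    out = grouped.merge(areas, on="sample_id")
    out["density"] = out["n_cells"] / out["area_mm2"]
    out["region"] = "whole"
    return out[["sample_id", "region", "phenotype", "panel", "n_cells",
                "area_mm2", "density"]]
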