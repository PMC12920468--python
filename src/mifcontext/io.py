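"""Cell-table and region-geometry I/O plus marker-flag phenotype gating.

Cell tables are tidy CSV files, one row per segmented cell:

    sample_id, panel, x_um, y_um, <one 0/1 column per marker>[, phenotypes, region]

Coordinates are centroids in micrometres with the image convention that the
y axis increases downward.  ``phenotypes`` is a semicolon-joined, sorted set
of derived labels; ``region`` is one of TC/IM/outside/unassigned.  A
documented alias map accepts QuPath-style headers ("Centroid X µm", "PDL1").

Region geometry travels as a GeoJSON FeatureCollection (coordinates in μm)
whose features are tagged ``role`` ∈ {tissue, tumor, interface, im_band, tc}.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .markers import MARKERS, PANEL_MARKERS, PANELS

log = logging.getLogger(__name__)

REGION_LABELS = ("TC", "IM", "outside", "unassigned")

#: Header alias map (case-insensitive keys): QuPath-style and loose spellings
#: → canonical column names.
HEADER_ALIASES: dict[str, str] = {
    "centroid x µm": "x_um",
    "centroid x um": "x_um",
    "centroid y µm": "y_um",
    "centroid y um": "y_um",
    "image": "sample_id",
    "sample": "sample_id",
    "pdl1": "PD-L1",
    "pd_l1": "PD-L1",
    "pd-l1": "PD-L1",
    "pd1": "PD-1",
    "pd_1": "PD-1",
    "pd-1": "PD-1",
    "foxp3": "Foxp3",
    "granzyme b": "GrzB",
    "grzb": "GrzB",
    "ki67": "Ki67",
    "ck": "CK",
    "panel": "panel",
}
# every canonical marker maps to itself, case-insensitively
HEADER_ALIASES.update({m.lower(): m for m in MARKERS})

_REQUIRED = ("sample_id", "panel", "x_um", "y_um")
_META_COLS = _REQUIRED + ("phenotypes", "region")


@dataclass(frozen=True)
class GatingRule:
    """One phenotype-call rule: all ``required_positive`` markers on, all
    ``required_negative`` off, applied to cells of ``panel`` only."""

    phenotype: str
    required_positive: frozenset[str]
    panel: str
    required_negative: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.required_positive & self.required_negative:
            raise ValueError(
                f"rule {self.phenotype!r}: positive and negative marker sets overlap"
            )
        if self.panel not in PANELS:
            raise ValueError(f"rule {self.phenotype!r}: unknown panel {self.panel!r}")


def _rules(*specs) -> tuple[GatingRule, ...]:
    return tuple(GatingRule(ph, frozenset(pos), panel, frozenset(neg))
                 for ph, pos, panel, neg in specs)


#: Default gating set: the association-table row phenotypes plus CK.
#: CD3 is measurable on panels 1 and 3, CD8 on panels 2 and 3, CK on all.
#: NK cells are gated CD56+ without requiring CD3- (see STRICT_NK_RULE).
DEFAULT_GATING_RULES: tuple[GatingRule, ...] = _rules(
    ("CD20+", {"CD20"}, "P1", ()),
    ("CD11c+", {"CD11c"}, "P1", ()),
    ("CD15+", {"CD15"}, "P1", ()),
    ("CD163+", {"CD163"}, "P1", ()),
    ("CD3+", {"CD3"}, "P1", ()),
    ("CD3+", {"CD3"}, "P3", ()),
    ("CD8+", {"CD8"}, "P2", ()),
    ("CD8+", {"CD8"}, "P3", ()),
    ("CD4+", {"CD4"}, "P3", ()),
    ("PD-1+", {"PD-1"}, "P2", ()),
    ("PD-L1+", {"PD-L1"}, "P2", ()),
    ("GrzB+", {"GrzB"}, "P2", ()),
    ("Ki67+", {"Ki67"}, "P2", ()),
    ("CD56+", {"CD56"}, "P3", ()),
    ("CD8+PD-1+", {"CD8", "PD-1"}, "P2", ()),
    ("CD4+Foxp3+", {"CD4", "Foxp3"}, "P3", ()),
    ("CK+", {"CK"}, "P1", ()),
    ("CK+", {"CK"}, "P2", ()),
    ("CK+", {"CK"}, "P3", ()),
)

#: Stricter NK gate (CD56+CD3-) available as an alternative.
STRICT_NK_RULE = GatingRule("CD56+CD3-", frozenset({"CD56"}), "P3",
                            frozenset({"CD3"}))


def new_cell_table(rows: list[dict] | None = None) -> pd.DataFrame:
    """Empty (or seeded) cell table with the canonical column order."""
    cols = list(_REQUIRED) + list(MARKERS) + ["phenotypes", "region"]
    df = pd.DataFrame(rows or [], columns=cols)
    if len(df):
        df[list(MARKERS)] = df[list(MARKERS)].fillna(0).astype(np.int8)
        df["phenotypes"] = df["phenotypes"].fillna("")
        df["region"] = df["region"].fillna("unassigned")
    else:
        df = df.astype({m: np.int8 for m in MARKERS} |
                       {"x_um": float, "y_um": float})
    return df


def read_cell_table(path, aliases: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a per-cell CSV, applying the header alias map.

    Missing coordinate/sample columns are a hard error.  Unknown columns are
    ignored with a warning; rows with non-finite coordinates are dropped with
    row-level diagnostics.  Markers absent from the file are added as 0.
    """
    alias = {k.lower(): v for k, v in HEADER_ALIASES.items()}
    if aliases:
        alias.update({k.lower(): v for k, v in aliases.items()})
    df = pd.read_csv(path)
    rename = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in alias:
            rename[col] = alias[key]
        elif key in (c.lower() for c in _META_COLS):
            rename[col] = next(c for c in _META_COLS if c.lower() == key)
    df = df.rename(columns=rename)

    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")

    known = set(_META_COLS) | set(MARKERS)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        warnings.warn(f"{path}: ignoring unknown column(s) {unknown}")
        df = df.drop(columns=unknown)

    bad = ~np.isfinite(df["x_um"].to_numpy(float)) | ~np.isfinite(df["y_um"].to_numpy(float))
    if bad.any():
        warnings.warn(
            f"{path}: dropping {int(bad.sum())} row(s) with non-finite coordinates "
            f"(rows {list(df.index[bad][:10])}{'...' if bad.sum() > 10 else ''})"
        )
        df = df[~bad]

    for m in MARKERS:
        if m not in df.columns:
            df[m] = 0
        df[m] = (df[m].fillna(0).astype(float) > 0).astype(np.int8)
    if "phenotypes" not in df.columns:
        df["phenotypes"] = ""
    df["phenotypes"] = df["phenotypes"].fillna("")
    if "region" not in df.columns:
        df["region"] = "unassigned"
    df["panel"] = df["panel"].astype(str)
    bad_panel = ~df["panel"].isin(PANELS)
    if bad_panel.any():
        raise ValueError(f"{path}: unknown panel value(s) "
                         f"{sorted(df.loc[bad_panel, 'panel'].unique())}")
    cols = list(_REQUIRED) + list(MARKERS) + ["phenotypes", "region"]
    return df[cols].reset_index(drop=True)


def write_cell_table(cells: pd.DataFrame, path) -> None:
    """Write a cell table in the canonical CSV dialect (round-trips with
    :func:`read_cell_table`)."""
    cols = list(_REQUIRED) + list(MARKERS) + ["phenotypes", "region"]
    out = cells.copy()
    for c in cols:
        if c not in out.columns:
            out[c] = "" if c == "phenotypes" else ("unassigned" if c == "region" else 0)
    out[list(MARKERS)] = out[list(MARKERS)].astype(int)
    out[cols].to_csv(path, index=False)


def _join(labels: set[str]) -> str:
    return ";".join(sorted(labels))


def gate_phenotypes(cells: pd.DataFrame,
                    rules: tuple[GatingRule, ...] = DEFAULT_GATING_RULES,
                    ) -> pd.DataFrame:
    """Derive phenotype labels from marker flags.

    Each cell receives every phenotype whose rule it satisfies on its own
    panel (multi-label: a CD3+CD8+ cell is both "CD3+" and "CD8+").  Labels
    are stored sorted, so the result is independent of rule order, and
    re-gating is idempotent (labels are recomputed from markers, not
    appended).  Rules referencing markers not stained on their panel are
    skipped with a warning.
    """
    cells = cells.copy()
    panel = cells["panel"].to_numpy()
    by_phenotype: dict[str, np.ndarray] = {}
    for rule in rules:
        need = rule.required_positive | rule.required_negative
        if not need <= PANEL_MARKERS[rule.panel]:
            log.warning("gating rule %r references marker(s) %s absent from panel %s; skipped",
                        rule.phenotype, sorted(need - PANEL_MARKERS[rule.panel]), rule.panel)
            continue
        mask = panel == rule.panel
        for m in rule.required_positive:
            mask = mask & (cells[m].to_numpy() > 0)
        for m in rule.required_negative:
            mask = mask & (cells[m].to_numpy() == 0)
        if rule.phenotype in by_phenotype:
            by_phenotype[rule.phenotype] |= mask
        else:
            by_phenotype[rule.phenotype] = mask
    # sorted labels joined per cell → order-independent, idempotent
    out = np.full(len(cells), "", dtype=object)
    for label in sorted(by_phenotype):
        mask = by_phenotype[label]
        out[mask] = np.char.add(out[mask].astype(str),  # type: ignore[arg-type]
                                label + ";")
    cells["phenotypes"] = [s[:-1] if s else "" for s in out]
    return cells


def split_pdl1_by_compartment(cells: pd.DataFrame) -> pd.DataFrame:
    """Split PD-L1+ cells into epithelial ("PD-L1+CK+") vs stromal/immune
    ("PD-L1+CK-") subsets using the CK co-stain on panel 2.

    PD-L1 is predominantly expressed on CK- stromal and immune cells in
    colorectal tumors; this split makes that dichotomy quantifiable.
    """
    cells = cells.copy()
    pdl1 = ((cells["panel"] == "P2") & (cells["PD-L1"] > 0)).to_numpy()
    ck = (cells["CK"] > 0).to_numpy()
    phen = cells["phenotypes"].to_numpy(object)
    for i in np.flatnonzero(pdl1):
        s = set(str(phen[i]).split(";")) - {""}
        s.add("PD-L1+CK+" if ck[i] else "PD-L1+CK-")
        phen[i] = _join(s)
    cells["phenotypes"] = phen
    return cells


def has_phenotype(cells: pd.DataFrame, phenotype: str) -> pd.Series:
    """Boolean mask of cells carrying ``phenotype`` (exact label match)."""
    pat = r"(?:^|;)" + re.escape(phenotype) + r"(?:;|$)"
    return cells["phenotypes"].str.contains(pat, regex=True, na=False)


# ---------------------------------------------------------------------------
# geometry GeoJSON


def write_geometry(geom, path) -> None:
    """Write a CompartmentGeometry as a GeoJSON FeatureCollection (μm)."""
    feats = []
    for role, g in (("tissue", geom.tissue_polygon),
                    ("tumor", geom.tumor_polygon),
                    ("interface", geom.interface),
                    ("im_band", geom.im_band),
                    ("tc", geom.tc_polygon)):
        if g is None or g.is_empty:
            continue
        props = {"role": role}
        if role == "im_band":
            props["im_width_um"] = geom.im_width_um
        feats.append({"type": "Feature", "properties": props,
                      "geometry": mapping(g)})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_geometry(path):
    """Read a CompartmentGeometry written by :func:`write_geometry`."""
    from .geometry import CompartmentGeometry  # local import: avoid cycle

    with open(path) as fh:
        fc = json.load(fh)
    by_role = {}
    width = 1000.0
    for feat in fc.get("features", []):
        role = feat.get("properties", {}).get("role")
        if role:
            by_role[role] = shape(feat["geometry"])
            if role == "im_band":
                width = float(feat["properties"].get("im_width_um", width))
    for need in ("tumor", "interface", "im_band", "tc"):
        if need not in by_role:
            raise ValueError(f"{path}: GeoJSON missing feature with role {need!r}")
    return CompartmentGeometry(
        tumor_polygon=by_role["tumor"], interface=by_role["interface"],
        im_band=by_role["im_band"], tc_polygon=by_role["tc"],
        im_width_um=width, tissue_polygon=by_role.get("tissue"))
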