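"""Phenotype-pair proximity: cells of type A with a type-B neighbor within
a fixed radius (default 20 μm).

The scored statistic is the *engaged density*: the number of A cells having
at least one B cell within the radius, per mm² of analyzed area.  The raw
A–B pair count (and its density) is also reported.  Distances are Euclidean
in μm and the ball is closed: a pair at exactly the radius counts.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import FieldROI, UM2_PER_MM2, _analysis_union, _cells_in
from .io import has_phenotype

DEFAULT_RADIUS_UM = 20.0


@dataclass
class ProximityRecord:
    sample_id: str
    region: str
    phenotype_a: str
    phenotype_b: str
    radius_um: float
    n_a: int
    n_b: int
    n_a_engaged: int
    n_pairs: int
    area_mm2: float
    engaged_density: float
    pair_density: float


def radius_pairs(a_points: np.ndarray, b_points: np.ndarray,
                 radius_um: float = DEFAULT_RADIUS_UM,
                 same_set: bool = False) -> np.ndarray:
    """All (i, j) index pairs with ||a_i - b_j|| <= radius (closed ball).

    With ``same_set=True`` the two inputs are treated as one point set:
    self-pairs are dropped and each unordered pair appears once (i < j).
    Returns an (n_pairs, 2) integer array.
    """
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    a = np.asarray(a_points, dtype=float).reshape(-1, 2)
    b = np.asarray(b_points, dtype=float).reshape(-1, 2)
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("coordinates must be finite")
    if len(a) == 0 or len(b) == 0:
        return np.empty((0, 2), dtype=np.intp)
    tree = cKDTree(b)
    hits = tree.query_ball_point(a, r=radius_um)  # closed: d <= r
    pairs = [(i, j) for i, js in enumerate(hits) for j in js]
    out = np.array(pairs, dtype=np.intp).reshape(-1, 2)
    if same_set and len(out):
        out = out[out[:, 0] < out[:, 1]]
    return out


def proximity_stat(cells: pd.DataFrame, region: str,
                   phenotype_a: str, phenotype_b: str,
                   fields: list[FieldROI],
                   radius_um: float = DEFAULT_RADIUS_UM,
                   panel: str | None = None,
                   sample_id: str | None = None) -> ProximityRecord:
    """Proximity summary for one sample and compartment.

    A cells are taken inside the analyzed area (union of field∩region); B
    cells inside that area dilated by the radius, so a neighbor sitting just
    outside a field border still counts.  ``n_a = 0`` yields an engaged
    density of 0 (a defined record, not a missing one).
    """
    if sample_id is None:
        ids = cells["sample_id"].unique()
        if len(ids) != 1:
            raise ValueError("pass sample_id explicitly for multi-sample tables")
        sample_id = ids[0]
    sub = cells[cells["sample_id"] == sample_id]
    if panel is not None:
        sub = sub[sub["panel"] == panel]
    ffs = [f for f in fields if f.region == region
           and f.sample_id in ("", sample_id)]
    if not ffs:
        raise ValueError(f"no analysis fields for {sample_id}/{region}")
    union = _analysis_union(ffs)
    area = union.area / UM2_PER_MM2
    dilated = union.buffer(radius_um)

    a_mask = has_phenotype(sub, phenotype_a).to_numpy() & _cells_in(sub, union)
    b_mask = has_phenotype(sub, phenotype_b).to_numpy() & _cells_in(sub, dilated)
    a_xy = sub.loc[a_mask, ["x_um", "y_um"]].to_numpy(float)
    b_xy = sub.loc[b_mask, ["x_um", "y_um"]].to_numpy(float)

    pairs = radius_pairs(a_xy, b_xy, radius_um)
    engaged = len(np.unique(pairs[:, 0])) if len(pairs) else 0
    return ProximityRecord(
        sample_id=sample_id, region=region,
        phenotype_a=phenotype_a, phenotype_b=phenotype_b,
        radius_um=float(radius_um),
        n_a=int(a_mask.sum()), n_b=int(b_mask.sum()),
        n_a_engaged=int(engaged), n_pairs=int(len(pairs)),
        area_mm2=area,
        engaged_density=engaged / area if area > 0 else 0.0,
        pair_density=len(pairs) / area if area > 0 else 0.0)


def proximity_table(records: list[ProximityRecord]) -> pd.DataFrame:
    """Tidy DataFrame of proximity records."""
    return pd.DataFrame([asdict(r) for r in records])
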