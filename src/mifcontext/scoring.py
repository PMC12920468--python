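"""Cohort-relative immune scores.

Both scores dichotomize each component metric at the cohort 50th percentile
(strictly greater than the cutoff scores 1) and sum the bits:

* Immunoscore — CD3+ and CD8+ densities in TC and IM → total 0–4,
  low 0–2 / high 3–4.
* CD8/PD-L1 composite — CD8+ density, PD-L1+ density and the CD8↔PD-L1
  20 μm engaged density, each in IM and TC → total 0–6, low 0–4 / high 5–6.

Cutoffs are computed per (metric, region) column over the scored cohort
only, so the scores are invariant to any common rescaling of the cohort.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Component column order for each scheme: (metric, region).
IMMUNOSCORE_COLUMNS: tuple[tuple[str, str], ...] = (
    ("CD3+", "IM"), ("CD8+", "IM"), ("CD3+", "TC"), ("CD8+", "TC"))
CD8_PDL1_COLUMNS: tuple[tuple[str, str], ...] = (
    ("CD8+", "IM"), ("PD-L1+", "IM"), ("proximity", "IM"),
    ("CD8+", "TC"), ("PD-L1+", "TC"), ("proximity", "TC"))

#: TC-only three-component variant of the composite (the original
#: checkpoint-augmented score restricted to the tumor center).
CD8_PDL1_TC_ONLY_COLUMNS: tuple[tuple[str, str], ...] = (
    ("CD8+", "TC"), ("PD-L1+", "TC"), ("proximity", "TC"))

SCHEMES = {
    "immunoscore": {"columns": IMMUNOSCORE_COLUMNS, "high_min": 3},
    "cd8_pdl1": {"columns": CD8_PDL1_COLUMNS, "high_min": 5},
    "cd8_pdl1_tc": {"columns": CD8_PDL1_TC_ONLY_COLUMNS, "high_min": 3},
}


def percentile_cutoff(values, p: float = 50.0) -> float:
    """Linear-interpolation percentile (k-th order statistic at probability
    (k-1)/(n-1)); requires at least two finite values."""
    arr = np.asarray(list(values), dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise ValueError("percentile cutoff needs >= 2 finite values")
    if not 0 <= p <= 100:
        raise ValueError("percentile must lie in [0, 100]")
    return float(np.percentile(arr, p, method="linear"))


def dichotomize(matrix: pd.DataFrame, p: float = 50.0
                ) -> tuple[pd.DataFrame, pd.Series]:
    """Per-column percentile dichotomization: bit = 1 iff value > cutoff.

    Strict inequality means ties at the cutoff score 0, so at most half the
    cohort is high per column.  Constant columns yield all-zero bits with a
    warning (degenerate cohort).  Returns (bits, cutoffs).
    """
    if matrix.isna().any().any():
        raise ValueError("metric matrix has missing values; drop incomplete samples first")
    cutoffs = {}
    bits = {}
    for col in matrix.columns:
        vals = matrix[col].to_numpy(float)
        cut = percentile_cutoff(vals, p)
        if np.all(vals == vals[0]):
            warnings.warn(f"column {col!r} is constant; all bits 0")
        cutoffs[col] = cut
        bits[col] = (vals > cut).astype(int)
    return (pd.DataFrame(bits, index=matrix.index),
            pd.Series(cutoffs, name="cutoff"))


#: Staining panel each scored density is read from: the Immunoscore uses the
#: T-cell panel carrying both CD3 and CD8 on one section; the composite uses
#: the checkpoint panel, the same section its proximity is measured on.
DEFAULT_METRIC_PANELS: dict[str, dict[str, str]] = {
    "immunoscore": {"CD3+": "P3", "CD8+": "P3"},
    "cd8_pdl1": {"CD8+": "P2", "PD-L1+": "P2"},
    "cd8_pdl1_tc": {"CD8+": "P2", "PD-L1+": "P2"},
}


def build_metric_matrix(densities: pd.DataFrame,
                        proximity: pd.DataFrame | None,
                        scheme: str,
                        metric_panels: dict[str, str] | None = None
                        ) -> pd.DataFrame:
    """Assemble the samples × (metric, region) matrix a scheme scores.

    ``densities`` is the tidy density table; ``proximity`` (needed for the
    composite schemes) supplies the engaged density per (sample, region).
    When the density table has a ``panel`` column, each metric is read from
    its scheme's default panel (overridable via ``metric_panels``).
    Samples missing any component are dropped with a log message.
    """
    cols = SCHEMES[scheme]["columns"]
    panels = dict(DEFAULT_METRIC_PANELS.get(scheme, {}))
    if metric_panels:
        panels.update(metric_panels)
    parts = {}
    for metric, region in cols:
        if metric == "proximity":
            if proximity is None:
                raise ValueError(f"scheme {scheme!r} needs a proximity table")
            sub = proximity[proximity["region"] == region]
            parts[(metric, region)] = sub.set_index("sample_id")["engaged_density"]
        else:
            sub = densities[(densities["phenotype"] == metric)
                            & (densities["region"] == region)]
            if "panel" in sub.columns and metric in panels:
                by_panel = sub[sub["panel"] == panels[metric]]
                if len(by_panel):
                    sub = by_panel
            parts[(metric, region)] = sub.set_index("sample_id")["density"]
    mat = pd.DataFrame(parts)
    complete = mat.dropna()
    dropped = sorted(set(mat.index) - set(complete.index))
    if dropped:
        log.info("excluding sample(s) missing a scored component: %s", dropped)
    mat = complete
    mat.columns = pd.MultiIndex.from_tuples(cols)[
        [list(cols).index(c) for c in mat.columns]]
    return mat[list(cols)]


def _score(matrix: pd.DataFrame, scheme: str, p: float = 50.0
           ) -> tuple[pd.DataFrame, pd.Series]:
    cols = list(SCHEMES[scheme]["columns"])
    high_min = SCHEMES[scheme]["high_min"]
    matrix = matrix[cols]
    bits, cutoffs = dichotomize(matrix, p)
    total = bits.sum(axis=1)
    out = pd.DataFrame({
        "sample_id": matrix.index,
        "scheme": scheme,
        "component_bits": ["".join(str(b) for b in row)
                           for row in bits.to_numpy()],
        "total": total.to_numpy(int),
        "category": np.where(total.to_numpy() >= high_min, "high", "low"),
    })
    return out.reset_index(drop=True), cutoffs


def immunoscore(matrix: pd.DataFrame, p: float = 50.0
                ) -> tuple[pd.DataFrame, pd.Series]:
    """Immunoscore per sample: bits (IM-CD3, IM-CD8, TC-CD3, TC-CD8),
    total 0–4, high ⇔ total ≥ 3.  Returns (scores, cutoffs)."""
    return _score(matrix, "immunoscore", p)


def cd8_pdl1_score(matrix: pd.DataFrame, p: float = 50.0,
                   tc_only: bool = False) -> tuple[pd.DataFrame, pd.Series]:
    """Composite CD8/PD-L1 score per sample.

    Bits ordered (IM-CD8, IM-PDL1, IM-prox, TC-CD8, TC-PDL1, TC-prox),
    total 0–6, high ⇔ total ≥ 5.  With ``tc_only`` the three TC components
    score 0–3 (high ⇔ 3).  Returns (scores, cutoffs)."""
    return _score(matrix, "cd8_pdl1_tc" if tc_only else "cd8_pdl1", p)
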