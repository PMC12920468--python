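"""Statistical battery for immune-contexture cohorts.

Paired IM-vs-TC enrichment (Wilcoxon matched-pairs signed-rank), high-vs-low
group comparison (Mann–Whitney U), Pearson correlation with linear
regression, and the association panel assembling those tests per phenotype
row with significance stars (ns p>0.05, * p≤0.05, ** p<0.01, *** p<0.001).

Small samples use exact distributions (signed-rank for n ≤ 25, U for
n₁+n₂ ≤ 20, when free of ties/zeros); larger or tied samples fall back to
the tie-corrected normal approximation.  No multiple-testing correction is
applied by default; Benjamini–Hochberg is available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    n: int
    estimate: float              # median difference, rank-biserial, or r
    ci_95: tuple[float, float] | None = None
    stratum: dict = field(default_factory=dict)
    degenerate: bool = False
    extra: dict = field(default_factory=dict)

    def asdict(self) -> dict:
        return asdict(self)


def stars(p: float) -> str:
    """Significance stars: ns p>0.05, * p≤0.05, ** p<0.01, *** p<0.001."""
    if not np.isfinite(p):
        return "ne"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p <= ALPHA:
        return "*"
    return "ns"


def _has_ties(x: np.ndarray) -> bool:
    return len(np.unique(x)) < len(x)


def wilcoxon_signed_rank(x, y, exact_max_n: int = 25) -> TestResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test on paired vectors.

    Exact distribution for n ≤ ``exact_max_n`` when there are no zero
    differences and no tied |differences|; tie-corrected normal
    approximation otherwise.  All-zero differences → p = 1, degenerate.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    d = x - y
    n = len(d)
    if n < 3:
        raise ValueError("need >= 3 pairs")
    if np.all(d == 0):
        return TestResult("wilcoxon_signed_rank", 0.0, 1.0, n, 0.0,
                          degenerate=True)
    nonzero = d[d != 0]
    clean = len(nonzero) == n and not _has_ties(np.abs(d))
    if n <= exact_max_n and clean:
        method: object = "exact"
    elif n <= 14:
        # ties or zeros at small n: exact sign-flip enumeration (2^n <= 16384)
        method = sps.PermutationMethod(n_resamples=2 ** 14 + 1)
    else:
        method = "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.wilcoxon(x, y, alternative="two-sided", method=method,
                           correction=method == "approx")
    return TestResult("wilcoxon_signed_rank", float(res.statistic),
                      float(min(res.pvalue, 1.0)), n, float(np.median(d)),
                      extra={"method": method if isinstance(method, str)
                             else "permutation_exact"})


def mann_whitney_u(x, y, exact_max_n: int = 20) -> TestResult:
    """Two-sided Mann–Whitney U: exact when n₁+n₂ ≤ ``exact_max_n`` and the
    pooled sample is tie-free, tie-corrected normal approximation otherwise.
    The estimate is the rank-biserial correlation 2U/(n₁n₂) − 1."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    use_exact = (n1 + n2 <= exact_max_n) and not _has_ties(pooled)
    method = "exact" if use_exact else "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u = float(res.statistic)
    return TestResult("mann_whitney_u", u, float(min(res.pvalue, 1.0)),
                      n1 + n2, 2.0 * u / (n1 * n2) - 1.0,
                      extra={"method": method, "n1": n1, "n2": n2})


def correlate(x, y) -> TestResult:
    """Pearson correlation with linear regression.

    Returns r, its t-based two-sided p, and the 95% CI on the regression
    slope; slope/intercept are in ``extra``.  Constant input is an error
    (r undefined)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3 for correlation")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for constant input")
    r, p = sps.pearsonr(x, y)
    reg = sps.linregress(x, y)
    tcrit = sps.t.ppf(0.975, len(x) - 2)
    ci = (reg.slope - tcrit * reg.stderr, reg.slope + tcrit * reg.stderr)
    return TestResult("pearson", float(r), float(p), len(x), float(r),
                      ci_95=(float(ci[0]), float(ci[1])),
                      extra={"slope": float(reg.slope),
                             "intercept": float(reg.intercept)})


def spearman(x, y) -> TestResult:
    """Spearman rank correlation (alternative association measure)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    rho, p = sps.spearmanr(x, y)
    return TestResult("spearman", float(rho), float(p), len(x), float(rho))


def paired_region_compare(densities: pd.DataFrame, phenotype: str,
                          panel: str | None = None) -> TestResult:
    """IM vs TC paired comparison of a phenotype's densities.

    Samples missing either region are dropped pairwise; at least three
    complete pairs are required."""
    sub = densities[densities["phenotype"] == phenotype]
    if panel:
        sub = sub[sub["panel"] == panel]
    wide = sub.pivot_table(index="sample_id", columns="region",
                           values="density", aggfunc="first")
    if "IM" not in wide or "TC" not in wide:
        raise ValueError(f"{phenotype}: need densities in both IM and TC")
    wide = wide.dropna(subset=["IM", "TC"])
    if len(wide) < 3:
        raise ValueError(f"{phenotype}: fewer than 3 complete IM/TC pairs")
    res = wilcoxon_signed_rank(wide["IM"].to_numpy(), wide["TC"].to_numpy())
    res.stratum = {"phenotype": phenotype, "comparison": "IM_vs_TC"}
    return res


def group_compare(values: pd.Series, groups: pd.Series) -> TestResult:
    """Mann–Whitney comparison of a metric between high and low groups.

    ``values`` indexed by sample; ``groups`` maps sample → 'high'/'low'."""
    values, groups = values.align(groups, join="inner")
    hi = values[groups == "high"].to_numpy(float)
    lo = values[groups == "low"].to_numpy(float)
    res = mann_whitney_u(hi, lo)
    res.stratum = {"comparison": "high_vs_low"}
    return res


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH-adjusted p-values (optional; off by default in panels)."""
    from statsmodels.stats.multitest import multipletests
    return multipletests(np.asarray(pvals, float), method="fdr_bh")[1]


#: Association-table row phenotypes grouped by staining panel.
PANEL_ROWS: tuple[tuple[str, str], ...] = (
    ("P1", "CD20+"), ("P1", "CD11c+"), ("P1", "CD15+"), ("P1", "CD3+"),
    ("P1", "CD163+"),
    ("P2", "PD-1+"), ("P2", "CD8+PD-1+"), ("P2", "Ki67+"), ("P2", "GrzB+"),
    ("P3", "CD3+"), ("P3", "CD4+"), ("P3", "CD4+Foxp3+"), ("P3", "CD56+"),
)


def _whole_density(densities: pd.DataFrame, phenotype: str,
                   panel: str) -> pd.Series:
    sub = densities[(densities["phenotype"] == phenotype)
                    & (densities["panel"] == panel)]
    return sub.set_index("sample_id")["density"]


def association_panel(densities_whole: pd.DataFrame, groups: pd.Series,
                      rows: tuple[tuple[str, str], ...] = PANEL_ROWS,
                      cd8_ref: pd.Series | None = None,
                      pdl1_ref: pd.Series | None = None,
                      method: str = "pearson",
                      adjust: bool = False) -> pd.DataFrame:
    """Phenotype association panel: per row, high-vs-low comparison of
    whole-tissue density plus correlations against the CD8+ and PD-L1+
    reference densities, each with significance stars.

    ``densities_whole`` is a tidy whole-tissue density table (see
    :func:`mifcontext.geometry.pool_regions`); reference series default to
    the panel-2 CD8+/PD-L1+ rows of the same table.  Rows whose density is
    zero everywhere (or absent) are marked not evaluable.
    """
    if cd8_ref is None:
        cd8_ref = _whole_density(densities_whole, "CD8+", "P2")
    if pdl1_ref is None:
        pdl1_ref = _whole_density(densities_whole, "PD-L1+", "P2")
    corr = {"pearson": correlate, "spearman": spearman}[method]

    out = []
    for panel, phen in rows:
        vals = _whole_density(densities_whole, phen, panel)
        rec = {"panel": panel, "phenotype": phen, "evaluable": True,
               "p_group": np.nan, "p_corr_cd8": np.nan,
               "p_corr_pdl1": np.nan}
        if len(vals) == 0 or np.all(vals.to_numpy() == 0):
            rec["evaluable"] = False
        else:
            try:
                rec["p_group"] = group_compare(vals, groups).p_value
                v1, r1 = vals.align(cd8_ref, join="inner")
                rec["p_corr_cd8"] = corr(v1.to_numpy(), r1.to_numpy()).p_value
                v2, r2 = vals.align(pdl1_ref, join="inner")
                rec["p_corr_pdl1"] = corr(v2.to_numpy(), r2.to_numpy()).p_value
            except ValueError:
                rec["evaluable"] = False
        out.append(rec)
    df = pd.DataFrame(out)
    if adjust:
        for c in ("p_group", "p_corr_cd8", "p_corr_pdl1"):
            ok = df[c].notna()
            df.loc[ok, c] = benjamini_hochberg(df.loc[ok, c])
    for c in ("p_group", "p_corr_cd8", "p_corr_pdl1"):
        df[c.replace("p_", "stars_")] = [
            stars(p) if ev else "ne" for p, ev in zip(df[c], df["evaluable"])]
    return df


def region_stratified_panel(densities: pd.DataFrame, groups: pd.Series,
                            msi: pd.Series | None = None,
                            rows: tuple[tuple[str, str], ...] = PANEL_ROWS,
                            method: str = "pearson",
                            min_n: int = 3) -> dict[tuple, pd.DataFrame]:
    """Association panels per (region × MSI) stratum.

    ``densities`` is the tidy per-region table; samples are filtered to the
    stratum before testing, and strata with fewer than ``min_n`` samples are
    suppressed with a warning.  Returns {(region, msi_label): panel}."""
    strata_msi = [None] if msi is None else sorted(msi.unique())
    panels: dict[tuple, pd.DataFrame] = {}
    for region in sorted(densities["region"].unique()):
        for m in strata_msi:
            sub = densities[densities["region"] == region]
            keep_groups = groups
            if m is not None:
                ids = set(msi[msi == m].index)
                sub = sub[sub["sample_id"].isin(ids)]
                keep_groups = groups[groups.index.isin(ids)]
            n = sub["sample_id"].nunique()
            if n < min_n:
                warnings.warn(f"stratum ({region}, {m}): only {n} samples; "
                              "panel suppressed")
                continue
            cd8 = sub[(sub["phenotype"] == "CD8+") & (sub["panel"] == "P2")
                      ].set_index("sample_id")["density"]
            pdl1 = sub[(sub["phenotype"] == "PD-L1+") & (sub["panel"] == "P2")
                       ].set_index("sample_id")["density"]
            panels[(region, m)] = association_panel(
                sub, keep_groups, rows=rows, cd8_ref=cd8, pdl1_ref=pdl1,
                method=method)
    return panels


def format_panel_markdown(panel: pd.DataFrame, title: str = "") -> str:
    """Render an association panel as a markdown table with star cells."""
    lines = []
    if title:
        lines.append(f"### {title}\n")
    lines.append("| Cell types | High vs low (p) | Corr. with CD8 (p) | Corr. with PD-L1 (p) |")
    lines.append("|---|---|---|---|")
    cur_panel = None
    for _, row in panel.iterrows():
        if row["panel"] != cur_panel:
            cur_panel = row["panel"]
            lines.append(f"| **Panel {cur_panel[1:]}** | | | |")
        if not row["evaluable"]:
            lines.append(f"| {row['phenotype']} | ne | ne | ne |")
            continue
        cells = [f"{row[f'stars_{k}']} ({row[f'p_{k}']:.4f})"
                 for k in ("group", "corr_cd8", "corr_pdl1")]
        lines.append(f"| {row['phenotype']} | " + " | ".join(cells) + " |")
    lines.append("\nns, p > 0.05; \\* p ≤ 0.05; \\*\\* p < 0.01; "
                 "\\*\\*\\* p < 0.001; ne, not evaluable.")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# generic contingency utilities (clinical covariates; not wired into the
# main pipeline)


def chi_square(table) -> TestResult:
    """Pearson chi-square test on an r×c contingency table."""
    chi2, p, dof, _ = sps.chi2_contingency(np.asarray(table))
    return TestResult("chi_square", float(chi2), float(p),
                      int(np.asarray(table).sum()), float(chi2),
                      extra={"dof": int(dof)})


def fisher_exact(table) -> TestResult:
    """Fisher's exact test on a 2×2 contingency table."""
    odds, p = sps.fisher_exact(np.asarray(table))
    return TestResult("fisher_exact", float(odds), float(p),
                      int(np.asarray(table).sum()), float(odds))
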