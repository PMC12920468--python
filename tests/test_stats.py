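"""Rank tests vs exact enumeration oracles, correlation, panels, stars."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from mifcontext.stats import (association_panel, correlate,
                              format_panel_markdown, group_compare,
                              mann_whitney_u, paired_region_compare,
                              region_stratified_panel, spearman, stars,
                              wilcoxon_signed_rank)


def wilcoxon_exact_oracle(x, y):
    """Two-sided signed-rank p by enumeration of all 2^n sign patterns."""
    d = np.asarray(x, float) - np.asarray(y, float)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    total = n * (n + 1) / 2
    lo, hi = min(w_obs, total - w_obs), max(w_obs, total - w_obs)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = ranks[np.array(signs, bool)].sum()
        if w <= lo or w >= hi:
            count += 1
    return count / 2 ** n


def mann_whitney_exact_oracle(x, y):
    """Two-sided U-test p by enumeration of all group assignments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    n1n2 = n1 * len(y)
    lo, hi = min(u_obs, n1n2 - u_obs), max(u_obs, n1n2 - u_obs)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        count += (u <= lo) or (u >= hi)
        total += 1
    return count / total


class TestWilcoxon:
    def test_identical_vectors_p_one_degenerate(self):
        r = wilcoxon_signed_rank([1., 2, 3, 4], [1., 2, 3, 4])
        assert r.p_value == 1.0 and r.degenerate

    def test_constant_shift_exact_enumeration(self):
        tc = np.arange(1., 7)
        r = wilcoxon_signed_rank(tc + 10, tc)
        assert r.p_value == pytest.approx(2 / 64)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        r = wilcoxon_signed_rank(x, y)
        assert r.p_value == pytest.approx(wilcoxon_exact_oracle(x, y))

    def test_estimate_is_median_difference(self):
        r = wilcoxon_signed_rank([5., 7, 9, 11, 13], [1., 2, 3, 4, 5])
        assert r.estimate == 6.0


class TestMannWhitney:
    def test_separated_groups_exact_p(self):
        r = mann_whitney_u([10., 11, 12], [1., 2, 3])
        assert r.statistic in (0.0, 9.0)
        assert r.p_value == pytest.approx(0.1)

    def test_identical_groups_p_near_one(self):
        r = mann_whitney_u([1., 2, 3, 4], [1.5, 2.5, 3.5, 0.5])
        assert r.p_value > 0.5

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_permutation_oracle_small_n(self, seed):
        rng = np.random.default_rng(100 + seed)
        n1 = int(rng.integers(3, 6))
        n2 = int(rng.integers(3, 6))
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        r = mann_whitney_u(x, y)
        assert r.p_value == pytest.approx(mann_whitney_exact_oracle(x, y))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestNullCalibration:
    def test_both_tests_reject_at_nominal_rate(self):
        rng = np.random.default_rng(2024)
        n_rep = 400
        rej_w = rej_m = 0
        for _ in range(n_rep):
            if wilcoxon_signed_rank(rng.normal(size=15),
                                    rng.normal(size=15)).p_value <= 0.05:
                rej_w += 1
            if mann_whitney_u(rng.normal(size=8),
                              rng.normal(size=8)).p_value <= 0.05:
                rej_m += 1
        assert 0.02 <= rej_w / n_rep <= 0.08
        assert 0.02 <= rej_m / n_rep <= 0.08


class TestCorrelate:
    def test_exact_line(self):
        r = correlate([0., 1, 2, 3], [1., 3, 5, 7])
        assert r.estimate == pytest.approx(1.0)
        assert r.extra["slope"] == pytest.approx(2.0)
        assert r.extra["intercept"] == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        x = np.array([1., 2, 4, 5, 7])
        y = np.array([2., 1, 5, 4, 8])
        r_hand = (np.sum((x - x.mean()) * (y - y.mean()))
                  / np.sqrt(np.sum((x - x.mean()) ** 2)
                            * np.sum((y - y.mean()) ** 2)))
        assert correlate(x, y).estimate == pytest.approx(r_hand)

    def test_null_r_centered_at_zero(self):
        rng = np.random.default_rng(5)
        rs = [correlate(rng.normal(size=50), rng.normal(size=50)).estimate
              for _ in range(200)]
        assert abs(np.mean(rs)) < 0.05

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            correlate([1., 1, 1, 1], [1., 2, 3, 4])


def _dens(records):
    return pd.DataFrame(records, columns=["sample_id", "region", "phenotype",
                                          "panel", "n_cells", "area_mm2",
                                          "density"])


class TestPairedRegionCompare:
    def test_im_enrichment_detected(self):
        recs = []
        for i in range(8):
            recs.append((f"S{i}", "IM", "PD-L1+", "P2", 0, 1.0, 100 + i * 3.0))
            recs.append((f"S{i}", "TC", "PD-L1+", "P2", 0, 1.0, 50 + i * 2.0))
        r = paired_region_compare(_dens(recs), "PD-L1+", "P2")
        assert r.p_value == pytest.approx(2 / 256)
        assert r.estimate > 0

    def test_missing_region_dropped_pairwise(self):
        recs = [(f"S{i}", rgn, "CD56+", "P3", 0, 1.0, 10.0 + i + (5 if rgn == "IM" else 0))
                for i in range(6) for rgn in ("IM", "TC")]
        recs.append(("S9", "IM", "CD56+", "P3", 0, 1.0, 99.0))  # no TC pair
        r = paired_region_compare(_dens(recs), "CD56+", "P3")
        assert r.n == 6


class TestAssociationPanel:
    @staticmethod
    def _cohort(n=50, seed=0):
        rng = np.random.default_rng(seed)
        cd8 = rng.lognormal(4, 0.5, n)
        rows = []
        groups = pd.Series(np.where(cd8 > np.median(cd8), "high", "low"),
                           index=[f"S{i:02d}" for i in range(n)])
        for i in range(n):
            sid = f"S{i:02d}"
            rows.append((sid, "whole", "CD8+", "P2", 0, 2.0, cd8[i]))
            rows.append((sid, "whole", "PD-L1+", "P2", 0, 2.0,
                         rng.lognormal(3, 0.5)))
            rows.append((sid, "whole", "CD3+", "P3", 0, 2.0, cd8[i] * 1.5))
            rows.append((sid, "whole", "CD15+", "P1", 0, 2.0, 0.0))
        return _dens(rows), groups

    def test_planted_correlation_reaches_three_stars(self):
        dens, groups = self._cohort()
        panel = association_panel(dens, groups,
                                  rows=(("P3", "CD3+"), ("P1", "CD15+")))
        cd3 = panel[panel["phenotype"] == "CD3+"].iloc[0]
        assert cd3["stars_corr_cd8"] == "***"

    def test_zero_density_row_not_evaluable(self):
        dens, groups = self._cohort()
        panel = association_panel(dens, groups, rows=(("P1", "CD15+"),))
        row = panel.iloc[0]
        assert not row["evaluable"]
        assert row["stars_group"] == "ne"

    def test_markdown_table_renders(self):
        dens, groups = self._cohort()
        panel = association_panel(dens, groups,
                                  rows=(("P3", "CD3+"), ("P1", "CD15+")))
        md = format_panel_markdown(panel, "test")
        assert "| CD3+ |" in md and "ne" in md


class TestRegionStratifiedPanel:
    @staticmethod
    def _regional_cohort(n=40, seed=1):
        rng = np.random.default_rng(seed)
        rows = []
        ids = [f"S{i:02d}" for i in range(n)]
        for sid in ids:
            cd8_im = rng.lognormal(4, 0.4)
            rows.append((sid, "IM", "CD8+", "P2", 0, 1.0, cd8_im))
            rows.append((sid, "TC", "CD8+", "P2", 0, 1.0, rng.lognormal(4, 0.4)))
            for rgn in ("IM", "TC"):
                rows.append((sid, rgn, "PD-L1+", "P2", 0, 1.0,
                             rng.lognormal(3, 0.4)))
            # CD56 tracks CD8 in IM only
            rows.append((sid, "IM", "CD56+", "P3", 0, 1.0, cd8_im * 0.3))
            rows.append((sid, "TC", "CD56+", "P3", 0, 1.0, rng.lognormal(2, 0.4)))
        groups = pd.Series("low", index=ids)
        groups.iloc[: n // 2] = "high"
        return _dens(rows), groups

    def test_planted_im_only_correlation(self):
        dens, groups = self._regional_cohort()
        panels = region_stratified_panel(dens, groups,
                                         rows=(("P3", "CD56+"),))
        im = panels[("IM", None)].iloc[0]
        tc = panels[("TC", None)].iloc[0]
        assert im["p_corr_cd8"] <= 0.05
        assert tc["p_corr_cd8"] > 0.05

    def test_small_stratum_suppressed(self):
        dens, groups = self._regional_cohort(n=6)
        msi = pd.Series(["MSI-H"] * 5 + ["MSS"], index=groups.index)
        with pytest.warns(UserWarning, match="suppressed"):
            panels = region_stratified_panel(dens, groups, msi=msi,
                                             rows=(("P3", "CD56+"),))
        assert ("IM", "MSS") not in panels
        assert ("IM", "MSI-H") in panels


class TestStars:
    @pytest.mark.parametrize("p,expected", [
        (0.2, "ns"), (0.051, "ns"), (0.05, "*"), (0.011, "*"),
        (0.009, "**"), (0.001, "**"), (0.0009, "***"),
    ])
    def test_footnote_mapping(self, p, expected):
        assert stars(p) == expected


def test_group_compare_on_series():
    vals = pd.Series([10., 12, 14, 1, 2, 3],
                     index=["A", "B", "C", "D", "E", "F"])
    groups = pd.Series(["high"] * 3 + ["low"] * 3, index=vals.index)
    r = group_compare(vals, groups)
    assert r.p_value == pytest.approx(0.1)


def test_spearman_monotone_transform_invariant():
    x = np.array([1., 2, 3, 4, 5, 6])
    y = x ** 3
    assert spearman(x, y).estimate == pytest.approx(1.0)
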