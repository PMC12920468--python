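"""Synthetic mIF-like cohorts with known ground truth.

Each sample is a marked spatial point pattern on a rectangular tissue whose
tumor–stroma interface (straight or sinusoidal) splits it into tumor and
stroma sides; the invasive-margin band and tumor center are derived from the
interface.  Per phenotype and compartment, cells are drawn from a
homogeneous Poisson process (count ~ Poisson(λ·area), uniform positions) or
a Thomas cluster process (Gaussian offspring around Poisson parents —
optionally the points of *another* phenotype, giving co-clustered pairs such
as PD-L1+ cells seeded at CD163+ macrophages).

Across samples, intensities vary lognormally around group means (planted
high/low infiltration × MSI status), and selected phenotype pairs share a
correlated lognormal latent factor so the cohort attains a target Pearson r
on log densities.  One integer seed fully determines a cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, box
from shapely.ops import split as _split_polygon, unary_union

from .geometry import CompartmentGeometry, derive_regions, UM2_PER_MM2
from .io import new_cell_table
from .markers import MARKERS, PHENOTYPE_MARKERS

UM_PER_MM = 1000.0


@dataclass(frozen=True)
class InterfaceSpec:
    """Shape of the tumor–stroma interface within a rectangular tissue.

    The interface runs left-to-right at mid-height (y increases downward;
    the tumor side is below the interface), centered horizontally, with an
    optional single-period sinusoidal deflection of ``amplitude_mm``.
    """

    length_mm: float
    shape: str = "straight"                      # straight | sinusoidal
    amplitude_mm: float = 0.0
    tissue_extent_mm: tuple[float, float] = (6.0, 4.0)

    def __post_init__(self) -> None:
        w, h = self.tissue_extent_mm
        if w <= 0 or h <= 0:
            raise ValueError("tissue extent must have positive width and height")
        if self.length_mm <= 0:
            raise ValueError("interface length must be positive")
        if self.length_mm > w:
            raise ValueError("interface longer than the tissue width")
        if self.shape not in ("straight", "sinusoidal"):
            raise ValueError(f"unknown interface shape {self.shape!r}")
        if self.amplitude_mm < 0:
            raise ValueError("amplitude must be nonnegative")
        if self.amplitude_mm >= h / 2:
            raise ValueError("interface amplitude leaves the tissue extent")


def _interface_coords(spec: InterfaceSpec) -> np.ndarray:
    w, h = (e * UM_PER_MM for e in spec.tissue_extent_mm)
    L = spec.length_mm * UM_PER_MM
    x0 = (w - L) / 2.0
    y0 = h / 2.0
    if spec.shape == "straight" or spec.amplitude_mm == 0:
        xs = np.array([x0, x0 + L])
        ys = np.array([y0, y0])
    else:
        xs = np.linspace(x0, x0 + L, 257)
        ys = y0 + spec.amplitude_mm * UM_PER_MM * np.sin(
            2 * np.pi * (xs - x0) / L)
    return np.column_stack([xs, ys])


def make_geometry(spec: InterfaceSpec, seed: int = 0,
                  im_width_um: float = 1000.0) -> CompartmentGeometry:
    """Build tissue, tumor/stroma split, interface, and IM/TC compartments.

    Deterministic for a fixed (spec, seed).  The tumor side is the half of
    the tissue below the interface (image convention).
    """
    w, h = (e * UM_PER_MM for e in spec.tissue_extent_mm)
    if w * h == 0:
        raise ValueError("degenerate tissue extent (zero area)")
    tissue = box(0.0, 0.0, w, h)
    coords = _interface_coords(spec)
    interface = LineString(coords)

    # splitter: the interface extended horizontally to beyond the tissue
    ext = np.vstack([[[-w, coords[0, 1]]], coords, [[2 * w, coords[-1, 1]]]])
    splitter = LineString(ext)
    pieces = _split_polygon(tissue, splitter)
    tumor_parts, stroma_parts = [], []
    for piece in pieces.geoms:
        p = piece.representative_point()
        # interpolate splitter height at the piece's x
        y_int = np.interp(p.x, ext[:, 0], ext[:, 1])
        (tumor_parts if p.y > y_int else stroma_parts).append(piece)
    tumor = unary_union(tumor_parts)
    stroma = unary_union(stroma_parts)
    geom = derive_regions(tumor, interface, im_width_um, tissue_polygon=tissue)
    geom.stroma_polygon = stroma  # extra attribute, used by area checks
    return geom


@dataclass(frozen=True)
class PhenotypeIntensitySpec:
    """Generating intensities (cells/mm²) for one phenotype in IM and TC.

    ``process='thomas'`` clusters offspring (Gaussian sd ``cluster_sd_um``)
    around Poisson parents at ``cluster_parent_rate``/mm², or around the
    generated points of ``coupled_to`` when given.  The phenotype's defining
    positive markers and staining panel default from the canonical label.
    """

    phenotype: str
    lambda_tc: float
    lambda_im: float
    process: str = "poisson"
    cluster_parent_rate: float = 0.0
    cluster_sd_um: float = 0.0
    coupled_to: str | None = None
    panel: str | None = None
    positive_markers: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lambda_tc) and np.isfinite(self.lambda_im)):
            raise ValueError("intensities must be finite")
        if self.lambda_tc < 0 or self.lambda_im < 0:
            raise ValueError("intensities must be nonnegative")
        if self.process not in ("poisson", "thomas"):
            raise ValueError(f"unknown process {self.process!r}")
        if self.process == "thomas":
            if self.cluster_sd_um <= 0:
                raise ValueError("thomas process needs cluster_sd_um > 0")
            if self.coupled_to is None and self.cluster_parent_rate <= 0:
                raise ValueError("thomas process needs cluster_parent_rate > 0 "
                                 "or a coupled_to phenotype")
        if self.panel is None and self.phenotype not in PHENOTYPE_MARKERS:
            raise ValueError(f"unknown phenotype {self.phenotype!r}: give an "
                             "explicit panel and positive_markers")

    def resolved_panel(self) -> str:
        return self.panel or PHENOTYPE_MARKERS[self.phenotype][0]

    def resolved_markers(self) -> frozenset[str]:
        if self.positive_markers is not None:
            return self.positive_markers
        return PHENOTYPE_MARKERS[self.phenotype][1]

    def scaled(self, im_factor: float, tc_factor: float) -> "PhenotypeIntensitySpec":
        return PhenotypeIntensitySpec(
            self.phenotype, self.lambda_tc * tc_factor,
            self.lambda_im * im_factor, self.process,
            self.cluster_parent_rate, self.cluster_sd_um, self.coupled_to,
            self.panel, self.positive_markers)


def _uniform_in(rng: np.random.Generator, poly, n: int) -> np.ndarray:
    """n points uniform in a polygon, by rejection from its bounding box."""
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = poly.bounds
    shapely.prepare(poly)
    frac = max(poly.area / ((maxx - minx) * (maxy - miny)), 1e-3)
    pts = np.empty((0, 2))
    while len(pts) < n:
        m = max(int((n - len(pts)) / frac * 1.3) + 16, 64)
        cand = rng.uniform((minx, miny), (maxx, maxy), size=(m, 2))
        keep = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
        pts = np.vstack([pts, cand[keep]])
    return pts[:n]


def _sample_region_points(rng, spec: PhenotypeIntensitySpec, poly,
                          lam: float, parents: np.ndarray | None
                          ) -> np.ndarray:
    area = poly.area / UM2_PER_MM2
    if lam == 0 or area == 0:
        return np.empty((0, 2))
    if spec.process == "poisson":
        return _uniform_in(rng, poly, rng.poisson(lam * area))
    # thomas cluster process
    if parents is None:
        parents = _uniform_in(rng, poly,
                              rng.poisson(spec.cluster_parent_rate * area))
    if len(parents) == 0:
        return np.empty((0, 2))
    mu = lam * area / len(parents)
    counts = rng.poisson(mu, size=len(parents))
    centers = np.repeat(parents, counts, axis=0)
    pts = centers + rng.normal(0.0, spec.cluster_sd_um, size=centers.shape)
    shapely.prepare(poly)
    keep = shapely.contains_xy(poly, pts[:, 0], pts[:, 1])
    return pts[keep]


def simulate_sample(specs: list[PhenotypeIntensitySpec],
                    geometry: CompartmentGeometry, seed: int,
                    sample_id: str = "S1") -> pd.DataFrame:
    """Simulate one sample's cell table on a derived geometry.

    Phenotypes with ``coupled_to`` are generated after their parent
    phenotype (same compartment) so offspring cluster around realized
    parent points.  Marker flags are the phenotype's defining positives;
    all other markers are negative.
    """
    by_name = {s.phenotype: s for s in specs}
    for s in specs:
        if s.coupled_to is not None and s.coupled_to not in by_name:
            raise ValueError(f"{s.phenotype}: coupled_to references unknown "
                             f"phenotype {s.coupled_to!r}")
    order, placed = [], set()
    pending = list(specs)
    while pending:
        progressed = False
        for s in list(pending):
            if s.coupled_to is None or s.coupled_to in placed:
                order.append(s)
                placed.add(s.phenotype)
                pending.remove(s)
                progressed = True
        if not progressed:
            raise ValueError("cyclic coupled_to dependencies among phenotypes")

    rng = np.random.default_rng(seed)
    points: dict[tuple[str, str], np.ndarray] = {}
    chunks = []
    for spec in order:
        for region, lam in (("IM", spec.lambda_im), ("TC", spec.lambda_tc)):
            poly = geometry.region_polygon(region)
            parents = (points.get((spec.coupled_to, region))
                       if spec.coupled_to else None)
            pts = _sample_region_points(rng, spec, poly, lam, parents)
            points[(spec.phenotype, region)] = pts
            if len(pts) == 0:
                continue
            chunk = pd.DataFrame({"sample_id": sample_id,
                                  "panel": spec.resolved_panel(),
                                  "x_um": pts[:, 0], "y_um": pts[:, 1]})
            pos = spec.resolved_markers()
            for m in MARKERS:
                chunk[m] = np.int8(1 if m in pos else 0)
            chunk["phenotypes"] = ""
            chunk["region"] = "unassigned"
            chunks.append(chunk)
    if not chunks:
        return new_cell_table()
    return pd.concat(chunks, ignore_index=True)


@dataclass
class CohortSpec:
    """A whole synthetic cohort: group/MSI labels per sample, per-group
    intensity sets, lognormal between-sample spread, and optional Pearson
    targets on log densities for chosen (phenotype, phenotype, region)."""

    n_samples: int
    groups: list[tuple[str, str]]                 # (planted group, MSI) per sample
    intensities: dict[str, list[PhenotypeIntensitySpec]]
    interface: InterfaceSpec = field(
        default_factory=lambda: InterfaceSpec(5.0, "sinusoidal", 0.3, (6.0, 4.0)))
    im_width_um: float = 1000.0
    sigma_log: float = 0.4
    correlation_targets: list[tuple[str, str, str, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("cohort needs at least 2 samples "
                             "(cohort cutoffs undefined otherwise)")
        if len(self.groups) != self.n_samples:
            raise ValueError("group labels must cover all samples")
        for g, _ in self.groups:
            if g not in self.intensities:
                raise ValueError(f"no intensity set for group {g!r}")
        for a, b, region, r in self.correlation_targets:
            if not abs(r) < 1:
                raise ValueError(f"target correlation |r| must be < 1, got {r}")
            if region not in ("IM", "TC"):
                raise ValueError(f"unknown region {region!r} in correlation target")


def simulate_cohort(spec: CohortSpec
                    ) -> tuple[pd.DataFrame, dict[str, CompartmentGeometry],
                               pd.DataFrame]:
    """Simulate a cohort; returns (cells, geometry per sample, truth table).

    The truth table records each sample's planted group, MSI label, and the
    realized generating intensities per phenotype and compartment.
    """
    rng = np.random.default_rng(spec.seed)
    geometry = make_geometry(spec.interface, seed=spec.seed,
                             im_width_um=spec.im_width_um)
    sigma = spec.sigma_log
    target_by_pair = {}
    for a, b, region, r in spec.correlation_targets:
        target_by_pair[(a, b, region)] = r

    cells_parts, truth_rows = [], {}
    geometries = {}
    sample_ids = [f"S{i + 1:02d}" for i in range(spec.n_samples)]
    for sid, (group, msi) in zip(sample_ids, spec.groups):
        base = spec.intensities[group]
        phenos = [s.phenotype for s in base]
        # shared lognormal latent per phenotype (both regions) ...
        z = {(ph, reg): v
             for ph, v in zip(phenos, rng.standard_normal(len(phenos)))
             for reg in ("IM", "TC")}
        # ... overridden per-region for correlation-target pairs
        for (a, b, region), r in target_by_pair.items():
            za = rng.standard_normal()
            zb = r * za + np.sqrt(1 - r * r) * rng.standard_normal()
            if a in phenos:
                z[(a, region)] = za
            if b in phenos:
                z[(b, region)] = zb
        factor = {k: float(np.exp(sigma * v - sigma ** 2 / 2))
                  for k, v in z.items()} if sigma > 0 else {k: 1.0 for k in z}

        sample_specs = [s.scaled(factor[(s.phenotype, "IM")],
                                 factor[(s.phenotype, "TC")]) for s in base]
        sample_seed = int(rng.integers(0, 2 ** 31))
        cells_parts.append(simulate_sample(sample_specs, geometry,
                                           seed=sample_seed, sample_id=sid))
        geometries[sid] = geometry
        row = {"sample_id": sid, "group": group, "msi": msi}
        for s in sample_specs:
            row[f"lambda_im_{s.phenotype}"] = s.lambda_im
            row[f"lambda_tc_{s.phenotype}"] = s.lambda_tc
        truth_rows[sid] = row

    cells = pd.concat(cells_parts, ignore_index=True)
    truth = pd.DataFrame(list(truth_rows.values()))
    return cells, geometries, truth


# ---------------------------------------------------------------------------
# study-condition defaults

#: Baseline (planted-low) intensities, cells/mm² (IM, TC).  PD-L1+ and
#: CD163+ are enriched in the invasive margin; PD-L1+ cells co-cluster with
#: CD163+ macrophages; CD20+ B cells form TLS-like clusters in the margin.
_BASELINES: tuple[PhenotypeIntensitySpec, ...] = (
    PhenotypeIntensitySpec("CK+", lambda_tc=1800, lambda_im=1200),
    PhenotypeIntensitySpec("CD20+", lambda_tc=40, lambda_im=150,
                           process="thomas", cluster_parent_rate=2.0,
                           cluster_sd_um=50.0),
    PhenotypeIntensitySpec("CD11c+", lambda_tc=60, lambda_im=100),
    PhenotypeIntensitySpec("CD15+", lambda_tc=50, lambda_im=80),
    PhenotypeIntensitySpec("CD163+", lambda_tc=120, lambda_im=300),
    PhenotypeIntensitySpec("CD3+", lambda_tc=250, lambda_im=400, panel="P3"),
    PhenotypeIntensitySpec("CD3+", lambda_tc=250, lambda_im=400, panel="P1"),
    PhenotypeIntensitySpec("CD8+", lambda_tc=120, lambda_im=250, panel="P2"),
    PhenotypeIntensitySpec("CD8+", lambda_tc=120, lambda_im=250, panel="P3"),
    PhenotypeIntensitySpec("PD-L1+", lambda_tc=60, lambda_im=180,
                           process="thomas", cluster_sd_um=30.0,
                           coupled_to="CD163+"),
    PhenotypeIntensitySpec("PD-1+", lambda_tc=80, lambda_im=150),
    PhenotypeIntensitySpec("CD8+PD-1+", lambda_tc=25, lambda_im=60),
    PhenotypeIntensitySpec("Ki67+", lambda_tc=300, lambda_im=250),
    PhenotypeIntensitySpec("GrzB+", lambda_tc=50, lambda_im=80),
    PhenotypeIntensitySpec("CD4+", lambda_tc=180, lambda_im=300),
    PhenotypeIntensitySpec("CD4+Foxp3+", lambda_tc=40, lambda_im=80),
    PhenotypeIntensitySpec("CD56+", lambda_tc=25, lambda_im=60),
)

#: Planted-high multipliers (both compartments): 3.5× on the CD8/PD-L1 axis
#: itself, 2.5–3× on the populations enriched with it.
_HIGH_MULTIPLIERS: dict[str, float] = {
    "CD8+": 3.5, "PD-L1+": 3.5, "CD3+": 2.5, "CD20+": 2.5,
    "PD-1+": 3.0, "CD8+PD-1+": 3.0, "CD56+": 2.5,
}

#: 15 samples: 6 planted high (5 MSI-H, 1 MSS), 9 planted low (3 MSI-H,
#: 6 MSS) — the composition of the cohort this generator emulates.
DEFAULT_GROUPS: tuple[tuple[str, str], ...] = (
    *((("planted_high", "MSI-H"),) * 5), ("planted_high", "MSS"),
    *((("planted_low", "MSI-H"),) * 3), *((("planted_low", "MSS"),) * 6),
)


def default_cohort_spec(seed: int = 0,
                        phenotypes: list[str] | None = None,
                        n_samples: int | None = None,
                        groups: list[tuple[str, str]] | None = None,
                        tissue_extent_mm: tuple[float, float] = (6.0, 4.0),
                        interface_length_mm: float = 5.0,
                        sigma_log: float = 0.4,
                        correlation_targets=None) -> CohortSpec:
    """The default study conditions, optionally restricted to a phenotype
    subset or resized (smaller cohorts for focused simulations).

    Defaults: 15 samples with the 6-high/9-low × MSI composition above, a
    5 mm sinusoidal interface in a 6×4 mm tissue, lognormal spread
    σ = 0.4 on log intensities, and an IM-region PD-L1+/CD163+ Pearson
    target of r = 0.8 on log densities.
    """
    base = list(_BASELINES)
    if phenotypes is not None:
        keep = set(phenotypes)
        base = [s for s in base if s.phenotype in keep]
        base = [s if (s.coupled_to is None or s.coupled_to in keep)
                else PhenotypeIntensitySpec(s.phenotype, s.lambda_tc,
                                            s.lambda_im, "poisson",
                                            panel=s.panel)
                for s in base]
    high = [s.scaled(_HIGH_MULTIPLIERS.get(s.phenotype, 1.0),
                     _HIGH_MULTIPLIERS.get(s.phenotype, 1.0)) for s in base]
    if groups is None:
        groups = list(DEFAULT_GROUPS)
    if n_samples is not None and n_samples != len(groups):
        reps = [groups[i % len(groups)] for i in range(n_samples)]
        groups = reps
    if correlation_targets is None:
        present = {s.phenotype for s in base}
        correlation_targets = ([("PD-L1+", "CD163+", "IM", 0.8)]
                               if {"PD-L1+", "CD163+"} <= present else [])
    return CohortSpec(
        n_samples=len(groups), groups=groups,
        intensities={"planted_low": base, "planted_high": high},
        interface=InterfaceSpec(interface_length_mm, "sinusoidal", 0.3,
                                tissue_extent_mm),
        sigma_log=sigma_log, correlation_targets=list(correlation_targets),
        seed=seed)
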