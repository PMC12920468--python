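# Methods

This document records the model implemented by `mifcontext`, its
parameter defaults (with units), the numerical choices, and the
limitations of the synthetic-cohort generator.

## Coordinate and data conventions

- Cell coordinates are in **μm** in image convention (y increases
  downward; for generated geometries, the tumor lies on the larger-y
  side of the interface). Densities are in **cells/mm²**
  (1 mm² = 10⁶ μm²).
- A cell table is a pandas DataFrame with columns `sample_id`,
  `panel`, `x_um`, `y_um`, one 0/1 column per marker, and derived
  `phenotypes` (semicolon-joined labels) and `region` columns. CSV
  readers accept QuPath-style headers (`Centroid X µm`, `PDL1`, …) via
  an alias map; rows with missing or non-finite coordinates are
  dropped with a warning, and absent marker columns are filled with 0.
- Three staining panels are modeled — P1 {CK, CD20, CD11c, CD15, CD3,
  CD163}, P2 {CK, PD-1, CD8, PD-L1, Ki67, GrzB}, P3 {CK, CD3, CD4,
  Foxp3, CD56, CD8} — and every density is keyed by *(phenotype,
  panel)*, because CD3⁺ and CD8⁺ are measurable on two panels each.
  Scoring uses P3 for the Immunoscore components and P2 for the
  composite-score components.

## Compartment geometry

The tumor–stroma interface is a polyline; the **invasive margin (IM)**
is its buffer of half-width `im_width_um / 2` on each side with flat
caps (`im_width_um` default **1000 μm**), clipped to the tissue
polygon. The **tumor center (TC)** is the tumor polygon minus the
band. Region assignment uses closed polygons (`shapely.covers`), with
IM taking precedence over TC on shared boundaries; everything else is
`outside`. For a straight 5 mm interface the band is exactly
1.0 mm × 5.0 mm = 5.0 mm².

**Fields.** Up to `n_fields` (default **5**) square analysis fields of
side `field_side_um` (default **1000 μm**) are placed per compartment
on a regular grid (stride = side length), ranked by overlap area with
the compartment, with a seeded random permutation breaking ties. Field
∩ compartment polygons are pooled per sample: density =
Σ counts / Σ analyzed area. If no grid cell center falls inside a
small compartment, a single clipped field at the compartment centroid
is used (with a warning).

## Proximity

Pairs within radius `r` (default **20 μm**, closed ball: distance ≤ r)
are found with a KD-tree. The **engaged density** of phenotype A
against phenotype B in a compartment is the number of A cells inside
the pooled analysis area having ≥ 1 B neighbor within r, divided by
the analyzed area. B cells are taken from the analysis area dilated by
r, so partners just outside a field still count. The pipeline's
default proximity statistic is engaged CD8⁺ (panel P2) against PD-L1⁺;
a raw pair-density variant is available.

## Scoring

For each score component (a *(phenotype or proximity, compartment)*
pair) the cohort cutoff is the **50th percentile** (numpy linear
interpolation) of the per-sample values; a component scores 1 when the
value is **strictly greater** than the cutoff. Totals: Immunoscore-like
score over (CD3⁺, CD8⁺) × (IM, TC) ∈ 0–4, *high* ⇔ ≥ 3; composite
CD8/PD-L1 score over (CD8⁺, PD-L1⁺, proximity) × (IM, TC) ∈ 0–6,
*high* ⇔ ≥ 5. A TC-only composite variant (0–3, high ⇔ ≥ 3) is
provided. Samples missing any component are excluded from that scheme
with a warning; cutoffs are cohort-relative, so scores are only
comparable within one cohort.

## Statistics

- **Paired IM vs TC:** Wilcoxon signed-rank. Exact distribution when
  n ≤ 25 without ties or zero differences; an exact permutation of all
  sign assignments (via `scipy.stats.PermutationMethod`) when n ≤ 14
  with ties/zeros; tie-corrected normal approximation otherwise. All
  differences zero ⇒ p = 1, flagged degenerate.
- **Group contrasts:** Mann–Whitney U, exact when n₁+n₂ ≤ 20 and
  tie-free, with a rank-biserial effect-size estimate.
- **Correlations:** Pearson on log densities (slope/intercept via least
  squares); Spearman available. A Fisher z 95 % interval is used to
  judge recovery of planted correlations.
- Association panels report significance stars (ns / * / ** / *** at
  0.05 / 0.01 / 0.001), mark all-zero rows "ne" (not evaluable),
  suppress strata with n < 3, and offer Benjamini–Hochberg adjustment.

## Synthetic-cohort generator

Each sample shares one geometry: a rectangular tissue (default
**6 × 4 mm**) split by a straight or sinusoidal interface (default
length **5 mm**, amplitude **0.3 mm**).

Per phenotype and compartment, points are drawn from:

- a **homogeneous Poisson process** with intensity λ (cells/mm²), or
- a **Thomas cluster process** — Poisson parents (`cluster_parent_rate`
  per mm², or parents taken from another phenotype's realized points
  via `coupled_to`), Gaussian offspring displacement
  (`cluster_sd_um`), offspring count per parent set so the mean
  intensity equals λ. Default baselines couple PD-L1⁺ offspring to
  CD163⁺ parents (σ = 30 μm) and give CD20⁺ B cells TLS-like clusters
  (2 parents/mm², σ = 50 μm).

Between-sample heterogeneity is lognormal: each sample draws a latent
standard normal z per phenotype and multiplies both compartment
intensities by exp(σz − σ²/2) (mean-preserving; σ default **0.4**).
**Correlation targets** replace the latent z of a chosen phenotype
pair in a chosen compartment by a bivariate standard normal with
correlation r, which makes the generating log intensities correlate at
r exactly in expectation.

The default cohort emulates a 15-sample study: 6 planted-high samples
(5 MSI-H, 1 MSS) and 9 planted-low (3 MSI-H, 6 MSS), where
planted-high multiplies the CD8/PD-L1-axis intensities by 3.5× (allied
populations 2.5–3×) in both compartments. Baseline intensities span
≈ 25–1800 cells/mm² across 17 phenotype specs with margin enrichment
of PD-L1⁺, CD163⁺, CD3⁺ and CD8⁺.

**What the generator does and does not emulate.** It reproduces
compartment-resolved densities, clustered/co-clustered spatial
structure, lognormal between-sample spread, planted group contrasts
and planted correlations — enough to validate every estimator against
ground truth. It does not model cell shapes or sizes (points only),
staining artifacts, intensity thresholds (marker calls are exact 0/1),
tissue folds/holes, or biologically realistic joint distributions
beyond the planted ones.

### A design note on correlation-recovery experiments

Recovery of a planted correlation must be tested on a **single-group
cohort** (`groups=[("planted_low", "MSS")] * n`). In a mixed cohort the
planted-high contrast multiplies PD-L1⁺ by 3.5× but leaves CD163⁺
unchanged, adding group-level variance to one axis only; the
log-density correlation is then attenuated from 0.8 to ≈ 0.44 by
construction — a confounded design, not an estimator failure. With a
homogeneous cohort the measured IM log-density correlation lands
inside the Fisher 95 % interval around r = 0.8 (n = 50) across seeds.

## Problem sizes and budgets

Defaults were chosen so the full test suite runs in ≈ 1.5 min and the
acceptance script in ≈ 1 min on a single CPU: validation experiments
use 2–3 mm tissues with 4–50 samples; oracle equivalence uses ≤ 2000
points per instance (brute force is O(n²)); null calibration uses 1000
replicates (Monte-Carlo SE ≈ 0.007 at α = 0.05); planted-label
recovery uses 50 replicate 15-sample cohorts. These sizes are the
package's own validation choices, not claims about any external
dataset.

## Determinism

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; cohort generation derives per-sample seeds
from the cohort seed. Pipeline reruns with the same configuration
produce byte-identical outputs; `manifest.json` records SHA-256
checksums, the configuration, package version and any warnings.
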