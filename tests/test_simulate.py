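"""Synthetic-cohort generator: calibration, coupling, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from mifcontext.geometry import UM2_PER_MM2
from mifcontext.simulate import (CohortSpec, InterfaceSpec,
                                 PhenotypeIntensitySpec, default_cohort_spec,
                                 make_geometry, simulate_cohort,
                                 simulate_sample)


class TestInterfaceSpec:
    def test_degenerate_extent_rejected(self):
        with pytest.raises(ValueError):
            InterfaceSpec(5.0, "straight", 0.0, (0.0, 4.0))

    def test_interface_longer_than_tissue_rejected(self):
        with pytest.raises(ValueError):
            InterfaceSpec(7.0, "straight", 0.0, (6.0, 4.0))

    def test_amplitude_outside_tissue_rejected(self):
        with pytest.raises(ValueError):
            InterfaceSpec(5.0, "sinusoidal", 2.5, (6.0, 4.0))


class TestMakeGeometry:
    def test_tumor_and_stroma_partition_tissue(self, straight_geometry):
        g = straight_geometry
        total = (g.tumor_polygon.area + g.stroma_polygon.area) / UM2_PER_MM2
        assert total == pytest.approx(24.0)

    def test_deterministic(self):
        spec = InterfaceSpec(5.0, "sinusoidal", 0.5, (6.0, 4.0))
        a = make_geometry(spec, seed=3)
        b = make_geometry(spec, seed=3)
        assert a.tumor_polygon.equals(b.tumor_polygon)
        assert list(a.interface.coords) == list(b.interface.coords)

    def test_sinusoid_arc_length_at_least_chord(self, sinus_geometry):
        assert sinus_geometry.interface.length >= 5000.0


class TestSimulateSample:
    def test_poisson_mean_calibration(self, straight_geometry):
        # λ_tc = 100 on the 9.5 mm² TC: mean count over replicates within 3 SE
        spec = PhenotypeIntensitySpec("CD8+", lambda_tc=100, lambda_im=0,
                                      panel="P2")
        area = straight_geometry.tc_polygon.area / UM2_PER_MM2
        n_rep = 200
        counts = [len(simulate_sample([spec], straight_geometry, seed=s))
                  for s in range(n_rep)]
        expect = 100 * area
        se = np.sqrt(expect / n_rep)
        assert abs(np.mean(counts) - expect) < 3 * se
        # Poisson: variance/mean ≈ 1
        assert 0.7 < np.var(counts) / np.mean(counts) < 1.4

    def test_zero_intensity_zero_cells(self, straight_geometry):
        spec = PhenotypeIntensitySpec("CD8+", lambda_tc=0, lambda_im=0,
                                      panel="P2")
        assert len(simulate_sample([spec], straight_geometry, seed=1)) == 0

    def test_cells_inside_tissue_with_consistent_markers(self, straight_geometry):
        specs = [PhenotypeIntensitySpec("CD8+PD-1+", 50, 50)]
        cells = simulate_sample(specs, straight_geometry, seed=2)
        assert (cells["CD8"] == 1).all() and (cells["PD-1"] == 1).all()
        assert (cells["CD4"] == 0).all()
        assert cells["x_um"].between(0, 6000).all()
        assert cells["y_um"].between(0, 4000).all()

    def test_unknown_coupled_phenotype_rejected(self, straight_geometry):
        spec = PhenotypeIntensitySpec("PD-L1+", 50, 50, process="thomas",
                                      cluster_sd_um=30, coupled_to="CD163+")
        with pytest.raises(ValueError, match="coupled_to"):
            simulate_sample([spec], straight_geometry, seed=0)

    def test_coupled_thomas_clusters_near_parents(self, straight_geometry):
        parents = PhenotypeIntensitySpec("CD163+", 100, 100)
        coupled = [parents,
                   PhenotypeIntensitySpec("PD-L1+", 100, 100, process="thomas",
                                          cluster_sd_um=30.0,
                                          coupled_to="CD163+")]
        independent = [parents,
                       PhenotypeIntensitySpec("PD-L1+", 100, 100)]

        def mean_nn(cells):
            pdl1 = cells[cells["PD-L1"] == 1][["x_um", "y_um"]].to_numpy()
            cd163 = cells[cells["CD163"] == 1][["x_um", "y_um"]].to_numpy()
            d, _ = cKDTree(cd163).query(pdl1)
            return d.mean()

        d_coupled = np.mean([mean_nn(simulate_sample(coupled, straight_geometry, s))
                             for s in range(5)])
        d_indep = np.mean([mean_nn(simulate_sample(independent, straight_geometry, s))
                           for s in range(5)])
        assert d_coupled < d_indep

    def test_thomas_without_parent_rate_rejected(self):
        with pytest.raises(ValueError, match="parent_rate"):
            PhenotypeIntensitySpec("CD20+", 50, 50, process="thomas",
                                   cluster_sd_um=40.0)


class TestSimulateCohort:
    def test_single_sample_cohort_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            default_cohort_spec(n_samples=1)

    def test_truth_table_structure(self):
        spec = default_cohort_spec(seed=5, phenotypes=["CD8+", "PD-L1+", "CD163+"],
                                   tissue_extent_mm=(2.0, 1.5),
                                   interface_length_mm=1.5)
        cells, geoms, truth = simulate_cohort(spec)
        assert len(truth) == 15
        assert set(truth["group"]) == {"planted_high", "planted_low"}
        assert set(truth["msi"]) == {"MSI-H", "MSS"}
        assert (truth["group"] == "planted_high").sum() == 6
        assert {"lambda_im_CD8+", "lambda_tc_CD8+"} <= set(truth.columns)
        assert set(cells["sample_id"]) == set(truth["sample_id"])
        assert set(geoms) == set(truth["sample_id"])

    def test_seed_reproducibility_byte_identical(self, tmp_path):
        spec = default_cohort_spec(seed=9, phenotypes=["CD8+"],
                                   tissue_extent_mm=(2.0, 1.5),
                                   interface_length_mm=1.5)
        from mifcontext.io import write_cell_table
        out = []
        for tag in ("a", "b"):
            cells, _, truth = simulate_cohort(spec)
            p = tmp_path / f"{tag}.csv"
            write_cell_table(cells, p)
            out.append(p.read_bytes())
        assert out[0] == out[1]

    def test_planted_high_intensities_scaled(self):
        spec = default_cohort_spec(seed=0, phenotypes=["CD8+", "CD163+"])
        hi = {s.phenotype: s for s in spec.intensities["planted_high"]}
        lo = {s.phenotype: s for s in spec.intensities["planted_low"]}
        assert hi["CD8+"].lambda_im == pytest.approx(lo["CD8+"].lambda_im * 3.5)
        assert hi["CD163+"].lambda_im == lo["CD163+"].lambda_im

    def test_correlation_target_recovered_on_log_densities(self):
        # r = 0.8 between PD-L1+ and CD163+ generating intensities in the IM
        # single-group cohort: the planted contrast scales PD-L1+ only and
        # would otherwise confound the correlation target
        spec = default_cohort_spec(
            seed=11, phenotypes=["PD-L1+", "CD163+"], n_samples=50,
            groups=[("planted_low", "MSS")] * 50,
            tissue_extent_mm=(2.0, 1.5), interface_length_mm=1.5,
            correlation_targets=[("PD-L1+", "CD163+", "IM", 0.8)])
        _, _, truth = simulate_cohort(spec)
        r = np.corrcoef(np.log(truth["lambda_im_PD-L1+"]),
                        np.log(truth["lambda_im_CD163+"]))[0, 1]
        # Fisher 95% interval around 0.8 at n=50
        z = np.arctanh(0.8)
        lo, hi = np.tanh(z - 1.96 / np.sqrt(47)), np.tanh(z + 1.96 / np.sqrt(47))
        assert lo < r < hi

    def test_invalid_correlation_target_rejected(self):
        with pytest.raises(ValueError, match="< 1"):
            CohortSpec(n_samples=2,
                       groups=[("planted_low", "MSS")] * 2,
                       intensities={"planted_low": [
                           PhenotypeIntensitySpec("CD8+", 10, 10)]},
                       correlation_targets=[("a", "b", "IM", 1.0)])
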