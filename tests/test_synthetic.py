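"""Synthetic generators: domain masks, planted lattices, abundance tables."""

import numpy as np
import pytest

from fibrilpfc.grid import GridSpec
from fibrilpfc.synthetic import (
    TIMEPOINTS,
    SyntheticAbundanceSpec,
    SyntheticDomainSpec,
    gen_abundance_table,
    gen_domain_mask,
    gen_hex_lattice,
    plant_defects,
    reference_analysis,
    reference_delaunay,
)


GRID = GridSpec(96, 96, dx=10.0)


class TestDomainMask:
    def test_zero_roughness_gives_a_disk(self):
        mask = gen_domain_mask(GRID, SyntheticDomainSpec(300.0, 0.0, 4, seed=1))
        area = mask.n_inside * GRID.dx**2
        assert area == pytest.approx(np.pi * 300.0**2, rel=0.02)
        # radial symmetry: bounding box is square and centered
        rows = np.nonzero(mask.inside.any(axis=1))[0]
        cols = np.nonzero(mask.inside.any(axis=0))[0]
        assert len(rows) == len(cols)

    def test_same_seed_reproduces_mask_exactly(self):
        spec = SyntheticDomainSpec(300.0, 0.3, 8, seed=42)
        m1 = gen_domain_mask(GRID, spec)
        m2 = gen_domain_mask(GRID, spec)
        assert np.array_equal(m1.inside, m2.inside)

    def test_different_seeds_differ(self):
        m1 = gen_domain_mask(GRID, SyntheticDomainSpec(300.0, 0.3, 8, seed=1))
        m2 = gen_domain_mask(GRID, SyntheticDomainSpec(300.0, 0.3, 8, seed=2))
        assert not np.array_equal(m1.inside, m2.inside)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    def test_area_within_analytic_annulus_bounds(self, seed):
        r, rough = 300.0, 0.3
        mask = gen_domain_mask(GRID, SyntheticDomainSpec(r, rough, 8, seed=seed))
        area = mask.n_inside * GRID.dx**2
        assert np.pi * (r * (1 - rough)) ** 2 <= area <= np.pi * (r * (1 + rough)) ** 2

    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    def test_single_component_not_touching_border(self, seed):
        mask = gen_domain_mask(GRID, SyntheticDomainSpec(350.0, 0.3, 8, seed=seed))
        assert mask.n_components() == 1
        assert not mask.touches_border()

    def test_oversized_blob_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            gen_domain_mask(GRID, SyntheticDomainSpec(460.0, 0.3, 8, seed=0))

    def test_invalid_roughness_rejected(self):
        with pytest.raises(ValueError):
            SyntheticDomainSpec(300.0, boundary_roughness=1.0)


class TestHexLattice:
    def test_interior_points_have_six_neighbors(self, perfect_lattice):
        lat = perfect_lattice
        assert lat.ground_truth_interior.sum() > 0
        assert (lat.ground_truth_neighbor_counts[lat.ground_truth_interior] == 6).all()
        assert lat.defect_proportion() == 0.0

    def test_interior_nearest_neighbor_distances_equal_spacing(self, perfect_lattice):
        pts = perfect_lattice.points
        interior = perfect_lattice.ground_truth_interior
        d2 = ((pts[None] - pts[:, None]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        nn = np.sqrt(d2.min(axis=1))
        assert np.allclose(nn[interior], 60.0, rtol=1e-9)

    def test_jittered_lattice_mode_still_six(self, jittered_lattice):
        counts = jittered_lattice.ground_truth_neighbor_counts[
            jittered_lattice.ground_truth_interior
        ]
        assert np.bincount(counts).argmax() == 6

    def test_determinism(self):
        a = gen_hex_lattice(60.0, 300.0, jitter_sd=3.0, seed=9)
        b = gen_hex_lattice(60.0, 300.0, jitter_sd=3.0, seed=9)
        assert np.array_equal(a.points, b.points)
        assert np.array_equal(
            a.ground_truth_neighbor_counts, b.ground_truth_neighbor_counts
        )

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            gen_hex_lattice(60.0, 100.0)  # extent < 4*spacing
        with pytest.raises(ValueError):
            gen_hex_lattice(60.0, 300.0, jitter_sd=-1.0)


class TestPlantDefects:
    def test_no_defects_is_identity_on_points(self, perfect_lattice):
        out = plant_defects(perfect_lattice, 0, 0, 0.0, seed=1)
        assert np.array_equal(out.points, perfect_lattice.points)
        assert out.defect_proportion() == 0.0

    def test_interstitial_raises_defect_proportion(self, interstitial_lattice):
        assert interstitial_lattice.defect_proportion() > 0.0

    def test_vacancy_raises_defect_proportion(self, vacancy_lattice):
        assert vacancy_lattice.defect_proportion() > 0.0

    def test_void_removes_points_and_no_edge_crosses_it(self, perfect_lattice):
        out = plant_defects(perfect_lattice, void_radius=120.0, seed=2)
        assert out.n < perfect_lattice.n
        (kind, center) = out.planted_defects[-1]
        assert kind == "void"
        edges, _, _ = reference_analysis(out.points)
        # no surviving edge may pass through the void center region
        a, b = out.points[edges[:, 0]], out.points[edges[:, 1]]
        mid = 0.5 * (a + b)
        assert (np.linalg.norm(mid - np.array(center), axis=1) > 30.0).all()

    def test_excessive_removals_rejected(self, perfect_lattice):
        n_int = int(perfect_lattice.ground_truth_interior.sum())
        with pytest.raises(ValueError):
            plant_defects(perfect_lattice, vacancies=n_int)


class TestReferenceDelaunay:
    def test_triangle(self):
        tri, edges = reference_delaunay(np.array([[0, 0], [1, 0], [0, 1.0]]))
        assert len(tri) == 1 and len(edges) == 3

    def test_square_with_center(self):
        # center connects to all corners; all corner-corner sides are edges
        pts = np.array([[0, 0], [2, 0], [2, 2], [0, 2], [1.0, 1.0 + 1e-6]])
        _, edges = reference_delaunay(pts)
        degrees = np.bincount(edges.ravel(), minlength=5)
        assert degrees[4] == 4

    def test_collinear_rejected(self):
        with pytest.raises(ValueError):
            reference_delaunay(np.array([[0, 0], [1, 0], [2.0, 0]]))


class TestAbundanceTable:
    def test_flat_noiseless_rows_are_constant(self):
        spec = SyntheticAbundanceSpec(
            n_proteins=30,
            trend_fractions=(("flat", 1.0),),
            noise_cv=0.0,
            missing_rate=0.0,
            seed=1,
        )
        table = gen_abundance_table(spec).table
        assert (table.nunique(axis=1) == 1).all()

    def test_noiseless_peak_proteins_peak_at_e13_5(self):
        spec = SyntheticAbundanceSpec(
            n_proteins=50,
            trend_fractions=(("peak", 0.5), ("rise", 0.5)),
            noise_cv=0.0,
            missing_rate=0.0,
            seed=2,
        )
        out = gen_abundance_table(spec)
        peaks = out.table.idxmax(axis=1)
        assert (peaks[out.trends == "peak"] == "E13.5").all()
        assert (peaks[out.trends == "rise"] == "E14.5").all()

    def test_all_missing_gives_all_nan(self):
        spec = SyntheticAbundanceSpec(n_proteins=10, missing_rate=1.0, seed=3)
        table = gen_abundance_table(spec).table
        assert table.isna().all().all()

    def test_determinism_and_structure(self):
        spec = SyntheticAbundanceSpec(n_proteins=40, seed=7)
        a = gen_abundance_table(spec).table
        b = gen_abundance_table(spec).table
        assert a.equals(b)
        assert list(a.columns) == list(TIMEPOINTS)
        assert ((a > 0) | a.isna()).all().all()
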