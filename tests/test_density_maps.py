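"""Difference-map synthesis, map evaluation, H support, voids."""
import numpy as np
import pytest

from ciflint import density_maps as dm
from ciflint import fixtures as fx
from ciflint import model_checks as mc
from ciflint.core import AtomSite, ReflectionSet, StructureModel, UnitCell
from ciflint.reflection_stats import merge_equivalents
from ciflint.symmetry import expand_hall


@pytest.fixture
def small_coefficients(simple_cell):
    return ReflectionSet(
        [[1, 0, 0], [2, 1, 1], [3, 0, 2], [0, 2, 1]],
        [121.0, 25.0, 16.0, 36.0], [1.0] * 4,
        fc2=[100.0, 25.0, 16.0, 49.0],
        phase=[0.0, 45.0, 120.0, -60.0], cell=simple_cell)


class TestDifferenceMap:
    def test_fo_equals_fc_gives_zero_map(self, small_coefficients):
        rs = small_coefficients.replace(fo2=small_coefficients.fc2.copy())
        grid = dm.difference_map(rs, grid_step=0.4)
        assert np.abs(grid.values).max() < 1e-13

    def test_single_coefficient_cosine_wave(self):
        cell = UnitCell(10, 10, 10)
        rs = ReflectionSet([[1, 0, 0]], [121.0], [1.0], fc2=[100.0],
                           phase=[0.0], cell=cell)
        grid = dm.difference_map(rs, grid_step=0.5)
        n = grid.dims[0]
        x = np.arange(n) / n
        expected = 2.0 * (11 - 10) / cell.volume * np.cos(2 * np.pi * x)
        np.testing.assert_allclose(grid.values[:, 0, 0], expected,
                                   atol=1e-12)

    def test_fft_equals_direct_summation(self, small_coefficients):
        grid = dm.difference_map(small_coefficients, grid_step=0.4)
        ref = dm.direct_summation(small_coefficients, grid.dims)
        assert np.abs(grid.values - ref.values).max() < 1e-8

    def test_map_mean_exactly_zero(self, small_coefficients):
        grid = dm.difference_map(small_coefficients, grid_step=0.4)
        assert abs(grid.values.mean()) < 1e-10

    def test_too_coarse_grid_rejected(self, small_coefficients):
        with pytest.raises(dm.MapError, match="too coarse"):
            dm.difference_map(small_coefficients, grid_step=2.0)

    def test_map_symmetry_invariance(self, golden_dataset):
        """Applying a group operator permutes voxels, not values."""
        merged = golden_dataset.merged
        setting = golden_dataset.model.setting
        grid = dm.difference_map(merged, grid_step=0.25)
        op = setting.ops[1]
        dims = grid.dims
        rng = np.random.default_rng(0)
        for _ in range(25):
            idx = tuple(rng.integers(0, d) for d in dims)
            frac = np.array(idx) / np.array(dims)
            img = op.apply(frac) % 1.0
            assert grid.interpolate(img) == pytest.approx(
                grid.values[idx], abs=5e-2)


class TestMapReport:
    def test_zero_map_reports_zeroes(self, golden_model):
        grid = dm.DensityGrid(np.zeros((12, 12, 12)), golden_model.cell)
        rep = dm.map_report(grid, golden_model)
        assert rep.rho_min == rep.rho_max == 0.0
        assert rep.findings == []

    def test_wrong_atom_type_flagged_on_site(self):
        ds = fx.make_dataset(fx.golden_spec(corruption=("wrong_atom_type",)))
        from ciflint.alert_engine import structure_from_block, _reflections_for
        from ciflint.cif_io import extract_embedded, parse_cif
        block = parse_cif(ds.cif).blocks[0]
        model = structure_from_block(block)
        refl, _ = _reflections_for(block, model, extract_embedded(block),
                                   None)
        merged, _ = merge_equivalents(refl, model.setting.rotations,
                                      include_friedel=True)
        grid = dm.difference_map(merged, grid_step=0.2)
        rep = dm.map_report(grid, model)
        flagged = [f for f in rep.findings if f.code == "on_atom_density"]
        assert flagged and "N1" in flagged[0].message

    def test_noise_free_bond_midpoints_zero(self, noise_free_dataset):
        # spherical-atom data contain no bonding density
        model = noise_free_dataset.model
        grid = dm.difference_map(noise_free_dataset.merged, grid_step=0.2)
        bonds = mc.build_connectivity(model)
        rep = dm.map_report(grid, model, bonds)
        assert rep.bond_midpoint_mean == pytest.approx(0.0, abs=1e-6)


class TestHSupport:
    def test_zero_map_all_supported(self, golden_model):
        grid = dm.DensityGrid(np.zeros((10, 10, 10)), golden_model.cell)
        support = dm.h_site_support(grid, golden_model, mode="asis")
        assert support and all(support.values())

    def test_misplaced_h_detected_with_nearby_peak(self):
        ds = fx.make_dataset(fx.golden_spec(corruption=("misplace_h",)))
        from ciflint.alert_engine import structure_from_block, _reflections_for
        from ciflint.cif_io import extract_embedded, parse_cif
        block = parse_cif(ds.cif).blocks[0]
        model = structure_from_block(block)
        refl, _ = _reflections_for(block, model, extract_embedded(block),
                                   None)
        merged, _ = merge_equivalents(refl, model.setting.rotations,
                                      include_friedel=True)
        grid = dm.difference_map(merged, grid_step=0.2)
        support = dm.h_site_support(grid, model, mode="asis")
        assert not all(support.values())
        # the true H position shows as a positive peak ~0.9 A away
        peaks = dm.peak_search(grid, model, threshold=0.15)
        assert peaks
        assert min(p.distance for p in peaks) < 1.2

    def test_omit_mode_supports_real_h(self, golden_dataset):
        # data include H; Fc from a model with H removed -> peaks at H sites
        model = golden_dataset.model
        no_h = StructureModel(cell=model.cell, sites=model.non_h_sites,
                              setting=model.setting,
                              wavelength=model.wavelength)
        sf = fx.structure_factors(no_h, hkl=golden_dataset.unmerged.hkl)
        rs = golden_dataset.unmerged.replace(fc2=sf.fc2, phase=sf.phase)
        merged, _ = merge_equivalents(rs, model.setting.rotations,
                                      include_friedel=True)
        grid = dm.difference_map(merged, grid_step=0.2)
        support = dm.h_site_support(grid, model, mode="omit")
        assert support and all(support.values())


class TestVoids:
    def test_empty_cell_is_one_big_void(self):
        model = StructureModel(cell=UnitCell(10, 10, 10), sites=[],
                               setting=expand_hall("P 1"))
        res = dm.find_voids(model, min_volume=5.0)
        assert len(res.regions) == 1
        assert res.regions[0].volume == pytest.approx(1000.0)

    def test_packed_structure_has_no_void(self, golden_model):
        res = dm.find_voids(golden_model)
        assert res.regions == []

    def test_single_atom_matches_brute_force_oracle(self):
        cell = UnitCell(10, 10, 10)
        model = StructureModel(cell=cell,
                               sites=[AtomSite("C1", "C", (0.5, 0.5, 0.5))],
                               setting=expand_hall("P 1"))
        res = dm.find_voids(model, probe=1.2, grid_step=0.25, min_volume=5.0)
        r = 1.7 + 1.2
        dims = res.dims
        frac = np.indices(dims).reshape(3, -1).T / np.array(dims)
        d = frac - 0.5
        d -= np.round(d)
        free = ((d * 10.0) ** 2).sum(axis=1) > r * r
        assert res.regions[0].voxel_count == int(free.sum())

    def test_void_volume_partitions_cell(self):
        cell = UnitCell(10, 10, 10)
        model = StructureModel(cell=cell,
                               sites=[AtomSite("C1", "C", (0.5, 0.5, 0.5))],
                               setting=expand_hall("P 1"))
        res = dm.find_voids(model, grid_step=0.25, min_volume=0.0)
        total = res.occupied_volume + sum(r.volume for r in res.regions)
        assert total == pytest.approx(cell.volume, rel=1e-12)

    def test_volume_shrinks_with_probe(self):
        cell = UnitCell(10, 10, 10)
        model = StructureModel(cell=cell,
                               sites=[AtomSite("C1", "C", (0.5, 0.5, 0.5))],
                               setting=expand_hall("P 1"))
        vols = [sum(r.volume for r in dm.find_voids(
            model, probe=p, grid_step=0.25, min_volume=0.0).regions)
            for p in (0.8, 1.2, 1.6)]
        assert vols[0] > vols[1] > vols[2]

    def test_periodic_connectivity_wraps(self):
        # an atom at the origin corner blocks all eight cell corners; the
        # remaining free space is a single wrapped region
        cell = UnitCell(8, 8, 8)
        model = StructureModel(cell=cell,
                               sites=[AtomSite("C1", "C", (0.0, 0.0, 0.0))],
                               setting=expand_hall("P 1"))
        res = dm.find_voids(model, grid_step=0.25, min_volume=5.0)
        assert len(res.regions) == 1


class TestElectronCount:
    def test_zero_map_counts_zero(self):
        cell = UnitCell(10, 10, 10)
        model = StructureModel(cell=cell,
                               sites=[AtomSite("C1", "C", (0.1, 0.1, 0.1))],
                               setting=expand_hall("P 1"))
        res = dm.find_voids(model, grid_step=0.25, min_volume=5.0)
        grid = dm.DensityGrid(np.zeros(res.dims), cell)
        assert dm.void_electron_count(res.regions[0], grid) == 0.0

    def test_omitted_water_recovered_within_truncation(self):
        """A 10-electron water deleted from the model of a centrosymmetric
        host leaves its electrons in the difference map; integrating the
        solvent-accessible void recovers them to within the series
        truncation (s_max = 0.65 1/A)."""
        cell = UnitCell(10.0, 10.0, 10.0)
        setting = expand_hall("-P 1")
        host = []
        centre = np.array([0.25, 0.25, 0.25])  # pocket (image at 0.75^3)
        k = 0
        for x in np.arange(0.05, 0.99, 0.28):
            for y in np.arange(0.05, 0.99, 0.28):
                for z in np.arange(0.05, 0.5, 0.28):
                    p = np.array([x, y, z])
                    for c in (centre, 1 - centre):
                        d = p - c
                        d -= np.round(d)
                        if np.linalg.norm(d * 10) < 3.6:
                            break
                    else:
                        d = 2 * p
                        d -= np.round(d)
                        if np.linalg.norm(d * 10) >= 2.0:
                            k += 1
                            host.append(AtomSite(
                                f"C{k}", "C",
                                tuple(round(v, 3) for v in p), uiso=0.03))
        water = [AtomSite("O1w", "O", (0.25, 0.25, 0.25), uiso=0.04),
                 AtomSite("H1w", "H", (0.345, 0.25, 0.25), uiso=0.05),
                 AtomSite("H2w", "H", (0.218, 0.34, 0.25), uiso=0.05)]
        full = StructureModel(cell=cell, sites=host + water, setting=setting,
                              wavelength=0.71073)
        partial = StructureModel(cell=cell, sites=host, setting=setting,
                                 wavelength=0.71073)
        sf_full = fx.structure_factors(full, s_max=0.65, anomalous=False)
        sf_part = fx.structure_factors(partial, hkl=sf_full.hkl,
                                       anomalous=False)
        rs = sf_full.replace(fc2=sf_part.fc2, phase=sf_part.phase)
        merged, _ = merge_equivalents(rs, setting.rotations,
                                      include_friedel=True)
        grid = dm.difference_map(merged, grid_step=0.2)
        voids = dm.find_voids(partial, probe=1.0, min_volume=10.0,
                              dims=grid.dims)
        assert voids.regions
        counts = [dm.void_electron_count(r, grid) for r in voids.regions]
        assert max(counts) == pytest.approx(10.0, rel=0.15)

    def test_count_additive_over_disjoint_voids(self):
        cell = UnitCell(10, 10, 10)
        rng = np.random.default_rng(2)
        grid = dm.DensityGrid(rng.normal(0, 0.1, (20, 20, 20)), cell)
        vox_a = np.argwhere(np.zeros((20, 20, 20)) == 0)[:100]
        vox_b = np.argwhere(np.zeros((20, 20, 20)) == 0)[100:250]
        a = dm.VoidRegion(len(vox_a), 0, (0, 0, 0), vox_a)
        b = dm.VoidRegion(len(vox_b), 0, (0, 0, 0), vox_b)
        ab = dm.VoidRegion(250, 0, (0, 0, 0),
                           np.concatenate([vox_a, vox_b]))
        assert dm.void_electron_count(ab, grid) == pytest.approx(
            dm.void_electron_count(a, grid) + dm.void_electron_count(b, grid))
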