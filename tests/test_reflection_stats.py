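"""Merging, R factors, variance analysis, absolute structure, screens."""
import math

import numpy as np
import pytest

from ciflint import reflection_stats as rst
from ciflint.core import ReflectionSet, UnitCell
from ciflint.reflection_stats import WeightParams
from ciflint.symmetry import expand_hall


class TestResolutionMeasures:
    def test_copper_sphere_in_mo_radiation(self):
        theta, d = rst.resolution_measures(0.65, 0.71073)
        assert theta == pytest.approx(27.5, abs=0.05)
        assert d == pytest.approx(0.77, abs=0.005)

    def test_copper_limit(self):
        assert 1.0 / 1.5418 == pytest.approx(0.65, abs=0.002)

    def test_cu_cutoff_angle(self):
        theta, _ = rst.resolution_measures(0.6, 0.71073)
        assert theta == pytest.approx(25.0, abs=0.3)

    def test_unreachable_resolution(self):
        with pytest.raises(ValueError, match="unreachable"):
            rst.resolution_measures(0.7, 1.5418)


class TestMerging:
    def test_identical_duplicates_rint_zero(self, p21c_setting):
        rs = ReflectionSet([[1, 2, 3], [1, 2, 3]], [50, 50], [2, 2])
        _, rint = rst.merge_equivalents(rs, p21c_setting.laue_rotations)
        assert rint == 0.0

    def test_hand_case_90_110(self, p21c_setting, simple_cell):
        rs = ReflectionSet([[1, 2, 3], [-1, 2, -3]], [90.0, 110.0],
                           [5.0, 5.0], cell=simple_cell, merged=False)
        merged, rint = rst.merge_equivalents(rs, p21c_setting.laue_rotations)
        assert len(merged) == 1
        assert merged.fo2[0] == pytest.approx(100.0)
        assert rint == pytest.approx(0.10)

    def test_rint_invariant_under_reindexing(self, p21c_setting, simple_cell):
        rng = np.random.default_rng(3)
        hkl = rng.integers(-6, 7, (300, 3))
        hkl = hkl[np.any(hkl != 0, axis=1)]
        rs = ReflectionSet(hkl, rng.uniform(10, 100, len(hkl)),
                           rng.uniform(1, 3, len(hkl)), cell=simple_cell,
                           merged=False)
        _, r_ref = rst.merge_equivalents(rs, p21c_setting.laue_rotations)
        for rot in p21c_setting.laue_rotations:
            _, r = rst.merge_equivalents(
                rs.replace(hkl=rs.hkl @ rot), p21c_setting.laue_rotations)
            assert r == pytest.approx(r_ref, abs=1e-12)

    def test_noise_free_fixture_rint_zero(self, noise_free_dataset):
        assert noise_free_dataset.rint == pytest.approx(0.0, abs=1e-12)


class TestWeightsAndRFactors:
    def test_sigma_only_weights(self):
        assert rst.weights(100.0, 5.0, 90.0, WeightParams()) == \
            pytest.approx(1 / 25)

    def test_two_parameter_weight_value(self):
        w = rst.weights(100.0, 5.0, 100.0, WeightParams(0.1, 0.0))
        assert w == pytest.approx(0.008)

    def test_negative_fo2_clamped_only_in_p(self):
        w_neg = rst.weights(-5.0, 2.0, 30.0, WeightParams(0.1, 0.2))
        p = (0.0 + 2 * 30.0) / 3
        assert w_neg == pytest.approx(1 / (4 + (0.1 * p) ** 2 + 0.2 * p))

    def test_three_reflection_hand_case(self):
        rs = ReflectionSet([[1, 0, 0], [2, 0, 0], [3, 0, 0]],
                           [100.0, 81.0, 25.0], [5.0] * 3,
                           fc2=[90.0, 81.0, 30.0])
        rf = rst.r_factors(rs, WeightParams(), n_params=1)
        assert rf.wr2 == pytest.approx(math.sqrt(125 / 17186), rel=1e-12)
        assert rf.goof == pytest.approx(math.sqrt(2.5), rel=1e-12)
        fo = [10.0, 9.0, 5.0]
        fc = [math.sqrt(90), 9.0, math.sqrt(30)]
        r1_hand = sum(abs(a - b) for a, b in zip(fo, fc)) / sum(fo)
        assert rf.r1 == pytest.approx(r1_hand, rel=1e-12)

    def test_perfect_data_all_zero(self, noise_free_dataset):
        rf = rst.r_factors(noise_free_dataset.merged, WeightParams())
        assert rf.r1 == pytest.approx(0.0, abs=1e-12)
        assert rf.wr2 == pytest.approx(0.0, abs=1e-12)

    def test_fixture_reported_values_reproduced(self, golden_dataset):
        from ciflint.cif_io import parse_cif, parse_uncertain
        block = parse_cif(golden_dataset.cif).blocks[0]
        n_par = int(parse_uncertain(
            block.get("_refine_ls_number_parameters")).value)
        rf = rst.r_factors(golden_dataset.merged, WeightParams(), n_par)
        for tag, val in (("_refine_ls_r_factor_gt", rf.r1),
                         ("_refine_ls_wr_factor_ref", rf.wr2),
                         ("_refine_ls_goodness_of_fit_ref", rf.goof)):
            assert parse_uncertain(block.get(tag)).value == \
                pytest.approx(val, abs=1e-4)

    def test_wr2_merged_vs_unmerged_noise_free(self, noise_free_dataset):
        setting = noise_free_dataset.model.setting
        merged, _ = rst.merge_equivalents(
            noise_free_dataset.unmerged, setting.rotations,
            include_friedel=setting.centrosymmetric)
        a = rst.r_factors(merged, WeightParams()).wr2
        b = rst.r_factors(noise_free_dataset.merged, WeightParams()).wr2
        assert a == pytest.approx(b, abs=1e-6)


class TestCompleteness:
    def test_unique_count_matches_enumeration(self):
        cell = UnitCell(10, 10, 10)
        p1 = expand_hall("P 1")
        count = rst.unique_reflection_count(p1, cell, 0.2)
        brute = sum(
            1 for h in range(-5, 6) for k in range(-5, 6)
            for l in range(-5, 6)
            if (h, k, l) != (0, 0, 0)
            and cell.s_of((h, k, l)) <= 0.2 + 1e-12)
        assert count == brute // 2  # Friedel-unique half sphere

    def test_full_set_is_complete(self, golden_dataset):
        prof = rst.completeness_profile(
            golden_dataset.merged, golden_dataset.model.setting,
            golden_dataset.model.cell)
        assert prof.completeness_at_smax == pytest.approx(1.0)
        for shell in prof.shells:
            if shell.possible:
                assert shell.completeness == pytest.approx(1.0)

    def test_truncation_detected_and_cutoff_suggested(self, golden_dataset):
        cell = golden_dataset.model.cell
        setting = golden_dataset.model.setting
        rs = golden_dataset.merged
        keep = cell.s_of(rs.hkl) <= 0.6
        prof = rst.completeness_profile(rs.select(keep), setting, cell,
                                        s_max=0.65)
        assert prof.completeness_at_0_6 == pytest.approx(1.0, abs=0.01)
        assert prof.completeness_at_smax < 0.95
        assert prof.shells[-1].completeness < 0.5  # only the 0.585-0.60 part

    def test_completeness_monotone_in_limit(self, golden_dataset):
        cell = golden_dataset.model.cell
        setting = golden_dataset.model.setting
        rs = golden_dataset.merged
        keep = cell.s_of(rs.hkl) <= 0.5
        vals = []
        for s_max in (0.5, 0.55, 0.6, 0.65):
            prof = rst.completeness_profile(rs.select(keep), setting, cell,
                                            s_max=s_max)
            vals.append(prof.completeness_at_smax)
            assert 0.0 <= vals[-1] <= 1.0
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


class TestVariance:
    def test_perfect_data(self, noise_free_dataset):
        t_res, t_fc = rst.analysis_of_variance(noise_free_dataset.merged,
                                               WeightParams())
        assert t_res.total == len(noise_free_dataset.merged)
        assert t_fc.total == len(noise_free_dataset.merged)
        for b in t_res.bins + t_fc.bins:
            if b.n:
                assert b.k == pytest.approx(1.0, abs=1e-9)
                assert b.goof == pytest.approx(0.0, abs=1e-6)

    def test_doubled_low_order_flagged(self, golden_dataset):
        rs = golden_dataset.merged
        s = rs.s()
        fo2 = np.where(s < np.quantile(s, 0.1), 2 * rs.fo2, rs.fo2)
        t_res, _ = rst.analysis_of_variance(rs.replace(fo2=fo2),
                                            WeightParams())
        assert t_res.bins[0].k == pytest.approx(2.0, abs=0.2)
        assert any(f.code == "variance_k" for f in t_res.findings)


class TestNormalProbability:
    def test_standard_normal_residuals(self):
        rng = np.random.default_rng(7)
        n = 400
        hkl = np.unique(rng.integers(-8, 9, (n, 3)), axis=0)
        hkl = hkl[np.any(hkl != 0, axis=1)]
        fc2 = rng.uniform(10, 200, len(hkl))
        rs = ReflectionSet(hkl, fc2 + rng.normal(0, 4, len(hkl)),
                           np.full(len(hkl), 4.0), fc2=fc2)
        npp = rst.normal_probability(rs, WeightParams())
        assert npp.slope == pytest.approx(1.0, abs=0.1)
        assert npp.intercept == pytest.approx(0.0, abs=0.1)

    def test_zero_residuals_degenerate(self):
        hkl = np.stack([np.arange(1, 21), np.zeros(20, int),
                        np.zeros(20, int)], axis=1)
        rs = ReflectionSet(hkl, np.full(20, 50.0), np.ones(20),
                           fc2=np.full(20, 50.0))
        npp = rst.normal_probability(rs, WeightParams())
        assert npp.degenerate
        assert npp.slope == 0.0

    def test_heavy_tails_more_s_shaped(self):
        rng = np.random.default_rng(11)
        n = 500
        hkl = np.unique(rng.integers(-9, 10, (n, 3)), axis=0)
        hkl = hkl[np.any(hkl != 0, axis=1)]
        fc2 = rng.uniform(10, 200, len(hkl))
        sig = np.full(len(hkl), 4.0)
        normal = ReflectionSet(hkl, fc2 + rng.normal(0, 4, len(hkl)), sig,
                               fc2=fc2)
        heavy = ReflectionSet(hkl, fc2 + 4 * rng.standard_t(2, len(hkl)),
                              sig, fc2=fc2)
        dev_n = rst.normal_probability(normal, WeightParams())
        dev_t = rst.normal_probability(heavy, WeightParams())
        assert dev_t.max_central_deviation > dev_n.max_central_deviation


def _bijvoet_set(x_true, rng, m=150, noise=1.0):
    base = rng.uniform(50, 200, m)
    diff = rng.normal(0, 10, m)
    icp, icm = base + diff / 2, base - diff / 2
    ip = (1 - x_true) * icp + x_true * icm
    im = (1 - x_true) * icm + x_true * icp
    hkl, fo2, sig, fc2 = [], [], [], []
    for i in range(m):
        h = (i + 1, (i % 5) + 1, (i % 7) + 2)
        for hh, io, ic in ((h, ip[i], icp[i]),
                           (tuple(-v for v in h), im[i], icm[i])):
            hkl.append(hh)
            fo2.append(io + (rng.normal(0, noise) if noise else 0.0))
            sig.append(max(noise, 1e-3))
            fc2.append(ic)
    return ReflectionSet(hkl, fo2, sig, fc2=fc2, merged=False)


class TestAbsoluteStructure:
    def test_exact_limits(self):
        rng = np.random.default_rng(1)
        est0 = rst.absolute_structure_estimate(_bijvoet_set(0.0, rng, noise=0))
        assert est0.x == pytest.approx(0.0, abs=1e-12)
        rng = np.random.default_rng(1)
        est1 = rst.absolute_structure_estimate(_bijvoet_set(1.0, rng, noise=0))
        assert est1.x == pytest.approx(1.0, abs=1e-12)
        assert est1.decision == "invert"

    def test_parameter_recovery_x03(self):
        rng = np.random.default_rng(7)
        est = rst.absolute_structure_estimate(_bijvoet_set(0.3, rng))
        assert abs(est.x - 0.3) < 3 * est.su

    def test_equivariance_under_model_inversion(self):
        rng = np.random.default_rng(3)
        rs = _bijvoet_set(0.2, rng)
        est = rst.absolute_structure_estimate(rs)
        # inverting the model swaps the calculated Friedel intensities
        flipped = {}
        for i, h in enumerate(map(tuple, rs.hkl.tolist())):
            flipped[h] = i
        fc2_inv = rs.fc2.copy()
        for h, i in flipped.items():
            j = flipped[tuple(-v for v in h)]
            fc2_inv[i] = rs.fc2[j]
        est_inv = rst.absolute_structure_estimate(rs.replace(fc2=fc2_inv))
        assert est_inv.x == pytest.approx(1.0 - est.x, abs=1e-6)

    def test_centrosymmetric_not_estimable(self):
        hkl = [(1, 0, 0), (-1, 0, 0), (2, 1, 0), (-2, -1, 0)]
        rs = ReflectionSet(hkl, [50, 50, 30, 30], [1] * 4,
                           fc2=[50, 50, 30, 30], merged=False)
        with pytest.raises(ValueError, match="not estimable"):
            rst.absolute_structure_estimate(rs)


class TestFabricationScreen:
    def test_exact_sigma_function_suspicious(self):
        rng = np.random.default_rng(5)
        i = rng.uniform(5, 500, 200)
        rs = ReflectionSet(rng.integers(-9, 10, (200, 3)), i,
                           0.02 * i + 1.0)
        assert rst.fabrication_screen(rs).verdict == "suspicious"

    def test_counting_statistics_unremarkable(self):
        rng = np.random.default_rng(5)
        i = rng.uniform(5, 500, 200)
        sig = np.sqrt(1 + 0.05 * i) * rng.uniform(0.8, 1.2, 200)
        rs = ReflectionSet(rng.integers(-9, 10, (200, 3)), i, sig)
        assert rst.fabrication_screen(rs).verdict == "unremarkable"

    def test_small_sets_not_assessed(self):
        rs = ReflectionSet(np.ones((10, 3), int), np.full(10, 5.0),
                           np.ones(10))
        assert rst.fabrication_screen(rs).verdict == "not_assessed"
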