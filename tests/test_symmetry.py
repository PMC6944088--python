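"""Hall expansion, group axioms, site symmetry, codes and absences."""
import numpy as np
import pytest
from fractions import Fraction
from hypothesis import given, strategies as st

from ciflint import symmetry as sym
from ciflint.core import ReflectionSet, UnitCell
from ciflint.symmetry import (HallError, SymmCodeError, decode_symmcode,
                              encode_symmcode, expand_hall, ops_from_triplets,
                              setting_from_ops, site_symmetry)

SAMPLE_HALLS = ["P 1", "-P 1", "P 2yb", "-P 2yn", "-P 2ybc", "C 2y",
                "P 2 2ab -1ab", "-P 4 2 3", "R 3 -2\"", "P 61 2 (0 0 -1)",
                "-F 4 2 3", "P 32 2\""]


class TestHallExpansion:
    def test_p21_n_generators(self):
        # origin on the inversion centre: -x,-y,-z and the n-glide screw
        setting = expand_hall("-P 2yn")
        trips = set(setting.triplets())
        assert "-x,-y,-z" in trips
        assert "-x+1/2,y+1/2,-z+1/2" in trips
        assert setting.nsym == 4

    def test_p1_is_identity_only(self):
        setting = expand_hall("P 1")
        assert setting.nsym == 1
        assert setting.ops[0].is_identity

    def test_p21c_matches_brute_force_closure(self):
        # independent closure oracle over the four listed generators
        gens = ops_from_triplets(
            ["x,y,z", "-x,y+1/2,-z+1/2", "-x,-y,-z", "x,-y+1/2,z+1/2"])
        oracle = setting_from_ops(gens)
        assert expand_hall("-P 2ybc").canonical_key() == oracle.canonical_key()

    @pytest.mark.parametrize("hall", SAMPLE_HALLS)
    def test_group_axioms(self, hall):
        setting = expand_hall(hall)
        ops = set(setting.ops)
        assert sym.SymOp.identity() in ops
        for g in setting.ops:
            assert g.inverse() in ops
            for h in setting.ops:
                assert g * h in ops
            assert abs(g.det) == 1

    @pytest.mark.parametrize("hall", SAMPLE_HALLS)
    def test_expansion_agrees_with_gemmi(self, hall):
        import gemmi

        mine = {(tuple(tuple(v * 24 for v in row) for row in op.rot),
                 tuple((Fraction(t) % 1) for t in op.tran))
                for op in expand_hall(hall).ops}
        ref = {(tuple(tuple(r) for r in op.rot),
                tuple(Fraction(v, 24) % 1 for v in op.tran))
               for op in gemmi.symops_from_hall(hall)}
        assert mine == ref

    @pytest.mark.parametrize("bad", ["", "Q 2", "-P 9", "P 2yq", "P 2 (0 0"])
    def test_malformed_symbols_rejected(self, bad):
        with pytest.raises(HallError):
            expand_hall(bad)

    def test_crystal_systems(self):
        for hall, system in [("P 1", "triclinic"), ("-P 2y", "monoclinic"),
                             ("P 2 2", "orthorhombic"), ("-P 4", "tetragonal"),
                             ("P 3", "trigonal"), ("-P 6", "hexagonal"),
                             ("-P 4 2 3", "cubic")]:
            assert expand_hall(hall).crystal_system == system


class TestConsistency:
    def test_consistent_block_has_no_findings(self, simple_cell):
        setting = expand_hall("-P 2ybc")
        cell = UnitCell(8, 9, 10, 90, 102, 90,
                        su=(0.001,) * 3 + (0.01,) * 3)
        findings = sym.check_symmetry_consistency(
            cell, setting, hm="P 21/c", hall="-P 2ybc",
            listed_ops=setting.ops)
        assert findings == []

    def test_metric_violation_beyond_3su(self):
        setting = expand_hall("-P 2ybc")
        cell = UnitCell(8, 9, 10, 90.20, 102, 90,
                        su=(0.001,) * 3 + (0.02,) * 3)  # deviation = 10 su
        codes = [f.code for f in sym.check_symmetry_consistency(
            cell, setting, hm="P 21/c", hall="-P 2ybc")]
        assert "cell_system_mismatch" in codes

    def test_operator_set_mismatch_detected(self):
        setting = expand_hall("-P 2yn")
        listed = ops_from_triplets(["x,y,z", "-x+1/2,y+1/2,-z+1/2"])
        codes = [f.code for f in sym.check_symmetry_consistency(
            None, setting, hall="-P 2yn", hm="P 21/n", listed_ops=listed)]
        assert "ops_mismatch" in codes

    def test_hm_hall_mismatch(self):
        codes = [f.code for f in sym.check_symmetry_consistency(
            None, None, hm="P 21/c", hall="-P 2yn")]
        assert "hm_hall_mismatch" in codes

    def test_untabulated_hall_skips_hm_comparison(self):
        codes = [f.code for f in sym.check_symmetry_consistency(
            None, None, hm="P 21/c", hall="P 2ybc")]
        assert "hm_hall_not_checked" in codes
        assert "hm_hall_mismatch" not in codes


class TestSiteSymmetry:
    def test_inversion_centre_sof_half(self, simple_cell):
        info = site_symmetry((0, 0, 0), 1.0, expand_hall("-P 2ybc"),
                             simple_cell)
        assert (info.sso, info.ssm, info.sof) == (2, 2, 0.5)

    def test_general_position(self, simple_cell):
        info = site_symmetry((0.13, 0.27, 0.41), 1.0,
                             expand_hall("-P 2ybc"), simple_cell)
        assert (info.sso, info.sof) == (1, 1.0)

    def test_twofold_axis_in_8op_group(self):
        # C2/c: atom on the two-fold at (0, y, 1/4)
        setting = expand_hall("-C 2yc")
        cell = UnitCell(12, 9, 11, 90, 100, 90)
        info = site_symmetry((0.0, 0.31, 0.25), 0.5, setting, cell)
        assert setting.nsym == 8
        assert (info.sso, info.ssm) == (2, 4)
        assert info.sof == pytest.approx(0.25)
        # sso equals the count of coincident images, by an independent count
        images = {tuple(np.round(op.apply((0.0, 0.31, 0.25)) % 1, 6))
                  for op in setting.ops}
        assert len(images) == info.ssm

    def test_sso_ssm_product_every_site(self, golden_model):
        setting = golden_model.setting
        for site in golden_model.sites:
            info = site_symmetry(site.xyz, site.occupancy, setting,
                                 golden_model.cell)
            assert info.sso * info.ssm == setting.nsym
            assert info.sof * info.sso == pytest.approx(site.occupancy)


class TestSymmCodes:
    def test_paper_examples(self):
        assert encode_symmcode(1, (2, 0, -1)) == "1_754"
        assert encode_symmcode(1, (0, 0, 0)) == "1_555"
        code = decode_symmcode("1_555")
        assert (code.op_index, code.uvw) == (1, (0, 0, 0))

    def test_out_of_range_translation(self):
        with pytest.raises(SymmCodeError, match="-5 to 4"):
            encode_symmcode(1, (5, 0, 0))
        encode_symmcode(1, (4, -5, 0))  # boundary values representable

    def test_multidigit_codes_rejected(self):
        with pytest.raises(SymmCodeError):
            decode_symmcode("1_5555")

    @given(op=st.integers(1, 4),
           uvw=st.tuples(*[st.integers(-5, 4)] * 3))
    def test_decode_encode_identity(self, op, uvw):
        code = decode_symmcode(encode_symmcode(op, uvw))
        assert (code.op_index, code.uvw) == (op, uvw)


class TestAbsences:
    def test_p21c_zones(self, p21c_setting):
        assert sym.extinct_mask([(0, 3, 0)], p21c_setting)[0]
        assert not sym.extinct_mask([(0, 2, 0)], p21c_setting)[0]
        assert sym.extinct_mask([(1, 0, 3)], p21c_setting)[0]
        assert not sym.extinct_mask([(1, 0, 2)], p21c_setting)[0]
        conditions = sym.absence_conditions(p21c_setting, 6)
        assert "0k0: k = 2n" in conditions
        assert "h0l: l = 2n" in conditions

    def test_p1_never_extinct(self):
        p1 = expand_hall("P 1")
        rng = np.random.default_rng(0)
        hkl = rng.integers(-6, 7, (100, 3))
        assert not sym.extinct_mask(hkl, p1).any()
        assert sym.absence_conditions(p1) == []

    def test_extinct_structure_factors_vanish(self, noise_free_dataset):
        # brute-force oracle: |F| < 1e-8 wherever the predicate says extinct
        rs = noise_free_dataset.unmerged
        mask = sym.extinct_mask(rs.hkl, noise_free_dataset.model.setting)
        assert mask.any()
        assert np.abs(rs.fc2[mask]).max() < 1e-8

    def test_injected_violation_flagged(self, p21c_setting, simple_cell):
        hkl = [(0, 3, 0), (0, 2, 0), (1, 2, 1)]
        rs = ReflectionSet(hkl, [250.0, 100.0, 90.0], [5.0, 5.0, 5.0],
                           cell=simple_cell, merged=False)
        viols = sym.absence_violations(rs, p21c_setting, nsigma=3)
        assert [v[0] for v in viols] == [(0, 3, 0)]


def test_standard_table_expands_to_230_types():
    halls = {r["number"]: r["hall"] for r in sym.standard_hall_table()
             if r["is_standard"]}
    assert len(halls) == 230
    keys = {expand_hall(h).canonical_key() for h in halls.values()}
    assert len(keys) == 230
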