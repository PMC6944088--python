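"""Formula arithmetic, Hirshfeld test, contacts, absorption, ratios."""
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ciflint import elements, model_checks as mc
from ciflint.core import AtomSite, StructureModel, UnitCell
from ciflint.symmetry import expand_hall


class TestFormula:
    def test_ethanol_weight(self):
        assert mc.molecular_weight(mc.parse_formula("C2 H6 O1")) == \
            pytest.approx(46.07, abs=0.01)

    def test_bracketed_solvent_excluded(self):
        fu = mc.parse_formula("C10 H14 N2 [+solvent]")
        assert fu.solvent_note == "+solvent"
        assert set(fu.counts) == {"C", "H", "N"}

    def test_unknown_element(self):
        with pytest.raises(mc.FormulaError, match="unknown element"):
            mc.parse_formula("Xx4")

    def test_empty_formula(self):
        with pytest.raises(mc.FormulaError):
            mc.parse_formula("   ")

    @given(n1=st.integers(1, 20), n2=st.integers(1, 20))
    def test_weight_is_additive(self, n1, n2):
        a = mc.molecular_weight(mc.parse_formula(f"C{n1}"))
        b = mc.molecular_weight(mc.parse_formula(f"N{n2}"))
        both = mc.molecular_weight(mc.parse_formula(f"C{n1} N{n2}"))
        assert both == pytest.approx(a + b, rel=1e-12)


class TestDensity:
    def test_calculated_density_formula(self):
        assert mc.calculated_density(500.0, 4, 46.07) == \
            pytest.approx(0.612, abs=0.001)

    def test_matching_density_passes(self):
        rho = mc.calculated_density(500.0, 4, 46.07)
        assert mc.density_check(500.0, 4, 46.07, rho) is None

    def test_missing_z(self):
        f = mc.density_check(500.0, None, 46.07, 0.6)
        assert f is not None and f.code == "missing_datum"


class TestHirshfeld:
    def test_identical_isotropic_u_gives_zero(self, simple_cell):
        a = AtomSite("C1", "C", (0.1, 0.1, 0.1), uiso=0.04)
        b = AtomSite("C2", "C", (0.25, 0.1, 0.1), uiso=0.04)
        assert mc.hirshfeld_test(a, b, simple_cell).delta == 0.0

    def test_axis_aligned_projection(self):
        cell = UnitCell(10, 11, 12)
        a = AtomSite("C1", "C", (0, 0, 0),
                     uaniso=(0.05, 0.04, 0.04, 0, 0, 0),
                     uaniso_su=(0.001,) * 6)
        b = AtomSite("C2", "C", (0.15, 0, 0),
                     uaniso=(0.03, 0.04, 0.04, 0, 0, 0),
                     uaniso_su=(0.001,) * 6)
        res = mc.hirshfeld_test(a, b, cell)
        assert res.delta == pytest.approx(0.02, abs=1e-12)
        assert res.su == pytest.approx(math.sqrt(2) * 0.001, rel=1e-6)
        assert res.flagged  # 0.02 / 0.0014 >> 5

    def test_random_tensor_matches_numeric_msda_oracle(self):
        rng = np.random.default_rng(42)
        cell = UnitCell(7.3, 8.1, 9.4, 83, 101, 96)
        for _ in range(5):
            L = rng.normal(size=(3, 3)) * 0.08
            ucif = L @ L.T + np.eye(3) * 0.02
            u6 = (ucif[0, 0], ucif[1, 1], ucif[2, 2],
                  ucif[1, 2], ucif[0, 2], ucif[0, 1])
            xa = rng.uniform(0, 1, 3)
            xb = xa + rng.uniform(0.08, 0.15, 3)
            a = AtomSite("N1", "N", tuple(xa), uaniso=u6)
            b = AtomSite("C1", "C", tuple(xb), uiso=0.04)
            res = mc.hirshfeld_test(a, b, cell)
            # oracle: project the Cartesian U tensor on the bond direction
            O = cell.orthogonalization
            N = np.diag(np.sqrt(np.diag(cell.reciprocal_metric)))
            ucart = O @ N @ ucif @ N @ O.T
            d = xb - xa
            d -= np.round(d)
            bond = cell.cartesian(d)
            u = bond / np.linalg.norm(bond)
            assert res.delta == pytest.approx(abs(u @ ucart @ u - 0.04),
                                              abs=1e-12)

    def test_swapping_atoms_is_symmetric(self, simple_cell):
        a = AtomSite("C1", "C", (0.1, 0.2, 0.3),
                     uaniso=(0.05, 0.03, 0.06, 0.01, -0.01, 0.0))
        b = AtomSite("O1", "O", (0.2, 0.3, 0.35), uiso=0.03)
        assert mc.hirshfeld_test(a, b, simple_cell).delta == \
            pytest.approx(mc.hirshfeld_test(b, a, simple_cell).delta)

    def test_zero_length_bond_rejected(self, simple_cell):
        a = AtomSite("C1", "C", (0.1, 0.1, 0.1), uiso=0.03)
        with pytest.raises(ValueError, match="zero-length"):
            mc.hirshfeld_test(a, a, simple_cell)


def _two_molecule_model(d_oo: float, element="O", cell_len=20.0):
    """Two isolated species a chosen distance apart in a P1 box."""
    cell = UnitCell(cell_len, cell_len, cell_len)
    sep = d_oo / cell_len
    sites = [
        AtomSite("A1", element, (0.25, 0.25, 0.25)),
        AtomSite("B1", element, (0.25 + sep, 0.25, 0.25)),
    ]
    return StructureModel(cell=cell, sites=sites,
                          setting=expand_hall("P 1"))


class TestContacts:
    def test_short_o_o_classified_missing_h(self):
        model = _two_molecule_model(2.45)
        contacts = mc.short_contacts(model)
        assert len(contacts) == 1
        assert contacts[0].kind == "missing_h"

    def test_cl_cl_at_330_is_informational(self):
        model = _two_molecule_model(3.30, element="Cl")
        contacts = mc.short_contacts(model)
        assert [c.kind for c in contacts] == ["halogen"]

    def test_far_pair_reports_nothing(self):
        vdw = 2 * elements.vdw_radius("O")
        model = _two_molecule_model(vdw + 1.0)
        assert mc.short_contacts(model) == []

    def test_contacts_reported_once(self, golden_model):
        contacts = mc.short_contacts(golden_model)
        keys = [(min(c.i, c.j), max(c.i, c.j), round(c.length, 4))
                for c in contacts]
        assert len(keys) == len(set(keys))

    def test_disordered_site_marked(self):
        model = _two_molecule_model(2.45)
        model.sites[0].disordered = True
        assert mc.short_contacts(model)[0].involves_disorder


class TestCentreOfGravity:
    def test_inside_passes(self, golden_model):
        assert mc.centre_of_gravity_check(golden_model) == []

    def test_translated_species_flagged_with_shift(self, golden_model):
        from dataclasses import replace
        moved = StructureModel(
            cell=golden_model.cell,
            sites=[replace(s, xyz=(s.xyz[0] + 1.0, s.xyz[1], s.xyz[2]))
                   for s in golden_model.sites],
            setting=golden_model.setting)
        findings = mc.centre_of_gravity_check(moved)
        assert len(findings) == 1
        assert findings[0].code == "centroid_outside"
        assert "(-1, 0, 0)" in findings[0].message

    def test_small_species_exempt(self):
        cell = UnitCell(10, 10, 10)
        water = StructureModel(
            cell=cell,
            sites=[AtomSite("O1", "O", (1.05, 0.5, 0.5)),
                   AtomSite("H1", "H", (1.10, 0.55, 0.5)),
                   AtomSite("H2", "H", (1.10, 0.45, 0.5))],
            setting=expand_hall("P 1"))
        findings = mc.centre_of_gravity_check(water)
        assert [f.code for f in findings] == ["centroid_small_species"]


class TestAbsorption:
    def test_massless_limit(self):
        tmin, tmax = mc.expected_transmission_range(0.0, 0.1, 0.4)
        assert (tmin, tmax) == (1.0, 1.0)

    def test_closed_form_range(self):
        tmin, tmax = mc.expected_transmission_range(0.5, 0.1, 0.4)
        assert tmin == pytest.approx(math.exp(-0.2), rel=1e-12)
        assert tmax == pytest.approx(math.exp(-0.05), rel=1e-12)

    def test_implausibly_narrow_range_flagged(self):
        findings = mc.transmission_range_findings(0.5, (0.1, 0.4),
                                                  (0.99, 1.00))
        assert [f.code for f in findings] == ["transmission_range"]

    def test_consistent_range_passes(self):
        tmin, tmax = mc.expected_transmission_range(0.5, 0.1, 0.4)
        assert mc.transmission_range_findings(0.5, (0.1, 0.4),
                                              (tmin, tmax)) == []

    def test_monotone_in_mu_and_path(self):
        t1 = mc.expected_transmission_range(0.2, 0.1, 0.4)
        t2 = mc.expected_transmission_range(0.4, 0.1, 0.4)
        t3 = mc.expected_transmission_range(0.2, 0.2, 0.8)
        assert t2[0] < t1[0] and t2[1] < t1[1]
        assert t3[0] < t1[0]
        for t in (t1, t2, t3):
            assert 0 < t[0] <= t[1] <= 1


class TestDataParameterRatio:
    @pytest.mark.parametrize("n,p,centro,ratio,level", [
        (2000, 100, False, 20.0, None),
        (500, 100, False, 5.0, "A"),
        (900, 100, True, 9.0, "B"),
        (1100, 100, True, 11.0, "C"),
    ])
    def test_threshold_rules(self, n, p, centro, ratio, level):
        got_ratio, got_level = mc.data_parameter_ratio(n, p, centro)
        assert got_ratio == pytest.approx(ratio)
        assert got_level == level


class TestResonant:
    def test_matching_values_pass(self):
        ref = elements.anomalous("C", elements.MO_KA)
        assert mc.resonant_check({"C": ref}, elements.MO_KA) == []

    def test_factor_ten_fdp_flagged(self):
        fp, fdp = elements.anomalous("Br", elements.MO_KA)
        findings = mc.resonant_check({"Br": (fp, 10 * fdp)}, elements.MO_KA)
        assert any(f.code == "resonant_mismatch" for f in findings)

    def test_far_wavelength_unverified(self):
        findings = mc.resonant_check({"C": (0.0, 0.0)}, 25.0)
        assert [f.code for f in findings] == ["unverified"]
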