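"""Structural-model validation.

Covers formula/Z/density arithmetic, ADP rigid-bond (Hirshfeld) behaviour,
connectivity, short intermolecular contacts, centre-of-gravity placement,
transmission-range plausibility, data-to-parameter ratio and resonant
scattering factors. Everything returns findings; nothing raises on a bad
model, only on unusable input.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import elements
from .core import AtomSite, StructureModel, UnitCell
from .symmetry import Finding

__all__ = [
    "FormulaUnit", "FormulaError", "parse_formula", "molecular_weight",
    "density_check", "HirshfeldResult", "hirshfeld_test",
    "Bond", "Contact", "build_connectivity", "short_contacts",
    "centre_of_gravity_check", "absorption_range_check",
    "data_parameter_ratio", "resonant_check", "linear_absorption_coefficient",
]

AMU_PER_A3_TO_G_CM3 = 1.66054


class FormulaError(ValueError):
    pass


@dataclass
class FormulaUnit:
    counts: Dict[str, float]
    solvent_note: Optional[str] = None


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)\s*(\d+\.?\d*|\.\d+)?")


def parse_formula(text: str) -> FormulaUnit:
    """Parse a sum formula like ``"C10 H14 N2 [+solvent]"``.

    A bracketed trailer records uninterpreted (solvent) content; it
    contributes nothing to the molecular weight or density.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula")
    solvent = None
    m = re.search(r"\[([^\]]*)\]", text)
    if m:
        solvent = m.group(1).strip()
        text = (text[: m.start()] + text[m.end():]).strip()
    counts: Dict[str, float] = {}
    pos = 0
    text = text.replace(",", " ")
    for m in _FORMULA_TOKEN.finditer(text):
        gap = text[pos:m.start()]
        if gap.strip():
            raise FormulaError(f"cannot parse formula near {gap.strip()!r}")
        pos = m.end()
        sym = m.group(1)
        try:
            elements.atomic_number(sym)
        except elements.UnknownElementError:
            raise FormulaError(f"unknown element {sym!r} in formula")
        n = float(m.group(2)) if m.group(2) else 1.0
        if n <= 0:
            raise FormulaError(f"non-positive count for {sym}")
        counts[sym] = counts.get(sym, 0.0) + n
    if text[pos:].strip():
        raise FormulaError(f"cannot parse formula near {text[pos:].strip()!r}")
    if not counts:
        raise FormulaError("formula contains no atoms")
    return FormulaUnit(counts=counts, solvent_note=solvent)


def molecular_weight(fu: FormulaUnit) -> float:
    """Mr in g/mol over the non-bracketed content only."""
    return sum(n * elements.atomic_weight(sym) for sym, n in fu.counts.items())


def density_check(volume: float, z: Optional[int], mr: float,
                  reported: Optional[float], tol: float = 0.01) -> Optional[Finding]:
    """Compare rho_calc = Z Mr 1.66054 / V (g/cm^3) with the reported value."""
    if volume <= 0 or mr <= 0:
        raise ValueError("volume and Mr must be positive")
    if z is None:
        return Finding("missing_datum", "Z (formula units per cell) not reported")
    rho = z * mr * AMU_PER_A3_TO_G_CM3 / volume
    if reported is None:
        return Finding("missing_datum",
                       f"calculated density {rho:.3f} g/cm^3 not reported")
    if abs(rho - reported) > tol:
        return Finding(
            "density_mismatch",
            f"reported density {reported:.3f} g/cm^3 differs from calculated "
            f"{rho:.3f} g/cm^3", value=abs(rho - reported))
    return None


def calculated_density(volume: float, z: int, mr: float) -> float:
    return z * mr * AMU_PER_A3_TO_G_CM3 / volume


# ---------------------------------------------------------------------------
# Hirshfeld rigid-bond test


@dataclass
class HirshfeldResult:
    pair: Tuple[str, str]
    delta: float          # |z_A - z_B| mean-square displacement along bond, A^2
    su: Optional[float]   # propagated from the U su's when available
    z_score: Optional[float]
    flagged: bool


def _msda_coefficients(cell: UnitCell, unit_bond_cart: np.ndarray) -> np.ndarray:
    """m such that u^T U_cart u = sum_ij m_i m_j U_ij (CIF convention U)."""
    gstar = cell.reciprocal_metric
    nstar = np.sqrt(np.diag(gstar))  # a*, b*, c*
    # U_cart = O N U N O^T with N = diag(a*,b*,c*); so the quadratic form in
    # the CIF U is built from m = N O^T u
    return np.diag(nstar) @ cell.orthogonalization.T @ unit_bond_cart


def hirshfeld_test(atom_a: AtomSite, atom_b: AtomSite, cell: UnitCell,
                   threshold_z: float = 5.0) -> HirshfeldResult:
    """Rigid-bond test: mean-square displacement amplitudes of bonded atoms
    projected on the bond should match.

    Isotropic atoms project to Uiso itself. ``flagged`` when
    delta/su > threshold_z (no flag when no su's are available).
    """
    dfrac = np.asarray(atom_b.xyz, dtype=float) - np.asarray(atom_a.xyz, dtype=float)
    dfrac -= np.round(dfrac)
    bond = cell.cartesian(dfrac)
    length = float(np.linalg.norm(bond))
    if length < 1e-6:
        raise ValueError("zero-length bond")
    u = bond / length
    m = _msda_coefficients(cell, u)

    def project(atom: AtomSite) -> Tuple[float, Optional[float]]:
        if not atom.anisotropic:
            return (atom.uiso if atom.uiso is not None else 0.0), None
        umat = atom.u_matrix_cif()
        z = float(m @ umat @ m)
        if atom.uaniso_su is None:
            return z, None
        s11, s22, s33, s23, s13, s12 = atom.uaniso_su
        var = (
            (m[0] * m[0] * s11) ** 2 + (m[1] * m[1] * s22) ** 2
            + (m[2] * m[2] * s33) ** 2 + (2 * m[1] * m[2] * s23) ** 2
            + (2 * m[0] * m[2] * s13) ** 2 + (2 * m[0] * m[1] * s12) ** 2
        )
        return z, var

    za, va = project(atom_a)
    zb, vb = project(atom_b)
    delta = abs(za - zb)
    su = None
    if va is not None or vb is not None:
        su = math.sqrt((va or 0.0) + (vb or 0.0))
    z_score = delta / su if su else None
    flagged = bool(z_score is not None and z_score > threshold_z)
    return HirshfeldResult(pair=(atom_a.label, atom_b.label), delta=delta,
                           su=su, z_score=z_score, flagged=flagged)


def hirshfeld_scan(model: StructureModel, threshold_z: float = 5.0,
                   metal_threshold_z: float = 12.0) -> List[HirshfeldResult]:
    """Run the rigid-bond test over every covalent bond between eligible
    atoms (H and disordered atoms excluded; metal-ligand bonds use the
    relaxed threshold)."""
    bonds = build_connectivity(model)
    out = []
    for bond in bonds:
        a = model.sites[bond.i]
        b = model.sites[bond.j]
        if a.is_h or b.is_h or a.disordered or b.disordered:
            continue
        thr = threshold_z
        if _is_metal(a.element) or _is_metal(b.element):
            thr = metal_threshold_z
        out.append(hirshfeld_test(a, b, model.cell, thr))
    return out


_METALS = set(
    "Li Be Na Mg Al K Ca Sc Ti V Cr Mn Fe Co Ni Cu Zn Ga Rb Sr Y Zr Nb Mo "
    "Tc Ru Rh Pd Ag Cd In Sn Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm "
    "Yb Lu Hf Ta W Re Os Ir Pt Au Hg Tl Pb Bi".split()
)


def _is_metal(symbol: str) -> bool:
    return symbol in _METALS


# ---------------------------------------------------------------------------
# connectivity / contacts


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    length: float
    symmetry: str = "1_555"  # s_uvw code of the image of j


@dataclass
class Contact:
    i: int
    j: int
    length: float
    vdw_sum: float
    kind: str  # h_h | missing_h | halogen | other
    symmetry: str
    involves_disorder: bool = False


_HALOGENS = {"F", "Cl", "Br", "I", "At"}


def build_connectivity(model: StructureModel, tol: float = 0.4) -> List[Bond]:
    """Bonds where d < r_cov(A) + r_cov(B) + tol, within the asymmetric unit
    (nearest periodic image)."""
    sites = model.sites
    out = []
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            cutoff = (elements.covalent_radius(sites[i].element)
                      + elements.covalent_radius(sites[j].element) + tol)
            d = model.cell.distance(sites[i].xyz, sites[j].xyz)
            if 0.0 < d < cutoff:
                out.append(Bond(i, j, d))
    return out


def _components(n: int, bonds: Sequence[Bond]) -> List[List[int]]:
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for b in bonds:
        ra, rb = find(b.i), find(b.j)
        if ra != rb:
            parent[ra] = rb
    comps: Dict[int, List[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    return list(comps.values())


def _classify_contact(ea: str, eb: str) -> str:
    pair = {ea, eb}
    if pair == {"H"}:
        return "h_h"
    if pair == {"O"} or pair == {"O", "N"}:
        return "missing_h"
    if pair <= _HALOGENS:
        return "halogen"
    return "other"


def short_contacts(model: StructureModel, slack: float = 0.2,
                   max_trans: int = 1) -> List[Contact]:
    """Intermolecular approaches shorter than sum(r_vdW) - slack.

    Pairs within the same covalently bonded component (identity images) are
    skipped; symmetry-generated approaches short enough to be bonds
    (polymeric links) are skipped too. Contacts touching a disordered site
    are marked for disorder-model inspection.
    """
    from .symmetry import encode_symmcode

    sites = model.sites
    bonds = build_connectivity(model)
    comp_of = {}
    for ci, comp in enumerate(_components(len(sites), bonds)):
        for idx in comp:
            comp_of[idx] = ci
    setting = model.setting
    ops = setting.ops if setting is not None else []
    out = []
    seen = set()
    trans_range = range(-max_trans, max_trans + 1)
    for i in range(len(sites)):
        xi = np.asarray(sites[i].xyz, dtype=float)
        for j in range(i, len(sites)):
            vdw = (elements.vdw_radius(sites[i].element)
                   + elements.vdw_radius(sites[j].element))
            cov = (elements.covalent_radius(sites[i].element)
                   + elements.covalent_radius(sites[j].element) + 0.4)
            cutoff = vdw - slack + 1e-9
            for op_idx, op in enumerate(ops, start=1):
                img0 = op.apply(sites[j].xyz)
                for tu in trans_range:
                    for tv in trans_range:
                        for tw in trans_range:
                            identity_image = (op.is_identity and
                                              (tu, tv, tw) == (0, 0, 0))
                            if identity_image and comp_of.get(i) == comp_of.get(j):
                                continue
                            img = img0 + (tu, tv, tw)
                            d = float(np.linalg.norm(
                                model.cell.cartesian(img - xi)))
                            if d < 1e-3 or d > cutoff:
                                continue
                            if d < cov:
                                continue  # a (polymeric) bond, not a contact
                            key = (min(i, j), max(i, j), round(d, 4))
                            if key in seen:
                                continue
                            seen.add(key)
                            try:
                                code = encode_symmcode(op_idx, (tu, tv, tw))
                            except Exception:
                                code = f"{op_idx}_?"
                            out.append(Contact(
                                i=i, j=j, length=d, vdw_sum=vdw,
                                kind=_classify_contact(sites[i].element,
                                                       sites[j].element),
                                symmetry=code,
                                involves_disorder=(sites[i].disordered
                                                   or sites[j].disordered)))
    out.sort(key=lambda c: c.length)
    return out


def centre_of_gravity_check(model: StructureModel,
                            small_species_atoms: int = 3) -> List[Finding]:
    """Each connected species should have its (unweighted) centroid inside
    [0,1)^3; small species (<= 3 non-H atoms) get a G-level note only."""
    bonds = build_connectivity(model)
    findings = []
    for comp in _components(len(model.sites), bonds):
        xyz = np.array([model.sites[i].xyz for i in comp], dtype=float)
        centroid = xyz.mean(axis=0)
        outside = (centroid < 0) | (centroid >= 1)
        if not outside.any():
            continue
        shift = tuple(int(-math.floor(c)) for c in centroid)
        n_heavy = sum(1 for i in comp if not model.sites[i].is_h)
        labels = ",".join(model.sites[i].label for i in comp[:4])
        msg = (f"species [{labels}{'...' if len(comp) > 4 else ''}] has "
               f"centre of gravity ({centroid[0]:.2f},{centroid[1]:.2f},"
               f"{centroid[2]:.2f}) outside the unit cell; suggested "
               f"translation {shift}")
        if n_heavy <= small_species_atoms:
            findings.append(Finding("centroid_small_species", msg + " (small "
                                    "species, e.g. water/counter-ion: note only)"))
        else:
            findings.append(Finding("centroid_outside", msg))
    return findings


# ---------------------------------------------------------------------------
# absorption


def linear_absorption_coefficient(fu: FormulaUnit, z: int, volume: float,
                                  wavelength: float) -> float:
    """mu in 1/mm from the cell content (photoabsorption, optical theorem)."""
    sigma_sum = 0.0  # A^2 per formula unit
    for sym, n in fu.counts.items():
        sigma_sum += n * elements.mu_per_atom(sym, wavelength)
    # atoms per cell = z * counts; mu = number density * sigma
    mu_per_angstrom = z * sigma_sum / volume  # 1/A
    return mu_per_angstrom * 1e7  # 1/mm


def expected_transmission_range(mu_mm: float, dim_min: float,
                                dim_max: float) -> Tuple[float, float]:
    """(Tmin, Tmax) expected for path lengths spanning the crystal dims."""
    return math.exp(-mu_mm * dim_max), math.exp(-mu_mm * dim_min)


def absorption_range_check(
    fu: FormulaUnit, z: Optional[int], volume: float, wavelength: float,
    dims: Optional[Tuple[float, float]], reported: Optional[Tuple[float, float]],
    factor: float = 2.0,
) -> List[Finding]:
    """Compare the reported Tmin/Tmax with exp(-mu t) over the crystal size.

    The test is a plausibility ratio on the absorbed fraction (1 - T) with a
    default factor of 2 either way.
    """
    if dims is None or z is None:
        return [Finding("cannot_assess",
                        "crystal dimensions or Z missing: transmission range "
                        "not assessed")]
    try:
        mu = linear_absorption_coefficient(fu, z, volume, wavelength)
    except (ValueError, elements.UnknownElementError) as exc:
        return [Finding("cannot_assess", f"mu not computable: {exc}")]
    return transmission_range_findings(mu, dims, reported, factor)


def transmission_range_findings(mu: float, dims: Tuple[float, float],
                                reported: Optional[Tuple[float, float]],
                                factor: float = 2.0) -> List[Finding]:
    """Ratio test on the absorbed fraction 1 - T at a given mu (1/mm)."""
    t_min_exp, t_max_exp = expected_transmission_range(mu, min(dims), max(dims))
    findings = []
    if reported is None:
        return [Finding("missing_datum",
                        f"no transmission range reported (expected about "
                        f"{t_min_exp:.3f}-{t_max_exp:.3f} for mu={mu:.3f}/mm)")]
    rep_min, rep_max = min(reported), max(reported)
    absorbed_exp = max(1.0 - t_min_exp, 1e-6)
    absorbed_rep = max(1.0 - rep_min, 1e-6)
    ratio = absorbed_rep / absorbed_exp
    if ratio < 1.0 / factor:
        findings.append(Finding(
            "transmission_range",
            f"reported transmission range {rep_min:.3f}-{rep_max:.3f} is "
            f"implausibly narrow for mu={mu:.3f}/mm and crystal size "
            f"{min(dims):.2f}-{max(dims):.2f} mm (expected "
            f"{t_min_exp:.3f}-{t_max_exp:.3f})", value=ratio))
    elif ratio > factor:
        findings.append(Finding(
            "transmission_range",
            f"reported transmission range {rep_min:.3f}-{rep_max:.3f} is "
            f"much wider than expected {t_min_exp:.3f}-{t_max_exp:.3f} "
            f"(mu={mu:.3f}/mm)", value=ratio))
    return findings


# ---------------------------------------------------------------------------
# data/parameter ratio and resonant scattering

_NP_THRESHOLDS = {
    False: ((6.0, "A"), (8.0, "B"), (10.0, "C")),   # non-centrosymmetric
    True: ((8.0, "A"), (10.0, "B"), (12.0, "C")),   # centrosymmetric
}


def data_parameter_ratio(n_reflections: int, n_params: int,
                         centrosymmetric: bool,
                         thresholds=None) -> Tuple[float, Optional[str]]:
    """N:p ratio with the level of the finding it triggers (None = pass).

    N is the count of Laue-group-averaged reflections.
    """
    if n_reflections <= 0 or n_params <= 0:
        raise ValueError("counts must be positive")
    ratio = n_reflections / n_params
    table = thresholds or _NP_THRESHOLDS[bool(centrosymmetric)]
    for limit, level in table:
        if ratio < limit:
            return ratio, level
    return ratio, None


def resonant_check(reported: Dict[str, Tuple[float, float]],
                   wavelength: float) -> List[Finding]:
    """Check reported f'/f'' per element against the computed values.

    Tolerance: max(0.1, 10% of the table value). Wavelengths outside the
    range of the anomalous tables degrade to an 'unverified' note.
    """
    findings = []
    for sym, (fp_rep, fdp_rep) in sorted(reported.items()):
        try:
            table = elements.anomalous(sym, wavelength)
        except elements.UnknownElementError:
            findings.append(Finding("unverified",
                                    f"unknown element {sym!r}: f'/f'' unverified"))
            continue
        if table is None:
            findings.append(Finding(
                "unverified",
                f"wavelength {wavelength} A outside anomalous tables: "
                f"f'/f'' for {sym} unverified"))
            continue
        for name, rep, ref in (("f'", fp_rep, table[0]), ("f''", fdp_rep, table[1])):
            tol = max(0.1, 0.1 * abs(ref))
            if abs(rep - ref) > tol:
                findings.append(Finding(
                    "resonant_mismatch",
                    f"{sym} {name} = {rep:.3f} deviates from expected "
                    f"{ref:.3f} at {wavelength} A", value=abs(rep - ref)))
    return findings
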