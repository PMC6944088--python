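"""Synthetic structures and reflection data for exercising every check.

The generator builds a random connected molecule in the asymmetric unit of
a requested space group, computes exact spherical-atom structure factors

    F(h) = sum_sites occ * (f0(s) + f' + i f'') * exp(-8 pi^2 U s^2)
           * sum_ops exp(2 pi i (R x + t) . h),

and derives observed data under a counting-statistics noise model
sigma^2(I) = sigma0^2 + k I. Deliberate corruptions (stripped inversion,
wrong atom type, misplaced H, twinning, inverted structure, fabricated
sigmas, edited embedded payloads, inflated low-order data) emulate the
failure modes the validation checks are designed to catch.

Everything is reproducible: the same spec yields identical bytes.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import elements
from .cif_io import (CifDocument, DataBlock, reference_checksum, write_cif,
                     write_reflections)
from .core import AtomSite, ReflectionSet, StructureModel, UnitCell
from .model_checks import calculated_density, molecular_weight, parse_formula
from .symmetry import expand_hall

__all__ = [
    "SyntheticSpec", "PackingError", "generate_structure",
    "structure_factors", "make_dataset",
]


@dataclass(frozen=True)
class SyntheticSpec:
    hall: str = "-P 2ybc"
    hm: Optional[str] = "P 21/c"
    cell: Tuple[float, ...] = (8.0, 9.0, 10.0, 90.0, 101.0, 90.0)
    elements_list: Tuple[str, ...] = ("C", "C", "C", "C", "N", "O")
    n_h: int = 4
    s_max: float = 0.65
    wavelength: float = 0.71073
    sigma0: float = 0.5
    k_noise: float = 0.02
    corruption: Tuple = ("none",)
    seed: int = 0


class PackingError(RuntimeError):
    pass


def golden_spec(seed: int = 7, **kw) -> SyntheticSpec:
    """Well-packed centrosymmetric (P2_1/c) structure: the golden path."""
    return SyntheticSpec(seed=seed, **kw)


def chiral_spec(seed: int = 2, corruption: Tuple = ("none",),
                resonant: bool = False, **kw) -> SyntheticSpec:
    """Well-packed non-centrosymmetric (P2_1) structure with a beta ~ 90
    deg cell (pseudo-merohedral-twin prone). ``resonant`` swaps a carbon
    for sulfur so Bijvoet differences carry absolute-structure signal."""
    els = ("C", "C", "C", "C", "C", "S" if resonant else "C", "N", "O")
    return SyntheticSpec(hall="P 2yb", hm="P 21",
                         cell=(7.0, 8.0, 8.5, 90.0, 90.2, 90.0),
                         elements_list=els, n_h=6, seed=seed,
                         corruption=corruption, **kw)


_BOND_LENGTH = {"H": 1.0}


def _rng(spec: SyntheticSpec) -> np.random.Generator:
    return np.random.default_rng(spec.seed)


def _place_molecule(spec: SyntheticSpec, rng) -> List[AtomSite]:
    """Grow a connected chain, rejecting overlaps with self and images."""
    cell = UnitCell(*spec.cell)
    setting = expand_hall(spec.hall)
    symbols = list(spec.elements_list) + ["H"] * spec.n_h
    for attempt in range(60):
        sites: List[AtomSite] = []
        coords: List[np.ndarray] = []
        ok = True
        for ai, sym in enumerate(symbols):
            placed = False
            for _ in range(250):
                base_idx = None
                if not coords:
                    cand = np.array([0.15, 0.15, 0.15]) + rng.uniform(0, 0.1, 3)
                else:
                    # hydrogens attach to the heavy skeleton; heavies chain on
                    if sym == "H":
                        base_idx = int(rng.integers(0, len(spec.elements_list)))
                    else:
                        base_idx = max(0, len(coords) - 1 -
                                       int(rng.integers(0, min(2, len(coords)))))
                    base = coords[base_idx]
                    length = _BOND_LENGTH.get(sym, 1.5)
                    v = rng.normal(size=3)
                    v *= length / np.linalg.norm(v)
                    cand = base + cell.fractionalization @ v
                clash = False
                for oi, other in enumerate(coords):
                    if oi == base_idx:
                        continue
                    min_sep = 0.9 if (sym == "H" or symbols[oi] == "H") else 1.2
                    if cell.distance(cand, other, min_image=False) < min_sep:
                        clash = True
                        break
                if clash:
                    continue
                # clashes with symmetry images and wrapped periodic images:
                # images must respect van der Waals separations so the
                # golden structure carries no short intermolecular contacts
                all_pts = coords + [cand]
                r_cand = elements.vdw_radius(sym)
                for op in setting.ops:
                    img = op.apply(cand)
                    for oi, xo in enumerate(all_pts):
                        osym = symbols[oi] if oi < len(symbols) else sym
                        min_sep = r_cand + elements.vdw_radius(osym) - 0.1
                        d = img - xo
                        d -= np.round(d)
                        dist = float(np.linalg.norm(cell.cartesian(d)))
                        if op.is_identity:
                            direct = float(np.linalg.norm(
                                cell.cartesian(img - xo)))
                            # only a *wrapped* image can clash here
                            if dist < min_sep and dist < direct - 1e-9:
                                clash = True
                                break
                        elif dist < min_sep:
                            clash = True
                            break
                    if clash:
                        break
                if not clash:
                    coords.append(cand)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            n_heavy = len(spec.elements_list)
            for i, (sym, xyz) in enumerate(zip(symbols, coords)):
                count = sum(1 for s in symbols[:i] if s == sym) + 1
                sites.append(AtomSite(
                    label=f"{sym}{count}", element=sym,
                    xyz=tuple(round(float(v), 5) for v in xyz),
                    occupancy=1.0,
                    uiso=round(0.025 + 0.003 * (i % 5), 4),
                    calculated=(sym == "H")))
            return sites
    raise PackingError("could not place a clash-free molecule")


def generate_structure(spec: SyntheticSpec) -> Tuple[StructureModel, str]:
    """Build a structure and its CIF text, mutually consistent by design."""
    rng = _rng(spec)
    cell = UnitCell(*spec.cell,
                    su=(0.001, 0.001, 0.001, 0.01, 0.01, 0.01))
    setting = expand_hall(spec.hall)
    sites = _place_molecule(spec, rng)
    z = setting.nsym  # general positions only
    counts: Dict[str, int] = {}
    for s in sites:
        counts[s.element] = counts.get(s.element, 0) + 1
    order = ["C", "H"] + sorted(k for k in counts if k not in ("C", "H"))
    formula = " ".join(f"{el}{counts[el]}" for el in order if el in counts)
    model = StructureModel(cell=cell, sites=sites, setting=setting,
                           wavelength=spec.wavelength, z=z, formula=formula)
    return model, model_to_cif(model, hm=spec.hm)


def model_to_cif(model: StructureModel, hm: Optional[str] = None,
                 block_name: str = "I", extra_items: Optional[dict] = None) -> str:
    cell = model.cell
    setting = model.setting
    block = DataBlock(name=block_name)
    it = block.items
    su = cell.su or (None,) * 6
    from .cif_io import format_uncertain

    for tag, v, s in (("_cell_length_a", cell.a, su[0]),
                      ("_cell_length_b", cell.b, su[1]),
                      ("_cell_length_c", cell.c, su[2]),
                      ("_cell_angle_alpha", cell.alpha, su[3]),
                      ("_cell_angle_beta", cell.beta, su[4]),
                      ("_cell_angle_gamma", cell.gamma, su[5])):
        it[tag] = format_uncertain(v, s) if s else f"{v:.4f}"
    it["_cell_volume"] = f"{cell.volume:.2f}"
    if model.z is not None:
        it["_cell_formula_units_z"] = str(model.z)
    if model.formula:
        it["_chemical_formula_sum"] = model.formula
        fu = parse_formula(model.formula)
        it["_chemical_formula_weight"] = f"{molecular_weight(fu):.2f}"
        it["_exptl_crystal_density_diffrn"] = (
            f"{calculated_density(cell.volume, model.z, molecular_weight(fu)):.3f}")
    if model.wavelength:
        it["_diffrn_radiation_wavelength"] = f"{model.wavelength:.5f}"
    if setting is not None:
        it["_space_group_name_hall"] = setting.hall
        if hm:
            it["_space_group_name_h-m_alt"] = hm
        block.loops.append((["_space_group_symop_operation_xyz"],
                            [[t] for t in setting.triplets()]))
    block.loops.append((
        ["_atom_site_label", "_atom_site_type_symbol",
         "_atom_site_fract_x", "_atom_site_fract_y", "_atom_site_fract_z",
         "_atom_site_u_iso_or_equiv", "_atom_site_occupancy",
         "_atom_site_calc_flag"],
        [[s.label, s.element,
          f"{s.xyz[0]:.5f}", f"{s.xyz[1]:.5f}", f"{s.xyz[2]:.5f}",
          f"{(s.uiso if s.uiso is not None else 0.03):.4f}",
          f"{s.occupancy:.3f}", "calc" if s.calculated else "d"]
         for s in model.sites]))
    if model.wavelength:
        block.loops.append(atom_type_loop(model, model.wavelength))
    if extra_items:
        it.update(extra_items)
    return write_cif(CifDocument(blocks=[block]))


# ---------------------------------------------------------------------------
# structure factors


def _full_sphere(cell: UnitCell, s_max: float) -> np.ndarray:
    gstar = cell.reciprocal_metric
    bounds = [int(2.0 * s_max / math.sqrt(gstar[i, i])) + 1 for i in range(3)]
    axes = [np.arange(-b, b + 1) for b in bounds]
    h, k, l = np.meshgrid(*axes, indexing="ij")
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    s = cell.s_of(hkl)
    return hkl[s <= s_max + 1e-12]


def structure_factors(model: StructureModel, s_max: float = 0.65,
                      wavelength: Optional[float] = None,
                      anomalous: bool = True,
                      hkl: Optional[np.ndarray] = None) -> ReflectionSet:
    """Exact spherical-atom structure factors over the full sphere.

    Returns a set with Fc^2, the calculated phase (degrees) and Fo^2 = Fc^2
    (noise is added by :func:`make_dataset`).
    """
    cell = model.cell
    lam = wavelength or model.wavelength or 0.71073
    if hkl is None:
        hkl = _full_sphere(cell, s_max)
    s = cell.s_of(hkl)
    f_of: Dict[str, np.ndarray] = {}
    for site in model.sites:
        if site.element in f_of:
            continue
        f0 = elements.form_factor(site.element, s)
        fp = fdp = 0.0
        if anomalous:
            an = elements.anomalous(site.element, lam)
            if an is not None:
                fp, fdp = an
        f_of[site.element] = f0 + fp + 1j * fdp
    ops = model.setting.ops if model.setting is not None else []
    if not ops:
        from .symmetry import SymOp
        ops = [SymOp.identity()]
    F = np.zeros(len(hkl), dtype=complex)
    for site in model.sites:
        x = np.asarray(site.xyz, dtype=float)
        u = site.uiso if site.uiso is not None else 0.0
        dw = np.exp(-8.0 * math.pi ** 2 * u * s ** 2)
        site_sum = np.zeros(len(hkl), dtype=complex)
        for op in ops:
            pos = op.apply(x)
            site_sum += np.exp(2j * np.pi * (hkl @ pos))
        F += site.occupancy * f_of[site.element] * dw * site_sum
    fc2 = np.abs(F) ** 2
    phase = np.degrees(np.angle(F))
    sig = np.full(len(hkl), 1e-6)
    return ReflectionSet(hkl, fc2.copy(), sig, fc2=fc2, phase=phase,
                         cell=cell, wavelength=lam, merged=False)


def direct_structure_factor(model: StructureModel, hkl_one, wavelength=None,
                            anomalous: bool = True) -> complex:
    """Naive single-reflection sum over all symmetry-expanded atoms
    (independent reference for tests)."""
    cell = model.cell
    lam = wavelength or model.wavelength or 0.71073
    s = cell.s_of(hkl_one)
    h = np.asarray(hkl_one, dtype=float)
    total = 0j
    ops = model.setting.ops if model.setting is not None else []
    for site in model.sites:
        f = elements.form_factor(site.element, s)
        if anomalous:
            an = elements.anomalous(site.element, lam)
            if an is not None:
                f = f + an[0] + 1j * an[1]
        u = site.uiso if site.uiso is not None else 0.0
        dw = math.exp(-8.0 * math.pi ** 2 * u * s ** 2)
        for op in ops:
            pos = op.apply(site.xyz)
            total += site.occupancy * f * dw * np.exp(2j * np.pi * float(h @ pos))
    return total


# ---------------------------------------------------------------------------
# datasets with corruptions


_TWO_FOLD_A = np.array([[1, 0, 0], [0, -1, 0], [0, 0, -1]])


@dataclass
class SyntheticDataset:
    model: StructureModel
    spec: SyntheticSpec
    cif: str
    fcf: str
    hklf4: str
    unmerged: ReflectionSet
    merged: ReflectionSet
    rint: Optional[float]


def _corrupt_model(model: StructureModel, spec: SyntheticSpec,
                   rng) -> StructureModel:
    kind = spec.corruption[0]
    sites = [replace(s) for s in model.sites]
    if kind == "wrong_atom_type":
        for s in sites:
            if s.element == "N":
                s.element = "C"
                break
        else:
            sites[0].element = "N"
    elif kind == "misplace_h":
        for s in sites:
            if s.is_h:
                shift = model.cell.fractionalization @ np.array([0.9, 0.0, 0.0])
                s.xyz = tuple(np.asarray(s.xyz) + shift)
                break
    return StructureModel(cell=model.cell, sites=sites, setting=model.setting,
                          wavelength=model.wavelength, z=model.z,
                          formula=model.formula)


def make_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate the full fixture: model, CIF with embedded payloads,
    FCF (merged, with Fc^2 and phases of the reported model) and HKLF4
    (unmerged observed data)."""
    from .reflection_stats import merge_equivalents

    rng = _rng(spec)
    model, _ = generate_structure(spec)
    kind = spec.corruption[0]

    # "true" structure produces the intensities; the reported model may differ
    true_model = model
    reported_model = model
    if kind in ("wrong_atom_type", "misplace_h"):
        reported_model = _corrupt_model(model, spec, rng)
    sf_true = structure_factors(true_model, spec.s_max)
    intensity = sf_true.fc2.copy()

    lookup = {tuple(h): i for i, h in enumerate(sf_true.hkl.tolist())}
    if kind == "twin":
        law = spec.corruption[1] if len(spec.corruption) > 1 else _TWO_FOLD_A
        alpha = spec.corruption[2] if len(spec.corruption) > 2 else 0.3
        law = np.asarray(law)
        mixed = intensity.copy()
        for i, h in enumerate(sf_true.hkl):
            h2 = tuple(int(round(v)) for v in h @ law)
            j = lookup.get(h2)
            if j is not None:
                mixed[i] = (1 - alpha) * intensity[i] + alpha * intensity[j]
        intensity = mixed
    elif kind == "invert_structure":
        inv = intensity.copy()
        for i, h in enumerate(sf_true.hkl):
            j = lookup.get(tuple(-v for v in h.tolist()))
            if j is not None:
                inv[i] = intensity[j]
        intensity = inv
    elif kind == "inflate_low_order":
        s = sf_true.s()
        intensity = np.where(s < 0.25, 2.0 * intensity, intensity)

    sigma = np.sqrt(spec.sigma0 ** 2 + spec.k_noise * np.maximum(intensity, 0.0))
    if kind == "fabricate_sigmas":
        fo2 = intensity.copy()
        sigma = 0.02 * np.maximum(fo2, 0.0) + 1.0
    else:
        fo2 = intensity + (rng.normal(0.0, sigma) if spec.sigma0 > 0
                           or spec.k_noise > 0 else 0.0)
        sigma = np.maximum(sigma, 1e-6)

    # Fc^2/phases of the *reported* model accompany the data
    sf_rep = (sf_true if reported_model is true_model
              else structure_factors(reported_model, spec.s_max))
    if kind == "strip_inversion":
        reported_model, sf_rep = _strip_inversion(true_model, spec, sf_rep)

    unmerged = ReflectionSet(sf_true.hkl, fo2, sigma, fc2=sf_rep.fc2,
                             phase=sf_rep.phase, cell=model.cell,
                             wavelength=spec.wavelength, merged=False)
    setting = reported_model.setting
    merged, rint = merge_equivalents(
        unmerged, setting.rotations,
        include_friedel=setting.centrosymmetric)
    hklf4 = write_reflections(unmerged, "hklf4")
    fcf = write_reflections(merged, "fcf")

    res_text = _res_text(reported_model)
    hkl_payload = hklf4
    if kind == "edit_embedded":
        checks = {"_shelx_res_checksum": str(reference_checksum(res_text)),
                  "_shelx_hkl_checksum": str(reference_checksum(hkl_payload))}
        res_text = res_text.replace("TITL", "TITLE", 1)  # post-checksum edit
    else:
        checks = {"_shelx_res_checksum": str(reference_checksum(res_text)),
                  "_shelx_hkl_checksum": str(reference_checksum(hkl_payload))}
    extra = _refinement_summary(reported_model, merged, len(unmerged), spec)
    extra.update({
        "_shelx_res_file": "\n" + res_text,
        "_shelx_hkl_file": "\n" + hkl_payload,
    })
    extra.update(checks)
    cif = model_to_cif(reported_model, hm=spec.hm, extra_items=extra)
    return SyntheticDataset(model=reported_model, spec=spec, cif=cif, fcf=fcf,
                            hklf4=hklf4, unmerged=unmerged, merged=merged,
                            rint=rint)


def _refinement_summary(model: StructureModel, merged, n_unmerged: int,
                        spec: SyntheticSpec) -> dict:
    """Refinement-summary datanames consistent with the generated data."""
    from .density_maps import difference_map
    from .model_checks import linear_absorption_coefficient
    from .reflection_stats import WeightParams, r_factors

    n_params = 4 * len(model.sites) + 1
    rf = r_factors(merged, WeightParams(), n_params)
    items = {
        "_diffrn_reflns_number": str(n_unmerged),
        "_reflns_number_total": str(len(merged)),
        "_reflns_number_gt": str(rf.n_observed),
        "_refine_ls_number_parameters": str(n_params),
        "_refine_ls_number_reflns": str(len(merged)),
        "_refine_ls_weighting_details":
            "w=1/[s^2(Fo^2)+(0.0000P)^2+0.0000P] where P=(Fo^2+2Fc^2)/3",
        "_refine_ls_goodness_of_fit_ref":
            f"{rf.goof:.4f}" if rf.goof is not None else "?",
        "_refine_ls_wr_factor_ref": f"{rf.wr2:.4f}",
    }
    if rf.r1 is not None:
        items["_refine_ls_r_factor_gt"] = f"{rf.r1:.4f}"
    try:
        s = merged.s()
        step = min(0.2, 1.0 / (2.0 * float(s.max())) / 3.0)
        grid = difference_map(merged, grid_step=step)
        items["_refine_diff_density_max"] = f"{grid.values.max():.3f}"
        items["_refine_diff_density_min"] = f"{grid.values.min():.3f}"
    except Exception:
        pass
    dims = (0.20, 0.26, 0.32)
    items["_exptl_crystal_size_min"] = f"{dims[0]:.2f}"
    items["_exptl_crystal_size_mid"] = f"{dims[1]:.2f}"
    items["_exptl_crystal_size_max"] = f"{dims[2]:.2f}"
    try:
        fu = parse_formula(model.formula)
        mu = linear_absorption_coefficient(fu, model.z, model.cell.volume,
                                           spec.wavelength)
        items["_exptl_absorpt_coefficient_mu"] = f"{mu:.4f}"
        items["_exptl_absorpt_correction_t_min"] = f"{math.exp(-mu*dims[2]):.4f}"
        items["_exptl_absorpt_correction_t_max"] = f"{math.exp(-mu*dims[0]):.4f}"
    except Exception:
        pass
    return items


def atom_type_loop(model: StructureModel, wavelength: float):
    """CIF _atom_type_ loop with the anomalous terms of the generator."""
    tags = ["_atom_type_symbol", "_atom_type_scat_dispersion_real",
            "_atom_type_scat_dispersion_imag"]
    rows = []
    for el in sorted({s.element for s in model.sites}):
        an = elements.anomalous(el, wavelength) or (0.0, 0.0)
        rows.append([el, f"{an[0]:.4f}", f"{an[1]:.4f}"])
    return tags, rows


def _strip_inversion(model: StructureModel, spec: SyntheticSpec, sf_rep):
    """Re-express a centrosymmetric structure in the index-2 subgroup
    without the inversion: the asymmetric unit doubles."""
    from .symmetry import setting_from_ops

    setting = model.setting
    sub_ops = [op for op in setting.ops if op.det > 0]
    sub = setting_from_ops(sub_ops, hall=setting.hall.lstrip("-"))
    if sub.nsym != setting.nsym // 2:
        raise ValueError("group has no proper-rotation halving subgroup")
    inv = next(op for op in setting.ops if op.is_inversion_like)
    doubled = []
    for s in model.sites:
        doubled.append(replace(s))
    for s in model.sites:
        img = inv.apply(s.xyz)
        doubled.append(replace(s, label=s.label + "B",
                               xyz=tuple(round(float(v), 5) for v in img)))
    return (StructureModel(cell=model.cell, sites=doubled, setting=sub,
                           wavelength=model.wavelength, z=model.z,
                           formula=model.formula), sf_rep)


def _res_text(model: StructureModel) -> str:
    c = model.cell
    lines = [
        "TITL synthetic structure (generated fixture)",
        f"CELL {model.wavelength or 0.71073:.5f} {c.a:.4f} {c.b:.4f} "
        f"{c.c:.4f} {c.alpha:.3f} {c.beta:.3f} {c.gamma:.3f}",
        f"ZERR {model.z or 1}  0.001 0.001 0.001 0.01 0.01 0.01",
    ]
    for s in model.sites:
        lines.append(f"{s.label:6s} 1 {s.xyz[0]:9.5f} {s.xyz[1]:9.5f} "
                     f"{s.xyz[2]:9.5f} {s.occupancy:7.4f} "
                     f"{(s.uiso or 0.03):7.4f}")
    lines.append("END")
    return "\n".join(lines) + "\n"
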