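"""Orchestration: run every check over a CIF/FCF pair and render a
levelled ALERT report.

ALERT levels follow the established convention: A (serious), B, C
(check), G (informative). Rule ids 007, 012, 977 and 978 mirror their
upstream analogues; all toolkit-assigned ids are >= 9000 to avoid
collision. A crash inside one check never aborts the run -- it degrades to
a toolkit-error alert. Level assignment is centralised in the rule
registry below so the mapping is auditable and overridable.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional

import numpy as np

from . import __version__, density_maps, model_checks, reflection_stats
from . import symmetry as sym
from . import symmetry_detect as det
from .cif_io import (CifDocument, CifValueError, extract_embedded,
                     parse_uncertain, read_reflections)
from .core import AtomSite, ReflectionSet, StructureModel, UnitCell
from .reflection_stats import WeightParams

__all__ = [
    "Alert", "AlertReport", "BlockReport", "ValidationConfig",
    "run_validation", "render_report", "structure_from_block", "RULES",
]

_LEVELS = ("A", "B", "C", "G")


@dataclass
class AlertRule:
    id: int
    level: str  # default level; some rules compute their own
    template: str


RULES: Dict[int, AlertRule] = {r.id: r for r in [
    AlertRule(7, "C", "H-atom placement questionable: {msg}"),
    AlertRule(12, "B", "embedded payload checksum mismatch: {msg}"),
    AlertRule(977, "C", "H atom not supported by the difference density: {msg}"),
    AlertRule(978, "G", "mean difference density on bonds: {msg}"),
    AlertRule(9001, "C", "missing datum: {msg}"),
    AlertRule(9002, "C", "invalid value: {msg}"),
    AlertRule(9010, "A", "symmetry operators inconsistent: {msg}"),
    AlertRule(9011, "B", "HM/Hall symbol mismatch: {msg}"),
    AlertRule(9012, "B", "cell metric violates crystal system: {msg}"),
    AlertRule(9013, "C", "space-group symbol missing: {msg}"),
    AlertRule(9014, "G", "symbol comparison skipped: {msg}"),
    AlertRule(9020, "B", "formula problem: {msg}"),
    AlertRule(9021, "B", "density inconsistent: {msg}"),
    AlertRule(9030, "B", "Hirshfeld rigid-bond violation: {msg}"),
    AlertRule(9031, "B", "short O...O/O...N contact (missing H?): {msg}"),
    AlertRule(9032, "C", "short H...H contact (misplaced H?): {msg}"),
    AlertRule(9033, "G", "short halogen...halogen contact: {msg}"),
    AlertRule(9034, "C", "species centre of gravity outside cell: {msg}"),
    AlertRule(9035, "C", "short intermolecular contact: {msg}"),
    AlertRule(9036, "G", "contact involves disordered site: {msg}"),
    AlertRule(9037, "G", "small-species centroid outside cell: {msg}"),
    AlertRule(9040, "C", "transmission range implausible: {msg}"),
    AlertRule(9041, "C", "data-to-parameter ratio low: {msg}"),
    AlertRule(9042, "C", "resonant scattering factors deviate: {msg}"),
    AlertRule(9043, "G", "resonant scattering factors unverified: {msg}"),
    AlertRule(9050, "C", "high Rint: {msg}"),
    AlertRule(9051, "B", "reported R values not reproduced: {msg}"),
    AlertRule(9052, "C", "analysis of variance: scaling K deviates: {msg}"),
    AlertRule(9053, "C", "analysis of variance: bin GooF deviates: {msg}"),
    AlertRule(9054, "C", "data incomplete: {msg}"),
    AlertRule(9055, "B", "sigma(I) suspiciously smooth vs I: {msg}"),
    AlertRule(9056, "B", "systematic-absence violations: {msg}"),
    AlertRule(9057, "B", "absolute structure: {msg}"),
    AlertRule(9058, "C", "goodness of fit far from 1: {msg}"),
    AlertRule(9059, "G", "normal probability plot: {msg}"),
    AlertRule(9060, "C", "residual density excursion: {msg}"),
    AlertRule(9061, "C", "reported residual density not reproduced: {msg}"),
    AlertRule(9062, "B", "density on atom site (atom-type error?): {msg}"),
    AlertRule(9063, "B", "solvent-accessible void(s): {msg}"),
    AlertRule(9064, "G", "residual density near heavy atom: {msg}"),
    AlertRule(9070, "A", "additional symmetry proposed (ADDSYM): {msg}"),
    AlertRule(9071, "B", "possible twin law: {msg}"),
    AlertRule(9080, "C", "reflection data unavailable: {msg}"),
    AlertRule(9081, "G", "check not assessed: {msg}"),
    AlertRule(9090, "C", "toolkit error during check: {msg}"),
    AlertRule(9091, "G", "embedded payload checksum unverified: {msg}"),
]}


@dataclass
class Alert:
    id: int
    level: str
    message: str
    value: Optional[float] = None
    threshold: Optional[str] = None

    def sort_key(self):
        return (_LEVELS.index(self.level), self.id, self.message)


@dataclass
class ValidationConfig:
    addsym_tol: float = 0.45
    addsym_nonfit: float = 15.0
    probe: float = 1.2
    grid_step: float = 0.2
    min_void_volume: float = 20.0
    contact_slack: float = 0.2
    hirshfeld_z: float = 5.0
    hirshfeld_z_serious: float = 10.0
    observed_nsigma: float = 2.0
    absence_nsigma: float = 3.0
    density_featureless: float = 0.5
    rint_limit: float = 0.12
    goof_band: float = 0.5
    completeness_limit: float = 0.95
    r_reproduce_tol: float = 0.01
    np_thresholds: Optional[tuple] = None
    seed: int = 0
    explanations: bool = True


@dataclass
class BlockReport:
    name: str
    summary: Dict[str, object] = field(default_factory=dict)
    alerts: List[Alert] = field(default_factory=list)

    def add(self, rule_id: int, msg: str, value=None, level: Optional[str] = None,
            threshold: Optional[str] = None):
        rule = RULES[rule_id]
        self.alerts.append(Alert(
            id=rule_id, level=level or rule.level,
            message=rule.template.format(msg=msg), value=value,
            threshold=threshold))

    def count(self, level: str) -> int:
        return sum(1 for a in self.alerts if a.level == level)


@dataclass
class AlertReport:
    blocks: List[BlockReport]
    provenance: Dict[str, object] = field(default_factory=dict)

    def count(self, level: str) -> int:
        return sum(b.count(level) for b in self.blocks)


# ---------------------------------------------------------------------------
# model extraction from a CIF block


def _get_number(block, tag):
    raw = block.get(tag)
    if raw in (None, "?", "."):
        return None
    try:
        return parse_uncertain(raw)
    except CifValueError:
        return None


def structure_from_block(block) -> StructureModel:
    """Build a StructureModel (cell + setting + sites) from a data block."""
    cell_vals = []
    sus = []
    for tag in ("_cell_length_a", "_cell_length_b", "_cell_length_c",
                "_cell_angle_alpha", "_cell_angle_beta", "_cell_angle_gamma"):
        uv = _get_number(block, tag)
        if uv is None:
            raise CifValueError(f"missing or invalid {tag}")
        cell_vals.append(uv.value)
        sus.append(uv.su)
    cell = UnitCell(*cell_vals, su=tuple(sus))
    hall = block.get("_space_group_name_hall") or block.get("_symmetry_space_group_name_hall")
    triplets = (block.loop_column("_space_group_symop_operation_xyz")
                or block.loop_column("_symmetry_equiv_pos_as_xyz"))
    setting = None
    if hall:
        try:
            setting = sym.expand_hall(hall)
        except sym.HallError:
            setting = None
    if setting is None and triplets:
        setting = sym.setting_from_ops(sym.ops_from_triplets(triplets))
    if setting is None:
        hm = block.get("_space_group_name_h-m_alt") or block.get(
            "_symmetry_space_group_name_h-m")
        if hm:
            expected = sym._hm_lookup(hm)
            if expected:
                setting = sym.expand_hall(expected)
    if setting is None:
        setting = sym.expand_hall("P 1")
    labels = block.loop_column("_atom_site_label") or []
    elems = block.loop_column("_atom_site_type_symbol") or []
    xs = block.loop_column("_atom_site_fract_x") or []
    ys = block.loop_column("_atom_site_fract_y") or []
    zs = block.loop_column("_atom_site_fract_z") or []
    occs = block.loop_column("_atom_site_occupancy") or []
    uisos = block.loop_column("_atom_site_u_iso_or_equiv") or []
    calcs = block.loop_column("_atom_site_calc_flag") or []
    disord = block.loop_column("_atom_site_disorder_group") or []
    sites = []
    for i, label in enumerate(labels):
        elem = elems[i] if i < len(elems) else "".join(
            c for c in label if c.isalpha())[:2].capitalize()
        try:
            xyz = tuple(parse_uncertain(v[i]).value for v in (xs, ys, zs))
        except (CifValueError, IndexError):
            continue
        occ = parse_uncertain(occs[i]).value if i < len(occs) and occs[i] not in ("?", ".") else 1.0
        uiso = None
        if i < len(uisos) and uisos[i] not in ("?", "."):
            try:
                uiso = parse_uncertain(uisos[i]).value
            except CifValueError:
                uiso = None
        sites.append(AtomSite(
            label=label, element=elem, xyz=xyz, occupancy=occ, uiso=uiso,
            calculated=(i < len(calcs) and calcs[i] == "calc"),
            disordered=(i < len(disord) and disord[i] not in (".", "?", "", "0"))))
    # anisotropic loop
    aniso_labels = block.loop_column("_atom_site_aniso_label") or []
    if aniso_labels:
        cols = {}
        for comp in ("11", "22", "33", "23", "13", "12"):
            cols[comp] = block.loop_column(f"_atom_site_aniso_u_{comp}") or []
        by_label = {s.label: s for s in sites}
        for i, label in enumerate(aniso_labels):
            site = by_label.get(label)
            if site is None:
                continue
            try:
                vals = [parse_uncertain(cols[c][i]) for c in
                        ("11", "22", "33", "23", "13", "12")]
            except (CifValueError, IndexError):
                continue
            site.uaniso = tuple(v.value for v in vals)
            if all(v.su is not None for v in vals):
                site.uaniso_su = tuple(v.su for v in vals)
    wl = _get_number(block, "_diffrn_radiation_wavelength")
    z = _get_number(block, "_cell_formula_units_z")
    return StructureModel(
        cell=cell, sites=sites, setting=setting,
        wavelength=wl.value if wl else None,
        z=int(z.value) if z else None,
        formula=block.get("_chemical_formula_sum"))


# ---------------------------------------------------------------------------
# stages


def _stage(report: BlockReport, name: str):
    """Context manager converting crashes into toolkit-error alerts."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is None:
                return False
            report.add(9090, f"{name}: {exc_type.__name__}: {exc}")
            return True
    return _Ctx()


_SYMMETRY_RULE = {
    "ops_mismatch": 9010, "hm_hall_mismatch": 9011,
    "cell_system_mismatch": 9012, "missing_symbol": 9013,
    "invalid_symbol": 9002, "hm_hall_not_checked": 9014,
}

_CONTACT_RULE = {"missing_h": 9031, "h_h": 9032, "halogen": 9033,
                 "other": 9035}


def _validate_block(block, fcf_text: Optional[str],
                    cfg: ValidationConfig) -> BlockReport:
    report = BlockReport(name=block.name)
    model: Optional[StructureModel] = None
    refl: Optional[ReflectionSet] = None
    refl_source = "none"

    # --- embedded payloads and checksums -----------------------------------
    embedded = []
    with _stage(report, "embedded extraction"):
        embedded = extract_embedded(block)
        for emb in embedded:
            if emb.checksum_ok == "fail":
                report.add(12, f"{emb.dataname} payload does not match its "
                               f"declared checksum (corrupt or edited)")
            elif emb.checksum_ok == "unverified":
                report.add(9091, f"{emb.dataname}: no checksum declared or "
                                 f"algorithm unknown")

    # --- model --------------------------------------------------------------
    with _stage(report, "model extraction"):
        model = structure_from_block(block)
    if model is None:
        report.add(9080, "no interpretable structural model; reflection and "
                         "map checks skipped")
        return report

    # --- symmetry consistency ----------------------------------------------
    with _stage(report, "symmetry consistency"):
        hall = block.get("_space_group_name_hall") or block.get(
            "_symmetry_space_group_name_hall")
        hm = block.get("_space_group_name_h-m_alt") or block.get(
            "_symmetry_space_group_name_h-m")
        triplets = (block.loop_column("_space_group_symop_operation_xyz")
                    or block.loop_column("_symmetry_equiv_pos_as_xyz"))
        listed = sym.ops_from_triplets(triplets) if triplets else None
        for f in sym.check_symmetry_consistency(
                model.cell, model.setting, hm=hm, hall=hall, listed_ops=listed):
            report.add(_SYMMETRY_RULE.get(f.code, 9002), f.message, f.value)

    # --- model checks --------------------------------------------------------
    fu = None
    with _stage(report, "formula and density"):
        if model.formula:
            fu = model_checks.parse_formula(model.formula)
            mr = model_checks.molecular_weight(fu)
            rho = _get_number(block, "_exptl_crystal_density_diffrn")
            f = model_checks.density_check(
                model.cell.volume, model.z, mr,
                rho.value if rho else None)
            if f is not None:
                report.add(9021 if f.code == "density_mismatch" else 9001,
                           f.message, f.value)
        else:
            report.add(9001, "_chemical_formula_sum missing")

    with _stage(report, "Hirshfeld rigid-bond test"):
        for res in model_checks.hirshfeld_scan(model, cfg.hirshfeld_z):
            if res.flagged:
                level = "A" if (res.z_score or 0) > cfg.hirshfeld_z_serious else "B"
                report.add(9030,
                           f"bond {res.pair[0]}-{res.pair[1]}: Delta = "
                           f"{res.delta:.4f} A^2 ({res.z_score:.1f} su)",
                           res.delta, level=level,
                           threshold=f"{cfg.hirshfeld_z} su")

    with _stage(report, "intermolecular contacts"):
        for c in model_checks.short_contacts(model, slack=cfg.contact_slack):
            la = model.sites[c.i].label
            lb = model.sites[c.j].label
            msg = (f"{la}...{lb} = {c.length:.2f} A (vdW sum "
                   f"{c.vdw_sum:.2f} A, {c.symmetry})")
            if c.involves_disorder:
                report.add(9036, msg + " -- inspect disorder model", c.length)
            else:
                report.add(_CONTACT_RULE[c.kind], msg, c.length)

    with _stage(report, "centre of gravity"):
        for f in model_checks.centre_of_gravity_check(model):
            report.add(9037 if f.code == "centroid_small_species" else 9034,
                       f.message)

    with _stage(report, "transmission range"):
        if fu is not None and model.wavelength:
            dims = []
            for tag in ("_exptl_crystal_size_min", "_exptl_crystal_size_mid",
                        "_exptl_crystal_size_max"):
                v = _get_number(block, tag)
                if v is not None:
                    dims.append(v.value)
            tmin = _get_number(block, "_exptl_absorpt_correction_t_min")
            tmax = _get_number(block, "_exptl_absorpt_correction_t_max")
            if dims and tmin and tmax:
                for f in model_checks.absorption_range_check(
                        fu, model.z, model.cell.volume, model.wavelength,
                        (min(dims), max(dims)), (tmin.value, tmax.value)):
                    rule = {"transmission_range": 9040,
                            "missing_datum": 9001,
                            "cannot_assess": 9081}.get(f.code, 9081)
                    report.add(rule, f.message, f.value)

    with _stage(report, "resonant scattering factors"):
        syms = block.loop_column("_atom_type_symbol")
        fps = block.loop_column("_atom_type_scat_dispersion_real")
        fdps = block.loop_column("_atom_type_scat_dispersion_imag")
        if syms and fps and fdps and model.wavelength:
            reported = {}
            for s_, fp_, fdp_ in zip(syms, fps, fdps):
                try:
                    reported[s_] = (parse_uncertain(fp_).value,
                                    parse_uncertain(fdp_).value)
                except CifValueError:
                    continue
            for f in model_checks.resonant_check(reported, model.wavelength):
                report.add(9042 if f.code == "resonant_mismatch" else 9043,
                           f.message, f.value)

    # --- reflection data ------------------------------------------------------
    with _stage(report, "reflection data"):
        refl, refl_source = _reflections_for(block, model, embedded, fcf_text)
        if refl is not None and refl.merged:
            # the duplicate-triple heuristic misses symmetry-equivalent
            # remeasurements: decide mergedness by Laue-orbit redundancy
            reps = reflection_stats._orbit_reps(
                refl.hkl, model.setting.laue_rotations,
                model.setting.centrosymmetric)
            if len({tuple(r) for r in reps.tolist()}) < len(refl):
                refl = refl.replace(merged=False)
    if refl is None:
        report.add(9080, "no FCF supplied and no usable embedded reflection "
                         "data; reflection, map and twinning checks skipped")
    report.summary["reflection_source"] = refl_source

    merged = None
    weight_params = _weighting_from_block(block)
    n_params = _n_params(block, model)
    if refl is not None:
        with _stage(report, "reflection statistics"):
            merged = _reflection_stage(block, model, refl, weight_params,
                                       n_params, cfg, report)

    # --- density maps ---------------------------------------------------------
    grid = None
    if merged is not None and merged.phase is not None:
        with _stage(report, "difference density map"):
            grid = _map_stage(block, model, merged, cfg, report)

    with _stage(report, "solvent-accessible voids"):
        voids = density_maps.find_voids(model, probe=cfg.probe,
                                        grid_step=max(cfg.grid_step, 0.25),
                                        min_volume=cfg.min_void_volume)
        report.summary["void_volume"] = sum(r.volume for r in voids.regions)
        for region in voids.regions:
            msg = (f"void of {region.volume:.0f} A^3 at "
                   f"({region.centroid[0]:.2f},{region.centroid[1]:.2f},"
                   f"{region.centroid[2]:.2f})")
            if grid is not None:
                try:
                    ne = density_maps.void_electron_count(region, grid)
                    msg += f", ~{ne:.1f} e integrated difference density"
                except density_maps.MapError:
                    pass
            report.add(9063, msg, region.volume)

    # --- missed symmetry / twinning -------------------------------------------
    with _stage(report, "missed symmetry (ADDSYM)"):
        props = det.addsym_search(model, tol=cfg.addsym_tol,
                                  allowed_nonfit=cfg.addsym_nonfit)
        if isinstance(props, det.NotAssessed):
            report.add(9081, f"ADDSYM: {props.reason}")
        else:
            for p in props:
                msg = (f"{p.kind} {p.op.triplet()} fits "
                       f"{p.fit_fraction:.0f}% of {p.n_eligible} atoms "
                       f"(max displacement {p.max_displacement:.2f} A, "
                       f"tol {cfg.addsym_tol} A); implied group "
                       f"{p.implied_group}")
                if refl is not None and not refl.merged:
                    try:
                        implied = sym.setting_from_ops(
                            list(model.setting.ops) + [p.op])
                        nviol = len(sym.absence_violations(
                            refl, implied, cfg.absence_nsigma))
                        msg += (f"; {nviol} reflections violate the implied "
                                f"extinctions")
                    except Exception:
                        pass
                report.add(9070, msg, p.fit_fraction)

    if merged is not None:
        with _stage(report, "twin-law search"):
            laws = det.twin_search(merged, model.cell, model.setting)
            if isinstance(laws, det.NotAssessed):
                report.add(9081, f"twin search: {laws.reason}")
            else:
                for law in laws[:3]:
                    report.add(9071,
                               f"two-fold about {law.candidate.axis} "
                               f"({law.candidate.axis_type}) explains "
                               f"{law.explained_fraction:.0f}% of outliers; "
                               f"alpha ~ {law.alpha_hat:.2f}, estimated R1 "
                               f"drop {law.r1_before:.3f} -> "
                               f"{law.r1_after:.3f}", law.alpha_hat)

    report.alerts.sort(key=lambda a: a.sort_key())
    return report


def _reflections_for(block, model, embedded, fcf_text):
    """Prefer recreating Fc-bearing unmerged data from embedded payloads;
    fall back to a supplied FCF."""
    from .fixtures import structure_factors

    for emb in embedded:
        if emb.kind != "hkl" or emb.checksum_ok == "fail":
            continue
        try:
            rs = read_reflections(emb.text, "hklf4")
        except Exception:
            continue
        sf = structure_factors(model, hkl=rs.hkl)
        rs = rs.replace(fc2=sf.fc2, phase=sf.phase, cell=model.cell,
                        wavelength=model.wavelength)
        return rs, f"embedded {emb.dataname} + recalculated Fc"
    if fcf_text:
        rs = read_reflections(fcf_text, "fcf")
        if rs.cell is None:
            rs = rs.replace(cell=model.cell)
        if rs.wavelength is None:
            rs = rs.replace(wavelength=model.wavelength)
        return rs, "supplied FCF"
    return None, "none"


def _weighting_from_block(block) -> WeightParams:
    import re

    details = block.get("_refine_ls_weighting_details") or ""
    m = re.search(r"\(\s*([\d.]+)\s*[pP]\s*\)\s*\^?2.*?([\d.]+)\s*[pP]",
                  details.replace(" ", ""))
    if not m:
        m = re.search(r"\((\d*\.?\d+)P\)\^?2\^?\+(\d*\.?\d+)P",
                      details.replace(" ", ""))
    if m:
        try:
            return WeightParams(float(m.group(1)), float(m.group(2)))
        except ValueError:
            pass
    return WeightParams(0.0, 0.0)


def _n_params(block, model) -> int:
    v = _get_number(block, "_refine_ls_number_parameters")
    if v is not None:
        return int(v.value)
    return 4 * len(model.sites) + 1


def _reflection_stage(block, model, refl, wp, n_params, cfg, report):
    setting = model.setting
    include_friedel = setting.centrosymmetric
    if refl.merged:
        merged, rint = refl, None
    else:
        # merge under the point-group rotations; Friedel mates are averaged
        # only for centrosymmetric structures (anomalous signal must survive)
        merged, rint = reflection_stats.merge_equivalents(
            refl, setting.rotations, include_friedel=include_friedel)
        if rint is not None:
            report.summary["rint"] = rint
            if rint > cfg.rint_limit:
                report.add(9050, f"Rint = {rint:.3f} over "
                           f"{len(refl)} measurements", rint,
                           threshold=f"{cfg.rint_limit}")
        with _stage(report, "systematic absences"):
            viols = sym.absence_violations(refl, setting, cfg.absence_nsigma)
            if viols:
                worst = viols[0]
                level = "B" if (worst[3] >= 6 or len(viols) >= 3) else "G"
                report.add(9056,
                           f"{len(viols)} extinct reflections observed above "
                           f"{cfg.absence_nsigma} sigma; strongest "
                           f"{worst[0]} at I/sigma = {worst[3]:.1f}",
                           float(len(viols)), level=level)
        with _stage(report, "fabrication screen"):
            screen = reflection_stats.fabrication_screen(refl)
            report.summary["fabrication"] = screen.verdict
            if screen.verdict == "suspicious":
                report.add(9055,
                           f"sigma^2 is an almost exact polynomial in I "
                           f"(R^2 = {screen.r_squared:.6f}); this flags "
                           f"possible fabrication, it is not proof",
                           screen.r_squared)

    if merged.fc2 is None:
        report.add(9080, "no calculated intensities available: R-value and "
                         "variance checks skipped")
        return merged

    rf_cif = reflection_stats.r_factors(merged, wp, n_params,
                                        cfg.observed_nsigma)
    rf_sigma = reflection_stats.r_factors(merged, WeightParams(), n_params,
                                          cfg.observed_nsigma)
    reported = {}
    for key, tag in (("r1", "_refine_ls_r_factor_gt"),
                     ("wr2", "_refine_ls_wr_factor_ref"),
                     ("goof", "_refine_ls_goodness_of_fit_ref")):
        v = _get_number(block, tag)
        reported[key] = v.value if v else None
    report.summary["r_factors"] = {
        "recalculated (CIF weights)": (rf_cif.r1, rf_cif.wr2, rf_cif.goof),
        "reweighted (sigma weights)": (rf_sigma.r1, rf_sigma.wr2,
                                       rf_sigma.goof),
        "reported": (reported["r1"], reported["wr2"], reported["goof"]),
    }
    report.summary["observed_criterion"] = rf_cif.observed_criterion
    if reported["r1"] is not None and rf_cif.r1 is not None:
        if abs(reported["r1"] - rf_cif.r1) > cfg.r_reproduce_tol:
            report.add(9051,
                       f"reported R1 = {reported['r1']:.4f} vs recalculated "
                       f"{rf_cif.r1:.4f}",
                       abs(reported["r1"] - rf_cif.r1),
                       threshold=f"{cfg.r_reproduce_tol}")
    if rf_cif.goof is not None and abs(rf_cif.goof - 1.0) > cfg.goof_band:
        report.add(9058, f"S = {rf_cif.goof:.2f} (CIF weights)",
                   rf_cif.goof, threshold=f"1 +- {cfg.goof_band}")

    with _stage(report, "analysis of variance"):
        t_res, t_fc = reflection_stats.analysis_of_variance(merged, wp)
        for f in t_res.findings + t_fc.findings:
            report.add(9052 if f.code == "variance_k" else 9053,
                       f.message, f.value)

    with _stage(report, "normal probability plot"):
        if len(merged) >= 10:
            npp = reflection_stats.normal_probability(merged, wp)
            report.summary["npp_slope"] = npp.slope
            if not npp.degenerate and (npp.slope > 2.0 or
                                       npp.max_central_deviation > 1.0):
                report.add(9059,
                           f"slope {npp.slope:.2f}, max central deviation "
                           f"{npp.max_central_deviation:.2f}")

    with _stage(report, "completeness"):
        prof = reflection_stats.completeness_profile(
            merged, setting, model.cell, observed_nsigma=cfg.observed_nsigma)
        comp = (prof.completeness_at_0_6
                if prof.completeness_at_0_6 is not None
                else prof.completeness_at_smax)
        where = "0.6/A" if prof.completeness_at_0_6 is not None else \
            f"{prof.s_max:.2f}/A"
        report.summary["completeness"] = comp
        if comp < cfg.completeness_limit:
            level = "B" if comp < cfg.completeness_limit - 0.10 else "C"
            report.add(9054, f"{100*comp:.1f}% complete to sin(theta)/lambda "
                             f"= {where}", comp, level=level,
                       threshold=f"{100*cfg.completeness_limit:.0f}%")

    with _stage(report, "absolute structure"):
        if not setting.centrosymmetric and not refl.merged:
            try:
                est = reflection_stats.absolute_structure_estimate(refl)
                report.summary["flack_x"] = (est.x, est.su, est.n_pairs)
                if est.decision == "invert":
                    report.add(9057,
                               f"Parsons-style quotient fit x = {est.x:.3f}"
                               f"({est.su:.3f}) > 0.5: invert the model",
                               est.x)
                elif est.decision == "indeterminate":
                    report.add(9081,
                               f"absolute structure indeterminate: x = "
                               f"{est.x:.3f}({est.su:.3f})")
            except ValueError as exc:
                report.add(9081, f"absolute structure: {exc}")
    return merged


def _map_stage(block, model, merged, cfg, report):
    s = merged.s()
    d_min = 1.0 / (2.0 * float(s.max()))
    step = min(cfg.grid_step, d_min / 3.0)
    grid = density_maps.difference_map(merged, grid_step=step)
    bonds = model_checks.build_connectivity(model)
    rep_max = _get_number(block, "_refine_diff_density_max")
    rep_min = _get_number(block, "_refine_diff_density_min")
    reported = None
    if rep_max is not None and rep_min is not None:
        reported = (rep_min.value, rep_max.value)
    mrep = density_maps.map_report(
        grid, model, bonds, reported_extrema=reported,
        featureless_bound=cfg.density_featureless)
    report.summary["residual_density"] = (mrep.rho_min, mrep.rho_max)
    rule_of = {"density_extremum_A": (9060, "A"), "density_extremum_B": (9060, "B"),
               "density_extremum_C": (9060, "C"),
               "density_report_mismatch": (9061, None),
               "on_atom_density": (9062, None),
               "density_near_heavy": (9064, None)}
    for f in mrep.findings:
        rule, level = rule_of.get(f.code, (9060, None))
        report.add(rule, f.message, f.value, level=level)
    if mrep.bond_midpoint_mean is not None:
        report.add(978, f"{mrep.bond_midpoint_mean:+.3f} e/A^3 over "
                        f"{len(bonds)} bonds (spherical-atom refinement "
                        f"assumed)", mrep.bond_midpoint_mean)
    support = density_maps.h_site_support(grid, model, mode="asis")
    unsupported = [lab for lab, ok in support.items() if not ok]
    for lab in unsupported:
        report.add(977, f"H atom {lab} sits in negative difference density")
    if unsupported:
        report.add(7, f"{len(unsupported)} H atom(s) in density holes; "
                      f"H positions not necessarily reliable")
    return grid


def run_validation(doc: CifDocument, fcf_text: Optional[str] = None,
                   config: Optional[ValidationConfig] = None) -> AlertReport:
    """Validate every structural block of a parsed CIF document.

    Non-structural blocks (no cell -- e.g. a leading publication block) are
    skipped. Raises only when no structural block exists at all.
    """
    cfg = config or ValidationConfig()
    blocks = doc.structural_blocks
    if not blocks:
        raise ValueError("no structural data block (with _cell_length_a) found")
    reports = [_validate_block(b, fcf_text, cfg) for b in blocks]
    return AlertReport(
        blocks=reports,
        provenance={
            "toolkit": f"ciflint {__version__}",
            "config": {k: v for k, v in asdict(cfg).items()},
            "skipped_blocks": [b.name for b in doc.blocks
                               if not b.is_structural],
        })


# ---------------------------------------------------------------------------
# rendering


def _fmt(v) -> str:
    if v is None:
        return "---"
    if isinstance(v, float):
        return f"{v:.4f}"
    return str(v)


def render_report(report: AlertReport, fmt: str = "chk",
                  explanations: bool = True) -> str:
    """Render the report; ``chk`` is deterministic text, ``json`` is a
    complete serialization."""
    if fmt == "json":
        payload = {
            "provenance": report.provenance,
            "blocks": [
                {
                    "name": b.name,
                    "summary": _jsonable(b.summary),
                    "alerts": [asdict(a) for a in b.alerts],
                }
                for b in report.blocks
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=str)
    if fmt != "chk":
        raise ValueError(f"unknown report format {fmt!r}")
    lines = []
    lines.append("=" * 72)
    lines.append(f"ciflint validation report ({report.provenance.get('toolkit')})")
    lines.append("=" * 72)
    for b in report.blocks:
        lines.append(f"data_{b.name}")
        lines.append("-" * 72)
        rfs = b.summary.get("r_factors")
        if rfs:
            lines.append("  R1       wR2      S        set")
            for label, (r1, wr2, s) in rfs.items():
                lines.append(f"  {_fmt(r1):8s} {_fmt(wr2):8s} {_fmt(s):8s} "
                             f"{label}")
        for key in ("rint", "completeness", "residual_density", "flack_x",
                    "void_volume", "reflection_source", "observed_criterion",
                    "fabrication"):
            if key in b.summary:
                val = b.summary[key]
                if isinstance(val, tuple):
                    val = " ".join(_fmt(v) for v in val)
                else:
                    val = _fmt(val)
                lines.append(f"  {key:20s} {val}")
        counts = ", ".join(f"{lvl}: {b.count(lvl)}" for lvl in _LEVELS)
        lines.append(f"  ALERT counts  {counts}")
        for a in b.alerts:
            line = f"  ALERT {a.id:04d} [{a.level}]"
            if explanations:
                line += f" {a.message}"
                if a.value is not None:
                    line += f" (value {_fmt(a.value)}"
                    line += f", threshold {a.threshold})" if a.threshold \
                        else ")"
            lines.append(line)
        lines.append("")
    return "\n".join(lines)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
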