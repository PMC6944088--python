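"""Agreement statistics recomputed from reflection data.

All intensity statistics work on F^2. The observed criterion defaults to
I > 2 sigma(I); it is configurable and every report states which was used.
The two-parameter weighting scheme is

    w = 1 / [ sigma^2(Fo^2) + (a P)^2 + b P ],   P = (max(Fo^2, 0) + 2 Fc^2)/3,

i.e. negative Fo^2 are clamped only inside P, never in the residuals.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import stats as _st

from .core import ReflectionSet, UnitCell
from .symmetry import SpaceGroupSetting, extinct_mask

__all__ = [
    "WeightParams", "RFactors", "VarianceTable", "AbsoluteStructureEstimate",
    "resolution_measures", "merge_equivalents", "completeness_profile",
    "weights", "r_factors", "analysis_of_variance", "normal_probability",
    "absolute_structure_estimate", "fabrication_screen",
]


@dataclass(frozen=True)
class WeightParams:
    a: float = 0.0
    b: float = 0.0

    def __post_init__(self):
        if self.a < 0 or self.b < 0:
            raise ValueError("weighting parameters must be non-negative")


def resolution_measures(s: float, wavelength: float) -> Tuple[float, float]:
    """(theta in degrees, d in Angstrom) for s = sin(theta)/lambda.

    theta = arcsin(s lambda); d = 1/(2s). s lambda > 1 is unreachable.
    """
    x = s * wavelength
    if x < 0 or x > 1:
        raise ValueError(f"sin(theta) = {x:.4f} outside [0, 1]: resolution "
                         f"unreachable at this wavelength")
    theta = math.degrees(math.asin(x))
    d = math.inf if s == 0 else 1.0 / (2.0 * s)
    return theta, d


# ---------------------------------------------------------------------------
# merging


def _orbit_reps(hkl: np.ndarray, laue_rotations, include_friedel: bool = True
                ) -> np.ndarray:
    """Canonical representative (lexicographically largest image) per row."""
    images = [hkl @ np.asarray(r) for r in laue_rotations]
    if include_friedel:
        images += [-im for im in images]
    stack = np.stack(images, axis=1)  # n x nops x 3
    # lexicographic max over images
    keys = (stack[..., 0] * 4_000_000 + stack[..., 1] * 2_000 + stack[..., 2])
    best = np.argmax(keys, axis=1)
    return stack[np.arange(len(hkl)), best]


def merge_equivalents(rs: ReflectionSet, laue_rotations,
                      include_friedel: bool = True
                      ) -> Tuple[ReflectionSet, Optional[float]]:
    """Inverse-variance merge under the Laue group.

    Rint = sum |Fo^2 - <Fo^2>| / sum Fo^2 over groups measured more than
    once (None when no reflection is multiply measured).
    """
    reps = _orbit_reps(rs.hkl, laue_rotations, include_friedel)
    order = np.lexsort((reps[:, 2], reps[:, 1], reps[:, 0]))
    reps_sorted = reps[order]
    boundaries = np.any(np.diff(reps_sorted, axis=0) != 0, axis=1)
    group_ids = np.concatenate([[0], np.cumsum(boundaries)])
    n_groups = group_ids[-1] + 1
    w = 1.0 / rs.sigma[order] ** 2
    i_sorted = rs.fo2[order]
    sum_w = np.bincount(group_ids, weights=w, minlength=n_groups)
    sum_wi = np.bincount(group_ids, weights=w * i_sorted, minlength=n_groups)
    counts = np.bincount(group_ids, minlength=n_groups)
    mean = sum_wi / sum_w
    # Rint over multiply measured groups
    multi = counts[group_ids] >= 2
    num = np.abs(i_sorted - mean[group_ids])[multi].sum()
    den = i_sorted[multi].sum()
    rint = float(num / den) if multi.any() and den > 0 else (
        0.0 if multi.any() else None)
    first = np.concatenate([[0], 1 + np.nonzero(boundaries)[0]])
    out_hkl = reps_sorted[first]
    out_fo2 = mean
    out_sig = 1.0 / np.sqrt(sum_w)
    fc2 = None if rs.fc2 is None else rs.fc2[order][first]
    phase = None if rs.phase is None else rs.phase[order][first]
    merged = ReflectionSet(out_hkl, out_fo2, out_sig, fc2=fc2, phase=phase,
                           cell=rs.cell, wavelength=rs.wavelength, merged=True)
    return merged, rint


# ---------------------------------------------------------------------------
# completeness


@dataclass
class CompletenessShell:
    s_lo: float
    s_hi: float
    possible: int
    measured: int
    observed: int

    @property
    def completeness(self) -> float:
        return self.measured / self.possible if self.possible else 1.0

    @property
    def observed_fraction(self) -> float:
        return self.observed / self.measured if self.measured else 0.0


@dataclass
class CompletenessProfile:
    shells: List[CompletenessShell]
    completeness_at_0_6: Optional[float]
    completeness_at_smax: float
    s_max: float
    suggested_cutoff: Optional[float]


def unique_reflection_count(setting: SpaceGroupSetting, cell: UnitCell,
                            s_limit: float,
                            include_friedel: bool = True) -> int:
    """Symmetry-unique, non-extinct lattice points with s <= limit."""
    return len(_unique_set(setting, cell, s_limit, include_friedel))


def _unique_set(setting, cell, s_limit, include_friedel=True):
    gstar = cell.reciprocal_metric
    bounds = [int(2.0 * s_limit / math.sqrt(gstar[i, i])) + 1 for i in range(3)]
    axes = [np.arange(-b, b + 1) for b in bounds]
    h, k, l = np.meshgrid(*axes, indexing="ij")
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    s = cell.s_of(hkl)
    hkl = hkl[s <= s_limit + 1e-12]
    hkl = hkl[~extinct_mask(hkl, setting)]
    reps = _orbit_reps(hkl, setting.laue_rotations, include_friedel)
    return {tuple(r) for r in reps.tolist()}


def completeness_profile(rs: ReflectionSet, setting: SpaceGroupSetting,
                         cell: UnitCell, s_max: Optional[float] = None,
                         n_shells: int = 10, observed_nsigma: float = 2.0,
                         noise_threshold: float = 0.30) -> CompletenessProfile:
    """Shell-wise completeness and observed fractions up to s_max.

    'Possible' counts symmetry-unique non-extinct lattice points; shells are
    equal-width in s. The suggested noise cutoff is the first shell boundary
    beyond which the observed fraction I > n sigma drops below the
    threshold.
    """
    s_meas = cell.s_of(rs.hkl)
    if s_max is None:
        s_max = float(s_meas.max())
    reps = _orbit_reps(rs.hkl, setting.laue_rotations, True)
    not_extinct = ~extinct_mask(rs.hkl, setting)
    uniq_meas: Dict[tuple, bool] = {}
    for rep, fo2, sig, keep in zip(map(tuple, reps.tolist()), rs.fo2,
                                   rs.sigma, not_extinct):
        if not keep:
            continue  # extinct positions are excluded from 'possible' too
        obs = fo2 > observed_nsigma * sig
        uniq_meas[rep] = uniq_meas.get(rep, False) or bool(obs)
    possible = _unique_set(setting, cell, s_max)
    edges = np.linspace(0.0, s_max, n_shells + 1)
    poss_arr = np.array(sorted(possible))
    s_poss = cell.s_of(poss_arr)
    meas_arr = np.array(sorted(uniq_meas))
    s_meas_u = cell.s_of(meas_arr)
    obs_flags = np.array([uniq_meas[tuple(r)] for r in meas_arr.tolist()])
    shells = []
    for i in range(n_shells):
        lo, hi = edges[i], edges[i + 1]
        in_poss = (s_poss > lo) & (s_poss <= hi + (1e-12 if i == n_shells - 1 else 0))
        in_meas = (s_meas_u > lo) & (s_meas_u <= hi + (1e-12 if i == n_shells - 1 else 0))
        shells.append(CompletenessShell(
            s_lo=float(lo), s_hi=float(hi),
            possible=int(in_poss.sum()), measured=int(in_meas.sum()),
            observed=int(obs_flags[in_meas].sum())))
    def _completeness_to(limit):
        p = (s_poss <= limit + 1e-12).sum()
        m = (s_meas_u <= limit + 1e-12).sum()
        return float(m / p) if p else 1.0
    comp06 = _completeness_to(0.6) if s_max >= 0.6 - 1e-9 else None
    comp_max = _completeness_to(s_max)
    cutoff = None
    for sh in shells:
        if sh.measured and sh.observed_fraction < noise_threshold:
            cutoff = sh.s_lo
            break
    return CompletenessProfile(shells=shells, completeness_at_0_6=comp06,
                               completeness_at_smax=comp_max, s_max=s_max,
                               suggested_cutoff=cutoff)


# ---------------------------------------------------------------------------
# weights and R factors


def weights(fo2, sigma, fc2, p: WeightParams) -> np.ndarray:
    fo2 = np.asarray(fo2, dtype=float)
    fc2 = np.asarray(fc2, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    big_p = (np.maximum(fo2, 0.0) + 2.0 * fc2) / 3.0
    return 1.0 / (sigma ** 2 + (p.a * big_p) ** 2 + p.b * big_p)


@dataclass
class RFactors:
    r1: Optional[float]
    wr2: float
    goof: Optional[float]
    n_observed: int
    n_all: int
    observed_criterion: str = "I > 2sigma(I)"


def r_factors(rs: ReflectionSet, p: WeightParams, n_params: int = 1,
              observed_nsigma: float = 2.0) -> RFactors:
    """R1 (on F, observed subset), wR2 and GooF (on F^2, all data).

    Negative Fo^2 contribute |Fo| = 0 to R1. R1 is None when nothing meets
    the observed criterion; GooF is None when n <= n_params.
    """
    if rs.fc2 is None:
        raise ValueError("Fc^2 required to compute R factors")
    w = weights(rs.fo2, rs.sigma, rs.fc2, p)
    delta2 = rs.fo2 - rs.fc2
    num_w = float((w * delta2 ** 2).sum())
    den_w = float((w * rs.fo2 ** 2).sum())
    wr2 = math.sqrt(num_w / den_w) if den_w > 0 else 0.0
    n = len(rs)
    goof = math.sqrt(num_w / (n - n_params)) if n > n_params else None
    obs = rs.fo2 > observed_nsigma * rs.sigma
    if obs.any():
        fo = np.sqrt(np.maximum(rs.fo2[obs], 0.0))
        fc = np.sqrt(np.maximum(rs.fc2[obs], 0.0))
        den = fo.sum()
        r1 = float(np.abs(fo - fc).sum() / den) if den > 0 else None
    else:
        r1 = None
    return RFactors(r1=r1, wr2=wr2, goof=goof, n_observed=int(obs.sum()),
                    n_all=n,
                    observed_criterion=f"I > {observed_nsigma:g}sigma(I)")


# ---------------------------------------------------------------------------
# analysis of variance


@dataclass
class VarianceBin:
    label: str
    n: int
    k: float              # <Fo^2>/<Fc^2>
    goof: float           # sqrt(sum w (Fo^2-Fc^2)^2 / n)
    observed_fraction: float


@dataclass
class VarianceTable:
    axis: str  # "resolution" | "fc_fraction"
    bins: List[VarianceBin]
    findings: List = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(b.n for b in self.bins)


_FC_EDGES = (0.0, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0)


def analysis_of_variance(rs: ReflectionSet, p: WeightParams,
                         n_bins: int = 10, k_limits=(0.8, 1.2),
                         goof_limit: float = 2.0,
                         observed_nsigma: float = 2.0,
                         min_bin: int = 10
                         ) -> Tuple[VarianceTable, VarianceTable]:
    """Fit statistics binned by resolution (equal population) and by
    Fc/Fc(max) (fixed fractional edges). K or bin-GooF outside limits
    become findings on the table; bins thinner than ``min_bin`` are listed
    but never flagged (the statistics are chi^2-noisy there)."""
    from .symmetry import Finding

    if rs.fc2 is None:
        raise ValueError("Fc^2 required for the analysis of variance")
    w = weights(rs.fo2, rs.sigma, rs.fc2, p)
    delta2 = rs.fo2 - rs.fc2
    obs = rs.fo2 > observed_nsigma * rs.sigma

    def table(axis, bin_idx, labels, n_total) -> VarianceTable:
        bins = []
        findings = []
        for bi in range(n_total):
            mask = bin_idx == bi
            n = int(mask.sum())
            if n == 0:
                bins.append(VarianceBin(labels[bi], 0, 1.0, 0.0, 0.0))
                continue
            mean_fc2 = rs.fc2[mask].mean()
            k = float(rs.fo2[mask].mean() / mean_fc2) if mean_fc2 > 0 else math.inf
            g = math.sqrt(float((w[mask] * delta2[mask] ** 2).sum()) / n)
            bins.append(VarianceBin(labels[bi], n, k, g,
                                    float(obs[mask].mean())))
            if n < min_bin:
                continue
            if not (k_limits[0] <= k <= k_limits[1]):
                findings.append(Finding(
                    "variance_k",
                    f"scaling K = {k:.2f} in {axis} bin {labels[bi]} outside "
                    f"[{k_limits[0]}, {k_limits[1]}]", value=k))
            if g > goof_limit:
                findings.append(Finding(
                    "variance_goof",
                    f"GooF = {g:.2f} in {axis} bin {labels[bi]} exceeds "
                    f"{goof_limit}", value=g))
        return VarianceTable(axis=axis, bins=bins, findings=findings)

    s = rs.s() if rs.cell is not None else np.arange(len(rs), dtype=float)
    order = np.argsort(s, kind="stable")
    ranks = np.empty(len(s), dtype=int)
    ranks[order] = np.arange(len(s))
    res_idx = np.minimum((ranks * n_bins) // len(s), n_bins - 1)
    res_labels = []
    for bi in range(n_bins):
        sel = s[res_idx == bi]
        res_labels.append(f"{sel.min():.3f}-{sel.max():.3f}" if len(sel) else "-")
    t_res = table("resolution", res_idx, res_labels, n_bins)

    fc = np.sqrt(np.maximum(rs.fc2, 0.0))
    frac = fc / fc.max() if fc.max() > 0 else fc
    fc_idx = np.clip(np.searchsorted(_FC_EDGES, frac, side="left") - 1,
                     0, len(_FC_EDGES) - 2)
    fc_labels = [f"{_FC_EDGES[i]:.1f}-{_FC_EDGES[i+1]:.1f}"
                 for i in range(len(_FC_EDGES) - 1)]
    t_fc = table("fc_fraction", fc_idx, fc_labels, len(_FC_EDGES) - 1)
    return t_res, t_fc


# ---------------------------------------------------------------------------
# normal probability plot


@dataclass
class NormalProbability:
    slope: float
    intercept: float
    max_central_deviation: float
    degenerate: bool = False


def normal_probability(rs: ReflectionSet, p: WeightParams,
                       central_fraction: float = 0.8) -> NormalProbability:
    """Ordered weighted residuals against normal order statistics.

    A straight central part with slope ~1 indicates a healthy error model;
    the S-shape metric is the largest deviation from the central fit line.
    """
    if rs.fc2 is None:
        raise ValueError("Fc^2 required")
    n = len(rs)
    if n < 10:
        raise ValueError("too few reflections for a normal probability plot")
    w = weights(rs.fo2, rs.sigma, rs.fc2, p)
    delta = np.sort((rs.fo2 - rs.fc2) * np.sqrt(w))
    expected = _st.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    if np.ptp(delta) == 0:
        return NormalProbability(slope=0.0, intercept=float(delta[0]),
                                 max_central_deviation=0.0, degenerate=True)
    lo = int(n * (1 - central_fraction) / 2)
    hi = n - lo
    slope, intercept = np.polyfit(expected[lo:hi], delta[lo:hi], 1)
    dev = np.abs(delta[lo:hi] - (slope * expected[lo:hi] + intercept))
    return NormalProbability(slope=float(slope), intercept=float(intercept),
                             max_central_deviation=float(dev.max()))


# ---------------------------------------------------------------------------
# absolute structure (Parsons-style quotient fit)


@dataclass
class AbsoluteStructureEstimate:
    x: float
    su: float
    n_pairs: int
    decision: str  # keep | invert | indeterminate


def absolute_structure_estimate(rs: ReflectionSet, min_qc: float = 1e-4
                                ) -> AbsoluteStructureEstimate:
    """Parsons-style quotient fit of the inversion-twin fraction x.

    Observed Bijvoet quotients q_o = (I+ - I-)/(I+ + I-) are regressed on
    the calculated quotients q_c of the x = 0 model via q_o = (1 - 2x) q_c,
    weighted by the propagated variance of q_o. Pairs with |q_c| below
    ``min_qc`` carry no signal and are dropped.
    """
    if rs.fc2 is None:
        raise ValueError("Fc^2 for both Friedel mates required")
    data: Dict[tuple, List[int]] = {}
    for idx, h in enumerate(map(tuple, rs.hkl.tolist())):
        data.setdefault(h, []).append(idx)

    def avg(idx_list):
        w = 1.0 / rs.sigma[idx_list] ** 2
        i = float((w * rs.fo2[idx_list]).sum() / w.sum())
        sig = float(1.0 / math.sqrt(w.sum()))
        fc = float(np.mean(rs.fc2[idx_list]))
        return i, sig, fc

    qo, qc, var = [], [], []
    seen = set()
    for h in data:
        if h in seen:
            continue
        mh = tuple(-v for v in h)
        if mh not in data or mh == h:
            continue
        seen.add(h)
        seen.add(mh)
        ip, sp, fcp = avg(data[h])
        im, sm, fcm = avg(data[mh])
        den_o = ip + im
        den_c = fcp + fcm
        if den_o <= 0 or den_c <= 0:
            continue
        q_c = (fcp - fcm) / den_c
        if abs(q_c) < min_qc:
            continue
        q_o = (ip - im) / den_o
        v = ((2 * im * sp) ** 2 + (2 * ip * sm) ** 2) / den_o ** 4
        qo.append(q_o)
        qc.append(q_c)
        var.append(max(v, 1e-20))
    n_pairs = len(qo)
    if n_pairs < 2:
        raise ValueError("not estimable: fewer than 2 Bijvoet pairs with "
                         "resonant signal (centrosymmetric or no f'')")
    qo = np.array(qo)
    qc = np.array(qc)
    w = 1.0 / np.array(var)
    denom = float((w * qc * qc).sum())
    slope = float((w * qc * qo).sum() / denom)
    x = (1.0 - slope) / 2.0
    su = 0.5 / math.sqrt(denom)
    if abs(x - 0.5) < 2.0 * su:
        decision = "indeterminate"
    elif x > 0.5:
        decision = "invert"
    else:
        decision = "keep"
    return AbsoluteStructureEstimate(x=x, su=su, n_pairs=n_pairs,
                                     decision=decision)


# ---------------------------------------------------------------------------
# fabricated-data screen


@dataclass
class FabricationScreen:
    verdict: str  # suspicious | unremarkable | not_assessed
    r_squared: Optional[float] = None
    rms_relative_residual: Optional[float] = None
    plot_data: Optional[np.ndarray] = None  # columns: 1/sigma, log10(I)


def fabrication_screen(rs: ReflectionSet, min_n: int = 50,
                       r2_limit: float = 0.9999,
                       rel_limit: float = 0.01) -> FabricationScreen:
    """Screen for sigmas that are an exact smooth function of intensity.

    Fits sigma^2 = c0 + c1 I + c2 I^2 over positive intensities; an almost
    perfect fit (R^2 and relative residuals beyond the limits) is flagged as
    suspicious -- an indication, never proof, of fabricated data. The
    relative-residual limit of 1% leaves room for the fixed-point rounding
    of reflection formats while staying an order of magnitude below the
    scatter of genuine counting statistics.
    """
    pos = rs.fo2 > 0
    n = int(pos.sum())
    if n < min_n:
        return FabricationScreen(verdict="not_assessed")
    i = rs.fo2[pos]
    sig = rs.sigma[pos]
    target = sig ** 2
    design = np.stack([np.ones_like(i), i, i * i], axis=1)
    coef, *_ = np.linalg.lstsq(design, target, rcond=None)
    fitted = design @ coef
    ss_res = float(((target - fitted) ** 2).sum())
    ss_tot = float(((target - target.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    sig_fit = np.sqrt(np.maximum(fitted, 0.0))
    rel = float(np.sqrt(np.mean(((sig - sig_fit) / sig) ** 2)))
    verdict = "suspicious" if (r2 > r2_limit and rel < rel_limit) else "unremarkable"
    plot = np.stack([1.0 / sig, np.log10(i)], axis=1)
    return FabricationScreen(verdict=verdict, r_squared=r2,
                             rms_relative_residual=rel, plot_data=plot)
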