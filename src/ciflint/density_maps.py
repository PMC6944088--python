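"""Difference-density synthesis and evaluation.

The Fc-phased |Fo| - |Fc| map is evaluated on a periodic grid by FFT,

    rho(x) = (1/V) sum_h (|Fo| - |Fc|) exp(i phi_c(h)) exp(-2 pi i h.x),

Friedel-completed and with the F(000) term excluded, so the map mean is
exactly zero. Solvent-accessible voids are found on a separate occupancy
grid: a voxel is blocked when it lies within r_vdW + probe of any
symmetry-expanded atom; unblocked voxels are clustered under periodic
6-connectivity.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.fft import next_fast_len

from . import elements
from .core import ReflectionSet, StructureModel, UnitCell
from .symmetry import Finding

__all__ = [
    "DensityGrid", "Peak", "VoidRegion", "VoidSearchResult",
    "difference_map", "map_report", "peak_search", "h_site_support",
    "find_voids", "void_electron_count", "export_grid",
]


@dataclass
class DensityGrid:
    values: np.ndarray  # e/A^3, indexed [ix, iy, iz], origin at (0,0,0)
    cell: UnitCell

    @property
    def dims(self) -> Tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        return self.cell.volume / np.prod(self.dims)

    def interpolate(self, frac) -> float:
        """Trilinear, periodic."""
        x = np.asarray(frac, dtype=float) % 1.0
        dims = np.array(self.dims)
        g = x * dims
        i0 = np.floor(g).astype(int)
        f = g - i0
        acc = 0.0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    wgt = ((f[0] if dx else 1 - f[0])
                           * (f[1] if dy else 1 - f[1])
                           * (f[2] if dz else 1 - f[2]))
                    idx = (i0 + (dx, dy, dz)) % dims
                    acc += wgt * self.values[tuple(idx)]
        return float(acc)


class MapError(ValueError):
    pass


def _grid_dims(cell: UnitCell, hkl: np.ndarray, grid_step: float) -> Tuple[int, int, int]:
    maxidx = np.abs(hkl).max(axis=0)
    dims = []
    for length, hmax in zip(cell.lengths, maxidx):
        n = max(int(math.ceil(length / grid_step)), 2 * int(hmax) + 1, 4)
        dims.append(next_fast_len(n))
    return tuple(dims)


def difference_map(rs: ReflectionSet, grid_step: float = 0.2) -> DensityGrid:
    """Fc-phased difference map from merged coefficients with phases.

    Requires Fc^2 and the calculated phase (degrees). ``grid_step`` must be
    finer than d_min/3; the grid is refined to satisfy both that and the
    index Nyquist bound.
    """
    if rs.cell is None:
        raise MapError("reflection set carries no cell")
    if rs.fc2 is None or rs.phase is None:
        raise MapError("difference synthesis needs Fc^2 and phases")
    if len(rs) == 0:
        raise MapError("empty coefficient set")
    s = rs.s()
    d_min = float(1.0 / (2.0 * s.max()))
    if grid_step > d_min / 3.0 + 1e-9:
        raise MapError(f"grid step {grid_step} A too coarse for d_min "
                       f"{d_min:.2f} A (need <= d_min/3)")
    dims = _grid_dims(rs.cell, rs.hkl, grid_step)
    coeff = np.zeros(dims, dtype=complex)
    dfa = np.sqrt(np.maximum(rs.fo2, 0.0)) - np.sqrt(np.maximum(rs.fc2, 0.0))
    phases = np.deg2rad(rs.phase)
    values = dfa * np.exp(1j * phases)
    seen = set()
    for (h, k, l), v in zip(map(tuple, rs.hkl.tolist()), values):
        if (h, k, l) == (0, 0, 0):
            continue  # F(000) excluded by construction
        if (h, k, l) in seen:
            continue
        seen.add((h, k, l))
        coeff[h % dims[0], k % dims[1], l % dims[2]] += v
        if (-h, -k, -l) not in seen:
            # Friedel completion with the conjugate coefficient
            coeff[-h % dims[0], -k % dims[1], -l % dims[2]] += np.conj(v)
            seen.add((-h, -k, -l))
    rho = np.fft.fftn(coeff).real / rs.cell.volume
    return DensityGrid(values=rho, cell=rs.cell)


def direct_summation(rs: ReflectionSet, dims: Tuple[int, int, int]) -> DensityGrid:
    """Reference Fourier synthesis by explicit summation (small sets only)."""
    if rs.fc2 is None or rs.phase is None or rs.cell is None:
        raise MapError("needs Fc^2, phases and a cell")
    dfa = np.sqrt(np.maximum(rs.fo2, 0.0)) - np.sqrt(np.maximum(rs.fc2, 0.0))
    values = dfa * np.exp(1j * np.deg2rad(rs.phase))
    grid = np.zeros(dims, dtype=complex)
    xs = [np.arange(n) / n for n in dims]
    fx, fy, fz = np.meshgrid(*xs, indexing="ij")
    seen = set()
    for (h, k, l), v in zip(map(tuple, rs.hkl.tolist()), values):
        if (h, k, l) == (0, 0, 0) or (h, k, l) in seen:
            continue
        seen.add((h, k, l))
        grid += v * np.exp(-2j * np.pi * (h * fx + k * fy + l * fz))
        if (-h, -k, -l) not in seen:
            seen.add((-h, -k, -l))
            grid += np.conj(v) * np.exp(2j * np.pi * (h * fx + k * fy + l * fz))
    return DensityGrid(values=grid.real / rs.cell.volume, cell=rs.cell)


# ---------------------------------------------------------------------------
# map evaluation


@dataclass
class Peak:
    frac: Tuple[float, float, float]
    height: float
    nearest_atom: Optional[str]
    distance: Optional[float]


@dataclass
class MapReport:
    rho_min: float
    rho_max: float
    site_density: Dict[str, float]
    bond_midpoint_mean: Optional[float]
    findings: List[Finding] = field(default_factory=list)


def _expanded_positions(model: StructureModel):
    ops = model.setting.ops if model.setting is not None else []
    out = []
    for site in model.sites:
        for op in (ops or [None]):
            pos = np.asarray(site.xyz, float) if op is None else op.apply(site.xyz)
            out.append((site.label, pos % 1.0))
    return out


def _nearest_atom(model: StructureModel, frac) -> Tuple[Optional[str], Optional[float]]:
    best = (None, None)
    for label, pos in _expanded_positions(model):
        d = model.cell.distance(frac, pos)
        if best[1] is None or d < best[1]:
            best = (label, d)
    return best


def map_report(grid: DensityGrid, model: StructureModel,
               bonds: Optional[Sequence] = None,
               reported_extrema: Optional[Tuple[float, float]] = None,
               featureless_bound: float = 0.5,
               level_bounds: Tuple[float, float, float] = (0.5, 1.0, 1.5),
               on_atom_threshold: float = 0.5,
               heavy_z: int = 20) -> MapReport:
    """Extrema, on-atom and on-bond density with gradings.

    Excursions beyond ~+-0.5 e/A^3 grade C/B/A at 0.5/1.0/1.5; extrema
    within 1 A of a heavy atom (Z >= heavy_z) are reported separately as
    probable absorption artefacts. A reported-vs-recalculated extremum
    mismatch beyond 0.05 + 5 % is a finding, as is large on-atom density
    (possible wrong atom type).
    """
    vals = grid.values
    rho_min = float(vals.min())
    rho_max = float(vals.max())
    findings: List[Finding] = []
    for rho, word in ((rho_max, "maximum"), (rho_min, "minimum")):
        mag = abs(rho)
        if mag <= featureless_bound:
            continue
        idx = np.unravel_index(np.argmax(vals) if rho == rho_max
                               else np.argmin(vals), vals.shape)
        frac = np.array(idx) / np.array(vals.shape)
        label, dist = _nearest_atom(model, frac)
        heavy = False
        if label is not None and dist is not None and dist <= 1.0:
            try:
                site = model.site_by_label(label)
                heavy = elements.atomic_number(site.element) >= heavy_z
            except KeyError:
                pass
        if heavy:
            findings.append(Finding(
                "density_near_heavy",
                f"residual-density {word} {rho:+.2f} e/A^3 within 1 A of "
                f"heavy atom {label}: probable absorption artefact",
                value=rho))
            continue
        level = "C"
        if mag > level_bounds[2]:
            level = "A"
        elif mag > level_bounds[1]:
            level = "B"
        findings.append(Finding(
            f"density_extremum_{level}",
            f"residual-density {word} {rho:+.2f} e/A^3 exceeds the "
            f"featureless bound (+-{featureless_bound}) "
            f"[nearest atom {label}, {dist:.2f} A]", value=rho))
    if reported_extrema is not None:
        rep_min, rep_max = min(reported_extrema), max(reported_extrema)
        for rep, calc, word in ((rep_max, rho_max, "maximum"),
                                (rep_min, rho_min, "minimum")):
            tol = 0.05 + 0.05 * abs(calc)
            if abs(rep - calc) > tol:
                findings.append(Finding(
                    "density_report_mismatch",
                    f"reported residual-density {word} {rep:+.2f} differs "
                    f"from recalculated {calc:+.2f} e/A^3",
                    value=abs(rep - calc)))
    site_density = {}
    for site in model.sites:
        rho = grid.interpolate(site.xyz)
        site_density[site.label] = rho
        if not site.is_h and abs(rho) > on_atom_threshold:
            findings.append(Finding(
                "on_atom_density",
                f"|difference density| {rho:+.2f} e/A^3 on atom {site.label}: "
                f"possible atom-type error", value=rho))
    bond_mean = None
    if bonds:
        mids = []
        for b in bonds:
            xa = np.asarray(model.sites[b.i].xyz, float)
            xb = np.asarray(model.sites[b.j].xyz, float)
            d = xb - xa
            d -= np.round(d)
            mids.append(grid.interpolate(xa + d / 2))
        bond_mean = float(np.mean(mids)) if mids else None
    return MapReport(rho_min=rho_min, rho_max=rho_max,
                     site_density=site_density,
                     bond_midpoint_mean=bond_mean, findings=findings)


def peak_search(grid: DensityGrid, model: Optional[StructureModel] = None,
                threshold: float = 0.2, max_peaks: int = 20) -> List[Peak]:
    """Local maxima above threshold with parabolic sub-voxel interpolation."""
    v = grid.values
    is_max = np.ones_like(v, dtype=bool)
    for axis in range(3):
        for shift in (1, -1):
            is_max &= v >= np.roll(v, shift, axis=axis)
    is_max &= v > threshold
    peaks = []
    dims = np.array(v.shape)
    for idx in np.argwhere(is_max):
        pos = idx.astype(float)
        for axis in range(3):
            m = np.array(idx)
            f0 = v[tuple(m)]
            m[axis] = (idx[axis] + 1) % dims[axis]
            fp = v[tuple(m)]
            m[axis] = (idx[axis] - 1) % dims[axis]
            fm = v[tuple(m)]
            denom = fm - 2 * f0 + fp
            if denom < 0:
                pos[axis] += 0.5 * (fm - fp) / denom
        frac = tuple((pos / dims) % 1.0)
        label = dist = None
        if model is not None:
            label, dist = _nearest_atom(model, frac)
        peaks.append(Peak(frac=frac, height=float(v[tuple(idx)]),
                          nearest_atom=label, distance=dist))
    peaks.sort(key=lambda p: -p.height)
    return peaks[:max_peaks]


def h_site_support(grid: DensityGrid, model: StructureModel,
                   mode: str = "asis",
                   asis_threshold: float = -0.2,
                   omit_threshold: float = 0.2) -> Dict[str, bool]:
    """Per-H-atom support flags (True = supported by the density).

    ``asis`` mode inspects the as-is difference map (H present in the
    model): density below -0.2 e/A^3 marks a misplaced H. ``omit`` mode
    expects a map computed with the H atoms left out of Fc: support then
    requires positive density above +0.2 e/A^3 at the site.
    """
    if mode not in ("asis", "omit"):
        raise ValueError("mode must be 'asis' or 'omit'")
    out = {}
    for site in model.sites:
        if not site.is_h:
            continue
        rho = grid.interpolate(site.xyz)
        if mode == "asis":
            out[site.label] = rho >= asis_threshold
        else:
            out[site.label] = rho >= omit_threshold
    return out


# ---------------------------------------------------------------------------
# voids


@dataclass
class VoidRegion:
    voxel_count: int
    volume: float
    centroid: Tuple[float, float, float]
    voxels: np.ndarray  # (n, 3) indices
    electron_count: Optional[float] = None


@dataclass
class VoidSearchResult:
    regions: List[VoidRegion]
    suppressed: int
    dims: Tuple[int, int, int]
    occupied_volume: float
    cell_volume: float


def _occupancy_mask(model: StructureModel, dims, probe: float) -> np.ndarray:
    cell = model.cell
    occ = np.zeros(dims, dtype=bool)
    ops = model.setting.ops if model.setting is not None else []
    positions = []
    for site in model.sites:
        r = elements.vdw_radius(site.element) + probe
        for op in (ops or [None]):
            pos = np.asarray(site.xyz, float) if op is None else op.apply(site.xyz)
            positions.append((pos % 1.0, r))
    nd = np.array(dims)
    orth = cell.orthogonalization
    # conservative fractional half-widths of the covering box per axis
    frac_inv = np.abs(cell.fractionalization)
    for pos, r in positions:
        half = frac_inv @ np.array([r, r, r])
        lo = np.floor((pos - half) * nd).astype(int)
        hi = np.ceil((pos + half) * nd).astype(int)
        ranges = [np.arange(lo[i], hi[i] + 1) for i in range(3)]
        gx, gy, gz = np.meshgrid(*ranges, indexing="ij")
        frac = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1) / nd
        d = frac - pos
        cart = d @ orth.T
        within = (cart ** 2).sum(axis=1) <= r * r
        if not within.any():
            continue
        idx = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)[within] % nd
        occ[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return occ


def _label_periodic(mask: np.ndarray):
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return labels, 0
    parent = list(range(n + 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for axis in range(3):
        lo = np.take(labels, 0, axis=axis)
        hi = np.take(labels, labels.shape[axis] - 1, axis=axis)
        both = (lo > 0) & (hi > 0)
        for a, b in zip(lo[both].ravel(), hi[both].ravel()):
            union(int(a), int(b))
    remap = {}
    next_id = 0
    for lab in range(1, n + 1):
        r = find(lab)
        if r not in remap:
            next_id += 1
            remap[r] = next_id
    lut = np.zeros(n + 1, dtype=int)
    for lab in range(1, n + 1):
        lut[lab] = remap[find(lab)]
    return lut[labels], next_id


def find_voids(model: StructureModel, probe: float = 1.2,
               grid_step: float = 0.2, min_volume: float = 20.0,
               dims: Optional[Tuple[int, int, int]] = None
               ) -> VoidSearchResult:
    """Solvent-accessible void regions.

    Voxels beyond r_vdW + probe of every symmetry-expanded atom are
    clustered under periodic 6-connectivity; regions below ``min_volume``
    A^3 are suppressed but counted. Pass ``dims`` to sample on the same
    grid as an existing :class:`DensityGrid` (required for
    :func:`void_electron_count`).
    """
    if probe < 0:
        raise ValueError("probe radius must be non-negative")
    cell = model.cell
    if dims is None:
        dims = tuple(max(4, int(math.ceil(length / grid_step)))
                     for length in cell.lengths)
    occ = _occupancy_mask(model, dims, probe)
    voxel_vol = cell.volume / np.prod(dims)
    labels, n = _label_periodic(~occ)
    regions = []
    suppressed = 0
    for lab in range(1, n + 1):
        voxels = np.argwhere(labels == lab)
        vol = len(voxels) * voxel_vol
        if vol < min_volume:
            suppressed += 1
            continue
        centroid = _periodic_centroid(voxels, dims)
        regions.append(VoidRegion(voxel_count=len(voxels), volume=float(vol),
                                  centroid=centroid, voxels=voxels))
    regions.sort(key=lambda r: -r.volume)
    return VoidSearchResult(regions=regions, suppressed=suppressed, dims=dims,
                            occupied_volume=float(occ.sum() * voxel_vol),
                            cell_volume=cell.volume)


def _periodic_centroid(voxels: np.ndarray, dims) -> Tuple[float, float, float]:
    out = []
    for axis in range(3):
        ang = voxels[:, axis] * (2 * math.pi / dims[axis])
        mean = math.atan2(np.sin(ang).mean(), np.cos(ang).mean())
        out.append((mean / (2 * math.pi)) % 1.0)
    return tuple(out)


def void_electron_count(void: VoidRegion, grid: DensityGrid) -> float:
    """Integrated electrons over the void voxels of a difference map that
    was synthesized from a model with the void content omitted."""
    dims = grid.dims
    if np.any(np.max(void.voxels, axis=0) >= np.array(dims)):
        raise MapError("void voxels outside the density grid (grid mismatch)")
    vals = grid.values[void.voxels[:, 0], void.voxels[:, 1], void.voxels[:, 2]]
    return float(vals.sum() * grid.voxel_volume)


def export_grid(grid: DensityGrid) -> str:
    """Plain-text periodic-grid export (header, then voxels fastest-x)."""
    c = grid.cell
    lines = [
        f"cell {c.a:.4f} {c.b:.4f} {c.c:.4f} {c.alpha:.3f} {c.beta:.3f} {c.gamma:.3f}",
        "dims " + " ".join(str(d) for d in grid.dims),
    ]
    flat = np.transpose(grid.values, (2, 1, 0)).ravel()  # z slowest, x fastest
    for i in range(0, len(flat), 6):
        lines.append(" ".join(f"{v:11.4e}" for v in flat[i:i + 6]))
    return "\n".join(lines) + "\n"
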