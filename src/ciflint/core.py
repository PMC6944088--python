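"""Shared containers: unit cell metric, reflections, atom sites.

Conventions used throughout the package:

* fractional coordinates, translations reduced to [0, 1);
* Cartesian frame with **a** along *x* and **b** in the *xy*-plane;
* intensities are F^2 on a common scale, sigma(F^2) > 0;
* s = sin(theta)/lambda in 1/Angstrom, d = 1/(2s).
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["UnitCell", "ReflectionSet", "AtomSite", "StructureModel"]


class CellError(ValueError):
    pass


@dataclass(frozen=True)
class UnitCell:
    """Unit-cell metric with optional standard uncertainties.

    Lengths in Angstrom, angles in degrees.
    """

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    su: Optional[tuple] = None  # (sa, sb, sc, sal, sbe, sga), None entries allowed

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise CellError("cell lengths must be positive")
        if not all(0 < x < 180 for x in (self.alpha, self.beta, self.gamma)):
            raise CellError("cell angles must be in (0, 180) degrees")

    @property
    def lengths(self):
        return (self.a, self.b, self.c)

    @property
    def angles(self):
        return (self.alpha, self.beta, self.gamma)

    @property
    def volume(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x)) for x in self.angles)
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            raise CellError("degenerate cell metric")
        return self.a * self.b * self.c * math.sqrt(arg)

    @property
    def metric(self) -> np.ndarray:
        """Direct-space metric tensor G (Angstrom^2)."""
        a, b, c = self.lengths
        ca, cb, cg = (math.cos(math.radians(x)) for x in self.angles)
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    @property
    def reciprocal_metric(self) -> np.ndarray:
        return np.linalg.inv(self.metric)

    @property
    def orthogonalization(self) -> np.ndarray:
        """Matrix O mapping fractional to Cartesian (a along x, b in xy)."""
        a, b, c = self.lengths
        ca, cb, cg = (math.cos(math.radians(x)) for x in self.angles)
        sg = math.sin(math.radians(self.gamma))
        v = self.volume
        return np.array(
            [
                [a, b * cg, c * cb],
                [0.0, b * sg, c * (ca - cb * cg) / sg],
                [0.0, 0.0, v / (a * b * sg)],
            ]
        )

    @property
    def fractionalization(self) -> np.ndarray:
        return np.linalg.inv(self.orthogonalization)

    def cartesian(self, frac) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.orthogonalization.T

    def s_of(self, hkl) -> np.ndarray:
        """sin(theta)/lambda for index triples (array-friendly)."""
        h = np.atleast_2d(np.asarray(hkl, dtype=float))
        gstar = self.reciprocal_metric
        inv_d2 = np.einsum("ni,ij,nj->n", h, gstar, h)
        s = 0.5 * np.sqrt(inv_d2)
        return s if np.ndim(hkl) > 1 else float(s[0])

    def d_of(self, hkl):
        s = self.s_of(hkl)
        with np.errstate(divide="ignore"):
            return np.where(s > 0, 1.0 / (2.0 * s), np.inf) if np.ndim(s) else (
                math.inf if s == 0 else 1.0 / (2.0 * s)
            )

    def distance(self, frac1, frac2, min_image: bool = True) -> float:
        """Cartesian distance; by default the nearest periodic image."""
        d = np.asarray(frac2, dtype=float) - np.asarray(frac1, dtype=float)
        if min_image:
            d -= np.round(d)
        return float(np.linalg.norm(self.cartesian(d)))


class ReflectionError(ValueError):
    pass


class ReflectionSet:
    """Reflections h,k,l with Fo^2, sigma(Fo^2), optional Fc^2 and phase.

    Intensities may be negative as read; sigmas must be positive. The
    ``merged`` flag records whether symmetry-equivalent measurements have
    been averaged.
    """

    def __init__(
        self,
        hkl,
        fo2,
        sigma,
        fc2=None,
        phase=None,
        cell: Optional[UnitCell] = None,
        wavelength: Optional[float] = None,
        merged: bool = True,
    ):
        self.hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
        self.fo2 = np.asarray(fo2, dtype=float)
        self.sigma = np.asarray(sigma, dtype=float)
        self.fc2 = None if fc2 is None else np.asarray(fc2, dtype=float)
        self.phase = None if phase is None else np.asarray(phase, dtype=float)
        self.cell = cell
        self.wavelength = wavelength
        self.merged = merged
        n = len(self.hkl)
        if n == 0:
            raise ReflectionError("empty reflection set")
        for name, arr in (("fo2", self.fo2), ("sigma", self.sigma)):
            if len(arr) != n:
                raise ReflectionError(f"{name} length does not match hkl")
        if self.fc2 is not None and len(self.fc2) != n:
            raise ReflectionError("fc2 length does not match hkl")
        if np.any(self.sigma <= 0):
            raise ReflectionError("sigma values must be positive")

    def __len__(self):
        return len(self.hkl)

    def s(self) -> np.ndarray:
        if self.cell is None:
            raise ReflectionError("no cell attached")
        return self.cell.s_of(self.hkl)

    def select(self, mask) -> "ReflectionSet":
        return ReflectionSet(
            self.hkl[mask],
            self.fo2[mask],
            self.sigma[mask],
            None if self.fc2 is None else self.fc2[mask],
            None if self.phase is None else self.phase[mask],
            cell=self.cell,
            wavelength=self.wavelength,
            merged=self.merged,
        )

    def replace(self, **kw) -> "ReflectionSet":
        args = dict(
            hkl=self.hkl, fo2=self.fo2, sigma=self.sigma, fc2=self.fc2,
            phase=self.phase, cell=self.cell, wavelength=self.wavelength,
            merged=self.merged,
        )
        args.update(kw)
        return ReflectionSet(**args)


@dataclass
class AtomSite:
    """One labelled site of the asymmetric unit.

    ``uaniso`` follows CIF order (U11, U22, U33, U23, U13, U12) in
    Angstrom^2; ``uaniso_su`` carries the matching standard uncertainties.
    """

    label: str
    element: str
    xyz: tuple
    occupancy: float = 1.0
    uiso: Optional[float] = None
    uaniso: Optional[tuple] = None
    uaniso_su: Optional[tuple] = None
    disordered: bool = False
    calculated: bool = False

    @property
    def is_h(self) -> bool:
        return self.element in ("H", "D")

    @property
    def anisotropic(self) -> bool:
        return self.uaniso is not None

    def u_matrix_cif(self) -> np.ndarray:
        if self.uaniso is None:
            u = self.uiso if self.uiso is not None else 0.0
            return np.eye(3) * u
        u11, u22, u33, u23, u13, u12 = self.uaniso
        return np.array([[u11, u12, u13], [u12, u22, u23], [u13, u23, u33]])


@dataclass
class StructureModel:
    """Asymmetric unit + cell + symmetry, enough to validate against."""

    cell: UnitCell
    sites: list
    setting: object = None  # SpaceGroupSetting; typed loosely to avoid cycles
    wavelength: Optional[float] = None
    z: Optional[int] = None
    formula: Optional[str] = None

    @property
    def non_h_sites(self):
        return [s for s in self.sites if not s.is_h]

    def site_by_label(self, label: str) -> AtomSite:
        for s in self.sites:
            if s.label == label:
                return s
        raise KeyError(label)
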