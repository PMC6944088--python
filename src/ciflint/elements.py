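"""Per-element data: weights, radii, scattering factors, absorption.

Backed by gemmi's compiled tables (standard atomic weights, Bondi-style van
der Waals radii, covalent radii, IT92 four-Gaussian spherical form-factor
coefficients, Cromer-Liberman anomalous terms). The spherical form factor
and the linear absorption coefficient are evaluated here:

* f0(s) = sum_m a_m exp(-b_m s^2) + c  with s = sin(theta)/lambda (1/A);
* the per-atom photoabsorption cross-section follows the optical theorem,
  sigma_a = 2 r_e lambda f''(lambda), which is accurate at the few-percent
  level for ordinary X-ray wavelengths and light-to-medium elements.
"""
from __future__ import annotations

from functools import lru_cache
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "UnknownElementError", "atomic_number", "atomic_weight", "vdw_radius",
    "covalent_radius", "cromer_mann", "form_factor", "anomalous",
    "mu_per_atom", "HC_EV_ANGSTROM", "CU_KA", "MO_KA",
]

HC_EV_ANGSTROM = 12398.425  # E[eV] = HC / lambda[A]
CU_KA = 1.54184
MO_KA = 0.71073
_R_E = 2.8179403e-5  # classical electron radius, Angstrom


class UnknownElementError(ValueError):
    pass


@lru_cache(maxsize=256)
def _element(symbol: str):
    import gemmi

    el = gemmi.Element(symbol)
    if el.atomic_number == 0:
        raise UnknownElementError(f"unknown element symbol {symbol!r}")
    return el


def atomic_number(symbol: str) -> int:
    return _element(symbol).atomic_number


def atomic_weight(symbol: str) -> float:
    return _element(symbol).weight


def vdw_radius(symbol: str) -> float:
    return _element(symbol).vdw_r


def covalent_radius(symbol: str) -> float:
    return _element(symbol).covalent_r


@lru_cache(maxsize=256)
def cromer_mann(symbol: str) -> Tuple[tuple, tuple, float]:
    """(a1..a4, b1..b4, c) four-Gaussian coefficients."""
    it = _element(symbol).it92
    if it is None:
        raise UnknownElementError(f"no form-factor coefficients for {symbol!r}")
    return tuple(it.a), tuple(it.b), it.c


def form_factor(symbol: str, s) -> np.ndarray:
    """Spherical-atom f0 at s = sin(theta)/lambda (scalar or array)."""
    a, b, c = cromer_mann(symbol)
    s2 = np.asarray(s, dtype=float) ** 2
    f = c + sum(ai * np.exp(-bi * s2) for ai, bi in zip(a, b))
    return f if np.ndim(s) else float(f)


@lru_cache(maxsize=1024)
def anomalous(symbol: str, wavelength: float) -> Optional[Tuple[float, float]]:
    """(f', f'') at the given wavelength, or None outside the valid range."""
    import gemmi

    z = atomic_number(symbol)
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    energy = HC_EV_ANGSTROM / wavelength
    if not (1000.0 <= energy <= 100000.0):
        return None
    fp, fdp = gemmi.cromer_liberman(z=z, energy=energy)
    return fp, fdp


def mu_per_atom(symbol: str, wavelength: float) -> float:
    """Photoabsorption cross-section per atom, Angstrom^2."""
    an = anomalous(symbol, wavelength)
    if an is None:
        raise ValueError(f"no absorption data for {symbol} at {wavelength} A")
    return 2.0 * _R_E * wavelength * max(an[1], 0.0)
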