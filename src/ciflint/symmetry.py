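"""Space-group machinery: Hall-symbol expansion, consistency checks,
site symmetry, s_uvw symmetry codes and systematic absences.

A space group is represented by its full operator list (rotation part with
integer entries, translation part as exact rationals reduced mod 1). Hall
symbols are decoded to generators and closed under composition; the closure
is the authority for everything downstream (crystal system, Laue group,
extinction rules). The Hermann-Mauguin <-> Hall correspondence for the
standard settings of the 230 space-group types (plus the tabulated
alternates such as P2₁/n) is materialised from gemmi's tables; the expansion
engine itself is independent of gemmi.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .core import UnitCell

__all__ = [
    "SymOp", "SpaceGroupSetting", "SymmCode", "SiteSymmetryInfo",
    "HallError", "expand_hall", "ops_from_triplets", "setting_from_ops",
    "check_symmetry_consistency", "site_symmetry",
    "encode_symmcode", "decode_symmcode", "SymmCodeError",
    "absence_conditions", "extinct_mask", "absence_violations",
    "standard_hall_table", "hall_is_tabulated",
]

_HALF = Fraction(1, 2)
_THIRD = Fraction(1, 3)
_QUARTER = Fraction(1, 4)


def _mod1(x: Fraction) -> Fraction:
    return x - (x.numerator // x.denominator)


class HallError(ValueError):
    pass


@dataclass(frozen=True)
class SymOp:
    """Affine operator x -> R x + t with t reduced mod 1."""

    rot: Tuple[Tuple[int, ...], ...]
    tran: Tuple[Fraction, Fraction, Fraction]

    @staticmethod
    def make(rot, tran) -> "SymOp":
        r = tuple(tuple(int(v) for v in row) for row in rot)
        t = tuple(_mod1(Fraction(v).limit_denominator(24)) for v in tran)
        return SymOp(r, t)

    @staticmethod
    def identity() -> "SymOp":
        return SymOp.make(np.eye(3, dtype=int), (0, 0, 0))

    @property
    def det(self) -> int:
        return int(round(np.linalg.det(np.array(self.rot))))

    @property
    def is_identity(self) -> bool:
        return self.rot == ((1, 0, 0), (0, 1, 0), (0, 0, 1)) and all(
            t == 0 for t in self.tran
        )

    @property
    def is_inversion_like(self) -> bool:
        return self.rot == ((-1, 0, 0), (0, -1, 0), (0, 0, -1))

    def __mul__(self, other: "SymOp") -> "SymOp":
        r1 = np.array(self.rot)
        r2 = np.array(other.rot)
        t = r1 @ [Fraction(x) for x in other.tran]
        return SymOp.make(r1 @ r2, [a + b for a, b in zip(t, self.tran)])

    def inverse(self) -> "SymOp":
        r = np.array(self.rot)
        rinv = np.array(np.round(np.linalg.inv(r)), dtype=int)
        t = rinv @ [Fraction(-x) for x in self.tran]
        return SymOp.make(rinv, t)

    def apply(self, frac) -> np.ndarray:
        return np.array(self.rot) @ np.asarray(frac, dtype=float) + [
            float(t) for t in self.tran
        ]

    def triplet(self) -> str:
        names = "xyz"
        parts = []
        for i in range(3):
            terms = ""
            for j in range(3):
                v = self.rot[i][j]
                if v == 0:
                    continue
                sign = "-" if v < 0 else ("+" if terms else "")
                terms += f"{sign}{names[j]}"
            t = self.tran[i]
            if t != 0:
                terms += f"+{t.numerator}/{t.denominator}"
            parts.append(terms or "0")
        return ",".join(parts)


class TripletError(ValueError):
    pass


_TERM_RE = re.compile(r"([+-]?)(\d+/\d+|\d*\.\d+|\d+|[xyz])")


def _parse_triplet_component(expr: str) -> Tuple[Tuple[int, int, int], Fraction]:
    expr = expr.replace(" ", "").lower()
    if not expr:
        raise TripletError("empty component in operator triplet")
    row = [0, 0, 0]
    tran = Fraction(0)
    pos = 0
    for m in _TERM_RE.finditer(expr):
        if m.start() != pos:
            raise TripletError(f"cannot parse operator component {expr!r}")
        pos = m.end()
        sign = -1 if m.group(1) == "-" else 1
        tok = m.group(2)
        if tok in "xyz":
            row["xyz".index(tok)] += sign
        elif "/" in tok:
            num, den = tok.split("/")
            tran += sign * Fraction(int(num), int(den))
        else:
            tran += sign * Fraction(tok).limit_denominator(24)
    if pos != len(expr):
        raise TripletError(f"cannot parse operator component {expr!r}")
    return tuple(row), tran


def ops_from_triplets(triplets: Iterable[str]) -> List[SymOp]:
    """Parse CIF ``_space_group_symop_operation_xyz`` strings."""
    ops = []
    for trip in triplets:
        comps = trip.split(",")
        if len(comps) != 3:
            raise TripletError(f"operator {trip!r} does not have 3 components")
        rows, trans = zip(*(_parse_triplet_component(c) for c in comps))
        ops.append(SymOp.make(rows, trans))
    return ops


# ---------------------------------------------------------------------------
# Hall symbol decoding

_LATTICE = {
    "P": [],
    "A": [(0, _HALF, _HALF)],
    "B": [(_HALF, 0, _HALF)],
    "C": [(_HALF, _HALF, 0)],
    "I": [(_HALF, _HALF, _HALF)],
    "R": [(2 * _THIRD, _THIRD, _THIRD), (_THIRD, 2 * _THIRD, 2 * _THIRD)],
    "H": [(2 * _THIRD, _THIRD, 0), (_THIRD, 2 * _THIRD, 0)],
    "F": [(0, _HALF, _HALF), (_HALF, 0, _HALF), (_HALF, _HALF, 0)],
}

_TRANSLATION = {
    "a": (_HALF, 0, 0),
    "b": (0, _HALF, 0),
    "c": (0, 0, _HALF),
    "n": (_HALF, _HALF, _HALF),
    "u": (_QUARTER, 0, 0),
    "v": (0, _QUARTER, 0),
    "w": (0, 0, _QUARTER),
    "d": (_QUARTER, _QUARTER, _QUARTER),
}

# proper rotation matrices about principal axes (Hall convention)
_PRINCIPAL = {
    (1, "z"): np.eye(3, dtype=int),
    (2, "x"): np.array([[1, 0, 0], [0, -1, 0], [0, 0, -1]]),
    (2, "y"): np.array([[-1, 0, 0], [0, 1, 0], [0, 0, -1]]),
    (2, "z"): np.array([[-1, 0, 0], [0, -1, 0], [0, 0, 1]]),
    (3, "x"): np.array([[1, 0, 0], [0, 0, -1], [0, 1, -1]]),
    (3, "y"): np.array([[-1, 0, 1], [0, 1, 0], [-1, 0, 0]]),
    (3, "z"): np.array([[0, -1, 0], [1, -1, 0], [0, 0, 1]]),
    (4, "x"): np.array([[1, 0, 0], [0, 0, -1], [0, 1, 0]]),
    (4, "y"): np.array([[0, 0, 1], [0, 1, 0], [-1, 0, 0]]),
    (4, "z"): np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]]),
    (6, "x"): np.array([[1, 0, 0], [0, 1, -1], [0, 1, 0]]),
    (6, "y"): np.array([[0, 0, 1], [0, 1, 0], [-1, 0, 1]]),
    (6, "z"): np.array([[1, -1, 0], [1, 0, 0], [0, 0, 1]]),
}

# diagonal two-folds, keyed by the preceding principal axis
_DIAGONAL = {
    ("'", "z"): np.array([[0, -1, 0], [-1, 0, 0], [0, 0, -1]]),
    ('"', "z"): np.array([[0, 1, 0], [1, 0, 0], [0, 0, -1]]),
    ("'", "x"): np.array([[-1, 0, 0], [0, 0, -1], [0, -1, 0]]),
    ('"', "x"): np.array([[-1, 0, 0], [0, 0, 1], [0, 1, 0]]),
    ("'", "y"): np.array([[0, 0, -1], [0, -1, 0], [-1, 0, 0]]),
    ('"', "y"): np.array([[0, 0, 1], [0, -1, 0], [1, 0, 0]]),
}

_BODY_DIAGONAL = np.array([[0, 0, 1], [1, 0, 0], [0, 1, 0]])  # 3-fold about [111]

_AXIS_VECTOR = {"x": (1, 0, 0), "y": (0, 1, 0), "z": (0, 0, 1)}


def _decode_rotation_field(tok: str, index: int, prev_order: Optional[int],
                           prev_axis: str) -> Tuple[np.ndarray, list, str, int]:
    orig = tok
    improper = tok.startswith("-")
    if improper:
        tok = tok[1:]
    if not tok or not tok[0].isdigit():
        raise HallError(f"malformed rotation field {orig!r}")
    order = int(tok[0])
    if order not in (1, 2, 3, 4, 6):
        raise HallError(f"invalid rotation order in field {orig!r}")
    tok = tok[1:]
    screw = 0
    if tok and tok[0].isdigit():
        screw = int(tok[0])
        if not 0 < screw < order:
            raise HallError(f"invalid screw translation in field {orig!r}")
        tok = tok[1:]
    axis = None
    if tok and tok[0] in "xyz'\"*":
        axis = tok[0]
        tok = tok[1:]
    if axis is None:
        if index == 0:
            axis = "z"
        elif order == 2:
            if prev_order in (2, 4):
                axis = "x"
            elif prev_order in (3, 6):
                axis = "'"
            else:
                raise HallError(f"cannot infer axis for field {orig!r}")
        elif order == 3:
            axis = "*"
        elif order == 1:
            axis = "z"
        else:
            raise HallError(f"cannot infer axis for field {orig!r}")
    if axis == "*":
        if order != 3 and order != 1:
            raise HallError(f"'*' axis requires a threefold in field {orig!r}")
        rot = _BODY_DIAGONAL if order == 3 else np.eye(3, dtype=int)
        principal = prev_axis
    elif axis in "'\"":
        try:
            rot = _DIAGONAL[(axis, prev_axis)]
        except KeyError:
            raise HallError(f"diagonal axis without preceding principal axis "
                            f"in field {orig!r}")
        if order != 2:
            raise HallError(f"diagonal axis requires order 2 in field {orig!r}")
        principal = prev_axis
    else:
        rot = _PRINCIPAL[(order, axis)]
        principal = axis
    if improper:
        rot = -rot
    tran = [Fraction(0)] * 3
    for ch in tok:
        if ch not in _TRANSLATION:
            raise HallError(f"unknown translation symbol {ch!r} in field {orig!r}")
        tran = [a + b for a, b in zip(tran, _TRANSLATION[ch])]
    if screw:
        if axis not in _AXIS_VECTOR:
            raise HallError(f"screw translation needs a principal axis in {orig!r}")
        v = _AXIS_VECTOR[axis]
        tran = [a + Fraction(screw, order) * b for a, b in zip(tran, v)]
    return rot, tran, principal, order


def _close_group(generators: Sequence[SymOp], limit: int = 192) -> List[SymOp]:
    # closure in a fast integer representation: translations in 24ths mod 24
    def pack(op: SymOp):
        t24 = []
        for t in op.tran:
            v = t * 24
            if v.denominator != 1:
                raise HallError("translation not expressible in 24ths")
            t24.append(v.numerator % 24)
        return op.rot, tuple(t24)

    def mul(a, b):
        (ra, ta), (rb, tb) = a, b
        rot = tuple(
            tuple(sum(ra[i][k] * rb[k][j] for k in range(3)) for j in range(3))
            for i in range(3)
        )
        tran = tuple(
            (sum(ra[i][k] * tb[k] for k in range(3)) + ta[i]) % 24
            for i in range(3)
        )
        return rot, tran

    gens = [pack(g) for g in generators]
    ident = (((1, 0, 0), (0, 1, 0), (0, 0, 1)), (0, 0, 0))
    ops = {ident}
    frontier = list(gens)
    while frontier:
        new = []
        for g in frontier:
            for h in list(ops):
                for prod in (mul(g, h), mul(h, g)):
                    if prod not in ops:
                        ops.add(prod)
                        new.append(prod)
            if g not in ops:
                ops.add(g)
        if len(ops) > limit:
            raise HallError(f"group closure exceeds order {limit}")
        frontier = new
    out = [SymOp(rot, tuple(Fraction(t, 24) for t in tran)) for rot, tran in ops]
    return sorted(out, key=lambda o: (not o.is_identity, o.rot,
                                      tuple(map(float, o.tran))))


_SYSTEM_ORDER = [
    "triclinic", "monoclinic", "orthorhombic", "tetragonal",
    "trigonal", "hexagonal", "cubic",
]


def _crystal_system(ops: Sequence[SymOp]) -> str:
    rots = {op.rot if np.linalg.det(op.rot) > 0 else
            tuple(tuple(-v for v in row) for row in op.rot) for op in ops}
    orders = []
    for r in rots:
        tr = int(np.trace(np.array(r)))
        orders.append({3: 1, -1: 2, 0: 3, 1: 4, 2: 6}[tr])
    n2 = orders.count(2)
    n3 = orders.count(3)
    n4 = orders.count(4)
    n6 = orders.count(6)
    if n3 >= 8:
        return "cubic"
    if n6 > 0:
        return "hexagonal"
    if n4 > 0:
        return "tetragonal"
    if n3 > 0:
        return "trigonal"
    if n2 >= 3:
        return "orthorhombic"
    if n2 >= 1:
        return "monoclinic"
    return "triclinic"


@dataclass
class SpaceGroupSetting:
    hall: str
    ops: List[SymOp]
    hm: Optional[str] = None

    def __post_init__(self):
        if not any(op.is_identity for op in self.ops):
            raise HallError("operator list lacks the identity")

    @property
    def nsym(self) -> int:
        return len(self.ops)

    @property
    def centrosymmetric(self) -> bool:
        return any(op.is_inversion_like for op in self.ops)

    @property
    def crystal_system(self) -> str:
        return _crystal_system(self.ops)

    @property
    def rotations(self) -> List[np.ndarray]:
        seen = []
        out = []
        for op in self.ops:
            if op.rot not in seen:
                seen.append(op.rot)
                out.append(np.array(op.rot))
        return out

    @property
    def laue_rotations(self) -> List[np.ndarray]:
        """Rotation parts of the Laue group (point group + inversion)."""
        mats = {op.rot for op in self.ops}
        mats |= {tuple(tuple(-v for v in row) for row in m) for m in mats}
        return [np.array(m) for m in sorted(mats)]

    @property
    def centering_translations(self) -> List[Tuple[Fraction, ...]]:
        ident = ((1, 0, 0), (0, 1, 0), (0, 0, 1))
        return [op.tran for op in self.ops
                if op.rot == ident and any(t != 0 for t in op.tran)]

    def canonical_key(self) -> tuple:
        return tuple(sorted((op.rot, op.tran) for op in self.ops))

    def contains(self, op: SymOp, tol: float = 1e-9) -> bool:
        for own in self.ops:
            if own.rot == op.rot and all(
                min(abs(float(a - b)), 1 - abs(float(a - b))) < tol
                for a, b in zip(own.tran, op.tran)
            ):
                return True
        return False

    def triplets(self) -> List[str]:
        return [op.triplet() for op in self.ops]


@lru_cache(maxsize=1024)
def expand_hall(hall: str) -> SpaceGroupSetting:
    """Expand a Hall symbol to the full operator group.

    Supports the concise-symbol grammar: lattice letter (optionally preceded
    by ``-`` for a centre at the origin), rotation fields with implied-axis
    rules, screw/glide translation suffixes and a trailing origin shift in
    twelfths, e.g. ``-P 2yn`` or ``P 32 2" (0 0 4)``.
    """
    text = hall.strip()
    if not text:
        raise HallError("empty Hall symbol")
    shift = None
    if "(" in text:
        head, _, tail = text.partition("(")
        if not tail.rstrip().endswith(")"):
            raise HallError(f"unterminated origin shift in {hall!r}")
        nums = tail.rstrip()[:-1].split()
        if len(nums) != 3:
            raise HallError(f"origin shift needs three numbers in {hall!r}")
        try:
            shift = [Fraction(int(v), 12) for v in nums]
        except ValueError:
            raise HallError(f"non-integer origin shift in {hall!r}")
        text = head.strip()
    tokens = text.split()
    lat = tokens[0]
    centro = lat.startswith("-")
    if centro:
        lat = lat[1:]
    lat = lat.upper()
    if lat not in _LATTICE:
        raise HallError(f"unknown lattice letter {lat!r} in {hall!r}")
    generators: List[SymOp] = []
    for tr in _LATTICE[lat]:
        generators.append(SymOp.make(np.eye(3, dtype=int), tr))
    if centro:
        generators.append(SymOp.make(-np.eye(3, dtype=int), (0, 0, 0)))
    prev_order: Optional[int] = None
    prev_axis = "z"
    for i, tok in enumerate(tokens[1:]):
        rot, tran, prev_axis, prev_order = _decode_rotation_field(
            tok, i, prev_order, prev_axis)
        generators.append(SymOp.make(rot, tran))
    if shift is not None:
        shifted = []
        for g in generators:
            r = np.array(g.rot)
            t = [Fraction(x) for x in g.tran]
            extra = [Fraction(s) for s in shift]
            rs = r @ extra
            newt = [t[i] + extra[i] - rs[i] for i in range(3)]
            shifted.append(SymOp.make(r, newt))
        generators = shifted
    ops = _close_group(generators)
    return SpaceGroupSetting(hall=hall.strip(), ops=ops)


def setting_from_ops(ops: Sequence[SymOp], hall: str = "?",
                     hm: Optional[str] = None) -> SpaceGroupSetting:
    closed = _close_group(list(ops))
    return SpaceGroupSetting(hall=hall, ops=closed, hm=hm)


# ---------------------------------------------------------------------------
# bundled Hall <-> HM table (materialised from gemmi's space-group tables)


@lru_cache(maxsize=1)
def standard_hall_table() -> List[dict]:
    """All tabulated settings: dicts with hall, hm, number, is_standard."""
    import gemmi

    standard = {}
    for n in range(1, 231):
        sg = gemmi.find_spacegroup_by_number(n)
        standard[n] = sg.hall.strip()
    rows = []
    seen_standard = set()
    for sg in gemmi.spacegroup_table():
        hall = sg.hall.strip()
        is_std = hall == standard[sg.number] and sg.number not in seen_standard
        if is_std:
            seen_standard.add(sg.number)
        rows.append({
            "hall": hall,
            "hm": sg.hm.strip(),
            "number": sg.number,
            "is_standard": is_std,
        })
    return rows


@lru_cache(maxsize=1)
def _hall_norms() -> set:
    return {r["hall"].lower().replace(" ", "") for r in standard_hall_table()}


def hall_is_tabulated(hall: str) -> bool:
    return hall.strip().lower().replace(" ", "") in _hall_norms()


def _hm_lookup(hm: str):
    import gemmi

    sg = gemmi.find_spacegroup_by_name(hm)
    return None if sg is None else sg.hall.strip()


# ---------------------------------------------------------------------------
# consistency checks


@dataclass
class Finding:
    code: str
    message: str
    value: Optional[float] = None


_SYSTEM_CONSTRAINTS = {
    # per crystal system: list of (kind, i, j) length-equalities and fixed angles
    "orthorhombic": {"angles": {0: 90, 1: 90, 2: 90}, "equal": []},
    "tetragonal": {"angles": {0: 90, 1: 90, 2: 90}, "equal": [(0, 1)]},
    "cubic": {"angles": {0: 90, 1: 90, 2: 90}, "equal": [(0, 1), (1, 2)]},
    "hexagonal": {"angles": {0: 90, 1: 90, 2: 120}, "equal": [(0, 1)]},
}


def _metric_findings(cell: UnitCell, setting: SpaceGroupSetting,
                     len_floor: float = 0.002, ang_floor: float = 0.02):
    system = setting.crystal_system
    su = cell.su or (None,) * 6
    lengths = cell.lengths
    angles = cell.angles
    out = []

    def ang_tol(i):
        s = su[3 + i]
        return max(3 * s, ang_floor) if s else ang_floor

    def len_tol(i, j):
        s = max((su[i] or 0), (su[j] or 0))
        return max(3 * s, len_floor) if s else len_floor

    constraints = None
    if system in _SYSTEM_CONSTRAINTS:
        constraints = _SYSTEM_CONSTRAINTS[system]
    elif system == "monoclinic":
        # find the unique (two-fold / mirror-normal) axis from the operators
        axis = None
        for r in setting.rotations:
            rr = r if np.linalg.det(r) > 0 else -r
            if int(np.trace(rr)) == -1:  # proper two-fold
                for i in range(3):
                    v = np.zeros(3)
                    v[i] = 1
                    if np.allclose(rr @ v, v):
                        axis = i
                if axis is not None:
                    break
        if axis is None:
            axis = 1
        fixed = {i: 90 for i in range(3) if i != axis}
        constraints = {"angles": fixed, "equal": []}
    elif system == "trigonal":
        if abs(angles[2] - 120) < abs(angles[2] - angles[0]):
            constraints = _SYSTEM_CONSTRAINTS["hexagonal"]
        else:
            # rhombohedral axes: a=b=c, alpha=beta=gamma
            for i, j in ((0, 1), (1, 2)):
                if abs(lengths[i] - lengths[j]) > len_tol(i, j):
                    out.append(Finding(
                        "cell_system_mismatch",
                        f"cell length {'abc'[i]} != {'abc'[j]} violates "
                        f"rhombohedral metric",
                        value=abs(lengths[i] - lengths[j])))
                if abs(angles[i] - angles[j]) > max(ang_tol(i), ang_tol(j)):
                    out.append(Finding(
                        "cell_system_mismatch",
                        "rhombohedral angles unequal",
                        value=abs(angles[i] - angles[j])))
            return out
    if constraints is None:
        return out
    names_a = ("alpha", "beta", "gamma")
    for i, target in constraints["angles"].items():
        dev = abs(angles[i] - target)
        if dev > ang_tol(i):
            out.append(Finding(
                "cell_system_mismatch",
                f"cell angle {names_a[i]}={angles[i]:.3f} deg deviates from "
                f"{target} deg required by the {system} system "
                f"(deviation {dev:.3f} deg, tolerance {ang_tol(i):.3f})",
                value=dev))
    for i, j in constraints["equal"]:
        dev = abs(lengths[i] - lengths[j])
        if dev > len_tol(i, j):
            out.append(Finding(
                "cell_system_mismatch",
                f"cell lengths {'abc'[i]} and {'abc'[j]} differ by "
                f"{dev:.4f} A but the {system} system requires equality",
                value=dev))
    return out


def check_symmetry_consistency(
    cell: Optional[UnitCell],
    setting: Optional[SpaceGroupSetting],
    hm: Optional[str] = None,
    hall: Optional[str] = None,
    listed_ops: Optional[Sequence[SymOp]] = None,
) -> List[Finding]:
    """Cross-check HM symbol, Hall symbol, listed operators and cell metric.

    All problems are findings, never exceptions. For Hall symbols not in the
    bundled table the HM<->Hall comparison is skipped and reported as such.
    """
    findings: List[Finding] = []
    if hall is None:
        findings.append(Finding("missing_symbol", "no Hall symbol reported"))
    if hm is None:
        findings.append(Finding("missing_symbol",
                                "no Hermann-Mauguin symbol reported"))
    hall_setting = None
    if hall is not None:
        try:
            hall_setting = expand_hall(hall)
        except HallError as exc:
            findings.append(Finding("invalid_symbol", f"Hall symbol: {exc}"))
    ref = setting or hall_setting
    if hall_setting is not None and listed_ops:
        listed = setting_from_ops(listed_ops)
        if listed.canonical_key() != hall_setting.canonical_key():
            findings.append(Finding(
                "ops_mismatch",
                f"listed operator set ({listed.nsym} ops after closure) does "
                f"not equal the Hall expansion ({hall_setting.nsym} ops)"))
    if hall is not None and hm is not None and hall_setting is not None:
        if not hall_is_tabulated(hall):
            findings.append(Finding(
                "hm_hall_not_checked",
                f"Hall symbol {hall!r} is not a tabulated setting; "
                f"HM<->Hall comparison skipped"))
        else:
            expected_hall = _hm_lookup(hm)
            if expected_hall is None:
                findings.append(Finding(
                    "hm_hall_not_checked",
                    f"HM symbol {hm!r} not recognised; comparison skipped"))
            else:
                try:
                    hm_setting = expand_hall(expected_hall)
                except HallError:
                    hm_setting = None
                if (hm_setting is not None and
                        hm_setting.canonical_key() != hall_setting.canonical_key()):
                    findings.append(Finding(
                        "hm_hall_mismatch",
                        f"HM symbol {hm!r} corresponds to Hall "
                        f"{expected_hall!r}, not {hall!r}"))
    if cell is not None and ref is not None:
        findings.extend(_metric_findings(cell, ref))
    return findings


# ---------------------------------------------------------------------------
# site symmetry


@dataclass(frozen=True)
class SiteSymmetryInfo:
    sso: int  # site symmetry order: ops fixing the site mod lattice
    ssm: int  # multiplicity: nsym / sso
    sof: float  # refinement-style site occupancy factor


def site_symmetry(xyz, occupancy: float, setting: SpaceGroupSetting,
                  cell: UnitCell, tol: float = 0.01) -> SiteSymmetryInfo:
    """Count coincident symmetry images of a site (Cartesian tolerance, A)."""
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    x = np.asarray(xyz, dtype=float)
    sso = 0
    for op in setting.ops:
        d = op.apply(x) - x
        d -= np.round(d)
        if np.linalg.norm(cell.cartesian(d)) < tol:
            sso += 1
    nsym = setting.nsym
    if nsym % sso:
        # cannot happen for an exact group; guard against tolerance artefacts
        raise ValueError(f"site symmetry order {sso} does not divide {nsym}")
    return SiteSymmetryInfo(sso=sso, ssm=nsym // sso, sof=occupancy / sso)


# ---------------------------------------------------------------------------
# s_uvw symmetry codes


class SymmCodeError(ValueError):
    pass


@dataclass(frozen=True)
class SymmCode:
    op_index: int  # 1-based into the operator list
    uvw: Tuple[int, int, int]


def encode_symmcode(op_index: int, uvw) -> str:
    """ORTEP-style code: digit = translation + 5, so only -5..4 encode."""
    if op_index < 1:
        raise SymmCodeError("operator index is 1-based")
    digits = []
    for t in uvw:
        if not -5 <= t <= 4:
            raise SymmCodeError(
                f"translation {t} not representable: the s_uvw code encodes "
                f"only translations in the range -5 to 4")
        digits.append(str(t + 5))
    return f"{op_index}_{''.join(digits)}"


def decode_symmcode(code: str, setting: Optional[SpaceGroupSetting] = None) -> SymmCode:
    try:
        s_part, uvw_part = code.split("_")
        op_index = int(s_part)
    except ValueError:
        raise SymmCodeError(f"malformed symmetry code {code!r}")
    if len(uvw_part) != 3 or not uvw_part.isdigit():
        raise SymmCodeError(
            f"malformed symmetry code {code!r}: translation part must be "
            f"exactly three digits (multi-digit extensions not representable)")
    if op_index < 1:
        raise SymmCodeError("operator index is 1-based")
    if setting is not None and op_index > setting.nsym:
        raise SymmCodeError(
            f"operator index {op_index} exceeds the {setting.nsym}-operator list")
    uvw = tuple(int(d) - 5 for d in uvw_part)
    return SymmCode(op_index=op_index, uvw=uvw)


# ---------------------------------------------------------------------------
# systematic absences


def extinct_mask(hkl, setting: SpaceGroupSetting) -> np.ndarray:
    """True where h is systematically extinct: some op has hR = h and
    h.t not integral."""
    h = np.atleast_2d(np.asarray(hkl, dtype=int))
    mask = np.zeros(len(h), dtype=bool)
    for op in setting.ops:
        if op.is_identity and all(t == 0 for t in op.tran):
            continue
        r = np.array(op.rot)
        t = np.array([float(x) for x in op.tran])
        fixed = np.all(h @ r == h, axis=1)
        if not fixed.any():
            continue
        phase = h @ t
        frac = np.abs(phase - np.round(phase))
        mask |= fixed & (frac > 1e-9)
    return mask


_ZONES = [
    ("h00", lambda n: (n, 0, 0)),
    ("0k0", lambda n: (0, n, 0)),
    ("00l", lambda n: (0, 0, n)),
    ("hk0", None),
    ("h0l", None),
    ("0kl", None),
    ("hhl", None),
    ("hkl", None),
]


def absence_conditions(setting: SpaceGroupSetting, max_index: int = 8) -> List[str]:
    """Human-readable extinction rules derived by enumeration.

    The authoritative predicate is :func:`extinct_mask`; these strings are a
    report-friendly summary over low-index zones.
    """
    out = []
    rng = range(-max_index, max_index + 1)

    def describe(name, triples):
        triples = [t for t in triples if any(t)]
        if not triples:
            return
        ext = extinct_mask(np.array(triples), setting)
        if not ext.any() or ext.all():
            if ext.all():
                out.append(f"{name}: all extinct (check the setting)")
            return
        # try simple modulus rules on each varying index and sums
        arr = np.array(triples)
        labels = {"h": arr[:, 0], "k": arr[:, 1], "l": arr[:, 2],
                  "h+k": arr[:, 0] + arr[:, 1],
                  "h+l": arr[:, 0] + arr[:, 2],
                  "k+l": arr[:, 1] + arr[:, 2],
                  "h+k+l": arr.sum(axis=1)}
        for lab, vals in labels.items():
            for m in (2, 3, 4, 6):
                present = vals[~ext] % m
                absent = vals[ext] % m
                if len(set(present.tolist())) == 1 and 0 in set(present.tolist()) \
                        and 0 not in set(absent.tolist()):
                    out.append(f"{name}: {lab} = {m}n")
                    return
        out.append(f"{name}: extinctions present (no simple modulus rule)")

    nz = [n for n in rng if n]
    describe("h00", [(n, 0, 0) for n in nz])
    describe("0k0", [(0, n, 0) for n in nz])
    describe("00l", [(0, 0, n) for n in nz])
    describe("hk0", [(h, k, 0) for h in nz for k in nz])
    describe("h0l", [(h, 0, l) for h in nz for l in nz])
    describe("0kl", [(0, k, l) for k in nz for l in nz])
    describe("hhl", [(h, h, l) for h in nz for l in nz])
    describe("hkl", [(h, k, l) for h in nz for k in nz for l in nz
                     if h != k and k != l])
    return out


def absence_violations(rs, setting: SpaceGroupSetting, nsigma: float = 3.0):
    """Extinct reflections measured significantly above noise.

    Returns a list of (hkl, I, sigma, I/sigma) ranked by I/sigma."""
    if len(rs) == 0:
        raise ValueError("empty reflection set")
    mask = extinct_mask(rs.hkl, setting)
    viol = mask & (rs.fo2 > nsigma * rs.sigma)
    idx = np.nonzero(viol)[0]
    ranked = sorted(idx, key=lambda i: -(rs.fo2[i] / rs.sigma[i]))
    return [
        (tuple(int(v) for v in rs.hkl[i]), float(rs.fo2[i]),
         float(rs.sigma[i]), float(rs.fo2[i] / rs.sigma[i]))
        for i in ranked
    ]
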