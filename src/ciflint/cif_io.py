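"""CIF 1.1 and reflection-file input/output.

The reader is deliberately strict and self-contained: validation needs
line-numbered parse errors, lowercased tags, and byte-exact preservation of
semicolon-delimited text fields (embedded refinement payloads are checksummed
over their verbatim bytes). CIF2/DDLm syntax is rejected.

Reflection dialects:

* ``fcf``   - CIF-style ``_refln_`` loop, merged or unmerged, F or F^2
              convention auto-detected from the loop tags (F^2 is canonical
              internally);
* ``hklf4`` - SHELX fixed-width (3I4,2F8.2) records terminated by the
              all-zero record.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .core import ReflectionSet, UnitCell

__all__ = [
    "CifDocument", "DataBlock", "UncertainValue", "EmbeddedFile",
    "CifParseError", "CifValueError", "parse_cif", "write_cif",
    "parse_uncertain", "format_uncertain", "read_reflections",
    "write_reflections", "extract_embedded", "reference_checksum",
]


class CifParseError(ValueError):
    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class CifValueError(ValueError):
    """A value present in the file cannot be interpreted as requested."""


@dataclass
class DataBlock:
    name: str
    items: Dict[str, str] = field(default_factory=dict)
    loops: List[Tuple[List[str], List[List[str]]]] = field(default_factory=list)

    def get(self, tag: str, default=None):
        return self.items.get(tag.lower(), default)

    def find_loop(self, tag: str):
        """Return (tags, rows) of the loop containing ``tag``, or None."""
        tag = tag.lower()
        for tags, rows in self.loops:
            if tag in tags:
                return tags, rows
        return None

    def loop_column(self, tag: str):
        found = self.find_loop(tag)
        if found is None:
            return None
        tags, rows = found
        i = tags.index(tag.lower())
        return [row[i] for row in rows]

    @property
    def is_structural(self) -> bool:
        return "_cell_length_a" in self.items


@dataclass
class CifDocument:
    blocks: List[DataBlock] = field(default_factory=list)

    def __getitem__(self, name: str) -> DataBlock:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(name)

    @property
    def structural_blocks(self) -> List[DataBlock]:
        return [b for b in self.blocks if b.is_structural]


@dataclass(frozen=True)
class UncertainValue:
    value: float
    su: Optional[float] = None

    def __float__(self):
        return self.value


@dataclass
class EmbeddedFile:
    kind: str  # res | hkl | fab
    text: str
    dataname: str
    declared_checksum: Optional[int] = None
    checksum_ok: str = "unverified"  # ok | fail | unverified


# ---------------------------------------------------------------------------
# tokenizer / parser

_QUOTE_RE = re.compile(r"""^(?:'(?P<s>[^']*(?:'[^\s][^']*)*)'|"(?P<d>[^"]*)")(?=\s|$)""")


def _tokenize(text: str):
    """Yield (token, kind, line_no); kind in {value, tag, data, loop, text}."""
    lines = text.split("\n")
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i]
        if line.startswith(";"):
            # semicolon-delimited text field; preserve bytes exactly
            first = line[1:]
            body = []
            j = i + 1
            while j < n and not lines[j].startswith(";"):
                body.append(lines[j])
                j += 1
            if j >= n:
                raise CifParseError("unterminated semicolon text field", i + 1)
            value = "\n".join(body) if not first else "\n".join([first] + body)
            yield value, "text", i + 1
            i = j + 1
            # anything after the closing ';' on the same line is an error in
            # CIF 1.1 except whitespace
            trailing = lines[j][1:].strip()
            if trailing:
                raise CifParseError("unexpected text after closing ';'", j + 1)
            continue
        pos = 0
        ln = i + 1
        while pos < len(line):
            ch = line[pos]
            if ch in " \t":
                pos += 1
                continue
            if ch == "#":
                break
            rest = line[pos:]
            if ch in "'\"":
                m = _QUOTE_RE.match(rest)
                if not m:
                    raise CifParseError("unterminated quoted string", ln)
                val = m.group("s") if m.group("s") is not None else m.group("d")
                yield val, "value", ln
                pos += m.end()
                continue
            m = re.match(r"\S+", rest)
            tok = m.group(0)
            low = tok.lower()
            if low.startswith("data_"):
                yield tok[5:], "data", ln
            elif low == "loop_":
                yield tok, "loop", ln
            elif tok.startswith("_"):
                yield low, "tag", ln
            elif low in ("stop_", "global_") or low.startswith("save_"):
                raise CifParseError(f"unsupported CIF construct '{tok}'", ln)
            elif tok.startswith("[") or tok.startswith("{"):
                raise CifParseError("CIF2/DDLm list syntax is not supported", ln)
            else:
                yield tok, "value", ln
            pos += m.end()
        i += 1


def parse_cif(text: str) -> CifDocument:
    """Parse CIF 1.1 text into a document of data blocks.

    Tags are lowercased; semicolon text fields keep their bytes verbatim.
    Duplicate tags, loop column/value mismatches and unterminated fields
    raise :class:`CifParseError` naming the offending line.
    """
    if not text.strip():
        raise CifParseError("empty CIF text", 1)
    if text.lstrip().startswith("#\\#CIF_2"):
        raise CifParseError("CIF 2.0 files are not supported (CIF 1.1 only)", 1)
    doc = CifDocument()
    block: Optional[DataBlock] = None
    tokens = _tokenize(text)
    pending: Optional[Tuple[str, int]] = None  # tag awaiting its value

    def _require_block(ln):
        if block is None:
            raise CifParseError("content before the first data_ block", ln)

    tok_iter = iter(tokens)
    buffer = []

    def nxt():
        if buffer:
            return buffer.pop()
        return next(tok_iter, None)

    while True:
        item = nxt()
        if item is None:
            break
        tok, kind, ln = item
        if kind == "data":
            if not tok:
                raise CifParseError("empty data-block name", ln)
            if any(b.name == tok for b in doc.blocks):
                raise CifParseError(f"duplicate data-block name '{tok}'", ln)
            block = DataBlock(name=tok)
            doc.blocks.append(block)
            pending = None
        elif kind == "tag":
            _require_block(ln)
            if pending is not None:
                raise CifParseError(f"tag '{pending[0]}' has no value", ln)
            pending = (tok, ln)
        elif kind in ("value", "text"):
            _require_block(ln)
            if pending is None:
                raise CifParseError("value without a preceding tag", ln)
            tag, _ = pending
            if tag in block.items:
                raise CifParseError(f"duplicate tag '{tag}' in block", ln)
            block.items[tag] = tok
            pending = None
        elif kind == "loop":
            _require_block(ln)
            if pending is not None:
                raise CifParseError(f"tag '{pending[0]}' has no value", ln)
            tags = []
            values = []
            loop_line = ln
            while True:
                item = nxt()
                if item is None:
                    break
                tok2, kind2, ln2 = item
                if kind2 == "tag" and not values:
                    tags.append(tok2)
                elif kind2 in ("value", "text"):
                    values.append(tok2)
                else:
                    buffer.append(item)
                    break
            if not tags:
                raise CifParseError("loop_ without column tags", loop_line)
            if len(set(tags)) != len(tags):
                raise CifParseError("duplicate column tag in loop", loop_line)
            if not values or len(values) % len(tags) != 0:
                raise CifParseError(
                    f"loop value count {len(values)} is not a multiple of "
                    f"column count {len(tags)}", loop_line)
            rows = [values[i:i + len(tags)] for i in range(0, len(values), len(tags))]
            block.loops.append((tags, rows))
    if pending is not None:
        raise CifParseError(f"tag '{pending[0]}' has no value", pending[1])
    if not doc.blocks:
        raise CifParseError("no data_ block found", 1)
    return doc


_BARE_OK = re.compile(r"^[^\s'\"#_$\[\];][^\s'\"]*$")


def _format_value(v: str) -> str:
    if "\n" in v or ("'" in v and '"' in v) or len(v) > 72:
        return ";" + (v if v.startswith("\n") else "\n" + v) + "\n;"
    if v == "":
        return "''"
    if _BARE_OK.match(v) and v.lower() not in ("loop_",) and not v.lower().startswith("data_"):
        return v
    if "'" not in v:
        return f"'{v}'"
    return f'"{v}"'


def write_cif(doc: CifDocument) -> str:
    """Serialize a document; bit-stable (same input -> same bytes)."""
    out = []
    for block in doc.blocks:
        out.append(f"data_{block.name}")
        for tag, value in block.items.items():
            fv = _format_value(value)
            if fv.startswith(";"):
                out.append(tag)
                out.append(fv)
            else:
                pad = " " * max(1, 34 - len(tag))
                out.append(f"{tag}{pad}{fv}")
        for tags, rows in block.loops:
            out.append("loop_")
            out.extend(f" {t}" for t in tags)
            for row in rows:
                fvs = [_format_value(v) for v in row]
                if any(f.startswith(";") for f in fvs):
                    for f in fvs:
                        out.append(f)
                else:
                    out.append(" " + " ".join(fvs))
        out.append("")
    return "\n".join(out)


# ---------------------------------------------------------------------------
# numeric values with standard uncertainties

_SU_RE = re.compile(
    r"^\s*(?P<num>[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)"
    r"(?:\((?P<su>\d+)\))?\s*$"
)


def parse_uncertain(raw: str) -> UncertainValue:
    """Parse ``"x(y)"`` notation; the su is scaled to the least significant
    printed digit of x (``"12.34(12)" -> 12.34 +/- 0.12``)."""
    if raw is None:
        raise CifValueError("missing value")
    m = _SU_RE.match(raw)
    if not m:
        raise CifValueError(f"not a numeric value: {raw!r}")
    num = m.group("num")
    value = float(num)
    su_digits = m.group("su")
    if su_digits is None:
        return UncertainValue(value, None)
    mantissa = num.lower().split("e")[0]
    exponent = int(num.lower().split("e")[1]) if "e" in num.lower() else 0
    if "." in mantissa:
        decimals = len(mantissa.split(".")[1])
    else:
        decimals = 0
    su = int(su_digits) * 10.0 ** (exponent - decimals)
    return UncertainValue(value, su)


def format_uncertain(value: float, su: Optional[float] = None, decimals: int = 4) -> str:
    if su is None:
        return f"{value:.{decimals}f}"
    if su <= 0:
        raise CifValueError("su must be positive")
    # choose the scale so that the su prints as 1..99 on the last digits
    ndec = max(0, -int(math.floor(math.log10(su))) + 1)
    su_int = int(round(su * 10 ** ndec))
    if su_int >= 100:
        ndec -= 1
        su_int = int(round(su * 10 ** ndec))
    return f"{value:.{ndec}f}({su_int})"


def parse_number(raw: str) -> float:
    return parse_uncertain(raw).value


# ---------------------------------------------------------------------------
# reflection files


class ReflectionFormatError(ValueError):
    pass


_FCF_H = "_refln_index_h"
_FCF_ALIASES = {
    "h": ["_refln_index_h", "_refln.index_h"],
    "k": ["_refln_index_k", "_refln.index_k"],
    "l": ["_refln_index_l", "_refln.index_l"],
    "f2o": ["_refln_f_squared_meas", "_refln.f_squared_meas"],
    "f2c": ["_refln_f_squared_calc", "_refln.f_squared_calc"],
    "f2s": ["_refln_f_squared_sigma", "_refln.f_squared_sigma"],
    "fo": ["_refln_f_meas", "_refln.f_meas"],
    "fc": ["_refln_f_calc", "_refln.f_calc"],
    "fs": ["_refln_f_sigma", "_refln.f_sigma"],
    "ph": ["_refln_phase_calc", "_refln.phase_calc"],
}


def _fcf_col(tags, rows, key):
    for alias in _FCF_ALIASES[key]:
        if alias in tags:
            i = tags.index(alias)
            return [r[i] for r in rows]
    return None


def _cell_from_block(block: DataBlock) -> Optional[UnitCell]:
    try:
        vals = [parse_uncertain(block.get(f"_cell_length_{x}")) for x in "abc"]
        angs = [
            parse_uncertain(block.get(f"_cell_angle_{x}"))
            for x in ("alpha", "beta", "gamma")
        ]
    except CifValueError:
        return None
    return UnitCell(
        vals[0].value, vals[1].value, vals[2].value,
        angs[0].value, angs[1].value, angs[2].value,
        su=tuple(v.su for v in vals + angs),
    )


def read_reflections(text: str, dialect: str = "fcf") -> ReflectionSet:
    """Read a reflection file; F^2 is the canonical internal convention.

    Negative Fo^2 are preserved as read. The merged/unmerged state is
    recorded from the presence of duplicate index triples.
    """
    if dialect == "fcf":
        return _read_fcf(text)
    if dialect == "hklf4":
        return _read_hklf4(text)
    raise ValueError(f"unknown reflection dialect {dialect!r}")


def _read_fcf(text: str) -> ReflectionSet:
    doc = parse_cif(text)
    for block in doc.blocks:
        found = block.find_loop(_FCF_H)
        if found:
            break
    else:
        raise ReflectionFormatError("no _refln_ loop found in FCF")
    tags, rows = found
    if not rows:
        raise ReflectionFormatError("zero reflections in _refln_ loop")
    cols = {key: _fcf_col(tags, rows, key) for key in _FCF_ALIASES}
    for key in ("h", "k", "l"):
        if cols[key] is None:
            raise ReflectionFormatError(f"missing index column for {key}")
    squared = cols["f2o"] is not None
    if not squared and cols["fo"] is None:
        raise ReflectionFormatError("no observed-amplitude column found")

    def as_floats(vals, what):
        out = []
        for v in vals:
            try:
                out.append(parse_number(v))
            except CifValueError:
                raise ReflectionFormatError(f"non-numeric {what} value: {v!r}")
        return np.array(out)

    hkl = np.stack(
        [as_floats(cols[k], "index").astype(int) for k in ("h", "k", "l")], axis=1
    )
    if squared:
        fo2 = as_floats(cols["f2o"], "F^2")
        sig = as_floats(cols["f2s"], "sigma") if cols["f2s"] else None
        fc2 = as_floats(cols["f2c"], "Fc^2") if cols["f2c"] else None
    else:
        f = as_floats(cols["fo"], "F")
        sf = as_floats(cols["fs"], "sigma(F)") if cols["fs"] else None
        fo2 = np.sign(f) * f * f
        sig = None if sf is None else np.maximum(2.0 * np.abs(f) * sf, 1e-10)
        fc = as_floats(cols["fc"], "Fc") if cols["fc"] else None
        fc2 = None if fc is None else fc * fc
    if sig is None:
        raise ReflectionFormatError("missing sigma column")
    phase = as_floats(cols["ph"], "phase") if cols["ph"] else None
    merged = len({tuple(r) for r in hkl.tolist()}) == len(hkl)
    block0 = doc.blocks[0]
    wl = None
    raw_wl = block0.get("_diffrn_radiation_wavelength")
    if raw_wl:
        try:
            wl = parse_number(raw_wl)
        except CifValueError:
            wl = None
    return ReflectionSet(
        hkl, fo2, sig, fc2=fc2, phase=phase,
        cell=_cell_from_block(block0), wavelength=wl, merged=merged,
    )


def _read_hklf4(text: str) -> ReflectionSet:
    hkl, fo2, sig = [], [], []
    terminated = False
    for ln, line in enumerate(text.split("\n"), start=1):
        if not line.strip():
            continue
        if line.lstrip().startswith("!"):
            continue
        line = line.rstrip("\r\n")
        if len(line) < 13:
            raise ReflectionFormatError(f"line {ln}: HKLF4 record too short")
        line = line.ljust(28)
        try:
            h = int(line[0:4])
            k = int(line[4:8])
            l = int(line[8:12])
            i = float(line[12:20])
            s = float(line[20:28])
        except ValueError:
            raise ReflectionFormatError(f"line {ln}: non-numeric HKLF4 field")
        if h == 0 and k == 0 and l == 0:
            terminated = True
            break
        hkl.append((h, k, l))
        fo2.append(i)
        sig.append(s)
    if not hkl:
        raise ReflectionFormatError("zero reflections before terminator")
    if not terminated:
        raise ReflectionFormatError("missing all-zero terminator record")
    merged = len(set(hkl)) == len(hkl)
    return ReflectionSet(np.array(hkl), fo2, sig, merged=merged)


def write_reflections(rs: ReflectionSet, dialect: str = "fcf") -> str:
    if dialect == "hklf4":
        lines = [
            f"{h:4d}{k:4d}{l:4d}{i:8.2f}{s:8.2f}"
            for (h, k, l), i, s in zip(rs.hkl.tolist(), rs.fo2, rs.sigma)
        ]
        lines.append(f"{0:4d}{0:4d}{0:4d}{0.0:8.2f}{0.0:8.2f}")
        return "\n".join(lines) + "\n"
    if dialect != "fcf":
        raise ValueError(f"unknown reflection dialect {dialect!r}")
    block = DataBlock(name="reflections")
    if rs.cell is not None:
        for tag, v in zip(
            ("a", "b", "c"), (rs.cell.a, rs.cell.b, rs.cell.c)
        ):
            block.items[f"_cell_length_{tag}"] = f"{v:.4f}"
        for tag, v in zip(
            ("alpha", "beta", "gamma"), rs.cell.angles
        ):
            block.items[f"_cell_angle_{tag}"] = f"{v:.4f}"
    if rs.wavelength:
        block.items["_diffrn_radiation_wavelength"] = f"{rs.wavelength:.5f}"
    tags = ["_refln_index_h", "_refln_index_k", "_refln_index_l"]
    if rs.fc2 is not None:
        tags.append("_refln_f_squared_calc")
    tags += ["_refln_f_squared_meas", "_refln_f_squared_sigma"]
    if rs.phase is not None:
        tags.append("_refln_phase_calc")
    rows = []
    for i in range(len(rs)):
        h, k, l = rs.hkl[i]
        row = [str(h), str(k), str(l)]
        if rs.fc2 is not None:
            row.append(f"{rs.fc2[i]:.4f}")
        row += [f"{rs.fo2[i]:.4f}", f"{rs.sigma[i]:.4f}"]
        if rs.phase is not None:
            row.append(f"{rs.phase[i]:.2f}")
        rows.append(row)
    block.loops.append((tags, rows))
    return write_cif(CifDocument(blocks=[block]))


# ---------------------------------------------------------------------------
# embedded payloads

_EMBEDDED_TAGS = {
    "_shelx_res_file": ("res", "_shelx_res_checksum"),
    "_shelx_hkl_file": ("hkl", "_shelx_hkl_checksum"),
    "_shelx_fab_file": ("fab", "_shelx_fab_checksum"),
    "_iucr_refine_instructions_details": ("res", None),
    "_iucr_refine_reflections_details": ("hkl", None),
    "_iucr_refine_fcf_details": ("hkl", None),
}


def reference_checksum(text: str) -> int:
    """Reference payload checksum (pluggable; see docs/methods.md).

    Linear-congruential digest over printable non-blank characters; returns
    a value in 1..714024. This is this toolkit's documented reference
    convention for embedded-payload integrity, used symmetrically by the
    fixture generator and the verifier.
    """
    h = 0
    for ch in text:
        o = ord(ch)
        if 32 < o < 127:
            h = (h * 1366 + 150889 + o) % 714025
    return h + 1


def extract_embedded(doc_or_block, checksum_fn=reference_checksum):
    """Collect embedded refinement payloads with checksum verification.

    Returns one :class:`EmbeddedFile` per embedded dataname present.
    ``checksum_ok`` is ``"unverified"`` when no checksum is declared.
    """
    blocks = doc_or_block.blocks if isinstance(doc_or_block, CifDocument) else [doc_or_block]
    out = []
    for block in blocks:
        for tag, (kind, sum_tag) in _EMBEDDED_TAGS.items():
            raw = block.get(tag)
            if raw is None:
                continue
            payload = raw[1:] if raw.startswith("\n") else raw
            declared = None
            status = "unverified"
            if sum_tag:
                raw_sum = block.get(sum_tag)
                if raw_sum is not None:
                    try:
                        declared = int(raw_sum)
                    except ValueError:
                        declared = None
                    if declared is not None:
                        status = "ok" if checksum_fn(payload) == declared else "fail"
            out.append(EmbeddedFile(kind=kind, text=payload, dataname=tag,
                                    declared_checksum=declared, checksum_ok=status))
    return out
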