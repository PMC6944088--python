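"""ciflint: validation toolkit for small-molecule crystal-structure archives.

Reads CIF 1.1 + FCF/HKLF reflection data, runs symmetry, model,
reflection-statistics, density-map, missed-symmetry and twinning checks,
and renders a levelled ALERT report.
"""

__version__ = "0.1.0"

from .core import AtomSite, ReflectionSet, StructureModel, UnitCell
from .cif_io import (
    CifDocument, DataBlock, EmbeddedFile, UncertainValue,
    parse_cif, write_cif, parse_uncertain, format_uncertain,
    read_reflections, write_reflections, extract_embedded,
)
from .symmetry import (
    SymOp, SpaceGroupSetting, expand_hall, site_symmetry,
    encode_symmcode, decode_symmcode,
)

__all__ = [
    "AtomSite", "ReflectionSet", "StructureModel", "UnitCell",
    "CifDocument", "DataBlock", "EmbeddedFile", "UncertainValue",
    "parse_cif", "write_cif", "parse_uncertain", "format_uncertain",
    "read_reflections", "write_reflections", "extract_embedded",
    "SymOp", "SpaceGroupSetting", "expand_hall", "site_symmetry",
    "encode_symmcode", "decode_symmcode",
    "run_validation", "render_report",
    "__version__",
]


def run_validation(*args, **kw):
    from .alert_engine import run_validation as _rv
    return _rv(*args, **kw)


def render_report(*args, **kw):
    from .alert_engine import render_report as _rr
    return _rr(*args, **kw)
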