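"""Minimal mzML reader (stdlib XML + base64; zlib compression supported).

Only the pieces needed here are implemented: per-spectrum m/z and intensity
binary arrays with 32/64-bit float encodings, optionally zlib-compressed.
Vendor raw formats are out of scope; convert with msconvert first.
"""

from __future__ import annotations

import base64
import zlib
from xml.etree import ElementTree

import numpy as np

from maldimtu.errors import ParseError

_NS = "{http://psi.hupo.org/ms/mzml}"

# controlled-vocabulary accessions for binary array semantics
_CV_MZ = "MS:1000514"
_CV_INTENSITY = "MS:1000515"
_CV_F64 = "MS:1000523"
_CV_F32 = "MS:1000521"
_CV_ZLIB = "MS:1000574"
_CV_NONE = "MS:1000576"


def _decode_array(elem) -> tuple[str | None, np.ndarray]:
    kind = None
    dtype = np.float64
    compressed = False
    for cv in elem.iter(_NS + "cvParam"):
        acc = cv.get("accession")
        if acc == _CV_MZ:
            kind = "mz"
        elif acc == _CV_INTENSITY:
            kind = "intensity"
        elif acc == _CV_F32:
            dtype = np.float32
        elif acc == _CV_F64:
            dtype = np.float64
        elif acc == _CV_ZLIB:
            compressed = True
        elif acc == _CV_NONE:
            compressed = False
    binary = elem.find(_NS + "binary")
    if binary is None or binary.text is None:
        return kind, np.empty(0)
    raw = base64.b64decode(binary.text)
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(np.float64)


def read_mzml(path: str) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Return ``(native_id, mz, intensity)`` for every spectrum in *path*."""
    try:
        tree = ElementTree.parse(path)
    except ElementTree.ParseError as exc:  # pragma: no cover - defensive
        raise ParseError(f"{path}: not well-formed mzML: {exc}") from exc
    out = []
    for spec in tree.iter(_NS + "spectrum"):
        arrays: dict[str, np.ndarray] = {}
        for bda in spec.iter(_NS + "binaryDataArray"):
            kind, values = _decode_array(bda)
            if kind is not None:
                arrays[kind] = values
        if "mz" not in arrays or "intensity" not in arrays:
            raise ParseError(
                f"{path}: spectrum {spec.get('id')!r} lacks m/z or intensity array"
            )
        out.append((spec.get("id") or "", arrays["mz"], arrays["intensity"]))
    return out
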