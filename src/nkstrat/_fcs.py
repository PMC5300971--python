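"""Minimal FCS 3.0/3.1 list-mode reader and FCS 3.1 writer.

Supports the subset of the standard needed for cytometry event tables:
single data set, list mode ($MODE L), float/double/integer data with
byte-aligned parameter widths, no analysis segment. Written files use
FCS 3.1 with little-endian float32 data.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

_DELIM = b"/"
_HEADER_LEN = 58  # 10-byte version string + six 8-byte offset fields


class FCSError(ValueError):
    """Raised when a file cannot be parsed as FCS."""


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FCSError("empty TEXT segment")
    delim = raw[:1]
    parts = raw.strip(delim).split(delim)
    if len(parts) % 2:
        # trailing empty value is tolerated
        parts = parts[:-1]
    return {
        parts[i].decode("ascii", "replace").strip().upper(): parts[i + 1]
        .decode("ascii", "replace")
        .strip()
        for i in range(0, len(parts) - 1, 2)
    }


def read_fcs(path: str | Path) -> pd.DataFrame:
    """Read an FCS 3.0/3.1 file into a DataFrame (events x channels)."""
    blob = Path(path).read_bytes()
    if len(blob) < _HEADER_LEN:
        raise FCSError(f"{path}: file shorter than an FCS header")
    version = blob[:6].decode("ascii", "replace")
    if not version.startswith("FCS"):
        raise FCSError(f"{path}: not an FCS file (version field {version!r})")

    def _offset(lo: int, hi: int) -> int:
        field = blob[lo:hi].decode("ascii", "replace").strip() or "0"
        return int(field)

    text_begin, text_end = _offset(10, 18), _offset(18, 26)
    data_begin, data_end = _offset(26, 34), _offset(34, 42)
    text = _parse_text_segment(blob[text_begin : text_end + 1])

    # header offsets may be zeroed for large files; TEXT keywords win
    if data_begin == 0:
        data_begin = int(text.get("$BEGINDATA", 0))
        data_end = int(text.get("$ENDDATA", 0))
    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    datatype = text.get("$DATATYPE", "F").upper()
    byteord = text.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    order = "<" if little else ">"

    widths = [int(text.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]
    names = [text.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    if datatype == "F":
        if any(w != 32 for w in widths):
            raise FCSError("float data requires 32-bit parameters")
        dtype = np.dtype(order + "f4")
    elif datatype == "D":
        if any(w != 64 for w in widths):
            raise FCSError("double data requires 64-bit parameters")
        dtype = np.dtype(order + "f8")
    elif datatype == "I":
        if len(set(widths)) != 1 or widths[0] not in (8, 16, 32):
            raise FCSError("integer data requires uniform 8/16/32-bit widths")
        dtype = np.dtype(order + f"u{widths[0] // 8}")
    else:
        raise FCSError(f"unsupported $DATATYPE {datatype!r}")

    raw = blob[data_begin : data_end + 1]
    need = n_par * n_tot * dtype.itemsize
    if len(raw) < need:
        raise FCSError(f"{path}: DATA segment truncated ({len(raw)} < {need} bytes)")
    values = np.frombuffer(raw[:need], dtype=dtype).reshape(n_tot, n_par)
    return pd.DataFrame(np.asarray(values, dtype=float), columns=names)


def write_fcs(path: str | Path, data: pd.DataFrame) -> None:
    """Write a DataFrame as FCS 3.1, little-endian float32, list mode."""
    arr = np.ascontiguousarray(data.to_numpy(dtype="<f4"))
    n_tot, n_par = arr.shape
    payload = arr.tobytes()

    def _text(data_begin: int, data_end: int) -> bytes:
        pairs = [
            ("$BEGINANALYSIS", "0"),
            ("$ENDANALYSIS", "0"),
            ("$BEGINSTEXT", "0"),
            ("$ENDSTEXT", "0"),
            ("$BEGINDATA", f"{data_begin:010d}"),
            ("$ENDDATA", f"{data_end:010d}"),
            ("$BYTEORD", "1,2,3,4"),
            ("$DATATYPE", "F"),
            ("$MODE", "L"),
            ("$NEXTDATA", "0"),
            ("$PAR", str(n_par)),
            ("$TOT", str(n_tot)),
        ]
        rng_val = float(np.nanmax(arr)) if arr.size else 1.0
        for i, name in enumerate(data.columns, start=1):
            pairs += [
                (f"$P{i}N", str(name)),
                (f"$P{i}B", "32"),
                (f"$P{i}E", "0,0"),
                (f"$P{i}R", f"{max(rng_val, 1.0):.6g}"),
            ]
        out = _DELIM
        for key, val in pairs:
            out += key.encode("ascii") + _DELIM + val.encode("ascii") + _DELIM
        return out

    # fixed-width offsets inside TEXT make its length independent of the values
    text_begin = _HEADER_LEN
    text_len = len(_text(0, 0))
    text_end = text_begin + text_len - 1
    data_begin = text_end + 1
    data_end = data_begin + len(payload) - 1
    text = _text(data_begin, data_end)
    assert len(text) == text_len

    def _hfield(value: int) -> bytes:
        s = str(value) if value <= 99_999_999 else "0"
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + b"".join(
        _hfield(v) for v in (text_begin, text_end, data_begin, data_end, 0, 0)
    )
    assert len(header) == _HEADER_LEN
    Path(path).write_bytes(header + text + payload)


__all__ = ["read_fcs", "write_fcs", "FCSError"]
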