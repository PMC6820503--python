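"""Minimal FCS 3.0/3.1 codec for list-mode cytometry data.

Scope is deliberately narrow: list-mode ($MODE L) files with float, double
or integer data segments, channel names from $PnN (falling back to $PnS),
and the bookkeeping keywords needed for a bit-stable float32 round trip.
Bead normalisation, spillover and keyword preservation beyond channels and
event count are out of scope. Files are written as FCS 3.1 with a single
little-endian float32 dataset, the modern CyTOF convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..containers import CellTable, raw_required
from ..errors import ContractError, FormatError

_HEADER_LEN = 58
_TEXT_START = 64  # leave a little slack after the 58-byte header
_DELIM = "/"


def _escape(value: str) -> str:
    return value.replace(_DELIM, _DELIM * 2)


def _build_text(keywords: dict[str, str]) -> bytes:
    parts = [_DELIM]
    for key, value in keywords.items():
        parts.append(f"{_escape(key)}{_DELIM}{_escape(str(value))}{_DELIM}")
    return "".join(parts).encode("ascii")


def write_fcs(table: CellTable, path) -> None:
    """Write a raw-scale :class:`CellTable` as an FCS 3.1 float32 file.

    Raises :class:`ContractError` for arcsinh-scale input: only raw
    intensities live on disk; transforms are an in-memory state.
    """
    raw_required(table, "write_fcs")
    data = np.ascontiguousarray(table.values, dtype="<f4")
    n_events, n_par = data.shape

    keywords: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        # fixed-width (10 char) values so the TEXT length is known up front
        "$BEGINDATA": " " * 10,
        "$ENDDATA": " " * 10,
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$TOT": str(n_events),
        "$PAR": str(n_par),
    }
    for i, name in enumerate(table.channel_names, start=1):
        if _DELIM in name:
            raise ContractError(f"channel name {name!r} contains the keyword delimiter")
        col_max = float(data[:, i - 1].max()) if n_events else 0.0
        keywords[f"$P{i}N"] = name
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = str(max(1, int(np.ceil(col_max)) + 1))

    text_begin = _TEXT_START
    text_len = len(_build_text(keywords))
    data_begin = text_begin + text_len
    data_end = data_begin + data.nbytes - 1 if data.nbytes else 0
    keywords["$BEGINDATA"] = f"{data_begin:>10d}"
    keywords["$ENDDATA"] = f"{data_end:>10d}"
    text = _build_text(keywords)
    assert len(text) == text_len

    def _hdr(n: int) -> bytes:
        s = str(n)
        return (s if len(s) <= 8 else "0").rjust(8).encode("ascii")

    header = b"FCS3.1    " + b"".join(
        _hdr(v) for v in (text_begin, text_begin + text_len - 1, data_begin if data.nbytes else 0, data_end, 0, 0)
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b" " * (text_begin - _HEADER_LEN))
        fh.write(text)
        fh.write(data.tobytes())


def _parse_text(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FormatError("empty TEXT segment")
    delim = chr(raw[0])
    body = raw.decode("latin-1")[1:]
    if body.endswith(delim):
        body = body[:-1]
    # split on the delimiter, re-joining tokens emptied by escaped delimiters
    tokens = body.split(delim)
    merged: list[str] = []
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        while i + 1 < len(tokens) and tokens[i + 1] == "" and i + 2 < len(tokens):
            tok += delim + tokens[i + 2]
            i += 2
        merged.append(tok)
        i += 1
    if len(merged) % 2:
        merged = merged[:-1]
    out: dict[str, str] = {}
    for k, v in zip(merged[::2], merged[1::2]):
        key = k.strip()
        out[key.upper() if key.startswith("$") else key] = v
    return out


def read_fcs(path) -> CellTable:
    """Read an FCS 3.0/3.1 file into a raw-scale :class:`CellTable`.

    Values are returned in acquisition order. Channel names come from
    $PnN with $PnS as the fallback. Donor/group metadata is not stored in
    FCS files here (one file per donor-sample, linked to the design by
    filename), so ``cell_meta`` comes back empty.
    """
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < _HEADER_LEN:
        raise FormatError("file shorter than an FCS header")
    version = blob[:6]
    if version not in (b"FCS3.0", b"FCS3.1"):
        raise FormatError(f"unsupported FCS version {version!r}")

    def _off(lo: int, hi: int) -> int:
        field = blob[lo:hi].strip()
        return int(field) if field else 0

    text_begin, text_end = _off(10, 18), _off(18, 26)
    data_begin, data_end = _off(26, 34), _off(34, 42)
    if text_begin <= 0 or text_end < text_begin:
        raise FormatError("malformed header: bad TEXT segment offsets")
    kw = _parse_text(blob[text_begin : text_end + 1])

    if kw.get("$MODE", "L") != "L":
        raise FormatError(f"unsupported $MODE {kw.get('$MODE')!r} (list mode only)")
    datatype = kw.get("$DATATYPE")
    if datatype not in ("F", "D", "I"):
        raise FormatError(f"unsupported $DATATYPE {datatype!r}")
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"

    try:
        n_events = int(kw["$TOT"])
        n_par = int(kw["$PAR"])
    except KeyError as exc:
        raise FormatError(f"missing required keyword {exc.args[0]}") from None

    if not data_begin:
        data_begin = int(kw.get("$BEGINDATA", 0))
        data_end = int(kw.get("$ENDDATA", 0))

    names = []
    for i in range(1, n_par + 1):
        name = kw.get(f"$P{i}N") or kw.get(f"$P{i}S") or f"Ch{i}"
        names.append(name)

    if datatype == "F":
        dtype = np.dtype(f"{endian}f4")
        widths = [32] * n_par
    elif datatype == "D":
        dtype = np.dtype(f"{endian}f8")
        widths = [64] * n_par
    else:
        widths = [int(kw.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]
        if len(set(widths)) != 1 or widths[0] not in (16, 32, 64):
            raise FormatError(f"unsupported integer $PnB widths {sorted(set(widths))}")
        dtype = np.dtype(f"{endian}u{widths[0] // 8}")

    nbytes = n_events * n_par * dtype.itemsize
    if n_events == 0:
        values = np.empty((0, n_par), dtype=np.float64)
    else:
        seg = blob[data_begin : data_begin + nbytes]
        if len(seg) < nbytes:
            raise FormatError("DATA segment shorter than $TOT*$PAR events")
        values = np.frombuffer(seg, dtype=dtype).reshape(n_events, n_par).astype(np.float64)

    return CellTable(
        values=values,
        channel_names=names,
        cell_meta=pd.DataFrame(index=pd.RangeIndex(n_events)),
        scale_state="raw",
    )
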