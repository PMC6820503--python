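"""Delimited-text cell tables: a first-class alternative to FCS.

A tabular cell file is a CSV/TSV with a header row; a :class:`TabularSchema`
says which columns are metadata (donor, group, population) and which are
channels. Readers never reorder cells, and round trips are lossless for
names and metadata and float-precision-stable for values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ..containers import CellTable
from ..errors import FormatError


@dataclass
class TabularSchema:
    """Column roles for a delimited cell file."""

    donor: str | None = "donor"
    group: str | None = "group"
    population: str | None = "population"
    channels: list[str] | None = None  # None: every non-metadata column
    scale: str = "raw"
    cofactor: float | None = None


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_tabular(path, schema: TabularSchema | None = None) -> CellTable:
    schema = schema or TabularSchema()
    df = pd.read_csv(path, sep=_sep_for(path))
    meta_cols = {}
    for role in ("donor", "group", "population"):
        col = getattr(schema, role)
        if col is not None and col in df.columns:
            meta_cols[role] = df[col].astype(str)
    if schema.channels is not None:
        missing = [c for c in schema.channels if c not in df.columns]
        if missing:
            raise FormatError(f"channel columns absent from {path}: {missing}")
        channels = list(schema.channels)
    else:
        claimed = {getattr(schema, r) for r in ("donor", "group", "population")}
        channels = [c for c in df.columns if c not in claimed]
    if not channels:
        raise FormatError(f"no channel columns found in {path}")
    values = df[channels].to_numpy(dtype=np.float64)
    meta = pd.DataFrame(meta_cols, index=pd.RangeIndex(len(df)))
    return CellTable(
        values=values,
        channel_names=channels,
        cell_meta=meta,
        scale_state=schema.scale,
        cofactor=schema.cofactor,
    )


def write_tabular(table: CellTable, path, float_format: str = "%.9g") -> None:
    df = pd.DataFrame(table.values, columns=table.channel_names)
    for col in ("population", "group", "donor"):  # insert metadata first
        if col in table.cell_meta.columns:
            df.insert(0, col, table.cell_meta[col].to_numpy())
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_sep_for(path), index=False, float_format=float_format)
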