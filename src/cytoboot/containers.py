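"""Core in-memory containers: per-cell tables, panels and study designs.

A :class:`CellTable` is the atom every analysis stage consumes: a dense
``(n_cells, n_channels)`` matrix of marker intensities plus per-cell
metadata (donor, group, optional population label) and a scale state that
records whether the values are raw ion counts or arcsinh-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ContractError

RAW = "raw"
ARCSINH = "arcsinh"

CONTROL = "control"
PREGNANT = "pregnant"
POSTPARTUM = "postpartum"
GROUPS = (CONTROL, PREGNANT, POSTPARTUM)

PANEL_CATEGORIES = ("lineage", "activating", "inhibitory", "functional", "viability", "other")


@dataclass
class CellTable:
    """Per-cell channel intensities with donor/group/population metadata.

    Parameters
    ----------
    values
        ``(n_cells, n_channels)`` float matrix; raw values are nonnegative
        and finite, arcsinh values are finite reals (may be negative).
    channel_names
        Ordered, unique channel names, one per value column.
    cell_meta
        One row per cell. Recognised columns: ``donor``, ``group``,
        ``population``. May be empty (e.g. a bare FCS file before it is
        linked to a study design).
    scale_state
        ``"raw"`` or ``"arcsinh"``.
    cofactor
        The arcsinh cofactor, set when ``scale_state == "arcsinh"``.
    """

    values: np.ndarray
    channel_names: list[str]
    cell_meta: pd.DataFrame = None  # type: ignore[assignment]
    scale_state: str = RAW
    cofactor: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            self.values = self.values.reshape(-1, len(self.channel_names))
        self.channel_names = [str(c) for c in self.channel_names]
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.RangeIndex(self.values.shape[0]))
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n, p = self.values.shape
        if len(self.channel_names) != p:
            raise ContractError(
                f"{len(self.channel_names)} channel names for {p} value columns"
            )
        if len(set(self.channel_names)) != p:
            raise ContractError("channel names must be unique")
        if len(self.cell_meta) != n:
            raise ContractError("cell_meta row count does not match values")
        if self.scale_state not in (RAW, ARCSINH):
            raise ContractError(f"unknown scale_state {self.scale_state!r}")
        if n and not np.isfinite(self.values).all():
            raise ContractError("cell values must be finite")
        if self.scale_state == RAW and n and self.values.min() < 0:
            raise ContractError("raw-scale values must be nonnegative")

    # -- accessors -------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in table") from None

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.channel_index(name)]

    def marker_matrix(self, markers: Sequence[str]) -> np.ndarray:
        idx = [self.channel_index(m) for m in markers]
        return self.values[:, idx]

    # -- manipulation ----------------------------------------------------
    def subset(self, mask: np.ndarray) -> "CellTable":
        """Row subset preserving cell order; metadata index is reset."""
        mask = np.asarray(mask)
        return replace(
            self,
            values=self.values[mask],
            cell_meta=self.cell_meta.iloc[mask].reset_index(drop=True),
        )

    def with_channel(self, name: str, values: np.ndarray) -> "CellTable":
        if name in self.channel_names:
            raise ContractError(f"channel {name!r} already present")
        vals = np.column_stack([self.values, np.asarray(values, dtype=np.float64)])
        return replace(self, values=vals, channel_names=self.channel_names + [name])

    @staticmethod
    def concatenate(tables: Iterable["CellTable"]) -> "CellTable":
        tables = list(tables)
        if not tables:
            raise ContractError("cannot concatenate zero tables")
        first = tables[0]
        for t in tables[1:]:
            if t.channel_names != first.channel_names:
                raise ContractError("channel names differ between tables")
            if t.scale_state != first.scale_state:
                raise ContractError("scale states differ between tables")
        return replace(
            first,
            values=np.vstack([t.values for t in tables]),
            cell_meta=pd.concat([t.cell_meta for t in tables], ignore_index=True),
        )


@dataclass
class PanelDefinition:
    """Antibody panel: marker name, metal/channel tag, functional category."""

    entries: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e[0] for e in self.entries]
        if len(set(names)) != len(names):
            raise ConfigError("panel marker names must be unique")
        for _, _, cat in self.entries:
            if cat not in PANEL_CATEGORIES:
                raise ConfigError(f"unknown panel category {cat!r}")

    @property
    def markers(self) -> list[str]:
        return [e[0] for e in self.entries]

    def category(self, marker: str) -> str:
        for name, _, cat in self.entries:
            if name == marker:
                return cat
        raise KeyError(marker)

    def resolve(self, markers: Sequence[str]) -> None:
        missing = [m for m in markers if m not in self.markers]
        if missing:
            raise ConfigError(f"markers not in panel: {missing}")


@dataclass
class StudyDesign:
    """Donor-sample roster with group, cohort and pregnant<->postpartum pairing.

    ``donors`` maps each donor-sample id to its group (control / pregnant /
    postpartum) and cohort (discovery / validation). ``pairing`` maps a
    pregnant donor id to the same woman's postpartum donor id; it must be a
    bijection on its domain.
    """

    donors: pd.DataFrame  # index: donor id; columns: group, cohort
    pairing: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.donors, pd.DataFrame):
            raise ConfigError("donors must be a DataFrame indexed by donor id")
        self.validate()

    def validate(self) -> None:
        if self.donors.index.duplicated().any():
            dupes = self.donors.index[self.donors.index.duplicated()].tolist()
            raise ConfigError(f"duplicate donor ids in design: {dupes}")
        bad = set(self.donors["group"]) - set(GROUPS)
        if bad:
            raise ConfigError(f"unknown group labels in design: {sorted(bad)}")
        values = list(self.pairing.values())
        if len(set(values)) != len(values):
            raise ConfigError("pairing is not a bijection (repeated postpartum id)")
        for preg, post in self.pairing.items():
            if preg == post:
                raise ConfigError(f"donor {preg!r} paired with itself")
            for did, want in ((preg, PREGNANT), (post, POSTPARTUM)):
                if did not in self.donors.index:
                    raise ConfigError(f"paired donor {did!r} absent from design")
                if self.donors.loc[did, "group"] != want:
                    raise ConfigError(
                        f"paired donor {did!r} has group "
                        f"{self.donors.loc[did, 'group']!r}, expected {want!r}"
                    )

    # -- accessors -------------------------------------------------------
    @property
    def donor_ids(self) -> list[str]:
        return list(self.donors.index)

    def group_of(self, donor: str) -> str:
        return str(self.donors.loc[donor, "group"])

    def donors_in_group(self, group: str) -> list[str]:
        return list(self.donors.index[self.donors["group"] == group])

    def complete_pairs(self, available: Iterable[str] | None = None) -> list[tuple[str, str]]:
        """(pregnant, postpartum) pairs, optionally restricted to donors with data."""
        avail = set(available) if available is not None else None
        out = []
        for preg in sorted(self.pairing):
            post = self.pairing[preg]
            if avail is None or (preg in avail and post in avail):
                out.append((preg, post))
        return out

    def check_donors_known(self, donor_ids: Iterable[str]) -> None:
        unknown = sorted(set(map(str, donor_ids)) - set(map(str, self.donors.index)))
        if unknown:
            raise ConfigError(f"donors present in cells but absent from design: {unknown}")


def arcsinh_required(table: CellTable, op: str) -> None:
    if table.scale_state != ARCSINH:
        raise ContractError(f"{op} requires an arcsinh-scale table, got {table.scale_state!r}")


def raw_required(table: CellTable, op: str) -> None:
    if table.scale_state != RAW:
        raise ContractError(f"{op} requires a raw-scale table, got {table.scale_state!r}")
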