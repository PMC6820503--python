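"""Boolean threshold gating of NK cells and gated-frequency computation.

Populations are defined declaratively: a root conjunction of per-marker
threshold gates (live, lineage-negative, ...) and named terminal
populations that add further constraints on top of the root. The NK gate
of interest is CD3-CD19-CD20-CD14- live cells, split into the CD56dim
(CD16+) and CD56bright (CD16 low/negative) subsets by a two-threshold
CD56 scheme. Manual gating is replaced by static per-study thresholds on
the arcsinh scale so every run is reproducible.

Threshold semantics: polarity ``above`` keeps ``value > threshold``,
``below`` keeps ``value <= threshold``. The dim/bright tie-break
conventions follow directly (bright: CD56 > hi and CD16 <= thr; dim:
lo < CD56 <= hi and CD16 > thr), so the two subsets are disjoint by
construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import CellTable
from .errors import ConfigError, ContractError, GateError

logger = logging.getLogger(__name__)

POLARITIES = ("above", "below")


@dataclass(frozen=True)
class GateDefinition:
    """Single threshold gate on one marker."""

    marker: str
    threshold: float
    polarity: str  # "above" (> threshold) or "below" (<= threshold)

    def __post_init__(self) -> None:
        if self.polarity not in POLARITIES:
            raise ConfigError(f"gate polarity must be one of {POLARITIES}, got {self.polarity!r}")
        if not math.isfinite(self.threshold):
            raise ConfigError(f"gate threshold for {self.marker!r} must be finite")

    def evaluate(self, table: CellTable) -> np.ndarray:
        if self.marker not in table.channel_names:
            raise GateError(f"gate marker {self.marker!r} missing from table channels")
        col = table.column(self.marker)
        return col > self.threshold if self.polarity == "above" else col <= self.threshold


@dataclass
class GateTree:
    """Ordered conjunction of gates with named terminal populations.

    ``gates`` is the root conjunction applied to every cell. Each entry of
    ``populations`` adds its own conjunction on top of the root; terminal
    populations must be pairwise disjoint (enforced at application time).
    When ``populations`` is empty the root conjunction itself is the single
    terminal population, named ``root_name``.
    """

    gates: list[GateDefinition]
    populations: dict[str, list[GateDefinition]] = field(default_factory=dict)
    root_name: str = "root"
    scale: str = "arcsinh"

    @property
    def n_threshold_nodes(self) -> int:
        return len(self.gates) + sum(len(g) for g in self.populations.values())

    def required_markers(self) -> list[str]:
        seen: list[str] = []
        for g in self.gates + [d for defs in self.populations.values() for d in defs]:
            if g.marker not in seen:
                seen.append(g.marker)
        return seen


def _conjunction(table: CellTable, gates: Sequence[GateDefinition]) -> np.ndarray:
    mask = np.ones(table.n_cells, dtype=bool)
    for g in gates:
        mask &= g.evaluate(table)
    return mask


def apply_gate_tree(table: CellTable, tree: GateTree) -> dict[str, CellTable]:
    """Assign cells to the tree's terminal populations.

    Each cell lands in at most one terminal population, so population
    sizes sum to at most the input cell count. Missing markers raise a
    :class:`GateError` naming the marker; overlapping terminal definitions
    raise as well rather than silently double-counting.
    """
    if table.scale_state != tree.scale:
        raise ContractError(
            f"gate tree is declared on the {tree.scale!r} scale but table is {table.scale_state!r}"
        )
    for m in tree.required_markers():
        if m not in table.channel_names:
            raise GateError(f"gate marker {m!r} missing from table channels")

    root = _conjunction(table, tree.gates)
    if not tree.populations:
        return {tree.root_name: table.subset(root)}

    out: dict[str, CellTable] = {}
    assigned = np.zeros(table.n_cells, dtype=bool)
    for name, defs in tree.populations.items():
        mask = root & _conjunction(table, defs)
        overlap = assigned & mask
        if overlap.any():
            raise GateError(
                f"terminal population {name!r} overlaps a previous population "
                f"({int(overlap.sum())} cells)"
            )
        assigned |= mask
        out[name] = table.subset(mask)
    return out


def split_nk_subsets(
    nk: CellTable,
    cd56_lo: float,
    cd56_hi: float,
    cd16_thr: float,
    cd56: str = "CD56",
    cd16: str = "CD16",
) -> dict[str, CellTable]:
    """Split gated NK cells into CD56dim and CD56bright subsets.

    bright: CD56 > cd56_hi and CD16 <= cd16_thr;
    dim: cd56_lo < CD56 <= cd56_hi and CD16 > cd16_thr.
    The two regions are disjoint because their CD56 intervals are.
    """
    if not cd56_lo < cd56_hi:
        raise ContractError(f"cd56_lo ({cd56_lo}) must be below cd56_hi ({cd56_hi})")
    for m in (cd56, cd16):
        if m not in nk.channel_names:
            raise GateError(f"gate marker {m!r} missing from table channels")
    c56 = nk.column(cd56)
    c16 = nk.column(cd16)
    bright = (c56 > cd56_hi) & (c16 <= cd16_thr)
    dim = (c56 > cd56_lo) & (c56 <= cd56_hi) & (c16 > cd16_thr)
    return {"dim": nk.subset(dim), "bright": nk.subset(bright)}


def combination_label(markers: Sequence[str]) -> str:
    return "".join(f"{m}+" for m in markers)


def positive_frequency(
    tables_by_donor: Mapping[str, CellTable],
    markers: Sequence[str],
    thresholds: Sequence[float],
    population: str = "NK",
) -> pd.DataFrame:
    """Per-donor frequency of cells positive for every listed marker.

    Returns a frequency table with one row per donor: numerator (cells
    above all thresholds), denominator (all cells of the donor's gated
    population) and the percentage 100*numerator/denominator. A donor with
    an empty denominator keeps its row, flagged ``undefined`` with a NaN
    percentage, rather than being dropped silently.
    """
    if len(markers) != len(thresholds):
        raise ContractError("one threshold per marker is required")
    combo = combination_label(markers)
    rows = []
    for donor in tables_by_donor:
        table = tables_by_donor[donor]
        denom = table.n_cells
        if denom:
            mask = np.ones(denom, dtype=bool)
            for m, thr in zip(markers, thresholds):
                if m not in table.channel_names:
                    raise GateError(f"gate marker {m!r} missing from table channels")
                mask &= table.column(m) > thr
            num = int(mask.sum())
            pct = 100.0 * num / denom
            undefined = False
        else:
            num, pct, undefined = 0, np.nan, True
            logger.warning("donor %s has an empty %s population; frequency undefined", donor, population)
        rows.append(
            {
                "donor": donor,
                "population": population,
                "combination": combo,
                "numerator": num,
                "denominator": denom,
                "percentage": pct,
                "undefined": undefined,
            }
        )
    return pd.DataFrame(rows)
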