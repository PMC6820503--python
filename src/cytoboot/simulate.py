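"""Synthetic mass-cytometry studies with known ground truth.

The generator emulates the statistical structure of a three-group
(control / pregnant / postpartum) CyTOF study of peripheral blood: a
mixture of cell populations (CD56dim NK, CD56bright NK, T, B, monocyte,
dead), donor-level random effects shared across a donor's cells,
zero-inflated nonnegative raw intensities, paired pregnant<->postpartum
samples drawn from the same latent donor, and condition effects
concentrated on a few markers (by default CD38 on both NK subsets and
NKp46 on CD56dim, the pregnancy signature the analyses should recover).

Generative model, per cell and marker (arcsinh scale):

    y = mu_m + offset_{pop,m} + delta_m * 1[group affected] + u_{d,m} + eps
    u_{d,m} ~ Normal(0, tau_m^2)   shared by all cells of latent donor d,
                                    reused in the paired postpartum sample
    eps     ~ Normal(0, sigma_m^2)

Raw intensity = cofactor * sinh(max(y, 0)), then with probability pi_m
the cell is a structural zero (raw value exactly 0). The floor at 0
before inversion guarantees nonnegative raw values; it is a deliberate
truncation, rare whenever mu_m is a few sigma above 0. The raw data are
therefore exactly arcsinh-invertible back to max(y, 0).

Randomness is a single seed expanded hierarchically (study -> latent
donor -> sample), so regenerating the same study is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    CONTROL,
    POSTPARTUM,
    PREGNANT,
    CellTable,
    PanelDefinition,
    StudyDesign,
)
from .errors import ConfigError

VIABILITY = "viability"


@dataclass(frozen=True)
class MarkerModel:
    """Per-marker generative parameters on the arcsinh scale."""

    name: str
    baseline: float          # mu_m
    cell_sd: float           # sigma_m > 0
    donor_sd: float = 0.0    # tau_m >= 0
    zero_inflation: float = 0.0  # pi_m in [0, 1]


@dataclass(frozen=True)
class PopulationSpec:
    """A mixture component with per-marker additive mean offsets."""

    name: str
    fraction: float
    offsets: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ConditionEffect:
    """Additive arcsinh-scale shift delta_m in the affected group.

    ``populations=None`` applies the shift in every population; otherwise
    only cells of the listed populations are shifted (e.g. NKp46 elevated
    on CD56dim NK cells only).
    """

    marker: str
    delta: float
    populations: tuple[str, ...] | None = None
    group: str = PREGNANT


@dataclass
class SimulationConfig:
    n_donors_per_group: int
    cells_per_donor: int
    markers: list[MarkerModel]
    populations: list[PopulationSpec]
    condition_effects: list[ConditionEffect] = field(default_factory=list)
    groups: tuple[str, ...] = (CONTROL, PREGNANT, POSTPARTUM)
    paired: bool = True
    cofactor: float = 5.0
    cohort: str = "discovery"
    seed: int = 0
    viability_live_mean: float = 0.5
    viability_dead_mean: float = 4.5
    viability_sd: float = 0.5

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_donors_per_group <= 0 or self.cells_per_donor <= 0:
            raise ConfigError("n_donors_per_group and cells_per_donor must be positive")
        if not self.markers:
            raise ConfigError("at least one marker is required")
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ConfigError("marker names must be unique")
        for m in self.markers:
            if m.cell_sd <= 0:
                raise ConfigError(f"marker {m.name}: cell_sd must be > 0")
            if m.donor_sd < 0:
                raise ConfigError(f"marker {m.name}: donor_sd must be >= 0")
            if not 0 <= m.zero_inflation <= 1:
                raise ConfigError(f"marker {m.name}: zero_inflation must be in [0, 1]")
        total = sum(p.fraction for p in self.populations)
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ConfigError(f"population fractions must sum to 1, got {total}")
        known = {p.name for p in self.populations}
        for eff in self.condition_effects:
            if eff.marker not in names:
                raise ConfigError(f"condition effect on unknown marker {eff.marker!r}")
            if eff.populations is not None:
                bad = set(eff.populations) - known
                if bad:
                    raise ConfigError(f"condition effect on unknown populations {sorted(bad)}")
        if self.cofactor <= 0:
            raise ConfigError("cofactor must be positive")

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    @property
    def population_names(self) -> list[str]:
        return [p.name for p in self.populations]


@dataclass
class SimulationTruth:
    """Ground truth for parameter-recovery tests."""

    condition_effects: list[ConditionEffect]
    population_labels: dict[str, np.ndarray]       # sample id -> per-cell labels
    donor_effects: pd.DataFrame                    # latent donor x marker, u_{d,m}
    sample_to_latent: dict[str, str]               # sample id -> latent donor id

    def validate_against(self, tables: Mapping[str, CellTable]) -> None:
        if set(self.population_labels) != set(tables):
            raise ConfigError("truth sample ids do not match emitted tables")
        for sid, labels in self.population_labels.items():
            if len(labels) != tables[sid].n_cells:
                raise ConfigError(f"truth labels for {sid} do not match cell count")


def make_viability_channel(
    population_labels: np.ndarray,
    rng: np.random.Generator,
    cofactor: float,
    live_mean: float = 0.5,
    dead_mean: float = 4.5,
    sd: float = 0.5,
) -> np.ndarray:
    """Raw viability-channel values: cisplatin-like live/dead separation.

    Dead cells draw from a high-mean arcsinh distribution and live cells
    from a low-mean one; with the defaults the means sit 8 pooled
    standard deviations apart, so a midpoint threshold gates live cells
    near-perfectly.
    """
    n = len(population_labels)
    means = np.where(np.asarray(population_labels) == "dead", dead_mean, live_mean)
    y = rng.normal(means, sd, size=n)
    return cofactor * np.sinh(np.maximum(y, 0.0))


def generate_study(
    config: SimulationConfig,
) -> tuple[dict[str, CellTable], StudyDesign, SimulationTruth]:
    """Generate one synthetic study: per-sample cell tables, design, truth."""
    n = config.n_donors_per_group
    width = max(2, len(str(n)))

    # latent donors: controls are their own; pregnant/postpartum may share one
    latent_ids = [f"L{i:0{width}d}" for i in range(1, n + 1)]  # shared preg/post
    control_latents = [f"LC{i:0{width}d}" for i in range(1, n + 1)]

    samples: list[tuple[str, str, str]] = []  # (sample id, group, latent donor)
    pairing: dict[str, str] = {}
    for group in config.groups:
        for i in range(1, n + 1):
            if group == CONTROL:
                samples.append((f"C{i:0{width}d}", group, control_latents[i - 1]))
            elif group == PREGNANT:
                samples.append((f"P{i:0{width}d}", group, latent_ids[i - 1]))
            elif group == POSTPARTUM:
                latent = latent_ids[i - 1] if config.paired else f"LQ{i:0{width}d}"
                samples.append((f"Q{i:0{width}d}", group, latent))
            else:
                raise ConfigError(f"unknown group {group!r}")
    if config.paired and PREGNANT in config.groups and POSTPARTUM in config.groups:
        pairing = {f"P{i:0{width}d}": f"Q{i:0{width}d}" for i in range(1, n + 1)}

    design = StudyDesign(
        donors=pd.DataFrame(
            {"group": [g for _, g, _ in samples], "cohort": config.cohort},
            index=pd.Index([s for s, _, _ in samples], name="donor"),
        ),
        pairing=pairing,
    )

    markers = config.markers
    m = len(markers)
    mu = np.array([mk.baseline for mk in markers])
    sigma = np.array([mk.cell_sd for mk in markers])
    tau = np.array([mk.donor_sd for mk in markers])
    pi = np.array([mk.zero_inflation for mk in markers])
    fractions = np.array([p.fraction for p in config.populations])
    pop_names = config.population_names
    name_to_col = {mk.name: j for j, mk in enumerate(markers)}

    # population offset matrix (population x marker)
    offsets = np.zeros((len(pop_names), m))
    for i, pop in enumerate(config.populations):
        for marker, off in pop.offsets.items():
            if marker not in name_to_col:
                raise ConfigError(f"population {pop.name!r} offsets unknown marker {marker!r}")
            offsets[i, name_to_col[marker]] = off

    # condition-effect matrix per (group, population, marker)
    effect = {g: np.zeros((len(pop_names), m)) for g in config.groups}
    for eff in config.condition_effects:
        if eff.group not in effect:
            continue
        pops = range(len(pop_names)) if eff.populations is None else [
            pop_names.index(p) for p in eff.populations
        ]
        for i in pops:
            effect[eff.group][i, name_to_col[eff.marker]] += eff.delta

    # hierarchical seed expansion: study -> latent donor -> sample
    root = np.random.SeedSequence(config.seed)
    latents = sorted({lat for _, _, lat in samples})
    latent_children = dict(zip(latents, root.spawn(len(latents))))

    donor_u = {}
    sample_streams: dict[str, np.random.Generator] = {}
    samples_of_latent: dict[str, list[str]] = {}
    for sid, _, lat in samples:
        samples_of_latent.setdefault(lat, []).append(sid)
    for lat in latents:
        donor_ss, *samp_ss = latent_children[lat].spawn(1 + len(samples_of_latent[lat]))
        donor_u[lat] = np.random.default_rng(donor_ss).normal(0.0, tau)
        for sid, ss in zip(sorted(samples_of_latent[lat]), samp_ss):
            sample_streams[sid] = np.random.default_rng(ss)

    has_dead = "dead" in pop_names
    tables: dict[str, CellTable] = {}
    pop_labels: dict[str, np.ndarray] = {}
    for sid, group, lat in samples:
        rng = sample_streams[sid]
        k = config.cells_per_donor
        pop_idx = rng.choice(len(pop_names), size=k, p=fractions)
        mean = mu + offsets[pop_idx] + effect[group][pop_idx] + donor_u[lat]
        y = rng.normal(mean, sigma, size=(k, m))
        raw = config.cofactor * np.sinh(np.maximum(y, 0.0))
        zero_mask = rng.random((k, m)) < pi
        raw[zero_mask] = 0.0
        labels = np.array([pop_names[i] for i in pop_idx])
        table = CellTable(
            values=raw,
            channel_names=list(config.marker_names),
            cell_meta=pd.DataFrame(
                {"donor": sid, "group": group, "population": labels}
            ),
            scale_state="raw",
        )
        if has_dead:
            via = make_viability_channel(
                labels,
                rng,
                config.cofactor,
                live_mean=config.viability_live_mean,
                dead_mean=config.viability_dead_mean,
                sd=config.viability_sd,
            )
            table = table.with_channel(VIABILITY, via)
        tables[sid] = table
        pop_labels[sid] = labels

    truth = SimulationTruth(
        condition_effects=list(config.condition_effects),
        population_labels=pop_labels,
        donor_effects=pd.DataFrame(donor_u, index=config.marker_names).T,
        sample_to_latent={sid: lat for sid, _, lat in samples},
    )
    truth.validate_against(tables)
    return tables, design, truth


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

#: Default marker panel: (baseline, cell sd, donor sd, zero inflation).
#: Lineage/identity markers are clean (no zero inflation) so gating is
#: exercised as designed; several functional receptors are zero-inflated,
#: as cytometry intensities are.
DEFAULT_MARKERS: list[MarkerModel] = [
    MarkerModel("CD3", 0.3, 0.4, 0.15, 0.0),
    MarkerModel("CD19", 0.3, 0.4, 0.15, 0.0),
    MarkerModel("CD20", 0.3, 0.4, 0.15, 0.0),
    MarkerModel("CD14", 0.3, 0.4, 0.15, 0.0),
    MarkerModel("CD56", 0.3, 0.35, 0.15, 0.0),
    MarkerModel("CD16", 0.3, 0.4, 0.15, 0.0),
    MarkerModel("CD38", 2.0, 0.5, 0.3, 0.0),
    MarkerModel("NKp46", 2.0, 0.5, 0.3, 0.0),
    MarkerModel("NKp30", 1.8, 0.5, 0.3, 0.05),
    MarkerModel("NKp44", 0.8, 0.5, 0.3, 0.2),
    MarkerModel("NKG2A", 1.5, 0.5, 0.3, 0.1),
    MarkerModel("NKG2C", 1.0, 0.5, 0.3, 0.2),
    MarkerModel("NKG2D", 2.2, 0.5, 0.3, 0.0),
    MarkerModel("PD1", 0.7, 0.5, 0.3, 0.3),
    MarkerModel("CD27", 1.2, 0.5, 0.3, 0.1),
    MarkerModel("CD57", 1.5, 0.6, 0.35, 0.15),
    MarkerModel("KIR2DL1", 1.0, 0.5, 0.3, 0.25),
    MarkerModel("CD107a", 0.8, 0.5, 0.3, 0.2),
    MarkerModel("CD25", 0.6, 0.4, 0.2, 0.3),
    MarkerModel("CD69", 1.0, 0.5, 0.3, 0.15),
]

#: PBMC mixture with bimodal CD56/CD16 structure for the NK subsets:
#: CD56bright sits high on CD56 and low on CD16, CD56dim mid-CD56/high-CD16.
DEFAULT_POPULATIONS: list[PopulationSpec] = [
    PopulationSpec("NK_dim", 0.10, {"CD56": 2.2, "CD16": 3.0, "CD57": 0.5}),
    PopulationSpec("NK_bright", 0.03, {"CD56": 4.2, "NKG2A": 0.8}),
    PopulationSpec("T", 0.44, {"CD3": 3.0, "CD27": 0.8}),
    PopulationSpec("B", 0.10, {"CD19": 3.0, "CD20": 3.0}),
    PopulationSpec("monocyte", 0.28, {"CD14": 3.0, "CD38": 0.5}),
    PopulationSpec("dead", 0.05, {}),
]

#: The pregnancy signature the study's analyses should recover: CD38 up on
#: both NK subsets, NKp46 up on CD56dim only.
DEFAULT_CONDITION_EFFECTS: list[ConditionEffect] = [
    ConditionEffect("CD38", 0.5, ("NK_dim", "NK_bright")),
    ConditionEffect("NKp46", 0.5, ("NK_dim",)),
]


def default_config(**overrides) -> SimulationConfig:
    """Study-shaped default: 21 donors per group, paired, full PBMC mixture."""
    base = dict(
        n_donors_per_group=21,
        cells_per_donor=1000,
        markers=list(DEFAULT_MARKERS),
        populations=list(DEFAULT_POPULATIONS),
        condition_effects=list(DEFAULT_CONDITION_EFFECTS),
        paired=True,
        cofactor=5.0,
        seed=0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def default_panel() -> PanelDefinition:
    """Panel matching the default generator (synthetic metal tags)."""
    cats = {
        "CD3": "lineage", "CD19": "lineage", "CD20": "lineage", "CD14": "lineage",
        "CD56": "lineage", "CD16": "lineage",
        "CD38": "activating", "NKp46": "activating", "NKp30": "activating",
        "NKp44": "activating", "NKG2C": "activating", "NKG2D": "activating",
        "NKG2A": "inhibitory", "PD1": "inhibitory", "KIR2DL1": "inhibitory",
        "CD27": "other", "CD57": "other", "CD107a": "functional",
        "CD25": "functional", "CD69": "functional",
        VIABILITY: "viability",
    }
    return PanelDefinition(
        entries=[(name, f"Sim{141 + i}Di", cat) for i, (name, cat) in enumerate(cats.items())]
    )


def two_group_nk_config(
    n_donors_per_group: int = 10,
    cells_per_donor: int = 1000,
    n_markers: int = 10,
    tau: float = 0.3,
    sigma: float = 0.5,
    baseline: float = 2.0,
    effects: Mapping[str, float] | None = None,
    seed: int = 0,
) -> SimulationConfig:
    """A pure-NK two-group benchmark study for GLM calibration and power.

    One homogeneous population, no zero inflation, control vs pregnant
    only, unpaired. The first markers are named after the study's NK
    receptors so effect configurations read naturally.
    """
    names = ["CD38", "NKp46", "NKp30", "NKp44", "NKG2A", "NKG2C", "NKG2D",
             "PD1", "CD27", "CD57", "KIR2DL1", "CD107a", "CD25", "CD69"]
    if n_markers > len(names):
        names += [f"M{i:02d}" for i in range(n_markers - len(names))]
    markers = [MarkerModel(nm, baseline, sigma, tau, 0.0) for nm in names[:n_markers]]
    cond = [ConditionEffect(mk, d) for mk, d in (effects or {}).items()]
    return SimulationConfig(
        n_donors_per_group=n_donors_per_group,
        cells_per_donor=cells_per_donor,
        markers=markers,
        populations=[PopulationSpec("NK_dim", 1.0, {})],
        condition_effects=cond,
        groups=(CONTROL, PREGNANT),
        paired=False,
        seed=seed,
    )
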