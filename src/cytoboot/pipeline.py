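"""End-to-end orchestration: simulate -> transform -> gate -> analyses.

One config (a YAML file or a :class:`PipelineConfig`) drives the whole
run: generate or load a study, arcsinh-transform, gate live NK cells and
split the CD56dim/CD56bright subsets, then per subset run the
donor-bootstrap GLM for each contrast, LDA over donor median profiles,
and nonparametric comparisons of the CD38+NKp46+ co-expression
frequency. Every artifact is a plain CSV/YAML file and the run manifest
records row counts and content checksums, so a run is reproducible and
each stage independently scriptable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .containers import (
    ARCSINH,
    CONTROL,
    PREGNANT,
    POSTPARTUM,
    CellTable,
    raw_required,
)
from .errors import AnalysisError, ConfigError, ContractError, CytobootError
from .gating import GateDefinition, GateTree, apply_gate_tree, positive_frequency, split_nk_subsets
from .glm import ModelSpec, bootstrap_glm, effects_table_export
from .group_stats import Contrast, compare_frequency_table, comparisons_frame
from .io.configs import write_design
from .lda import donor_medians, fit_lda
from .simulate import SimulationConfig, default_config, generate_study

logger = logging.getLogger(__name__)

DEFAULT_COFACTOR = 5.0


def arcsinh_transform(
    table: CellTable, cofactor: float = DEFAULT_COFACTOR, exclude: list[str] | None = None
) -> CellTable:
    """Elementwise asinh(value / cofactor) on a raw-scale table.

    ``exclude`` names channels declared non-expression (left untouched).
    Transforming an already-transformed table is a contract error; the
    transform is strictly increasing and odd per channel.
    """
    raw_required(table, "arcsinh_transform")
    if cofactor <= 0:
        raise ContractError("cofactor must be positive")
    values = table.values.copy()
    cols = [i for i, c in enumerate(table.channel_names) if not exclude or c not in exclude]
    values[:, cols] = np.arcsinh(values[:, cols] / cofactor)
    return replace(table, values=values, scale_state=ARCSINH, cofactor=cofactor)


def default_gate_tree() -> GateTree:
    """Live, lineage-negative NK gate on the arcsinh scale.

    NK cells are the live CD3-CD19-CD20-CD14- CD56+ cells; the dim and
    bright terminals are carved out by the two-threshold CD56 scheme with
    the CD16 conjunction. Thresholds are tuned to the default synthetic
    generator and are configuration, not biology.
    """
    root = [
        GateDefinition("viability", 2.5, "below"),
        GateDefinition("CD3", 1.5, "below"),
        GateDefinition("CD19", 1.5, "below"),
        GateDefinition("CD20", 1.5, "below"),
        GateDefinition("CD14", 1.5, "below"),
    ]
    return GateTree(gates=root, populations={}, root_name="live_lin_neg", scale=ARCSINH)


@dataclass
class NKThresholds:
    cd56_lo: float = 1.2
    cd56_hi: float = 3.5
    cd16_thr: float = 1.5


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = None  # type: ignore[assignment]
    cofactor: float = DEFAULT_COFACTOR
    gate_tree: GateTree = field(default_factory=default_gate_tree)
    nk_thresholds: NKThresholds = field(default_factory=NKThresholds)
    glm_markers: list[str] | None = None      # None: non-gating panel markers
    contrasts: list[Contrast] = field(default_factory=lambda: [
        Contrast(CONTROL, PREGNANT, paired=False),
        Contrast(POSTPARTUM, PREGNANT, paired=True),
    ])
    n_boot: int = 500
    coexpression_markers: tuple[str, str] = ("CD38", "NKp46")
    coexpression_thresholds: tuple[float, float] = (2.0, 2.0)
    lda_shrinkage: float | None = None
    outdir: str = "cytoboot_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.simulation is None:
            self.simulation = default_config(seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: Mapping[str, Any]) -> "PipelineConfig":
        from .simulate import ConditionEffect, MarkerModel, PopulationSpec

        kwargs: dict[str, Any] = {}
        sim = doc.get("simulation")
        if sim is not None:
            sim = dict(sim)
            if "markers" in sim:
                sim["markers"] = [MarkerModel(**m) for m in sim["markers"]]
            if "populations" in sim:
                sim["populations"] = [
                    PopulationSpec(p["name"], p["fraction"], p.get("offsets", {}))
                    for p in sim["populations"]
                ]
            if "condition_effects" in sim:
                sim["condition_effects"] = [
                    ConditionEffect(
                        e["marker"], e["delta"],
                        tuple(e["populations"]) if e.get("populations") else None,
                    )
                    for e in sim["condition_effects"]
                ]
            if "groups" in sim:
                sim["groups"] = tuple(sim["groups"])
            try:
                # unspecified fields fall back to the default study conditions
                kwargs["simulation"] = default_config(**sim)
            except TypeError as exc:
                raise ConfigError(f"bad simulation block: {exc}") from None
        if "nk_thresholds" in doc:
            kwargs["nk_thresholds"] = NKThresholds(**doc["nk_thresholds"])
        if "contrasts" in doc:
            kwargs["contrasts"] = [
                Contrast(c["reference"], c["comparison"], bool(c.get("paired", False)))
                for c in doc["contrasts"]
            ]
        for key in ("cofactor", "glm_markers", "n_boot", "lda_shrinkage", "outdir", "seed"):
            if key in doc:
                kwargs[key] = doc[key]
        if "coexpression_markers" in doc:
            kwargs["coexpression_markers"] = tuple(doc["coexpression_markers"])
        if "coexpression_thresholds" in doc:
            kwargs["coexpression_thresholds"] = tuple(doc["coexpression_thresholds"])
        return cls(**kwargs)


@dataclass
class RunManifest:
    config_digest: str
    seed: int
    stages: list[dict] = field(default_factory=list)
    artifacts: dict[str, str] = field(default_factory=dict)  # path -> sha256
    complete: bool = False

    def record_stage(self, name: str, **counts) -> None:
        self.stages.append({"stage": name, **counts})

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_digest": self.config_digest,
                "seed": self.seed,
                "complete": self.complete,
                "stages": self.stages,
                "artifacts": self.artifacts,
            },
            indent=2,
            sort_keys=True,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_digest(config: PipelineConfig) -> str:
    blob = repr(config).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis; artifacts land under ``config.outdir``.

    Stage order: simulate, transform, gate, glm, lda, stats, manifest.
    Any stage error aborts with the stage named; the manifest is still
    written with ``complete: false`` and the already-produced artifacts.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_digest=_config_digest(config), seed=config.seed)

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        manifest.artifacts[name] = _sha256(path)
        return path

    stage = "simulate"
    try:
        sim_config = replace(config.simulation, seed=config.seed)
        tables, design, truth = generate_study(sim_config)
        emit("design.csv", lambda p: write_design(design, p))
        manifest.record_stage(
            stage,
            n_samples=len(tables),
            n_cells=int(sum(t.n_cells for t in tables.values())),
        )

        stage = "transform"
        tables = {d: arcsinh_transform(t, config.cofactor) for d, t in tables.items()}
        manifest.record_stage(stage, cofactor=config.cofactor)

        stage = "gate"
        thr = config.nk_thresholds
        subsets: dict[str, dict[str, CellTable]] = {"dim": {}, "bright": {}}
        nk_by_donor: dict[str, CellTable] = {}
        live_cells = 0
        for donor, t in tables.items():
            gated = apply_gate_tree(t, config.gate_tree)
            live = gated[config.gate_tree.root_name]
            live_cells += live.n_cells
            split = split_nk_subsets(
                live, cd56_lo=thr.cd56_lo, cd56_hi=thr.cd56_hi, cd16_thr=thr.cd16_thr
            )
            subsets["dim"][donor] = split["dim"]
            subsets["bright"][donor] = split["bright"]
            nk_by_donor[donor] = CellTable.concatenate([split["dim"], split["bright"]])
        nk_cells = {s: int(sum(t.n_cells for t in subsets[s].values())) for s in subsets}
        if sum(nk_cells.values()) > live_cells:
            raise AnalysisError("gated population sizes exceed upstream live-cell count")
        manifest.record_stage(stage, live_cells=live_cells, **{f"nk_{s}": c for s, c in nk_cells.items()})

        markers = config.glm_markers
        if markers is None:
            gate_markers = set(config.gate_tree.required_markers()) | {"CD56", "CD16"}
            markers = [
                m for m in sim_config.marker_names if m not in gate_markers
            ]

        stage = "glm"
        ss = np.random.SeedSequence(config.seed).spawn(len(subsets) * len(config.contrasts))
        i = 0
        effects = {}
        for subset_name in ("dim", "bright"):
            for contrast in config.contrasts:
                spec = ModelSpec(
                    contrast=(contrast.reference, contrast.comparison),
                    markers=list(markers),
                    n_boot=config.n_boot,
                    seed=int(ss[i].generate_state(1)[0] % (2**31)),
                    paired=contrast.paired,
                )
                i += 1
                met = bootstrap_glm(subsets[subset_name], design, spec)
                effects[(subset_name, contrast.reference, contrast.comparison)] = met
                emit(
                    f"effects_{subset_name}_{contrast.reference}_vs_{contrast.comparison}.csv",
                    lambda p, met=met: effects_table_export(met).to_csv(p, index=False),
                )
        manifest.record_stage(stage, n_models=len(effects), markers=len(markers))

        stage = "lda"
        groups_by_donor = design.donors["group"].to_dict()
        for subset_name in ("dim", "bright"):
            nonempty = {d: t for d, t in subsets[subset_name].items() if t.n_cells > 0}
            dsm = donor_medians(nonempty, markers, groups_by_donor)
            res = fit_lda(dsm, shrinkage=config.lda_shrinkage)
            emit(
                f"lda_{subset_name}_projections.csv",
                lambda p, res=res: res.projections.to_csv(p),
            )
            emit(
                f"lda_{subset_name}_contributions.csv",
                lambda p, res=res: res.marker_contributions.to_csv(p),
            )
        manifest.record_stage(stage, n_subsets=2)

        stage = "stats"
        co_m = list(config.coexpression_markers)
        co_t = list(config.coexpression_thresholds)
        freq = positive_frequency(nk_by_donor, co_m, co_t, population="NK")
        emit("frequencies.csv", lambda p: freq.to_csv(p, index=False))
        results = compare_frequency_table(freq, design, config.contrasts)
        emit("comparisons.csv", lambda p: comparisons_frame(results).to_csv(p, index=False))
        manifest.record_stage(stage, n_comparisons=len(results))

        manifest.complete = True
    except CytobootError as exc:
        manifest.record_stage(stage, error=str(exc))
        (outdir / "manifest.json").write_text(manifest.to_json())
        raise AnalysisError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
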