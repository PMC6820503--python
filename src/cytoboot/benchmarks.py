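"""Seeded simulation benchmarks for calibration, power and recovery.

These functions define the package's reference study conditions — the
geometries used to verify that the donor-bootstrap GLM is calibrated
under the null, powered against the configured pregnancy signature, and
that the full pipeline recovers injected effects end to end. Both the
test suite and ``scripts/acceptance.py`` run them, so the numbers they
report are always recomputed, never stored.

All randomness flows from one base seed through ``SeedSequence.spawn``,
so a benchmark is a deterministic function of its arguments.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CONTROL, PREGNANT
from .glm import DIRECTION_COMPARISON, ModelSpec, bootstrap_glm
from .group_stats import Contrast
from .pipeline import PipelineConfig, arcsinh_transform, run_pipeline
from .simulate import ConditionEffect, default_config, generate_study, two_group_nk_config

#: benchmark geometry: a two-group NK study at cohort scale
N_DONORS = 10
CELLS_PER_DONOR = 1000
N_MARKERS = 10
TAU = 0.3
N_BOOT = 200


def _seeds(ss: np.random.SeedSequence, n: int) -> list[int]:
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def _one_glm_study(study_seed: int, glm_seed: int, effects: dict[str, float] | None):
    cfg = two_group_nk_config(
        n_donors_per_group=N_DONORS,
        cells_per_donor=CELLS_PER_DONOR,
        n_markers=N_MARKERS,
        tau=TAU,
        effects=effects,
        seed=study_seed,
    )
    tables, design, _ = generate_study(cfg)
    tables = {d: arcsinh_transform(t) for d, t in tables.items()}
    spec = ModelSpec(
        contrast=(CONTROL, PREGNANT),
        markers=cfg.marker_names,
        n_boot=N_BOOT,
        seed=glm_seed,
    )
    return bootstrap_glm(tables, design, spec), cfg


def null_calibration(base_seed: int = 0, n_replicates: int = 50) -> float:
    """Mean fraction of null markers whose 95% CI excludes zero.

    Replicate studies have no condition effects, donor heterogeneity
    tau = 0.3, 10 donors per group, 1000 cells per donor, 10 markers and
    200 bootstrap resamples; under correct donor-level accounting the
    fraction should sit near the nominal 0.05, modestly inflated by the
    small number of donors.
    """
    fracs = []
    for ss in np.random.SeedSequence(base_seed).spawn(n_replicates):
        s1, s2 = _seeds(ss, 2)
        met, _ = _one_glm_study(s1, s2, None)
        fracs.append(float(met.table["significant"].mean()))
    return float(np.mean(fracs))


@dataclass
class RecoveryOutcome:
    recovery_rate: float       # replicates flagging every true marker, right direction
    median_false_flags: float  # median count of flagged null markers


def effect_recovery(
    base_seed: int = 0,
    n_replicates: int = 50,
    delta: float = 0.5,
    true_markers: tuple[str, str] = ("CD38", "NKp46"),
) -> RecoveryOutcome:
    """Power against a two-marker pregnancy signature (delta on arcsinh scale)."""
    hits, false_flags = [], []
    for ss in np.random.SeedSequence(base_seed).spawn(n_replicates):
        s1, s2 = _seeds(ss, 2)
        met, cfg = _one_glm_study(s1, s2, {m: delta for m in true_markers})
        t = met.table
        hits.append(
            all(
                bool(t.loc[m, "significant"]) and t.loc[m, "direction"] == DIRECTION_COMPARISON
                for m in true_markers
            )
        )
        nulls = [m for m in cfg.marker_names if m not in true_markers]
        false_flags.append(int(t.loc[nulls, "significant"].sum()))
    return RecoveryOutcome(
        recovery_rate=float(np.mean(hits)),
        median_false_flags=float(np.median(false_flags)),
    )


def recovery_pipeline_config(seed: int, outdir: str) -> PipelineConfig:
    """End-to-end study: CD38 up on both NK subsets, NKp46 on CD56dim only."""
    sim = default_config(
        n_donors_per_group=10,
        cells_per_donor=3000,
        condition_effects=[
            ConditionEffect("CD38", 0.6, ("NK_dim", "NK_bright")),
            ConditionEffect("NKp46", 0.6, ("NK_dim",)),
        ],
        groups=(CONTROL, PREGNANT),
        paired=False,
        seed=seed,
    )
    return PipelineConfig(
        simulation=sim,
        n_boot=N_BOOT,
        contrasts=[Contrast(CONTROL, PREGNANT, paired=False)],
        outdir=outdir,
        seed=seed,
    )


def _pipeline_hit(outdir: Path) -> bool:
    dim = pd.read_csv(outdir / "effects_dim_control_vs_pregnant.csv").set_index("marker")
    bright = pd.read_csv(outdir / "effects_bright_control_vs_pregnant.csv").set_index("marker")

    def flagged(tab, marker):
        return bool(tab.loc[marker, "significant"]) and tab.loc[marker, "direction"] == DIRECTION_COMPARISON

    return flagged(dim, "CD38") and flagged(dim, "NKp46") and flagged(bright, "CD38")


def pipeline_recovery(base_seed: int = 0, n_replicates: int = 20) -> float:
    """Fraction of full pipeline runs recovering the injected signature."""
    hits = []
    for ss in np.random.SeedSequence(base_seed).spawn(n_replicates):
        seed = _seeds(ss, 1)[0]
        with tempfile.TemporaryDirectory() as td:
            run_pipeline(recovery_pipeline_config(seed, td))
            hits.append(_pipeline_hit(Path(td)))
    return float(np.mean(hits))


def pipeline_determinism(seed: int = 0) -> bool:
    """Two same-seed pipeline runs produce checksum-identical artifacts."""
    with tempfile.TemporaryDirectory() as td1, tempfile.TemporaryDirectory() as td2:
        cfg1 = recovery_pipeline_config(seed, td1)
        cfg2 = recovery_pipeline_config(seed, td2)
        m1 = run_pipeline(cfg1)
        m2 = run_pipeline(cfg2)
        return m1.artifacts == m2.artifacts
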