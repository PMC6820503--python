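"""Donor-bootstrap logistic GLM: which markers predict pregnancy?

The model is a cell-level logistic regression with the predictor/outcome
roles flipped relative to classical differential expression: standardized
arcsinh marker expressions jointly predict the donor's condition (e.g.
control vs pregnant), so each coefficient is the change in log-odds of
the condition per 1 SD of marker expression. Cells from one donor are
correlated, so naive cell-level standard errors would be wildly
anti-conservative; uncertainty therefore comes from a cluster bootstrap
that resamples whole donors with replacement, stratified by group (or
pregnant<->postpartum pairs as single units for paired contrasts). A
marker is called predictive when its percentile bootstrap CI excludes
zero — the "bar does not cross zero" criterion of a forest plot.

Orientation convention: the fit is always performed with the outcome
indicator set to the alphabetically later group label and coefficient
signs flipped afterwards if the requested comparison group is the other
one. This makes the label-swap antisymmetry (reversing the contrast
negates every estimate and mirrors every CI) hold bitwise-exactly rather
than merely to optimizer tolerance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import CellTable, StudyDesign, arcsinh_required
from .errors import AnalysisError, ContractError, ModelError

logger = logging.getLogger(__name__)

MAX_ITER = 100
GRAD_TOL = 1e-8
SEPARATION_BETA = 30.0
SEPARATION_RIDGE = 1e-6

DIRECTION_COMPARISON = "predicts_comparison"
DIRECTION_REFERENCE = "predicts_reference"
DIRECTION_NONE = "none"


@dataclass
class ModelSpec:
    """Configuration of one bootstrap-GLM contrast."""

    contrast: tuple[str, str]          # (reference, comparison)
    markers: list[str]
    n_boot: int = 500
    ci_level: float = 0.95
    cells_per_donor: int | None = None  # None: downsample to min donor count
    seed: int = 0
    paired: bool = False

    def __post_init__(self) -> None:
        if len(self.contrast) != 2 or self.contrast[0] == self.contrast[1]:
            raise ContractError("contrast must name two distinct groups")
        if not 0 < self.ci_level < 1:
            raise ContractError("ci_level must lie in (0, 1)")
        if self.n_boot < 0:
            raise ContractError("n_boot must be nonnegative")


@dataclass
class ScalingRecord:
    """Means/SDs used to standardize markers, for inverse mapping."""

    markers: list[str]
    means: np.ndarray
    sds: np.ndarray
    dropped: list[str] = field(default_factory=list)

    def inverse(self, standardized: np.ndarray) -> np.ndarray:
        return standardized * self.sds + self.means


@dataclass
class CoefficientVector:
    intercept: float
    coefficients: np.ndarray        # per retained marker
    markers: list[str]
    n_iter: int
    grad_norm: float
    converged: bool
    separated: bool = False

    def as_series(self) -> pd.Series:
        return pd.Series(self.coefficients, index=self.markers)


@dataclass
class MarkerEffectTable:
    """Per-marker log-odds, bootstrap 95% CI and significance flags.

    ``table`` columns: estimate, ci_low, ci_high, significant, direction;
    index = marker. Significance is exactly "the CI excludes zero".
    """

    table: pd.DataFrame
    contrast: tuple[str, str]
    n_boot: int
    ci_level: float
    seed: int
    n_failed_resamples: int
    scaling: ScalingRecord
    bootstrap_estimates: np.ndarray | None = None  # (n_kept, n_markers)

    def validate(self) -> None:
        t = self.table
        with_ci = t.dropna(subset=["ci_low", "ci_high"])
        if not (with_ci["ci_low"] <= with_ci["ci_high"]).all():
            raise ModelError("ci_low exceeds ci_high")
        excl = (with_ci["ci_low"] > 0) | (with_ci["ci_high"] < 0)
        if not (with_ci["significant"] == excl).all():
            raise ModelError("significance flag inconsistent with interval")


def standardize_markers(
    table: CellTable, markers: Sequence[str]
) -> tuple[np.ndarray, ScalingRecord]:
    """Center and scale marker columns to mean 0, SD 1 (population SD).

    Zero-variance markers are dropped with a warning and recorded; if all
    markers are constant there is nothing to model and a ModelError is
    raised. Standardization makes log-odds comparable across markers on
    one forest plot.
    """
    arcsinh_required(table, "standardize_markers")
    if table.n_cells < 2:
        raise ContractError("standardization needs at least 2 cells")
    X = table.marker_matrix(markers)
    means = X.mean(axis=0)
    sds = X.std(axis=0)  # ddof=0: population SD convention
    keep = sds > 0
    dropped = [m for m, k in zip(markers, keep) if not k]
    if dropped:
        warnings.warn(f"dropping zero-variance markers: {dropped}", stacklevel=2)
    if not keep.any():
        raise ModelError("all markers have zero variance")
    kept = [m for m, k in zip(markers, keep) if k]
    Xs = (X[:, keep] - means[keep]) / sds[keep]
    return Xs, ScalingRecord(markers=kept, means=means[keep], sds=sds[keep], dropped=dropped)


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    markers: Sequence[str] | None = None,
    ridge: float = 0.0,
) -> CoefficientVector:
    """Newton-Raphson logistic fit with step-halving.

    ``X`` is the design matrix with the intercept as its first column.
    Convergence: max |gradient| < 1e-8 or 100 iterations. Complete or
    quasi-complete separation (coefficient norm diverging) is flagged and
    the last stable iterate returned. An optional ridge penalty on the
    slopes (never the intercept) stabilises separated refits.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if y.min() == y.max():
        raise ContractError("outcome y contains a single class")
    n, p = X.shape
    penalty = np.zeros(p)
    penalty[1:] = ridge

    beta = np.zeros(p)
    eta = X @ beta
    ll = _log_likelihood(eta, y) - 0.5 * float(penalty @ beta**2)
    grad_norm = np.inf
    separated = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        prob = expit(eta)
        grad = X.T @ (y - prob) - penalty * beta
        grad_norm = float(np.abs(grad).max())
        if grad_norm < GRAD_TOL:
            break
        w = prob * (1.0 - prob)
        H = (X * w[:, None]).T @ X + np.diag(penalty)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            separated = True
            break
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            eta_c = X @ cand
            ll_c = _log_likelihood(eta_c, y) - 0.5 * float(penalty @ cand**2)
            if ll_c >= ll - 1e-12:
                break
            scale *= 0.5
        if np.abs(cand).max() > SEPARATION_BETA:
            separated = True  # keep the last stable iterate
            break
        beta, eta, ll = cand, eta_c, ll_c

    # complete/quasi-complete separation can also "converge" by gradient
    # tolerance: every cell then sits on the correct side (margin >= 0) and
    # the slope is large, because the likelihood has no interior maximum
    if len(y) and not separated:
        margin = (2.0 * y - 1.0) * (X @ beta)
        if margin.min() >= -1e-6 and np.abs(beta).max() > 10.0:
            separated = True

    coef = CoefficientVector(
        intercept=float(beta[0]),
        coefficients=beta[1:].copy(),
        markers=list(markers) if markers is not None else [f"x{i}" for i in range(1, p)],
        n_iter=it,
        grad_norm=grad_norm,
        converged=grad_norm < GRAD_TOL,
        separated=separated,
    )
    return coef


def _percentile_ci(samples: np.ndarray, level: float) -> tuple[np.ndarray, np.ndarray]:
    alpha = 100.0 * (1.0 - level) / 2.0
    lo = np.percentile(samples, alpha, axis=0)
    hi = np.percentile(samples, 100.0 - alpha, axis=0)
    return lo, hi


def _resample_units(
    rng: np.random.Generator, units_by_stratum: Mapping[str, list]
) -> list:
    """Sample units with replacement within each stratum, preserving sizes.

    Strata are visited in sorted key order so the draw sequence does not
    depend on the orientation of the requested contrast.
    """
    chosen = []
    for stratum in sorted(units_by_stratum):
        units = units_by_stratum[stratum]
        idx = rng.integers(0, len(units), size=len(units))
        chosen.extend(units[i] for i in idx)
    return chosen


def bootstrap_glm(
    tables_by_donor: Mapping[str, CellTable],
    design: StudyDesign,
    spec: ModelSpec,
) -> MarkerEffectTable:
    """Donor-stratified bootstrap of the cell-level logistic GLM.

    Procedure: (1) optionally downsample each donor to a common cell
    count (default: the minimum donor cell count, so no donor dominates
    the likelihood); (2) standardize markers once over the assembled
    contrast; (3) point estimate on the full assembled data; (4) n_boot
    cluster resamples of donors (pairs, for paired contrasts) with
    replacement within group strata, refitting with the same scaling;
    (5) percentile CIs, with significance = CI excludes zero. A resample
    that hits separation is refit with a tiny slope ridge and counted in
    ``n_failed_resamples``; resamples that remain non-finite are dropped.
    More than 20% failures aborts the analysis.
    """
    ref, comp = spec.contrast
    for g in (ref, comp):
        if g not in set(design.donors["group"]):
            raise ContractError(f"contrast group {g!r} absent from design")

    avail = set(tables_by_donor)
    if spec.paired:
        pairs = design.complete_pairs(avail)
        if not pairs:
            raise ContractError("paired contrast has no complete pregnant<->postpartum pairs")
        donors = sorted({d for pair in pairs for d in pair})
    else:
        donors = sorted(
            d for g in (ref, comp) for d in design.donors_in_group(g) if d in avail
        )
    group_of = {d: design.group_of(d) for d in donors}
    for g in (ref, comp):
        if sum(1 for d in donors if group_of[d] == g) < 2:
            raise ContractError(f"need at least 2 donors with data in group {g!r}")

    # canonical orientation: indicator = alphabetically later group
    canonical_one = max(ref, comp)
    flip = comp != canonical_one

    root = np.random.SeedSequence(spec.seed)
    sub_ss, boot_ss = root.spawn(2)

    counts = {d: tables_by_donor[d].n_cells for d in donors}
    if min(counts.values()) == 0:
        empty = sorted(d for d, c in counts.items() if c == 0)
        raise ContractError(f"donors with zero cells in contrast: {empty}")
    k = spec.cells_per_donor if spec.cells_per_donor is not None else min(counts.values())

    # per-donor balanced subsample, seeded per donor in sorted order
    sub_children = dict(zip(donors, sub_ss.spawn(len(donors))))
    blocks_X: dict[str, np.ndarray] = {}
    scaling_parts = []
    for d in donors:
        t = tables_by_donor[d]
        arcsinh_required(t, "bootstrap_glm")
        M = t.marker_matrix(spec.markers)
        if k < counts[d]:
            rng_d = np.random.default_rng(sub_children[d])
            idx = np.sort(rng_d.choice(counts[d], size=k, replace=False))
            M = M[idx]
        blocks_X[d] = M
        scaling_parts.append(M)

    pooled = np.vstack(scaling_parts)
    means = pooled.mean(axis=0)
    sds = pooled.std(axis=0)
    keep = sds > 0
    dropped = [m for m, kp in zip(spec.markers, keep) if not kp]
    if dropped:
        warnings.warn(f"dropping zero-variance markers: {dropped}", stacklevel=2)
    if not keep.any():
        raise ModelError("all markers have zero variance in the assembled contrast")
    kept = [m for m, kp in zip(spec.markers, keep) if kp]
    scaling = ScalingRecord(markers=kept, means=means[keep], sds=sds[keep], dropped=dropped)
    for d in donors:
        blocks_X[d] = (blocks_X[d][:, keep] - scaling.means) / scaling.sds
    y_of = {d: 1.0 if group_of[d] == canonical_one else 0.0 for d in donors}

    def assemble(chosen_donors: list[str]) -> tuple[np.ndarray, np.ndarray]:
        Xb = np.vstack([blocks_X[d] for d in chosen_donors])
        yb = np.concatenate(
            [np.full(blocks_X[d].shape[0], y_of[d]) for d in chosen_donors]
        )
        return np.column_stack([np.ones(len(yb)), Xb]), yb

    X_full, y_full = assemble(donors)
    point = fit_logistic(X_full, y_full, markers=kept)
    if point.separated:
        point = fit_logistic(X_full, y_full, markers=kept, ridge=SEPARATION_RIDGE)
        point.separated = True
    estimates = point.coefficients * (-1.0 if flip else 1.0)

    n_failed = 0
    boot = None
    if spec.n_boot > 0:
        if spec.paired:
            units_by_stratum = {"pairs": [list(p) for p in design.complete_pairs(avail)]}
        else:
            units_by_stratum = {
                g: [[d] for d in donors if group_of[d] == g] for g in sorted((ref, comp))
            }
        rng_b = np.random.default_rng(boot_ss)
        kept_rows = []
        for _ in range(spec.n_boot):
            chosen_units = _resample_units(rng_b, units_by_stratum)
            chosen = [d for unit in chosen_units for d in unit]
            Xb, yb = assemble(chosen)
            fit = fit_logistic(Xb, yb, markers=kept)
            if fit.separated:
                n_failed += 1
                fit = fit_logistic(Xb, yb, markers=kept, ridge=SEPARATION_RIDGE)
            if np.all(np.isfinite(fit.coefficients)):
                kept_rows.append(fit.coefficients)
            # non-finite ridge refits stay excluded; already counted above
        if n_failed > 0.2 * spec.n_boot:
            raise AnalysisError(
                f"{n_failed}/{spec.n_boot} bootstrap resamples hit separation; "
                "consider fewer markers or more cells per donor"
            )
        boot = np.asarray(kept_rows) * (-1.0 if flip else 1.0)

    if boot is not None and len(boot):
        ci_low, ci_high = _percentile_ci(boot, spec.ci_level)
        significant = (ci_low > 0) | (ci_high < 0)
        direction = np.where(
            ci_low > 0, DIRECTION_COMPARISON, np.where(ci_high < 0, DIRECTION_REFERENCE, DIRECTION_NONE)
        )
    else:
        ci_low = ci_high = np.full(len(kept), np.nan)
        significant = np.zeros(len(kept), dtype=bool)
        direction = np.array([DIRECTION_NONE] * len(kept))

    table = pd.DataFrame(
        {
            "estimate": estimates,
            "ci_low": ci_low,
            "ci_high": ci_high,
            "significant": significant,
            "direction": direction,
        },
        index=pd.Index(kept, name="marker"),
    )
    result = MarkerEffectTable(
        table=table,
        contrast=(ref, comp),
        n_boot=spec.n_boot,
        ci_level=spec.ci_level,
        seed=spec.seed,
        n_failed_resamples=n_failed,
        scaling=scaling,
        bootstrap_estimates=boot,
    )
    result.validate()
    return result


def effects_table_export(result: MarkerEffectTable) -> pd.DataFrame:
    """Plot-ready records: markers ascending by estimate, ties alphabetical."""
    df = result.table.reset_index()
    df = df.sort_values(["estimate", "marker"], kind="mergesort").reset_index(drop=True)
    return df[["marker", "estimate", "ci_low", "ci_high", "significant", "direction"]]


def effects_table_import(df: pd.DataFrame, contrast: tuple[str, str]) -> MarkerEffectTable:
    """Rebuild a MarkerEffectTable from exported records (round trip)."""
    table = df.set_index("marker")[["estimate", "ci_low", "ci_high", "significant", "direction"]]
    return MarkerEffectTable(
        table=table,
        contrast=contrast,
        n_boot=0,
        ci_level=0.95,
        seed=0,
        n_failed_resamples=0,
        scaling=ScalingRecord(markers=list(table.index), means=np.zeros(len(table)), sds=np.ones(len(table))),
    )
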