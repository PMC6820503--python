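"""Fisher linear discriminant analysis over per-donor marker profiles.

The observation unit is the donor-sample, not the cell: each row of the
input matrix is a donor's median arcsinh expression over their gated NK
population. Donors are the independent units in a cohort study, and the
published projections show one point per sample; running LDA on cells
would pseudo-replicate within-donor correlation. The discriminant axes
are the leading eigenvectors of (S_W + lambda*I)^-1 S_B, where S_W and
S_B are the within- and between-class scatter matrices; an optional
ridge (shrinkage) handles panels with nearly as many markers as donors.
Marker contributions are axis coefficients scaled by the pooled
within-class SD, so they rank markers by how much they drive the group
separation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .containers import CellTable, arcsinh_required
from .errors import ContractError, ModelError

logger = logging.getLogger(__name__)


@dataclass
class DonorSummaryMatrix:
    """Donor-sample x marker median-expression matrix with group labels."""

    values: pd.DataFrame   # index donor-sample id, columns markers
    groups: pd.Series      # index donor-sample id -> group label

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.groups.index):
            raise ContractError("summary matrix and group labels are misaligned")
        if self.values.isna().any().any():
            raise ContractError("summary matrix contains missing entries")
        counts = self.groups.value_counts()
        if len(counts) < 2 or (counts < 2).any():
            raise ContractError("need at least 2 groups with at least 2 donors each")


@dataclass
class LDAResult:
    axes: pd.DataFrame                 # markers x axes (LD1, LD2, ...), unit norm
    eigenvalues: np.ndarray            # nonnegative, descending
    projections: pd.DataFrame          # donor-sample x axes, plus 'group' column
    marker_contributions: pd.DataFrame  # markers x axes, SD-standardized loadings
    shrinkage: float

    def validate(self) -> None:
        norms = np.linalg.norm(self.axes.to_numpy(), axis=0)
        if not np.allclose(norms, 1.0):
            raise ModelError("discriminant axes are not unit-norm")
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ModelError("eigenvalues are not descending")


def donor_medians(
    tables_by_donor: Mapping[str, CellTable],
    markers: Sequence[str],
    groups_by_donor: Mapping[str, str],
) -> DonorSummaryMatrix:
    """Per-donor median arcsinh expression (midpoint convention for even n).

    Donors whose gated population is empty are excluded with a warning
    rather than producing missing entries.
    """
    rows, labels, index = [], [], []
    for donor in tables_by_donor:
        t = tables_by_donor[donor]
        arcsinh_required(t, "donor_medians")
        if t.n_cells == 0:
            logger.warning("donor %s has no gated cells; excluded from LDA input", donor)
            continue
        rows.append(np.median(t.marker_matrix(markers), axis=0))
        labels.append(groups_by_donor[donor])
        index.append(donor)
    values = pd.DataFrame(rows, index=pd.Index(index, name="donor"), columns=list(markers))
    return DonorSummaryMatrix(values=values, groups=pd.Series(labels, index=values.index, name="group"))


def scatter_matrices(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Within-class and between-class scatter of centered data."""
    grand = X.mean(axis=0)
    S_W = np.zeros((X.shape[1], X.shape[1]))
    S_B = np.zeros_like(S_W)
    for g in np.unique(y):
        Xg = X[y == g]
        mu = Xg.mean(axis=0)
        D = Xg - mu
        S_W += D.T @ D
        d = (mu - grand)[:, None]
        S_B += len(Xg) * (d @ d.T)
    return S_W, S_B


def default_shrinkage(S_W: np.ndarray, n_markers: int, n_rows: int) -> float:
    """Ridge used when the panel is as wide as the cohort (near-singular S_W)."""
    if n_markers >= n_rows:
        return 1e-3 * float(np.trace(S_W)) / n_markers
    return 0.0


def fit_lda(matrix: DonorSummaryMatrix, shrinkage: float | None = None) -> LDAResult:
    """Fit Fisher LDA: axes = leading eigenvectors of (S_W + lambda I)^-1 S_B.

    Axes are unit-norm with the sign fixed so each axis's largest-|loading|
    marker has a positive contribution; eigenvalues (Fisher ratios) come
    back descending. A singular S_W with shrinkage 0 raises a ModelError
    advising a positive shrinkage.
    """
    X = matrix.values.to_numpy(dtype=np.float64)
    y = matrix.groups.to_numpy()
    classes = np.unique(y)
    n, m = X.shape
    Xc = X - X.mean(axis=0)
    S_W, S_B = scatter_matrices(X, y)
    lam = default_shrinkage(S_W, m, n) if shrinkage is None else float(shrinkage)
    if lam < 0:
        raise ContractError("shrinkage must be nonnegative")

    A = S_W + lam * np.eye(m)
    try:
        evals, evecs = scipy.linalg.eigh(S_B, A)
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError):
        raise ModelError(
            "within-class scatter is singular; refit with shrinkage > 0"
        ) from None
    order = np.argsort(evals)[::-1]
    n_axes = min(len(classes) - 1, m)
    evals = np.maximum(evals[order][:n_axes], 0.0)
    W = evecs[:, order][:, :n_axes]
    W /= np.linalg.norm(W, axis=0, keepdims=True)

    # pooled within-class SD per marker for standardized contributions
    pooled_sd = np.sqrt(np.diag(S_W) / max(n - len(classes), 1))
    contrib = W * pooled_sd[:, None]
    # sign convention: largest-|contribution| entry of each axis positive
    for j in range(n_axes):
        i_max = int(np.argmax(np.abs(contrib[:, j])))
        if contrib[i_max, j] < 0:
            W[:, j] *= -1.0
            contrib[:, j] *= -1.0

    axis_names = [f"LD{j + 1}" for j in range(n_axes)]
    proj = pd.DataFrame(Xc @ W, index=matrix.values.index, columns=axis_names)
    proj.insert(0, "group", matrix.groups)
    result = LDAResult(
        axes=pd.DataFrame(W, index=matrix.values.columns, columns=axis_names),
        eigenvalues=evals,
        projections=proj,
        marker_contributions=pd.DataFrame(contrib, index=matrix.values.columns, columns=axis_names),
        shrinkage=lam,
    )
    result.validate()
    return result


def fisher_ratio(w: np.ndarray, S_W: np.ndarray, S_B: np.ndarray, lam: float = 0.0) -> float:
    """Between/within scatter ratio of a direction (the LDA objective)."""
    w = np.asarray(w, dtype=np.float64)
    denom = float(w @ (S_W + lam * np.eye(len(w))) @ w)
    return float(w @ S_B @ w) / denom


def rank_markers(result: LDAResult, axis: int = 0) -> list[str]:
    """Markers by descending |standardized loading|; ties alphabetical."""
    if not 0 <= axis < result.marker_contributions.shape[1]:
        raise ContractError(f"axis {axis} does not exist")
    col = result.marker_contributions.iloc[:, axis]
    order = sorted(col.index, key=lambda mk: (-abs(col[mk]), mk))
    return order
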