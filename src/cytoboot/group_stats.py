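"""Nonparametric comparisons of per-donor gated frequencies.

Unpaired contrasts (control vs pregnant) use the Mann-Whitney U test;
the pregnant vs postpartum contrast, where the same woman is sampled
twice, uses the Wilcoxon signed-rank test on paired differences. Both
tests are exact by full enumeration at the small cohort sizes of such
studies and fall back to the tie- and continuity-corrected normal
approximation beyond fixed crossover sizes. Two-sided p values double
the smaller tail, capped at 1. Significance stars follow the usual
convention: * p < 0.05, ** p < 0.01, *** p < 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .containers import StudyDesign
from .errors import ContractError

MANN_WHITNEY = "mann_whitney"
WILCOXON = "wilcoxon_signed_rank"

#: exact-enumeration crossover sizes (configurable per call)
MW_EXACT_MAX_N = 12         # always exact up to this pooled size
MW_EXACT_MAX_N_NOTIES = 20  # exact up to this pooled size when tie-free
WSR_EXACT_MAX_N = 15

_EPS = 1e-9


def stars(p: float) -> str:
    """Map a p value to the figure-caption star convention."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    p_two_sided: float
    method: str                    # "exact" or "normal_approx"
    n1: int | None = None
    n2: int | None = None
    n_pairs: int | None = None
    degenerate: bool = False
    underpowered: bool = False
    population: str | None = None
    combination: str | None = None
    contrast: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        self.stars = stars(self.p_two_sided)


def _two_sided(p_low: float, p_high: float) -> float:
    return min(1.0, 2.0 * min(p_low, p_high))


def mann_whitney_u(
    a: Sequence[float],
    b: Sequence[float],
    exact_max_n: int = MW_EXACT_MAX_N,
    exact_max_n_noties: int = MW_EXACT_MAX_N_NOTIES,
) -> ComparisonResult:
    """Mann-Whitney U with 0.5 credit per tie and exact enumeration.

    The exact branch enumerates all C(n1+n2, n1) group labelings of the
    pooled midranks whenever n1+n2 <= 12, or up to 20 when the data are
    tie-free; otherwise the normal approximation with tie-corrected
    variance and a 0.5 continuity correction is used.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ContractError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    n = n1 + n2
    ranks = rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())
    exact = n <= exact_max_n or (not has_ties and n <= exact_max_n_noties)

    if exact:
        idx_sums = np.fromiter(
            (ranks[list(c)].sum() for c in combinations(range(n), n1)),
            dtype=np.float64,
        )
        u_all = idx_sums - n1 * (n1 + 1) / 2.0
        p_low = float(np.mean(u_all <= u_obs + _EPS))
        p_high = float(np.mean(u_all >= u_obs - _EPS))
        return ComparisonResult(
            test=MANN_WHITNEY, statistic=u_obs, p_two_sided=_two_sided(p_low, p_high),
            method="exact", n1=n1, n2=n2,
        )

    mean = n1 * n2 / 2.0
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all observations identical
        return ComparisonResult(
            test=MANN_WHITNEY, statistic=u_obs, p_two_sided=1.0,
            method="normal_approx", n1=n1, n2=n2, degenerate=True,
        )
    diff = u_obs - mean
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var) if diff != 0 else 0.0
    p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return ComparisonResult(
        test=MANN_WHITNEY, statistic=u_obs, p_two_sided=p,
        method="normal_approx", n1=n1, n2=n2,
    )


def wilcoxon_signed_rank(
    differences: Sequence[float],
    exact_max_n: int = WSR_EXACT_MAX_N,
) -> ComparisonResult:
    """Wilcoxon signed-rank on paired differences (zeros discarded).

    W = sum of positive midranks of |differences|. Exact two-sided p by
    enumeration of all 2^n sign patterns for n <= 15, otherwise the
    tie- and continuity-corrected normal approximation. All differences
    zero yields the degenerate p = 1.
    """
    d = np.asarray(differences, dtype=np.float64)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return ComparisonResult(
            test=WILCOXON, statistic=0.0, p_two_sided=1.0, method="exact",
            n_pairs=0, degenerate=True,
        )
    ranks = rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())

    if n <= exact_max_n:
        signs = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(np.float64)
        w_all = signs @ ranks
        p_low = float(np.mean(w_all <= w_obs + _EPS))
        p_high = float(np.mean(w_all >= w_obs - _EPS))
        return ComparisonResult(
            test=WILCOXON, statistic=w_obs, p_two_sided=_two_sided(p_low, p_high),
            method="exact", n_pairs=n,
        )

    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - float((tie_counts**3 - tie_counts).sum()) / 48.0
    if var <= 0:
        return ComparisonResult(
            test=WILCOXON, statistic=w_obs, p_two_sided=1.0,
            method="normal_approx", n_pairs=n, degenerate=True,
        )
    diff = w_obs - mean
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var) if diff != 0 else 0.0
    p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return ComparisonResult(
        test=WILCOXON, statistic=w_obs, p_two_sided=p,
        method="normal_approx", n_pairs=n,
    )


@dataclass(frozen=True)
class Contrast:
    reference: str
    comparison: str
    paired: bool = False


def compare_frequency_table(
    freq: pd.DataFrame,
    design: StudyDesign,
    contrasts: Sequence[Contrast],
) -> list[ComparisonResult]:
    """One test per (population, marker-combination, contrast).

    Unpaired contrasts compare per-donor percentages with Mann-Whitney;
    paired contrasts compute comparison-minus-reference differences over
    complete pregnant<->postpartum pairs and use the signed-rank test.
    Undefined rows (empty denominators) are excluded. A contrast group
    with fewer than 2 donors is flagged underpowered but still computed
    when possible.
    """
    present = set(design.donors["group"])
    for c in contrasts:
        for g in (c.reference, c.comparison):
            if g not in present:
                raise ContractError(f"contrast references absent group {g!r}")

    usable = freq[~freq["undefined"]]
    group_of = design.donors["group"].to_dict()
    results: list[ComparisonResult] = []
    for (population, combo), sub in usable.groupby(["population", "combination"], sort=True):
        pct = sub.set_index("donor")["percentage"]
        for c in contrasts:
            if c.paired:
                pairs = design.complete_pairs(set(pct.index))
                # pairs are (pregnant, postpartum); orient to (reference, comparison)
                diffs = []
                for preg, post in pairs:
                    ref_d, comp_d = (preg, post) if group_of[preg] == c.reference else (post, preg)
                    diffs.append(float(pct[comp_d] - pct[ref_d]))
                if not diffs:
                    raise ContractError(
                        f"paired contrast {c.reference} vs {c.comparison}: no complete pairs"
                    )
                res = wilcoxon_signed_rank(diffs)
                res.underpowered = len(diffs) < 2
            else:
                a = pct[[d for d in pct.index if group_of[d] == c.reference]]
                b = pct[[d for d in pct.index if group_of[d] == c.comparison]]
                res = mann_whitney_u(a.to_numpy(), b.to_numpy())
                res.underpowered = min(len(a), len(b)) < 2
            res.population = population
            res.combination = combo
            res.contrast = (c.reference, c.comparison)
            results.append(res)
    return results


def comparisons_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Flat table of comparison results with the stars column."""
    return pd.DataFrame(
        [
            {
                "population": r.population,
                "combination": r.combination,
                "reference": r.contrast[0] if r.contrast else None,
                "comparison": r.contrast[1] if r.contrast else None,
                "test": r.test,
                "statistic": r.statistic,
                "p_two_sided": r.p_two_sided,
                "method": r.method,
                "n1": r.n1,
                "n2": r.n2,
                "n_pairs": r.n_pairs,
                "stars": r.stars,
                "underpowered": r.underpowered,
            }
            for r in results
        ]
    )
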