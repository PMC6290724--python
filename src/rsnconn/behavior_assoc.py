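"""Spearman association of altered connectivity with cognitive scores.

Connectivity measures flagged as altered by the group comparison are
correlated with cognitive screening scores (MMSE, MoCA) in the patient
group, after removing potential outliers.  The analysis is explicitly
exploratory: significance is declared at uncorrected p < 0.05 and no
multiplicity correction is applied.

Outlier removal defaults to the Tukey boxplot rule applied to each variable
of the pair: a point is dropped if its x or y value falls outside the closed
fences [Q1 - k*IQR, Q3 + k*IQR] with k = 1.5, quartiles by linear
interpolation between order statistics.  Removed indices are always
reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

MIN_POINTS = 5


def _tukey_keep(v: np.ndarray, k: float) -> np.ndarray:
    q1, q3 = np.percentile(v, [25, 75])  # linear interpolation
    iqr = q3 - q1
    return (v >= q1 - k * iqr) & (v <= q3 + k * iqr)


def remove_outliers(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "iqr",
    k: float = 1.5,
) -> np.ndarray:
    """Indices of points kept by the outlier rule (single pass).

    ``method="iqr"`` applies the per-variable Tukey fence; ``method="resid"``
    applies the same fence to the residuals of a robust (Theil-Sen) fit of y
    on x, a bivariate alternative.  Fewer than 5 surviving points is an
    error, since the downstream correlation would not be reportable.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be paired 1-D arrays")
    if not (np.isfinite(xv).all() and np.isfinite(yv).all()):
        raise ValueError("x and y must be finite")
    if xv.size < MIN_POINTS:
        raise ValueError(f"need at least {MIN_POINTS} points")
    if method == "iqr":
        keep = _tukey_keep(xv, k) & _tukey_keep(yv, k)
    elif method == "resid":
        slope, intercept, *_ = stats.theilslopes(yv, xv)
        keep = _tukey_keep(yv - (intercept + slope * xv), k)
    else:
        raise ValueError(f"unknown outlier method {method!r}")
    kept = np.flatnonzero(keep)
    if kept.size < MIN_POINTS:
        raise ValueError(
            f"only {kept.size} points survive outlier removal; "
            f"need at least {MIN_POINTS}"
        )
    return kept


def _spearman_exact_p(rho: float, n: int) -> float:
    """Exact two-tailed p by enumerating all n! rank permutations."""
    ranks = np.arange(1, n + 1, dtype=float)
    rx = (ranks - ranks.mean()) / ranks.std()
    count = 0
    total = 0
    for perm in permutations(range(n)):
        ry = rx[list(perm)]
        r = float(np.mean(rx * ry))
        total += 1
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    return count / total


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho (Pearson correlation of mid-ranks) with two-tailed p.

    p is exact by enumeration for n <= 7 without ties, otherwise the
    t-distribution approximation.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size or xv.size < MIN_POINTS:
        raise ValueError(f"need paired samples with n >= {MIN_POINTS}")
    if np.unique(xv).size == 1 or np.unique(yv).size == 1:
        raise ValueError("constant input; Spearman correlation undefined")
    no_ties = np.unique(xv).size == xv.size and np.unique(yv).size == yv.size
    res = stats.spearmanr(xv, yv)
    rho = float(res.statistic)
    if xv.size <= 7 and no_ties:
        p = _spearman_exact_p(rho, xv.size)
    else:
        p = float(res.pvalue)
    return rho, p


@dataclass(frozen=True)
class AssociationResult:
    measure: str
    score: str
    rho: float
    pvalue: float
    n_used: int
    removed_indices: tuple[int, ...]

    @property
    def significant_uncorrected(self) -> bool:
        return self.pvalue < 0.05


def associate_alterations(
    measures: pd.DataFrame,
    scores: pd.DataFrame,
    altered_ids: Sequence[str],
    outlier_method: str = "iqr",
    outlier_k: float = 1.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman association of each altered measure with each score column.

    ``measures`` and ``scores`` are indexed by subject (patients only, per
    the study design); subjects with a missing score are excluded pairwise.
    Returns one row per (measure, score) sorted by p, with the removed-point
    indices (positions within the pairwise-complete subject list) reported.
    """
    missing = [m for m in altered_ids if m not in measures.columns]
    if missing:
        raise KeyError(f"altered measures not in table: {missing}")
    rows = []
    for m in altered_ids:
        for score_name in scores.columns:
            s = scores[score_name]
            ok = s.notna() & measures[m].notna()
            x = measures.loc[ok, m].to_numpy(dtype=float)
            y = s[ok].to_numpy(dtype=float)
            kept = remove_outliers(x, y, method=outlier_method, k=outlier_k)
            removed = tuple(sorted(set(range(x.size)) - set(kept.tolist())))
            rho, p = spearman(x[kept], y[kept])
            rows.append(
                AssociationResult(
                    measure=m,
                    score=score_name,
                    rho=rho,
                    pvalue=p,
                    n_used=int(kept.size),
                    removed_indices=removed,
                )
            )
    df = pd.DataFrame(
        {
            "measure": [r.measure for r in rows],
            "score": [r.score for r in rows],
            "rho": [r.rho for r in rows],
            "p": [r.pvalue for r in rows],
            "n_used": [r.n_used for r in rows],
            "removed_indices": [
                ";".join(map(str, r.removed_indices)) for r in rows
            ],
        }
    )
    df["sig_unc"] = df["p"] < alpha
    return df.sort_values("p", kind="mergesort").reset_index(drop=True)
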