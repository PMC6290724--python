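"""Covariate-adjusted group comparison with permutation significance and FDR.

Each summary measure is compared between patients and controls with the t
statistic of the group coefficient in the linear model

    measure ~ intercept + group + age + sex,

equivalent to a pooled two-sample t on covariate-adjusted values.  Its
significance comes from a permutation test (default 5,000 permutations,
Freedman-Lane residual permutation when covariates are present), with
Benjamini-Hochberg FDR control at alpha = 0.05 across each measure family
and a lenient uncorrected p < 0.05 tier alongside.

The module also houses the demographics tests (two-sample t, Welch t,
Fisher's exact, Mann-Whitney U) used for cohort characteristics tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.05
DEFAULT_N_PERMUTATIONS = 5000
_TIE_EPS = 1e-12


def group_indicator(labels: Sequence) -> np.ndarray:
    """Map labels to a 0/1 patient indicator (patients coded 1).

    Accepts "patient"/"control" strings, booleans, or a 0/1 vector.  The
    sign convention everywhere is patients minus controls.
    """
    arr = np.asarray(labels)
    if arr.dtype.kind in "b":
        g = arr.astype(float)
    elif arr.dtype.kind in "iuf":
        vals = set(np.unique(arr).tolist())
        if not vals <= {0, 1}:
            raise ValueError("numeric labels must be 0/1 (1 = patient)")
        g = arr.astype(float)
    else:
        lut = {"patient": 1.0, "control": 0.0}
        try:
            g = np.array([lut[str(v)] for v in arr])
        except KeyError as e:
            raise ValueError(f"unknown group label {e.args[0]!r}") from None
    if g.sum() == 0 or g.sum() == g.size:
        raise ValueError("both groups must be nonempty")
    return g


def _design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    """Reduced-model design: intercept plus covariate columns."""
    if covariates is None:
        return np.ones((n, 1))
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    if cov.shape[0] != n:
        raise ValueError("covariates must have one row per subject")
    Z = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("covariate design matrix is rank deficient")
    return Z


class GroupModel:
    """Vectorised OLS for measure ~ intercept + covariates + group.

    Precomputes the projectors of the full design so that the group t
    statistic can be evaluated for many measures (and many permuted
    outcome matrices) with plain matrix products.
    """

    def __init__(self, g: np.ndarray, Z: np.ndarray):
        X = np.column_stack([Z, g])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("full design matrix (covariates + group) is rank deficient")
        self.n, self.p = X.shape
        if self.n <= self.p:
            raise ValueError("need more subjects than model parameters")
        self.X = X
        self.Z = Z
        self.pinvX = np.linalg.pinv(X)
        self.pinvZ = np.linalg.pinv(Z)
        self.c_var = np.linalg.inv(X.T @ X)[-1, -1]
        self.df = self.n - self.p
        # pieces for the closed-form permuted statistic: the group row of
        # pinv(X) (orthogonal to the nuisance columns) and an orthonormal
        # basis of the full design's column space
        self.w = self.pinvX[-1]
        self.U = np.linalg.qr(X)[0]

    def tstats(self, Y: np.ndarray) -> np.ndarray:
        """Group-coefficient t for outcome matrix Y of shape (n, M) or (B, n, M)."""
        beta = self.pinvX @ Y
        resid = Y - self.X @ beta
        rss = np.sum(resid * resid, axis=-2)
        sigma2 = rss / self.df
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta[..., -1, :] / np.sqrt(sigma2 * self.c_var)
        return t

    def reduced_fit(self, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Fitted values and residuals of the reduced (nuisance-only) model."""
        fitted = self.Z @ (self.pinvZ @ Y)
        return fitted, Y - fitted

    def freedman_lane_tstats(self, resid: np.ndarray, perm_idx: np.ndarray) -> np.ndarray:
        """Group t for every row-permutation of the reduced-model residuals.

        Equivalent to re-attaching permuted residuals to the nuisance fit
        and refitting the full model, but computed in closed form: the
        nuisance fit is in the design's column space, so it contributes
        nothing to the group coefficient (w is orthogonal to the nuisance
        columns) nor to the residual sum of squares, which reduces to
        ||R||^2 - ||U^T P R||^2.  Avoids materialising the (B, n, M)
        permuted outcome tensor.

        ``resid``: (n, M) reduced-model residuals; ``perm_idx``: (B, n)
        permutation index rows.  Returns (B, M).
        """
        B = perm_idx.shape[0]
        rows = np.arange(B)[:, None]
        rss0 = np.sum(resid * resid, axis=0)
        W = np.zeros((B, self.n))
        W[rows, perm_idx] = self.w
        beta = W @ resid
        Ut = np.zeros((B, self.n, self.p))
        Ut[rows, perm_idx] = self.U
        G = np.matmul(Ut.transpose(0, 2, 1), resid)
        hpr2 = np.sum(G * G, axis=1)
        sigma2 = np.maximum(rss0[None, :] - hpr2, 0.0) / self.df
        with np.errstate(divide="ignore", invalid="ignore"):
            return beta / np.sqrt(sigma2 * self.c_var)


def residualize(values: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """OLS residuals of a measure on intercept + covariates."""
    y = np.asarray(values, dtype=float)
    Z = _design(covariates, y.shape[0])
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    return y - Z @ beta


def adjusted_group_ttest(
    values: Sequence[float],
    labels: Sequence,
    covariates: np.ndarray | None = None,
) -> float:
    """t statistic (patients minus controls) adjusted for covariates."""
    y = np.asarray(values, dtype=float)[:, None]
    g = group_indicator(labels)
    model = GroupModel(g, _design(covariates, g.size))
    t = float(model.tstats(y)[0])
    if not np.isfinite(t) and np.ptp(y) == 0:
        raise ValueError("measure has no variance; t undefined")
    return t


def _pooled_t_by_assignment(Y: np.ndarray, assign: np.ndarray) -> np.ndarray:
    """Pooled two-sample t for every label assignment (rows of ``assign``).

    ``assign`` is (K, n) boolean, True marking patients.  Vectorised through
    group sums; infinities (zero pooled variance) propagate.
    """
    n = Y.shape[0]
    n1 = assign[0].sum()
    n2 = n - n1
    A = assign.astype(float)
    s1 = A @ Y
    q1 = A @ (Y * Y)
    tot = Y.sum(axis=0)
    totq = (Y * Y).sum(axis=0)
    s2 = tot - s1
    q2 = totq - q1
    m1, m2 = s1 / n1, s2 / n2
    ss = (q1 - s1 * s1 / n1) + (q2 - s2 * s2 / n2)
    sp2 = ss / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return t


def _tail_count(t_perm: np.ndarray, t_obs: np.ndarray, alternative: str) -> np.ndarray:
    if alternative == "two-sided":
        return (np.abs(t_perm) >= np.abs(t_obs) - _TIE_EPS).sum(axis=0)
    if alternative == "greater":
        return (t_perm >= t_obs - _TIE_EPS).sum(axis=0)
    if alternative == "less":
        return (t_perm <= t_obs + _TIE_EPS).sum(axis=0)
    raise ValueError(f"unknown alternative {alternative!r}")


def permutation_pvalues(
    measures: np.ndarray | pd.DataFrame,
    labels: Sequence,
    covariates: np.ndarray | None = None,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int | np.random.Generator | None = None,
    alternative: str = "two-sided",
    p_convention: str = "add_one",
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation p-value of the adjusted group t for each measure column.

    Labels are permuted identically across measures within a permutation.
    With covariates the Freedman-Lane scheme is used: reduced-model
    residuals are row-permuted, re-attached to the nuisance fit, and the
    full model is refit.  Without covariates, when the number of distinct
    label assignments C(n, n_patients) does not exceed ``n_permutations``,
    the null is enumerated exhaustively (deterministic, seed-independent)
    and the p-value is the exact tail proportion.

    Sampled p-values use the add-one convention (1+b)/(1+B) so that p is
    never 0; ``p_convention="proportion"`` gives the raw b/B proportion.

    Returns (observed t, p) arrays, one entry per measure.  A constant
    measure yields t = 0, p = 1 with a warning.
    """
    Y = np.asarray(measures, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    g = group_indicator(labels)
    n = g.size
    if Y.shape[0] != n:
        raise ValueError("measures must have one row per subject")
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    if p_convention not in ("add_one", "proportion"):
        raise ValueError(f"unknown p_convention {p_convention!r}")

    constant = Y.std(axis=0) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant measure(s); p set to 1",
            RuntimeWarning,
            stacklevel=2,
        )

    Z = _design(covariates, n)
    model = GroupModel(g, Z)
    t_obs = model.tstats(Y)

    n_pat = int(g.sum())
    n_assign = comb(n, n_pat)
    if covariates is None and n_assign <= n_permutations:
        assign = np.zeros((n_assign, n), dtype=bool)
        for k, idx in enumerate(combinations(range(n), n_pat)):
            assign[k, list(idx)] = True
        t_perm = _pooled_t_by_assignment(Y, assign)
        count = _tail_count(t_perm, t_obs, alternative)
        p = count / n_assign
    else:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        _, resid = model.reduced_fit(Y)
        perm_idx = np.argsort(rng.random((n_permutations, n)), axis=1)
        count = np.zeros(Y.shape[1])
        chunk = max(1, int(5e7 // max(1, n * Y.shape[1])))
        for start in range(0, n_permutations, chunk):
            idx = perm_idx[start : start + chunk]
            t_perm = model.freedman_lane_tstats(resid, idx)
            count += _tail_count(t_perm, t_obs, alternative)
        if p_convention == "add_one":
            p = (1.0 + count) / (n_permutations + 1.0)
        else:
            p = count / n_permutations
    t_obs = np.where(constant, 0.0, t_obs)
    p = np.where(constant, 1.0, np.clip(p, 0.0, 1.0))
    return t_obs, p


def fdr_bh(
    pvalues: Sequence[float], alpha: float = DEFAULT_ALPHA
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection flags, monotone adjusted p)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table by hypergeometric enumeration.

    With both margins fixed, the p-value sums the probabilities of every
    table whose point probability does not exceed the observed one (relative
    tolerance 1e-7 guards equal-probability tables against floating-point
    misclassification).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table entries must be nonnegative integers")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2, c1 = a + b, c + d, a + c
    N = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == N:
        raise ValueError("a margin of the 2x2 table is zero")
    dist = stats.hypergeom(N, r1, c1)
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(a)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(p, 1.0)


def welch_ttest(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, Welch-Satterthwaite df, two-tailed p)."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise ValueError("both samples have zero variance")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (of the first sample) with two-tailed p.

    Exact enumeration when the combined n is at most 12 and there are no
    ties; otherwise the normal approximation with tie correction.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("each sample must be nonempty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def measure_family(measure_name: str) -> str:
    """FDR family of a measure column: nodal (Gamma) vs network composites."""
    return "nodal" if measure_name.startswith("gamma_") else "network"


def compare_groups(
    measures: pd.DataFrame,
    labels: Sequence,
    covariates: np.ndarray | None = None,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int | np.random.Generator | None = None,
    alpha: float = DEFAULT_ALPHA,
    p_convention: str = "add_one",
) -> pd.DataFrame:
    """Permutation group comparison of every measure column, FDR per family.

    The nodal-integration measures form one multiplicity family and the
    intra/inter network composites another; BH-FDR at ``alpha`` is applied
    within each family, and the lenient uncorrected p < alpha tier is
    reported alongside.
    """
    t, p = permutation_pvalues(
        measures.to_numpy(dtype=float),
        labels,
        covariates=covariates,
        n_permutations=n_permutations,
        seed=seed,
        p_convention=p_convention,
    )
    out = pd.DataFrame(
        {
            "measure": measures.columns,
            "family": [measure_family(m) for m in measures.columns],
            "t": t,
            "p_perm": p,
        }
    )
    out["p_fdr"] = np.nan
    out["sig_fdr"] = False
    for fam, idx in out.groupby("family").groups.items():
        reject, p_adj = fdr_bh(out.loc[idx, "p_perm"].to_numpy(), alpha=alpha)
        out.loc[idx, "p_fdr"] = p_adj
        out.loc[idx, "sig_fdr"] = reject
    out["sig_unc"] = out["p_perm"] < alpha
    return out


@dataclass(frozen=True)
class DemographicTest:
    characteristic: str
    test: str
    statistic: float
    pvalue: float


def demographics_table(records: Sequence) -> pd.DataFrame:
    """Cohort characteristics table mirroring the standard clinical layout.

    Age uses the pooled two-sample t; sex and any binary factors use the
    two-sided Fisher exact test; education and mean FD use Mann-Whitney U;
    MMSE and MoCA use Welch's t (scores have clearly unequal spread between
    impaired and intact groups).
    """
    pat = [r for r in records if r.group == "patient"]
    con = [r for r in records if r.group == "control"]

    def vals(rs, attr):
        return np.array([getattr(r, attr) for r in rs if getattr(r, attr) is not None],
                        dtype=float)

    rows: list[DemographicTest] = []
    res = stats.ttest_ind(vals(pat, "age"), vals(con, "age"))
    rows.append(DemographicTest("age", "two-sample t", float(res.statistic), float(res.pvalue)))

    male_pat = sum(r.sex == "male" for r in pat)
    male_con = sum(r.sex == "male" for r in con)
    p = fisher_exact_2x2(
        [[male_pat, len(pat) - male_pat], [male_con, len(con) - male_con]]
    )
    rows.append(DemographicTest("sex", "Fisher exact", np.nan, p))

    for attr, test in (
        ("education", "Mann-Whitney U"),
        ("mmse", "Welch t"),
        ("moca", "Welch t"),
        ("mean_fd", "Mann-Whitney U"),
    ):
        x, y = vals(pat, attr), vals(con, attr)
        if x.size == 0 or y.size == 0:
            continue
        if test == "Welch t":
            t_stat, _, pv = welch_ttest(x, y)
            rows.append(DemographicTest(attr, test, t_stat, pv))
        else:
            u, pv = mann_whitney_u(x, y)
            rows.append(DemographicTest(attr, test, u, pv))
    return pd.DataFrame([r.__dict__ for r in rows])
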