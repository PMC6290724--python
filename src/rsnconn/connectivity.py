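"""Pearson ROI-pair correlation matrices and the exponential eta transform.

Static functional connectivity between ROI pairs is the sample Pearson
correlation r_ij of their time series.  Because negative correlations would
offset positive ones in nodal and network averages, r is converted to a
positive similarity

    eta_ij = exp(-xi * d_ij),    d_ij = (1 - r_ij) / (1 + r_ij),

where d is a hyperbolic distance (0 at r=1, diverging as r -> -1) and xi > 0
sets how fast similarity decays with distance; the default is xi = 2.  The
map r -> eta is strictly increasing, with eta(1) = 1 and eta in (0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import ROISet, SubjectRecord

DEFAULT_XI = 2.0
R_CLAMP_EPS = 1e-12


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric N x N Pearson matrix with unit diagonal."""

    values: np.ndarray
    roiset: ROISet | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if np.nanmax(np.abs(v)) > 1 + 1e-9:
            raise ValueError("correlation entries must lie in [-1, 1]")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class EtaMatrix:
    """Symmetric N x N eta-similarity matrix with its decay constant xi."""

    values: np.ndarray
    xi: float = DEFAULT_XI
    roiset: ROISet | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("eta matrix must be square")
        if self.xi <= 0:
            raise ValueError("xi must be > 0")
        if v.min() < 0 or v.max() > 1 + 1e-12:
            raise ValueError("eta entries must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def correlation_matrix(
    record: SubjectRecord, roiset: ROISet | None = None
) -> CorrelationMatrix:
    """Sample Pearson correlation between every ROI pair of one subject."""
    ts = record.timeseries
    sd = ts.std(axis=0)
    if (sd == 0).any():
        names = record.zero_variance_rois(roiset)
        raise ValueError(
            f"subject {record.id}: zero-variance ROI column(s) {names}; "
            "Pearson correlation undefined"
        )
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(values=(r + r.T) / 2.0, roiset=roiset)


def eta_from_r(
    r: np.ndarray | float,
    xi: float = DEFAULT_XI,
    clamp_eps: float = R_CLAMP_EPS,
    on_minus_one: str = "clamp",
) -> np.ndarray | float:
    """Elementwise eta transform of correlation values.

    r = -1 makes the hyperbolic distance diverge; by default r is clamped to
    -1 + ``clamp_eps`` (a warning is issued), which at xi=2 puts eta far
    below the double-precision floor, so it flushes to exactly 0.
    Set ``on_minus_one="error"`` to hard-error instead.
    """
    if xi <= 0:
        raise ValueError("xi must be > 0")
    arr = np.asarray(r, dtype=float)
    if np.any(arr < -1 - 1e-9) or np.any(arr > 1 + 1e-9):
        raise ValueError("correlations must lie in [-1, 1]")
    at_floor = arr <= -1 + clamp_eps
    if at_floor.any():
        if on_minus_one == "error":
            raise ValueError("correlation of -1 encountered; eta undefined")
        warnings.warn(
            "correlation(s) at -1 clamped to -1+eps; eta underflows to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    clamped = np.clip(arr, -1 + clamp_eps, 1.0)
    with np.errstate(over="ignore", under="ignore"):
        d = (1.0 - clamped) / (1.0 + clamped)
        eta = np.exp(-xi * d)
    return eta if isinstance(r, np.ndarray) else float(eta)


def r_from_eta(eta: np.ndarray | float, xi: float = DEFAULT_XI) -> np.ndarray | float:
    """Inverse transform: r = (1 - d) / (1 + d) with d = -ln(eta)/xi."""
    if xi <= 0:
        raise ValueError("xi must be > 0")
    arr = np.asarray(eta, dtype=float)
    if np.any(arr <= 0) or np.any(arr > 1 + 1e-12):
        raise ValueError("eta must lie in (0, 1]")
    d = -np.log(arr) / xi
    r = (1.0 - d) / (1.0 + d)
    return r if isinstance(eta, np.ndarray) else float(r)


def eta_transform(
    corr: CorrelationMatrix,
    xi: float = DEFAULT_XI,
    on_minus_one: str = "clamp",
) -> EtaMatrix:
    """Transform a correlation matrix entrywise; diagonal is exactly 1."""
    eta = eta_from_r(corr.values, xi=xi, on_minus_one=on_minus_one)
    np.fill_diagonal(eta, 1.0)
    return EtaMatrix(values=eta, xi=xi, roiset=corr.roiset)


def _labels(mat, n: int) -> list[str]:
    return mat.roiset.abbrevs if mat.roiset is not None else [str(i) for i in range(n)]


def write_matrix_tsv(mat: CorrelationMatrix | EtaMatrix, path: str | Path) -> None:
    """Square matrix as TSV with ROI abbreviations as header row/column."""
    labels = _labels(mat, mat.n)
    pd.DataFrame(mat.values, index=labels, columns=labels).to_csv(path, sep="\t")


def write_edge_list(
    corr: CorrelationMatrix, eta: EtaMatrix, path: str | Path
) -> pd.DataFrame:
    """Long-format unordered edge list ``roi_a roi_b r eta`` (upper triangle)."""
    labels = _labels(corr, corr.n)
    iu, ju = np.triu_indices(corr.n, k=1)
    df = pd.DataFrame(
        {
            "roi_a": [labels[i] for i in iu],
            "roi_b": [labels[j] for j in ju],
            "r": corr.values[iu, ju],
            "eta": eta.values[iu, ju],
        }
    )
    df.to_csv(path, index=False)
    return df
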