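"""Nodal integration and intra-/inter-network composite scores.

Three summaries are derived from each subject's eta matrix:

* nodal integration  Gamma_i = sum_{j != i} eta_ij  — a node's total
  transformed connectivity to every other node (range (0, N-1]);
* intra-network composite  c^X  — mean eta over the C(m, 2) unordered ROI
  pairs inside network X;
* inter-network composite  c^{X,Y}  — mean eta over the |X|*|Y| pairs with
  one ROI in X and the other in Y.

The diagonal (eta_ii = 1) is excluded everywhere, and each unordered pair is
counted once.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .connectivity import EtaMatrix
from .data_model import ROISet


@dataclass(frozen=True)
class SummaryMeasures:
    """Per-subject Gamma vector plus network composites."""

    subject_id: str
    gamma: np.ndarray
    intra: dict[str, float]
    inter: dict[tuple[str, str], float]


def nodal_integration(eta: EtaMatrix, include_diagonal: bool = False) -> np.ndarray:
    """Gamma_i = sum over j of eta_ij, by default excluding the j = i term."""
    v = eta.values
    gamma = v.sum(axis=1)
    if not include_diagonal:
        gamma = gamma - np.diag(v)
    return gamma


def intra_composite(eta: EtaMatrix, roiset: ROISet, network: str) -> float:
    """Mean eta over unordered within-network ROI pairs (diagonal excluded)."""
    idx = roiset.network_indices(network)
    if idx.size < 2:
        raise ValueError(f"network {network!r} has fewer than 2 ROIs")
    block = eta.values[np.ix_(idx, idx)]
    iu, ju = np.triu_indices(idx.size, k=1)
    return float(block[iu, ju].mean())


def inter_composite(eta: EtaMatrix, roiset: ROISet, net_x: str, net_y: str) -> float:
    """Mean eta over all cross pairs between two distinct networks."""
    if net_x == net_y:
        raise ValueError("inter-network composite requires two distinct networks")
    ix = roiset.network_indices(net_x)
    iy = roiset.network_indices(net_y)
    return float(eta.values[np.ix_(ix, iy)].mean())


def network_pairs(roiset: ROISet) -> list[tuple[str, str]]:
    """Unordered network pairs, each keyed alphabetically for stable output."""
    nets = sorted(roiset.networks)
    return [tuple(sorted(p)) for p in combinations(nets, 2)]


def summarize_subject(
    subject_id: str, eta: EtaMatrix, roiset: ROISet
) -> SummaryMeasures:
    return SummaryMeasures(
        subject_id=subject_id,
        gamma=nodal_integration(eta),
        intra={net: intra_composite(eta, roiset, net) for net in sorted(roiset.networks)},
        inter={
            pair: inter_composite(eta, roiset, *pair) for pair in network_pairs(roiset)
        },
    )


def measure_columns(roiset: ROISet) -> list[str]:
    """Column names of the cohort measure table: Gamma, intra, inter."""
    cols = [f"gamma_{a}" for a in roiset.abbrevs]
    cols += [f"intra_{net}" for net in sorted(roiset.networks)]
    cols += [f"inter_{a}_{b}" for a, b in network_pairs(roiset)]
    return cols


def summarize_cohort(
    etas: Sequence[EtaMatrix],
    roiset: ROISet,
    subject_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One row per subject, N + n_intra + n_inter measure columns.

    All matrices must share the atlas ordering; an empty input yields an
    empty table with the full column set.
    """
    cols = measure_columns(roiset)
    if subject_ids is None:
        subject_ids = [f"sub-{k:03d}" for k in range(len(etas))]
    if len(subject_ids) != len(etas):
        raise ValueError("subject_ids must align with etas")
    rows = []
    for sid, eta in zip(subject_ids, etas):
        if eta.n != roiset.n:
            raise ValueError(
                f"subject {sid}: eta matrix is {eta.n}x{eta.n}, atlas has {roiset.n} ROIs"
            )
        if eta.roiset is not None and eta.roiset.abbrevs != roiset.abbrevs:
            raise ValueError(f"subject {sid}: eta matrix ROI ordering differs from atlas")
        sm = summarize_subject(sid, eta, roiset)
        row = list(sm.gamma) + [sm.intra[n] for n in sorted(roiset.networks)]
        row += [sm.inter[p] for p in network_pairs(roiset)]
        rows.append(row)
    df = pd.DataFrame(rows, columns=cols, index=pd.Index(subject_ids, name="id"))
    return df


def write_measure_table(
    measures: pd.DataFrame, groups: Sequence[str], path: str | Path
) -> None:
    out = measures.copy()
    out.insert(0, "group", list(groups))
    out.to_csv(path)
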