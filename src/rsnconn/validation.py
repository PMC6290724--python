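"""Monte-Carlo calibration experiments over synthetic studies.

These routines measure the operating characteristics of the pipeline under
the synthetic-study generator: family-wise error of the network-based
statistic under the global null, recovery of a planted edge component, and
calibration of the exploratory brain-behavior association.  They are used
by the test suite and by the reproduction script; each takes an explicit
seed and fans it out to per-replicate child seeds.
"""

from __future__ import annotations

import numpy as np

from .behavior_assoc import associate_alterations
from .connectivity import correlation_matrix, eta_transform
from .nbs import nbs_test, stack_edge_matrix
from .synthetic_data import (
    PlantedEffect,
    ScoreModel,
    SyntheticStudyConfig,
    default_planted_component,
    simulate_study,
)

import pandas as pd


def _study_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def _study_etas(config: SyntheticStudyConfig):
    study = simulate_study(config)
    roiset = study.roiset
    etas = [
        eta_transform(correlation_matrix(r, roiset)) for r in study.records
    ]
    labels = [r.group for r in study.records]
    cov = np.column_stack(
        [
            [r.age for r in study.records],
            [1.0 if r.sex == "male" else 0.0 for r in study.records],
        ]
    )
    return study, etas, labels, cov


def _run_nbs(config: SyntheticStudyConfig, n_permutations: int, perm_seed: int):
    study, etas, labels, cov = _study_etas(config)
    Y, _ = stack_edge_matrix(etas)
    return study, nbs_test(
        Y,
        labels,
        covariates=cov,
        n_permutations=n_permutations,
        seed=perm_seed,
        n_nodes=study.roiset.n,
    )


def nbs_null_fwer(
    n_studies: int = 200,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of all-null studies reporting any significant NBS component.

    Each study is an independent draw from the default generator with no
    planted effects (15+15 subjects, T=220, 36 ROIs); a study counts as a
    false positive if any component in either direction attains corrected
    p < alpha.
    """
    hits = 0
    for s in _study_seeds(seed, n_studies):
        config = SyntheticStudyConfig(seed=s)
        _, result = _run_nbs(config, n_permutations, perm_seed=s + 1)
        if result.significant(alpha):
            hits += 1
    return hits / n_studies


def planted_recovery_rate(
    n_replicates: int = 50,
    delta: float = -0.25,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    min_edges_recovered: int = 4,
    seed: int = 0,
) -> float:
    """Fraction of replicates recovering the planted AN-SMN component.

    The default 6-edge component is shifted by ``delta`` in the patients; a
    replicate counts as a success if some significant component contains at
    least ``min_edges_recovered`` of the 6 planted edges.
    """
    planted = default_planted_component()
    hits = 0
    for s in _study_seeds(seed, n_replicates):
        config = SyntheticStudyConfig(
            seed=s,
            planted_effects=(PlantedEffect(edges=planted, delta=delta),),
        )
        study, result = _run_nbs(config, n_permutations, perm_seed=s + 1)
        roiset = study.roiset
        planted_idx = {
            tuple(sorted((roiset.index(a), roiset.index(b)))) for a, b in planted
        }
        for comp in result.significant(alpha):
            edges = {tuple(sorted(e)) for e in comp.edges}
            if len(edges & planted_idx) >= min_edges_recovered:
                hits += 1
                break
    return hits / n_replicates


def _patient_edge_measures(
    config: SyntheticStudyConfig, edge_ids: list[tuple[str, str]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Patient-only table of selected edge eta values plus scores."""
    study, etas, labels, _ = _study_etas(config)
    roiset = study.roiset
    pat = [k for k, lbl in enumerate(labels) if lbl == "patient"]
    cols = {}
    for a, b in edge_ids:
        i, j = roiset.index(a), roiset.index(b)
        cols[f"eta_{a}_{b}"] = [etas[k].values[i, j] for k in pat]
    ids = [study.records[k].id for k in pat]
    measures = pd.DataFrame(cols, index=pd.Index(ids, name="id"))
    scores = pd.DataFrame(
        {
            "mmse": [float(study.records[k].mmse) for k in pat],
            "moca": [float(study.records[k].moca) for k in pat],
        },
        index=pd.Index(ids, name="id"),
    )
    return measures, scores


# a spread of candidate "altered" edges used by the calibration experiments:
# the planted AN-SMN path plus inter-network edges untouched by any plant
CANDIDATE_EDGES: list[tuple[str, str]] = list(default_planted_component()) + [
    ("PCC", "lIPS"),
    ("vmPFC", "laPFC"),
    ("lCal", "rLO"),
    ("lFEF", "SMA"),
]


def behavior_null_flag_rate(
    n_replicates: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Flagged-pair rate of the association tier under the null score model.

    Scores are independent of connectivity (slope 0); the rate of
    (measure, score) pairs reaching uncorrected p < alpha should sit at the
    nominal level.
    """
    flagged = 0
    total = 0
    for s in _study_seeds(seed, n_replicates):
        config = SyntheticStudyConfig(seed=s)
        measures, scores = _patient_edge_measures(config, CANDIDATE_EDGES)
        table = associate_alterations(
            measures, scores, list(measures.columns), alpha=alpha
        )
        flagged += int(table["sig_unc"].sum())
        total += len(table)
    return flagged / total


def behavior_coupling_top_rank_rate(
    n_replicates: int = 100,
    slope: float = 150.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> float:
    """How often the truly coupled (edge, score) pair ranks first by p.

    MMSE is linearly coupled to the eta value of the first candidate edge
    with a steep slope and small noise; the intercept is set so scores stay
    inside the 0-30 range (the coupled edge sits at eta(0) ~= 0.135 under
    the default generator).  Success: the coupled pair is the top row of
    the p-sorted association table.
    """
    target = CANDIDATE_EDGES[0]
    hits = 0
    for s in _study_seeds(seed, n_replicates):
        config = SyntheticStudyConfig(
            seed=s,
            score_model=ScoreModel(
                target_edge=target,
                slope=slope,
                noise_sd=noise_sd,
                intercept_mmse=20.0 - slope * 0.135,
                intercept_moca=18.6,
            ),
        )
        measures, scores = _patient_edge_measures(config, CANDIDATE_EDGES)
        table = associate_alterations(measures, scores, list(measures.columns))
        top = table.iloc[0]
        if top["measure"] == f"eta_{target[0]}_{target[1]}" and top["score"] == "mmse":
            hits += 1
    return hits / n_replicates
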