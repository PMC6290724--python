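"""Synthetic two-group resting-state studies with known ground truth.

The generator emulates the study conditions of the analysis: two groups
(15 patients, 15 controls by default) of T = 220 timepoint, 36-ROI series
whose population correlation matrix has resting-state-network block
structure — a common within-network level, a lower between-network level,
and optional planted group differences on chosen edges or network pairs.
Temporal smoothness is injected with an AR(1) filter (which leaves the
cross-correlation structure unchanged, since every channel shares the same
filter).  Cognitive scores (MMSE, MoCA; 0-30) are drawn around
group-specific means and can be linearly coupled to the observed eta value
of a designated edge so that brain-behavior recovery is testable.

All randomness flows from a single study seed through per-subject spawned
child seeds, so any subject is reproducible in isolation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from .connectivity import correlation_matrix, eta_transform
from .data_model import ROISet, SubjectRecord, default_roi_set, write_manifest, write_roi_set

# Cohort characteristics used as sampling defaults: age range/mean/sd,
# male counts, mean-FD mean/sd, and MMSE/MoCA mean/sd per group.
PATIENT_AGE = (61.7, 6.3, 49.0, 72.0)
CONTROL_AGE = (61.4, 5.4, 54.0, 71.0)
PATIENT_MALE_FRACTION = 7 / 15
CONTROL_MALE_FRACTION = 8 / 15
PATIENT_FD = (0.0857, 0.0425)
CONTROL_FD = (0.0725, 0.0294)
SCORE_BASELINES = {
    ("patient", "mmse"): (23.7, 4.0),
    ("control", "mmse"): (28.1, 1.0),
    ("patient", "moca"): (18.6, 4.1),
    ("control", "moca"): (27.1, 1.0),
}


@dataclass(frozen=True)
class PlantedEffect:
    """Additive shift of target correlations on a set of edges for one group."""

    edges: tuple[tuple[str, str], ...]
    delta: float
    group: str = "patient"

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ValueError("PlantedEffect.group must be patient|control")


@dataclass(frozen=True)
class ScoreModel:
    """score = intercept + slope * eta(target_edge) + Gaussian noise.

    The slope applies to ``coupled_score`` only; the other score keeps its
    baseline model.  Intercepts default to the group-specific baselines;
    ``noise_sd`` of None uses the group-specific baseline SDs.  Scores are
    rounded and clipped to [0, 30].  slope = 0 (default) yields scores
    independent of connectivity.
    """

    target_edge: tuple[str, str] | None = None
    slope: float = 0.0
    noise_sd: float | None = None
    coupled_score: str = "mmse"
    intercept_mmse: float | None = None
    intercept_moca: float | None = None


@dataclass
class SyntheticStudyConfig:
    n_patients: int = 15
    n_controls: int = 15
    T: int = 220
    base_r_within: float = 0.3
    base_r_between: float = 0.0
    planted_effects: tuple[PlantedEffect, ...] = ()
    ar1: float = 0.3
    score_model: ScoreModel = field(default_factory=ScoreModel)
    seed: int = 0
    roiset: ROISet | None = None

    def __post_init__(self) -> None:
        if self.roiset is None:
            self.roiset = default_roi_set()
        if self.T < 3:
            raise ValueError("need T >= 3")
        if not (0 <= abs(self.ar1) < 1):
            raise ValueError("AR(1) coefficient must satisfy |ar1| < 1")


@dataclass
class SyntheticStudy:
    """In-memory study: subjects, atlas, and the ground-truth record."""

    records: list[SubjectRecord]
    roiset: ROISet
    ground_truth: dict
    config: SyntheticStudyConfig


def network_pair_edges(
    roiset: ROISet, net_x: str, net_y: str
) -> tuple[tuple[str, str], ...]:
    """All cross edges between two networks as abbreviation pairs."""
    ax = [roiset.rois[i].abbrev for i in roiset.network_indices(net_x)]
    ay = [roiset.rois[i].abbrev for i in roiset.network_indices(net_y)]
    return tuple((a, b) for a in ax for b in ay)


def default_planted_component() -> tuple[tuple[str, str], ...]:
    """A 6-edge connected AN-SMN path with max node degree 2.

    The low degree bounds the spectral norm of a delta-perturbation on these
    edges, so plants up to |delta| ~ 0.25 keep the default block target
    positive definite without repair.
    """
    return (
        ("lSTG", "lPreC"),
        ("lPreC", "rSTG"),
        ("rSTG", "rPreC"),
        ("rPreC", "lHes"),
        ("lHes", "lPoC"),
        ("lPoC", "rHes"),
    )


def build_target_covariance(
    config: SyntheticStudyConfig, group: str, max_repair_change: float = 0.05
) -> np.ndarray:
    """Group-specific target correlation matrix with RSN block structure.

    Within-network entries sit at ``base_r_within``, between-network entries
    at ``base_r_between``; planted effects for ``group`` are added on their
    edges.  If the result is not positive definite it is repaired by
    eigenvalue clipping (and re-scaled to unit diagonal); a repair that
    moves any entry by more than ``max_repair_change`` rejects the config.
    """
    roiset = config.roiset
    n = roiset.n
    target = np.full((n, n), config.base_r_between)
    for net in roiset.networks:
        idx = roiset.network_indices(net)
        target[np.ix_(idx, idx)] = config.base_r_within
    np.fill_diagonal(target, 1.0)
    for eff in config.planted_effects:
        if eff.group != group:
            continue
        for a, b in eff.edges:
            i, j = roiset.index(a), roiset.index(b)
            target[i, j] += eff.delta
            target[j, i] = target[i, j]
    off = target[~np.eye(n, dtype=bool)]
    if np.abs(off).max() >= 1.0:
        raise ValueError("planted effects push |r| to 1 or beyond")
    eigval = np.linalg.eigvalsh(target)
    if eigval.min() <= 1e-10:
        repaired = _nearest_pd_corr(target)
        change = np.abs(repaired - target).max()
        if change > max_repair_change:
            raise ValueError(
                f"positive-definiteness repair changed an entry by {change:.3f} "
                f"> {max_repair_change}; config too aggressive"
            )
        warnings.warn(
            f"target correlation repaired to positive definite "
            f"(max entry change {change:.2e})",
            RuntimeWarning,
            stacklevel=2,
        )
        target = repaired
    return target


def _nearest_pd_corr(mat: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue clipping followed by re-normalisation to unit diagonal."""
    w, v = np.linalg.eigh(mat)
    w = np.clip(w, floor, None)
    rep = (v * w) @ v.T
    d = np.sqrt(np.diag(rep))
    rep = rep / np.outer(d, d)
    np.fill_diagonal(rep, 1.0)
    return (rep + rep.T) / 2


def simulate_subject(
    target: np.ndarray,
    T: int,
    ar1: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Zero-mean stationary T x N series with the target cross-correlation.

    Innovations are multivariate normal with covariance ``target``; each
    channel is then passed through the same AR(1) filter, which preserves
    the cross-channel correlation matrix.  For ar1 = 0 the expected sample
    correlation equals the target exactly.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    target = np.asarray(target, dtype=float)
    try:
        L = np.linalg.cholesky(target)
    except np.linalg.LinAlgError:
        raise ValueError("target covariance is not positive definite") from None
    innov = rng.standard_normal((T, target.shape[0])) @ L.T
    if ar1 == 0.0:
        return innov
    return lfilter([1.0], [1.0, -ar1], innov, axis=0)


def simulate_scores(
    measure: np.ndarray,
    groups: Sequence[str],
    score_model: ScoreModel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """(MMSE, MoCA) integer score arrays for given per-subject measures."""
    mmse = np.empty(len(groups), dtype=int)
    moca = np.empty(len(groups), dtype=int)
    overrides = {
        "mmse": score_model.intercept_mmse,
        "moca": score_model.intercept_moca,
    }
    for k, grp in enumerate(groups):
        for name, out in (("mmse", mmse), ("moca", moca)):
            intercept, base_sd = SCORE_BASELINES[(grp, name)]
            if overrides[name] is not None:
                intercept = overrides[name]
            coupled = name == score_model.coupled_score
            sd = (
                score_model.noise_sd
                if (score_model.noise_sd is not None and coupled)
                else base_sd
            )
            slope = score_model.slope if coupled else 0.0
            raw = intercept + slope * measure[k] + rng.normal(0.0, sd)
            out[k] = int(np.clip(round(raw), 0, 30))
    return mmse, moca


def _sample_demographics(
    group: str, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, list[str], np.ndarray]:
    age_mean, age_sd, age_lo, age_hi = PATIENT_AGE if group == "patient" else CONTROL_AGE
    ages = np.clip(rng.normal(age_mean, age_sd, size=n), age_lo, age_hi).round(1)
    frac = PATIENT_MALE_FRACTION if group == "patient" else CONTROL_MALE_FRACTION
    n_male = int(round(frac * n))
    sexes = ["male"] * n_male + ["female"] * (n - n_male)
    rng.shuffle(sexes)
    fd_mean, fd_sd = PATIENT_FD if group == "patient" else CONTROL_FD
    fds = np.clip(rng.normal(fd_mean, fd_sd, size=n), 0.01, None).round(4)
    return ages, sexes, fds


def simulate_study(
    config: SyntheticStudyConfig, out_dir: str | Path | None = None
) -> SyntheticStudy:
    """Generate a complete study; optionally write the on-disk layout.

    Writes (when ``out_dir`` is given) the manifest CSV + per-subject TSVs
    consumed by the data model, the ROI table, and ``ground_truth.json``
    recording planted effects, group target matrices and score couplings.
    """
    roiset = config.roiset
    master = np.random.SeedSequence(config.seed)
    demo_rng = np.random.default_rng(master.spawn(1)[0])
    targets = {
        grp: build_target_covariance(config, grp) for grp in ("patient", "control")
    }

    groups = ["patient"] * config.n_patients + ["control"] * config.n_controls
    subject_seeds = master.spawn(len(groups) + 1)
    score_rng = np.random.default_rng(subject_seeds[-1])

    ages_p, sexes_p, fds_p = _sample_demographics("patient", config.n_patients, demo_rng)
    ages_c, sexes_c, fds_c = _sample_demographics("control", config.n_controls, demo_rng)
    ages = np.concatenate([ages_p, ages_c])
    sexes = sexes_p + sexes_c
    fds = np.concatenate([fds_p, fds_c])

    series = []
    for k, grp in enumerate(groups):
        rng_k = np.random.default_rng(subject_seeds[k])
        series.append(
            simulate_subject(targets[grp], config.T, ar1=config.ar1, rng=rng_k)
        )

    sm = config.score_model
    if sm.target_edge is not None:
        i, j = roiset.index(sm.target_edge[0]), roiset.index(sm.target_edge[1])
        measure = np.empty(len(groups))
        for k, ts in enumerate(series):
            rec = SubjectRecord(
                id=f"tmp{k}", group=groups[k], age=50.0, sex="male", timeseries=ts
            )
            eta = eta_transform(correlation_matrix(rec, roiset))
            measure[k] = eta.values[i, j]
    else:
        measure = np.zeros(len(groups))
    mmse, moca = simulate_scores(measure, groups, sm, score_rng)

    records = []
    for k, grp in enumerate(groups):
        records.append(
            SubjectRecord(
                id=f"sub-{k + 1:03d}",
                group=grp,
                age=float(ages[k]),
                sex=sexes[k],
                education=float(np.clip(round(demo_rng.normal(8.3, 2.5)), 6, 15)),
                mmse=int(mmse[k]),
                moca=int(moca[k]),
                mean_fd=float(fds[k]),
                timeseries=series[k],
            )
        )

    ground_truth = {
        "seed": config.seed,
        "n_patients": config.n_patients,
        "n_controls": config.n_controls,
        "T": config.T,
        "ar1": config.ar1,
        "base_r_within": config.base_r_within,
        "base_r_between": config.base_r_between,
        "planted_effects": [
            {"edges": [list(e) for e in eff.edges], "delta": eff.delta, "group": eff.group}
            for eff in config.planted_effects
        ],
        "score_model": {
            "target_edge": list(sm.target_edge) if sm.target_edge else None,
            "slope": sm.slope,
            "noise_sd": sm.noise_sd,
        },
        "target_patient": targets["patient"].round(6).tolist(),
        "target_control": targets["control"].round(6).tolist(),
    }

    study = SyntheticStudy(
        records=records, roiset=roiset, ground_truth=ground_truth, config=config
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_manifest(records, out_dir)
        write_roi_set(roiset, out_dir / "rois.tsv")
        with open(out_dir / "ground_truth.json", "w") as fh:
            json.dump(ground_truth, fh, indent=1)
    return study
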