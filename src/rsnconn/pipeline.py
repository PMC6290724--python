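"""End-to-end orchestration: QC -> connectivity -> summaries -> inference.

`run_study` executes every analysis stage on an on-disk study (manifest +
per-subject time-series TSVs + ROI table), writes each stage's CSV outputs
plus a JSON provenance record, and returns the collected results.  All
analysis parameters (xi, F threshold, permutation count, alpha, seed,
conventions) live in `RunConfig`; the defaults are the standard ones used
throughout the package (xi=2, F=5.3, B=5000, alpha=0.05).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior_assoc import associate_alterations
from .connectivity import (
    correlation_matrix,
    eta_transform,
    write_edge_list,
    write_matrix_tsv,
)
from .data_model import (
    ROISet,
    default_roi_set,
    load_manifest,
    load_roi_set,
    qc_exclude_high_motion,
)
from .group_inference import compare_groups, demographics_table
from .nbs import nbs_test, stack_edge_matrix
from .summary_levels import summarize_cohort, write_measure_table

log = logging.getLogger("rsnconn")


@dataclass
class RunConfig:
    manifest: str
    out_dir: str
    roi_table: str | None = None  # None -> packaged six-network atlas
    xi: float = 2.0
    f_threshold: float = 5.3
    n_permutations: int = 5000
    alpha: float = 0.05
    seed: int = 0
    p_convention: str = "add_one"  # add_one | proportion
    paper_strict: bool = False
    qc_per_group: bool = False
    outlier_rule: str = "iqr"
    outlier_k: float = 1.5
    skip_nbs: bool = False
    skip_association: bool = False

    def validate(self) -> None:
        if not Path(self.manifest).exists():
            raise FileNotFoundError(f"manifest not found: {self.manifest}")
        if self.roi_table is not None and not Path(self.roi_table).exists():
            raise FileNotFoundError(f"ROI table not found: {self.roi_table}")
        if self.xi <= 0:
            raise ValueError("xi must be > 0")
        if self.f_threshold <= 0:
            raise ValueError("f_threshold must be > 0")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def run_study(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a dict of stage results.

    Any stage error aborts with a stage-labelled message; outputs written up
    to that point are retained next to a FAILED marker file.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    t0 = time.time()
    try:
        roiset = (
            load_roi_set(config.roi_table) if config.roi_table else default_roi_set()
        )
        records = load_manifest(config.manifest, roiset)
        log.info("loaded %d subjects, %d ROIs", len(records), roiset.n)

        stage = "qc"
        fds = [r.mean_fd for r in records]
        if all(fd is not None for fd in fds):
            groups_arg = [r.group for r in records] if config.qc_per_group else None
            keep = qc_exclude_high_motion(fds, groups=groups_arg)
            dropped = [r.id for r, k in zip(records, keep) if not k]
            if dropped:
                log.info("QC dropped %d subject(s): %s", len(dropped), dropped)
            records = [r for r, k in zip(records, keep) if k]
        else:
            dropped = []
            log.info("mean FD not available for all subjects; QC skipped")

        stage = "connectivity"
        labels = [r.group for r in records]
        covariates = np.column_stack(
            [
                [r.age for r in records],
                [1.0 if r.sex == "male" else 0.0 for r in records],
            ]
        )
        corrs = [correlation_matrix(r, roiset) for r in records]
        etas = [eta_transform(c, xi=config.xi) for c in corrs]
        conn_dir = out / "connectivity"
        conn_dir.mkdir(exist_ok=True)
        for rec, c, e in zip(records, corrs, etas):
            write_matrix_tsv(e, conn_dir / f"{rec.id}_eta.tsv")
            write_edge_list(c, e, conn_dir / f"{rec.id}_edges.csv")

        stage = "summaries"
        measures = summarize_cohort(etas, roiset, [r.id for r in records])
        write_measure_table(measures, labels, out / "measures.csv")

        stage = "demographics"
        demo = demographics_table(records)
        demo.to_csv(out / "demographics.csv", index=False)

        stage = "group_inference"
        t_stage = time.time()
        comparison = compare_groups(
            measures,
            labels,
            covariates=covariates,
            n_permutations=config.n_permutations,
            seed=config.seed,
            alpha=config.alpha,
            p_convention=config.p_convention,
        )
        comparison.to_csv(out / "group_comparison.csv", index=False)
        log.info("group inference: %.1fs", time.time() - t_stage)

        nbs_result = None
        if not config.skip_nbs:
            stage = "nbs"
            t_stage = time.time()
            edge_vals, edge_idx = stack_edge_matrix(etas)
            nbs_result = nbs_test(
                edge_vals,
                labels,
                covariates=covariates,
                f_threshold=config.f_threshold,
                n_permutations=config.n_permutations,
                seed=config.seed + 1,
                n_nodes=roiset.n,
                paper_strict=config.paper_strict,
            )
            _write_nbs(nbs_result, roiset, out)
            log.info("NBS: %.1fs", time.time() - t_stage)

        association = None
        if not config.skip_association:
            stage = "behavior_association"
            altered = comparison.loc[comparison["sig_unc"], "measure"].tolist()
            patients = [r for r in records if r.group == "patient"]
            pat_ids = [r.id for r in patients]
            scores = pd.DataFrame(
                {
                    "mmse": [r.mmse for r in patients],
                    "moca": [r.moca for r in patients],
                },
                index=pd.Index(pat_ids, name="id"),
                dtype=float,
            )
            if altered and len(patients) >= 5:
                association = associate_alterations(
                    measures.loc[pat_ids],
                    scores,
                    altered,
                    outlier_method=config.outlier_rule,
                    outlier_k=config.outlier_k,
                    alpha=config.alpha,
                )
                association.to_csv(out / "behavior_association.csv", index=False)

        stage = "report"
        provenance = {
            "package_version": __version__,
            "config": asdict(config),
            "n_subjects_analyzed": len(records),
            "qc_dropped": dropped,
            "n_measures": int(measures.shape[1]),
            "n_edges": roiset.n * (roiset.n - 1) // 2,
            "input_hashes": {
                "manifest": _sha256(Path(config.manifest)),
                "roi_table": _sha256(Path(config.roi_table))
                if config.roi_table
                else "packaged",
            },
            "library_versions": _library_versions(),
            "elapsed_seconds": round(time.time() - t0, 2),
        }
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=1)
        _write_summary(out, comparison, nbs_result, association, roiset, provenance)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage label
        (out / "FAILED").write_text(f"stage={stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return {
        "records": records,
        "roiset": roiset,
        "measures": measures,
        "demographics": demo,
        "comparison": comparison,
        "nbs": nbs_result,
        "association": association,
        "provenance": provenance,
    }


def _library_versions() -> dict[str, str]:
    import networkx
    import scipy
    import statsmodels

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "networkx": networkx.__version__,
        "statsmodels": statsmodels.version.full_version
        if hasattr(statsmodels, "version")
        else statsmodels.__version__,
    }


def _write_nbs(result, roiset: ROISet, out: Path) -> None:
    ab = roiset.abbrevs
    comp_rows, edge_rows = [], []
    for cid, comp in enumerate(result.components):
        comp_rows.append(
            {
                "direction": comp.direction,
                "component_id": cid,
                "size": comp.size,
                "p_corrected": comp.p_corrected,
            }
        )
        for i, j in comp.edges:
            k = _edge_pos(result.edge_stats, i, j)
            edge_rows.append(
                {
                    "roi_a": ab[i],
                    "roi_b": ab[j],
                    "F": result.edge_stats.F[k],
                    "t": result.edge_stats.t[k],
                    "direction": comp.direction,
                    "component_id": cid,
                }
            )
    pd.DataFrame(
        comp_rows, columns=["direction", "component_id", "size", "p_corrected"]
    ).to_csv(out / "nbs_components.csv", index=False)
    pd.DataFrame(
        edge_rows, columns=["roi_a", "roi_b", "F", "t", "direction", "component_id"]
    ).to_csv(out / "nbs_edges.csv", index=False)
    null_rows = []
    for direction, null in result.null_max_size.items():
        sizes, counts = np.unique(null, return_counts=True)
        for s, c in zip(sizes, counts):
            null_rows.append({"direction": direction, "max_size": int(s), "count": int(c)})
    pd.DataFrame(null_rows, columns=["direction", "max_size", "count"]).to_csv(
        out / "nbs_null_distribution.csv", index=False
    )
    # simple weighted edge list consumable by standard network viewers
    with open(out / "nbs_edges.ncol", "w") as fh:
        for row in edge_rows:
            fh.write(f"{row['roi_a']} {row['roi_b']} {row['t']:.4f}\n")


def _edge_pos(stats, i: int, j: int) -> int:
    match = np.flatnonzero((stats.edges[:, 0] == i) & (stats.edges[:, 1] == j))
    return int(match[0])


def _write_summary(out, comparison, nbs_result, association, roiset, provenance):
    lines = [
        "rsnconn run summary",
        "===================",
        f"subjects analyzed: {provenance['n_subjects_analyzed']}"
        f" (QC dropped: {len(provenance['qc_dropped'])})",
        f"atlas: {roiset.n} ROIs in {len(roiset.networks)} networks",
        f"tested summary measures: {provenance['n_measures']}",
        f"tested edges: {provenance['n_edges']}",
        "",
        f"measures significant (FDR): "
        f"{int(comparison['sig_fdr'].sum())}",
        f"measures significant (uncorrected): "
        f"{int(comparison['sig_unc'].sum())}",
    ]
    if nbs_result is not None:
        sig = nbs_result.significant()
        lines.append(
            f"NBS components with corrected p < 0.05: {len(sig)}"
            + (
                " (sizes: " + ", ".join(str(c.size) for c in sig) + ")"
                if sig
                else ""
            )
        )
    if association is not None:
        lines.append(
            f"behavior associations at uncorrected p < 0.05: "
            f"{int(association['sig_unc'].sum())} of {len(association)}"
        )
    (Path(out) / "summary.txt").write_text("\n".join(lines) + "\n")
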