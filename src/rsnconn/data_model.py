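"""ROI atlas, subject records, and head-motion quality control.

The atlas is an ordered list of spherical regions of interest (ROIs) in MNI
millimetre space, each assigned to one of six resting-state networks (RSNs):
default mode (DMN), dorsal attention (DAN), frontal-parietal control (FPCN),
auditory (AN), sensorimotor (SMN) and visual (VN).  The atlas order is
authoritative: it defines the row/column order of every connectivity matrix
downstream.

Subjects carry a T x N ROI time-series matrix (assumed fully preprocessed),
demographics, optional cognitive screening scores (MMSE, MoCA; 0-30), and a
mean frame-wise displacement (FD) summarising head motion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

NETWORKS = ("DMN", "DAN", "FPCN", "AN", "SMN", "VN")

ROI_TABLE_COLUMNS = ["network", "name", "abbrev", "x", "y", "z", "radius"]

MANIFEST_COLUMNS = [
    "id", "group", "age", "sex", "education", "mmse", "moca", "mean_fd", "path",
]


@dataclass(frozen=True)
class ROIDefinition:
    """One spherical ROI: anatomical label, network, MNI centre and radius."""

    name: str
    abbrev: str
    network: str
    center: tuple[float, float, float]
    radius: float = 6.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"ROI {self.abbrev!r}: radius must be > 0")
        if self.network not in NETWORKS:
            raise ValueError(
                f"ROI {self.abbrev!r}: unknown network {self.network!r}; "
                f"expected one of {NETWORKS}"
            )
        if len(self.center) != 3:
            raise ValueError(f"ROI {self.abbrev!r}: center must be a 3-vector")


@dataclass(frozen=True)
class ROISet:
    """Ordered ROI atlas; ordering defines matrix row/column indices."""

    rois: tuple[ROIDefinition, ...]

    def __post_init__(self) -> None:
        abbrevs = [r.abbrev for r in self.rois]
        dupes = {a for a in abbrevs if abbrevs.count(a) > 1}
        if dupes:
            raise ValueError(f"duplicate ROI abbreviations: {sorted(dupes)}")
        if not self.rois:
            raise ValueError("ROISet must contain at least one ROI")

    @property
    def n(self) -> int:
        return len(self.rois)

    @property
    def abbrevs(self) -> list[str]:
        return [r.abbrev for r in self.rois]

    @property
    def networks(self) -> list[str]:
        """Distinct network labels in first-appearance order."""
        seen: list[str] = []
        for r in self.rois:
            if r.network not in seen:
                seen.append(r.network)
        return seen

    def network_indices(self, network: str) -> np.ndarray:
        idx = np.array(
            [i for i, r in enumerate(self.rois) if r.network == network],
            dtype=int,
        )
        if idx.size == 0:
            raise KeyError(f"no ROIs in network {network!r}")
        return idx

    def index(self, abbrev: str) -> int:
        for i, r in enumerate(self.rois):
            if r.abbrev == abbrev:
                return i
        raise KeyError(f"unknown ROI abbreviation {abbrev!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "network": [r.network for r in self.rois],
                "name": [r.name for r in self.rois],
                "abbrev": [r.abbrev for r in self.rois],
                "x": [r.center[0] for r in self.rois],
                "y": [r.center[1] for r in self.rois],
                "z": [r.center[2] for r in self.rois],
                "radius": [r.radius for r in self.rois],
            }
        )


def load_roi_set(path: str | Path) -> ROISet:
    """Read a tab-separated ROI table (columns: network name abbrev x y z radius).

    Row order is preserved and becomes the matrix index order.  Duplicate
    abbreviations and unknown network labels are hard errors.
    """
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"ROI table {path} contains no rows")
    missing = [c for c in ROI_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ROI table {path} missing columns: {missing}")
    rois = []
    for i, row in df.iterrows():
        if row["network"] not in NETWORKS:
            raise ValueError(
                f"ROI table row {i} ({row['abbrev']!r}): unknown network "
                f"{row['network']!r}"
            )
        rois.append(
            ROIDefinition(
                name=str(row["name"]),
                abbrev=str(row["abbrev"]),
                network=str(row["network"]),
                center=(float(row["x"]), float(row["y"]), float(row["z"])),
                radius=float(row["radius"]),
            )
        )
    return ROISet(rois=tuple(rois))


def write_roi_set(roiset: ROISet, path: str | Path) -> None:
    roiset.to_frame().to_csv(path, sep="\t", index=False)


def default_roi_set() -> ROISet:
    """The packaged 36-ROI / six-network atlas."""
    with resources.as_file(
        resources.files("rsnconn.data").joinpath("rois_six_rsn.tsv")
    ) as p:
        return load_roi_set(p)


@dataclass
class SubjectRecord:
    """One subject: time series, demographics, cognition, motion summary."""

    id: str
    group: str  # "patient" | "control"
    age: float
    sex: str  # "male" | "female"
    timeseries: np.ndarray  # T x N
    education: float | None = None
    mmse: int | None = None
    moca: int | None = None
    mean_fd: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ValueError(f"subject {self.id}: group must be patient|control")
        if self.sex not in ("male", "female"):
            raise ValueError(f"subject {self.id}: sex must be male|female")
        ts = np.asarray(self.timeseries, dtype=float)
        if ts.ndim != 2:
            raise ValueError(f"subject {self.id}: timeseries must be 2-D (T x N)")
        if ts.shape[0] < 3:
            raise ValueError(f"subject {self.id}: need T >= 3 timepoints")
        if not np.isfinite(ts).all():
            raise ValueError(f"subject {self.id}: non-finite timeseries entries")
        self.timeseries = ts

    @property
    def n_timepoints(self) -> int:
        return self.timeseries.shape[0]

    def zero_variance_rois(self, roiset: ROISet | None = None) -> list[str]:
        """Flag ROI columns with no temporal variance (correlation undefined)."""
        flat = self.timeseries.std(axis=0) == 0
        if roiset is not None:
            return [a for a, z in zip(roiset.abbrevs, flat) if z]
        return [str(j) for j in np.flatnonzero(flat)]


def extract_roi_timeseries(image, roiset: ROISet) -> np.ndarray:
    """Mean time series per spherical ROI from a 4-D volumetric image.

    ``image`` is a nibabel spatial image (or path to one) whose affine maps
    voxel indices to MNI mm.  A voxel belongs to an ROI iff the Euclidean
    distance from its centre to the ROI centre is <= the ROI radius.

    Returns a T x N matrix in atlas order.  An ROI whose sphere contains no
    voxel centres is a hard error naming the ROI.
    """
    import nibabel as nib
    from nibabel.affines import apply_affine

    if isinstance(image, (str, Path)):
        image = nib.load(str(image))
    data = np.asanyarray(image.dataobj, dtype=float)
    if data.ndim == 3:
        data = data[..., np.newaxis]
    if data.ndim != 4:
        raise ValueError("expected a 3-D or 4-D volumetric image")
    affine = image.affine
    units = image.header.get_xyzt_units()[0] if hasattr(image, "header") else "mm"
    if units not in ("mm", "unknown"):
        raise ValueError(
            f"image spatial units {units!r} are not millimetres; ROI centres are MNI mm"
        )
    nx, ny, nz, T = data.shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    world = apply_affine(affine, vox)  # (V, 3) voxel-centre mm coordinates
    flat = data.reshape(-1, T)

    out = np.empty((T, roiset.n), dtype=float)
    for j, roi in enumerate(roiset.rois):
        d2 = np.sum((world - np.asarray(roi.center)) ** 2, axis=1)
        mask = d2 <= roi.radius**2
        if not mask.any():
            raise ValueError(
                f"ROI {roi.abbrev!r} at {roi.center} contains no voxel centres "
                "within its radius (outside the field of view?)"
            )
        out[:, j] = flat[mask].mean(axis=0)
    return out


def compute_fd_power(
    motion_params: np.ndarray, head_radius: float = 50.0
) -> np.ndarray:
    """Frame-wise displacement (Power): sum of absolute backward differences
    of the six realignment parameters, rotations converted to arc length on a
    sphere of ``head_radius`` mm.  FD of the first frame is 0.
    """
    p = np.asarray(motion_params, dtype=float)
    if p.ndim != 2 or p.shape[1] != 6:
        raise ValueError("motion_params must be T x 6 (3 translations, 3 rotations)")
    if p.shape[0] < 2:
        raise ValueError("need at least 2 frames to compute FD")
    if head_radius <= 0:
        raise ValueError("head_radius must be > 0")
    d = np.abs(np.diff(p, axis=0))
    d[:, 3:] *= head_radius
    fd = np.concatenate([[0.0], d.sum(axis=1)])
    return fd


def qc_exclude_high_motion(
    mean_fds: Sequence[float],
    groups: Sequence[str] | None = None,
    n_sd: float = 2.0,
) -> np.ndarray:
    """Keep/drop flags for the mean-FD exclusion rule.

    A subject is dropped iff mean FD > mean + ``n_sd`` * SD (sample SD,
    ddof=1), computed in a single pass over all input subjects.  If
    ``groups`` is given, the threshold is computed within each group instead
    of over the pooled sample.

    Returns a boolean array, True = keep.
    """
    fd = np.asarray(mean_fds, dtype=float)
    if fd.ndim != 1 or fd.size < 3:
        raise ValueError("need at least 3 subjects for the motion exclusion rule")
    if not np.isfinite(fd).all():
        raise ValueError("non-finite mean FD values")
    keep = np.ones(fd.size, dtype=bool)
    if groups is None:
        thr = fd.mean() + n_sd * fd.std(ddof=1)
        keep = fd <= thr
    else:
        g = np.asarray(groups)
        if g.shape != fd.shape:
            raise ValueError("groups must align with mean_fds")
        for label in np.unique(g):
            sel = g == label
            if sel.sum() < 3:
                raise ValueError(
                    f"group {label!r} has fewer than 3 subjects for per-group QC"
                )
            thr = fd[sel].mean() + n_sd * fd[sel].std(ddof=1)
            keep[sel] = fd[sel] <= thr
    return keep


def _opt(v, cast=float):
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return cast(v)


def load_manifest(
    manifest_path: str | Path, roiset: ROISet | None = None
) -> list[SubjectRecord]:
    """Read the subject manifest CSV and every per-subject time-series TSV.

    Manifest columns: ``id group age sex education mmse moca mean_fd path``;
    ``path`` is resolved relative to the manifest's directory.  Each TSV is a
    headerless T x N matrix in atlas column order.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        ts_path = Path(row["path"])
        if not ts_path.is_absolute():
            ts_path = manifest_path.parent / ts_path
        ts = np.loadtxt(ts_path, delimiter="\t", ndmin=2)
        if roiset is not None and ts.shape[1] != roiset.n:
            raise ValueError(
                f"subject {row['id']}: {ts.shape[1]} columns, atlas has {roiset.n}"
            )
        records.append(
            SubjectRecord(
                id=str(row["id"]),
                group=str(row["group"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                education=_opt(row.get("education")),
                mmse=_opt(row.get("mmse"), lambda v: int(round(float(v)))),
                moca=_opt(row.get("moca"), lambda v: int(round(float(v)))),
                mean_fd=_opt(row.get("mean_fd")),
                timeseries=ts,
            )
        )
    return records


def write_manifest(records: Iterable[SubjectRecord], out_dir: str | Path) -> Path:
    """Write per-subject TSVs plus the manifest CSV under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        rel = f"timeseries/{rec.id}.tsv"
        ts_path = out_dir / rel
        ts_path.parent.mkdir(exist_ok=True)
        np.savetxt(ts_path, rec.timeseries, delimiter="\t", fmt="%.6f")
        rows.append(
            {
                "id": rec.id,
                "group": rec.group,
                "age": rec.age,
                "sex": rec.sex,
                "education": rec.education,
                "mmse": rec.mmse,
                "moca": rec.moca,
                "mean_fd": rec.mean_fd,
                "path": rel,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest
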