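"""Motion-artifact detection analyses: scrubbing and QC:RSFC.

Both analyses work on an edge table — every ROI pair's timeseries
correlation, plotted against the Euclidean distance between ROI centers —
and summarize the distance dependence with a smoothing curve and an OLS
slope.  Scrubbing asks how much each edge's correlation changes when
high-motion volumes are withheld (``Δr = r_all - r_kept``, positive when
censoring lowers the correlation); QC:RSFC asks how each edge covaries with
mean motion across subjects.  Distance-dependent motion artifact shows up
as short-distance edges being affected more than long-distance ones, i.e. a
negative slope.

The slope is this package's quantitative proxy for the visual "slope of the
points" in distance plots; it is ordinary least squares of the smoothed
values on distance, reported per mm so it is comparable across processing
states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .qc import CensorMask, FDTrace
from .types import Mask, Scan

__all__ = [
    "ROISet",
    "DistanceCurve",
    "ScrubbingResult",
    "QCRSFCResult",
    "make_roi_grid",
    "extract_roi_timeseries",
    "edge_correlations",
    "distance_smooth",
    "scrubbing_analysis",
    "qcrsfc_analysis",
]


@dataclass
class ROISet:
    """Spherical ROIs: world-mm centers (relative to volume center) and a
    common radius."""

    centers: np.ndarray
    radius_mm: float

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, float))
        if self.centers.shape[1] != 3:
            raise ValueError("ROI centers must be N x 3 (world mm)")
        if len(np.unique(self.centers, axis=0)) != len(self.centers):
            raise ValueError("ROI centers must be pairwise distinct")
        if not self.radius_mm > 0:
            raise ValueError("ROI radius must be positive")

    def __len__(self):
        return len(self.centers)

    def distances(self) -> np.ndarray:
        """Condensed upper-triangle inter-center distances (mm)."""
        diff = self.centers[:, None, :] - self.centers[None, :, :]
        d = np.sqrt((diff**2).sum(-1))
        iu = np.triu_indices(len(self.centers), k=1)
        return d[iu]


@dataclass
class DistanceCurve:
    """Smoothed value-vs-distance curve (moving mean over sorted points)."""

    distance: np.ndarray
    value: np.ndarray
    window: int

    def __post_init__(self):
        if len(self.distance) != len(self.value):
            raise ValueError("distance and value lengths differ")


@dataclass
class ScrubbingResult:
    delta_r: np.ndarray          # per-edge mean over subjects of r_all - r_kept
    distance: np.ndarray
    curve: DistanceCurve
    slope: float                 # OLS slope of smoothed Δr on distance, per mm
    slope_stderr: float
    n_subjects_used: int
    excluded_subjects: list = field(default_factory=list)


@dataclass
class QCRSFCResult:
    qc_rsfc: np.ndarray          # per-edge across-subject corr(edge r, mean FD)
    distance: np.ndarray
    curve: DistanceCurve
    slope: float
    slope_stderr: float
    n_subjects: int = 0


def make_roi_grid(
    mask: Mask, spacing_mm: float, radius_mm: float, voxel_mm=(3.0, 3.0, 3.0)
) -> ROISet:
    """Regular grid of spherical ROIs lying wholly inside the mask.

    A synthetic analog of a whole-brain ROI set: candidate centers sit on a
    regular world-space lattice; a candidate survives if every voxel whose
    center falls within ``radius_mm`` of it is inside the mask.
    Deterministic for a given mask.
    """
    if not spacing_mm > 2 * radius_mm:
        raise ValueError("spacing must exceed the ROI diameter")
    grid = np.asarray(mask.grid, bool)
    voxel = np.asarray(voxel_mm, float)
    shape = np.asarray(grid.shape)
    center = (shape - 1) / 2.0
    extent = (shape - 1) * voxel / 2.0

    axes = [
        np.arange(-ext, ext + 1e-9, spacing_mm) for ext in extent
    ]
    # center the lattice on the volume
    axes = [a - (a[0] + a[-1]) / 2.0 for a in axes]
    cand = np.array(np.meshgrid(*axes, indexing="ij")).reshape(3, -1).T

    ii, jj, kk = np.nonzero(np.ones(grid.shape, bool))
    vox_world = (np.stack([ii, jj, kk], axis=1) - center) * voxel
    keep = []
    for c in cand:
        d2 = ((vox_world - c) ** 2).sum(1)
        inside = d2 <= radius_mm**2
        if inside.any() and grid.reshape(-1)[inside].all():
            keep.append(c)
    if not keep:
        raise ValueError("no ROI of the requested radius fits inside the mask")
    return ROISet(np.array(keep), radius_mm)


def extract_roi_timeseries(scan: Scan, rois: ROISet) -> np.ndarray:
    """T x R matrix: per volume, mean intensity over each sphere's voxels."""
    scan = scan.retained()
    shape = np.asarray(scan.spatial_shape)
    center = (shape - 1) / 2.0
    voxel = np.asarray(scan.voxel_mm)
    flat = scan.data.reshape(-1, scan.n_volumes)
    ii, jj, kk = np.unravel_index(np.arange(flat.shape[0]), tuple(shape))
    vox_world = (np.stack([ii, jj, kk], axis=1) - center) * voxel
    out = np.empty((scan.n_volumes, len(rois)))
    for r, c in enumerate(rois.centers):
        inside = ((vox_world - c) ** 2).sum(1) <= rois.radius_mm**2
        if not inside.any():
            raise ValueError(f"ROI {r} at {c} contains no voxel centers")
        out[:, r] = flat[inside].mean(axis=0)
    return out


def edge_correlations(
    ts: np.ndarray, rois: ROISet, kept: CensorMask | np.ndarray | None = None
) -> pd.DataFrame:
    """Pearson correlation per ROI pair over kept volumes.

    Returns a DataFrame with columns ``i, j, distance, r, valid``; edges
    touching a constant timeseries get ``valid = False`` and NaN rather than
    a silent zero.
    """
    ts = np.asarray(ts, float)
    if kept is not None:
        keep = kept.kept if isinstance(kept, CensorMask) else np.asarray(kept, bool)
        ts = ts[keep]
    if ts.shape[0] < 3:
        raise ValueError("need at least 3 kept volumes to correlate")
    n = ts.shape[1]
    sd = ts.std(axis=0)
    good = sd > 0
    z = ts - ts.mean(axis=0)
    denom = np.where(good, sd, 1.0) * np.sqrt(ts.shape[0])
    zn = z / denom
    r = np.clip(zn.T @ zn, -1.0, 1.0)
    iu = np.triu_indices(n, k=1)
    valid = good[iu[0]] & good[iu[1]]
    rvals = np.where(valid, r[iu], np.nan)
    return pd.DataFrame(
        {
            "i": iu[0],
            "j": iu[1],
            "distance": rois.distances(),
            "r": rvals,
            "valid": valid,
        }
    )


def distance_smooth(distance, value, window: int = 2000) -> DistanceCurve:
    """Centered moving mean over points sorted by distance.

    The window shrinks symmetrically near the ends; a window at least as
    large as the number of points collapses every output to the global mean.
    """
    distance = np.asarray(distance, float)
    value = np.asarray(value, float)
    n = len(distance)
    if n < 2:
        raise ValueError("need at least 2 points to smooth")
    order = np.argsort(distance, kind="stable")
    d, v = distance[order], value[order]
    finite = np.isfinite(v)
    if window >= n:
        smoothed = np.full(n, v[finite].mean() if finite.any() else np.nan)
    else:
        half = window // 2
        csum = np.concatenate([[0.0], np.cumsum(np.where(finite, v, 0.0))])
        ccnt = np.concatenate([[0.0], np.cumsum(finite.astype(float))])
        idx = np.arange(n)
        h = np.minimum(np.minimum(idx, n - 1 - idx), half)
        lo, hi = idx - h, idx + h + 1
        cnt = ccnt[hi] - ccnt[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            smoothed = np.where(cnt > 0, (csum[hi] - csum[lo]) / cnt, np.nan)
    return DistanceCurve(d, smoothed, window=min(window, n))


def _slope(curve: DistanceCurve):
    ok = np.isfinite(curve.value)
    if ok.sum() < 2 or np.ptp(curve.distance[ok]) == 0:
        raise ValueError("cannot fit a distance slope: too few finite points")
    if np.ptp(curve.value[ok]) == 0:
        return 0.0, 0.0
    res = stats.linregress(curve.distance[ok], curve.value[ok])
    return float(res.slope), float(res.stderr)


def scrubbing_analysis(
    ts_list: Sequence[np.ndarray],
    fd_list: Sequence[FDTrace],
    rois: ROISet,
    threshold_mm: float,
    window: int = 2000,
    min_kept: int = 3,
) -> ScrubbingResult:
    """Scrubbing: per-edge mean over subjects of ``r_all - r_kept``.

    Each subject's edge correlations are computed over all volumes and again
    over only the volumes with FD at or below the threshold; subjects
    retaining fewer than ``min_kept`` volumes are excluded (and listed in
    the result).  A threshold above every FD value yields exactly zero
    everywhere.
    """
    if len(ts_list) != len(fd_list):
        raise ValueError("mismatched timeseries and FD lists")
    deltas, excluded = [], []
    for i, (ts, fd) in enumerate(zip(ts_list, fd_list)):
        kept = fd.fd <= threshold_mm
        if kept.sum() < min_kept:
            excluded.append(i)
            continue
        if kept.all():
            deltas.append(np.zeros(len(rois) * (len(rois) - 1) // 2))
            continue
        r_all = edge_correlations(ts, rois)["r"].to_numpy()
        r_kept = edge_correlations(ts, rois, kept=kept)["r"].to_numpy()
        deltas.append(r_all - r_kept)
    if not deltas:
        raise ValueError("no subject retains enough volumes at this threshold")
    delta_r = np.nanmean(np.stack(deltas), axis=0)
    distance = rois.distances()
    curve = distance_smooth(distance, delta_r, window)
    slope, stderr = _slope(curve)
    return ScrubbingResult(
        delta_r=delta_r,
        distance=distance,
        curve=curve,
        slope=slope,
        slope_stderr=stderr,
        n_subjects_used=len(deltas),
        excluded_subjects=excluded,
    )


def qcrsfc_analysis(
    edge_r: Sequence[np.ndarray] | np.ndarray,
    mean_fd: Sequence[float],
    rois: ROISet,
    window: int = 2000,
) -> QCRSFCResult:
    """QC:RSFC: per edge, across-subject correlation of edge r with mean FD.

    ``edge_r`` stacks each subject's per-edge correlations (S x E); the QC
    vector is each subject's mean FD.  A constant QC vector leaves the
    correlation undefined and raises.
    """
    edge_mat = np.asarray(edge_r, float)
    if edge_mat.ndim != 2:
        edge_mat = np.stack(list(edge_r))
    qc = np.asarray(mean_fd, float)
    if edge_mat.shape[0] != len(qc):
        raise ValueError("one mean FD per subject is required")
    if len(qc) < 4:
        raise ValueError("need at least 4 subjects for QC:RSFC")
    if np.ptp(qc) == 0:
        raise ValueError("constant QC vector: QC:RSFC correlation undefined")
    qz = (qc - qc.mean()) / qc.std()
    ez = edge_mat - edge_mat.mean(axis=0)
    sd = edge_mat.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (qz @ ez) / (len(qc) * sd)
    corr = np.where(sd > 0, np.clip(corr, -1, 1), np.nan)
    distance = rois.distances()
    curve = distance_smooth(distance, corr, window)
    slope, stderr = _slope(curve)
    return QCRSFCResult(
        qc_rsfc=corr,
        distance=distance,
        curve=curve,
        slope=slope,
        slope_stderr=stderr,
        n_subjects=len(qc),
    )
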