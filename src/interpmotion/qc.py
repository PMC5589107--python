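"""Quality-control traces and summaries: FD, DVARS, censoring, paired tests.

Framewise displacement (FD) at volume ``t`` is the sum of absolute backward
differences of the six position parameters, with rotations converted to arc
length at a 50 mm head radius; FD = 0 at the first volume by convention.
DVARS is the RMS over in-brain voxels of the temporal derivative of the
image, likewise 0 at the first volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import Mask, PositionTrace, Scan

__all__ = [
    "FDTrace",
    "DVARSTrace",
    "CensorMask",
    "compute_fd",
    "compute_dvars",
    "censor_mask",
    "matched_fraction_threshold",
    "fd_reduction_summary",
]


@dataclass
class FDTrace:
    fd: np.ndarray
    radius_mm: float = 50.0

    def __post_init__(self):
        self.fd = np.asarray(self.fd, float)
        if self.fd.ndim != 1:
            raise ValueError("FD trace must be 1-D")

    def __len__(self):
        return len(self.fd)

    @property
    def mean(self) -> float:
        return float(np.mean(self.fd))


@dataclass
class DVARSTrace:
    dvars: np.ndarray

    def __post_init__(self):
        self.dvars = np.asarray(self.dvars, float)

    def __len__(self):
        return len(self.dvars)


@dataclass
class CensorMask:
    """True where a volume is censored (its FD exceeded the threshold)."""

    censored: np.ndarray
    threshold_mm: float

    def __post_init__(self):
        self.censored = np.asarray(self.censored, bool)

    def __len__(self):
        return len(self.censored)

    @property
    def kept(self) -> np.ndarray:
        return ~self.censored

    @property
    def n_censored(self) -> int:
        return int(self.censored.sum())


def compute_fd(trace: PositionTrace, radius_mm: float = 50.0) -> FDTrace:
    """FD from a position trace: sum |Δtranslation| + radius·|Δrotation|."""
    params = trace.params
    if len(params) < 2:
        raise ValueError("need at least 2 volumes for FD")
    if not np.all(np.isfinite(params)):
        raise ValueError("non-finite position parameters")
    d = np.abs(np.diff(params, axis=0))
    d[:, 3:] *= radius_mm * np.pi / 180.0
    fd = np.concatenate([[0.0], d.sum(axis=1)])
    return FDTrace(fd, radius_mm=radius_mm)


def compute_dvars(scan: Scan, mask: Mask) -> DVARSTrace:
    """RMS over in-mask voxels of the volume-to-volume signal difference."""
    scan = scan.retained()
    if scan.n_volumes < 2:
        raise ValueError("need at least 2 volumes for DVARS")
    if mask.n_voxels == 0:
        raise ValueError("empty mask")
    vox = scan.data[mask.grid].astype(np.float64)  # (n_voxels, T)
    diff = np.diff(vox, axis=1)
    dvars = np.concatenate([[0.0], np.sqrt(np.mean(diff**2, axis=0))])
    return DVARSTrace(dvars)


def censor_mask(fd: FDTrace, threshold_mm: float) -> CensorMask:
    """Censor volumes with FD strictly above the threshold."""
    if not threshold_mm > 0:
        raise ValueError("threshold must be positive")
    return CensorMask(fd.fd > threshold_mm, threshold_mm)


def matched_fraction_threshold(
    reference_fd: FDTrace, target_fd: FDTrace, reference_threshold: float
) -> float:
    """Threshold for ``target_fd`` censoring as many volumes as the reference.

    Used to compare FD traces before/after temporal interpolation at matched
    censored fractions: the count of reference volumes above
    ``reference_threshold`` fixes the count for the target, and the returned
    threshold is the midpoint between the bracketing order statistics of the
    target trace.
    """
    ref = np.asarray(reference_fd.fd)
    tgt = np.asarray(target_fd.fd)
    if len(ref) != len(tgt):
        raise ValueError("traces must have the same length")
    if np.ptp(tgt) == 0:
        raise ValueError("degenerate trace: all target FD values equal")
    n_censor = int(np.sum(ref > reference_threshold))
    srt = np.sort(tgt)  # ascending
    if n_censor == 0:
        return float(srt[-1])
    if n_censor >= len(tgt):
        return float(srt[0]) / 2.0
    # censor the n_censor largest: cut between order stats n-c and n-c+1
    return float(0.5 * (srt[-n_censor - 1] + srt[-n_censor]))


def fd_reduction_summary(raw_fds, processed_fds):
    """Cohort summary of motion reduction by a processing step.

    Takes matched per-subject lists of raw and post-interpolation FD traces.
    Returns ``(table, ratios, tstat, pvalue)`` where the table holds each
    subject's mean FD before and after plus the percent reduction, ``ratios``
    pools the per-volume ratio processed/raw over all subjects (volumes with
    raw FD = 0, including the first, are excluded — the ratio is undefined
    there), and the test is a two-sided paired t-test on mean FD.
    """
    if len(raw_fds) != len(processed_fds):
        raise ValueError("mismatched cohort sizes")
    rows, ratios = [], []
    for i, (raw, proc) in enumerate(zip(raw_fds, processed_fds)):
        r, p = np.asarray(raw.fd), np.asarray(proc.fd)
        if len(r) != len(p):
            raise ValueError(f"subject {i}: trace lengths differ")
        ok = r > 0
        ratios.append(p[ok] / r[ok])
        rows.append(
            {
                "subject": i,
                "mean_fd_raw": r.mean(),
                "mean_fd_processed": p.mean(),
                "reduction_pct": 100.0 * (r.mean() - p.mean()) / r.mean()
                if r.mean() > 0 else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    ratios = np.concatenate(ratios) if ratios else np.array([])
    a = table["mean_fd_raw"].to_numpy()
    b = table["mean_fd_processed"].to_numpy()
    if len(table) < 3:
        raise ValueError("need at least 3 subjects for the paired test")
    if np.allclose(a, b):
        tstat, pvalue = 0.0, 1.0  # identical pairs: no evidence by convention
    else:
        tstat, pvalue = stats.ttest_rel(a, b)
    return table, ratios, float(tstat), float(pvalue)
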