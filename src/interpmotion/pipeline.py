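"""High-level drivers tying the modules into the study's workflows.

The canonical experiment: generate a cohort, run each subject's scan
through one or more processing states (raw / DS / TS / DS+TS / TS+DS),
realign each processed version, and collect position, FD and despike
traces.  Everything downstream — reduction summaries, scrubbing, QC:RSFC —
consumes the :class:`SubjectResult` records this module produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .analysis import ROISet, extract_roi_timeseries, make_roi_grid
from .mask import compute_brain_mask
from .qc import compute_fd
from .realign import RealignConfig, estimate_motion
from .synthetic import CohortSpec, GroundTruth, make_subject
from .temporal import DespikeParams, apply_order
from .types import Mask, Scan

__all__ = ["SubjectResult", "process_and_realign", "run_cohort"]


@dataclass
class SubjectResult:
    """Traces for one subject across the requested processing states."""

    subject: int
    record: dict
    ground_truth: GroundTruth
    mask: Mask
    traces: dict = field(default_factory=dict)        # order -> PositionTrace
    fd: dict = field(default_factory=dict)            # order -> FDTrace
    despike_traces: dict = field(default_factory=dict)  # order -> DespikeTrace
    roi_ts: dict = field(default_factory=dict)        # order -> T x R matrix


def process_and_realign(
    scan: Scan,
    orders: Sequence[str],
    realign_config: RealignConfig | None = None,
    despike_params: DespikeParams | None = None,
    stc_method: str = "cubic",
    mask: Mask | None = None,
    rois: ROISet | None = None,
    roi_only_orders: Sequence[str] = (),
):
    """Run one scan through processing states and realign each version.

    Returns ``(traces, fds, despike_traces, roi_ts)`` keyed by order.  ROI
    timeseries, when requested, are extracted from the *processed* (not
    realigned) data, matching how the scrubbing analyses consume them.
    States listed in ``roi_only_orders`` are processed and sampled at the
    ROIs but not realigned — useful when an analysis fixes the censor set
    from another state's FD trace.
    """
    realign_config = realign_config or RealignConfig()
    if mask is None:
        mask = compute_brain_mask(scan)
    traces, fds, ds_traces, roi_ts = {}, {}, {}, {}
    for order in list(orders) + list(roi_only_orders):
        processed, ds = apply_order(
            scan, order, despike_params=despike_params,
            stc_method=stc_method, mask=mask,
        )
        if order in orders:
            trace = estimate_motion(processed, realign_config, mask=mask)
            traces[order] = trace
            fds[order] = compute_fd(trace)
        if ds is not None:
            ds_traces[order] = ds
        if rois is not None:
            roi_ts[order] = extract_roi_timeseries(processed, rois)
    return traces, fds, ds_traces, roi_ts


def run_cohort(
    spec: CohortSpec,
    orders: Sequence[str] = ("raw", "DS+TS"),
    realign_config: RealignConfig | None = None,
    despike_params: DespikeParams | None = None,
    stc_method: str = "cubic",
    roi_spacing_mm: float | None = None,
    roi_radius_mm: float = 4.0,
    roi_only_orders: Sequence[str] = (),
):
    """Generate and fully process a cohort, one subject at a time.

    Subjects are generated, processed and discarded sequentially so memory
    stays flat.  When ``roi_spacing_mm`` is given, a shared ROI grid is
    built from the first subject's mask and per-order ROI timeseries are
    extracted for every subject.

    Returns ``(results, rois)`` — a list of :class:`SubjectResult` and the
    shared :class:`ROISet` (or None).
    """
    results = []
    rois = None
    for i in range(spec.n_subjects):
        scan, gt, record = make_subject(spec, i)
        mask = compute_brain_mask(scan)
        if roi_spacing_mm is not None and rois is None:
            rois = make_roi_grid(mask, roi_spacing_mm, roi_radius_mm, scan.voxel_mm)
        traces, fds, ds_traces, roi_ts = process_and_realign(
            scan, orders, realign_config, despike_params, stc_method,
            mask=mask, rois=rois, roi_only_orders=roi_only_orders,
        )
        results.append(
            SubjectResult(
                subject=i, record=record, ground_truth=gt, mask=mask,
                traces=traces, fd=fds, despike_traces=ds_traces, roi_ts=roi_ts,
            )
        )
    return results, rois
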