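"""Temporal interpolation operators: despiking and slice-time correction.

These are the two operators whose effect on subsequent motion estimation
the package exists to study.  Both replace signal at a timepoint partly
with signal from neighbouring timepoints, which is what dampens
motion-induced intensity changes.

Despiking follows the classic per-voxel recipe: fit a robust low-order
polynomial trend, express residuals in robust-sigma units
(``sigma = sqrt(pi/2) * median |residual|``), leave values within ``c1``
sigma alone, and squash larger excursions through a tanh saturation that
caps replacements at ``c2`` sigma from the trend.

Slice-time correction resamples each slice's voxel timeseries — nominally
sampled at the slice's acquisition offset within the TR — onto volume
onsets (the 'tzero 0' reference).  Linear, Catmull-Rom cubic, and Fourier
phase-shift kernels are offered; polynomial kernels use clamped one-sided
interpolation at the run boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mask import compute_brain_mask
from .types import Mask, Scan, slice_offsets

__all__ = [
    "DespikeParams",
    "DespikeTrace",
    "despike",
    "spike_replacement",
    "slice_time_correct",
    "apply_order",
    "ORDERS",
]

ORDERS = ("raw", "DS", "TS", "DS+TS", "TS+DS")


@dataclass
class DespikeParams:
    """Spike threshold ``c1`` and saturation bound ``c2`` in robust-sigma
    units, and the per-voxel polynomial trend order (default quadratic)."""

    c1: float = 2.5
    c2: float = 4.0
    trend_order: int = 2

    def __post_init__(self):
        if not 0 < self.c1 < self.c2:
            raise ValueError("need 0 < c1 < c2")
        if self.trend_order < 0:
            raise ValueError("trend order must be >= 0")


@dataclass
class DespikeTrace:
    """Percent of in-mask voxels whose signal was changed, per volume."""

    percent: np.ndarray

    def __post_init__(self):
        self.percent = np.asarray(self.percent, float)
        if np.any((self.percent < 0) | (self.percent > 100)):
            raise ValueError("despike trace values must lie in [0, 100]")

    def __len__(self):
        return len(self.percent)


def spike_replacement(r: np.ndarray, c1: float, c2: float) -> np.ndarray:
    """Squashed residual (sigma units) substituted for a spike of residual r.

    ``s(r) = sign(r) * (c1 + (c2-c1) * tanh((|r|-c1)/(c2-c1)))`` for
    ``|r| > c1``; values within c1 are returned unchanged.  Monotone in r
    and bounded by c2.
    """
    r = np.asarray(r, float)
    a = np.abs(r)
    squashed = c1 + (c2 - c1) * np.tanh((a - c1) / (c2 - c1))
    return np.where(a > c1, np.sign(r) * squashed, r)


def _robust_trend(y: np.ndarray, order: int, n_reweights: int = 2) -> np.ndarray:
    """Per-voxel polynomial trend by iteratively reweighted least squares.

    ``y`` is (T, N).  Huber weights (k = 1.345) with a robust scale from the
    median absolute residual downweight spikes so the trend is not dragged
    toward them.  Returns the fitted trend, same shape as ``y``.
    """
    T = y.shape[0]
    t = np.linspace(-1.0, 1.0, T)
    X = np.vander(t, order + 1, increasing=True)  # (T, p)
    # initial OLS
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)  # (p, N)
    for _ in range(n_reweights):
        resid = y - X @ beta
        scale = np.sqrt(np.pi / 2.0) * np.median(np.abs(resid), axis=0)  # (N,)
        scale = np.where(scale > 0, scale, 1.0)
        u = np.abs(resid) / (1.345 * scale)
        w = np.minimum(1.0, 1.0 / np.maximum(u, 1e-12))  # (T, N) Huber weights
        # weighted normal equations, batched over voxels
        G = np.einsum("tp,tq,tn->npq", X, X, w)
        b = np.einsum("tp,tn,tn->np", X, w, y)
        beta = np.linalg.solve(G, b[..., None])[..., 0].T  # (p, N)
    return X @ beta


def despike(
    scan: Scan,
    params: DespikeParams | None = None,
    mask: Mask | None = None,
):
    """Despike every voxel timeseries; returns ``(scan, DespikeTrace)``.

    The whole volume is despiked (as with AFNI's ``-nomask``); the mask only
    scopes the trace, which reports the percent of *in-mask* voxels changed
    at each volume.  Voxels whose robust residual scale is zero (constant in
    time) are left untouched.  A value counts as changed when it moved by
    more than 1e-9 native intensity units.
    """
    params = params or DespikeParams()
    scan = scan.retained()
    if scan.n_volumes < 10:
        raise ValueError("need at least 10 volumes to fit the despike trend")
    if mask is None:
        mask = compute_brain_mask(scan)

    shape = scan.spatial_shape
    T = scan.n_volumes
    y = scan.data.reshape(-1, T).T.astype(np.float64)  # (T, N)
    fit = _robust_trend(y, params.trend_order)
    resid = y - fit
    sigma = np.sqrt(np.pi / 2.0) * np.median(np.abs(resid), axis=0)  # (N,)
    ok = sigma > 0
    r = np.zeros_like(resid)
    r[:, ok] = resid[:, ok] / sigma[ok]
    out = y.copy()
    spikes = (np.abs(r) > params.c1) & ok[None, :]
    out[spikes] = (fit + spike_replacement(r, params.c1, params.c2) * sigma)[spikes]

    changed = np.abs(out - y) > 1e-9
    in_mask = mask.grid.reshape(-1)
    n_in = max(int(in_mask.sum()), 1)
    percent = 100.0 * changed[:, in_mask].sum(axis=1) / n_in

    new = scan.with_data(out.T.reshape(shape + (T,)).astype(scan.data.dtype))
    return new, DespikeTrace(percent)


def _stc_linear(s: np.ndarray, delta: float) -> np.ndarray:
    """Linear resampling of (T, ...) samples at fractional shift delta."""
    out = np.empty_like(s)
    out[1:] = delta * s[:-1] + (1.0 - delta) * s[1:]
    # one-sided extrapolation from the first interval
    out[0] = s[0] - delta * (s[1] - s[0])
    return out


def _stc_cubic(s: np.ndarray, delta: float) -> np.ndarray:
    """Catmull-Rom resampling at fractional shift delta, clamped at edges."""
    T = s.shape[0]
    u = 1.0 - delta  # position within [s[k-1], s[k]]
    w0 = -0.5 * u**3 + u**2 - 0.5 * u
    w1 = 1.5 * u**3 - 2.5 * u**2 + 1.0
    w2 = -1.5 * u**3 + 2.0 * u**2 + 0.5 * u
    w3 = 0.5 * u**3 - 0.5 * u**2
    idx = np.arange(T)
    i0 = np.clip(idx - 2, 0, T - 1)
    i1 = np.clip(idx - 1, 0, T - 1)
    i2 = idx
    i3 = np.clip(idx + 1, 0, T - 1)
    return w0 * s[i0] + w1 * s[i1] + w2 * s[i2] + w3 * s[i3]


def fourier_phase_shift(s: np.ndarray, delta: float) -> np.ndarray:
    """Shift (T, ...) samples by ``delta`` sample intervals via the FFT.

    Exact for band-limited periodic series; preserves signal energy
    (Parseval).  Callers should detrend first — a trend makes the series
    non-periodic and rings.
    """
    T = s.shape[0]
    freqs = np.fft.fftfreq(T).reshape((T,) + (1,) * (s.ndim - 1))
    phase = np.exp(-2j * np.pi * freqs * delta)
    return np.fft.ifft(np.fft.fft(s, axis=0) * phase, axis=0).real


def _stc_fourier(s: np.ndarray, delta: float) -> np.ndarray:
    """Exact phase shift after linear detrending; the trend is restored
    evaluated at the shifted sample positions.

    The trend is the line through the first and last samples: it removes
    drift (the main source of FFT edge ringing) while leaving a periodic
    series, for which the phase shift is exact, untouched.
    """
    T = s.shape[0]
    k = np.arange(T, dtype=float).reshape((T,) + (1,) * (s.ndim - 1))
    slope = (s[-1] - s[0]) / (T - 1)
    trend = s[0] + slope * k
    shifted = fourier_phase_shift(s - trend, delta)
    trend_shifted = s[0] + slope * (k - delta)
    return shifted + trend_shifted


_STC_KERNELS = {"linear": _stc_linear, "cubic": _stc_cubic, "fourier": _stc_fourier}


def slice_time_correct(scan: Scan, method: str = "cubic") -> Scan:
    """Resample every slice's timeseries to volume onset (tzero = 0).

    A slice acquired ``tau`` seconds into the TR has its series, nominally
    sampled at ``k*TR + tau``, re-evaluated at ``k*TR``.  The shift is a
    constant fraction ``tau/TR`` of a sample per slice, so each kernel acts
    uniformly along time.
    """
    if method not in _STC_KERNELS:
        raise ValueError(f"unknown slice-timing method {method!r}")
    scan = scan.retained()
    if scan.n_volumes < 4:
        raise ValueError("need at least 4 volumes for slice-time correction")
    kernel = _STC_KERNELS[method]
    taus = slice_offsets(scan.n_slices, scan.slice_order, scan.tr_s)
    out = np.empty_like(scan.data, dtype=np.float64)
    for z in range(scan.n_slices):
        delta = taus[z] / scan.tr_s
        s = scan.data[:, :, z, :].astype(np.float64)
        if delta == 0.0:
            out[:, :, z, :] = s
        else:
            # kernels operate on the leading axis
            out[:, :, z, :] = np.moveaxis(kernel(np.moveaxis(s, -1, 0), delta), 0, -1)
    return scan.with_data(out.astype(scan.data.dtype))


def apply_order(
    scan: Scan,
    order: str,
    despike_params: DespikeParams | None = None,
    stc_method: str = "cubic",
    mask: Mask | None = None,
):
    """Apply a processing state: raw, DS, TS, DS+TS, or TS+DS.

    Returns ``(scan, DespikeTrace | None)``; the trace is present whenever
    the state includes despiking.
    """
    if order not in ORDERS:
        raise ValueError(f"unknown processing order {order!r}; expected one of {ORDERS}")
    scan = scan.retained()
    trace = None
    if order == "raw":
        return scan, None
    if order == "DS":
        return despike(scan, despike_params, mask)
    if order == "TS":
        return slice_time_correct(scan, stc_method), None
    if order == "DS+TS":
        ds, trace = despike(scan, despike_params, mask)
        return slice_time_correct(ds, stc_method), trace
    # TS+DS
    ts = slice_time_correct(scan, stc_method)
    return despike(ts, despike_params, mask)
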