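"""Synthetic resting-state scans with known ground-truth motion.

The generator emulates the features of real resting-state data that the
pipeline's analyses depend on, at desk scale:

* a tissue phantom of concentric ellipsoids (CSF ring, gray shell, white
  core) whose intensity boundaries are what make motion visible to a
  realignment algorithm and to a despiker;
* temporally autocorrelated BOLD-like signal with shared latent components
  (so ROI-pair correlations have structure), slow drift and white noise;
* rigid-body motion injected *slice by slice*: every acquired slice is
  sampled from the continuously positioned phantom at that slice's
  acquisition time, so mid-volume events produce volumes whose slices come
  from different true positions (the missampling mechanism);
* an optional motion-coupled artifact with a distance-dependent spatial
  profile, which is what scrubbing and QC:RSFC analyses are built to detect.

Default geometry is 32 x 32 x 16 voxels at 3 mm, 150 volumes, TR 2.5 s,
interleaved 'alt+z2' acquisition — the scale of a typical 3T resting-state
protocol, shrunk to a grid a laptop can process in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .qc import compute_fd
from .types import (
    PositionTrace,
    RigidTransform,
    Scan,
    slice_acquisition_order,
)

__all__ = [
    "PhantomSpec",
    "MotionEvent",
    "GroundTruth",
    "CohortSpec",
    "make_phantom",
    "simulate_bold",
    "inject_motion",
    "inject_artifact",
    "make_cohort",
    "missampling_audit",
    "random_events",
    "random_midvolume_event",
    "NoiseSpec",
    "ARC_MM_PER_DEG",
]

# arc length at the standard 50 mm head radius per degree of rotation;
# used to express rotations in mm-equivalent amplitude
ARC_MM_PER_DEG = 50.0 * np.pi / 180.0


@dataclass
class PhantomSpec:
    """Concentric-ellipsoid tissue phantom.

    Relative radii partition the outer ellipsoid (a fraction
    ``outer_fraction`` of the half-extent per axis) into a CSF ring, a gray
    shell and a white core.  ``blur_vox`` Gaussian-blurs the intensity image
    so tissue boundaries have intermediate intensities, as in real EPI; the
    label map stays crisp.

    Like a head, the phantom is deliberately asymmetric: the in-plane
    semi-axes differ (``axis_scales``) and the white core sits off-center
    (``core_offset_vox``).  A rotationally symmetric phantom would leave
    rotations invisible to an intensity-based realignment algorithm.
    """

    shape: tuple = (32, 32, 16)
    voxel_mm: tuple = (3.0, 3.0, 3.0)
    intensities: tuple = (500.0, 1000.0, 700.0)  # CSF, gray, white
    outer_fraction: float = 0.86
    csf_fraction: float = 0.88   # inner edge of CSF ring, relative to outer
    white_fraction: float = 0.55  # outer edge of white core, relative to outer
    axis_scales: tuple = (0.80, 1.0, 0.95)
    core_offset_vox: tuple = (1.5, 1.0, 0.5)
    texture_amp: float = 80.0
    texture_sigma_vox: float = 1.2
    blur_vox: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if tuple(self.shape) < (16, 16, 8):
            raise ValueError(f"phantom shape must be >= (16, 16, 8), got {self.shape}")
        if len(set(self.intensities)) != 3:
            raise ValueError("tissue intensities must be distinct")
        if not 0 < self.outer_fraction <= 1.0:
            raise ValueError("outer_fraction must lie in (0, 1]")


def make_phantom(spec: PhantomSpec | None = None):
    """Build the phantom; returns ``(volume, labels)``.

    Labels: 0 background, 1 CSF, 2 gray, 3 white.  Deterministic for a given
    spec (the geometry has no random element; the seed is carried for API
    symmetry with the other generators).
    """
    spec = spec or PhantomSpec()
    shape = tuple(int(s) for s in spec.shape)
    half = (np.array(shape) - 1.0) / 2.0
    semi = spec.outer_fraction * half * np.asarray(spec.axis_scales)
    if np.any(semi < 2.0):
        raise ValueError("degenerate geometry: outer ellipsoid thinner than 2 voxels")
    if np.any(semi > half):
        raise ValueError("degenerate geometry: ellipsoid larger than the grid")
    grids = np.meshgrid(*[np.arange(n) - h for n, h in zip(shape, half)], indexing="ij")
    rho = np.sqrt(sum((g / s) ** 2 for g, s in zip(grids, semi)))
    core = np.sqrt(
        sum(((g - o) / s) ** 2
            for g, o, s in zip(grids, spec.core_offset_vox, semi))
    )

    csf_i, gray_i, white_i = spec.intensities
    labels = np.zeros(shape, dtype=np.int8)
    labels[rho <= 1.0] = 1
    labels[rho <= spec.csf_fraction] = 2
    labels[(core <= spec.white_fraction) & (labels == 2)] = 3
    volume = np.choose(labels, [0.0, csf_i, gray_i, white_i])
    if spec.texture_amp > 0:
        # static intra-tissue texture stands in for gyral/sulcal structure;
        # without it, rotations are nearly invisible to realignment
        rng = np.random.default_rng(spec.seed)
        tex = ndimage.gaussian_filter(
            rng.standard_normal(shape), spec.texture_sigma_vox
        )
        tissue = labels > 0
        rms = np.sqrt(np.mean(tex[tissue] ** 2)) if tissue.any() else 1.0
        volume += np.where(tissue, tex / rms * spec.texture_amp, 0.0)
    if spec.blur_vox > 0:
        volume = ndimage.gaussian_filter(volume, spec.blur_vox)
    return volume, labels


@dataclass
class NoiseSpec:
    """Per-voxel noise model: white sigma (intensity units), AR(1) phi, and
    the standard deviation of per-voxel linear drift amplitude."""

    sigma: float = 10.0
    ar1_phi: float = 0.3
    drift_amp: float = 5.0

    def __post_init__(self):
        if self.sigma < 0 or self.drift_amp < 0:
            raise ValueError("noise amplitudes must be nonnegative")
        if not -1 < self.ar1_phi < 1:
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")


def _latent_loadings(rng, shape, tissue_mask, n_components, amp, decay_frac=0.06):
    """Smooth random loading maps restricted to tissue, RMS-normalized."""
    loadings = np.zeros((n_components,) + shape)
    sigma = np.maximum(np.asarray(shape, float) * decay_frac, 1.0)
    for c in range(n_components):
        f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
        f *= tissue_mask
        rms = np.sqrt(np.mean(f[tissue_mask] ** 2)) if tissue_mask.any() else 1.0
        loadings[c] = f / rms * amp if rms > 0 else 0.0
    return loadings


def simulate_bold(
    phantom: np.ndarray,
    n_volumes: int,
    tr_s: float,
    noise: NoiseSpec | None = None,
    n_latents: int = 3,
    latent_amp: float = 3.0,
    loadings: np.ndarray | None = None,
    series: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    slice_order: str = "alt+z2",
    voxel_mm=(3.0, 3.0, 3.0),
    seed: int = 0,
) -> Scan:
    """Simulate a motion-free BOLD-like series on a phantom.

    Signal model per voxel: phantom intensity + latent components (shared,
    spatially smooth loadings within tissue) + linear drift + AR(1) noise.
    Explicit ``loadings`` ((C, x, y, z)) and latent ``series`` ((T, C))
    override the random ones — handy for controlled tests.
    """
    if n_volumes < 10:
        raise ValueError("need at least 10 volumes")
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    phantom = np.asarray(phantom, float)
    shape = phantom.shape
    tissue = labels > 0 if labels is not None else phantom > 0

    data = np.repeat(phantom[..., None], n_volumes, axis=3).astype(np.float64)

    if loadings is None and n_latents > 0 and latent_amp > 0:
        loadings = _latent_loadings(rng, shape, tissue, n_latents, latent_amp)
    if loadings is not None:
        loadings = np.asarray(loadings, float)
        ncomp = loadings.shape[0]
        if series is None:
            white = rng.standard_normal((n_volumes, ncomp))
            phi = 0.5
            series = signal.lfilter([np.sqrt(1 - phi**2)], [1, -phi], white, axis=0)
        series = np.asarray(series, float)
        data += np.tensordot(loadings, series, axes=([0], [1]))

    if noise.drift_amp > 0:
        slope = rng.normal(0.0, noise.drift_amp, size=shape)
        ramp = np.linspace(-0.5, 0.5, n_volumes)
        data += slope[..., None] * ramp

    if noise.sigma > 0:
        white = rng.normal(0.0, noise.sigma, size=shape + (n_volumes,))
        phi = noise.ar1_phi
        if phi != 0:
            white = signal.lfilter([np.sqrt(1 - phi**2)], [1, -phi], white, axis=3)
        data += white

    return Scan(
        data.astype(np.float32),
        tr_s=tr_s,
        slice_order=slice_order,
        voxel_mm=voxel_mm,
        n_ignore=0,
        meta={"seed": seed},
    )


@dataclass(frozen=True)
class MotionEvent:
    """A transient rigid-body displacement with a trapezoidal time course.

    The head leaves baseline at the event onset, ramps at constant velocity
    to ``displacement`` over ``ramp_volumes`` (0 = an instantaneous step),
    holds the displaced position for ``duration_volumes``, and ramps back
    over ``ramp_volumes`` again.  The onset is the start of volume
    ``onset_volume`` unless ``onset_slice_acq`` places it mid-volume,
    between acquisition ranks ``onset_slice_acq - 1`` and
    ``onset_slice_acq``; slices of that volume acquired earlier sample the
    pre-motion position.  Ramped events likewise produce volumes whose
    slices come from different true positions, because each slice samples
    the continuous position at its own acquisition time.
    """

    onset_volume: int
    displacement: RigidTransform
    duration_volumes: int = 1
    onset_slice_acq: Optional[int] = None
    ramp_volumes: float = 0.0

    def __post_init__(self):
        if self.duration_volumes < 1:
            raise ValueError("event duration must be >= 1 volume")
        if self.ramp_volumes < 0:
            raise ValueError("ramp must be >= 0 volumes")

    def onset_u(self, n_slices: int) -> float:
        """Event onset in continuous volume units."""
        frac = (self.onset_slice_acq or 0) / n_slices
        return self.onset_volume + frac

    def end_u(self, n_slices: int) -> float:
        """End of the ramp-down in continuous volume units."""
        return self.onset_u(n_slices) + 2 * self.ramp_volumes + self.duration_volumes

    def scale_at(self, u: float, n_slices: int) -> float:
        """Fraction of the full displacement at continuous time ``u``."""
        u0 = self.onset_u(n_slices)
        r = self.ramp_volumes
        hold_start, hold_end = u0 + r, u0 + r + self.duration_volumes
        if u < u0 or u >= hold_end + r:
            return 0.0
        if u < hold_start:
            return (u - u0) / r if r > 0 else 1.0
        if u < hold_end:
            return 1.0
        return 1.0 - (u - hold_end) / r if r > 0 else 0.0

    def volumes_spanned(self, n_slices: int) -> range:
        """Volumes with any displacement (ramps included)."""
        last = int(np.ceil(self.end_u(n_slices) - 1e-9)) - 1
        return range(self.onset_volume, last + 1)


@dataclass
class GroundTruth:
    """True injected positions and the material needed to audit them.

    ``volume_params``: T x 6 true per-volume position (the position holding
    for the majority of slice acquisitions in the volume).
    ``slice_params``: T x n_slices x 6 true position at each spatial slice's
    acquisition time.
    ``labels``: crisp tissue label map of the underlying phantom, for
    missampling audits.
    """

    volume_params: np.ndarray
    slice_params: np.ndarray
    labels: Optional[np.ndarray]
    events: tuple
    tr_s: float
    slice_order: str
    voxel_mm: tuple

    def true_fd(self, radius_mm: float = 50.0):
        return compute_fd(PositionTrace(self.volume_params), radius_mm=radius_mm)

    @property
    def mean_fd(self) -> float:
        return float(np.mean(self.true_fd().fd))


def _compose_params(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Parameters of the transform 'a after b' (matrix product a @ b)."""
    ta = RigidTransform.from_params(a)
    tb = RigidTransform.from_params(b)
    return ta.compose(tb).params


def inject_motion(
    scan: Scan,
    schedule: Sequence[MotionEvent],
    labels: np.ndarray | None = None,
    jitter: np.ndarray | None = None,
    kernel: str = "cubic",
):
    """Apply a schedule of rigid-body motions slice-by-slice.

    Every acquired slice is sampled from the continuously positioned volume
    at that slice's acquisition time (slice times follow the scan's
    interleave order and TR).  Between-volume step events therefore move
    whole volumes; mid-volume or ramped events produce volumes whose slices
    come from different true positions.  ``jitter`` (T x 6) adds a small
    baseline position per volume, composed with any event displacement.

    Events may not overlap (including their ramps) — overlapping schedules
    have ambiguous composition semantics and are rejected.

    Returns ``(moved scan, GroundTruth)``.
    """
    from .realign import _KERNEL_ORDER, resample  # local import avoids a cycle

    nvol = scan.n_volumes
    nz = scan.n_slices
    order = slice_acquisition_order(nz, scan.slice_order)
    rank = np.empty(nz, int)
    rank[order] = np.arange(nz)
    # continuous acquisition time of each spatial slice, in volume units
    u_frac = rank / nz

    covered = {}
    for ev in schedule:
        if ev.onset_volume < 0 or ev.volumes_spanned(nz)[-1] >= nvol:
            raise ValueError(f"event {ev} extends outside the scan (T={nvol})")
        if ev.onset_slice_acq is not None and not 0 < ev.onset_slice_acq < nz:
            raise ValueError(
                f"onset_slice_acq must lie in 1..{nz - 1}, got {ev.onset_slice_acq}"
            )
        for v in ev.volumes_spanned(nz):
            if v in covered:
                raise ValueError(f"overlapping motion events at volume {v}")
            covered[v] = ev

    if jitter is not None:
        jitter = np.asarray(jitter, float)
        if jitter.shape != (nvol, 6):
            raise ValueError(f"jitter must be T x 6, got {jitter.shape}")

    volume_params = np.zeros((nvol, 6))
    slice_params = np.zeros((nvol, nz, 6))
    out = np.array(scan.data, dtype=np.float64, copy=True)
    interp_order = _KERNEL_ORDER[kernel]
    mid_slice = order[nz // 2]
    xg, yg = np.meshgrid(
        np.arange(scan.spatial_shape[0], dtype=float),
        np.arange(scan.spatial_shape[1], dtype=float),
        indexing="ij",
    )

    for t in range(nvol):
        base = jitter[t] if jitter is not None else np.zeros(6)
        ev = covered.get(t)
        if ev is None:
            scales = np.zeros(nz)
        else:
            scales = np.array([ev.scale_at(t + f, nz) for f in u_frac])

        # group slices by displacement fraction: one resampling per group
        groups: dict = {}
        for z in range(nz):
            groups.setdefault(scales[z], []).append(z)
        for s, zs in groups.items():
            params = base if (ev is None or s == 0.0) else _compose_params(
                s * ev.displacement.params, base
            )
            slice_params[t, zs] = params
            if not np.any(params):
                continue
            transform = RigidTransform.from_params(params)
            if len(zs) == nz:
                moved = resample(
                    scan.data[..., t].astype(float), transform,
                    kernel=kernel, voxel_mm=scan.voxel_mm,
                )
                out[..., t] = moved
            else:
                vol = scan.data[..., t].astype(float)
                if interp_order > 1:
                    vol = ndimage.spline_filter(vol, order=interp_order)
                from .realign import _index_affine

                a, off = _index_affine(
                    transform, scan.spatial_shape, scan.voxel_mm, forward=False
                )
                for z in zs:
                    pts = np.stack(
                        [xg, yg, np.full_like(xg, float(z))], axis=0
                    ).reshape(3, -1)
                    coords = a @ pts + off[:, None]
                    out[:, :, z, t] = ndimage.map_coordinates(
                        vol, coords, order=interp_order, prefilter=False,
                        mode="constant", cval=0.0,
                    ).reshape(xg.shape)
        volume_params[t] = slice_params[t, mid_slice]

    gt = GroundTruth(
        volume_params=volume_params,
        slice_params=slice_params,
        labels=None if labels is None else np.asarray(labels),
        events=tuple(schedule),
        tr_s=scan.tr_s,
        slice_order=scan.slice_order,
        voxel_mm=scan.voxel_mm,
    )
    return scan.with_data(out.astype(np.float32)), gt


def missampling_audit(gt: GroundTruth, event: MotionEvent):
    """Audit which tissue a mid-volume event never scanned or scanned twice.

    The onset volume's slices split into the pre-motion and post-motion
    acquisition groups.  Each material tissue voxel is projected into
    acquired-slice coordinates under each group's true position; the voxel
    is sampled by a group exactly when its nearest slice belongs to that
    group (each slice images a one-slice-thick slab of the continuously
    positioned head).  Tissue whose projection lands, in both groups, on
    slices the *other* group acquired is never scanned; tissue landing on
    an acquired slice in both groups is scanned twice.

    Returns ``(missing, duplicated)``: sets of original z-slab indices
    containing never-scanned / twice-scanned tissue voxels.
    """
    if gt.labels is None:
        raise ValueError("ground truth carries no label map")
    if event.onset_slice_acq is None:
        raise ValueError("audit applies to mid-volume events only")

    labels = np.asarray(gt.labels)
    shape = labels.shape
    nz = shape[2]
    order = slice_acquisition_order(nz, gt.slice_order)
    rank = np.empty(nz, int)
    rank[order] = np.arange(nz)
    t = event.onset_volume
    pre = np.nonzero(rank < event.onset_slice_acq)[0]
    post = np.nonzero(rank >= event.onset_slice_acq)[0]
    in_group = {"pre": np.isin(np.arange(nz), pre),
                "post": np.isin(np.arange(nz), post)}

    vox = np.asarray(gt.voxel_mm, float)
    center = (np.asarray(shape, float) - 1.0) / 2.0
    ii, jj, kk = np.nonzero(labels > 0)
    world = (np.stack([ii, jj, kk], axis=1) - center) * vox

    counts = np.zeros(len(ii), int)
    for name, zs in (("pre", pre), ("post", post)):
        params = gt.slice_params[t, zs[0]]
        moved_z = RigidTransform.from_params(params).apply(world)[:, 2]
        zi = moved_z / vox[2] + center[2]
        nearest = np.round(zi).astype(int)
        ok = (nearest >= 0) & (nearest < nz)
        hit = np.zeros(len(ii), bool)
        hit[ok] = in_group[name][nearest[ok]]
        counts += hit

    missing = set(kk[counts == 0].tolist())
    duplicated = set(kk[counts >= 2].tolist())
    return missing, duplicated


def random_events(
    rng: np.random.Generator,
    n_volumes: int,
    n_events: int,
    amplitude_mm: float,
    duration_range=(1, 2),
    ramp_volumes: float = 0.0,
    mid_volume: bool = False,
    n_slices: int = 16,
    min_gap: int = 4,
) -> list:
    """Draw non-overlapping transient events of given mm-equivalent amplitude.

    The amplitude of an event is its FD-equivalent displacement: the sum of
    absolute translations plus rotations converted to arc length at 50 mm.
    The amplitude is split across the six parameters by a Dirichlet draw
    with random signs, so events mix translations and rotations.
    """
    events = []
    span_max = int(np.ceil(max(duration_range) + 2 * ramp_volumes)) + 1
    lo = 5  # keep events clear of the realignment reference volume
    hi = n_volumes - span_max - 2
    if hi <= lo:
        raise ValueError("scan too short for the requested events")
    # a short scan cannot hold an arbitrary number of separated events;
    # the 0.65 factor reflects the packing loss of random placement
    capacity = max(1, int(0.65 * (hi - lo) / (span_max + min_gap)))
    n_events = min(n_events, capacity)
    taken = np.zeros(n_volumes, bool)
    attempts = 0
    while len(events) < n_events and attempts < 200 * n_events:
        attempts += 1
        onset = int(rng.integers(lo, hi))
        dur = int(rng.integers(duration_range[0], duration_range[1] + 1))
        end = onset + dur + int(np.ceil(2 * ramp_volumes)) + 1
        if taken[max(onset - min_gap, 0):end + min_gap].any():
            continue
        amp = amplitude_mm * rng.uniform(0.8, 1.2)
        w = rng.dirichlet(np.ones(6)) * rng.choice([-1.0, 1.0], 6)
        params = amp * w
        params[3:] /= ARC_MM_PER_DEG  # rotations: mm arc -> degrees
        onset_slice = (
            int(rng.integers(n_slices // 4, 3 * n_slices // 4)) if mid_volume else None
        )
        events.append(
            MotionEvent(
                onset_volume=onset,
                displacement=RigidTransform.from_params(params),
                duration_volumes=dur,
                onset_slice_acq=onset_slice,
                ramp_volumes=ramp_volumes,
            )
        )
        taken[onset:end] = True
    if len(events) < n_events:
        raise RuntimeError("could not place the requested number of events")
    return sorted(events, key=lambda e: e.onset_volume)


def random_midvolume_event(
    rng: np.random.Generator,
    n_volumes: int,
    n_slices: int,
    voxel_z_mm: float,
) -> MotionEvent:
    """Draw a mid-volume event with a genuine through-plane component.

    Through-plane translation of 0.8-1.8 slice thicknesses plus a 2-3
    degree pitch, onset in the middle half of the acquisition order: a
    moderate, realistic head nod caught mid-acquisition.  Shifts near an
    even whole number of slices are excluded because, at the slice lattice's
    resolution, an interleave's second pass then exactly retiles the moved
    tissue and no missampling is detectable.
    """
    tz = float(rng.uniform(0.8, 1.8)) * voxel_z_mm * float(rng.choice([-1.0, 1.0]))
    pitch = float(rng.uniform(2.0, 3.0)) * float(rng.choice([-1.0, 1.0]))
    onset = int(rng.integers(5, max(6, n_volumes - 4)))
    k = int(rng.integers(n_slices // 4, 3 * n_slices // 4))
    return MotionEvent(
        onset_volume=onset,
        displacement=RigidTransform(tz=tz, pitch=pitch),
        duration_volumes=2,
        onset_slice_acq=k,
    )


@dataclass
class CohortSpec:
    """A multi-subject synthetic cohort.

    Subject ``i`` is generated with seed ``seed + i``, so a cohort with
    ``seed=1`` and 20 subjects uses seeds 1-20.  Each subject draws a motion
    amplitude scale uniformly from ``amplitude_range`` (mm-equivalent) and a
    Poisson number of transient events (mean ``event_rate``, floor 2).
    ``artifact_gain`` couples a distance-dependent signal artifact to true
    framewise displacement (intensity units per mm of FD); 0 disables it.
    """

    n_subjects: int = 20
    n_volumes: int = 150
    tr_s: float = 2.5
    slice_order: str = "alt+z2"
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    regime: str = "transient"  # or "still"
    event_rate: float = 6.0
    amplitude_range: tuple = (0.5, 2.0)
    duration_range: tuple = (1, 1)  # brief nods: displaced for ~3 volumes total
    ramp_volumes: float = 1.0  # heads move continuously, not in steps
    jitter_mm: float = 0.01
    artifact_gain: float = 0.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    n_latents: int = 3
    latent_amp: float = 3.0
    seed: int = 1

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("a cohort needs at least 2 subjects")
        if self.regime not in ("transient", "still"):
            raise ValueError(f"unknown regime {self.regime!r}")


def make_subject(spec: CohortSpec, index: int):
    """Generate one subject of a cohort; returns (scan, gt, record)."""
    seed = spec.seed + index
    rng = np.random.default_rng(seed)
    phantom, labels = make_phantom(spec.phantom)
    nz = spec.phantom.shape[2]

    scan = simulate_bold(
        phantom,
        spec.n_volumes,
        spec.tr_s,
        noise=spec.noise,
        n_latents=spec.n_latents,
        latent_amp=spec.latent_amp,
        labels=labels,
        slice_order=spec.slice_order,
        voxel_mm=spec.phantom.voxel_mm,
        seed=seed,
    )

    if spec.regime == "still":
        amplitude, events, jitter = 0.0, [], None
    else:
        amplitude = float(rng.uniform(*spec.amplitude_range))
        n_events = max(2, int(rng.poisson(spec.event_rate)))
        events = random_events(
            rng, spec.n_volumes, n_events, amplitude,
            duration_range=spec.duration_range,
            ramp_volumes=spec.ramp_volumes, n_slices=nz,
        )
        jitter = np.zeros((spec.n_volumes, 6))
        if spec.jitter_mm > 0:
            jitter[:, :3] = rng.normal(0, spec.jitter_mm, (spec.n_volumes, 3))
            jitter[:, 3:] = rng.normal(
                0, spec.jitter_mm / ARC_MM_PER_DEG, (spec.n_volumes, 3)
            )
    moved, gt = inject_motion(scan, events, labels=labels, jitter=jitter)
    if spec.artifact_gain > 0:
        moved = inject_artifact(
            moved, gt, spec.artifact_gain, tissue_mask=labels > 0, seed=seed
        )
    record = {
        "subject": index,
        "seed": seed,
        "amplitude_mm": amplitude,
        "n_events": len(events),
        "true_mean_fd": gt.mean_fd,
        "artifact_gain": spec.artifact_gain,
    }
    return moved, gt, record


def make_cohort(spec: CohortSpec):
    """Generate a full cohort; returns (subjects, manifest).

    ``subjects`` is a list of ``(Scan, GroundTruth)``; the manifest is a
    DataFrame recording each subject's seed, assigned amplitude, event count
    and true mean FD.
    """
    subjects, records = [], []
    for i in range(spec.n_subjects):
        scan, gt, rec = make_subject(spec, i)
        subjects.append((scan, gt))
        records.append(rec)
    return subjects, pd.DataFrame.from_records(records)


def artifact_profile(shape, tissue_mask, seed=0, global_weight=0.5):
    """Spatial artifact profile: global offset plus a smooth random field.

    The global component (uniform over tissue) inflates correlations at all
    distances; the random field, smoothed to a correlation length of about a
    quarter of the grid extent, adds the short-distance excess.  RMS over
    tissue is normalized to 1 for each component before mixing.
    """
    rng = np.random.default_rng(seed)
    sigma = np.maximum(np.asarray(shape, float) / 8.0, 1.0)
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    f *= tissue_mask
    rms = np.sqrt(np.mean(f[tissue_mask] ** 2))
    f = f / rms if rms > 0 else f
    return (global_weight * tissue_mask.astype(float) + (1 - global_weight) * f)


def inject_artifact(
    scan: Scan,
    gt: GroundTruth,
    gain: float,
    tissue_mask: np.ndarray | None = None,
    profile: np.ndarray | None = None,
    seed: int = 0,
) -> Scan:
    """Add motion-coupled signal artifact: ``gain * trueFD(t) * profile(x)``.

    ``gain`` is intensity units per mm of true framewise displacement; 0
    returns the scan unchanged.  A motionless subject is unchanged by
    construction.
    """
    if gain < 0:
        raise ValueError("artifact gain must be >= 0")
    if gain == 0:
        return scan
    if tissue_mask is None:
        tissue_mask = (
            gt.labels > 0 if gt.labels is not None
            else scan.data.mean(axis=3) > 0
        )
    if profile is None:
        profile = artifact_profile(scan.spatial_shape, tissue_mask, seed=seed)
    fd = gt.true_fd().fd
    data = scan.data.astype(np.float64) + gain * profile[..., None] * fd[None, None, None, :]
    return scan.with_data(data.astype(np.float32))
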