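"""Core data types: scans, rigid-body transforms, position traces, masks.

Conventions
-----------
World coordinates are RAS millimetres with the origin at the spatial center
of the volume: +X right, +Y anterior, +Z superior.  Rotations are degrees,
right-handed: pitch about +X (nose up positive), roll about +Y (tilt right
positive), yaw about +Z (nose left positive).  A :class:`RigidTransform`
maps a material point ``p`` (world mm) to ``R @ p + t`` where the rotation
matrix composes as ``R = Rz(yaw) @ Rx(pitch) @ Ry(roll)`` — one ordering is
fixed and documented because packages in this field disagree on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SLICE_ORDERS = ("alt+z", "alt+z2", "seq+z")

__all__ = [
    "RigidTransform",
    "Scan",
    "PositionTrace",
    "Mask",
    "SLICE_ORDERS",
    "slice_acquisition_order",
    "slice_offsets",
]


@dataclass(frozen=True)
class RigidTransform:
    """Six-parameter rigid-body position: mm translations and degree rotations."""

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    pitch: float = 0.0
    roll: float = 0.0
    yaw: float = 0.0

    def __post_init__(self):
        if not np.all(np.isfinite(self.params)):
            raise ValueError("rigid-transform parameters must be finite")

    @property
    def params(self) -> np.ndarray:
        """Canonical 6-vector (tx, ty, tz, pitch, roll, yaw)."""
        return np.array(
            [self.tx, self.ty, self.tz, self.pitch, self.roll, self.yaw], float
        )

    @classmethod
    def from_params(cls, params) -> "RigidTransform":
        p = np.asarray(params, float).ravel()
        if p.shape != (6,):
            raise ValueError("expected 6 parameters (tx ty tz pitch roll yaw)")
        return cls(*p)

    def rotation_matrix(self) -> np.ndarray:
        """3x3 rotation, composed yaw @ pitch @ roll (degrees, right-handed)."""
        a, b, c = np.deg2rad([self.pitch, self.roll, self.yaw])
        ca, sa = np.cos(a), np.sin(a)
        cb, sb = np.cos(b), np.sin(b)
        cc, sc = np.cos(c), np.sin(c)
        rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
        ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
        rz = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
        return rz @ rx @ ry

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix acting on centered world coordinates (mm)."""
        m = np.eye(4)
        m[:3, :3] = self.rotation_matrix()
        m[:3, 3] = [self.tx, self.ty, self.tz]
        return m

    @classmethod
    def from_matrix(cls, m) -> "RigidTransform":
        """Recover parameters from a homogeneous matrix (Rz@Rx@Ry ordering).

        Valid away from the pitch = +/-90 deg gimbal singularity, far beyond
        the head-motion regime.
        """
        m = np.asarray(m, float)
        r = m[:3, :3]
        pitch = np.degrees(np.arcsin(np.clip(r[2, 1], -1.0, 1.0)))
        yaw = np.degrees(np.arctan2(-r[0, 1], r[1, 1]))
        roll = np.degrees(np.arctan2(-r[2, 0], r[2, 2]))
        return cls(m[0, 3], m[1, 3], m[2, 3], pitch, roll, yaw)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform applying ``other`` first, then ``self``."""
        return RigidTransform.from_matrix(self.matrix() @ other.matrix())

    def invert(self) -> "RigidTransform":
        r = self.rotation_matrix().T
        t = -r @ np.array([self.tx, self.ty, self.tz])
        m = np.eye(4)
        m[:3, :3] = r
        m[:3, 3] = t
        return RigidTransform.from_matrix(m)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 3) centered-world points through the transform."""
        pts = np.atleast_2d(np.asarray(points, float))
        return pts @ self.rotation_matrix().T + [self.tx, self.ty, self.tz]

    def is_identity(self, tol: float = 0.0) -> bool:
        return bool(np.all(np.abs(self.params) <= tol))


identity = RigidTransform()


@dataclass
class Scan:
    """A 4-D BOLD-like image plus the acquisition metadata the pipeline needs.

    ``data`` is indexed ``(x, y, z, t)`` in arbitrary intensity units.
    ``n_ignore`` initial volumes are excluded from all processing (the usual
    steady-state magnetization discard).
    """

    data: np.ndarray
    tr_s: float
    slice_order: str = "alt+z"
    voxel_mm: tuple = (3.0, 3.0, 3.0)
    n_ignore: int = 4
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4-D image, got {self.data.ndim}-D")
        nx, ny, nz, nt = self.data.shape
        if min(nx, ny, nz) < 4 or nt < 2:
            raise ValueError(f"scan too small: shape {self.data.shape}")
        if not self.tr_s > 0:
            raise ValueError(f"nonpositive TR: {self.tr_s}")
        if self.slice_order not in SLICE_ORDERS:
            raise ValueError(
                f"unknown slice order {self.slice_order!r}; expected one of {SLICE_ORDERS}"
            )
        self.voxel_mm = tuple(float(v) for v in self.voxel_mm)
        if len(self.voxel_mm) != 3 or any(v <= 0 for v in self.voxel_mm):
            raise ValueError(f"voxel sizes must be 3 positive values, got {self.voxel_mm}")
        if not 0 <= self.n_ignore < nt:
            raise ValueError(f"n_ignore={self.n_ignore} out of range for {nt} volumes")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    def retained(self) -> "Scan":
        """Scan with the initial ``n_ignore`` volumes dropped."""
        if self.n_ignore == 0:
            return self
        return Scan(
            self.data[..., self.n_ignore:],
            tr_s=self.tr_s,
            slice_order=self.slice_order,
            voxel_mm=self.voxel_mm,
            n_ignore=0,
            meta=dict(self.meta),
        )

    def with_data(self, data: np.ndarray) -> "Scan":
        """Copy of the scan carrying new image data, same metadata."""
        return Scan(
            data,
            tr_s=self.tr_s,
            slice_order=self.slice_order,
            voxel_mm=self.voxel_mm,
            n_ignore=self.n_ignore,
            meta=dict(self.meta),
        )

    def center_voxel(self) -> np.ndarray:
        """Spatial center in voxel index units (may be half-integer)."""
        return (np.asarray(self.spatial_shape, float) - 1.0) / 2.0


@dataclass
class PositionTrace:
    """Per-volume rigid-body position relative to a reference volume.

    ``params`` is a T x 6 array ordered (tx, ty, tz, pitch, roll, yaw),
    mm and degrees.
    """

    params: np.ndarray
    reference_index: int = 0

    def __post_init__(self):
        self.params = np.atleast_2d(np.asarray(self.params, float))
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(f"position trace must be T x 6, got {self.params.shape}")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("position trace contains non-finite entries")
        if not 0 <= self.reference_index < len(self.params):
            raise ValueError("reference index out of range")

    def __len__(self) -> int:
        return len(self.params)

    def transform(self, t: int) -> RigidTransform:
        return RigidTransform.from_params(self.params[t])


@dataclass
class Mask:
    """Boolean 3-D brain mask matching a scan's spatial shape."""

    grid: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, bool)
        if self.grid.ndim != 3:
            raise ValueError("mask must be 3-D")

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())


def slice_acquisition_order(n_slices: int, slice_order: str) -> np.ndarray:
    """Spatial slice indices in the order they are acquired.

    'seq+z'   : 0, 1, 2, ...
    'alt+z'   : 0, 2, 4, ..., 1, 3, 5, ...   (interleaved, starts slice 1)
    'alt+z2'  : 1, 3, 5, ..., 0, 2, 4, ...   (interleaved, starts slice 2)
    """
    if slice_order == "seq+z":
        return np.arange(n_slices)
    if slice_order == "alt+z":
        return np.concatenate([np.arange(0, n_slices, 2), np.arange(1, n_slices, 2)])
    if slice_order == "alt+z2":
        return np.concatenate([np.arange(1, n_slices, 2), np.arange(0, n_slices, 2)])
    raise ValueError(f"unknown slice order {slice_order!r}; expected one of {SLICE_ORDERS}")


def slice_offsets(n_slices: int, slice_order: str, tr_s: float) -> np.ndarray:
    """Acquisition-time offset (seconds from volume onset) of each spatial slice.

    Slice with acquisition rank ``k`` is acquired at ``k * TR / n_slices``.
    """
    order = slice_acquisition_order(n_slices, slice_order)
    rank = np.empty(n_slices, int)
    rank[order] = np.arange(n_slices)
    return rank * tr_s / n_slices
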