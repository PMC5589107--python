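"""File I/O: NIfTI-1 scans, 6-column motion traces, masks, run configuration.

The motion-file dialect is deliberately a single canonical one — six
whitespace-delimited numeric columns ``tx ty tz pitch roll yaw`` (mm,
degrees), one row per volume, with ``#`` comment headers — because software
packages in this field disagree on column order and units and supporting
every dialect invites silent unit errors.
"""

from __future__ import annotations

import hashlib
import os

import nibabel as nib
import numpy as np
import yaml

from .types import PositionTrace, Scan

__all__ = [
    "read_scan",
    "write_scan",
    "read_position_trace",
    "write_position_trace",
    "load_config",
    "DEFAULT_CONFIG",
    "file_sha256",
]

_TRACE_HEADER = "# tx(mm) ty(mm) tz(mm) pitch(deg) roll(deg) yaw(deg)"

DEFAULT_CONFIG = {
    "tr_s": None,  # fall back to the NIfTI header when absent
    "slice_order": "alt+z",
    "n_ignore": 4,
    "despike": {"c1": 2.5, "c2": 4.0, "trend_order": 2},
    "stc": {"method": "cubic"},
    "realign": {"max_iter": 25, "reference": "first", "kernel": "cubic"},
    "analysis": {"thresholds": [0.5, 0.4, 0.3, 0.2, 0.15]},
    "seeds": {"base": 0},
}


def read_scan(path, tr_s=None, slice_order="alt+z", n_ignore=4, meta=None) -> Scan:
    """Read a 4-D NIfTI-1 file into a :class:`Scan`.

    TR is taken from the header's fourth pixdim unless ``tr_s`` overrides it;
    slice order must come from the caller because NIfTI files do not reliably
    carry it.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such image: {path}")
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"expected 4-D image, got {img.ndim}-D: {path}")
    zooms = img.header.get_zooms()
    if tr_s is None:
        tr_s = float(zooms[3]) if len(zooms) > 3 else 0.0
    if not tr_s > 0:
        raise ValueError(
            f"nonpositive TR ({tr_s}); supply tr_s explicitly for {path}"
        )
    data = np.asarray(img.dataobj, dtype=np.float32)
    return Scan(
        data,
        tr_s=float(tr_s),
        slice_order=slice_order,
        voxel_mm=tuple(float(z) for z in zooms[:3]),
        n_ignore=n_ignore,
        meta=dict(meta or {}),
    )


def write_scan(scan: Scan, path) -> str:
    """Write a :class:`Scan` as float32 NIfTI-1 with voxel sizes and TR set.

    The affine is diagonal RAS with the origin at the volume center, matching
    the package's world-coordinate convention.
    """
    data = np.asarray(scan.data, dtype=np.float32)
    affine = np.diag(list(scan.voxel_mm) + [1.0])
    affine[:3, 3] = -scan.center_voxel() * scan.voxel_mm
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(tuple(scan.voxel_mm) + (scan.tr_s,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return str(path)


def read_position_trace(path) -> PositionTrace:
    """Read a canonical 6-column motion file (tx ty tz pitch roll yaw)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ValueError(
                    f"{path}:{lineno}: expected 6 columns, found {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric entry") from exc
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return PositionTrace(np.array(rows))


def write_position_trace(trace: PositionTrace, path) -> str:
    with open(path, "w") as fh:
        fh.write(_TRACE_HEADER + "\n")
        fh.write(f"# reference_index {trace.reference_index}\n")
        for row in trace.params:
            fh.write(" ".join(f"{v:.8f}" for v in row) + "\n")
    return str(path)


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, overrides=None) -> dict:
    """Load a YAML run configuration, merged over package defaults."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"{path}: configuration must be a mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def file_sha256(path) -> str:
    """Checksum used by the CLI to log exactly which inputs a run consumed."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
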