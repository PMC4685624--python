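"""Velocity preprocessing: temporal phase unwrapping, stationary-tissue
background correction, and resampling of the cardiac cycle to a fixed number
of phases.

Phase-contrast velocities alias modulo ``2 * venc``; unwrapping here is
*temporal*: each voxel's per-component time series is unwrapped along the
phase axis, so only wraps that produce a jump between consecutive phases are
corrected.  Background phase offsets (eddy currents and similar slowly varying
errors) are modelled per phase and per component as an affine function of
physical position, ``v ~ a + b*x + c*y + d*z``, fitted by least squares over
stationary-tissue voxels and subtracted everywhere.

The fixed processing order is unwrap -> fit -> correct -> resample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .flow_io import MaskSeries, VelocityField4D

__all__ = [
    "BackgroundModel",
    "unwrap_velocity",
    "fit_background",
    "apply_background_correction",
    "resample_phases",
    "voxel_coordinates_mm",
]

MIN_STATIONARY_VOXELS = 16


def voxel_coordinates_mm(field: VelocityField4D) -> np.ndarray:
    """Physical coordinates (mm) of every voxel center, shape (nx, ny, nz, 3)."""
    nx, ny, nz = field.grid_shape
    idx = np.stack(
        np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"),
        axis=-1,
    ).astype(float)
    return nib_apply_affine(field.affine, idx)


def nib_apply_affine(affine: np.ndarray, coords: np.ndarray) -> np.ndarray:
    return coords @ affine[:3, :3].T + affine[:3, 3]


def unwrap_velocity(field: VelocityField4D) -> tuple[VelocityField4D, np.ndarray]:
    """Temporally unwrap aliased velocities voxel-by-voxel.

    Wherever the difference between consecutive phases of a component exceeds
    ``venc``, integer multiples of ``2 * venc`` are added to minimise temporal
    jumps (``numpy.unwrap`` with period ``2 * venc``).  A constant aliasing
    offset present at *every* phase produces no temporal jump and is not
    detectable by this pass.

    Returns
    -------
    (unwrapped, wrap_count)
        ``wrap_count`` is an integer lattice (nx, ny, nz) counting, per voxel,
        the number of (phase, component) samples that were corrected.

    Raises
    ------
    ValueError
        If the field has fewer than 3 phases.
    """
    if field.nt < 3:
        raise ValueError(
            f"temporal unwrapping needs at least 3 phases, got nt={field.nt}"
        )
    period = 2.0 * field.venc
    unwrapped = np.unwrap(field.values, axis=3, period=period)
    # reconstruct exactly as original + k * 2 * venc with integer k
    k = np.rint((unwrapped - field.values) / period)
    out = field.values + k * period
    wrap_count = (k != 0).sum(axis=(3, 4)).astype(int)
    return field.copy(values=out), wrap_count


@dataclass
class BackgroundModel:
    """Per-phase, per-component affine background velocity model.

    ``coeffs[t, c] = (a, b, c, d)`` gives the modelled background of component
    ``c`` at phase ``t`` as ``a + b*x + c*y + d*z`` with (x, y, z) in mm and
    the result in cm/s (offset in cm/s, slopes in cm/s/mm).
    """

    coeffs: np.ndarray  # (nt, 3, 4)

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != 3 or self.coeffs.shape[1:] != (3, 4):
            raise ValueError(
                f"coeffs must have shape (nt, 3, 4), got {self.coeffs.shape}"
            )

    @property
    def nt(self) -> int:
        return self.coeffs.shape[0]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({"coeffs": self.coeffs.tolist()}, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "BackgroundModel":
        return cls(coeffs=np.asarray(json.loads(Path(path).read_text())["coeffs"]))


def fit_background(field: VelocityField4D, stationary: MaskSeries) -> BackgroundModel:
    """Least-squares affine fit of velocity over stationary tissue, per phase
    and component.

    Regressors are physical voxel coordinates (mm), centered on the
    stationary-voxel centroid for conditioning; coefficients are returned in
    absolute (uncentered) coordinates.

    Raises
    ------
    ValueError
        If any phase has fewer than 16 stationary voxels, or the stationary
        voxels are coplanar/collinear (rank-deficient design), naming the phase.
    """
    stationary.check_grid(field)
    coords = voxel_coordinates_mm(field)
    nt = field.nt
    coeffs = np.zeros((nt, 3, 4))
    for t in range(nt):
        m = stationary.masks[..., t]
        n = int(m.sum())
        if n < MIN_STATIONARY_VOXELS:
            raise ValueError(
                f"phase {t}: {n} stationary voxels, need >= {MIN_STATIONARY_VOXELS}"
            )
        xyz = coords[m]
        centroid = xyz.mean(axis=0)
        xc = xyz - centroid
        design = np.column_stack([np.ones(n), xc])
        if np.linalg.matrix_rank(design) < 4:
            raise ValueError(
                f"phase {t}: stationary voxels are coplanar/collinear; "
                "background fit is rank-deficient"
            )
        v = field.values[..., t, :][m]  # (n, 3)
        sol, *_ = np.linalg.lstsq(design, v, rcond=None)  # (4, 3)
        for c in range(3):
            a_c, b, cc, d = sol[:, c]
            # uncenter: a' = a - slopes . centroid
            coeffs[t, c] = (a_c - sol[1:, c] @ centroid, b, cc, d)
    return BackgroundModel(coeffs=coeffs)


def apply_background_correction(
    field: VelocityField4D, model: BackgroundModel
) -> VelocityField4D:
    """Subtract the modelled affine background from every voxel of every phase."""
    if model.nt != field.nt:
        raise ValueError(
            f"background model has {model.nt} phases, field has {field.nt}"
        )
    coords = voxel_coordinates_mm(field)  # (nx, ny, nz, 3)
    design = np.concatenate(
        [np.ones(coords.shape[:3] + (1,)), coords], axis=-1
    )  # (nx, ny, nz, 4)
    # background[..., t, c] = design . coeffs[t, c]
    bg = np.einsum("xyzk,tck->xyztc", design, model.coeffs)
    return field.copy(values=field.values - bg)


def resample_phases(field: VelocityField4D, n_target: int = 40) -> VelocityField4D:
    """Resample the cycle to ``n_target`` uniformly spaced phases by periodic
    linear interpolation in time (voxel-wise, per component).

    Output timestamps are ``k * rr_ms / n_target``; values between the last
    and first stored phase wrap periodically.
    """
    if n_target < 2:
        raise ValueError(f"n_target must be >= 2, got {n_target}")
    t_new = np.arange(n_target) * field.rr_ms / n_target
    if field.nt == n_target and np.allclose(t_new, field.timestamps):
        return field.copy()
    ts = field.timestamps
    nt = field.nt
    out = np.empty(field.grid_shape + (n_target, 3), dtype=float)
    for j, t in enumerate(t_new):
        # bracketing phases on the periodic time axis
        i1 = int(np.searchsorted(ts, t, side="right")) % nt
        i0 = (i1 - 1) % nt
        t0, t1 = ts[i0], ts[i1]
        dt = (t1 - t0) % field.rr_ms
        if dt == 0:
            w = 0.0
        else:
            w = ((t - t0) % field.rr_ms) / dt
        out[..., j, :] = (1 - w) * field.values[..., i0, :] + w * field.values[..., i1, :]
    return VelocityField4D(
        values=out,
        spacing=field.spacing,
        timestamps=t_new,
        rr_ms=field.rr_ms,
        venc=field.venc,
        affine=field.affine.copy(),
    )
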