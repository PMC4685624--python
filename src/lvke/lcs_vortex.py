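"""Particle tracing, finite-time Lyapunov exponents (FTLE) and vortex-ring
extraction from time-resolved velocity fields.

The diastolic vortex ring is bounded by Lagrangian coherent structures:
ridges of the backward-time FTLE field (attracting material surfaces) computed
on the imaging grid.  Particles are advected with classic fourth-order
Runge-Kutta through a velocity field that is trilinear in space and linear and
periodic in time; the flow-map gradient is taken by central differences over
neighbouring seeds and the FTLE is

    sigma = ln(sqrt(lambda_max((dPhi)^T dPhi))) / |T|

with T the integration span in seconds.  Velocities in m/s equal mm/ms, so
positions in mm and times in ms need no unit conversion inside the integrator.

Vortex extraction thresholds the FTLE at a percentile within the LV, closes
and fills the ridge set, and keeps the connected component containing the
centroid of the basal third of the LV (the mitral-inflow side).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .flow_io import MaskSeries, VelocityField4D
from .kinetic_energy import signed_max_change

__all__ = [
    "TrajectorySet",
    "FTLEField",
    "VortexParams",
    "sample_velocity",
    "trace_particles",
    "compute_ftle",
    "ftle_on_lattice",
    "extract_vortex_mask",
    "compute_vortex_masks",
    "vortex_volume",
]


@dataclass
class TrajectorySet:
    """Integrated particle paths.

    ``positions`` has shape (n_seeds, n_times, 3) in mm; particles that left
    the spatial domain are frozen at their last in-domain position and flagged
    in ``left_domain``.
    """

    seeds: np.ndarray
    times: np.ndarray
    positions: np.ndarray
    left_domain: np.ndarray

    @property
    def endpoints(self) -> np.ndarray:
        return self.positions[:, -1, :]


@dataclass
class FTLEField:
    """FTLE values on a structured seed grid.

    ``sigma`` (1/s) is NaN on the seed-grid boundary layer and wherever the
    central-difference stencil touched a particle that left the domain.
    """

    sigma: np.ndarray  # (m1, m2, m3)
    seed_points: np.ndarray  # (m1, m2, m3, 3) mm
    t0: float  # ms
    T: float  # ms, signed
    direction: str  # "forward" | "backward"


def _voxel_coords(field: VelocityField4D, x_mm: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(field.affine)
    return x_mm @ inv[:3, :3].T + inv[:3, 3]


def sample_velocity(
    field: VelocityField4D, x_mm: np.ndarray, t_ms: float
) -> tuple[np.ndarray, np.ndarray]:
    """Velocity (m/s) at physical positions ``x_mm`` and time ``t_ms``.

    Trilinear interpolation in space; linear, periodic interpolation in time.
    Returns ``(velocity, in_domain)``; out-of-domain queries return zero
    velocity with ``in_domain`` False (a signal, not an error).
    """
    x_mm = np.atleast_2d(np.asarray(x_mm, dtype=float))
    u = _voxel_coords(field, x_mm)
    nx, ny, nz = field.grid_shape
    in_dom = (
        (u[:, 0] >= 0) & (u[:, 0] <= nx - 1)
        & (u[:, 1] >= 0) & (u[:, 1] <= ny - 1)
        & (u[:, 2] >= 0) & (u[:, 2] <= nz - 1)
    )
    # bracketing phases on the periodic time axis
    ts = field.timestamps
    nt = field.nt
    t = float(t_ms) % field.rr_ms
    i1 = int(np.searchsorted(ts, t, side="right")) % nt
    i0 = (i1 - 1) % nt
    dt = (ts[i1] - ts[i0]) % field.rr_ms
    w = 0.0 if dt == 0 else ((t - ts[i0]) % field.rr_ms) / dt
    vol = (1 - w) * field.values[..., i0, :] + w * field.values[..., i1, :]

    out = np.zeros_like(x_mm)
    if np.any(in_dom):
        uu = u[in_dom]
        i = np.minimum(np.floor(uu).astype(int), np.array([nx, ny, nz]) - 2)
        i = np.maximum(i, 0)
        f = uu - i
        v = np.zeros((uu.shape[0], 3))
        for dx in (0, 1):
            wx = f[:, 0] if dx else 1 - f[:, 0]
            for dy in (0, 1):
                wy = f[:, 1] if dy else 1 - f[:, 1]
                for dz in (0, 1):
                    wz = f[:, 2] if dz else 1 - f[:, 2]
                    w8 = (wx * wy * wz)[:, None]
                    v += w8 * vol[i[:, 0] + dx, i[:, 1] + dy, i[:, 2] + dz, :]
        out[in_dom] = v * 0.01  # cm/s -> m/s
    return out, in_dom


def trace_particles(
    field: VelocityField4D,
    seeds: np.ndarray,
    t0: float,
    T: float,
    dt: float | None = None,
) -> TrajectorySet:
    """Advect seeds with classic RK4 from ``t0`` over the signed span ``T`` ms.

    ``dt`` (ms, magnitude) defaults to half the inter-phase spacing; it is
    adjusted so an integer number of steps exactly covers ``T``.  Particles
    whose RK4 stages touch points outside the spatial domain are frozen at
    their last position and flagged.
    """
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    if T == 0:
        raise ValueError("integration span T must be nonzero")
    if dt is None:
        dt = 0.5 * float(np.min(np.diff(field.timestamps)))
    if dt == 0:
        raise ValueError("dt must be nonzero")
    dt = abs(dt)
    n_steps = max(1, int(round(abs(T) / dt)))
    h = T / n_steps  # signed step
    times = t0 + h * np.arange(n_steps + 1)
    n = seeds.shape[0]
    positions = np.empty((n, n_steps + 1, 3))
    positions[:, 0, :] = seeds
    x = seeds.copy()
    active = np.ones(n, dtype=bool)
    for k in range(n_steps):
        t = times[k]
        k1, ok1 = sample_velocity(field, x, t)
        k2, ok2 = sample_velocity(field, x + 0.5 * h * k1, t + 0.5 * h)
        k3, ok3 = sample_velocity(field, x + 0.5 * h * k2, t + 0.5 * h)
        k4, ok4 = sample_velocity(field, x + h * k3, t + h)
        ok = ok1 & ok2 & ok3 & ok4
        step = (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        x_new = x + np.where((active & ok)[:, None], step, 0.0)
        # freeze particles that stepped outside the domain
        _, still_in = sample_velocity(field, x_new, t + h)
        newly_out = active & (~ok | ~still_in)
        x_new[newly_out] = x[newly_out]
        active &= ~newly_out
        x = x_new
        positions[:, k + 1, :] = x
    return TrajectorySet(
        seeds=seeds, times=times, positions=positions, left_domain=~active
    )


def compute_ftle(
    field: VelocityField4D,
    seed_points: np.ndarray,
    t0: float,
    T: float,
    dt: float | None = None,
) -> FTLEField:
    """FTLE on a structured, axis-aligned seed grid.

    ``seed_points`` has shape (m1, m2, m3, 3) in mm.  The flow-map gradient is
    taken by central differences over neighbouring seeds; along degenerate
    grid axes (size < 3) the deformation gradient column is the identity, so
    quasi-2D grids are handled naturally.  Positive ``T`` gives forward FTLE,
    negative gives backward.
    """
    seed_points = np.asarray(seed_points, dtype=float)
    if seed_points.ndim != 4 or seed_points.shape[-1] != 3:
        raise ValueError("seed_points must have shape (m1, m2, m3, 3)")
    if T == 0:
        raise ValueError("integration span T must be nonzero")
    m1, m2, m3, _ = seed_points.shape
    flat = seed_points.reshape(-1, 3)
    traj = trace_particles(field, flat, t0, T, dt=dt)
    phi = traj.endpoints.reshape(m1, m2, m3, 3)
    left = traj.left_domain.reshape(m1, m2, m3)

    F = np.zeros((m1, m2, m3, 3, 3))
    F[..., :, :] = np.eye(3)
    valid = np.ones((m1, m2, m3), dtype=bool)
    for axis, m in enumerate((m1, m2, m3)):
        if m < 3:
            continue  # degenerate axis: identity column
        plus = np.roll(phi, -1, axis=axis)
        minus = np.roll(phi, 1, axis=axis)
        sp = np.roll(seed_points, -1, axis=axis)
        sm = np.roll(seed_points, 1, axis=axis)
        # physical spacing along this axis (assumed rectilinear)
        denom = np.linalg.norm(sp - sm, axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            F[..., :, axis] = (plus - minus) / denom[..., None]
        # boundary layer along this axis is undefined
        sl = [slice(None)] * 3
        sl[axis] = slice(0, 1)
        valid[tuple(sl)] = False
        sl[axis] = slice(m - 1, m)
        valid[tuple(sl)] = False
        valid &= ~np.roll(left, -1, axis=axis) & ~np.roll(left, 1, axis=axis)
    valid &= ~left

    C = np.einsum("...ki,...kj->...ij", F, F)
    lam = np.linalg.eigvalsh(C)[..., -1]
    T_s = abs(T) / 1000.0
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma = np.log(np.sqrt(np.maximum(lam, 1e-300))) / T_s
    sigma = np.where(valid, sigma, np.nan)
    return FTLEField(
        sigma=sigma,
        seed_points=seed_points,
        t0=float(t0),
        T=float(T),
        direction="forward" if T > 0 else "backward",
    )


@dataclass
class VortexParams:
    """Parameters of the automated vortex-ring extraction."""

    q: float = 90.0  # FTLE percentile within the LV for ridge voxels
    closing_radius: int = 1  # voxels, morphological closing of the ridge set
    long_axis: int = 2  # imaging axis closest to the LV long axis
    basal_sign: int = 1  # +1: basal (inflow) side at high index along long_axis
    direction: str = "backward"
    dt: float | None = None  # ms; default half the inter-phase spacing


def ftle_on_lattice(
    field: VelocityField4D,
    lv: MaskSeries,
    phase: int,
    T: float,
    dt: float | None = None,
) -> np.ndarray:
    """Backward/forward FTLE seeded at every voxel center of the LV bounding
    box at ``phase``, returned as a full-lattice array (NaN elsewhere)."""
    lv_t = lv.masks[..., phase]
    if not lv_t.any():
        return np.full(field.grid_shape, np.nan)
    idx = np.argwhere(lv_t)
    lo = np.maximum(idx.min(axis=0) - 1, 0)
    hi = np.minimum(idx.max(axis=0) + 1, np.array(field.grid_shape) - 1)
    axes = [np.arange(lo[a], hi[a] + 1) for a in range(3)]
    gi = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).astype(float)
    seeds = gi @ field.affine[:3, :3].T + field.affine[:3, 3]
    t0 = float(field.timestamps[phase])
    res = compute_ftle(field, seeds, t0=t0, T=T, dt=dt)
    sigma_full = np.full(field.grid_shape, np.nan)
    sigma_full[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] = res.sigma
    return sigma_full


def extract_vortex_mask(
    sigma: np.ndarray,
    lv_t: np.ndarray,
    params: VortexParams | None = None,
) -> np.ndarray:
    """Vortex-ring region from an FTLE lattice at one phase.

    Ridge voxels are those with sigma above the q-th percentile of sigma
    within the LV; the ridge set is morphologically closed and hole-filled,
    intersected with the LV, and the connected component containing the
    centroid of the basal third of the LV is kept.  Returns a boolean lattice
    (possibly empty) always contained in ``lv_t``.
    """
    params = params or VortexParams()
    inside = lv_t & np.isfinite(sigma)
    if not inside.any():
        return np.zeros_like(lv_t, dtype=bool)
    thr = np.percentile(sigma[inside], params.q)
    ridge = inside & (sigma >= thr)
    if not ridge.any() or thr <= 0:
        return np.zeros_like(lv_t, dtype=bool)
    struct = _ball(params.closing_radius)
    closed = ndimage.binary_closing(ridge, structure=struct)
    filled = ndimage.binary_fill_holes(closed) & lv_t
    labels, n_lab = ndimage.label(filled)
    if n_lab == 0:
        return np.zeros_like(lv_t, dtype=bool)
    target = _basal_third_centroid(lv_t, params.long_axis, params.basal_sign)
    # component containing (or nearest to) the basal-third centroid
    comp_vox = np.argwhere(filled)
    d2 = np.sum((comp_vox - target) ** 2, axis=1)
    order = np.lexsort((comp_vox[:, 2], comp_vox[:, 1], comp_vox[:, 0], d2))
    chosen = labels[tuple(comp_vox[order[0]])]
    return labels == chosen


def _ball(radius: int) -> np.ndarray:
    # Chebyshev ball (full cube): 26-connected closing bridges diagonal gaps
    # in thin FTLE ridge shells that a 6-connected element leaves open
    r = int(radius)
    return np.ones((2 * r + 1,) * 3, dtype=bool)


def _basal_third_centroid(lv_t: np.ndarray, long_axis: int, basal_sign: int) -> np.ndarray:
    idx = np.argwhere(lv_t)
    coord = idx[:, long_axis]
    lo, hi = coord.min(), coord.max()
    span = hi - lo + 1
    if basal_sign >= 0:
        basal = idx[coord >= hi - span // 3]
    else:
        basal = idx[coord <= lo + span // 3]
    return basal.mean(axis=0)


def compute_vortex_masks(
    field: VelocityField4D,
    lv: MaskSeries,
    diastolic_phases: np.ndarray,
    es_time_ms: float,
    params: VortexParams | None = None,
) -> tuple[MaskSeries, dict[int, np.ndarray]]:
    """Automated vortex-ring masks for each diastolic phase.

    For each seeded phase the integration span is the elapsed diastole (time
    since end-systole), capped at ``rr_ms / 2``, run backward in time for
    attracting structures (or forward if requested).  Returns the vortex
    MaskSeries and the per-phase FTLE lattices.
    """
    params = params or VortexParams()
    masks = np.zeros(lv.masks.shape, dtype=bool)
    sigmas: dict[int, np.ndarray] = {}
    for phase in np.atleast_1d(diastolic_phases):
        phase = int(phase)
        span = (float(field.timestamps[phase]) - es_time_ms) % field.rr_ms
        span = min(max(span, float(np.min(np.diff(field.timestamps)))), field.rr_ms / 2)
        T = -span if params.direction == "backward" else span
        sigma = ftle_on_lattice(field, lv, phase, T=T, dt=params.dt)
        sigmas[phase] = sigma
        masks[..., phase] = extract_vortex_mask(sigma, lv.masks[..., phase], params)
    return MaskSeries(role="vortex", masks=masks), sigmas


def vortex_volume(
    vortex: MaskSeries, spacing: tuple[float, float, float]
) -> tuple[np.ndarray, float]:
    """Per-phase vortex volume (ml) and the signed maximal change from
    formation (first nonempty phase) onward."""
    voxvol_ml = spacing[0] * spacing[1] * spacing[2] / 1000.0
    vols = vortex.masks.sum(axis=(0, 1, 2)) * voxvol_ml
    valid = vortex.valid_phases
    delta = signed_max_change(vols[valid]) if valid.size >= 2 else 0.0
    return vols, delta
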