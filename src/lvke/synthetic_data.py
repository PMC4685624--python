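"""Synthetic 4D-flow datasets with analytic ground truth.

Three families of generators:

* :func:`make_hill_vortex` — Hill's spherical vortex, the classic steady,
  divergence-free vortex ring with closed-form velocity everywhere and a
  closed-form interior kinetic energy, used as the analytic oracle for the
  KE and FTLE stages.
* :func:`make_double_gyre` — the standard time-periodic double-gyre
  stream-function flow (extruded to 3D with zero z-velocity), the usual FTLE
  benchmark.
* :func:`make_lv_cycle` — a beating ellipsoidal LV: a prescribed volume curve
  with systolic emptying and E-/A-wave filling, a diastolic inflow jet
  carrying a translating Hill-type vortex, a systolic outflow jet, a
  stationary-tissue shell carrying an injected affine background offset,
  optional Gaussian velocity noise, and optional aliasing beyond VENC.
* :func:`make_ke_curve` — curve-level fixtures for the pattern classifier.

All generators are deterministic under a fixed seed.  The LV mask is
voxelised by taking exactly ``round(V(t)/voxel_volume)`` voxels in order of
ellipsoidal radius, so emitted mask volumes match the prescribed volume curve
to within one voxel at every phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .flow_io import DatasetMeta, MaskSeries, VelocityField4D
from .kinetic_energy import KECurve
from .volumetrics import CardiacPhases, _cyclic_range

__all__ = [
    "SyntheticSpec",
    "hill_vortex_velocity",
    "hill_vortex_ke",
    "make_hill_vortex",
    "make_double_gyre",
    "make_lv_cycle",
    "make_ke_curve",
    "wrap_velocities",
]

# E/A inflow-velocity ratios that realise each curve pattern
_PATTERN_EA_RATIO = {"control_like": 2.0, "p1": 0.6, "p2": 1.6, "p3": 1.0}


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic LV exam.

    Defaults describe an idealised healthy exam at the acquisition geometry
    typical for 4D flow: a 48^3 lattice of 3 mm isotropic voxels, 40 phases
    over an RR interval of 1000 ms, VENC 100 cm/s, and a control-like volume
    curve (EDV 150 ml, ESV 60 ml).  Corruptions (background offsets, noise,
    aliasing) are off by default and opt-in.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    rr_ms: float = 1000.0
    n_phases: int = 40
    venc: float = 100.0
    density: float = 1050.0
    edv: float = 150.0  # ml
    esv: float = 60.0  # ml
    pattern: str = "control_like"
    e_a_ratio: float | None = None  # E/A inflow-velocity ratio; None -> per pattern
    jet_peak_cm_s: float = 80.0  # E-wave inflow jet peak velocity
    vortex_radius_mm: float = 12.0
    vortex_speed_cm_s: float = 25.0  # vortex translation speed toward the apex
    background_coeffs: np.ndarray | None = None  # (3, 4) or (n_phases, 3, 4)
    noise_sd_cm_s: float = 0.0
    inject_wraps: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.edv > self.esv > 0):
            raise ValueError(f"need edv > esv > 0, got edv={self.edv}, esv={self.esv}")
        if self.n_phases < 8:
            raise ValueError(f"n_phases must be >= 8, got {self.n_phases}")
        if self.pattern not in _PATTERN_EA_RATIO:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.e_a_ratio is None:
            self.e_a_ratio = _PATTERN_EA_RATIO[self.pattern]

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(self.n_phases) * self.rr_ms / self.n_phases

    def meta(self, subject_id: str = "synthetic") -> DatasetMeta:
        return DatasetMeta(
            rr_ms=self.rr_ms, venc=self.venc, density=self.density, subject_id=subject_id
        )


# ---------------------------------------------------------------------------
# Hill's spherical vortex


def hill_vortex_velocity(
    points_mm: np.ndarray,
    center_mm: np.ndarray,
    a_mm: float,
    U_cm_s: float,
    frame: str = "comoving",
) -> np.ndarray:
    """Velocity (cm/s) of Hill's spherical vortex at arbitrary points.

    Axis of propagation is +z.  In the co-moving frame the sphere is at rest
    and the far field tends to ``-U z_hat``; the interior is the rotational
    Hill solution and the exterior is potential flow past the sphere.  In the
    lab frame (``frame="lab"``) the uniform stream ``+U z_hat`` is added, so
    the far field is at rest and the vortex translates at ``+U z_hat``.
    """
    if frame not in ("comoving", "lab"):
        raise ValueError(f"frame must be comoving|lab, got {frame!r}")
    p = np.asarray(points_mm, dtype=float) - np.asarray(center_mm, dtype=float)
    x, y, z = p[..., 0], p[..., 1], p[..., 2]
    s2 = x**2 + y**2
    r2 = s2 + z**2
    a2 = a_mm**2
    k = 3.0 * U_cm_s / (2.0 * a2)
    inside = r2 < a2
    # interior: u_s = k s z, u_z = k (a^2 - 2 s^2 - z^2)
    us_over_s = np.where(inside, k * z, 0.0)
    uz = np.where(inside, k * (a2 - 2.0 * s2 - z**2), 0.0)
    # exterior: potential flow past the sphere, far field -U z_hat
    with np.errstate(divide="ignore", invalid="ignore"):
        r5 = np.where(r2 > 0, r2**2.5, np.inf)
        ext_us_over_s = 1.5 * U_cm_s * a_mm**3 * z / r5
        ext_uz = -U_cm_s * (1.0 - a_mm**3 / np.where(r2 > 0, r2**1.5, np.inf)) \
            - 1.5 * U_cm_s * a_mm**3 * s2 / r5
    us_over_s = np.where(inside, us_over_s, ext_us_over_s)
    uz = np.where(inside, uz, ext_uz)
    v = np.stack([us_over_s * x, us_over_s * y, uz], axis=-1)
    if frame == "lab":
        v[..., 2] += U_cm_s
    return v


def hill_vortex_ke(a_mm: float, U_cm_s: float, density: float = 1050.0) -> float:
    """Closed-form kinetic energy (joules) of the Hill-vortex interior in the
    co-moving frame: ``KE = (3 pi / 7) rho U^2 a^3``."""
    a_m = a_mm * 1e-3
    U_m = U_cm_s * 1e-2
    return 3.0 * np.pi / 7.0 * density * U_m**2 * a_m**3


def _lattice_coords(shape, spacing) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-center physical coordinates (mm) and the diagonal affine."""
    affine = np.diag([*spacing, 1.0])
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    return pts, affine


def make_hill_vortex(
    shape: tuple[int, int, int] = (48, 48, 48),
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0),
    a_mm: float = 20.0,
    U_cm_s: float = 30.0,
    center_mm: np.ndarray | None = None,
    frame: str = "comoving",
    n_phases: int = 2,
    rr_ms: float = 1000.0,
    venc: float = 100.0,
) -> VelocityField4D:
    """Steady Hill-vortex velocity field sampled at voxel centers.

    The sphere must lie strictly inside the grid.  The field is replicated
    over ``n_phases`` identical phases (steady flow).
    """
    pts, affine = _lattice_coords(shape, spacing)
    extent = np.array([(n - 1) * s for n, s in zip(shape, spacing)])
    if center_mm is None:
        center_mm = extent / 2.0
    center_mm = np.asarray(center_mm, dtype=float)
    if np.any(center_mm - a_mm < 0) or np.any(center_mm + a_mm > extent):
        raise ValueError("vortex sphere intersects the grid boundary")
    v = hill_vortex_velocity(pts, center_mm, a_mm, U_cm_s, frame=frame)
    values = np.repeat(v[:, :, :, None, :], n_phases, axis=3)
    return VelocityField4D(
        values=values,
        spacing=spacing,
        timestamps=np.arange(n_phases) * rr_ms / n_phases,
        rr_ms=rr_ms,
        venc=venc,
        affine=affine,
    )


def make_translating_hill_vortex(
    shape: tuple[int, int, int] = (40, 40, 40),
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0),
    a_mm: float = 16.0,
    U_cm_s: float = -5.0,
    z0_mm: float = 70.0,
    n_phases: int = 9,
    dt_ms: float = 50.0,
    rr_ms: float = 1000.0,
    venc: float = 100.0,
) -> tuple[VelocityField4D, np.ndarray]:
    """Lab-frame translating Hill vortex: the far field is at rest and the
    vortex sphere translates along z at ``U_cm_s`` starting from ``z0_mm``.

    The unsteady lab-frame flow differs from the steady co-moving flow by a
    Galilean boost, so its FTLE field is identical, while particles far from
    the vortex stay (nearly) put — the configuration the FTLE/vortex
    extraction stages see in a real filling LV.  Returns the field and the
    vortex center per phase (mm).
    """
    pts, affine = _lattice_coords(shape, spacing)
    extent = np.array([(n - 1) * s for n, s in zip(shape, spacing)])
    ts = np.arange(n_phases) * dt_ms
    if ts[-1] >= rr_ms:
        raise ValueError("phase range exceeds the cycle length")
    centers = np.zeros((n_phases, 3))
    values = np.zeros(shape + (n_phases, 3))
    for i, t in enumerate(ts):
        c = np.array([extent[0] / 2, extent[1] / 2, z0_mm + 0.01 * U_cm_s * t])
        if (c[2] - a_mm) < 0 or (c[2] + a_mm) > extent[2]:
            raise ValueError(f"vortex sphere leaves the grid at phase {i}")
        centers[i] = c
        values[..., i, :] = hill_vortex_velocity(pts, c, a_mm, U_cm_s, frame="lab")
    field = VelocityField4D(
        values=values, spacing=spacing, timestamps=ts, rr_ms=rr_ms,
        venc=venc, affine=affine,
    )
    return field, centers


# ---------------------------------------------------------------------------
# double gyre


def make_double_gyre(
    nx: int = 64,
    ny: int = 32,
    nz: int = 3,
    L_mm: float = 100.0,
    A_cm_s: float = 10.0,
    epsilon: float = 0.25,
    rr_ms: float = 1000.0,
    n_phases: int = 20,
    venc: float = 100.0,
) -> VelocityField4D:
    """Time-periodic double-gyre flow on [0, 2L] x [0, L], extruded in z.

    Stream function ``psi = A sin(pi f(x, t)) sin(pi y)`` with
    ``f = eps sin(wt) x^2 + (1 - 2 eps sin(wt)) x`` in domain units; the flow
    period equals ``rr_ms`` and no fluid crosses the domain boundary (the
    normal velocity component vanishes on the box edges).
    ``A_cm_s`` scales the velocity amplitude; the z-component is zero.
    """
    spacing = (2.0 * L_mm / (nx - 1), L_mm / (ny - 1), L_mm / max(nz - 1, 1))
    ts = np.arange(n_phases) * rr_ms / n_phases
    x = np.linspace(0.0, 2.0, nx)
    y = np.linspace(0.0, 1.0, ny)
    X, Y = np.meshgrid(x, y, indexing="ij")
    omega = 2.0 * np.pi / rr_ms
    values = np.zeros((nx, ny, nz, n_phases, 3))
    for j, t in enumerate(ts):
        at = epsilon * np.sin(omega * t)
        bt = 1.0 - 2.0 * epsilon * np.sin(omega * t)
        f = at * X**2 + bt * X
        dfdx = 2.0 * at * X + bt
        u = -np.pi * A_cm_s * np.sin(np.pi * f) * np.cos(np.pi * Y)
        v = np.pi * A_cm_s * np.cos(np.pi * f) * np.sin(np.pi * Y) * dfdx
        values[:, :, :, j, 0] = u[:, :, None]
        values[:, :, :, j, 1] = v[:, :, None]
    return VelocityField4D(
        values=values,
        spacing=spacing,
        timestamps=ts,
        rr_ms=rr_ms,
        venc=venc,
        affine=np.diag([*spacing, 1.0]),
    )


# ---------------------------------------------------------------------------
# beating LV


def _periodic_bump(t: np.ndarray, center: float, width: float) -> np.ndarray:
    """Gaussian bump on the periodic unit interval."""
    d = (t - center + 0.5) % 1.0 - 0.5
    return np.exp(-0.5 * (d / width) ** 2)


# normalised cycle timing (fractions of RR): ES at 0.40
_T_ES = 0.40
_SYS_BUMP = (0.20, 0.08)
_FILL_BUMPS = {
    # pattern: (E center, E width, A center, A width)
    "control_like": (0.55, 0.05, 0.87, 0.045),
    "p1": (0.55, 0.05, 0.87, 0.045),
    "p2": (0.55, 0.05, 0.87, 0.045),
    "p3": (0.62, 0.09, 0.78, 0.09),  # overlapping -> fused peaks
}


def _rate_curves(spec: SyntheticSpec, t: np.ndarray):
    """Normalised emptying and E/A filling rate shapes on the unit cycle."""
    ec, ew, ac, aw = _FILL_BUMPS[spec.pattern]
    empty = _periodic_bump(t, *_SYS_BUMP)
    fill_e = _periodic_bump(t, ec, ew)
    fill_a = _periodic_bump(t, ac, aw) / spec.e_a_ratio
    return empty, fill_e, fill_a


def prescribed_volume_curve(spec: SyntheticSpec) -> np.ndarray:
    """Ground-truth LV volume (ml) at each phase: EDV at phase 0, emptying to
    ESV, then E- and A-wave refilling back to EDV."""
    fine = np.linspace(0.0, 1.0, 4001)
    empty, fill_e, fill_a = _rate_curves(spec, fine)
    rate = -empty / np.trapezoid(empty, fine)
    fill = fill_e + fill_a
    rate = rate + fill / np.trapezoid(fill, fine)
    v = np.concatenate([[0.0], np.cumsum((rate[1:] + rate[:-1]) / 2 * np.diff(fine))])
    t_phase = spec.timestamps / spec.rr_ms
    v = np.interp(t_phase, fine, v)
    # affine-rescale the *sampled* curve so the phase-grid extrema hit
    # EDV/ESV exactly
    return spec.esv + (v - v.min()) * (spec.edv - spec.esv) / (v.max() - v.min())


def _ellipsoid_mask(shape, spacing, center_mm, volume_ml, axis_ratio=1.6):
    """Exactly-counted ellipsoidal voxel mask of the requested volume.

    Voxels are ranked by ellipsoidal radius and the first
    ``round(volume / voxel_volume)`` are taken, so the mask volume matches the
    request to within one voxel.  Returns (mask, semi_axes_mm).
    """
    voxvol_ml = spacing[0] * spacing[1] * spacing[2] / 1000.0
    n_vox = int(round(volume_ml / voxvol_ml))
    ax = (3.0 * volume_ml * 1000.0 / (4.0 * np.pi * axis_ratio)) ** (1.0 / 3.0)
    semi = np.array([ax, ax, ax * axis_ratio])
    pts, _ = _lattice_coords(shape, spacing)
    e = np.sum(((pts - center_mm) / semi) ** 2, axis=-1)
    order = np.argsort(e.ravel(), kind="stable")[:n_vox]
    mask = np.zeros(np.prod(shape), dtype=bool)
    mask[order] = True
    return mask.reshape(shape), semi


def wrap_velocities(values_cm_s: np.ndarray, venc: float) -> np.ndarray:
    """Alias velocities modulo 2*venc into [-venc, venc): the wrap model of
    phase-contrast encoding."""
    return ((values_cm_s + venc) % (2.0 * venc)) - venc


def make_lv_cycle(spec: SyntheticSpec | None = None):
    """Generate a full synthetic exam: velocity field, LV and stationary
    masks, and the ground-truth record.

    Returns
    -------
    (field, lv, stationary, truth)
        ``truth`` is a dict with keys ``volume_ml``, ``time_ms``, ``pattern``,
        ``vortex_center_mm`` (per phase, NaN where absent),
        ``vortex_radius_mm``, ``background_coeffs`` (or None),
        ``clean_values`` (the uncorrupted velocity lattice, cm/s),
        ``ed_index``, ``es_index``.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    shape, spacing = spec.shape, spec.spacing
    nt = spec.n_phases
    pts, affine = _lattice_coords(shape, spacing)
    extent = np.array([(n - 1) * s for n, s in zip(shape, spacing)])
    center = extent / 2.0

    vol = prescribed_volume_curve(spec)
    t_frac = spec.timestamps / spec.rr_ms
    empty, fill_e, fill_a = _rate_curves(spec, t_frac)
    fill = fill_e + fill_a
    fill_peak = fill.max()
    empty_peak = empty.max()

    lv_masks = np.zeros(shape + (nt,), dtype=bool)
    values = np.zeros(shape + (nt, 3))
    vortex_center = np.full((nt, 3), np.nan)
    a_v = spec.vortex_radius_mm
    semi_ed = None
    for tphase in range(nt):
        lv_t, semi = _ellipsoid_mask(shape, spacing, center, vol[tphase])
        lv_masks[..., tphase] = lv_t
        if tphase == 0:
            semi_ed = semi
        # jet amplitudes follow the instantaneous volume rates
        v_in = spec.jet_peak_cm_s * fill[tphase] / fill_peak
        v_out = spec.jet_peak_cm_s * empty[tphase] / empty_peak
        s2 = np.sum((pts[..., :2] - center[:2]) ** 2, axis=-1)
        r_jet = 0.45 * semi[0]
        radial = np.exp(-s2 / r_jet**2)
        zrel = (pts[..., 2] - center[2]) / semi[2]  # -1 apex .. +1 base
        v_t = np.zeros(shape + (3,))
        if v_in > 0.5:
            axial = np.clip(zrel, 0.0, 1.0)
            v_t[..., 2] -= v_in * radial * axial
        if v_out > 0.5:
            axial = np.clip(zrel + 0.3, 0.0, 1.0)
            v_t[..., 2] += v_out * radial * axial
        # translating Hill-type vortex during diastolic filling
        if fill[tphase] / fill_peak > 0.1 and t_frac[tphase] > _T_ES:
            progress = (t_frac[tphase] - _T_ES) / (1.0 - _T_ES)
            zc = center[2] + 0.5 * semi[2] - spec.vortex_speed_cm_s * 10.0 * progress * (1.0 - _T_ES)
            zc = max(zc, center[2] - 0.3 * semi[2])
            c_v = np.array([center[0], center[1], zc])
            if (c_v[2] - a_v) > 0 and (c_v[2] + a_v) < extent[2]:
                amp = fill[tphase] / fill_peak
                v_t += amp * hill_vortex_velocity(
                    pts, c_v, a_v, -spec.vortex_speed_cm_s, frame="lab"
                )
                vortex_center[tphase] = c_v
        # no-slip-like taper: velocities vanish smoothly at the moving LV wall,
        # so mask changes between phases never create artificial velocity jumps
        e_t = np.sqrt(np.sum(((pts - center) / semi) ** 2, axis=-1))
        w = np.clip((1.0 - e_t) / 0.25, 0.0, 1.0)
        v_t *= (w * w * (3.0 - 2.0 * w))[..., None]
        v_t[~lv_t] = 0.0
        values[..., tphase, :] = v_t

    # stationary-tissue shell around the end-diastolic LV
    e_ed = np.sqrt(np.sum(((pts - center) / semi_ed) ** 2, axis=-1))
    shell = (e_ed > 1.12) & (e_ed < 1.45)
    stationary = MaskSeries(
        role="stationary", masks=np.repeat(shell[..., None], nt, axis=3)
    )
    clean = values.copy()

    bg = spec.background_coeffs
    if bg is not None:
        bg = np.asarray(bg, dtype=float)
        if bg.shape == (3, 4):
            bg = np.repeat(bg[None], nt, axis=0)
        design = np.concatenate([np.ones(shape + (1,)), pts], axis=-1)
        values = values + np.einsum("xyzk,tck->xyztc", design, bg)
    if spec.noise_sd_cm_s > 0:
        values = values + rng.normal(0.0, spec.noise_sd_cm_s, values.shape)
    if spec.inject_wraps:
        values = wrap_velocities(values, spec.venc)

    field = VelocityField4D(
        values=values,
        spacing=spacing,
        timestamps=spec.timestamps,
        rr_ms=spec.rr_ms,
        venc=spec.venc,
        affine=affine,
    )
    lv = MaskSeries(role="lv", masks=lv_masks)
    truth = {
        "volume_ml": vol,
        "time_ms": spec.timestamps,
        "pattern": spec.pattern,
        "vortex_center_mm": vortex_center,
        "vortex_radius_mm": a_v,
        "background_coeffs": bg,
        "clean_values": clean,
        "ed_index": int(np.argmax(vol)),
        "es_index": int(np.argmin(vol)),
    }
    return field, lv, stationary, truth


# ---------------------------------------------------------------------------
# curve-level fixtures

_KE_BUMPS = {
    # pattern: [(center, width, amplitude key), ...]
    "control_like": [(0.20, 0.05, "sys"), (0.55, 0.045, "e"), (0.87, 0.04, "a")],
    "p1": [(0.20, 0.05, "sys"), (0.55, 0.045, "e"), (0.87, 0.04, "a")],
    "p2": [(0.20, 0.05, "sys"), (0.55, 0.045, "e"), (0.87, 0.04, "a")],
    "p3": [(0.20, 0.05, "sys"), (0.80, 0.13, "fused")],
}

_KE_AMPLITUDES = {
    "control_like": {"sys": 3.3, "e": 6.4, "a": 2.0},
    "p1": {"sys": 3.3, "e": 2.0, "a": 4.0},
    "p2": {"sys": 3.3, "e": 4.0, "a": 2.0},
    "p3": {"sys": 3.3, "fused": 4.0},
}


def make_ke_curve(
    pattern: str,
    n_phases: int = 40,
    rr_ms: float = 1000.0,
    amplitudes: dict[str, float] | None = None,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> tuple[KECurve, CardiacPhases, str]:
    """Sum-of-bumps KE time curve with a known pattern label.

    ``amplitudes`` override the per-pattern default peak heights (mJ);
    ``noise_frac`` adds Gaussian noise with SD = noise_frac * curve max,
    clipped at zero.  Returns (curve, phase partition, true label).
    """
    if pattern not in _KE_BUMPS:
        raise ValueError(f"unknown pattern {pattern!r}")
    amps = dict(_KE_AMPLITUDES[pattern])
    if amplitudes:
        amps.update(amplitudes)
    if any(v < 0 for v in amps.values()):
        raise ValueError("amplitudes must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.arange(n_phases) / n_phases
    total = np.full(n_phases, 0.15)
    for center, width, key in _KE_BUMPS[pattern]:
        total = total + amps[key] * _periodic_bump(t, center, width)
    if noise_frac > 0:
        total = total + rng.normal(0.0, noise_frac * total.max(), n_phases)
        total = np.clip(total, 0.0, None)
    time = t * rr_ms
    es = int(round(_T_ES * n_phases))
    n = n_phases
    systole = _cyclic_range(0, es, n)
    diastole = _cyclic_range(es, 0, n)

    def _window(lo_frac, hi_frac):
        return diastole[(t[diastole] >= lo_frac) & (t[diastole] < hi_frac)]

    if pattern == "p3":
        e_wave = diastole
        diastasis = diastole[:0]
        a_wave = diastole[:0]
    else:
        e_wave = _window(_T_ES, 0.70)
        diastasis = _window(0.70, 0.80)
        a_wave = _window(0.80, 1.0)
    phases = CardiacPhases(
        systole=systole, diastole=diastole,
        e_wave=e_wave, diastasis=diastasis, a_wave=a_wave,
    )
    return KECurve(time=time, total=total), phases, pattern
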