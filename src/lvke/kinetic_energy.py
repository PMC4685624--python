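"""Voxel-wise blood kinetic energy and its temporal/region summaries.

KE per voxel is ``1/2 * m * v^2`` with ``m = density * voxel_volume`` (blood
density 1050 kg/m^3 by default) and ``v`` the velocity magnitude; the LV KE
time curve is the sum of voxel KE over the endocardial mask at each phase.
Region sums use a fixed (C-order) summation order so that the inside/outside
vortex split is exactly conservative: inside + outside = total to the last
bit on every phase where the vortex is defined.

Units: KE fields are stored in joules per voxel; curves and summaries report
mJ, and volume-indexed averages report uJ/ml (mean mJ / ml * 1000).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .flow_io import MaskSeries, VelocityField4D
from .volumetrics import CardiacPhases, VolumetricsSummary

__all__ = [
    "KEField",
    "KECurve",
    "KESummary",
    "compute_ke_field",
    "sum_region_ke",
    "partition_vortex_ke",
    "summarize_ke",
    "signed_max_change",
]


@dataclass
class KEField:
    """Scalar kinetic energy per voxel and phase, joules."""

    ke: np.ndarray  # (nx, ny, nz, nt)
    time: np.ndarray  # ms

    def __post_init__(self) -> None:
        self.ke = np.asarray(self.ke, dtype=float)
        if self.ke.ndim != 4:
            raise ValueError(f"ke must be 4D, got shape {self.ke.shape}")
        if np.any(self.ke < 0):
            raise ValueError("kinetic energy must be non-negative")


@dataclass
class KECurve:
    """Per-phase KE (mJ): total over the LV, and, where a vortex mask exists,
    the inside/outside split.  ``inside``/``outside`` are NaN on phases where
    the vortex is undefined."""

    time: np.ndarray  # ms
    total: np.ndarray  # mJ
    inside: np.ndarray | None = None  # mJ, NaN where undefined
    outside: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.total = np.asarray(self.total, dtype=float)
        if self.total.shape != self.time.shape:
            raise ValueError("total and time must have equal length")
        for name in ("inside", "outside"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.total.shape:
                    raise ValueError(f"{name} length does not match total")
                setattr(self, name, v)

    @property
    def vortex_phases(self) -> np.ndarray:
        if self.inside is None:
            return np.array([], dtype=int)
        return np.flatnonzero(~np.isnan(self.inside))


@dataclass
class KESummary:
    """Temporal summaries of the LV KE curve.

    Vortex-dependent fields are ``None`` (undefined, not zero) when no vortex
    mask was provided.
    """

    sys_avg: float  # mJ
    dia_avg: float  # mJ
    sys_peak: float  # mJ
    dia_peak: float  # mJ
    sys_avg_per_sv: float  # uJ/ml
    dia_avg_per_sv: float  # uJ/ml
    sys_avg_per_edv: float  # uJ/ml
    dia_avg_per_edv: float  # uJ/ml
    cv: float  # SD/mean of the full total curve
    vortex_fraction: float | None = None  # %
    delta_ke_diastole: float | None = None  # mJ, signed
    delta_ke_diastasis: float | None = None  # mJ, signed
    delta_vortex_volume: float | None = None  # ml, signed


def compute_ke_field(field: VelocityField4D, density: float = 1050.0) -> KEField:
    """KE per voxel: ``1/2 * density * voxel_volume_m3 * |v|^2`` with |v| in m/s."""
    if density <= 0:
        raise ValueError(f"density must be > 0, got {density}")
    voxvol_m3 = field.voxel_volume_mm3 * 1e-9
    speed2 = np.sum((field.values * 0.01) ** 2, axis=-1)  # cm/s -> m/s
    return KEField(ke=0.5 * density * voxvol_m3 * speed2, time=field.timestamps)


def sum_region_ke(kef: KEField, region: MaskSeries) -> np.ndarray:
    """Per-phase sum of voxel KE over the region, in mJ.

    Phases where the region is empty contribute 0 (an empty region holds no
    energy); grid mismatch raises.
    """
    if region.masks.shape != kef.ke.shape:
        raise ValueError(
            f"region grid {region.masks.shape} does not match KE grid {kef.ke.shape}"
        )
    nt = kef.ke.shape[3]
    out = np.empty(nt)
    for t in range(nt):
        out[t] = kef.ke[..., t][region.masks[..., t]].sum() * 1000.0
    return out


def partition_vortex_ke(
    kef: KEField, lv: MaskSeries, vortex: MaskSeries
) -> KECurve:
    """Split LV KE into inside- and outside-vortex parts per phase.

    ``inside + outside == total`` exactly on every vortex phase (identical
    summation order over complementary index sets).  Phases where the vortex
    mask is empty get inside = NaN (undefined) unless the phase is in the
    vortex series' valid set.
    """
    vortex.check_subset_of(lv)
    total = sum_region_ke(kef, lv)
    nt = kef.ke.shape[3]
    inside = np.full(nt, np.nan)
    outside = np.full(nt, np.nan)
    for t in vortex.valid_phases:
        ke_t = kef.ke[..., t]
        lv_t = lv.masks[..., t]
        vx_t = vortex.masks[..., t]
        inside[t] = ke_t[vx_t].sum() * 1000.0
        outside[t] = ke_t[lv_t & ~vx_t].sum() * 1000.0
        total[t] = inside[t] + outside[t]  # bitwise conservation by construction
    return KECurve(time=kef.time, total=total, inside=inside, outside=outside)


def signed_max_change(series: np.ndarray) -> float:
    """Signed change from the first sample with maximal absolute value.

    Used for the diastolic ΔKE and Δvortex-volume measures: the change of
    largest magnitude relative to the formation (first) sample, keeping its
    sign; the earliest such sample wins ties.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        return 0.0
    deltas = series[1:] - series[0]
    i = int(np.argmax(np.abs(deltas)))
    return float(deltas[i])


def summarize_ke(
    curve: KECurve,
    phases: CardiacPhases,
    vols: VolumetricsSummary,
    vortex_volume_ml: np.ndarray | None = None,
) -> KESummary:
    """Temporal averages, peaks, indexed values, variability, and the vortex
    partition summaries of an LV KE curve.

    ``cv`` is the sample (n-1) standard deviation over the full curve divided
    by its mean.  The vortex fraction is 100 * (temporal mean of inside KE)
    / (temporal mean of inside + outside KE) over the diastolic vortex phases.
    ΔKE values use :func:`signed_max_change` over the cyclically ordered
    diastolic vortex phases (formation -> end-diastole).
    """
    if curve.total.shape[0] != phases.n_phases:
        raise ValueError("curve and phase partition have different lengths")
    if vols.sv <= 0 or vols.edv <= 0:
        raise ValueError("SV and EDV must be positive for indexed KE values")
    tot = curve.total
    sys_idx, dia_idx = phases.systole, phases.diastole
    sys_avg = float(tot[sys_idx].mean())
    dia_avg = float(tot[dia_idx].mean())
    mean = tot.mean()
    if mean == 0:
        raise ValueError("zero-mean KE curve: cv undefined")
    summary = KESummary(
        sys_avg=sys_avg,
        dia_avg=dia_avg,
        sys_peak=float(tot[sys_idx].max()),
        dia_peak=float(tot[dia_idx].max()),
        sys_avg_per_sv=sys_avg / vols.sv * 1000.0,
        dia_avg_per_sv=dia_avg / vols.sv * 1000.0,
        sys_avg_per_edv=sys_avg / vols.edv * 1000.0,
        dia_avg_per_edv=dia_avg / vols.edv * 1000.0,
        cv=float(tot.std(ddof=1) / mean),
    )
    if curve.inside is None:
        return summary
    # diastolic vortex phases in cyclic diastolic order (formation first)
    vset = set(curve.vortex_phases.tolist())
    dia_vortex = np.array([i for i in dia_idx if i in vset], dtype=int)
    if dia_vortex.size == 0:
        return summary
    inside = curve.inside[dia_vortex]
    outside = curve.outside[dia_vortex]
    denom = (inside + outside).mean()
    if denom > 0:
        summary.vortex_fraction = float(100.0 * inside.mean() / denom)
    summary.delta_ke_diastole = signed_max_change(inside)
    dstasis = set(phases.diastasis.tolist())
    in_dstasis = np.array([i in dstasis for i in dia_vortex])
    if in_dstasis.sum() >= 2:
        summary.delta_ke_diastasis = signed_max_change(inside[in_dstasis])
    if vortex_volume_ml is not None:
        vv = np.asarray(vortex_volume_ml, dtype=float)[dia_vortex]
        summary.delta_vortex_volume = signed_max_change(vv)
    return summary
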