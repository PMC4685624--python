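"""LV volume curve, global volumes, filling/emptying rates and the
systole/diastole/diastasis phase partition.

End-diastole (ED) is the global volume maximum and end-systole (ES) the global
minimum, ties broken toward the earliest phase.  All phase index sets are
expressed in the original phase ordering but enumerated cyclically starting at
ED, i.e. systole = [ED, ES) and diastole = [ES, ED) on the periodic phase
axis.  E-wave, diastasis and A-wave are derived from the cyclic dV/dt of the
volume curve: the E-wave ends where dV/dt first falls below ``alpha * PFR``
after the PFR peak, and the A-wave starts where dV/dt last rises above that
same threshold before the final diastolic filling peak.  The E/A timing here
is a dV/dt surrogate for transmitral-inflow timing; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import argrelextrema

from .flow_io import MaskSeries

__all__ = [
    "VolumeCurve",
    "VolumetricsSummary",
    "CardiacPhases",
    "compute_volume_curve",
    "compute_volumetrics",
    "split_phases",
    "cyclic_dvdt",
]


@dataclass
class VolumeCurve:
    """LV blood-pool volume per phase (ml) with its time axis (ms)."""

    volume: np.ndarray
    time: np.ndarray
    rr_ms: float

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if self.volume.shape != self.time.shape or self.volume.ndim != 1:
            raise ValueError("volume and time must be 1D arrays of equal length")
        if np.any(self.volume < 0):
            raise ValueError("volumes must be non-negative")

    @property
    def n_phases(self) -> int:
        return self.volume.shape[0]


@dataclass
class VolumetricsSummary:
    edv: float  # ml
    esv: float  # ml
    sv: float  # ml
    ef: float  # %
    per: float  # ml/s, peak emptying rate (positive)
    pfr: float  # ml/s, peak filling rate (positive)
    ed_index: int
    es_index: int


@dataclass
class CardiacPhases:
    """Index sets partitioning the cycle; indices refer to the original phase
    ordering, listed cyclically starting at ED."""

    systole: np.ndarray  # [ED, ES)
    diastole: np.ndarray  # [ES, ED)
    e_wave: np.ndarray
    diastasis: np.ndarray
    a_wave: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.systole) + len(self.diastole)
        union = np.concatenate([self.systole, self.diastole])
        if len(np.unique(union)) != n:
            raise ValueError("systole and diastole must be disjoint")
        sub = np.concatenate([self.e_wave, self.diastasis, self.a_wave])
        if len(np.unique(sub)) != len(sub) or not np.isin(sub, self.diastole).all():
            raise ValueError("e_wave/diastasis/a_wave must be disjoint subsets of diastole")

    @property
    def n_phases(self) -> int:
        return len(self.systole) + len(self.diastole)


def compute_volume_curve(lv: MaskSeries, spacing: tuple[float, float, float],
                         time: np.ndarray, rr_ms: float) -> VolumeCurve:
    """Volume per phase as voxel count times voxel volume (ml).

    Raises on any phase with an empty LV mask: the blood pool never vanishes.
    """
    counts = lv.masks.sum(axis=(0, 1, 2))
    if np.any(counts == 0):
        empty = np.flatnonzero(counts == 0)
        raise ValueError(f"LV mask empty at phase(s) {empty.tolist()}")
    voxvol_ml = spacing[0] * spacing[1] * spacing[2] / 1000.0
    return VolumeCurve(volume=counts * voxvol_ml, time=np.asarray(time, float), rr_ms=rr_ms)


def cyclic_dvdt(curve: VolumeCurve) -> np.ndarray:
    """dV/dt in ml/s by cyclic central differences on the (periodic) time axis."""
    v = curve.volume
    t = curve.time
    n = curve.n_phases
    ip = (np.arange(n) + 1) % n
    im = (np.arange(n) - 1) % n
    dt_ms = (t[ip] - t[im]) % curve.rr_ms
    return (v[ip] - v[im]) / dt_ms * 1000.0


def compute_volumetrics(curve: VolumeCurve) -> VolumetricsSummary:
    """EDV/ESV/SV/EF and peak emptying/filling rates from the volume curve.

    SV = EDV - ESV and EF = 100 * SV / EDV; PER is the largest -dV/dt over
    systole and PFR the largest dV/dt over diastole, with derivatives taken as
    cyclic central differences.
    """
    v = curve.volume
    if np.ptp(v) == 0:
        raise ValueError("constant volume curve: ED and ES are undefined")
    ed = int(np.argmax(v))
    es = int(np.argmin(v))
    edv, esv = float(v[ed]), float(v[es])
    sv = edv - esv
    dvdt = cyclic_dvdt(curve)
    n = curve.n_phases
    sys_idx = _cyclic_range(ed, es, n)
    dia_idx = _cyclic_range(es, ed, n)
    per = float(np.max(-dvdt[sys_idx]))
    pfr = float(np.max(dvdt[dia_idx]))
    return VolumetricsSummary(
        edv=edv, esv=esv, sv=sv, ef=100.0 * sv / edv,
        per=per, pfr=pfr, ed_index=ed, es_index=es,
    )


def _cyclic_range(start: int, stop: int, n: int) -> np.ndarray:
    """Indices [start, stop) on the cyclic phase axis of length n."""
    if stop > start:
        return np.arange(start, stop)
    return np.concatenate([np.arange(start, n), np.arange(0, stop)])


def split_phases(curve: VolumeCurve, alpha: float = 0.2) -> CardiacPhases:
    """Partition the cycle into systole/diastole and diastole into
    E-wave/diastasis/A-wave.

    ``alpha`` is the fraction of PFR used to terminate the E-wave (and,
    symmetrically, to locate the A-wave onset).  With a single filling peak
    the whole diastole is labelled E-wave and diastasis/A-wave are empty.
    """
    vols = compute_volumetrics(curve)
    n = curve.n_phases
    ed, es = vols.ed_index, vols.es_index
    systole = _cyclic_range(ed, es, n)
    diastole = _cyclic_range(es, ed, n)
    if len(diastole) < 2:
        raise ValueError("diastole spans fewer than 2 phases")
    dvdt = cyclic_dvdt(curve)
    d = dvdt[diastole]  # filling rate along the cyclic diastolic ordering
    pfr_pos = int(np.argmax(d))
    thresh = alpha * vols.pfr
    # local maxima of the diastolic filling rate (interior points)
    maxima = argrelextrema(d, np.greater_equal, order=1)[0]
    maxima = maxima[(maxima > 0) & (maxima < len(d) - 1)]
    maxima = maxima[d[maxima] > thresh]
    last_peak = int(maxima[-1]) if len(maxima) else pfr_pos
    # E-wave ends at the first sub-threshold filling rate after the PFR peak
    after = np.flatnonzero(d[pfr_pos + 1:] < thresh)
    e_end = pfr_pos + 1 + int(after[0]) if len(after) else len(d)
    if last_peak <= pfr_pos or e_end >= len(d):
        # single filling wave: everything is E-wave
        return CardiacPhases(
            systole=systole, diastole=diastole,
            e_wave=diastole, diastasis=diastole[:0], a_wave=diastole[:0],
        )
    # A-wave onset: last sub-threshold filling rate before the final peak
    before = np.flatnonzero(d[e_end:last_peak + 1] < thresh)
    a_start = e_end + int(before[-1]) + 1 if len(before) else e_end
    return CardiacPhases(
        systole=systole,
        diastole=diastole,
        e_wave=diastole[:e_end],
        diastasis=diastole[e_end:a_start],
        a_wave=diastole[a_start:],
    )
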