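"""Diastolic E/A peak features of LV KE time curves, the three-pattern
heart-failure taxonomy, and agreement statistics against diastolic-dysfunction
grades.

Heart-failure KE time curves fall into three morphologies: (1) E-wave KE peak
lower than the A-wave peak, (2) E-wave peak higher than the A-wave peak, and
(3) partial or complete fusion of the two diastolic peaks.  Healthy controls
show a separated, E-dominant curve ("control-like").  The detector
operationalises the visual criteria with three configurable thresholds:
peak prominence ``p`` (fraction of the diastolic maximum), inter-peak trough
ratio ``theta`` (a trough shallower than ``theta * min(peaks)`` counts as
fusion) and systolic spill-over ``s`` (KE at systole onset relative to the
diastolic maximum).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .kinetic_energy import KECurve, summarize_ke
from .volumetrics import CardiacPhases

__all__ = [
    "PatternResult",
    "AgreementTable",
    "PatternParams",
    "detect_diastolic_peaks",
    "classify_pattern",
    "cohen_kappa",
    "curve_cv_compare",
    "PATTERN_LABELS",
    "GRADE_LABELS",
]

PATTERN_LABELS = ("control_like", "p1", "p2", "p3")
GRADE_LABELS = ("impaired", "pseudonormal", "restrictive")


@dataclass
class PatternParams:
    prominence: float = 0.10  # p: candidate-peak prominence, fraction of diastolic max
    trough_ratio: float = 0.7  # theta: fusion if trough > theta * min(peaks)
    spillover_ratio: float = 0.5  # s: spill-over if KE at systole onset > s * diastolic max
    smooth: bool = True  # cyclic 3-point moving average before peak detection


@dataclass
class PatternResult:
    """E/A peak features and (after classification) the curve label.

    ``ke_e``/``ke_a`` are the diastolic KE peaks at the E- and A-wave (mJ),
    NaN when the peaks are fused.
    """

    ke_e: float
    ke_a: float
    fused: bool
    spillover: bool
    label: str | None = None
    tie: bool = False


@dataclass
class AgreementTable:
    """Contingency counts of curve pattern x diastolic-dysfunction grade."""

    counts: np.ndarray
    row_labels: tuple[str, ...] = ("p1", "p2", "p3")
    col_labels: tuple[str, ...] = GRADE_LABELS
    excluded: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError(f"counts must be square, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


def detect_diastolic_peaks(
    curve: KECurve,
    phases: CardiacPhases,
    params: PatternParams | None = None,
) -> PatternResult:
    """Locate E- and A-wave KE peaks over diastole and the fusion/spill-over flags.

    Local maxima of total KE over the (cyclically ordered) diastolic phases
    with prominence at least ``p * diastolic max`` are candidates; E is the
    earliest and A the latest.  Fewer than two candidates, or an inter-peak
    trough above ``theta * min(E, A)``, counts as fusion.

    Candidate positions and the trough are located on a lightly smoothed
    series (cyclic 3-point moving average, ``params.smooth``) so isolated
    noise samples do not masquerade as diastolic peaks; the reported peak
    amplitudes are read from the raw curve at the detected positions.
    """
    params = params or PatternParams()
    dia = phases.diastole
    if len(dia) < 4:
        raise ValueError(f"diastole has {len(dia)} phases, need >= 4")
    total = curve.total
    smoothed = total
    if params.smooth:
        smoothed = (np.roll(total, 1) + total + np.roll(total, -1)) / 3.0
    series = total[dia]
    series_sm = smoothed[dia]
    dmax = float(series_sm.max())
    if dmax <= 0:
        raise ValueError("all-zero diastolic KE curve")
    peaks, _ = find_peaks(series_sm, prominence=params.prominence * dmax)
    spill = bool(smoothed[phases.systole[0]] > params.spillover_ratio * dmax)
    if len(peaks) < 2:
        return PatternResult(ke_e=np.nan, ke_a=np.nan, fused=True, spillover=spill)
    e_pos, a_pos = int(peaks[0]), int(peaks[-1])
    ke_e, ke_a = float(series[e_pos]), float(series[a_pos])
    trough = float(series_sm[e_pos:a_pos + 1].min())
    fused = trough > params.trough_ratio * min(ke_e, ke_a)
    if fused:
        return PatternResult(ke_e=np.nan, ke_a=np.nan, fused=True, spillover=spill)
    return PatternResult(ke_e=ke_e, ke_a=ke_a, fused=False, spillover=spill)


def classify_pattern(
    features: PatternResult, subject_class: str = "patient"
) -> PatternResult:
    """Assign the curve label from extracted features.

    Fused peaks give pattern 3.  Otherwise an A-dominant curve is pattern 1
    and an E-dominant curve is pattern 2 for patients, or control-like for
    controls.  An exact E/A tie (non-fused) is labelled pattern 2 with the
    tie flag set.
    """
    if subject_class not in ("patient", "control"):
        raise ValueError(f"subject_class must be patient|control, got {subject_class!r}")
    if features.fused:
        features.label = "p3"
        return features
    if features.ke_e < features.ke_a:
        features.label = "p1"
    elif features.ke_e > features.ke_a:
        features.label = "control_like" if subject_class == "control" else "p2"
    else:
        features.label = "p2"
        features.tie = True
    return features


def cohen_kappa(table: AgreementTable) -> tuple[float, float, tuple[float, float]]:
    """Unweighted Cohen's kappa with asymptotic SE and 95% CI.

    kappa = (Po - Pe) / (1 - Pe) with Po the observed and Pe the chance
    agreement from the table marginals; the standard large-sample standard
    error ``sqrt(Po (1 - Po) / (n (1 - Pe)^2))`` gives the normal-theory CI.
    """
    counts = table.counts
    n = counts.sum()
    if n < 2:
        raise ValueError("need at least 2 rated subjects")
    po = np.trace(counts) / n
    rows = counts.sum(axis=1) / n
    cols = counts.sum(axis=0) / n
    pe = float(rows @ cols)
    if pe >= 1.0:
        raise ValueError("degenerate marginals: chance agreement Pe = 1")
    kappa = (po - pe) / (1 - pe)
    se = float(np.sqrt(po * (1 - po) / (n * (1 - pe) ** 2)))
    z = 1.959963984540054  # 97.5% normal quantile
    ci = (kappa - z * se, kappa + z * se)
    return float(kappa), se, ci


def curve_cv_compare(
    curves: dict[str, KECurve],
    phases: dict[str, CardiacPhases] | CardiacPhases,
    vols,
) -> pd.DataFrame:
    """Coefficient of variation (sample SD / mean of the total KE curve) per
    subject, tabulated for group comparison.

    ``phases``/``vols`` may be single objects (shared design) or per-subject
    dicts keyed like ``curves``.
    """
    if not curves:
        raise ValueError("no curves supplied")
    rows = []
    for sid, curve in curves.items():
        ph = phases[sid] if isinstance(phases, dict) else phases
        vo = vols[sid] if isinstance(vols, dict) else vols
        summary = summarize_ke(curve, ph, vo)
        rows.append({"subject_id": sid, "cv": summary.cv})
    return pd.DataFrame(rows)
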