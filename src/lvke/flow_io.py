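"""Readers and writers for 4D-flow velocity fields, segmentation masks and curve tables.

On-disk convention: one scalar 4D NIfTI-1 file per velocity component
(``vx.nii.gz``, ``vy.nii.gz``, ``vz.nii.gz``, cm/s, in the physical axes of
the shared affine) plus a JSON sidecar with timing and encoding metadata::

    {"rr_ms": ..., "venc_cm_s": ..., "timestamps_ms": [...],
     "density_kg_m3": 1050.0, "subject_id": "..."}

Masks are 4D NIfTI label volumes of 0/1 integers on the same grid.
All tabular output is plain CSV with a leading ``time_ms`` column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VelocityField4D",
    "MaskSeries",
    "DatasetMeta",
    "read_flow_dataset",
    "write_flow_dataset",
    "read_mask_series",
    "write_mask_series",
    "write_curve_table",
    "read_curve_table",
]

_COMPONENT_FILES = ("vx.nii.gz", "vy.nii.gz", "vz.nii.gz")
_SIDECAR = "meta.json"


@dataclass
class DatasetMeta:
    """Acquisition-level metadata for one 4D-flow exam.

    Parameters
    ----------
    rr_ms : float
        Cardiac cycle length (RR interval), ms.
    venc : float
        Velocity-encoding limit, cm/s; velocities alias modulo ``2 * venc``.
    density : float
        Blood density, kg/m^3. Default 1050.
    subject_id : str
        Free-text identifier.
    """

    rr_ms: float
    venc: float
    density: float = 1050.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.rr_ms <= 0:
            raise ValueError(f"rr_ms must be > 0, got {self.rr_ms}")
        if self.density <= 0:
            raise ValueError(f"density must be > 0, got {self.density}")
        if self.venc <= 0:
            raise ValueError(f"venc must be > 0, got {self.venc}")


@dataclass
class VelocityField4D:
    """Time-resolved three-component velocity field on a regular voxel lattice.

    Attributes
    ----------
    values : ndarray, shape (nx, ny, nz, nt, 3)
        Velocity in cm/s, components expressed along the *physical* axes of
        ``affine`` (not voxel axes).
    spacing : tuple of float
        Voxel spacing (dx, dy, dz), mm.
    timestamps : ndarray, shape (nt,)
        Trigger time of each phase, ms, strictly increasing, all < ``rr_ms``.
    rr_ms : float
        Cardiac cycle length, ms; the time axis is periodic with this period.
    venc : float
        Velocity-encoding limit, cm/s.
    affine : ndarray, shape (4, 4)
        Voxel-index -> physical-mm map.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    timestamps: np.ndarray
    rr_ms: float
    venc: float
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 5 or self.values.shape[-1] != 3:
            raise ValueError(
                f"values must have shape (nx, ny, nz, nt, 3), got {self.values.shape}"
            )
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.nt < 2:
            raise ValueError(f"need at least 2 phases, got nt={self.nt}")
        if self.timestamps.shape != (self.nt,):
            raise ValueError(
                f"timestamps length {self.timestamps.shape} does not match nt={self.nt}"
            )
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.rr_ms <= 0:
            raise ValueError(f"rr_ms must be > 0, got {self.rr_ms}")
        if self.timestamps[-1] >= self.rr_ms:
            raise ValueError(
                f"timestamps must all be < rr_ms={self.rr_ms}, got max {self.timestamps[-1]}"
            )
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        self.spacing = spacing
        if self.venc <= 0:
            raise ValueError(f"venc must be > 0, got {self.venc}")
        if self.affine is None:
            self.affine = np.diag([*spacing, 1.0])
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {self.affine.shape}")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape[:3]

    @property
    def nt(self) -> int:
        return self.values.shape[3]

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def copy(self, values: np.ndarray | None = None) -> "VelocityField4D":
        return VelocityField4D(
            values=self.values.copy() if values is None else values,
            spacing=self.spacing,
            timestamps=self.timestamps.copy(),
            rr_ms=self.rr_ms,
            venc=self.venc,
            affine=self.affine.copy(),
        )


@dataclass
class MaskSeries:
    """Per-phase binary region labels aligned to a velocity grid.

    ``role`` is one of ``{"lv", "stationary", "vortex"}``; ``valid_phases``
    is the set of phase indices with at least one set voxel.
    """

    role: str
    masks: np.ndarray  # (nx, ny, nz, nt) bool

    ROLES = ("lv", "stationary", "vortex")

    def __post_init__(self) -> None:
        if self.role not in self.ROLES:
            raise ValueError(f"role must be one of {self.ROLES}, got {self.role!r}")
        masks = np.asarray(self.masks)
        if masks.ndim != 4:
            raise ValueError(f"masks must be 4D (nx, ny, nz, nt), got {masks.shape}")
        if masks.dtype != bool:
            vals = np.unique(masks)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(
                    f"mask values must be 0/1, found {vals[~np.isin(vals, (0, 1))][:5]}"
                )
            masks = masks.astype(bool)
        self.masks = masks

    @property
    def nt(self) -> int:
        return self.masks.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.masks.shape[:3]

    @property
    def valid_phases(self) -> np.ndarray:
        return np.flatnonzero(self.masks.any(axis=(0, 1, 2)))

    def check_grid(self, field: VelocityField4D) -> None:
        if self.grid_shape != field.grid_shape or self.nt != field.nt:
            raise ValueError(
                f"mask grid {self.masks.shape} does not match velocity grid "
                f"{field.values.shape[:4]}"
            )

    def check_subset_of(self, other: "MaskSeries") -> None:
        """Raise if this mask is not voxel-wise contained in ``other`` on every
        phase where this mask is defined; names the first offending phase."""
        for t in self.valid_phases:
            if np.any(self.masks[..., t] & ~other.masks[..., t]):
                raise ValueError(
                    f"{self.role} mask not contained in {other.role} mask at phase {t}"
                )


# ---------------------------------------------------------------------------
# dataset I/O


def write_flow_dataset(path: str | Path, field: VelocityField4D, meta: DatasetMeta) -> Path:
    """Write a velocity field as three component NIfTIs plus a JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, name in enumerate(_COMPONENT_FILES):
        img = nib.Nifti1Image(np.asarray(field.values[..., i]), field.affine)
        img.header.set_xyzt_units("mm", "msec")
        nib.save(img, path / name)
    sidecar = {
        "rr_ms": meta.rr_ms,
        "venc_cm_s": meta.venc,
        "timestamps_ms": field.timestamps.tolist(),
        "density_kg_m3": meta.density,
        "subject_id": meta.subject_id,
    }
    (path / _SIDECAR).write_text(json.dumps(sidecar, indent=2))
    return path


def read_flow_dataset(path: str | Path) -> tuple[VelocityField4D, DatasetMeta]:
    """Read a velocity field written by :func:`write_flow_dataset`.

    Raises
    ------
    FileNotFoundError
        If a component file or the sidecar is missing (named in the message).
    ValueError
        On grid-shape mismatch across components or unsorted timestamps.
    """
    path = Path(path)
    comps = []
    affine = None
    shape = None
    for name in _COMPONENT_FILES:
        f = path / name
        if not f.exists():
            raise FileNotFoundError(f"missing velocity component file: {f}")
        img = nib.load(str(f))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 4:
            raise ValueError(f"{name}: expected a 4D volume, got shape {data.shape}")
        if shape is None:
            shape, affine = data.shape, img.affine
        elif data.shape != shape:
            raise ValueError(
                f"grid-shape mismatch: {name} has {data.shape}, "
                f"{_COMPONENT_FILES[0]} has {shape}"
            )
        comps.append(data)
    sidecar_path = path / _SIDECAR
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in ("rr_ms", "venc_cm_s", "timestamps_ms"):
        if key not in sidecar:
            raise ValueError(f"sidecar missing required field {key!r}")
    ts = np.asarray(sidecar["timestamps_ms"], dtype=float)
    if np.any(np.diff(ts) <= 0):
        raise ValueError("sidecar field 'timestamps_ms' is not strictly increasing")
    spacing = tuple(float(s) for s in nib.affines.voxel_sizes(affine))
    meta = DatasetMeta(
        rr_ms=float(sidecar["rr_ms"]),
        venc=float(sidecar["venc_cm_s"]),
        density=float(sidecar.get("density_kg_m3", 1050.0)),
        subject_id=str(sidecar.get("subject_id", "")),
    )
    fld = VelocityField4D(
        values=np.stack(comps, axis=-1),
        spacing=spacing,
        timestamps=ts,
        rr_ms=meta.rr_ms,
        venc=meta.venc,
        affine=affine,
    )
    return fld, meta


def write_mask_series(path: str | Path, mask: MaskSeries, affine: np.ndarray | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(mask.masks.astype(np.uint8), np.asarray(affine, dtype=float))
    nib.save(img, path)
    return path


def read_mask_series(
    path: str | Path,
    role: str,
    reference: VelocityField4D | None = None,
) -> MaskSeries:
    """Read a 4D 0/1 NIfTI label volume as a :class:`MaskSeries`.

    Non-integer voxel values are rejected; if ``reference`` is given the grid
    must match it exactly.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 3:  # single-phase mask: treat as one-phase series
        data = data[..., None]
    if not np.isin(np.unique(data), (0, 1)).all():
        bad = np.unique(data)
        raise ValueError(f"mask {path} contains non-binary values, e.g. {bad[:5]}")
    mask = MaskSeries(role=role, masks=data.astype(bool))
    if reference is not None:
        mask.check_grid(reference)
    return mask


# ---------------------------------------------------------------------------
# curve tables


def write_curve_table(
    curves: dict[str, np.ndarray], time_ms: np.ndarray, path: str | Path
) -> Path:
    """Write per-phase series to CSV with a leading ``time_ms`` column.

    All series must share the phase axis length; an empty ``curves`` dict
    yields a header-only file with the time column.
    """
    time_ms = np.asarray(time_ms, dtype=float)
    n = time_ms.shape[0]
    for name, series in curves.items():
        series = np.asarray(series)
        if series.shape != (n,):
            raise ValueError(
                f"series {name!r} has length {series.shape}, expected ({n},)"
            )
    df = pd.DataFrame({"time_ms": time_ms, **{k: np.asarray(v, dtype=float) for k, v in curves.items()}})
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def read_curve_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
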