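import numpy as np
import pytest

from lvke.flow_io import VelocityField4D
from lvke.synthetic_data import SyntheticSpec, make_lv_cycle

# Small-grid study conditions used across tests: 32^3 voxels at 4 mm keeps a
# full exam under a second to generate while preserving every qualitative
# feature (E/A filling, vortex, shell) of the default 48^3 / 3 mm geometry.
SMALL = dict(shape=(32, 32, 32), spacing=(4.0, 4.0, 4.0), vortex_radius_mm=10.0)


@pytest.fixture(scope="session")
def lv_exam():
    """Noise-free control-like synthetic exam (field, lv, stationary, truth)."""
    return make_lv_cycle(SyntheticSpec(**SMALL))


def linear_field(
    grad: np.ndarray,
    n: int = 21,
    spacing: float = 4.0,
    nt: int = 2,
    rr_ms: float = 2000.0,
    offset_cm_s: np.ndarray | None = None,
) -> VelocityField4D:
    """Steady velocity field v_i = sum_j grad[i, j] * x_j, centred on the grid.

    ``grad`` is in 1/s acting on positions in m (so v m/s = grad @ x_m);
    stored values are cm/s on a grid in mm.
    """
    coords = (np.arange(n) - n // 2) * spacing
    X, Y, Z = np.meshgrid(coords, coords, coords, indexing="ij")
    pos_mm = np.stack([X, Y, Z], axis=-1)
    v_cm_s = 0.1 * pos_mm @ np.asarray(grad, dtype=float).T  # 0.1 = 100 cm/m * 1e-3 m/mm
    if offset_cm_s is not None:
        v_cm_s = v_cm_s + np.asarray(offset_cm_s, dtype=float)
    values = np.repeat(v_cm_s[:, :, :, None, :], nt, axis=3)
    affine = np.diag([spacing, spacing, spacing, 1.0])
    affine[:3, 3] = coords[0]
    return VelocityField4D(
        values=values,
        spacing=(spacing,) * 3,
        timestamps=np.arange(nt) * rr_ms / nt,
        rr_ms=rr_ms,
        venc=300.0,
        affine=affine,
    )
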