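import numpy as np
import pytest

from lvke.flow_io import MaskSeries, VelocityField4D
from lvke.kinetic_energy import (
    KECurve,
    compute_ke_field,
    partition_vortex_ke,
    signed_max_change,
    sum_region_ke,
    summarize_ke,
)
from lvke.synthetic_data import (
    hill_vortex_ke,
    make_hill_vortex,
    make_ke_curve,
)
from lvke.volumetrics import CardiacPhases, VolumetricsSummary


def _uniform_field(speed_cm_s, shape=(4, 4, 4), spacing=(3.0, 3.0, 3.0), nt=2):
    values = np.zeros(shape + (nt, 3))
    values[..., 0] = speed_cm_s
    return VelocityField4D(
        values=values, spacing=spacing,
        timestamps=np.arange(nt) * 100.0, rr_ms=1000.0, venc=200.0,
    )


# hand arithmetic from the defining formula: one 3 mm voxel at 100 cm/s,
# KE = 1/2 * 1050 kg/m^3 * 2.7e-8 m^3 * (1 m/s)^2 = 1.41750e-5 J
SINGLE_VOXEL_KE_J = 0.5 * 1050.0 * 2.7e-8 * 1.0**2


class TestKEField:
    def test_zero_velocity_zero_ke(self):
        kef = compute_ke_field(_uniform_field(0.0))
        assert np.all(kef.ke == 0.0)

    def test_single_voxel_hand_arithmetic(self):
        kef = compute_ke_field(_uniform_field(100.0), density=1050.0)
        assert kef.ke[0, 0, 0, 0] == pytest.approx(SINGLE_VOXEL_KE_J, rel=1e-12)
        assert kef.ke[0, 0, 0, 0] == pytest.approx(1.4175e-5, rel=1e-12)

    def test_ke_quadratic_in_speed(self):
        k1 = compute_ke_field(_uniform_field(30.0)).ke
        k2 = compute_ke_field(_uniform_field(60.0)).ke
        np.testing.assert_allclose(k2, 4 * k1, rtol=1e-12)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError, match="density"):
            compute_ke_field(_uniform_field(10.0), density=-1.0)


class TestRegionSum:
    def test_whole_grid_single_voxel_value(self):
        field = _uniform_field(100.0, shape=(1, 1, 1))
        kef = compute_ke_field(field)
        region = MaskSeries("lv", np.ones((1, 1, 1, 2), dtype=bool))
        np.testing.assert_allclose(
            sum_region_ke(kef, region), SINGLE_VOXEL_KE_J * 1000.0, rtol=1e-12)

    def test_empty_region_zero(self):
        kef = compute_ke_field(_uniform_field(50.0))
        region = MaskSeries("lv", np.zeros((4, 4, 4, 2), dtype=bool))
        np.testing.assert_array_equal(sum_region_ke(kef, region), 0.0)

    def test_additive_over_disjoint_regions(self):
        rng = np.random.default_rng(0)
        field = _uniform_field(0.0)
        field.values[:] = rng.normal(0, 30, field.values.shape)
        kef = compute_ke_field(field)
        a = np.zeros((4, 4, 4, 2), dtype=bool)
        b = np.zeros((4, 4, 4, 2), dtype=bool)
        a[:2], b[2:] = True, True
        s = sum_region_ke(kef, MaskSeries("lv", a | b))
        sa = sum_region_ke(kef, MaskSeries("lv", a))
        sb = sum_region_ke(kef, MaskSeries("lv", b))
        np.testing.assert_allclose(s, sa + sb, rtol=1e-12)


class TestHillVortexEnergy:
    def test_discrete_ke_converges_to_closed_form(self):
        # voxel-sum KE inside the sphere vs the closed-form interior energy;
        # per-halving error ratio measured across two halvings of the spacing
        a_mm, U = 20.0, 30.0
        exact = hill_vortex_ke(a_mm, U)
        errs = []
        for h in (3.0, 1.5, 0.75):
            n = int(np.ceil(64 / h))
            field = make_hill_vortex(
                shape=(n, n, n), spacing=(h, h, h), a_mm=a_mm, U_cm_s=U, n_phases=2)
            kef = compute_ke_field(field)
            pts = np.stack(np.meshgrid(
                *[np.arange(n) * h for _ in range(3)], indexing="ij"), axis=-1)
            center = np.full(3, (n - 1) * h / 2)
            inside = np.sum((pts - center) ** 2, axis=-1) < a_mm**2
            ke = kef.ke[..., 0][inside].sum()
            errs.append(abs(ke - exact))
        assert errs[0] > errs[1] > errs[2]
        per_halving = np.sqrt(errs[0] / errs[2])
        assert per_halving >= 3.0
        assert errs[2] / exact < 0.01


class TestVortexPartition:
    def _setup(self, vortex_frac=0.4):
        rng = np.random.default_rng(1)
        field = _uniform_field(0.0, shape=(10, 10, 10))
        field.values[:] = rng.normal(0, 40, field.values.shape)
        kef = compute_ke_field(field)
        lv = np.zeros((10, 10, 10, 2), dtype=bool)
        lv[1:9, 1:9, 1:9] = True
        vx = np.zeros_like(lv)
        n_lv = lv[..., 0].sum()
        idx = np.argwhere(lv[..., 0])[: int(round(vortex_frac * n_lv))]
        for t in range(2):
            vx[idx[:, 0], idx[:, 1], idx[:, 2], t] = True
        return kef, MaskSeries("lv", lv), MaskSeries("vortex", vx)

    def test_conservation_exact(self):
        kef, lv, vx = self._setup()
        curve = partition_vortex_ke(kef, lv, vx)
        # bitwise: inside + outside equals total on vortex phases
        assert np.all(curve.inside + curve.outside == curve.total)

    def test_vortex_equals_lv_gives_zero_outside(self):
        kef, lv, _ = self._setup()
        curve = partition_vortex_ke(kef, lv, MaskSeries("vortex", lv.masks.copy()))
        np.testing.assert_array_equal(curve.outside, 0.0)

    def test_uniform_ke_fraction_matches_voxel_fraction(self):
        field = _uniform_field(50.0, shape=(10, 10, 10))
        kef = compute_ke_field(field)
        _, lv, vx = self._setup(vortex_frac=0.4)
        curve = partition_vortex_ke(kef, lv, vx)
        frac = vx.masks[..., 0].sum() / lv.masks[..., 0].sum()
        np.testing.assert_allclose(curve.inside / curve.total, frac, rtol=1e-12)

    def test_containment_violation_rejected(self):
        kef, lv, vx = self._setup()
        bad = vx.masks.copy()
        bad[0, 0, 0, 1] = True  # outside LV
        with pytest.raises(ValueError, match="phase 1"):
            partition_vortex_ke(kef, lv, MaskSeries("vortex", bad))


def _simple_phases(n=40, es=16):
    sys_idx = np.arange(0, es)
    dia_idx = np.arange(es, n)
    return CardiacPhases(systole=sys_idx, diastole=dia_idx,
                         e_wave=dia_idx[:8], diastasis=dia_idx[8:12],
                         a_wave=dia_idx[12:])


def _vols():
    return VolumetricsSummary(edv=200.0, esv=100.0, sv=100.0, ef=50.0,
                              per=400.0, pfr=400.0, ed_index=0, es_index=16)


class TestSummaries:
    def test_constant_curve_flat_summaries(self):
        curve = KECurve(time=np.arange(40) * 25.0, total=np.full(40, 2.5))
        s = summarize_ke(curve, _simple_phases(), _vols())
        assert s.sys_avg == s.dia_avg == 2.5
        assert s.cv == 0.0
        assert s.vortex_fraction is None  # undefined without a vortex, not zero

    def test_indexed_units(self):
        curve = KECurve(time=np.arange(40) * 25.0, total=np.full(40, 2.0))
        s = summarize_ke(curve, _simple_phases(), _vols())
        # 2.0 mJ averaged over 200 ml EDV -> 10.0 uJ/ml
        assert s.dia_avg_per_edv == pytest.approx(10.0)
        assert s.dia_avg_per_sv == pytest.approx(20.0)

    def test_cv_sample_sd(self):
        total = np.zeros(40)
        total[::2] = 2.0  # mean 1, sample SD just above 1
        curve = KECurve(time=np.arange(40) * 25.0, total=total)
        s = summarize_ke(curve, _simple_phases(), _vols())
        expected = np.std(total, ddof=1) / total.mean()
        assert s.cv == pytest.approx(expected, rel=1e-12)

    def test_delta_ke_signed_max_change(self):
        assert signed_max_change(np.array([1.0, 3.0, 2.0])) == 2.0
        assert signed_max_change(np.array([10.0, 30.0, 20.0])) == 20.0
        assert signed_max_change(np.array([5.0, 1.0, 4.0])) == -4.0

    def test_vortex_fraction_of_uniform_split(self):
        n = 40
        inside = np.full(n, np.nan)
        outside = np.full(n, np.nan)
        total = np.full(n, 5.0)
        dia = _simple_phases().diastole
        inside[dia] = 2.0
        outside[dia] = 3.0
        curve = KECurve(time=np.arange(n) * 25.0, total=total,
                        inside=inside, outside=outside)
        s = summarize_ke(curve, _simple_phases(), _vols())
        assert s.vortex_fraction == pytest.approx(40.0)

    def test_summary_invariant_to_consistent_phase_roll(self):
        curve, phases, _ = make_ke_curve("control_like", seed=4)
        vols = _vols()
        s0 = summarize_ke(curve, phases, vols)
        shift = 7
        n = len(curve.total)
        rolled = KECurve(time=curve.time, total=np.roll(curve.total, shift))
        rphases = CardiacPhases(
            systole=(phases.systole + shift) % n,
            diastole=(phases.diastole + shift) % n,
            e_wave=(phases.e_wave + shift) % n,
            diastasis=(phases.diastasis + shift) % n,
            a_wave=(phases.a_wave + shift) % n,
        )
        s1 = summarize_ke(rolled, rphases, vols)
        assert s1.sys_avg == pytest.approx(s0.sys_avg)
        assert s1.dia_avg == pytest.approx(s0.dia_avg)
        assert s1.cv == pytest.approx(s0.cv)
        assert s1.dia_peak == pytest.approx(s0.dia_peak)

    def test_zero_sv_rejected(self):
        curve = KECurve(time=np.arange(40) * 25.0, total=np.full(40, 2.0))
        vols = _vols()
        vols.sv = 0.0
        with pytest.raises(ValueError, match="SV"):
            summarize_ke(curve, _simple_phases(), vols)
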