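import numpy as np
import pytest

from lvke.flow_io import MaskSeries, VelocityField4D
from lvke.preprocess import (
    apply_background_correction,
    fit_background,
    resample_phases,
    unwrap_velocity,
    voxel_coordinates_mm,
)
from lvke.synthetic_data import wrap_velocities


def _series_field(series, venc=100.0):
    """One-voxel-thick field whose z-component follows ``series`` in time."""
    nt = len(series)
    values = np.zeros((3, 3, 3, nt, 3))
    values[1, 1, 1, :, 2] = series
    return VelocityField4D(
        values=values, spacing=(3.0, 3.0, 3.0),
        timestamps=np.arange(nt) * 50.0, rr_ms=1000.0, venc=venc,
    )


class TestUnwrap:
    def test_single_wrapped_sample_restored(self):
        # true series exceeds venc at one phase; the wrap model maps 120 -> -80
        true = np.array([0.0, 90.0, 120.0, 90.0, 0.0])
        field = _series_field(wrap_velocities(true, 100.0))
        assert field.values[1, 1, 1, 2, 2] == -80.0
        out, wc = unwrap_velocity(field)
        np.testing.assert_allclose(out.values[1, 1, 1, :, 2], true, atol=1e-12)
        assert wc[1, 1, 1] == 1

    def test_below_venc_is_identity(self):
        # speeds below venc and consecutive jumps below venc: nothing to do
        field = _series_field([0.0, 50.0, -40.0, 20.0])
        out, wc = unwrap_velocity(field)
        np.testing.assert_array_equal(out.values, field.values)
        assert wc.sum() == 0

    def test_constant_alias_not_recoverable(self):
        # a wrap present at every phase produces no temporal jump: documented
        # limitation of temporal unwrapping
        true = np.full(5, 120.0)
        field = _series_field(wrap_velocities(true, 100.0))
        out, wc = unwrap_velocity(field)
        np.testing.assert_array_equal(out.values[1, 1, 1, :, 2], np.full(5, -80.0))
        assert wc.sum() == 0

    def test_corrections_are_multiples_of_two_venc(self):
        rng = np.random.default_rng(7)
        true = np.cumsum(rng.normal(0, 60, 12))
        field = _series_field(wrap_velocities(true, 100.0))
        out, _ = unwrap_velocity(field)
        k = (out.values - field.values) / (2 * field.venc)
        np.testing.assert_allclose(k, np.round(k), atol=1e-12)

    def test_two_phase_field_refused(self):
        field = _series_field([0.0, 10.0])
        with pytest.raises(ValueError, match="3 phases"):
            unwrap_velocity(field)


def _stationary_box(field):
    masks = np.zeros(field.grid_shape + (field.nt,), dtype=bool)
    masks[1:5, 1:5, 1:5, :] = True
    return MaskSeries("stationary", masks)


def _field_with_affine_background(coeffs, n=8, nt=3):
    """Velocity = a + b x + c y + d z (mm) per component, identical phases."""
    field = VelocityField4D(
        values=np.zeros((n, n, n, nt, 3)), spacing=(4.0, 4.0, 4.0),
        timestamps=np.arange(nt) * 100.0, rr_ms=1000.0, venc=100.0,
    )
    coords = voxel_coordinates_mm(field)
    design = np.concatenate([np.ones(coords.shape[:3] + (1,)), coords], axis=-1)
    bg = design @ np.asarray(coeffs).T  # (n,n,n,3)
    field.values += bg[:, :, :, None, :]
    return field


class TestBackgroundFit:
    COEFFS = np.array([
        [2.0, 0.1, 0.0, 0.0],
        [-1.0, 0.0, 0.05, 0.0],
        [0.5, -0.02, 0.0, 0.03],
    ])

    def test_exact_affine_field_recovered(self):
        field = _field_with_affine_background(self.COEFFS)
        model = fit_background(field, _stationary_box(field))
        np.testing.assert_allclose(
            model.coeffs, np.broadcast_to(self.COEFFS, (3, 3, 4)), atol=1e-10)

    def test_zero_velocities_give_zero_coefficients(self):
        field = _field_with_affine_background(np.zeros((3, 4)))
        model = fit_background(field, _stationary_box(field))
        np.testing.assert_allclose(model.coeffs, 0.0, atol=1e-12)

    def test_coplanar_stationary_voxels_rejected(self):
        field = _field_with_affine_background(self.COEFFS)
        masks = np.zeros(field.grid_shape + (field.nt,), dtype=bool)
        masks[1:6, 1:6, 3, :] = True  # single z-plane
        with pytest.raises(ValueError, match="phase 0"):
            fit_background(field, MaskSeries("stationary", masks))

    def test_too_few_stationary_voxels_rejected(self):
        field = _field_with_affine_background(self.COEFFS)
        masks = np.zeros(field.grid_shape + (field.nt,), dtype=bool)
        masks[1:3, 1:3, 1:3, :] = True  # 8 voxels
        with pytest.raises(ValueError, match=">= 16"):
            fit_background(field, MaskSeries("stationary", masks))

    def test_correction_zeroes_stationary_mean_and_is_idempotent(self):
        rng = np.random.default_rng(3)
        field = _field_with_affine_background(self.COEFFS)
        field.values += rng.normal(0, 1.0, field.values.shape)
        stationary = _stationary_box(field)
        model = fit_background(field, stationary)
        corr = apply_background_correction(field, model)
        # least-squares residual has zero mean over the fitted voxels
        resid = corr.values[stationary.masks[..., 0]]
        assert np.abs(resid.mean(axis=0)).max() < 1e-10
        # refit on corrected data is (numerically) the zero model
        model2 = fit_background(corr, stationary)
        corr2 = apply_background_correction(corr, model2)
        assert np.abs(corr2.values - corr.values).max() < 1e-9

    def test_correction_never_increases_stationary_rms(self):
        rng = np.random.default_rng(11)
        field = _field_with_affine_background(self.COEFFS)
        field.values += rng.normal(0, 2.0, field.values.shape)
        stationary = _stationary_box(field)
        corr = apply_background_correction(field, fit_background(field, stationary))
        for t in range(field.nt):
            before = np.sqrt((field.values[..., t, :][stationary.masks[..., t]] ** 2).mean())
            after = np.sqrt((corr.values[..., t, :][stationary.masks[..., t]] ** 2).mean())
            assert after <= before + 1e-12

    def test_zero_model_is_identity(self):
        from lvke.preprocess import BackgroundModel

        field = _field_with_affine_background(self.COEFFS)
        model = BackgroundModel(coeffs=np.zeros((field.nt, 3, 4)))
        out = apply_background_correction(field, model)
        np.testing.assert_array_equal(out.values, field.values)

    def test_model_json_round_trip(self, tmp_path):
        from lvke.preprocess import BackgroundModel

        field = _field_with_affine_background(self.COEFFS)
        model = fit_background(field, _stationary_box(field))
        model.to_json(tmp_path / "bg.json")
        back = BackgroundModel.from_json(tmp_path / "bg.json")
        np.testing.assert_allclose(back.coeffs, model.coeffs, rtol=1e-12)


class TestResample:
    def test_constant_field_unchanged(self):
        field = _series_field([5.0] * 10)
        out = resample_phases(field, 40)
        assert out.nt == 40
        np.testing.assert_allclose(out.values[1, 1, 1, :, 2], 5.0)

    def test_matching_grid_is_identity(self):
        field = _series_field(np.sin(np.arange(20)))
        out = resample_phases(field, 20)
        np.testing.assert_array_equal(out.values, field.values)

    def test_sinusoid_within_linear_interpolation_error(self):
        # one full period sampled at 10 phases; the piecewise-linear
        # interpolant of a sinusoid has max error (w h)^2 / 8
        rr = 1000.0
        t10 = np.arange(10) * rr / 10
        series = np.sin(2 * np.pi * t10 / rr)
        field = _series_field(series)
        field.timestamps = t10
        out = resample_phases(field, 40)
        expected = np.sin(2 * np.pi * out.timestamps / rr)
        w = 2 * np.pi / (rr / 1000.0)
        h = (rr / 10) / 1000.0
        bound = (w * h) ** 2 / 8
        err = np.abs(out.values[1, 1, 1, :, 2] - expected).max()
        assert err <= bound

    def test_temporal_mean_preserved_for_uniform_grids(self):
        rng = np.random.default_rng(5)
        series = rng.normal(size=8)
        field = _series_field(series)
        field.timestamps = np.arange(8) * 125.0
        out = resample_phases(field, 40)  # refinement of the same uniform grid
        # trapezoidal (periodic) mean of the linear interpolant is preserved
        assert abs(out.values[1, 1, 1, :, 2].mean() - series.mean()) < 1e-12

    def test_single_target_phase_rejected(self):
        with pytest.raises(ValueError, match="n_target"):
            resample_phases(_series_field([0, 1, 2, 3.0]), 1)
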