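import numpy as np
import pandas as pd
import pytest

from boldcvr import (
    BoldSeries,
    MotionTrajectory,
    RealignConfig,
    RigidTransform,
    estimate_rigid,
    generate_subject,
    motion_qc,
    realign_series,
    smooth_gaussian,
)
from boldcvr._transforms import resample_volume
from boldcvr.realign import fwhm_to_sigma


@pytest.fixture(scope="module")
def structured_volume(small_atlas):
    """One noise-free structured volume in the small test geometry."""
    series, _ = generate_subject(
        small_atlas, {}, seed=0, n_volumes=1,
        noise=None,
    )
    return series.data[..., 0], small_atlas.geometry


class TestRigidTransform:
    def test_identity_is_all_zero(self):
        assert not np.any(RigidTransform.identity().params)

    @pytest.mark.parametrize("seed", range(4))
    def test_compose_inverse_is_identity(self, seed):
        rng = np.random.default_rng(seed)
        t = RigidTransform(*rng.uniform(-1, 1, 3), *rng.uniform(-0.3, 0.3, 3))
        round_trip = t.compose(t.inverse())
        np.testing.assert_allclose(round_trip.params, 0.0, atol=1e-12)

    def test_composition_matches_matrices(self):
        a = RigidTransform(0.5, -0.2, 0.1, 0.1, -0.05, 0.2)
        b = RigidTransform(-0.3, 0.4, 0.0, -0.2, 0.1, 0.05)
        c = a.compose(b)
        np.testing.assert_allclose(c.rotation, a.rotation @ b.rotation,
                                   atol=1e-12)
        np.testing.assert_allclose(
            c.translation, a.rotation @ b.translation + a.translation,
            atol=1e-12,
        )


class TestEstimateRigid:
    def test_identity_for_equal_volumes(self, structured_volume):
        vol, geo = structured_volume
        t = estimate_rigid(vol, vol, geo)
        assert np.abs(t.translation).max() < 0.01
        assert np.abs(t.params[3:]).max() < 0.001

    def test_recovers_one_voxel_translation(self, structured_volume):
        vol, geo = structured_volume
        shift = np.array([geo.voxel_size[0], 0.0, 0.0])  # 1 in-plane voxel
        moved = resample_volume(vol, np.eye(3), shift, geo.voxel_size, order=1)
        t = estimate_rigid(moved, vol, geo)
        # pull convention: the fitted transform maps reference into the moved
        # frame, so it should equal the injected shift inverted
        np.testing.assert_allclose(-t.translation, shift, atol=0.03)

    def test_recovers_two_degree_rotation(self, structured_volume):
        vol, geo = structured_volume
        from boldcvr._transforms import rotation_matrix

        rz = np.deg2rad(2.0)
        moved = resample_volume(vol, rotation_matrix(0, 0, rz),
                                np.zeros(3), geo.voxel_size, order=1)
        t = estimate_rigid(moved, vol, geo)
        assert abs(np.rad2deg(-t.rz) - 2.0) < 0.2

    @pytest.mark.parametrize("seed", range(3))
    def test_estimate_then_compose_is_identity(self, structured_volume, seed):
        """estimate(T(x), x) composed with T ~ identity for random small T."""
        vol, geo = structured_volume
        rng = np.random.default_rng(seed)
        true = RigidTransform(
            *(rng.uniform(-1, 1, 3) * np.asarray(geo.voxel_size)),
            *rng.uniform(-np.deg2rad(3), np.deg2rad(3), 3),
        )
        moved = resample_volume(vol, true.rotation, true.translation,
                                geo.voxel_size, order=1)
        est = estimate_rigid(moved, vol, geo)
        resid = est.compose(true)  # should be ~identity
        assert np.abs(resid.translation).max() < 0.05
        # out-of-plane rotations are weakly determined on a thin (10-slice)
        # volume, so the rotation residual bound is looser than the pinned
        # pure-rotation case above
        assert np.abs(resid.params[3:]).max() < 0.015

    def test_flat_reference_rejected(self, structured_volume):
        vol, geo = structured_volume
        with pytest.raises(ValueError, match="zero variance"):
            estimate_rigid(vol, np.zeros_like(vol), geo)


class TestRealignSeries:
    def test_motion_free_series_stays_still(self, small_atlas):
        series, _ = generate_subject(small_atlas, {}, seed=1, n_volumes=6)
        out, table = realign_series(series, RealignConfig())
        assert np.abs(table[["tx", "ty", "tz"]].to_numpy()).max() < 0.02
        assert out.data.shape == series.data.shape

    def test_recovers_sinusoidal_trajectory(self, small_atlas):
        traj = MotionTrajectory.sinusoidal(10, amplitude_mm=0.07, axis=0,
                                           period=5.0)
        series, _ = generate_subject(small_atlas, {}, motion=traj, seed=2,
                                     n_volumes=10)
        _, table = realign_series(series)
        est = table[["tx", "ty", "tz"]].to_numpy()
        resid = est - traj.params[:, :3]
        resid -= resid.mean(axis=0)  # trajectory identified up to an offset
        rms = float(np.sqrt((resid**2).mean()))
        assert rms < 0.02

    def test_single_volume_rejected(self, small_atlas):
        series, _ = generate_subject(small_atlas, {}, seed=0, n_volumes=1)
        with pytest.raises(ValueError, match="at least 2"):
            realign_series(series)


class TestSmoothing:
    def test_zero_fwhm_is_identity(self, tiny_atlas):
        series, _ = generate_subject(tiny_atlas, {}, seed=0, n_volumes=3)
        out = smooth_gaussian(series, 0.0)
        np.testing.assert_array_equal(out.data, series.data)

    def test_constant_volume_unchanged(self, tiny_atlas):
        data = np.full((*tiny_atlas.geometry.dims, 2), 7.0)
        series = BoldSeries(tiny_atlas.geometry.with_volumes(2), data)
        out = smooth_gaussian(series, 0.8)
        np.testing.assert_allclose(out.data, 7.0, rtol=1e-12)

    def test_impulse_response_variance(self):
        """Discrete kernel variance matches sigma^2 within 2% (0.8 mm FWHM)."""
        from boldcvr.io import VolumeGeometry

        geo = VolumeGeometry((41, 41, 41), (0.3125, 0.3125, 0.3125), tr=1.0,
                             n_volumes=1)
        data = np.zeros(geo.shape4d)
        data[20, 20, 20, 0] = 1.0
        out = smooth_gaussian(BoldSeries(geo, data), 0.8).data[..., 0]
        x_mm = (np.arange(41) - 20) * 0.3125
        marginal = out.sum(axis=(1, 2))
        var = float((marginal * x_mm**2).sum() / marginal.sum())
        assert var == pytest.approx(fwhm_to_sigma(0.8) ** 2, rel=0.02)

    def test_mean_preserved_with_reflective_boundaries(self, tiny_atlas):
        series, _ = generate_subject(tiny_atlas, {}, seed=4, n_volumes=2)
        out = smooth_gaussian(series, 0.8)
        for t in range(2):
            before = series.data[..., t].mean()
            after = out.data[..., t].mean()
            assert abs(after - before) / before < 0.005

    def test_negative_fwhm_rejected(self, tiny_atlas):
        series, _ = generate_subject(tiny_atlas, {}, seed=0, n_volumes=2)
        with pytest.raises(ValueError):
            smooth_gaussian(series, -1.0)


class TestMotionQC:
    @staticmethod
    def _table(displacements):
        n = len(displacements)
        return pd.DataFrame(
            {
                "volume": np.arange(1, n + 1),
                "tx": displacements, "ty": 0.0, "tz": 0.0,
                "rx": 0.0, "ry": 0.0, "rz": 0.0,
                "displacement": np.abs(displacements),
            }
        )

    def test_observed_range_passes(self):
        report = motion_qc(self._table(np.linspace(0.027, 0.070, 20)))
        assert report.passed
        assert report.max_displacement_mm == pytest.approx(0.070)

    def test_single_large_displacement_fails_with_volume(self):
        disp = np.zeros(10)
        disp[6] = 0.4
        report = motion_qc(self._table(disp), max_pixels=1.0)
        assert not report.passed
        assert report.offending_volumes == [7]

    def test_identity_motion_passes_with_zero_summary(self):
        report = motion_qc(self._table(np.zeros(5)))
        assert report.passed
        assert report.max_displacement_mm == 0.0
        assert report.offending_volumes == []

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            motion_qc(self._table(np.zeros(0)))
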