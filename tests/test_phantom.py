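import numpy as np
import pytest

from boldcvr import (
    MotionTrajectory,
    NoiseModel,
    ResponseProfile,
    generate_cohort,
    generate_subject,
    response_curve,
)


class TestResponseCurve:
    def test_boxcar(self):
        prof = ResponseProfile(amplitude=2.0, onset_volume=4, offset_volume=6,
                               ramp_tau=0.0)
        r = response_curve(prof, 10)
        expected = np.array([0, 0, 0, 2, 2, 2, 0, 0, 0, 0], dtype=float)
        np.testing.assert_allclose(r, expected)

    def test_ramp_approaches_plateau(self):
        prof = ResponseProfile(amplitude=3.0, onset_volume=11, offset_volume=60,
                               ramp_tau=3.0)
        r = response_curve(prof, 80)
        assert r[:10].max() == 0
        assert r[59] == pytest.approx(3.0, abs=1e-5)  # ~50 volumes past onset
        assert 0 < r[10] < 3.0

    def test_sustained_offset(self):
        prof = ResponseProfile(amplitude=3.0, onset_volume=3, offset_volume=5,
                               ramp_tau=0.0, sustain_offset=1.0)
        r = response_curve(prof, 12)
        np.testing.assert_allclose(r[5:], 1.0)  # instant relax to sustain

    def test_bump(self):
        prof = ResponseProfile(amplitude=0.0, bump_amplitude=1.5,
                               bump_window=(8, 9), onset_volume=2,
                               offset_volume=4)
        r = response_curve(prof, 10)
        np.testing.assert_allclose(r[7:9], 1.5)
        assert r[[0, 5, 9]].max() == 0

    def test_invalid_windows_rejected(self):
        with pytest.raises(ValueError):
            ResponseProfile(onset_volume=10, offset_volume=5)
        with pytest.raises(ValueError):
            response_curve(ResponseProfile(offset_volume=100), n_volumes=50)


class TestGenerateSubject:
    def test_null_phantom_constant(self, tiny_atlas, quiet_noise):
        series, _ = generate_subject(
            tiny_atlas, {}, noise=quiet_noise, seed=0, n_volumes=12
        )
        tissue = tiny_atlas.brain_mask
        per_voxel_range = np.ptp(series.data[tissue], axis=1)
        assert per_voxel_range.max() == 0.0
        assert np.all(series.data[~tissue] == 0)

    def test_noiseless_boxcar_exact_percent(self, tiny_atlas, quiet_noise):
        prof = ResponseProfile(amplitude=2.0, onset_volume=6, offset_volume=10,
                               ramp_tau=0.0)
        series, truth = generate_subject(
            tiny_atlas, {"ctx_01": prof}, noise=quiet_noise, seed=0,
            n_volumes=15,
        )
        vox = tiny_atlas.labels == tiny_atlas.label_of("ctx_01")
        x = series.data[vox]
        pct = 100.0 * (x - x[:, :5].mean(axis=1, keepdims=True)) / x[
            :, :5
        ].mean(axis=1, keepdims=True)
        np.testing.assert_allclose(pct[:, 5:10], 2.0, atol=1e-12)
        assert truth.total_responders == int(vox.sum())

    def test_determinism(self, tiny_atlas):
        a, _ = generate_subject(tiny_atlas, {}, seed=42, n_volumes=10)
        b, _ = generate_subject(tiny_atlas, {}, seed=42, n_volumes=10)
        np.testing.assert_array_equal(a.data, b.data)

    def test_unknown_region_rejected(self, tiny_atlas):
        with pytest.raises(KeyError, match="nowhere"):
            generate_subject(tiny_atlas, {"nowhere": ResponseProfile(1.0)})

    def test_motion_length_mismatch_rejected(self, tiny_atlas):
        with pytest.raises(ValueError, match="trajectory"):
            generate_subject(
                tiny_atlas, {}, motion=MotionTrajectory.none(5), n_volumes=10
            )

    def test_ar1_autocorrelation_matches_analytic(self, tiny_atlas):
        """Sample lag-1 autocorrelation over 100 seeds ~ rho (analytic AR(1))."""
        noise = NoiseModel(sigma=5.0, rho=0.4, drift_per_volume=0.0)
        vox = np.argwhere(tiny_atlas.brain_mask)[0]
        acs = []
        for seed in range(100):
            series, _ = generate_subject(
                tiny_atlas, {}, noise=noise, seed=seed, n_volumes=200
            )
            x = series.data[tuple(vox)]
            x = x - x.mean()
            acs.append((x[:-1] * x[1:]).sum() / (x * x).sum())
        assert np.mean(acs) == pytest.approx(0.4, abs=0.1)

    def test_noise_variance_matches_stationary_ar1(self, tiny_atlas):
        """Empirical variance ~ sigma^2/(1-rho^2) within 5% at 1e4 samples."""
        noise = NoiseModel(sigma=5.0, rho=0.4, drift_per_volume=0.0)
        series, _ = generate_subject(
            tiny_atlas, {}, noise=noise, seed=3, n_volumes=100
        )
        x = series.data[tiny_atlas.brain_mask]
        resid = x - x.mean(axis=1, keepdims=True)
        n = resid.shape[0] * (resid.shape[1] - 1)
        assert n > 10_000
        var = (resid**2).sum() / n
        expected = 25.0 / (1 - 0.16)
        assert var == pytest.approx(expected, rel=0.05)

    def test_true_voa_conservation(self, tiny_atlas):
        profs = {
            "ctx": ResponseProfile(3.0, onset_volume=3, offset_volume=6),
            "sub_01": ResponseProfile(0.5, onset_volume=3, offset_volume=6),
        }
        _, truth = generate_subject(tiny_atlas, profs, seed=0, n_volumes=10)
        assert sum(truth.true_voa.values()) == truth.total_responders
        assert truth.true_voa["sub_01"] == 0  # below the 1% threshold


class TestMotionTrajectory:
    def test_realistic_within_observed_range(self):
        for seed in range(5):
            traj = MotionTrajectory.realistic(50, seed=seed)
            assert 0.027 <= traj.max_displacement <= 0.070

    def test_rejected_preset_exceeds_one_pixel(self):
        traj = MotionTrajectory.rejected(20, displaced_volume=7)
        assert traj.max_displacement > 0.3125
        assert traj.displacements[6] == pytest.approx(0.4)


class TestGenerateCohort:
    def test_cohort_layout_and_determinism(self, tiny_atlas, tmp_path):
        profiles = {
            "sham": {"ctx": ResponseProfile(3.0, onset_volume=3, offset_volume=6)},
            "injured": {"ctx": ResponseProfile(1.5, onset_volume=3, offset_volume=6)},
        }
        kw = dict(
            atlas=tiny_atlas, condition_profiles=profiles, n_per_group=2,
            seed=7, n_volumes=8,
        )
        m1, t1 = generate_cohort(out_dir=tmp_path / "a", **kw)
        m2, _ = generate_cohort(out_dir=tmp_path / "b", **kw)
        assert len(m1.table) == 4
        assert sorted(m1.table["condition"]) == ["injured"] * 2 + ["sham"] * 2
        for sid in m1.subjects:
            p1 = m1.path_of(sid).read_bytes()
            p2 = (tmp_path / "b" / m1.path_of(sid).name).read_bytes()
            assert p1 == p2, f"{sid} not byte-identical across reruns"
        assert (tmp_path / "a" / "ground_truth.json").exists()
        assert (tmp_path / "a" / "phantom_params.yaml").exists()

    def test_fourteen_subject_design(self, tiny_atlas, tmp_path):
        m, truths = generate_cohort(
            tiny_atlas, {"sham": {}, "injured": {}}, n_per_group=7,
            out_dir=tmp_path, seed=0, n_volumes=4,
        )
        assert len(m.table) == 14
        assert (m.table["condition"] == "sham").sum() == 7
        assert len(truths) == 14

    def test_identical_profiles_give_identical_truth(self, tiny_atlas, tmp_path):
        prof = {"ctx": ResponseProfile(2.0, onset_volume=2, offset_volume=3)}
        _, truths = generate_cohort(
            tiny_atlas, {"sham": prof, "injured": prof}, n_per_group=1,
            out_dir=tmp_path, seed=1, n_volumes=4,
        )
        assert truths["sham_01"].true_voa == truths["injured_01"].true_voa
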