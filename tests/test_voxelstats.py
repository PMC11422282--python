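import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from boldcvr import (
    NoiseModel,
    ResponseProfile,
    WindowDesign,
    activation_map,
    analyze_subject,
    fdr_filter,
    generate_subject,
    percent_change,
    voxel_window_test,
)


from tests_oracles import bh_step_up as bh_oracle, welch_oracle


class TestPercentChange:
    def test_constant_series_all_zero(self):
        design = WindowDesign((1, 4), (5, 8), None)
        data = np.full((2, 2, 1, 8), 1000.0)
        mask = np.ones((2, 2, 1), dtype=bool)
        pct, valid = percent_change(data, design, mask)
        np.testing.assert_array_equal(pct, 0.0)
        assert valid.all()

    def test_two_percent_step(self):
        design = WindowDesign((1, 4), (5, 8), None)
        data = np.full((1, 1, 1, 8), 1000.0)
        data[..., 4:] = 1020.0
        pct, _ = percent_change(data, design, np.ones((1, 1, 1), bool))
        np.testing.assert_allclose(pct[0, 0, 0, 4:], 2.0)
        np.testing.assert_allclose(pct[0, 0, 0, :4], 0.0)

    def test_baseline_window_mean_is_zero(self):
        design = WindowDesign((1, 5), (6, 10), None)
        rng = np.random.default_rng(0)
        data = 500 + rng.uniform(0, 50, (3, 3, 2, 10))
        pct, valid = percent_change(data, design, np.ones((3, 3, 2), bool))
        np.testing.assert_allclose(pct[..., :5].mean(axis=-1), 0.0, atol=1e-10)

    def test_nonpositive_baseline_dropped(self, caplog):
        design = WindowDesign((1, 4), (5, 8), None)
        data = np.full((2, 1, 1, 8), 100.0)
        data[1] = -5.0
        pct, valid = percent_change(data, design, np.ones((2, 1, 1), bool))
        assert valid[0, 0, 0] and not valid[1, 0, 0]

    def test_noiseless_phantom_recovers_amplitude(self, tiny_atlas, quiet_noise):
        design = WindowDesign((1, 10), (11, 20), (21, 30))
        prof = ResponseProfile(amplitude=2.0, onset_volume=11, offset_volume=20,
                               ramp_tau=0.0)
        series, truth = generate_subject(
            tiny_atlas, {"ctx": prof}, noise=quiet_noise, seed=0, n_volumes=30
        )
        pct, valid = percent_change(series, design, tiny_atlas.brain_mask)
        responders = truth.responder_mask
        window_mean = pct[..., design.challenge_slice].mean(axis=-1)
        np.testing.assert_allclose(window_mean[responders], 2.0, atol=1e-9)


class TestWindowTest:
    def test_identical_windows_null(self):
        design = WindowDesign((1, 4), (5, 8), None)
        x = np.tile([1.0, 2.0, 3.0, 4.0], 2)[np.newaxis, :]
        delta, t, p, deg = voxel_window_test(x, design)
        assert t[0] == 0.0 and p[0] == 1.0 and not deg[0]

    def test_zero_variance_unequal_means_degenerate(self):
        design = WindowDesign((1, 4), (5, 8), None)
        x = np.array([[0.0, 0, 0, 0, 2, 2, 2, 2]])
        delta, t, p, deg = voxel_window_test(x, design)
        assert deg[0] and p[0] == 0.0 and np.isinf(t[0])
        assert delta[0] == pytest.approx(2.0)

    def test_matches_textbook_welch(self):
        base = [0.1, -0.2, 0.05, 0.0, 0.1]
        chal = [1.9, 2.2, 2.0, 1.8, 2.1]
        design = WindowDesign((1, 5), (6, 10), None)
        x = np.array([base + chal])
        delta, t, p, _ = voxel_window_test(x, design)
        t_exp, p_exp = welch_oracle(chal, base)
        assert t[0] == pytest.approx(t_exp, abs=1e-10)
        assert p[0] == pytest.approx(p_exp, abs=1e-10)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_scipy_welch(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((4, 20))
        design = WindowDesign((1, 10), (11, 20), None)
        delta, t, p, _ = voxel_window_test(x, design)
        ref = stats.ttest_ind(x[:, 10:], x[:, :10], axis=1, equal_var=False)
        np.testing.assert_allclose(t, ref.statistic, atol=1e-12)
        np.testing.assert_allclose(p, ref.pvalue, atol=1e-12)

    def test_window_validation(self):
        with pytest.raises(ValueError, match="disjoint"):
            WindowDesign((1, 50), (40, 100), None)
        with pytest.raises(ValueError, match="fewer than 2"):
            WindowDesign((1, 1), (2, 10), None)
        with pytest.raises(ValueError, match="series has"):
            voxel_window_test(np.zeros((1, 60)), WindowDesign((1, 50), (51, 100)))


class TestFdrFilter:
    def test_spec_example(self):
        p = np.array([0.01, 0.02, 0.04, 0.5])
        reject = fdr_filter(p, q=0.05)
        np.testing.assert_array_equal(reject, [True, True, False, False])

    def test_all_extremes(self):
        assert not fdr_filter(np.ones(10), q=0.05).any()
        assert fdr_filter(np.zeros(10), q=0.05).all()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 40))
    def test_matches_brute_force_step_up(self, seed, m):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, m) ** 2
        np.testing.assert_array_equal(fdr_filter(p, 0.05), bh_oracle(p, 0.05))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fdr_filter(np.array([0.5]), mask=np.array([False]))

    def test_bh_calibrated_on_valid_pvalues(self):
        """Mean realized FDP of BH on independent uniform nulls stays <= q."""
        rng = np.random.default_rng(0)
        fdps = []
        for _ in range(300):
            p = rng.uniform(0, 1, 2000)
            r = fdr_filter(p, q=0.05)
            fdps.append(1.0 if r.any() else 0.0)
        assert np.mean(fdps) <= 0.05 + 2 * np.std(fdps) / np.sqrt(len(fdps))


class TestActivationMap:
    @pytest.mark.parametrize(
        "delta,rejected,expected",
        [(2.0, True, True), (0.5, True, False), (-3.0, True, False),
         (2.0, False, False)],
    )
    def test_conjunction_rule(self, delta, rejected, expected):
        out = activation_map(np.array([delta]), np.array([rejected]), 1.0)
        assert bool(out[0]) is expected

    def test_gain_invariance(self, tiny_atlas):
        """Activation is unchanged by affine intensity rescaling of the raw
        series (percent change removes the gain)."""
        design = WindowDesign((1, 10), (11, 20), (21, 30))
        prof = ResponseProfile(amplitude=3.0, onset_volume=11, offset_volume=20)
        noise = NoiseModel(sigma=10.0, rho=0.2, drift_per_volume=0.0)
        series, _ = generate_subject(
            tiny_atlas, {"ctx": prof}, noise=noise, seed=5, n_volumes=30
        )
        r1 = analyze_subject(series.data, design, tiny_atlas.brain_mask)
        r2 = analyze_subject(series.data * 3.7, design, tiny_atlas.brain_mask)
        np.testing.assert_array_equal(r1.activated, r2.activated)

    def test_power_at_snr_one(self, small_atlas):
        """>= 95% of true responders detected at 3% amplitude, 2% noise."""
        design = WindowDesign()
        prof = ResponseProfile(amplitude=3.0)
        series, truth = generate_subject(
            small_atlas, {"prefrontal_cortex": prof, "cerebellum": prof},
            seed=11, n_volumes=150,
        )
        res = analyze_subject(series, design, small_atlas.brain_mask)
        detected = res.activated & truth.responder_mask
        assert detected.sum() / truth.total_responders >= 0.95
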