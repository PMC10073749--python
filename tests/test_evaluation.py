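import math

import numpy as np
import pytest

from ivnirf import evaluation, run_calibration, simulate
from ivnirf.errors import DomainError, IvnirfWarning
from conftest import make_single_frame_scene


class TestAccuracy:
    def test_perfect(self):
        acc, var = evaluation.accuracy([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert acc == 100.0
        assert var == 0.0

    def test_uniform_bias(self):
        truth = np.array([10.0, 20.0, 5.0])
        acc, var = evaluation.accuracy(0.8 * truth, truth)
        assert acc == pytest.approx(80.0)
        assert var == pytest.approx(0.0, abs=1e-9)

    def test_mixed_halves(self):
        acc, var = evaluation.accuracy([1.0, 0.8], [1.0, 1.0])
        assert acc == pytest.approx(90.0)
        assert var == pytest.approx(100.0)  # population variance, %^2

    def test_clamped_at_zero(self):
        acc, _ = evaluation.accuracy([10.0], [1.0])
        assert acc == 0.0

    def test_scale_invariance(self):
        c = np.array([0.9, 1.3, 0.7])
        t = np.array([1.0, 1.2, 0.8])
        a1, v1 = evaluation.accuracy(c, t)
        a2, v2 = evaluation.accuracy(17.0 * c, 17.0 * t)
        assert a1 == pytest.approx(a2, rel=1e-12)
        assert v1 == pytest.approx(v2, rel=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            evaluation.accuracy([], [])


class TestFoldImprovement:
    def test_identical_sequences_give_one(self):
        u = np.array([1.1, 0.9, 1.3])
        t = np.array([1.0, 1.0, 1.0])
        assert evaluation.fold_improvement(u, u, t) == pytest.approx(1.0)

    def test_reported_ratio_arithmetic(self):
        # the published pairing: 24.2% uncorrected vs 11% corrected error
        assert 0.242 / 0.11 == pytest.approx(2.2, abs=0.0001)

    def test_zero_corrected_error_returns_infinity(self):
        t = np.array([1.0, 2.0, 3.0])
        fold = evaluation.fold_improvement(t * 0.5 + 0.1, t, t)
        assert math.isinf(fold)

    def test_gain_normalization_removes_scale(self):
        t = np.array([1.0, 2.0, 4.0])
        u = 100.0 * t  # perfectly proportional: zero error after gain
        fold = evaluation.fold_improvement(u, 0.9 * t, t)
        assert fold == pytest.approx(0.0)


class TestAgreementMetric:
    def test_identity(self):
        assert evaluation.agreement_metric([0.5, 2.0], [0.5, 2.0]) == 100.0

    def test_printed_coefficient_pairs(self):
        val = evaluation.agreement_metric([0.0028, 0.0034], [0.0028, 0.0033])
        assert val == pytest.approx(98.5294, abs=1e-3)
        assert val >= 98.0

    def test_length_mismatch(self):
        with pytest.raises(DomainError):
            evaluation.agreement_metric([1.0], [1.0, 2.0])


class TestSensitivityAnalysis:
    @pytest.fixture(scope="class")
    def single_frame(self, water_calibration_um):
        scene = make_single_frame_scene(d_gw=0.7, d_t=0.3, cb=3.4, cw=0.9)
        return scene, water_calibration_um

    def test_zero_delta_is_exact(self, single_frame):
        scene, calib = single_frame
        report = evaluation.sensitivity_analysis(scene, calib, [0.0, 50.0])
        assert report.accuracy_per_delta[0] == pytest.approx(100.0, abs=1e-6)

    def test_hand_derived_plus_100um(self, single_frame):
        # oracle chain: cb_est = 3.4*0.7/0.8, error factor exp(cb_est*0.4 - 3.4*0.3)
        scene, calib = single_frame
        report = evaluation.sensitivity_analysis(scene, calib, [0.0, 100.0])
        assert report.accuracy_per_delta[-1] == pytest.approx(81.5, abs=0.1)

    def test_mean_over_default_deltas(self, single_frame):
        # frozen oracle: mean of {79.719, 90.067, 90.510, 81.470}
        scene, calib = single_frame
        report = evaluation.sensitivity_analysis(scene, calib)
        assert report.mean_accuracy == pytest.approx(85.441, abs=0.01)
        assert report.mean_accuracy >= 70.0

    def test_asymmetry_of_signed_deltas(self, single_frame):
        scene, calib = single_frame
        report = evaluation.sensitivity_analysis(scene, calib, [-100.0, 0.0, 100.0])
        plus = report.accuracy_per_delta[report.deltas_um == 100.0][0]
        minus = report.accuracy_per_delta[report.deltas_um == -100.0][0]
        assert plus != pytest.approx(minus, abs=1e-6)
        assert plus < 100.0 and minus < 100.0

    def test_invalidating_delta_skipped_with_warning(self, water_calibration_um):
        scene = make_single_frame_scene(d_t=0.05)
        with pytest.warns(IvnirfWarning, match="skipped"):
            report = evaluation.sensitivity_analysis(
                scene, water_calibration_um, [-100.0, 50.0]
            )
        assert -100.0 not in report.deltas_um

    def test_artery_default_geometry_above_70(self, water_calibration_um):
        scene = simulate.artery_scene(cb_true=3.4 / 1000.0, unit_scale=1000.0)
        report = evaluation.sensitivity_analysis(scene, water_calibration_um)
        assert report.mean_accuracy >= 70.0


class TestValidateCbFit:
    @pytest.fixture(scope="class")
    def reference_calibration(self):
        # calibration source matched to the 27-uM reference capillary
        scene = simulate.calibration_scene(unit_scale=1000.0, concentration_uM=27.0)
        return run_calibration(simulate.simulate_calibration_phantom(scene))

    def test_noiseless_fit_equals_framewise(self, reference_calibration):
        scene = simulate.reference_validation_scene(
            cb_true=3.4 / 1000.0, unit_scale=1000.0
        )
        pb = simulate.simulate_capillary_phantom(scene)
        cb_fit, cb_calc = evaluation.validate_cb_fit(pb, reference_calibration)
        assert cb_fit == pytest.approx(3.4, rel=1e-9)
        np.testing.assert_allclose(cb_calc, 3.4, rtol=1e-9)
        assert evaluation.agreement_metric(cb_calc, np.full_like(cb_calc, cb_fit)) == (
            pytest.approx(100.0, abs=1e-6)
        )

    def test_noisy_agreement_at_least_95(self, reference_calibration):
        scene = simulate.reference_validation_scene(
            cb_true=3.4 / 1000.0, unit_scale=1000.0, noise_sigma=0.05, seed=31
        )
        pb = simulate.simulate_capillary_phantom(scene)
        cb_fit, cb_calc = evaluation.validate_cb_fit(pb, reference_calibration)
        agreement = evaluation.agreement_metric(cb_calc, np.full_like(cb_calc, cb_fit))
        assert agreement >= 95.0

    def test_short_span_warns(self, reference_calibration):
        scene = simulate.reference_validation_scene(
            cb_true=3.4 / 1000.0, unit_scale=1000.0, d_range=(0.5, 0.6)
        )
        pb = simulate.simulate_capillary_phantom(scene)
        with pytest.warns(IvnirfWarning, match="span"):
            cb_fit, _ = evaluation.validate_cb_fit(pb, reference_calibration)
        assert cb_fit == pytest.approx(3.4, rel=1e-6)


class TestNoisyParameterRecovery:
    def test_twenty_replicates_recover_cb_and_accuracy(self, water_calibration_um):
        # synthetic analogue of the reported tissue accuracy
        cb_true = 3.4
        accs, cbs = [], []
        for seed in range(20):
            scene = simulate.artery_scene(
                cb_true=cb_true / 1000.0, unit_scale=1000.0,
                noise_sigma=0.05, seed=seed,
            )
            pb = simulate.simulate_artery_pullback(scene)
            series = simulate_and_correct(pb, water_calibration_um)
            mask = pb.labels == 2
            acc, _ = evaluation.accuracy(
                series.concentration_map[mask], pb.truth.concentration[mask]
            )
            accs.append(acc)
            cbs.append(np.mean(series.cb_series))
        assert abs(np.mean(cbs) - cb_true) / cb_true < 0.05
        assert np.mean(accs) >= 85.0


def simulate_and_correct(pullback, calib):
    from ivnirf.pipeline import correct_pullback

    return correct_pullback(pullback, calib, 50.0)
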