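import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivnirf import model
from ivnirf.errors import (
    DomainError,
    NegativeCoefficientWarning,
    SuperUnityTransmissionWarning,
)
from ivnirf.model import OpticalPathModel


class TestForwardAttenuate:
    def test_direct_evaluation(self):
        # frozen oracle: 1000*exp(-0.001*0.2)*exp(-3.4*0.5)
        assert model.forward_attenuate(1000, 0.001, 0.2, 3.4, 0.5) == pytest.approx(
            182.646991, abs=0.01
        )

    def test_zero_path_is_identity(self):
        assert model.forward_attenuate(1000, 0.7, 0.0, 1.3, 0.0) == 1000.0

    def test_equal_media_collapse_to_single_medium(self):
        cw = 0.8
        both = model.forward_attenuate(500, cw, 0.3, cw, 0.9)
        single = 500 * math.exp(-cw * (0.3 + 0.9))
        assert both == pytest.approx(single, rel=1e-12)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(i_source=1.0, cw=-0.1, ds=0.1, c_medium=1.0, d_out=0.1),
            dict(i_source=1.0, cw=0.1, ds=-0.1, c_medium=1.0, d_out=0.1),
            dict(i_source=1.0, cw=0.1, ds=0.1, c_medium=-1.0, d_out=0.1),
            dict(i_source=1.0, cw=0.1, ds=0.1, c_medium=1.0, d_out=-0.1),
            dict(i_source=-1.0, cw=0.1, ds=0.1, c_medium=1.0, d_out=0.1),
        ],
    )
    def test_negative_inputs_rejected(self, kwargs):
        with pytest.raises(DomainError):
            model.forward_attenuate(**kwargs)

    def test_strictly_decreasing_in_distance(self):
        d = np.linspace(0.0, 2.0, 50)
        out = model.forward_attenuate(1000.0, 0.5, 0.2, 2.0, d)
        assert np.all(np.diff(out) < 0)


class TestWaterCorrectToSheath:
    def test_zero_distance_identity(self):
        assert model.water_correct_to_sheath(123.4, 0.9, 0.0) == 123.4

    def test_inverse_of_forward(self):
        assert model.water_correct_to_sheath(999.8, 0.001, 0.2) == pytest.approx(
            1000.0, abs=0.01
        )

    def test_composition_leaves_medium_term(self):
        i = model.forward_attenuate(1000, 0.7, 0.4, 2.5, 0.6)
        back = model.water_correct_to_sheath(i, 0.7, 0.4)
        assert back == pytest.approx(1000 * math.exp(-2.5 * 0.6), rel=1e-12)

    def test_result_not_smaller_than_input(self):
        assert model.water_correct_to_sheath(5.0, 1.0, 1.0) >= 5.0


class TestEstimateCbFrame:
    calib = OpticalPathModel(cw=0.001, i0=1000.0)

    def test_derived_inversion(self):
        cb = model.estimate_cb_frame(182.684, self.calib, 0.5)
        assert cb == pytest.approx(3.400, abs=1e-3)

    def test_water_indistinguishable_returns_cw(self):
        igw = 1000.0 * math.exp(-0.001 * 0.5)
        assert model.estimate_cb_frame(igw, self.calib, 0.5) == pytest.approx(
            0.001, abs=1e-12
        )

    @pytest.mark.parametrize("igw,d", [(0.0, 0.5), (-1.0, 0.5), (10.0, 0.0), (10.0, -1.0)])
    def test_domain_errors(self, igw, d):
        with pytest.raises(DomainError):
            model.estimate_cb_frame(igw, self.calib, d)

    def test_super_unity_transmission_warns_but_returns(self):
        with pytest.warns(SuperUnityTransmissionWarning):
            cb = model.estimate_cb_frame(2000.0, self.calib, 0.5)
        assert cb < 0 or math.isfinite(cb)

    def test_negative_cb_warned_not_clamped_by_default(self):
        igw = 1000.0 * math.exp(0.5)  # brighter than any water reference
        with pytest.warns((NegativeCoefficientWarning, SuperUnityTransmissionWarning)):
            cb = model.estimate_cb_frame(igw, self.calib, 0.5)
        assert cb < 0

    def test_clamping_is_opt_in(self):
        igw = 1000.0 * math.exp(0.5)
        with pytest.warns((NegativeCoefficientWarning, SuperUnityTransmissionWarning)):
            cb = model.estimate_cb_frame(igw, self.calib, 0.5, clamp_negative=True)
        assert cb == 0.0


class TestBloodCorrect:
    def test_zero_coefficient_identity(self):
        assert model.blood_correct(42.0, 0.0, 1.5) == 42.0

    def test_inverse_of_forward_example(self):
        assert model.blood_correct(182.684, 3.4, 0.5) == pytest.approx(1000.0, abs=0.01)

    def test_full_round_trip_exact(self):
        i = model.forward_attenuate(777.0, 0.9, 0.35, 3.1, 0.8)
        star = model.water_correct_to_sheath(i, 0.9, 0.35)
        assert model.blood_correct(star, 3.1, 0.8) == pytest.approx(777.0, rel=1e-12)


class TestGroundTruthCorrect:
    def test_zero_coefficient_identity(self):
        assert model.ground_truth_correct(10.0, 0.0, 1.0, 1.0) == 10.0

    def test_derived_value(self):
        assert model.ground_truth_correct(998.0, 0.001, 1.0, 1.0) == pytest.approx(
            999.998, abs=0.01
        )

    def test_inverts_water_medium_forward(self):
        i = model.forward_attenuate(321.0, 0.9, 0.2, 0.9, 0.7)
        assert model.ground_truth_correct(i, 0.9, 0.2, 0.7) == pytest.approx(
            321.0, rel=1e-12
        )


class TestToConcentration:
    def test_reference_maps_to_coating_concentration(self):
        assert model.to_concentration(400.0, 400.0, 50.0) == 50.0

    def test_linearity(self):
        assert model.to_concentration(200.0, 400.0, 50.0) == 25.0

    def test_zero_intensity(self):
        assert model.to_concentration(0.0, 400.0, 50.0) == 0.0

    def test_invalid_reference(self):
        with pytest.raises(DomainError):
            model.to_concentration(1.0, 0.0, 50.0)


@given(
    i_source=st.floats(1e-3, 1e6),
    cw=st.floats(0.0, 5.0),
    cb=st.floats(0.0, 5.0),
    ds=st.floats(0.0, 2.0),
    d_out=st.floats(1e-3, 2.0),
)
@settings(max_examples=200, deadline=None)
def test_round_trip_recovers_source_and_coefficient(i_source, cw, cb, ds, d_out):
    """Noiseless pipeline identity: water-correct -> estimate -> blood-correct
    recovers both the generating coefficient and the source intensity."""
    calib = OpticalPathModel(cw=cw, i0=i_source)
    measured = model.forward_attenuate(i_source, cw, ds, cb, d_out)
    star = model.water_correct_to_sheath(measured, cw, ds)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NegativeCoefficientWarning)
        cb_est = model.estimate_cb_frame(star, calib, d_out)
    assert cb_est == pytest.approx(cb, rel=1e-9, abs=1e-9)
    recovered = model.blood_correct(star, cb_est, d_out)
    assert recovered == pytest.approx(i_source, rel=1e-9)
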