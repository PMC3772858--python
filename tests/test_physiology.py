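"""Response curves and couplings of the circulation model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvpop import physiology as phys
from cvpop.errors import ConfigurationError, DomainError
from cvpop.physiology import ModelParameters, SigmoidSpec, default_parameters


@st.composite
def sigmoid_specs(draw):
    low = draw(st.floats(-10, 10))
    span = draw(st.floats(0.1, 1e4))
    return SigmoidSpec(
        low=low,
        high=low + span,
        sensitivity=draw(st.floats(0.1, 20)),
        setpoint=draw(st.floats(-100, 1e4)),
        width=draw(st.floats(0.1, 1e4)),
    )


class TestSigmoid:
    @given(spec=sigmoid_specs(), x=st.floats(-1e6, 1e6))
    @settings(max_examples=200, deadline=None)
    def test_bounded(self, spec, x):
        y = phys.sigmoid(x, spec)
        assert spec.low <= y <= spec.high
        # strictly inside the bounds wherever the exponent has not saturated
        z = spec.sensitivity * (x - spec.setpoint) / spec.width
        if abs(z) < 30:
            assert spec.low < y < spec.high

    @given(spec=sigmoid_specs())
    @settings(max_examples=100, deadline=None)
    def test_half_max_at_setpoint_and_monotone(self, spec):
        assert phys.sigmoid(spec.setpoint, spec) == pytest.approx(
            (spec.low + spec.high) / 2, rel=1e-12
        )
        xs = spec.setpoint + np.linspace(-2, 2, 41) * spec.width / spec.sensitivity
        ys = phys.sigmoid(xs, spec)
        assert np.all(np.diff(ys) > 0)

    def test_asymptotes(self):
        spec = SigmoidSpec(0.0, 2.0, 3.0, 10.0, 5.0)
        assert phys.sigmoid(-1e9, spec) == pytest.approx(0.0, abs=1e-12)
        assert phys.sigmoid(1e9, spec) == pytest.approx(2.0, abs=1e-12)

    def test_starling_half_max(self, params):
        # CO_max 15230 with set point 2.85 mmHg: half-maximal output there
        assert phys.starling_co(2.85, params) == pytest.approx(7615.0)
        assert phys.starling_co(1e6, params) == pytest.approx(15230.0)

    def test_invalid_spec_reports_field(self):
        with pytest.raises(ConfigurationError, match="high"):
            phys.sigmoid(0.0, SigmoidSpec(1.0, 1.0, 1.0, 0.0, 1.0))
        with pytest.raises(ConfigurationError, match="sensitivity"):
            phys.sigmoid(0.0, SigmoidSpec(0.0, 1.0, -1.0, 0.0, 1.0))

    def test_inverse_round_trip(self, params):
        spec = params.starling_spec()
        for rap in (-3.0, 0.0, 2.85, 8.0):
            assert phys.sigmoid_inverse(phys.sigmoid(rap, spec), spec) == pytest.approx(rap)


class TestCouplings:
    def test_effective_tpr(self):
        assert phys.effective_tpr(0.02265, 1.0) == pytest.approx(0.02265)
        assert phys.effective_tpr(0.02265, 0.9333) == pytest.approx(0.021140, abs=1e-6)
        assert phys.effective_tpr(0.3, 0.7) == phys.effective_tpr(0.7, 0.3)
        with pytest.raises(DomainError):
            phys.effective_tpr(-1.0, 1.0)

    def test_map_from_flow(self):
        assert phys.map_from_flow(5126, 0.0211) == pytest.approx(108.16, abs=0.01)
        assert phys.map_from_flow(0.0, 0.02) == 0.0
        assert phys.map_from_flow(5126, 0.0195) == pytest.approx(99.96, abs=0.01)
        with pytest.raises(DomainError):
            phys.map_from_flow(-1.0, 0.02)

    def test_rvr_linear_in_tpr(self, params):
        assert phys.rvr(0.0195, params) == pytest.approx(0.0296 * 0.0195 + 0.000839)
        assert phys.rvr(1e-12, params) == pytest.approx(0.000839)
        t = 0.02
        assert phys.rvr(2 * t, params) - phys.rvr(t, params) == pytest.approx(0.0296 * t)
        with pytest.raises(DomainError):
            phys.rvr(0.0, params)

    def test_venous_return(self):
        assert phys.venous_return(6.3, 6.3, 0.0014162) == 0.0
        assert phys.venous_return(6.3, -1.57, 0.0014162) == pytest.approx(5557.0, abs=1.0)
        # slope -1/RVR above the collapse pressure
        v1 = phys.venous_return(6.3, 0.0, 0.0014162)
        v2 = phys.venous_return(6.3, 1.0, 0.0014162)
        assert v1 - v2 == pytest.approx(1.0 / 0.0014162)
        with pytest.raises(DomainError):
            phys.venous_return(6.3, 0.0, 0.0)

    def test_venous_return_plateau(self):
        # below the venous collapse pressure the curve is flat (bounded above)
        cap = phys.venous_return(6.3, -2.2, 0.0014, p_vc=-2.2)
        assert phys.venous_return(6.3, -10.0, 0.0014, p_vc=-2.2) == cap
        assert phys.venous_return(6.3, -2.0, 0.0014, p_vc=-2.2) < cap


class TestBaroreflex:
    def test_afferent_rises_as_pressure_falls(self, params):
        # activity grows with the pressure deficit (p_adapt - MAP)
        base = phys.afferent_signal(100.0, 100.0, params)
        assert phys.afferent_signal(90.0, 100.0, params) > base
        # spec convention: afferent(deficit +10) > afferent(deficit 0)
        assert phys.afferent_signal(90.0, 100.0, params) > phys.afferent_signal(
            100.0, 100.0, params
        )

    def test_afferent_saturates_far_field(self, params):
        a1 = phys.afferent_signal(100.0 - 280.0, 100.0, params)
        a2 = phys.afferent_signal(100.0 - 300.0, 100.0, params)
        assert abs(a2 - a1) < 0.01 * params.A_aff

    def test_sna_extremes_match_table(self, params):
        # saturating low-pressure extreme: floor + max increase
        aff_max = params.A_aff
        assert phys.sympathetic_multiplier(aff_max, params) == pytest.approx(1.9374, abs=0.01)
        # saturating high-pressure extreme: minimal sympathetic outflow
        assert phys.sympathetic_multiplier(0.0, params) == pytest.approx(0.9333, abs=0.005)

    def test_sna_midpoint_at_setpoint(self, params):
        mid = phys.sympathetic_multiplier(0.5349, params)
        assert mid == pytest.approx(0.9333 + 1.0041 / 2, rel=1e-9)

    def test_sna_falls_with_pressure(self, params):
        p_adapt = 100.0
        snas = [
            phys.sympathetic_multiplier(phys.afferent_signal(m, p_adapt, params), params)
            for m in (60.0, 80.0, 100.0, 120.0)
        ]
        assert snas == sorted(snas, reverse=True)


class TestRenal:
    def test_uo_balances_intake_at_setpoint(self, params):
        sna0 = phys.sympathetic_multiplier(phys.afferent_signal(100.0, 100.0, params), params)
        assert phys.urine_output(params.p_renal * sna0, sna0, params) == pytest.approx(1.0)

    def test_uo_exponential_slope(self, params):
        sna0 = 1.0
        m0 = params.p_renal * sna0
        ratio = phys.urine_output(m0 + 20.0, sna0, params) / phys.urine_output(m0, sna0, params)
        assert ratio == pytest.approx(np.exp(0.05 * 20.0), rel=1e-12)

    def test_uo_suppressed_by_sna(self, params):
        assert phys.urine_output(100.0, 1.2, params) < phys.urine_output(100.0, 1.0, params)

    def test_blood_volume_partition(self, params):
        assert phys.blood_volume(1e9, params) == pytest.approx(7900.0)
        assert phys.blood_volume(15570.0, params) == pytest.approx(3950.0)
        assert phys.blood_volume(14000.0, params) < phys.blood_volume(16000.0, params)
        with pytest.raises(DomainError):
            phys.blood_volume(-5.0, params)

    def test_blood_volume_slope_below_one(self, params):
        ecfv = np.linspace(8000.0, 30000.0, 200)
        assert np.all(phys.blood_volume_slope(ecfv, params) < 1.0)


class TestFillingPressure:
    def test_unstressed_volume(self, params):
        m, sv, _ = phys.mcfp(3500.0, 1.0, params)
        assert m == 0.0 and sv == 0.0

    def test_elastance_arithmetic(self):
        # with the SNA-linear term switched off, E is the constant coefficient
        p = ModelParameters(e_lin=1e-12).resolve()
        m, sv, e = phys.mcfp(5000.0, 1.0, p)
        assert m == pytest.approx(6.8145, abs=1e-3)
        assert sv == 1500.0

    def test_mcfp_nondecreasing_in_sna(self, params):
        m1, _, _ = phys.mcfp(5000.0, 1.0, params)
        m2, _, _ = phys.mcfp(5000.0, 1.5, params)
        assert m2 >= m1

    def test_negative_stressed_volume_clamps(self, params):
        m, sv, _ = phys.mcfp(3000.0, 1.0, params)
        assert m == 0.0 and sv < 0


class TestParameterIO:
    def test_defaults_validate(self):
        default_parameters().validate()

    def test_unknown_key_rejected(self, tmp_path):
        f = tmp_path / "p.yaml"
        f.write_text("A_auto: 0.0453\nbogus_key: 1\n")
        with pytest.raises(ConfigurationError, match="bogus_key"):
            phys.load_parameters(f)

    def test_round_trip(self, tmp_path, params):
        f = tmp_path / "p.yaml"
        phys.save_parameters(params, f)
        loaded = phys.load_parameters(f)
        assert loaded.as_dict() == params.as_dict()
        assert loaded.p_renal == pytest.approx(params.p_renal)

    def test_invariant_violations_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelParameters(sna_min=1.5).validate()
        with pytest.raises(ConfigurationError):
            ModelParameters(V0=9000.0).validate()
        with pytest.raises(ConfigurationError, match="positive"):
            ModelParameters(BV_max=-1.0).validate()
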