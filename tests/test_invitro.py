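"""In-vitro parameter derivation: permeability, binding, partition ratios,
intrinsic clearance and the well-stirred hepatic clearance model."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pktranslate import invitro, synthetic
from pktranslate.invitro import (DepletionCurve, DialysisObservation,
                                 TranswellObservation)


def _transwell(slope_nmol_h, area=1.12, c0=1.0, times=(0.5, 1.0, 1.5, 2.0)):
    return TranswellObservation(
        direction="A2B", c0=c0, area=area,
        receiver_amounts=tuple((t, slope_nmol_h * t) for t in times))


class TestPapp:
    def test_hand_unit_conversion(self):
        # slope 0.06 nmol/h over 1.12 cm2 at 1 uM donor:
        # 0.06 / (1.12 * 1 * 3600) cm/s = 1.488e-5 cm/s = 14.88e-6 cm/s
        obs = _transwell(0.06)
        assert invitro.papp(obs) == pytest.approx(14.880952, rel=1e-6)

    def test_zero_slope_is_error(self):
        obs = _transwell(0.0)
        with pytest.raises(ValueError, match="no measurable transport"):
            invitro.papp(obs)

    def test_generator_inversion_at_zero_noise(self):
        spec = synthetic.GeneratorSpec(design="transwell", noise_cv=0.0,
                                       seed=3, true_params={"papp": 10.1})
        fixtures, _ = synthetic.gen_transwell(spec)
        for obs in fixtures:
            assert invitro.papp(obs) == pytest.approx(10.1, rel=1e-6)

    @given(scale=st.floats(0.1, 10.0))
    def test_invariant_under_concentration_rescaling(self, scale):
        # scaling donor concentration and transported amounts together
        # leaves the permeability unchanged
        base = _transwell(0.06)
        scaled = TranswellObservation(
            direction="A2B", c0=base.c0 * scale, area=base.area,
            receiver_amounts=tuple((t, a * scale)
                                   for t, a in base.receiver_amounts))
        assert invitro.papp(scaled) == pytest.approx(invitro.papp(base),
                                                     rel=1e-9)


class TestEffluxRatio:
    @pytest.mark.parametrize("ab,ba,expected", [
        (5.29, 7.51, 1.42), (14.7, 6.09, 0.414)])
    def test_assay_quotients(self, ab, ba, expected):
        assert invitro.efflux_ratio(ab, ba) == pytest.approx(expected,
                                                             rel=5e-3)

    def test_symmetry_gives_unity(self):
        assert invitro.efflux_ratio(3.3, 3.3) == 1.0

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            invitro.efflux_ratio(0.0, 5.0)


class TestFup:
    def test_strong_binder(self):
        obs = DialysisObservation(c_plasma=1000.0, c_buffer=2.0)
        assert invitro.fup(obs) == pytest.approx(0.002)

    def test_no_binding_limit(self):
        obs = DialysisObservation(c_plasma=50.0, c_buffer=50.0)
        assert invitro.fup(obs) == 1.0

    def test_binding_artifact_rejected(self):
        obs = DialysisObservation(c_plasma=10.0, c_buffer=11.0)
        with pytest.raises(ValueError, match="binding artifact"):
            invitro.fup(obs)

    def test_triplicate_mean_recovers_truth(self):
        spec = synthetic.GeneratorSpec(
            design="dialysis", noise_cv=0.0, seed=5,
            true_params={"fup": 0.013, "replicates": 3})
        fixtures, _ = synthetic.gen_dialysis(spec)
        assert invitro.fup(fixtures) == pytest.approx(0.013, rel=1e-9)


class TestMatrixRatio:
    def test_blood_plasma_mean(self):
        times = [0.5, 2.0, 8.0]
        plasma = [(t, 100.0) for t in times]
        blood = [(0.5, 54.0), (2.0, 55.0), (8.0, 66.0)]
        ratios, mean = invitro.matrix_ratio(blood, plasma, times)
        assert ratios[0.5] == pytest.approx(0.54)
        assert mean == pytest.approx(0.5833, rel=1e-3)

    def test_identical_profiles(self):
        prof = [(0.5, 12.0), (2.0, 7.0)]
        _, mean = invitro.matrix_ratio(prof, prof, [0.5, 2.0])
        assert mean == 1.0

    def test_zero_denominator_time_excluded(self):
        plasma = [(0.5, 100.0), (2.0, 0.0)]
        blood = [(0.5, 58.0), (2.0, 1.0)]
        ratios, mean = invitro.matrix_ratio(blood, plasma, [0.5, 2.0])
        assert list(ratios) == [0.5]
        with pytest.raises(ValueError):
            invitro.matrix_ratio(blood, [(0.5, 0.0), (2.0, 0.0)], [0.5, 2.0])

    def test_tissue_kp_recovery_from_generator(self):
        spec = synthetic.GeneratorSpec(
            design="tissue_study", noise_cv=0.0, seed=2,
            true_params={"kp": {"liver": 12.9}, "bp_ratio": 0.58,
                         "cl_per_kg": 1.9, "vss_per_kg": 0.75,
                         "ka": 2.0, "f": 0.12})
        ds, _ = synthetic.gen_tissue_study(spec)
        times = [0.5, 2.0, 8.0]
        liver = [(t, ds.mean_profile("liver").set_index("time_h")
                  .loc[t, "conc_ng_per_ml"]) for t in times]
        plasma = [(t, ds.mean_profile("plasma").set_index("time_h")
                   .loc[t, "conc_ng_per_ml"]) for t in times]
        _, mean = invitro.matrix_ratio(liver, plasma, times)
        assert mean == pytest.approx(12.9, rel=1e-6)


class TestClint:
    def test_closed_form_half_life(self, rat):
        t = (0.0, 5.0, 15.0, 30.0, 60.0, 90.0, 120.0)
        curve = DepletionCurve(times_min=t,
                               fraction_remaining=tuple(
                                   math.exp(-0.01 * tt) for tt in t),
                               cell_density=1.0)
        res = invitro.clint_from_depletion(curve, rat, fup_plasma=0.013,
                                           bp_ratio=0.58)
        assert res.t_half_min == pytest.approx(69.3147, rel=1e-4)
        assert res.clint_invitro == pytest.approx(10.0, rel=1e-6)
        assert not res.poor_fit
        assert res.cl_hepatic_predicted < rat.q_hepatic

    def test_depletion_generator_inversion(self, rat):
        spec = synthetic.GeneratorSpec(design="depletion", noise_cv=0.0,
                                       seed=1, true_params={"t_half_min": 60})
        curve, _ = synthetic.gen_depletion(spec)
        res = invitro.clint_from_depletion(curve, rat, 0.013, 0.58)
        assert res.t_half_min == pytest.approx(60.0, rel=1e-6)

    def test_well_stirred_zero_limit(self):
        assert invitro.well_stirred_cl(55.2, 0.02, 0.0) == 0.0

    def test_well_stirred_flow_limit(self):
        # fu_b * CLint >> Qh drives hepatic clearance to the blood flow
        cl = invitro.well_stirred_cl(55.2, 1.0, 1e9)
        assert cl == pytest.approx(55.2, rel=1e-6)

    @given(clint=st.floats(1.0, 1e6))
    def test_well_stirred_monotone_and_bounded(self, clint):
        q = 55.2
        lo = invitro.well_stirred_cl(q, 0.02, clint)
        hi = invitro.well_stirred_cl(q, 0.02, clint * 1.5)
        assert 0 < lo < hi < q
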