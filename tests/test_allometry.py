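"""Interspecies scaling methods against arithmetic oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pktranslate import allometry as al
from pktranslate.allometry import AllometricInput
from pktranslate.physiology import DOG, HUMAN, RAT

RAT_IN = AllometricInput("rat", 0.245, cl=7.758, fup=0.013, q_hepatic=13.524)
DOG_IN = AllometricInput("dog", 7.21, cl=24.033, fup=0.003,
                         q_hepatic=222.789)


class TestSSS:
    def test_rat_prediction(self):
        # 0.4655 L/h * (60/0.245)^0.66 = 17.56 L/h = 292.7 mL/min
        p = al.cl_sss(RAT_IN, 60.0, exponent=0.66)
        assert p.value == pytest.approx(292.7, rel=2e-3)

    def test_identity_at_equal_weight(self):
        p = al.cl_sss(RAT_IN, RAT_IN.body_weight, exponent=0.66)
        assert p.value == pytest.approx(RAT_IN.cl, rel=1e-12)

    def test_linear_at_exponent_one(self):
        p = al.cl_sss(RAT_IN, 2 * RAT_IN.body_weight, exponent=1.0)
        assert p.value == pytest.approx(2 * RAT_IN.cl, rel=1e-12)


class TestSSAS:
    def test_rat_prediction(self):
        # (0.4655/0.013) * 244.9^0.75 * 0.002 = 4.43 L/h = 73.9 mL/min
        p = al.cl_ssas_fu(RAT_IN, 60.0, target_fup=0.002)
        assert p.value == pytest.approx(73.9, rel=2e-3)

    def test_reduces_to_sss_when_fup_equal(self):
        ssas = al.cl_ssas_fu(RAT_IN, 60.0, target_fup=RAT_IN.fup)
        sss = al.cl_sss(RAT_IN, 60.0, exponent=0.75)
        assert ssas.value == pytest.approx(sss.value, rel=1e-12)

    def test_joint_fup_rescaling_invariance(self):
        from dataclasses import replace
        doubled = replace(RAT_IN, fup=2 * RAT_IN.fup)
        assert al.cl_ssas_fu(doubled, 60.0, 0.004).value == pytest.approx(
            al.cl_ssas_fu(RAT_IN, 60.0, 0.002).value, rel=1e-12)


class TestTSAS:
    def test_two_point_log_log_solve(self):
        p = al.cl_tsas([RAT_IN, DOG_IN], 60.0)
        assert p.exponent == pytest.approx(0.334, abs=1e-3)
        assert p.value == pytest.approx(48.8, rel=2e-3)

    def test_recovers_exact_power_law(self):
        a, b = 10.0, 0.75
        inputs = [AllometricInput(f"s{i}", bw, cl=a * bw ** b)
                  for i, bw in enumerate((0.02, 0.25, 3.0, 12.0))]
        p = al.cl_tsas(inputs, 70.0)
        assert p.exponent == pytest.approx(b, rel=1e-9)
        assert p.value == pytest.approx(a * 70 ** b, rel=1e-9)

    def test_interpolates_source_species(self):
        # a two-point log-log fit passes through the data exactly
        p = al.cl_tsas([RAT_IN, DOG_IN], DOG_IN.body_weight)
        assert p.value == pytest.approx(DOG_IN.cl, rel=1e-9)

    def test_identical_weights_rejected(self):
        with pytest.raises(ValueError):
            al.cl_tsas([RAT_IN, AllometricInput("x", 0.245, cl=1.0)], 60.0)


class TestFCIM:
    def test_rat_single_species(self):
        # a = 7.758/0.245^0.75 = 22.28; Rfu = 6.5; 33.35*(a/Rfu)^0.77 = 86.1
        p = al.cl_fcim(RAT_IN, target_fup=0.002)
        assert p.coefficient == pytest.approx(22.28, rel=1e-3)
        assert p.value == pytest.approx(86.1, rel=2e-3)

    def test_intercept_definition(self):
        inp = AllometricInput("x", 1.0, cl=1.0, fup=0.5)
        p = al.cl_fcim(inp, target_fup=0.5)
        assert p.value == pytest.approx(33.35, rel=1e-12)

    def test_homogeneity(self):
        from dataclasses import replace
        scaled = replace(RAT_IN, cl=RAT_IN.cl * 2 ** (1 / 0.77))
        assert al.cl_fcim(scaled, 0.002).value == pytest.approx(
            2 * al.cl_fcim(RAT_IN, 0.002).value, rel=1e-9)


class TestHBF:
    def test_extraction_transfer(self):
        # rat extraction 7.758/13.524 = 0.5737 onto human hepatic flow
        # 20.7 mL/min/kg * 60 kg = 1242 mL/min -> 712.5 mL/min
        p = al.cl_hbf(RAT_IN, target_q_hepatic=HUMAN.q_hepatic_total)
        assert p.value == pytest.approx(0.5737 * 1242, rel=1e-3)

    def test_unit_extraction(self):
        inp = AllometricInput("x", 1.0, cl=10.0, q_hepatic=10.0)
        assert al.cl_hbf(inp, 1242.0).value == pytest.approx(1242.0)

    def test_implausible_extraction_flagged(self):
        inp = AllometricInput("x", 1.0, cl=20.0, q_hepatic=10.0)
        p = al.cl_hbf(inp, 1242.0)
        assert "extraction_ratio_gt_1" in p.flags


class TestVss:
    def test_dog_per_kg(self):
        p = al.vss_perkg(AllometricInput("dog", 7.21, vss=1.05 * 7.21), 60.0)
        assert p.value == pytest.approx(63.0, rel=1e-9)

    def test_rat_per_kg(self):
        p = al.vss_perkg(AllometricInput("rat", 0.245, vss=0.75 * 0.245), 60.0)
        assert p.value == pytest.approx(45.0, rel=1e-9)

    def test_oie_tozer_prediction(self):
        inputs = [AllometricInput("rat", 0.245, vss=0.75 * 0.245, fup=0.013),
                  AllometricInput("dog", 7.21, vss=1.05 * 7.21, fup=0.003)]
        p = al.vss_oie_tozer(inputs, {"rat": RAT, "dog": DOG}, HUMAN, 0.002)
        # library-constant arithmetic oracle; within 5% of reported 17.1 L
        assert p.value == pytest.approx(17.64, rel=5e-3)
        assert abs(p.value - 17.1) / 17.1 < 0.05

    def test_oie_tozer_bound_free_limit(self):
        # fup = 1 removes protein-binding asymmetry: Vss/kg ->
        # Vp + Ve + Vr/fut
        inp = AllometricInput("rat", 0.245, vss=0.75 * 0.245, fup=1.0)
        p = al.vss_oie_tozer([inp], {"rat": RAT}, HUMAN, 1.0)
        v = HUMAN.oie_tozer
        expected = (v.vp + v.ve + v.vr / p.coefficient) * 60
        assert p.value == pytest.approx(expected, rel=1e-9)

    def test_vss_below_plasma_space_rejected(self):
        inp = AllometricInput("rat", 0.245, vss=0.005 * 0.245, fup=0.013)
        with pytest.raises(ValueError, match="plasma space"):
            al.vss_oie_tozer([inp], {"rat": RAT}, HUMAN, 0.002)


class TestAggregate:
    def test_dog_clearance_policy(self):
        preds = al.predictions_from_reference()
        agg = al.aggregate([p for p in preds if p.parameter == "cl"],
                           policy="dog_single_species")
        assert agg.value == pytest.approx(138.4, abs=0.05)
        assert len(agg.members) == 4

    def test_vss_mean(self):
        preds = al.predictions_from_reference()
        agg = al.aggregate([p for p in preds if p.parameter == "vss"])
        assert agg.value == pytest.approx(41.8, abs=1e-9)

    def test_singleton(self):
        preds = al.predictions_from_reference()
        one = [p for p in preds if p.method == "OieTozer"]
        assert al.aggregate(one).value == 17.1

    def test_empty_filter_rejected(self):
        preds = al.predictions_from_reference()
        with pytest.raises(ValueError):
            al.aggregate([p for p in preds if p.parameter == "cl"],
                         species="monkey")

    @given(perm=st.permutations([96.4, 92.3, 181.0, 184.0]))
    def test_permutation_invariance(self, perm):
        preds = [al.AllometricPrediction("SSS", "cl", ("dog",), v)
                 for v in perm]
        assert al.aggregate(preds).value == pytest.approx(138.425)


@given(scale=st.floats(0.1, 10.0))
def test_clearance_predictors_homogeneous_in_cl(scale):
    from dataclasses import replace
    scaled = replace(RAT_IN, cl=RAT_IN.cl * scale)
    assert al.cl_sss(scaled, 60, 0.66).value == pytest.approx(
        scale * al.cl_sss(RAT_IN, 60, 0.66).value, rel=1e-9)
    assert al.cl_hbf(scaled, 1242).value == pytest.approx(
        scale * al.cl_hbf(RAT_IN, 1242).value, rel=1e-9)
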