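"""Structural PK model: clinical formulas, covariate effects, bolus predictions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import txapk as tx
from txapk import pk

from _oracles import ode_conc

FINAL = tx.PKParamsIndividual(v1=12.77, v2=6.857, cl1=3.263, cl2=2.859)

positive = st.floats(min_value=0.1, max_value=100.0, allow_nan=False)


class TestCockcroftGault:
    @pytest.mark.parametrize(
        "age,bw,scr,sex,expected",
        [
            (69.0, 61.4, 85.7 / 88.4, "male", 62.4548),  # cohort-median patient
            (40.0, 72.0, 1.0, "male", 100.0),  # closed-form round number
        ],
    )
    def test_hand_arithmetic(self, age, bw, scr, sex, expected):
        assert tx.cockcroft_gault(age, bw, scr, sex) == pytest.approx(expected, abs=1e-3)

    def test_female_factor(self):
        male = tx.cockcroft_gault(69, 61.4, 0.9695, "male")
        female = tx.cockcroft_gault(69, 61.4, 0.9695, "female")
        assert female == pytest.approx(0.85 * male, rel=1e-12)

    @pytest.mark.parametrize("bad", [{"scr": -1}, {"bw": 0}, {"age": 150}])
    def test_invalid_inputs(self, bad):
        kwargs = {"age": 60, "bw": 70, "scr": 1.0, "sex": "male", **bad}
        with pytest.raises(ValueError):
            tx.cockcroft_gault(**kwargs)


class TestDuBoisBsa:
    @pytest.mark.parametrize(
        "bw,height,expected",
        [(61.4, 161.8, 1.6514), (70.0, 170.0, 1.8097)],
    )
    def test_direct_evaluation(self, bw, height, expected):
        assert tx.dubois_bsa(bw, height) == pytest.approx(expected, abs=1e-3)

    @settings(derandomize=True, max_examples=30)
    @given(bw=positive, height=st.floats(min_value=100, max_value=210))
    def test_power_law_homogeneity(self, bw, height):
        assert tx.dubois_bsa(2 * bw, height) == pytest.approx(
            2**0.425 * tx.dubois_bsa(bw, height), rel=1e-12
        )


class TestApplyCovariates:
    THETA = {"v1": 12.77, "v2": 6.857, "cl1": 3.263, "cl2": 2.859}
    EFFECTS = (
        tx.CovariateEffect("v1", "bw", reference=61.4, exponent=0.911),
        tx.CovariateEffect("cl1", "clcr", reference=61.0, exponent=0.752),
    )

    def test_worked_example_cl1(self):
        # final-model CL1 at the cohort-median body weight and CLcr 60 mL/min
        p = tx.apply_covariates(self.THETA, self.EFFECTS, {"bw": 61.4, "clcr": 60.0})
        assert p.cl1 == pytest.approx(3.223, abs=5e-4)
        # in mL/min (paper rounds the L/h figure first, hence the wider band)
        assert p.cl1 * 1000 / 60 == pytest.approx(53.72, abs=1.5e-2)
        assert p.v1 == pytest.approx(12.77, rel=1e-12)

    def test_identity_at_reference(self):
        p = tx.apply_covariates(self.THETA, self.EFFECTS, {"bw": 61.4, "clcr": 61.0})
        assert p.v1 == pytest.approx(12.77, rel=1e-12)
        assert p.cl1 == pytest.approx(3.263, rel=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(bw=positive)
    def test_zero_exponent_is_inert(self, bw):
        eff = (tx.CovariateEffect("v1", "bw", reference=61.4, exponent=0.0),)
        p = tx.apply_covariates(self.THETA, eff, {"bw": bw})
        assert p.v1 == self.THETA["v1"]

    def test_unknown_parameter_rejected(self):
        eff = (tx.CovariateEffect("v9", "bw", reference=61.4, exponent=1.0),)
        with pytest.raises(KeyError):
            tx.apply_covariates(self.THETA, eff, {"bw": 61.4})

    def test_missing_covariate_rejected(self):
        with pytest.raises(KeyError):
            tx.apply_covariates(self.THETA, self.EFFECTS, {"bw": 61.4})


class TestIndividualize:
    def test_zero_eta_is_identity(self):
        assert tx.individualize(FINAL, {"cl1": 0.0, "v1": 0.0}) == FINAL

    def test_log2_eta_doubles(self):
        p = tx.individualize(FINAL, {"cl1": math.log(2)})
        assert p.cl1 == pytest.approx(2 * FINAL.cl1, rel=1e-12)
        assert p.v1 == FINAL.v1

    def test_geometric_mean_is_typical_value(self):
        # log-normal IIV: the geometric mean of P_i converges to TV(P)
        rng = np.random.default_rng(42)
        etas = rng.normal(0.0, 0.3, 20000)
        cl = np.array([tx.individualize(FINAL, {"cl1": e}).cl1 for e in etas[:2000]])
        geo = math.exp(np.mean(np.log(cl)))
        assert geo == pytest.approx(FINAL.cl1, rel=0.02)


class TestMacroConstants:
    @settings(derandomize=True, max_examples=100)
    @given(v1=positive, v2=positive, cl1=positive, cl2=positive)
    def test_root_identities(self, v1, v2, cl1, cl2):
        p = tx.PKParamsIndividual(v1=v1, v2=v2, cl1=cl1, cl2=cl2)
        mc = tx.MacroConstants.from_params(p)
        assert mc.coefA + mc.coefB == pytest.approx(1.0, abs=1e-12)
        assert mc.alpha * mc.beta == pytest.approx(mc.k10 * mc.k21, rel=1e-10)
        assert mc.alpha + mc.beta == pytest.approx(mc.k10 + mc.k12 + mc.k21, rel=1e-12)
        assert mc.alpha >= mc.beta >= 0


class TestPredictConc:
    DOSES = [tx.DoseEvent(0.0, 1000.0)]

    def test_initial_concentration_is_dose_over_v1(self):
        # coefA + coefB = 1 makes C(0+) = dose / V1 = 78.31 mg/L
        assert tx.predict_conc(1e-9, self.DOSES, FINAL) == pytest.approx(
            1000 / 12.77, rel=1e-6
        )

    def test_collapses_to_one_compartment_when_cl2_zero(self):
        p2 = tx.PKParamsIndividual(v1=12.77, v2=5.0, cl1=3.263, cl2=0.0)
        p1 = tx.PKParamsIndividual(v1=12.77, cl1=3.263)
        t = np.linspace(0, 24, 50)
        np.testing.assert_allclose(
            tx.predict_conc(t, self.DOSES, p2, 2),
            tx.predict_conc(t, self.DOSES, p1, 1),
            rtol=1e-12,
        )

    def test_superposition_of_split_doses(self):
        split = [tx.DoseEvent(0.0, 500.0), tx.DoseEvent(0.0, 500.0)]
        t = np.linspace(0, 24, 50)
        np.testing.assert_allclose(
            tx.predict_conc(t, split, FINAL),
            tx.predict_conc(t, self.DOSES, FINAL),
            rtol=1e-12,
        )

    @settings(derandomize=True, max_examples=25)
    @given(scale=st.floats(min_value=0.01, max_value=100))
    def test_linearity_in_dose(self, scale):
        t = np.array([0.5, 2.0, 8.0])
        base = tx.predict_conc(t, [(0.0, 1000.0)], FINAL)
        scaled = tx.predict_conc(t, [(0.0, 1000.0 * scale)], FINAL)
        np.testing.assert_allclose(scaled, scale * base, rtol=1e-12)

    def test_zero_before_first_dose(self):
        doses = [tx.DoseEvent(2.0, 1000.0)]
        assert tx.predict_conc(1.0, doses, FINAL) == 0.0

    @pytest.mark.parametrize("n_comp", [1, 2])
    def test_against_ode_oracle(self, n_comp):
        doses = [tx.DoseEvent(0.0, 1000.0), tx.DoseEvent(2.8333, 1000.0)]
        t = np.array([0.5, 1.0, 2.0, 2.8333, 3.8, 8.8, 18.8])
        got = tx.predict_conc(t, doses, FINAL, n_comp)
        want = ode_conc(t, doses, FINAL, n_comp)
        np.testing.assert_allclose(got, want, rtol=1e-6)

    def test_near_degenerate_roots_stay_finite(self):
        # alpha ~= beta (within ~1e-4 relative): guarded evaluation must
        # stay finite and agree with the ODE oracle
        p = tx.PKParamsIndividual(v1=10.0, v2=5e-7, cl1=2.0, cl2=1e-7)
        t = np.array([0.1, 1.0, 5.0, 20.0])
        got = tx.predict_conc(t, self.DOSES, p)
        assert np.all(np.isfinite(got)) and np.all(got >= 0)
        np.testing.assert_allclose(got, ode_conc(t, self.DOSES, p), rtol=1e-6)

    def test_mass_balance_auc(self):
        # total exposure from one bolus equals dose / CL1
        from scipy.integrate import quad

        auc, _ = quad(
            lambda t: tx.predict_conc(t, self.DOSES, FINAL), 0, np.inf, limit=200
        )
        assert auc == pytest.approx(1000.0 / FINAL.cl1, rel=1e-6)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            tx.predict_conc(-1.0, self.DOSES, FINAL)
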