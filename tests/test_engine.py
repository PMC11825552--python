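"""FOCE engine: objective construction, estimation, model comparison."""

import math
from dataclasses import replace

import numpy as np
import pytest

import txapk as tx
from txapk import engine

from _oracles import exact_ofv

FAST = tx.FitOptions(compute_se=False)


def _toy_subject(obs, doses=((0.0, 1000.0),)):
    cov = tx.CovariateRecord(sex="male", age=60, bw=70, height=170, scr=80)
    return tx.SubjectRecord(
        id=1,
        covariates=cov,
        doses=tuple(tx.DoseEvent(t, a) for t, a in doses),
        observations=tuple(tx.Observation(t, c) for t, c in obs),
    )


class TestResidualSd:
    def test_additive_limit(self):
        assert tx.residual_sd(0.0, tx.SigmaParams(1.5, 0.2)) == 1.5

    def test_pure_additive_model(self):
        assert tx.residual_sd(500.0, tx.SigmaParams(2.0, 0.0)) == 2.0

    def test_combined_hand_value(self):
        # sqrt(1 + (100*0.15)^2) = sqrt(226)
        assert tx.residual_sd(100.0, tx.SigmaParams(1.0, 0.15)) == pytest.approx(
            15.0333, abs=1e-4
        )

    def test_negative_prediction_rejected(self):
        with pytest.raises(ValueError):
            tx.residual_sd(-1.0, tx.SigmaParams(1.0, 0.1))

    def test_sigma1_must_be_positive(self):
        with pytest.raises(ValueError):
            tx.SigmaParams(0.0, 0.1)


class TestSubjectObjective:
    MODEL = tx.PopModelSpec(n_compartments=1, iiv=("cl1",))
    PARAMS = tx.ParamSet(
        theta={"v1": 10.0, "cl1": 2.0},
        omega2={"cl1": 0.09},
        sigma=tx.SigmaParams(1.0, 0.1),
    )

    def test_zero_observations_pure_eta_penalty(self):
        sub = _toy_subject([])
        got = tx.subject_objective(sub, self.MODEL, self.PARAMS, {"cl1": 0.3})
        want = 0.3**2 / 0.09 + math.log(0.09)
        assert got == pytest.approx(want, rel=1e-12)

    def test_perfect_prediction_leaves_log_terms(self):
        sub0 = _toy_subject([])
        t = 1.5
        cpred = tx.predict_conc(
            t, sub0.doses, tx.PKParamsIndividual(v1=10.0, cl1=2.0), 1
        )
        sub = _toy_subject([(t, cpred)])
        got = tx.subject_objective(sub, self.MODEL, self.PARAMS, {"cl1": 0.0})
        sd2 = 1.0 + (0.1 * cpred) ** 2
        assert got == pytest.approx(math.log(sd2) + math.log(0.09), rel=1e-10)

    def test_matches_symbolic_hand_expansion(self):
        # one obs, one eta: fully expand the joint -2 log density by hand
        t, y, eta = 2.0, 40.0, 0.25
        sub = _toy_subject([(t, y)])
        got = tx.subject_objective(sub, self.MODEL, self.PARAMS, {"cl1": eta})
        cl = 2.0 * math.exp(eta)
        f = 1000.0 / 10.0 * math.exp(-cl / 10.0 * t)
        sd2 = 1.0**2 + (0.1 * f) ** 2
        want = (y - f) ** 2 / sd2 + math.log(sd2) + eta**2 / 0.09 + math.log(0.09)
        assert got == pytest.approx(want, rel=1e-10)


class TestOfv:
    def test_vanishing_iiv_reduces_to_wls_deviance(self, truth, small_cohort):
        no_iiv = replace(truth.model, iiv=())
        p_no = tx.ParamSet(truth.params.theta, truth.params.exponents, {}, truth.params.sigma)
        p_tiny = tx.ParamSet(
            truth.params.theta,
            truth.params.exponents,
            {"cl1": 1e-12, "v1": 1e-12},
            truth.params.sigma,
        )
        wls = tx.ofv(small_cohort, no_iiv, p_no)
        foce = tx.ofv(small_cohort, truth.model, p_tiny)
        assert foce == pytest.approx(wls, abs=1e-5)

    def test_additive_over_subjects(self, truth, small_cohort):
        doubled = tx.PopDataset(
            tuple(small_cohort.subjects)
            + tuple(replace(s, id=100 + i) for i, s in enumerate(small_cohort.subjects))
        )
        one = tx.ofv(small_cohort, truth.model, truth.params)
        two = tx.ofv(doubled, truth.model, truth.params)
        assert two == pytest.approx(2 * one, rel=1e-10)

    def test_agrees_with_gauss_hermite_two_eta(self, truth):
        ds = tx.simulate_dataset(tx.CohortDesign(n=5), truth, seed=11)
        got = tx.ofv(ds, truth.model, truth.params)
        want = exact_ofv(ds, truth.model, truth.params)
        assert abs(got - want) < 0.5

    def test_agrees_with_gauss_hermite_one_eta(self, truth):
        model = replace(truth.model, iiv=("cl1",))
        params = tx.ParamSet(
            truth.params.theta, truth.params.exponents, {"cl1": 0.09}, truth.params.sigma
        )
        ds = tx.simulate_dataset(
            tx.CohortDesign(n=5), tx.TruthParams(model, params), seed=5
        )
        got = tx.ofv(ds, model, params)
        want = exact_ofv(ds, model, params)
        assert abs(got - want) < 0.5

    def test_deterministic(self, truth, small_cohort):
        a = tx.ofv(small_cohort, truth.model, truth.params)
        b = tx.ofv(small_cohort, truth.model, truth.params)
        assert a == b


class TestLrt:
    def test_chi2_threshold_df1(self):
        res = tx.lrt(100.0, 95.0, df=1)
        assert res.threshold == pytest.approx(6.635, abs=5e-4)

    def test_printed_base_model_comparison(self):
        # one- vs two-compartment base models: dOFV = -109.550, significant
        res = tx.lrt(3492.0236, 3382.4731, df=1)
        assert res.delta_ofv == pytest.approx(-109.550, abs=1e-3)
        assert res.significant

    def test_below_threshold_not_significant(self):
        assert not tx.lrt(100.0, 94.0, df=1).significant

    def test_antisymmetric_in_model_order(self):
        fwd = tx.lrt(120.0, 100.0, df=1)
        rev = tx.lrt(100.0, 120.0, df=1)
        assert fwd.delta_ofv == -rev.delta_ofv

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            tx.lrt(1.0, 0.0, df=0)


class TestFitPopulation:
    def test_noise_free_recovery(self, truth):
        # omega^2 = 0, sigma2 = 0, small sigma1: estimates must hit the truth
        gen_model = replace(truth.model, iiv=())
        gen_params = tx.ParamSet(
            truth.params.theta, truth.params.exponents, {}, tx.SigmaParams(0.01, 0.0)
        )
        ds = tx.simulate_dataset(
            tx.CohortDesign(n=20), tx.TruthParams(gen_model, gen_params), seed=13
        )
        fit = tx.fit_population(ds, gen_model, options=FAST)
        assert fit.converged
        for name, tv in truth.params.theta.items():
            assert fit.params.theta[name] == pytest.approx(tv, rel=0.01)
        for got, want in zip(fit.params.exponents, truth.params.exponents):
            assert got == pytest.approx(want, abs=0.02)

    def test_refit_from_optimum_is_fixed_point(self, truth, small_cohort):
        fit = tx.fit_population(small_cohort, truth.model, options=FAST)
        refit = tx.fit_population(small_cohort, truth.model, fit.params, options=FAST)
        assert abs(refit.ofv - fit.ofv) < 0.01

    def test_invariant_under_subject_relabeling(self, truth, small_cohort):
        perm = np.random.default_rng(3).permutation(len(small_cohort.subjects))
        shuffled = tx.PopDataset(
            tuple(replace(small_cohort.subjects[j], id=i + 1) for i, j in enumerate(perm))
        )
        tight = tx.FitOptions(compute_se=False, outer_ftol=1e-13, outer_gtol=1e-6)
        f1 = tx.fit_population(small_cohort, truth.model, options=tight)
        f2 = tx.fit_population(shuffled, truth.model, options=tight)
        for name in f1.params.theta:
            assert f2.params.theta[name] == pytest.approx(
                f1.params.theta[name], rel=1e-4
            )

    def test_ofv_invariant_under_time_rescaling(self, truth, small_cohort):
        # hours -> minutes with clearances rescaled: identical deviance
        minute_subjects = []
        for s in small_cohort.subjects:
            doses = tuple(tx.DoseEvent(d.time * 60, d.amount) for d in s.doses)
            obs = tuple(
                tx.Observation(o.time * 60, o.concentration, o.missing)
                for o in s.observations
            )
            minute_subjects.append(replace(s, doses=doses, observations=obs))
        ds_min = tx.PopDataset(tuple(minute_subjects))
        theta_min = dict(truth.params.theta)
        theta_min["cl1"] /= 60.0
        theta_min["cl2"] /= 60.0
        params_min = tx.ParamSet(
            theta_min, truth.params.exponents, truth.params.omega2, truth.params.sigma
        )
        a = tx.ofv(small_cohort, truth.model, truth.params)
        b = tx.ofv(ds_min, truth.model, params_min)
        assert b == pytest.approx(a, rel=1e-6)

    def test_too_few_observations_rejected(self, truth):
        sub = _toy_subject([(1.0, 50.0)])
        with pytest.raises(tx.EngineError):
            tx.fit_population(tx.PopDataset((sub,)), truth.model)

    def test_standard_errors_reported(self, truth, small_cohort):
        fit = tx.fit_population(small_cohort, truth.model)
        assert fit.se is not None
        for name, est in fit.params.flat().items():
            assert fit.rse[name] == pytest.approx(100 * fit.se[name] / abs(est))


class TestShotgunSearch:
    def test_zero_candidates_gives_base_only(self, truth, small_cohort):
        base = replace(truth.model, covariate_effects=())
        table = tx.shotgun_covariate_search(small_cohort, base, [], options=FAST)
        assert len(table.rows) == 1
        assert table.selected == ()
        assert table.rows[0].description == "Base model"

    def test_too_many_candidates_rejected(self, truth, small_cohort):
        base = replace(truth.model, covariate_effects=())
        cands = [tx.CovariateEffect("v1", c) for c in "abcde"]
        with pytest.raises(ValueError):
            tx.shotgun_covariate_search(small_cohort, base, cands)

    def test_duplicate_candidates_rejected(self, truth, small_cohort):
        base = replace(truth.model, covariate_effects=())
        cands = [tx.CovariateEffect("v1", "bw"), tx.CovariateEffect("v1", "bw")]
        with pytest.raises(ValueError):
            tx.shotgun_covariate_search(small_cohort, base, cands)

    def test_table_delta_consistency(self, truth, small_cohort):
        base = replace(truth.model, covariate_effects=(), iiv=("cl1", "v1"))
        cands = [tx.CovariateEffect("v1", "bw"), tx.CovariateEffect("cl1", "clcr")]
        table = tx.shotgun_covariate_search(small_cohort, base, cands, options=FAST)
        by_subset = {r.subset: r for r in table.rows}
        for row in table.rows:
            if row.parent is not None:
                assert row.delta_ofv == pytest.approx(
                    row.ofv - by_subset[row.parent].ofv, abs=1e-9
                )
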