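"""Estimation engine: joint likelihood, empirical-Bayes modes, marginal OFV.

The linear-Gaussian model y = theta + eta + eps (one observation per
subject) has a closed-form marginal -2LL, log(sig2+om2) + r^2/(sig2+om2)
per subject in the no-2pi convention; the Laplace approximation is exact
there, which pins down every constant of the implementation.
"""

import math
from dataclasses import replace

import numpy as np
import pytest

from tacmpa import reference
from tacmpa.estimation import (EstimationSettings, PopPKModel, SubjectData,
                               estimate_etas, fit_population,
                               individual_joint_m2ll, marginal_ofv,
                               route_estimation_method)
from tacmpa.models import RandomEffectsSpec, ResidualModel, ResidualSpec

class ConstantModel:
    """y = theta + eta: the simplest mixed-effects model (duck-typed)."""

    eta_names = ("mu",)
    analytes = ("TAC",)

    def predict(self, theta, eta, subj):
        n = subj.n_obs()
        return np.full(n, theta["mu"] + (eta[0] if len(eta) else 0.0))

    def initial_theta(self):
        return {"mu": 0.0}


def _subject(values, sid="1"):
    values = np.asarray(values, dtype=float)
    return SubjectData(subject_id=sid, is_expresser=False, covariates={},
                       periods=[{"period": 1, "dose_tac": 0.0, "dose_mmf": 0.0,
                                 "times": np.arange(len(values), dtype=float),
                                 "analytes": ["TAC"] * len(values),
                                 "dv": values,
                                 "blq": np.zeros(len(values), bool),
                                 "lloq": np.full(len(values), 0.5)}])


class TestJointM2ll:
    def test_hand_computed_single_observation_value(self):
        # f=10, prop SD 0.1 -> var=1, dv=10, eta=0, om2=0.04:
        # log(1) + 0 + log(0.04) + 0 = log(0.04)
        model = ConstantModel()
        sigma = {"TAC": ResidualModel("prop", sigma_prop=0.1)}
        val = individual_joint_m2ll(model, _subject([10.0]), {"mu": 10.0},
                                    np.array([0.04]), sigma, np.array([0.0]))
        assert val == pytest.approx(math.log(0.04), abs=1e-12)

    def test_residual_term_vanishes_when_dv_equals_prediction(self):
        model = ConstantModel()
        sigma = {"TAC": ResidualModel("add", sigma_add=2.0)}
        val = individual_joint_m2ll(model, _subject([5.0]), {"mu": 5.0},
                                    np.array([0.04]), sigma, np.array([0.0]))
        assert val == pytest.approx(math.log(4.0) + math.log(0.04), abs=1e-12)

    def test_doubling_omega_reduces_eta_penalty(self):
        model = ConstantModel()
        sigma = {"TAC": ResidualModel("add", sigma_add=1.0)}
        eta = np.array([0.5])
        v1 = individual_joint_m2ll(model, _subject([5.0]), {"mu": 5.0},
                                   np.array([0.1]), sigma, eta)
        v2 = individual_joint_m2ll(model, _subject([5.0]), {"mu": 5.0},
                                   np.array([0.2]), sigma, eta)
        # quadratic penalty halves; log|Omega| grows by log 2 < 1.25
        assert (v2 - math.log(0.2)) < (v1 - math.log(0.1))

    def test_zero_prediction_with_proportional_error_raises(self):
        model = ConstantModel()
        sigma = {"TAC": ResidualModel("prop", sigma_prop=0.1)}
        with pytest.raises(ValueError, match="variance"):
            individual_joint_m2ll(model, _subject([1.0]), {"mu": 0.0},
                                  np.array([0.04]), sigma, np.array([0.0]))


class TestEstimateEtas:
    def _tac_setup(self, n_subjects=1, eta_true=0.0, seed=0):
        # additive error: with a proportional term the log-variance part of
        # the joint objective shifts the mode slightly off the generating eta
        spec = replace(reference.independent_spec(),
                       iiv=RandomEffectsSpec({"cl_tac": 0.25}),
                       residual=ResidualSpec({"TAC": ResidualModel("add",
                                                                   sigma_add=0.05)}))
        model = PopPKModel(spec, "tac")
        theta = model.initial_theta()
        from tacmpa.models import solve_tac_closed_form
        times = np.array([1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0, 48.0, 72.0])
        p = replace(spec.tac, cl=spec.tac.cl * math.exp(eta_true))
        dv = solve_tac_closed_form(p, 5.0, times)
        subj = SubjectData("1", False, {}, [{
            "period": 2, "dose_tac": 5.0, "dose_mmf": 0.0, "times": times,
            "analytes": ["TAC"] * len(times), "dv": dv,
            "blq": np.zeros(len(times), bool), "lloq": np.full(len(times), 0.5)}])
        return model, theta, subj, spec

    def test_noise_free_data_at_zero_eta_gives_zero_mode(self):
        model, theta, subj, spec = self._tac_setup(eta_true=0.0)
        eta, _, conv = estimate_etas(model, subj, theta, np.array([0.25]),
                                     spec.residual.per_analyte)
        assert np.linalg.norm(eta) < 1e-4

    def test_known_eta_recovered_from_rich_noise_free_data(self):
        model, theta, subj, spec = self._tac_setup(eta_true=0.3)
        eta, _, _ = estimate_etas(model, subj, theta, np.array([10.0]),
                                  spec.residual.per_analyte)
        # huge omega -> mode driven by the data alone
        assert eta[0] == pytest.approx(0.3, abs=1e-3)

    def test_mode_value_never_exceeds_start_value(self):
        model, theta, subj, spec = self._tac_setup(eta_true=0.4)
        om2 = np.array([0.25])
        sigma = spec.residual.per_analyte
        eta, val, _ = estimate_etas(model, subj, theta, om2, sigma)
        at_zero = individual_joint_m2ll(model, subj, theta, om2, sigma,
                                        np.array([0.0]))
        assert val <= at_zero + 1e-12


class TestMarginalOfv:
    def _linear_population(self, n=12, sig=0.5, om=0.8, mu=10.0, seed=5):
        rng = np.random.default_rng(seed)
        y = mu + om * rng.standard_normal(n) + sig * rng.standard_normal(n)
        subjects = [_subject([y[i]], sid=str(i)) for i in range(n)]
        return subjects, y

    def _closed_form_ofv(self, y, mu, sig2, om2):
        r = y - mu
        return float(np.sum(np.log(sig2 + om2) + r**2 / (sig2 + om2)))

    @pytest.mark.parametrize("method", ["Laplace", "FOCE-I"])
    def test_matches_closed_form_on_linear_gaussian_model(self, method):
        subjects, y = self._linear_population()
        model = ConstantModel()
        sigma = {"TAC": ResidualModel("add", sigma_add=0.5)}
        settings = EstimationSettings(method=method)
        ofv = marginal_ofv(subjects, model, {"mu": 10.0}, np.array([0.64]),
                           sigma, settings)
        expected = self._closed_form_ofv(y, 10.0, 0.25, 0.64)
        assert ofv == pytest.approx(expected, abs=1e-5)

    def test_vanishing_omega_approaches_fixed_effects_m2ll(self):
        subjects, y = self._linear_population()
        model = ConstantModel()
        sigma = {"TAC": ResidualModel("add", sigma_add=0.5)}
        ofv = marginal_ofv(subjects, model, {"mu": 10.0}, np.array([1e-10]),
                           sigma, EstimationSettings(method="Laplace"))
        fixed = self._closed_form_ofv(y, 10.0, 0.25, 0.0)
        assert ofv == pytest.approx(fixed, abs=1e-3)

    def test_m3_equals_omit_without_blq_records(self):
        subjects, _ = self._linear_population()
        model = ConstantModel()
        sigma = {"TAC": ResidualModel("add", sigma_add=0.5)}
        a = marginal_ofv(subjects, model, {"mu": 10.0}, np.array([0.64]), sigma,
                         EstimationSettings(method="Laplace", blq_strategy="M3"))
        b = marginal_ofv(subjects, model, {"mu": 10.0}, np.array([0.64]), sigma,
                         EstimationSettings(method="Laplace", blq_strategy="omit"))
        assert a == pytest.approx(b, abs=1e-9)

    def test_subject_permutation_leaves_ofv_unchanged(self):
        subjects, _ = self._linear_population()
        model = ConstantModel()
        sigma = {"TAC": ResidualModel("add", sigma_add=0.5)}
        s = EstimationSettings()
        a = marginal_ofv(subjects, model, {"mu": 10.0}, np.array([0.64]), sigma, s)
        b = marginal_ofv(subjects[::-1], model, {"mu": 10.0}, np.array([0.64]),
                         sigma, s)
        assert a == pytest.approx(b, abs=1e-9)


class TestRouting:
    @pytest.mark.parametrize("frac,method,strategy", [
        (0.05, "FOCE-I", "omit"),
        (0.0, "FOCE-I", "omit"),
        (0.10, "Laplace", "replace-with-ipred"),  # 'less than 10%' is strict
        (0.5, "Laplace", "replace-with-ipred"),
    ])
    def test_ten_percent_rule(self, frac, method, strategy):
        out = route_estimation_method({"TAC": frac})
        assert out["TAC"].method == method
        assert out["TAC"].blq_strategy == strategy

    def test_invalid_fraction_raises(self):
        with pytest.raises(ValueError):
            route_estimation_method({"TAC": 1.2})


@pytest.fixture(scope="module")
def fast_settings():
    fixed = frozenset({"k23", "k32", "tlag", "cyp3a5_fold",
                       "omega2_v2", "omega2_ka_tac", "sigma_prop_TAC"})
    return EstimationSettings(method="FOCE-I", blq_strategy="omit",
                              max_iter=60, fixed=fixed)


class TestFitPopulation:

    def test_refit_from_truth_does_not_increase_ofv(self, small_tac_trial,
                                                    fast_settings):
        spec = reference.independent_spec()
        from tacmpa.estimation import dataset_ofv
        ofv0 = dataset_ofv(small_tac_trial, spec, fast_settings, kind="tac")
        fit = fit_population(small_tac_trial, spec, fast_settings, kind="tac")
        assert fit.ofv <= ofv0 + 1e-6

    def test_identical_settings_give_identical_fits(self, small_tac_trial,
                                                    fast_settings):
        spec = reference.independent_spec()
        fit1 = fit_population(small_tac_trial, spec, fast_settings, kind="tac")
        fit2 = fit_population(small_tac_trial, spec, fast_settings, kind="tac")
        assert fit1.ofv == fit2.ofv
        assert fit1.theta == fit2.theta

    def test_single_subject_raises(self, small_tac_trial, fast_settings):
        ds = small_tac_trial
        from tacmpa.dataset import TrialDataset
        one = TrialDataset([r for r in ds.records if r.subject_id == "1"],
                           {"1": ds.covariates["1"]}, ds.analyte_specs)
        with pytest.raises(ValueError, match="at least 2"):
            fit_population(one, reference.independent_spec(), fast_settings,
                           kind="tac")
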