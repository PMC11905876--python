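"""FOCE-I objective, EBEs, residuals, summaries and covariate selection."""

import math
from dataclasses import replace

import numpy as np
import pytest

from certepk.cohort import CohortConfig, build_design, sample_covariates, simulate_observations
from certepk.covariates import CovariateEffect, PopulationModel
from certepk.dataset import DoseEvent, ObservationRecord, PKDataset, SubjectCovariates
from certepk.estimation import (
    EncodedData,
    ParamSpec,
    ResidualSpec,
    add_effect,
    backward_eliminate,
    condition_number,
    cv_percent_iiv,
    cv_percent_residual,
    cwres,
    empirical_bayes,
    fit,
    forward_select,
    ofv,
    remove_effect,
    residual_sd,
    selection_threshold,
    shrinkage,
)
from certepk.reference import final_model


class TestResidualAndSummaries:
    def test_proportional_only_sd(self):
        spec = ResidualSpec("proportional", sigma2_prop=0.04)
        assert residual_sd(1000.0, spec) == pytest.approx(200.0)

    def test_additive_only_sd_flat(self):
        spec = ResidualSpec("additive", sigma2_add=25.0)
        assert residual_sd(0.0, spec) == 5.0
        assert residual_sd(1e4, spec) == 5.0

    def test_published_proportional_sd_at_500(self):
        spec = ResidualSpec("proportional", sigma2_prop=0.0393)
        assert residual_sd(500.0, spec) == pytest.approx(99.12, abs=0.01)

    def test_degenerate_error_model_rejected(self):
        with pytest.raises(ValueError):
            residual_sd(1.0, ResidualSpec("proportional", 0.0, 0.0))

    def test_shrinkage_examples(self):
        assert shrinkage([0.1, -0.1], 0.01) == pytest.approx(
            100 * (1 - np.std([0.1, -0.1], ddof=1) / 0.1)
        )
        assert shrinkage([0.0] * 10, 0.04) == pytest.approx(100.0)
        rng = np.random.default_rng(0)
        etas = rng.normal(0, 1, 400)
        etas = etas / etas.std(ddof=1) * 0.15
        assert shrinkage(etas, 0.0447) == pytest.approx(29.05, abs=0.1)

    def test_shrinkage_undefined_for_zero_variance(self):
        assert math.isnan(shrinkage([0.1, 0.2], 0.0))

    def test_iiv_cv_always_exceeds_sqrt_convention(self):
        for w2 in (0.001, 0.0301, 0.0447, 0.2, 1.0):
            assert cv_percent_iiv(w2) > cv_percent_residual(w2)


def _flat_dataset(n_subj, times, dose=224.0, obs_values=None):
    ds = PKDataset(lloq=1e-9)
    for i in range(n_subj):
        sid = f"S{i}"
        ds.covariates[sid] = SubjectCovariates(weight=70.0, age=60.0, sex="male", bcrcl=90.0)
        ds.doses.append(DoseEvent(sid, 0.0, dose))
        for j, t in enumerate(times):
            dv = 1.0 if obs_values is None else obs_values[i][j]
            ds.observations.append(ObservationRecord(sid, t, dv))
    return ds


NOIIV_THETA = {"vc": 5.87, "cl": 6.88, "vp": 10.3, "q": 24.9}


class TestObjective:
    def test_zero_iiv_limit_equals_weighted_least_squares_deviance(self):
        """With Omega = 0 the FOCE objective must collapse exactly to
        sum[(y - pred)^2 / W^2 + log(2 pi W^2)]."""
        times = [0.1, 0.5, 1.0, 3.0]
        rng = np.random.default_rng(1)
        model = PopulationModel(theta=NOIIV_THETA, sigma2_prop=0.0393)
        ds = _flat_dataset(3, times)
        enc = EncodedData(ds)
        pred = enc.predict(*[np.full(3, NOIIV_THETA[k]) for k in ("vc", "cl", "vp", "q")])
        y = pred * (1 + 0.1 * rng.standard_normal(pred.shape))
        for i, sid in enumerate(enc.subject_ids):
            for j, o in enumerate(ds.observations_for(sid)):
                o.dv = float(y[i, j])
        w2 = 0.0393 * pred**2
        expected = float(np.sum((y - pred) ** 2 / w2 + np.log(2 * np.pi * w2)))
        assert ofv(ds, model) == pytest.approx(expected, abs=1e-8)

    def test_duplicated_observation_adds_its_analytic_contribution(self):
        times = [0.5, 2.0]
        model = PopulationModel(theta=NOIIV_THETA, sigma2_prop=0.04)
        ds = _flat_dataset(1, times)
        enc = EncodedData(ds)
        pred = enc.predict(*[np.array([NOIIV_THETA[k]]) for k in ("vc", "cl", "vp", "q")])
        for j, o in enumerate(ds.observations):
            o.dv = float(pred[0, j]) * 1.05
        base = ofv(ds, model)
        extra = ds.observations[1]
        ds2 = ds.copy()
        ds2.observations.append(ObservationRecord("S0", extra.time, extra.dv))
        w2 = 0.04 * float(pred[0, 1]) ** 2
        point = (extra.dv - float(pred[0, 1])) ** 2 / w2 + math.log(2 * math.pi * w2)
        assert ofv(ds2, model) == pytest.approx(base + point, abs=1e-8)

    def test_matches_dense_quadrature_marginal_for_single_observation_subjects(self):
        """One observation per subject, additive error, IIV on CL only: the
        exact marginal likelihood is a 1-D integral, evaluated here by dense
        trapezoidal quadrature (the likelihood peak is only ~0.004 wide in
        eta, so the grid must resolve it).  The FOCE approximation error
        must be small and shrink with omega^2."""
        times = [2.0]
        rng = np.random.default_rng(4)
        diffs = {}
        for om2 in (0.0025, 0.04):
            model = PopulationModel(
                theta=NOIIV_THETA, omega2={"cl": om2}, sigma2_add=400.0
            )
            ds = _flat_dataset(6, times)
            enc = EncodedData(ds)
            pred = enc.predict(*[np.full(6, NOIIV_THETA[k]) for k in ("vc", "cl", "vp", "q")])
            y = pred + 20.0 * rng.standard_normal(pred.shape)
            for i, sid in enumerate(enc.subject_ids):
                ds.observations_for(sid)[0].dv = float(abs(y[i, 0]))
            # dense quadrature oracle on eta ~ N(0, om2)
            eta = np.linspace(-1.0, 1.0, 40_001)
            n = 6
            f = enc.predict(
                np.full((len(eta), n), NOIIV_THETA["vc"]),
                NOIIV_THETA["cl"] * np.exp(eta)[:, None] * np.ones(n),
                np.full((len(eta), n), NOIIV_THETA["vp"]),
                np.full((len(eta), n), NOIIV_THETA["q"]),
            )[:, :, 0]
            dv = np.array([ds.observations_for(s)[0].dv for s in enc.subject_ids])
            integrand = (
                np.exp(-0.5 * (dv[None, :] - f) ** 2 / 400.0)
                * np.exp(-0.5 * eta**2 / om2)[:, None]
                / math.sqrt(2 * math.pi * om2)
            )
            lik = np.trapezoid(integrand, eta, axis=0) / math.sqrt(2 * math.pi * 400.0)
            exact = float(np.sum(-2.0 * np.log(lik)))
            diffs[om2] = abs(ofv(ds, model) - exact)
        assert diffs[0.0025] < 1e-3
        assert diffs[0.04] < 0.05

    def test_ofv_reproducible_across_warm_starts(self, analysis_dataset, truth_model):
        enc = EncodedData(analysis_dataset)
        v1, eta = ofv(enc, truth_model, return_eta=True)
        v2 = ofv(enc, truth_model, eta0=eta)
        assert v2 == pytest.approx(v1, abs=1e-6)


class TestEmpiricalBayes:
    def test_subject_without_observations_sits_at_prior_mode(self, truth_model):
        ds = _flat_dataset(1, [])
        ds.doses.append(DoseEvent("S0", 0.0, 224.0))
        ebes = empirical_bayes(ds, truth_model)
        assert all(v == 0.0 for v in ebes["S0"].values())

    def test_recovers_large_known_eta_with_rich_low_noise_data(self, truth_model):
        quiet = replace(truth_model, sigma2_prop=1e-6)
        times = np.linspace(0.05, 6.0, 24)
        ds = _flat_dataset(1, list(times))
        from certepk.covariates import RandomEffects, individual_params
        from certepk.twocomp import conc_single_infusion

        p = individual_params(
            quiet, ds.covariates["S0"], RandomEffects({"cl": 0.5})
        )
        for o, t in zip(ds.observations, times):
            o.dv = float(conc_single_infusion(p, 224.0, 1 / 60, t))
        ebes = empirical_bayes(ds, quiet)
        assert ebes["S0"]["cl"] == pytest.approx(0.5, abs=0.05)
        assert abs(ebes["S0"]["vc"]) < 0.05

    def test_vanishing_omega_shrinks_all_ebes_to_zero(self, truth_model):
        tiny = replace(truth_model, omega2={"vc": 1e-8, "cl": 1e-8, "vp": 1e-8})
        ds = _flat_dataset(2, [0.5, 2.0])
        for o in ds.observations:
            o.dv = 5000.0
        ebes = empirical_bayes(ds, tiny)
        assert all(abs(v) < 1e-3 for e in ebes.values() for v in e.values())


class TestCwres:
    def test_collapses_to_weighted_residual_without_iiv(self):
        model = PopulationModel(theta=NOIIV_THETA, sigma2_prop=0.04)
        ds = _flat_dataset(2, [0.5, 2.0])
        enc = EncodedData(ds)
        pred = enc.predict(*[np.full(2, NOIIV_THETA[k]) for k in ("vc", "cl", "vp", "q")])
        for i, sid in enumerate(enc.subject_ids):
            for j, o in enumerate(ds.observations_for(sid)):
                o.dv = float(pred[i, j]) * (1.1 if j else 0.9)
        tab = cwres(ds, model)
        w = 0.2 * pred  # sqrt(0.04) * pred
        manual = ((np.array([0.9, 1.1]) - 1.0) * pred[0] / w[0])
        np.testing.assert_allclose(np.sort(tab[tab.subject_id == "S0"]["cwres"]), np.sort(manual), rtol=1e-6)

    def test_calibrated_under_the_generating_model(self, analysis_dataset, truth_model):
        """CWRES of data simulated under the model: mean ~0, SD ~1."""
        tab = cwres(analysis_dataset, truth_model)
        assert len(tab) >= 500
        assert abs(tab["cwres"].mean()) < 0.1
        assert 0.85 <= tab["cwres"].std() <= 1.15
        assert not tab["outlier"].any()


class TestConditionNumber:
    def test_identity_correlation_gives_one(self):
        assert condition_number(np.diag([2.0, 3.0, 4.0])) == pytest.approx(1.0)

    def test_two_by_two_closed_form(self):
        cov = np.array([[1.0, 0.6], [0.6, 1.0]])
        assert condition_number(cov) == pytest.approx(4.0)

    def test_unavailable_covariance_raises(self):
        with pytest.raises(ValueError):
            condition_number(None)


class TestFit:
    def test_deterministic_limit_recovers_truth_within_one_percent(self):
        """No IIV, tiny residual noise, many subjects: estimates converge
        to the generating values."""
        cfg = CohortConfig(n_subjects=24, group_sizes=(4, 4, 8, 8), n_occasions=1)
        skeleton = build_design(sample_covariates(cfg, seed=9), cfg)
        gen = PopulationModel(theta=NOIIV_THETA, sigma2_prop=1e-4)
        sim, _ = simulate_observations(skeleton, gen, seed=9)
        init = PopulationModel(
            theta={"vc": 7.5, "cl": 5.0, "vp": 13.0, "q": 18.0}, sigma2_prop=1e-3
        )
        fr = fit(sim, init, compute_covariance=False)
        for k in NOIIV_THETA:
            assert ParamSpec._get(fr.estimates, k) == pytest.approx(
                NOIIV_THETA[k], rel=0.01
            )

    def test_refit_from_optimum_is_a_fixed_point(self, analysis_dataset, recovery_fit):
        again = fit(analysis_dataset, recovery_fit.estimates, compute_covariance=False)
        assert again.ofv == pytest.approx(recovery_fit.ofv, abs=2e-3)
        for k in recovery_fit.param_names:
            assert ParamSpec._get(again.estimates, k) == pytest.approx(
                ParamSpec._get(recovery_fit.estimates, k), rel=2e-3
            )

    def test_param_spec_pack_unpack_round_trip(self, truth_model):
        spec = ParamSpec.from_model(truth_model)
        x = spec.pack(truth_model)
        back = spec.unpack(x, truth_model)
        for name in spec.names:
            assert ParamSpec._get(back, name) == pytest.approx(
                ParamSpec._get(truth_model, name), rel=1e-12
            )


class TestSelection:
    def test_chi_square_cutoff_is_10_8(self):
        assert selection_threshold() == pytest.approx(10.83, abs=0.01)

    def test_empty_candidate_list_returns_base_only(self, small_cohort):
        ds, _ = small_cohort
        from certepk.reference import base_model

        trace = forward_select(ds, base_model(), [], maxiter=150)
        assert len(trace.steps) == 1 and trace.steps[0]["action"] == "base"
        assert trace.final_model.covariate_effects == ()

    def test_true_weight_effect_accepted_and_ofv_decreases(self, small_cohort):
        ds, _ = small_cohort
        from certepk.reference import base_model

        candidates = [
            CovariateEffect("vc", "weight", "power", "wt_vc", 70.0),
            CovariateEffect("cl", "bcrcl", "linear_renal", ""),
        ]
        trace = forward_select(ds, base_model(), candidates, maxiter=150)
        accepted = [s for s in trace.steps if s["accepted"]]
        ofvs = [s["ofv"] for s in accepted]
        assert all(np.diff(ofvs) < 0)  # OFV strictly improves along the path
        assert len(accepted) >= 2  # base + at least one true effect

    def test_null_sex_effect_eliminated_backward(self, small_cohort):
        """Sex does not enter the generating model once CrCL is accounted
        for, so backward elimination at alpha 0.001 must drop it."""
        ds, truth = small_cohort
        model = add_effect(
            final_model(),
            CovariateEffect("cl", "sex", "proportional", "sex_cl", 1.0),
        )
        eff = model.covariate_effects[-1]
        trace = backward_eliminate(ds, model, maxiter=150, effects=[eff])
        assert all(
            e.theta_key != "sex_cl" for e in trace.final_model.covariate_effects
        )

    def test_true_renal_effect_survives_backward(self, small_cohort):
        ds, _ = small_cohort
        model = final_model()
        renal = next(e for e in model.covariate_effects if e.form == "linear_renal")
        trace = backward_eliminate(ds, model, maxiter=150, effects=[renal])
        assert trace.final_model.has_renal_cl

    def test_add_remove_effect_round_trip(self):
        model = final_model()
        eff = CovariateEffect("cl", "age", "power", "age_cl", 60.0)
        bigger = add_effect(model, eff, init=0.2)
        assert "age_cl" in bigger.theta
        back = remove_effect(bigger, eff)
        assert back.theta == model.theta
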