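import math
from dataclasses import replace

import numpy as np
import pytest

from denopk import estimation as est
from denopk import model_core as mc
from denopk.dataset_io import SubjectData
from denopk.estimation import RandomEffectsSpec, ResidualSpec


def _subject(times, dv, sid=1, wt=75.0, dose=35.0, trt=1, study=0):
    times = np.asarray(times, float)
    dv = np.asarray(dv, float)
    return SubjectData(
        id=sid, wt=wt, trt=trt, study=study,
        dose_times=np.array([0.0]), dose_amts=np.array([dose]),
        obs_times=times, dv=dv, blq=np.zeros(times.size, bool),
    )


class TestMarginalOFV:
    def test_no_random_effects_equals_exact_gaussian(self, phase1_truth):
        model = replace(phase1_truth, iiv=RandomEffectsSpec(0.0, 0.0, 0.0))
        s = _subject([10.0, 60.0], [3.0, 1.2])
        ofv = est.marginal_ofv(model, [s])
        f = est.predict_subject(model, s)
        var = model.residual.sigma_prop**2 * f**2 + est.EPS_FLOOR**2
        exact = np.sum(np.log(2 * np.pi * var) + (s.dv - f) ** 2 / var)
        assert ofv == pytest.approx(exact, abs=1e-9)

    def test_single_eta_matches_quadrature_oracle(self, phase1_truth):
        model = replace(phase1_truth, iiv=RandomEffectsSpec(0.37**2, 0.0, 0.0))
        s = _subject([10.0, 60.0], [3.0, 1.2])
        lap = est.marginal_ofv(model, [s])
        agq = est.gauss_hermite_ofv(model, s)
        assert lap == pytest.approx(agq, abs=0.1)

    def test_independence_duplicating_subjects_doubles_ofv(self, phase1_truth):
        s1 = _subject([1.0, 10.0, 60.0], [1.5, 3.0, 1.2], sid=1)
        s2 = _subject([1.0, 10.0, 60.0], [1.5, 3.0, 1.2], sid=2)
        one = est.marginal_ofv(phase1_truth, [s1])
        two = est.marginal_ofv(phase1_truth, [s1, s2])
        assert two == pytest.approx(2 * one, abs=1e-6)

    def test_unit_coherence_of_log_likelihood(self, phase1_truth):
        # rescaling concentrations by c and shifting mu_v by -ln c shifts
        # the OFV by exactly 2 n ln c under proportional error (vmax = 0)
        model = replace(
            phase1_truth,
            fixed=replace(phase1_truth.fixed, mu_vm=-30.0),
        )
        s = _subject([1.0, 10.0, 60.0], [1.5, 3.0, 1.2])
        c = 1000.0
        s_scaled = replace(s, dv=s.dv * c)
        # changing concentration units rescales every volume-bearing
        # parameter: V and CL divide by c, Km multiplies by c
        model_scaled = replace(
            model,
            fixed=replace(
                model.fixed,
                mu_v=model.fixed.mu_v - math.log(c),
                mu_cl=model.fixed.mu_cl - math.log(c),
                mu_km=model.fixed.mu_km + math.log(c),
            ),
        )
        ofv = est.marginal_ofv(model, [s])
        ofv_scaled = est.marginal_ofv(model_scaled, [s_scaled])
        assert ofv_scaled - ofv == pytest.approx(2 * 3 * math.log(c), rel=1e-6)


class TestEmpiricalBayes:
    def test_uninformative_subject_returns_prior_mode(self, phase1_truth):
        s = _subject([0.0], [0.0])  # single predose zero carries no signal
        eta = est.empirical_bayes(phase1_truth, s)
        np.testing.assert_allclose(eta, 0.0, atol=1e-6)

    def test_degenerate_prior_pins_eta_at_zero(self, phase1_truth):
        model = replace(phase1_truth, iiv=RandomEffectsSpec(0.0, 0.0, 0.0))
        s = _subject([10.0, 60.0], [3.0, 1.2])
        np.testing.assert_array_equal(est.empirical_bayes(model, s), 0.0)

    def test_recovers_true_eta_with_rich_low_noise_data(self, phase1_truth):
        model = replace(phase1_truth, residual=ResidualSpec(0.01))
        eta_true = np.array([0.3, -0.1, 0.2])
        cov = mc.CovariateRecord(wt=75.0)
        p = mc.individual_params(model.fixed, eta_true, cov)
        times = np.array([0.5, 1, 2, 3, 6, 11, 22, 43, 85, 113.0])
        conc = mc.solve_profile(p, [mc.DoseEvent(0.0, 35.0)], times).conc
        s = _subject(times, conc)
        eta = est.empirical_bayes(model, s)
        np.testing.assert_allclose(eta, eta_true, atol=0.05)


class TestShrinkage:
    def test_limits(self):
        iiv = RandomEffectsSpec(0.04, 0.0, 0.04)
        ebes = np.zeros((50, 3))
        spread = np.linspace(-0.4, 0.4, 50)
        ebes[:, 0] = spread * 0.2 / np.std(spread, ddof=1)  # SD(EBE) == omega
        s = est.eta_shrinkage(ebes, iiv)
        assert s["cl"] == pytest.approx(0.0, abs=1.0)
        assert s["ka"] == pytest.approx(100.0)
        assert math.isnan(s["v"])


class TestFitAndLRT:
    def test_small_recovery_fit(self, small_phase1_trial, phase1_truth):
        _, subjects, _ = small_phase1_trial
        res = est.fit(subjects, est.nca_init(subjects), compute_se=False, seed=5)
        assert res.converged
        cl = math.exp(res.estimates.fixed.mu_cl)
        assert cl == pytest.approx(0.123, rel=0.25)
        # nesting: the fitted model cannot be worse than its own init
        assert res.ofv <= est.marginal_ofv(phase1_truth, subjects) + 0.5

    def test_fit_self_consistency_at_degenerate_noise(self, phase1_truth):
        # eta-free, tiny-noise data: initializing at the truth stays there
        truth0 = replace(
            phase1_truth,
            iiv=RandomEffectsSpec(0.0, 0.0, 0.0),
            residual=ResidualSpec(0.02),
        )
        times = np.array([0.5, 1, 2, 3, 6, 11, 22, 43, 85, 113.0])
        rng = np.random.default_rng(8)
        subs = []
        for i in range(12):
            wt = float(rng.normal(82, 8))
            p = mc.individual_params(truth0.fixed, (0, 0, 0), mc.CovariateRecord(wt=wt))
            conc = mc.solve_profile(p, [mc.DoseEvent(0.0, 35.0)], times).conc
            dv = conc * (1 + rng.normal(0, 0.02, times.size))
            subs.append(_subject(times, dv, sid=i + 1, wt=wt))
        res = est.fit(
            subs, truth0,
            fix=("omega2_cl", "omega2_v", "omega2_ka"),
            compute_se=True, seed=8,
        )
        assert res.converged
        assert math.exp(res.estimates.fixed.mu_cl) == pytest.approx(0.123, rel=0.03)
        assert math.exp(res.estimates.fixed.mu_v) == pytest.approx(9.33, rel=0.03)
        # Wald machinery produces finite natural-scale summaries
        assert res.rse_pct["mu_cl"] > 0
        lo, hi = res.ci95["mu_cl"]
        assert lo < math.exp(res.estimates.fixed.mu_cl) < hi

    def test_lrt_null_treatment_effect(self, small_phase1_trial):
        _, subjects, _ = small_phase1_trial
        pair = [s for s in subjects if s.trt in (1, 2)]
        base = est.nca_init(pair)
        ext = replace(base, trt_on=("cl",), trt_test_arm=2)
        res = est.lrt_covariate(pair, base, ext, alpha=0.05, seed=3)
        assert res.df == 1
        assert res.delta_ofv >= 0.0
        assert res.ofv_full <= res.ofv_reduced + 0.5
        # arms simulated from identical truth: no real effect at this size
        assert res.p_value > 0.01
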