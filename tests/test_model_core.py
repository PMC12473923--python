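import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from denopk import model_core as mc

TIMES = np.array([0.0, 0.5, 1, 2, 3, 6, 11, 22, 43, 85, 141, 197, 253.0])


def _params(**kw):
    base = dict(ka=0.406, v=9.33, cl=0.123, km=0.124, vmax=0.139)
    base.update(kw)
    return mc.StructuralParams(**base)


class TestIndividualParams:
    def test_reference_subject_recovers_typical_clearance(self):
        fx = mc.FixedEffects(
            mu_cl=math.log(0.123), mu_v=math.log(9.33), mu_ka=math.log(0.406),
            mu_km=math.log(0.124), mu_vm=math.log(0.139), beta_bw_cl=1.32,
        )
        p = mc.individual_params(fx, (0, 0, 0), mc.CovariateRecord(wt=70.0))
        assert p.cl == pytest.approx(0.123)
        assert p.v == pytest.approx(9.33)
        assert p.ka == pytest.approx(0.406)

    def test_centering_makes_covariates_vanish_at_reference(self):
        fx = mc.FixedEffects(0.5, 2.0, -1.0, -2.0, -2.0, beta_bw_cl=2.5, beta_study_v=-0.5)
        p = mc.individual_params(fx, (0, 0, 0), mc.CovariateRecord(wt=70.0, study=0))
        assert p.cl == pytest.approx(math.exp(0.5), rel=1e-12)
        assert p.v == pytest.approx(math.exp(2.0), rel=1e-12)

    def test_weight_power_law(self):
        fx = mc.FixedEffects(
            mu_cl=math.log(0.123), mu_v=0.0, mu_ka=0.0, mu_km=0.0, mu_vm=0.0,
            beta_bw_cl=1.32,
        )
        p = mc.individual_params(fx, (0, 0, 0), mc.CovariateRecord(wt=83.0))
        assert p.cl == pytest.approx(0.123 * (83 / 70) ** 1.32, rel=1e-12)

    def test_study_shift_and_eta_are_multiplicative(self):
        fx = mc.FixedEffects(0.0, math.log(9.0), 0.0, 0.0, 0.0, beta_study_v=-0.534)
        p = mc.individual_params(fx, (0.0, 0.25, 0.0), mc.CovariateRecord(wt=70, study=1))
        assert p.v == pytest.approx(9.0 * math.exp(-0.534 + 0.25), rel=1e-12)

    def test_treatment_effect_only_in_test_arm(self):
        fx = mc.FixedEffects(math.log(0.1), 0.0, 0.0, 0.0, 0.0, beta_trt_cl=0.3)
        cov_ref = mc.CovariateRecord(wt=70, trt=1)
        cov_test = mc.CovariateRecord(wt=70, trt=2)
        p_ref = mc.individual_params(fx, (0, 0, 0), cov_ref, trt_test_arm=2)
        p_test = mc.individual_params(fx, (0, 0, 0), cov_test, trt_test_arm=2)
        assert p_ref.cl == pytest.approx(0.1)
        assert p_test.cl == pytest.approx(0.1 * math.exp(0.3))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            mc.StructuralParams(ka=-1, v=9, cl=0.1, km=0.1, vmax=0.1)
        with pytest.raises(ValueError):
            mc.CovariateRecord(wt=-5.0)


class TestRHS:
    def test_empty_system_is_at_rest(self):
        d = mc.rhs(0.0, np.zeros(2), _params())
        assert np.all(d == 0)

    def test_linear_limit_matches_first_order_elimination(self):
        p = _params(vmax=0.0)
        c0 = 2.0
        d = mc.rhs(0.0, np.array([0.0, p.v * c0]), p)
        assert d[1] == pytest.approx(-p.cl * c0, rel=1e-12)

    def test_saturable_term_approaches_ceiling(self):
        p = _params()
        c_big = 1e6 * p.km
        d = mc.rhs(0.0, np.array([0.0, p.v * c_big]), p)
        # elimination = cl*C + (almost exactly) vmax
        assert -d[1] == pytest.approx(p.cl * c_big + p.vmax, rel=1e-5)


class TestSolveProfile:
    def test_matches_bateman_closed_form_without_saturation(self):
        p = _params(vmax=0.0)
        doses = [mc.DoseEvent(0.0, 35.0)]
        grid = np.linspace(0.0, 253.0, 200)[1:]
        prof = mc.solve_profile(p, doses, grid)
        ref = mc.bateman_profile(35.0, p.ka, p.v, p.cl, grid)
        assert np.max(np.abs(prof.conc - ref) / ref) < 1e-5

    def test_predose_concentration_is_zero(self):
        prof = mc.solve_profile(_params(), [mc.DoseEvent(0.0, 35.0)], [0.0, 1.0])
        assert prof.conc[0] == 0.0
        assert prof.conc[1] > 0.0

    def test_dose_linearity_without_saturation(self):
        p = _params(vmax=0.0)
        t = TIMES[1:]
        c1 = mc.solve_profile(p, [mc.DoseEvent(0.0, 35.0)], t).conc
        c2 = mc.solve_profile(p, [mc.DoseEvent(0.0, 70.0)], t).conc
        assert c2 == pytest.approx(2 * c1, rel=1e-7)

    def test_mass_balance_with_saturable_pathway(self):
        prof = mc.solve_profile(_params(), [mc.DoseEvent(0.0, 35.0)], TIMES[1:])
        total = prof.depot + prof.central + prof.eliminated
        assert np.max(np.abs(total - 35.0)) < 0.001 * 35.0

    def test_auc_strictly_decreases_with_clearance(self):
        aucs = []
        for cl in (0.08, 0.123, 0.2):
            grid = np.linspace(0, 253, 500)[1:]
            prof = mc.solve_profile(_params(cl=cl), [mc.DoseEvent(0.0, 35.0)], grid)
            aucs.append(np.trapezoid(prof.conc, grid))
        assert aucs[0] > aucs[1] > aucs[2]

    def test_high_km_limit_equals_linear_model_with_extra_clearance(self):
        # as km -> inf with vmax/km fixed the MM pathway becomes linear
        p0 = _params(vmax=0.0)
        grid = np.linspace(0, 253, 120)[1:]
        cmax = mc.solve_profile(p0, [mc.DoseEvent(0.0, 35.0)], grid).conc.max()
        ratio = 0.05  # vmax/km = extra clearance, L/day
        km = 1e6 * cmax
        p_mm = _params(km=km, vmax=ratio * km)
        p_lin = _params(vmax=0.0, cl=p0.cl + ratio)
        c_mm = mc.solve_profile(p_mm, [mc.DoseEvent(0.0, 35.0)], grid).conc
        c_lin = mc.solve_profile(p_lin, [mc.DoseEvent(0.0, 35.0)], grid).conc
        assert np.max(np.abs(c_mm - c_lin) / c_lin) < 0.005

    def test_multiple_doses_with_predose_sampling(self):
        doses = [mc.DoseEvent(0.0, 60.0), mc.DoseEvent(183.0, 60.0)]
        prof = mc.solve_profile(_params(), doses, np.array([0.0, 183.0, 184.0]))
        # observation at the dose time is predose: the next day jumps up
        assert prof.conc[2] > prof.conc[1]

    def test_agrees_with_lsoda_reference_integrator(self):
        p = _params()
        doses = [mc.DoseEvent(0.0, 35.0)]
        t = TIMES[1:]
        fast = mc.solve_profile(p, doses, t).conc
        slow = mc.solve_profile(p, doses, t, method="lsoda").conc
        assert fast == pytest.approx(slow, rel=1e-5, abs=1e-10)

    @settings(max_examples=15, deadline=None)
    @given(
        ka=st.floats(0.05, 2.0),
        v=st.floats(2.0, 20.0),
        cl=st.floats(0.01, 1.0),
        km=st.floats(0.01, 2.0),
        vmax=st.floats(0.0, 1.0),
        dose=st.floats(10.0, 200.0),
    )
    def test_mass_balance_and_nonnegativity_property(self, ka, v, cl, km, vmax, dose):
        p = mc.StructuralParams(ka=ka, v=v, cl=cl, km=km, vmax=vmax)
        prof = mc.solve_profile(p, [mc.DoseEvent(0.0, dose)], TIMES[1:])
        assert np.all(prof.conc >= 0)
        total = prof.depot + prof.central + prof.eliminated
        assert np.max(np.abs(total - dose)) < 1e-3 * dose
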