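import math
from dataclasses import replace

import numpy as np
import pytest

from denopk import derived_pk as dp
from denopk import model_core as mc
from denopk.estimation import RandomEffectsSpec


def _params(**kw):
    base = dict(ka=0.406, v=9.33, cl=0.123, km=0.124, vmax=0.139)
    base.update(kw)
    return mc.StructuralParams(**base)


DOSE35 = [mc.DoseEvent(0.0, 35.0)]


class TestExposureMetrics:
    def test_auc_inf_equals_dose_over_clearance_without_saturation(self):
        d = dp.exposure_metrics(_params(vmax=0.0), DOSE35, tau=253.0)
        assert d.auc_inf == pytest.approx(35.0 / 0.123, rel=0.002)

    def test_cmax_matches_bateman_maximum(self):
        p = _params(vmax=0.0)
        k = p.cl / p.v
        tstar = math.log(p.ka / k) / (p.ka - k)
        cmax_cf = mc.bateman_profile(35.0, p.ka, p.v, p.cl, [tstar])[0]
        d = dp.exposure_metrics(p, DOSE35, tau=253.0)
        assert d.cmax == pytest.approx(cmax_cf, rel=1e-4)

    def test_auc_tau_bounded_by_auc_inf(self):
        d = dp.exposure_metrics(_params(), DOSE35, tau=253.0)
        assert 0 < d.auc_tau <= d.auc_inf

    def test_auc_decreases_with_saturable_capacity(self):
        aucs = [
            dp.exposure_metrics(_params(vmax=vm), DOSE35, tau=253.0).auc_inf
            for vm in (0.0, 0.139, 0.4)
        ]
        assert aucs[0] > aucs[1] > aucs[2]

    def test_dose_proportionality_only_without_saturation(self):
        lin60 = dp.exposure_metrics(_params(vmax=0.0), [mc.DoseEvent(0, 60.0)], tau=400.0)
        lin120 = dp.exposure_metrics(_params(vmax=0.0), [mc.DoseEvent(0, 120.0)], tau=400.0)
        assert lin120.auc_inf / lin60.auc_inf == pytest.approx(2.0, rel=1e-3)
        mm60 = dp.exposure_metrics(_params(), [mc.DoseEvent(0, 60.0)], tau=400.0)
        mm120 = dp.exposure_metrics(_params(), [mc.DoseEvent(0, 120.0)], tau=400.0)
        assert mm120.auc_inf / mm60.auc_inf > 2.0  # saturable loss hits low doses harder

    def test_non_decaying_profile_rejected(self):
        with pytest.raises(ValueError):
            dp.exposure_metrics(_params(cl=0.0, vmax=0.0), DOSE35, tau=10.0)


class TestGMR:
    def test_identical_arms_give_unity(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r = dp.gmr_ci(x, x)
        assert r.gmr_pct == pytest.approx(100.0)
        assert r.ci90_pct[0] <= 100.0 <= r.ci90_pct[1]

    def test_constant_scaling_gives_exact_ratio(self):
        test = np.array([1.0, 2.0, 3.0, 4.0])
        r = dp.gmr_ci(test, 1.21 * test)
        assert r.gmr_pct == pytest.approx(121.0, rel=1e-12)

    def test_large_true_difference_fails_margin(self, rng):
        test = np.exp(rng.normal(0.0, 0.35, 85))
        ref = 0.7 * np.exp(rng.normal(0.0, 0.35, 85))
        r = dp.gmr_ci(test, ref)
        assert not r.passed

    def test_input_validation(self):
        with pytest.raises(ValueError):
            dp.gmr_ci(np.array([1.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            dp.gmr_ci(np.array([1.0, -1.0]), np.array([1.0, 2.0]))


class TestExtrapolation:
    def test_degenerate_population_has_zero_spread(self, pooled_truth):
        model = replace(pooled_truth, iiv=RandomEffectsSpec(0.0, 0.0, 0.0))

        def fixed_demo(rng):
            return 70.0, 0

        s = dp.extrapolate_dose(model, dose_mg=120.0, n=4, seed=1, demographics=fixed_demo)
        assert s.sd_auc_inf == pytest.approx(0.0, abs=1e-6)
        typical = dp.exposure_metrics(
            mc.StructuralParams(
                ka=math.exp(model.fixed.mu_ka),
                v=math.exp(model.fixed.mu_v),
                cl=math.exp(model.fixed.mu_cl),
                km=math.exp(model.fixed.mu_km),
                vmax=math.exp(model.fixed.mu_vm),
            ),
            [mc.DoseEvent(0.0, 120.0)],
            tau=28.0,
        )
        assert s.mean_auc_inf == pytest.approx(typical.auc_inf, rel=1e-3)

    def test_linear_degenerate_closed_form(self, pooled_truth):
        model = replace(
            pooled_truth,
            iiv=RandomEffectsSpec(0.0, 0.0, 0.0),
            fixed=replace(pooled_truth.fixed, mu_vm=-30.0),
        )

        def fixed_demo(rng):
            return 70.0, 0

        s = dp.extrapolate_dose(model, dose_mg=120.0, n=2, seed=1, demographics=fixed_demo)
        assert s.mean_auc_inf == pytest.approx(120.0 / 0.143, rel=0.002)

    def test_reporting_scale(self, pooled_truth):
        s = dp.extrapolate_dose(pooled_truth, n=20, seed=2)
        assert s.mean_auc_inf_ng_day_ml == pytest.approx(1000 * s.mean_auc_inf)
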