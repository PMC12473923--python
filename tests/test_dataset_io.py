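import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from denopk import dataset_io as dio


def _subject(dv_ng_ml, times=None, **kw):
    dv = np.asarray(dv_ng_ml, dtype=float) * dio.NG_ML_TO_MG_L
    t = np.arange(len(dv), dtype=float) if times is None else np.asarray(times, float)
    base = dict(
        id=1, wt=75.0, trt=1, study=0,
        dose_times=np.array([0.0]), dose_amts=np.array([35.0]),
        obs_times=t, dv=dv, blq=dv < dio.DEFAULT_LLOQ_NG_ML * dio.NG_ML_TO_MG_L,
    )
    base.update(kw)
    return dio.SubjectData(**base)


class TestBLQPolicy:
    def test_toy_sequence_rules(self):
        # flags: B B M M B M B B  ->  0 0 M M - M - -
        dv = [5, 8, 100, 200, 10, 150, 9, 3]
        s, rep = dio.apply_blq_policy(_subject(dv), lloq_ng_ml=20.0)
        assert rep.n_imputed_zero == 2
        assert rep.n_dropped_trailing == 2
        assert rep.n_dropped_intermediate == 1
        assert s.n_obs == 5  # 2 imputed zeros + 3 measurable
        np.testing.assert_allclose(s.dv[:2], 0.0)
        np.testing.assert_allclose(s.dv[2:] * 1000, [100, 200, 150])
        np.testing.assert_array_equal(s.obs_times, [0, 1, 2, 3, 5])

    def test_no_blq_is_noop(self):
        dv = [100, 200, 150]
        s, rep = dio.apply_blq_policy(_subject(dv), 20.0)
        assert (rep.n_imputed_zero, rep.n_dropped_trailing, rep.n_dropped_intermediate) == (0, 0, 0)
        np.testing.assert_allclose(s.dv * 1000, dv)

    def test_single_measurable_surrounded(self):
        s, rep = dio.apply_blq_policy(_subject([5, 100, 5]), 20.0)
        assert rep.n_imputed_zero == 1
        assert rep.n_dropped_trailing == 1
        assert s.n_obs == 2
        assert s.dv[0] == 0.0

    def test_all_blq_profile_is_degenerate(self):
        s, rep = dio.apply_blq_policy(_subject([1, 2, 3]), 20.0)
        assert rep.degenerate
        assert rep.n_imputed_zero == 3
        np.testing.assert_allclose(s.dv, 0.0)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.sampled_from([5.0, 100.0, 250.0]), min_size=1, max_size=12))
    def test_idempotent_and_preserves_measurable(self, dv):
        s0 = _subject(dv)
        s1, rep1 = dio.apply_blq_policy(s0, 20.0)
        s2, rep2 = dio.apply_blq_policy(s1, 20.0)
        np.testing.assert_array_equal(s1.obs_times, s2.obs_times)
        np.testing.assert_allclose(s1.dv, s2.dv)
        assert rep2.n_dropped_trailing == rep2.n_dropped_intermediate == 0
        # measurable records are untouched and the count identity holds
        meas0 = s0.dv[s0.dv >= 0.02]
        meas1 = s1.dv[s1.dv >= 0.02]
        np.testing.assert_allclose(np.sort(meas0), np.sort(meas1))
        dropped = rep1.n_dropped_trailing + rep1.n_dropped_intermediate
        assert s1.n_obs == s0.n_obs - dropped


class TestRoundTrip:
    def test_unit_conversion(self, tmp_path):
        s = _subject([2288.0])
        assert s.dv[0] == pytest.approx(2.288)
        path = tmp_path / "d.csv"
        dio.write_dataset([s], path)
        (s2,) = dio.read_dataset(path)
        assert s2.dv[0] == pytest.approx(2.288, rel=1e-12)

    def test_round_trip_preserves_numeric_fields(self, tmp_path):
        s = _subject([123.456, 78.91, 2288.123456], times=[0.3333, 1.0, 2.0], wt=82.974321)
        path = tmp_path / "d.csv"
        dio.write_dataset([s], path)
        (s2,) = dio.read_dataset(path)
        np.testing.assert_allclose(s2.dv, s.dv, rtol=1e-12)
        np.testing.assert_allclose(s2.obs_times, s.obs_times, rtol=1e-12)
        np.testing.assert_allclose(s2.dose_amts, s.dose_amts, rtol=1e-12)
        assert s2.wt == pytest.approx(s.wt, rel=1e-12)
        assert (s2.trt, s2.study) == (s.trt, s.study)

    def test_count_preservation(self, tmp_path):
        subs = [_subject(np.linspace(100, 2000, 23), times=np.arange(23.0), id=i) for i in (1, 2)]
        path = tmp_path / "d.csv"
        dio.write_dataset(subs, path)
        back = dio.read_dataset(path)
        assert len(back) == 2
        assert all(s.n_obs == 23 for s in back)

    def test_errors(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("ID,TIME,AMT\n1,0,35\n")
        with pytest.raises(ValueError, match="missing required columns"):
            dio.read_dataset(p)
        p.write_text(
            "ID,TIME,AMT,DV,EVID,MDV,WT,TRT,STUDY,BLQ\n"
            "1,1.0,0,100,0,0,70,1,0,0\n1,0.5,0,90,0,0,70,1,0,0\n"
        )
        with pytest.raises(ValueError, match="non-monotone"):
            dio.read_dataset(p)
        p.write_text(
            "ID,TIME,AMT,DV,EVID,MDV,WT,TRT,STUDY,BLQ\n1,0,35,.,4,1,70,1,0,0\n"
        )
        with pytest.raises(ValueError, match="EVID"):
            dio.read_dataset(p)
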