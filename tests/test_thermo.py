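"""Thermocouple statistics: Welch t-test, treatment comparison, offset fit."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from pyrocosm import (
    DataError,
    DegenerateDataError,
    NoiseModel,
    ThermocoupleTrace,
    compare_treatments,
    gen_thermocouple_traces,
    load_table1_reference,
    model_vs_observed,
    read_traces_csv,
    welch_t,
    write_traces_csv,
)


class TestWelch:
    def test_identical_samples_give_t0_p1(self):
        res = welch_t([1, 2, 3], [1, 2, 3])
        assert res["t"] == 0.0 and res["p"] == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # means 2.5 vs 3.5, equal variances 5/3, n = 4 each:
        # t = -1/sqrt(5/6) = -1.0954, Welch-Satterthwaite dof = 6
        res = welch_t([1, 2, 3, 4], [2, 3, 4, 5])
        assert res["t"] == pytest.approx(-1.095, abs=5e-4)
        assert res["dof"] == pytest.approx(6.0)
        # cross-check against the independent scipy implementation
        ref = sps.ttest_ind([1, 2, 3, 4], [2, 3, 4, 5], equal_var=False)
        assert res["t"] == pytest.approx(ref.statistic)
        assert res["p"] == pytest.approx(ref.pvalue)

    def test_errors(self):
        with pytest.raises(DataError):
            welch_t([1.0], [1, 2, 3])
        with pytest.raises(DegenerateDataError):
            welch_t([2, 2, 2], [3, 3, 3])

    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=12),
           st.lists(st.floats(-50, 50), min_size=3, max_size=12),
           st.floats(-100, 100))
    def test_antisymmetry_and_shift_invariance(self, a, b, c):
        a, b = np.asarray(a), np.asarray(b)
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            return
        r1 = welch_t(a, b)
        r2 = welch_t(b, a)
        assert r1["t"] == pytest.approx(-r2["t"], rel=1e-9, abs=1e-12)
        assert r1["p"] == pytest.approx(r2["p"], rel=1e-9, abs=1e-12)
        r3 = welch_t(a + c, b + c)
        assert r3["t"] == pytest.approx(r1["t"], rel=1e-6, abs=1e-8)


def _trace(cover, fire, rep, depth, temps, times=None):
    temps = np.asarray(temps, float)
    if times is None:
        times = np.arange(temps.size, dtype=float)
    return ThermocoupleTrace(cover=cover, fire_temp=fire, replicate=rep,
                             depth_nominal=depth, times=times, temps=temps)


class TestCompareTreatments:
    def test_identical_pair_means_match(self):
        a = _trace("bare", "450", 1, 2.0, [30, 40, 50, 60])
        b = _trace("biocrust", "450", 1, 2.0, [30, 40, 50, 60])
        out = compare_treatments([a, b], window=10.0)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["mean_bare_C"] == row["mean_bsc_C"]
        assert row["t_statistic"] == 0.0

    def test_known_offset_recovered(self, field_600):
        # bare runs +10 C hotter; noise sd 1 -> difference within 3 SE of 10
        kw = dict(depths=(2.0,), reps=3,
                  noise=NoiseModel(temp_sd=1.0, depth_jitter_sd=0.0, seed=11))
        bare = gen_thermocouple_traces(field_600, cover="bare", fire_temp="600",
                                       temp_offset_C=10.0, **kw)
        bsc = gen_thermocouple_traces(field_600, cover="biocrust", fire_temp="600",
                                      temp_offset_C=0.0, **kw)
        out = compare_treatments(bare + bsc, window=1800.0)
        row = out.iloc[0]
        diff = row["mean_bare_C"] - row["mean_bsc_C"]
        n = row["n_bare"]
        se = np.sqrt(2.0 / n)  # sd 1 per sample in both pools
        assert abs(diff - 10.0) <= 3 * se

    def test_full_design_yields_six_strata(self, field_450, field_600):
        traces = []
        for fire, field in (("450", field_450), ("600", field_600)):
            for cover, off in (("bare", 0.0), ("biocrust", -10.0)):
                traces += gen_thermocouple_traces(
                    field, depths=(2.0, 5.0, 8.0), reps=2,
                    noise=NoiseModel(temp_sd=2.0, depth_jitter_sd=0.0, seed=5),
                    cover=cover, fire_temp=fire, temp_offset_C=off)
        out = compare_treatments(traces, window=1800.0)
        assert len(out) == 6
        assert set(out["fire_temp"]) == {"450", "600"}
        assert set(out["depth_cm"]) == {2.0, 5.0, 8.0}
        assert (out["p_value"] < 0.05).all()
        assert (out["mean_bare_C"] > out["mean_bsc_C"]).all()

    def test_missing_cover_stratum_skipped_with_warning(self, caplog):
        a = _trace("bare", "450", 1, 2.0, [30, 40, 50, 60])
        with caplog.at_level("WARNING"):
            out = compare_treatments([a], window=10.0)
        assert out.empty
        assert any("skipped" in r.message for r in caplog.records)


class TestModelVsObserved:
    def test_exact_slice_has_zero_rmse_and_offset(self, field_600):
        tr = _trace("bare", "600", 1, 5.0,
                    field_600.temps[field_600.depth_index(5.0)],
                    times=field_600.times)
        res = model_vs_observed(field_600, tr)
        assert res["rmse_at_nominal"] == pytest.approx(0.0, abs=1e-9)
        assert res["best_offset"] == 0.0

    def test_mislabelled_depth_recovers_plus_1cm(self, field_600):
        # probe actually at 3 cm but labelled 2 cm
        tr = _trace("biocrust", "600", 1, 2.0,
                    field_600.temps[field_600.depth_index(3.0)],
                    times=field_600.times)
        res = model_vs_observed(field_600, tr)
        assert res["best_offset"] == pytest.approx(1.0)
        assert res["rmse_at_best"] < res["rmse_at_nominal"]

    def test_noisy_offset_recovery_within_grid_step(self, field_600):
        rng = np.random.default_rng(42)
        true = field_600.at_depth(2.5)
        errs = []
        for _ in range(20):
            tr = _trace("bare", "600", 1, 2.0, true + rng.normal(0, 2.0, true.size),
                        times=field_600.times)
            errs.append(model_vs_observed(field_600, tr)["best_offset"] - 0.5)
        assert abs(np.median(errs)) <= 0.2

    def test_no_time_overlap_raises(self, field_600):
        tr = _trace("bare", "600", 1, 2.0, [30.0, 40.0],
                    times=np.array([1e6, 1e6 + 1]))
        with pytest.raises(DataError):
            model_vs_observed(field_600, tr)


def test_trace_csv_round_trip(tmp_path, field_450):
    traces = gen_thermocouple_traces(
        field_450, depths=(2.0, 5.0), reps=2,
        noise=NoiseModel(temp_sd=1.0, depth_jitter_sd=0.2, seed=3),
        cover="biocrust", fire_temp="450")
    path = tmp_path / "traces.csv"
    write_traces_csv(traces, path)
    back = read_traces_csv(path)
    assert len(back) == len(traces)
    key = lambda t: (t.cover, t.fire_temp, t.replicate, t.depth_nominal)
    for orig, rt in zip(sorted(traces, key=key), sorted(back, key=key)):
        assert key(orig) == key(rt)
        np.testing.assert_allclose(rt.temps, orig.temps, atol=1e-9)


def test_table1_reference_fixture_shape():
    ref = load_table1_reference()
    assert len(ref) == 6
    assert set(ref["fire_temp"]) == {450, 600}
    assert set(ref["depth_cm"]) == {2, 5, 8}
    # published maxima: bare exceeds biocrust in every stratum
    assert (ref["max_bare_C"] > ref["max_bsc_C"]).all()
    assert ref["max_bare_C"].max() == pytest.approx(502.1)
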