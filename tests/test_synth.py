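"""Synthetic-data generators and thermotolerance parameter recovery."""

import numpy as np
import pytest

from pyrocosm import (
    DataError,
    DesignSpec,
    NoiseModel,
    SurvivalModel,
    build_design,
    fit_lethal_midpoint,
    gen_cfu_grid,
    gen_thermocouple_traces,
)


class TestBuildDesign:
    def test_default_design_has_360_plates(self):
        d = build_design(DesignSpec())
        assert len(d) == 360
        assert d["growth"].isna().all()
        assert d[["cover", "fire_temp", "depth_cm", "replicate"]].duplicated().sum() == 0

    def test_zero_replicates_empty(self):
        assert len(build_design(DesignSpec(replicates=0))) == 0

    def test_product_count(self):
        spec = DesignSpec(covers=("bare",), fire_levels=("600",),
                          depths=tuple(range(1, 11)), replicates=1)
        assert len(build_design(spec)) == 10
        assert spec.total == 10


class TestTraceGenerator:
    def test_zero_noise_reproduces_exact_slices(self, field_600):
        noise = NoiseModel(temp_sd=0.0, depth_jitter_sd=0.0, seed=1)
        traces = gen_thermocouple_traces(field_600, depths=(2.0, 5.0), reps=2,
                                         noise=noise)
        for tr in traces:
            exact = field_600.temps[field_600.depth_index(tr.depth_nominal)]
            np.testing.assert_array_equal(tr.temps, exact)

    def test_residual_sd_matches_noise_model(self, field_600):
        # 2461 samples: sample sd lies within the [1.8, 2.2] chi-square band
        noise = NoiseModel(temp_sd=2.0, depth_jitter_sd=0.0, seed=2)
        (tr,) = gen_thermocouple_traces(field_600, depths=(5.0,), reps=1,
                                        noise=noise)
        resid = tr.temps - field_600.temps[field_600.depth_index(5.0)]
        assert 1.8 <= resid.std(ddof=1) <= 2.2

    def test_depth_jitter_visible_to_offset_search(self, field_600):
        from pyrocosm import model_vs_observed
        noise = NoiseModel(temp_sd=0.0, depth_jitter_sd=0.5, seed=3)
        traces = gen_thermocouple_traces(field_600, depths=(2.0,), reps=12,
                                         noise=noise)
        recovered = [model_vs_observed(field_600, tr)["best_offset"]
                     for tr in traces]
        # offsets scatter around zero with the jitter scale, and are not all zero
        assert np.abs(np.mean(recovered)) < 0.5
        assert np.std(recovered) > 0.1

    def test_deterministic_given_seed(self, field_600):
        noise = NoiseModel(temp_sd=2.0, depth_jitter_sd=0.5, seed=9)
        a = gen_thermocouple_traces(field_600, depths=(2.0, 8.0), reps=2, noise=noise)
        b = gen_thermocouple_traces(field_600, depths=(2.0, 8.0), reps=2, noise=noise)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.temps, y.temps)

    def test_adding_replicates_preserves_earlier_draws(self, field_600):
        noise = NoiseModel(temp_sd=2.0, depth_jitter_sd=0.5, seed=9)
        few = gen_thermocouple_traces(field_600, depths=(2.0,), reps=2, noise=noise)
        many = gen_thermocouple_traces(field_600, depths=(2.0,), reps=5, noise=noise)
        for x, y in zip(few, many[:2]):
            np.testing.assert_array_equal(x.temps, y.temps)


class TestCFUGenerator:
    def test_no_thermal_mortality_reaches_baseline(self, peaks_by_fire):
        model = SurvivalModel(T50=1e6, slope=10.0, p_base=0.9)
        g = gen_cfu_grid(peaks_by_fire, model=model, seed=4)
        frac = g["growth"].mean()
        se = np.sqrt(0.9 * 0.1 / len(g))
        assert abs(frac - 0.9) <= 3 * se

    def test_universal_mortality_all_absent(self, peaks_by_fire):
        model = SurvivalModel(T50=0.0, slope=1.0, p_base=0.9)
        g = gen_cfu_grid(peaks_by_fire, model=model, seed=4)
        assert g["growth"].sum() == 0

    def test_monte_carlo_matches_analytic_expectation(self, peaks_by_fire):
        # single-treatment design: fraction averaged over 200 seeds vs sum p(d)/10
        model = SurvivalModel(T50=100.0, slope=10.0, p_base=0.9)
        spec = DesignSpec(covers=("bare",), fire_levels=("600",), replicates=6)
        p = model.prob(peaks_by_fire["600"].to_numpy())
        expect = p.mean()
        fracs = [gen_cfu_grid(peaks_by_fire, model=model, spec=spec, seed=s)
                 ["growth"].mean() for s in range(200)]
        n_draws = 200 * spec.total
        se = np.sqrt((p * (1 - p)).mean() / n_draws)
        assert abs(np.mean(fracs) - expect) <= 3 * se

    def test_growth_probability_monotone_in_peak(self, peaks_by_fire):
        model = SurvivalModel()
        p = model.prob(np.array([20.0, 60.0, 100.0, 140.0, 300.0]))
        assert np.all(np.diff(p) < 0)

    def test_missing_fire_level_raises(self, peaks_by_fire):
        with pytest.raises(DataError):
            gen_cfu_grid({"450": peaks_by_fire["450"]}, seed=1)

    def test_deterministic_given_seed(self, peaks_by_fire):
        a = gen_cfu_grid(peaks_by_fire, seed=5)
        b = gen_cfu_grid(peaks_by_fire, seed=5)
        assert a.equals(b)
        c = gen_cfu_grid(peaks_by_fire, seed=6)
        assert not a["growth"].equals(c["growth"])


class TestT50Recovery:
    def test_median_recovery_within_10C_over_50_seeds(self, peaks_by_fire):
        model = SurvivalModel(T50=100.0, slope=10.0, p_base=0.9)
        estimates = []
        for seed in range(50):
            g = gen_cfu_grid(peaks_by_fire, model=model, seed=seed)
            estimates.append(fit_lethal_midpoint(g, peaks_by_fire).t50)
        assert abs(np.median(estimates) - 100.0) <= 10.0

    def test_error_decreases_with_replicates(self, peaks_by_fire):
        model = SurvivalModel(T50=100.0, slope=10.0, p_base=0.9)
        med_err = {}
        for reps in (6, 24, 96):
            errs = []
            for seed in range(15):
                g = gen_cfu_grid(peaks_by_fire, model=model,
                                 spec=DesignSpec(replicates=reps), seed=seed)
                errs.append(abs(fit_lethal_midpoint(g, peaks_by_fire).t50 - 100.0))
            med_err[reps] = np.median(errs)
        assert med_err[96] <= med_err[24] <= med_err[6]

    def test_all_positive_grid_hits_upper_bound_and_flags(self, peaks_by_fire):
        g = gen_cfu_grid(peaks_by_fire, model=SurvivalModel(T50=1e6, p_base=1.0),
                         seed=1)
        assert g["growth"].all()
        fit = fit_lethal_midpoint(g, peaks_by_fire)
        assert fit.at_boundary
        assert fit.t50 == fit.grid_hi

    def test_likelihood_peaks_near_truth_for_large_grid(self, peaks_by_fire):
        model = SurvivalModel(T50=100.0, slope=10.0, p_base=0.9)
        g = gen_cfu_grid(peaks_by_fire, model=model,
                         spec=DesignSpec(replicates=100), seed=7)
        grid = np.array([50.0, 100.0, 150.0])
        fit = {t: fit_lethal_midpoint(g, peaks_by_fire,
                                      t50_grid=np.array([t])).log_likelihood
               for t in grid}
        assert fit[100.0] > fit[50.0] and fit[100.0] > fit[150.0]
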