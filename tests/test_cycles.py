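"""Cycle detection, convoy fitting, pooled regression and inter-convoy
statistics."""

import numpy as np
import pytest

from convoyquant import (
    ConvoyParams,
    FittedConvoy,
    IntensityTrace,
    NoiseModel,
    analytic_durations,
    find_isolated_cycles,
    fit_convoy_cycle,
    interconvoy_stats,
    pooled_upramp_regression,
    simulate_convoy_trace,
)


def _best_cycle(trace, **kw):
    cycles = [c for c in find_isolated_cycles(trace, **kw) if c.n_frames >= 8]
    return max(cycles, key=lambda c: c.core_end - c.core_start)


class TestFindIsolatedCycles:
    def test_all_zero_trace(self):
        tr = IntensityTrace(np.arange(50) * 3.0, np.zeros(50),
                            units="rna_equivalents")
        assert find_isolated_cycles(tr) == []

    def test_empty_trace_raises(self):
        tr = IntensityTrace(np.array([]), np.array([]), units="rna_equivalents")
        with pytest.raises(ValueError):
            find_isolated_cycles(tr)

    def test_two_convoys_with_long_gap(self, geom, hiv_params):
        """Two cycles separated by 120 s of silence are both found with
        boundaries within one frame of the generator's ground truth."""
        dt = 3.0
        d = analytic_durations(hiv_params, geom)
        v = hiv_params.v_el * 1000 / 60
        gap = 120.0
        t0_a = 30.0
        t0_b = t0_a + geom.l_pre / v + d["visible_total"] + gap - geom.l_pre / v
        times = np.arange(0.0, t0_b + 500.0, dt)
        from convoyquant import ts_intensity

        vals = ts_intensity(times, hiv_params, geom, t0_a) + ts_intensity(
            times, hiv_params, geom, t0_b
        )
        tr = IntensityTrace(times, vals, units="rna_equivalents")
        cycles = find_isolated_cycles(tr)
        assert len(cycles) == 2
        # oracle: frames where each convoy's own signal exceeds threshold
        for cyc, t0 in zip(cycles, (t0_a, t0_b)):
            own = ts_intensity(times, hiv_params, geom, t0)
            above = np.flatnonzero(own > 0.5)
            assert cyc.isolated
            assert abs(cyc.core_start - above[0]) <= 1
            assert abs(cyc.core_end - (above[-1] + 1)) <= 1

    def test_cycle_touching_boundary_not_isolated(self, geom, hiv_params):
        tr = simulate_convoy_trace(hiv_params, geom, dt=3.0, duration=200.0,
                                   t0=-60.0)
        cycles = find_isolated_cycles(tr)
        assert len(cycles) == 1
        assert not cycles[0].isolated


class TestFitConvoyCycle:
    def test_noiseless_round_trip_exact(self, geom, hiv_params):
        tr = simulate_convoy_trace(hiv_params, geom, dt=3.0, duration=450.0,
                                   t0=30.0)
        fit = fit_convoy_cycle(_best_cycle(tr), geom)
        assert fit.params.n_pol == hiv_params.n_pol
        assert fit.params.t_space == pytest.approx(hiv_params.t_space, rel=0.01)
        assert fit.params.v_el == pytest.approx(hiv_params.v_el, rel=0.01)
        assert fit.params.t_proc == pytest.approx(hiv_params.t_proc, rel=0.01)
        assert fit.t0 == pytest.approx(30.0, abs=2.0)
        # relative residual on noiseless input is numerically zero
        tss = np.sqrt(np.sum(_best_cycle(tr).values ** 2))
        assert fit.residual_norm / tss < 1e-5

    def test_noiseless_round_trip_random_params(self, geom):
        """Generator round trip across the parameter ranges the study spans."""
        rng = np.random.default_rng(7)
        n_sets = 12
        for _ in range(n_sets):
            params = ConvoyParams(
                int(rng.integers(3, 40)),
                float(rng.uniform(2.0, 12.0)),
                float(rng.uniform(1.0, 6.0)),
                float(rng.uniform(30.0, 200.0)),
            )
            d = analytic_durations(params, geom)
            tr = simulate_convoy_trace(
                params, geom, dt=3.0, duration=d["visible_total"] + 150.0, t0=30.0
            )
            fit = fit_convoy_cycle(_best_cycle(tr), geom)
            assert fit.params.n_pol == params.n_pol
            if not fit.v_el_is_lower_bound:
                assert fit.params.t_space == pytest.approx(params.t_space, rel=0.02)
                assert fit.params.v_el == pytest.approx(params.v_el, rel=0.02)
                # release times are invisible between sample points, so
                # t_proc carries a flat identifiability cell of order dt/3
                assert fit.params.t_proc == pytest.approx(
                    params.t_proc, rel=0.02, abs=1.0
                )

    def test_noisy_recovery_medians(self, geom, hiv_params):
        """Median |error| over seeded noisy replicates: n_pol within 10%,
        t_space within 15%."""
        err_n, err_ts = [], []
        for seed in range(20):
            tr = simulate_convoy_trace(
                hiv_params, geom, dt=3.0, duration=420.0,
                noise=NoiseModel(additive_sd=0.5), seed=seed, t0=30.0,
            )
            fit = fit_convoy_cycle(_best_cycle(tr), geom, seed=seed)
            err_n.append(abs(fit.params.n_pol / hiv_params.n_pol - 1))
            err_ts.append(abs(fit.params.t_space / hiv_params.t_space - 1))
        assert np.median(err_n) <= 0.10
        assert np.median(err_ts) <= 0.15

    def test_truncated_noisy_cycles_set_lower_bound_flag(self, geom):
        """With no plateau the elongation rate is weakly constrained: the
        residual profile is flat in v_el for most noise realizations."""
        params = ConvoyParams(30, 8.0, 6.0, 103.0)
        assert analytic_durations(params, geom)["truncated"]
        flags = []
        for seed in range(5):
            tr = simulate_convoy_trace(
                params, geom, dt=3.0, duration=600.0,
                noise=NoiseModel(additive_sd=1.0), seed=seed, t0=30.0,
            )
            fit = fit_convoy_cycle(_best_cycle(tr), geom, seed=seed)
            flags.append(fit.v_el_is_lower_bound)
        assert sum(flags) >= 3

    def test_too_short_cycle_raises(self, geom, hiv_params):
        tr = simulate_convoy_trace(hiv_params, geom, dt=3.0, duration=450.0,
                                   t0=30.0)
        cyc = _best_cycle(tr)
        cyc.times = cyc.times[:5]
        cyc.values = cyc.values[:5]
        cyc.end = cyc.start + 5
        cyc.core_end = min(cyc.core_end, cyc.end)
        with pytest.raises(ValueError):
            fit_convoy_cycle(cyc, geom)


def _make_fit(n_pol, t_space, v_el, t_proc=103.0, t0=0.0):
    return FittedConvoy(
        params=ConvoyParams(n_pol, t_space, v_el, t_proc),
        t0=t0,
        residual_norm=0.0,
    )


class TestPooledRegression:
    def test_closed_form_slope_intercept(self, geom):
        """Cohort with common t_space = 4 s and l_ms2/v_el = 40 s gives
        slope 4 and intercept 36 exactly."""
        v_el = geom.l_ms2 / 40.0 * 60 / 1000
        fits = [_make_fit(n, 4.0, v_el) for n in range(5, 31)]
        out = pooled_upramp_regression(fits, geom)
        assert out["slope"] == pytest.approx(4.0, abs=1e-9)
        assert out["intercept"] == pytest.approx(36.0, abs=1e-6)
        assert out["v_el_pooled"] == pytest.approx(v_el, rel=1e-6)

    def test_single_n_pol_rejected(self, geom):
        fits = [_make_fit(10, 4.0, 4.0) for _ in range(5)]
        with pytest.raises(ValueError):
            pooled_upramp_regression(fits, geom)

    def test_pooled_agrees_with_mean_of_per_cycle_fits(self, geom):
        """On a synthetic cohort the pooled regression estimates match the
        mean of the per-cycle fits within 10%."""
        t_space, v_el = 4.1, 4.1
        fits = []
        for n in (8, 12, 16, 20, 24, 28):
            params = ConvoyParams(n, t_space, v_el, 103.0)
            d = analytic_durations(params, geom)
            tr = simulate_convoy_trace(
                params, geom, dt=3.0, duration=d["visible_total"] + 150.0,
                t0=30.0,
            )
            fits.append(fit_convoy_cycle(_best_cycle(tr), geom))
        out = pooled_upramp_regression(fits, geom)
        mean_ts = np.mean([f.params.t_space for f in fits])
        mean_v = np.mean([f.params.v_el for f in fits])
        assert out["slope"] == pytest.approx(mean_ts, rel=0.10)
        assert out["v_el_pooled"] == pytest.approx(mean_v, rel=0.10)

    def test_independent_draws_have_null_correlation(self, geom):
        rng = np.random.default_rng(3)
        n = 400
        fits = [
            _make_fit(int(rng.integers(5, 30)), float(rng.uniform(2, 8)), 4.0)
            for _ in range(n)
        ]
        out = pooled_upramp_regression(fits, geom)
        assert abs(out["npol_tspace_correlation"]) < 2 / np.sqrt(n)


class TestInterconvoyStats:
    def test_duration_product_rule(self, geom):
        fits = [_make_fit(19, 4.1, 4.1)]
        out = interconvoy_stats([fits], geom)
        assert out["convoy_durations"][0] == pytest.approx(77.9)

    def test_single_cycle_no_gaps(self, geom):
        out = interconvoy_stats([[_make_fit(10, 4.0, 4.0)]], geom)
        assert out["gaps"].size == 0
        assert out["exp_fit_tau"] is None

    def test_gap_measurement_and_exponential_tau(self, geom):
        """Gaps measured end-of-UP-ramp to start-of-next-UP-ramp; the MLE
        time constant of exponential gaps is consistent."""
        rng = np.random.default_rng(1)
        tau = 100.0
        per_trace = []
        v = 4.0 * 1000 / 60
        for _ in range(250):
            d = analytic_durations(ConvoyParams(10, 4.0, 4.0, 100.0), geom)
            gap = float(rng.exponential(tau))
            t0_a = 0.0
            up_end_a = t0_a + geom.l_pre / v + d["up_ramp"]
            # place the next cycle so its UP ramp starts exactly gap later
            t0_b = up_end_a + gap - geom.l_pre / v
            per_trace.append(
                [_make_fit(10, 4.0, 4.0, 100.0, t0_a),
                 _make_fit(10, 4.0, 4.0, 100.0, t0_b)]
            )
        out = interconvoy_stats(per_trace, geom)
        assert out["gaps"].size == 250
        se = tau / np.sqrt(250)
        assert abs(out["exp_fit_tau"] - tau) < 3 * se
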