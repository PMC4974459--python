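"""Four-state promoter model: stationary algebra, constrained-rate solving,
population Monte-Carlo and distribution comparison."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from convoyquant import (
    CellCounts,
    GridSpec,
    PopulationSummary,
    PromoterModel,
    SimSettings,
    compare_distributions,
    fit_dwell,
    simulate_population,
    solve_constrained_rates,
    stationary_stats,
)
from convoyquant.promoter import _chi2_nascent


@pytest.fixture
def hiv_regime_model():
    """A grid-member model completed from the reported HIV-1 population means
    (492 mature, 32 nascent pre-mRNAs per cell)."""
    grid = GridSpec()
    partial, _ = next(iter(grid.combos()))
    res = solve_constrained_rates(partial, PopulationSummary(492.0, 32.0))
    assert res.status == "ok"
    return res.model


class TestStationaryStats:
    def test_telegraph_limit(self):
        m = PromoterModel(k_on1=0.02, k_off1=0.01, k_off2=0.0, f1=0.5,
                          k_on2a=1 / 300, k_on2b=1 / 1200, k_ini=0.3,
                          k_release=0.01, k_deg=0.001)
        ss = stationary_stats(m)
        assert ss.pi["ON"] == pytest.approx(0.02 / 0.03)
        assert ss.pi["OFF2a"] == 0.0

    def test_release_decay_ratio_identity(self, hiv_regime_model):
        ss = stationary_stats(hiv_regime_model)
        assert ss.mean_mature / ss.mean_nascent == pytest.approx(
            hiv_regime_model.k_release / hiv_regime_model.k_deg
        )

    def test_absorbing_on_warns(self):
        m = PromoterModel(k_on1=0.01, k_off1=0.0, k_off2=0.0, f1=0.5,
                          k_on2a=0.1, k_on2b=0.1, k_ini=0.1,
                          k_release=0.01, k_deg=0.001)
        with pytest.warns(UserWarning):
            ss = stationary_stats(m)
        assert ss.pi["ON"] == 1.0

    def test_matches_empirical_occupancy(self, hiv_regime_model):
        """Analytic pi vs end-state occupancy of a simulated population,
        within 3 binomial SEs per state."""
        m = hiv_regime_model
        n = 1500
        _, states = simulate_population(m, n, 18000, 2.0, seed=3,
                                        return_states=True)
        ss = stationary_stats(m)
        for name in ("ON", "OFF1", "OFF2a", "OFF2b"):
            frac = float(np.mean(states == name))
            p = ss.pi[name]
            se = np.sqrt(p * (1 - p) / n)
            assert abs(frac - p) < 3 * se + 1e-12

    def test_linear_vs_branched_equivalence(self):
        """A branched model (OFF2 states entered from OFF1 with split f1)
        has the same stationary law as the equivalent linear chain with a
        single lumped OFF2 exit rate when the two exits are equal."""
        k = dict(k_on1=1 / 120, k_off1=1 / 110, k_ini=0.3, k_release=0.01,
                 k_deg=0.001)
        branched = PromoterModel(k_off2=0.004, f1=0.3, k_on2a=1 / 300,
                                 k_on2b=1 / 300, **k)
        # lumped: one OFF2 pool with the same exit rate
        lumped = PromoterModel(k_off2=0.004, f1=1.0, k_on2a=1 / 300,
                               k_on2b=1 / 999, **k)
        pb = stationary_stats(branched).pi
        pl = stationary_stats(lumped).pi
        assert pb["ON"] == pytest.approx(pl["ON"])
        assert pb["OFF2a"] + pb["OFF2b"] == pytest.approx(pl["OFF2a"])


class TestSolveConstrainedRates:
    def test_reported_release_rate_arithmetic(self):
        grid = GridSpec()
        partial, _ = next(iter(grid.combos()))
        res = solve_constrained_rates(partial, PopulationSummary(492.0, 32.0))
        # k_release = k_deg * meanMat/meanNasc = (492/32)/75 per min
        assert res.k_release * 60.0 == pytest.approx((492 / 32) / 75, rel=1e-9)

    def test_algebraic_round_trip(self):
        m = PromoterModel(k_on1=1 / 120, k_off1=1 / 110, k_off2=0.001, f1=0.8,
                          k_on2a=1 / 300, k_on2b=1 / 1800, k_ini=1 / 3,
                          k_release=0.0034, k_deg=1 / 4500)
        ss = stationary_stats(m)
        partial = replace(m, k_off2=0.0, k_release=0.0)
        res = solve_constrained_rates(
            partial, PopulationSummary(ss.mean_mature, ss.mean_nascent)
        )
        assert res.status == "ok"
        assert res.k_off2 == pytest.approx(0.001, abs=1e-9)
        assert res.k_release == pytest.approx(m.k_release, rel=1e-9)

    def test_unreachable_mean_is_infeasible(self):
        grid = GridSpec()
        partial, _ = next(iter(grid.combos()))
        # demand more mature RNA than the k_off2 = 0 ceiling allows
        ceiling = stationary_stats(replace(partial, k_off2=0.0,
                                           k_release=1.0)).mean_mature
        res = solve_constrained_rates(
            partial, PopulationSummary(ceiling * 2, ceiling * 2 / 15.0)
        )
        assert res.status == "infeasible"
        assert res.model is None


class TestSimulatePopulation:
    def test_zero_initiation_zero_counts(self):
        m = PromoterModel(k_on1=1 / 120, k_off1=1 / 110, k_off2=0.001, f1=0.8,
                          k_on2a=1 / 300, k_on2b=1 / 1800, k_ini=0.0,
                          k_release=0.0034, k_deg=1 / 4500)
        counts = simulate_population(m, 50, 2000, 1.0, seed=1)
        assert np.all(counts.nascent == 0)
        assert np.all(counts.mature == 0)

    def test_dt_stability_guard_names_rate(self, hiv_regime_model):
        with pytest.raises(ValueError, match="k_"):
            simulate_population(hiv_regime_model, 10, 100, 60.0, seed=0)

    def test_fixed_step_matches_exact_scheme(self, hiv_regime_model):
        """Mean nascent and mature counts agree between the discretized and
        the event-driven samplers within 3 SEs."""
        m = hiv_regime_model
        fix = simulate_population(m, 600, 18000, 1.0, seed=11)
        exact = simulate_population(m, 300, 18000, 1.0, seed=12, scheme="exact")
        for a, b in ((fix.nascent, exact.nascent), (fix.mature, exact.mature)):
            se = np.sqrt(a.std() ** 2 / a.size + b.std() ** 2 / b.size)
            assert abs(a.mean() - b.mean()) < 3 * se

    def test_means_match_stationary_stats(self, hiv_regime_model):
        m = hiv_regime_model
        ss = stationary_stats(m)
        counts = simulate_population(m, 1000, 18000, 2.0, seed=21)
        for vals, mean in ((counts.nascent, ss.mean_nascent),
                           (counts.mature, ss.mean_mature)):
            se = vals.std() / np.sqrt(vals.size)
            assert abs(vals.mean() - mean) < 3 * se

    def test_dt_refinement_control(self, hiv_regime_model):
        """Halving the step from 1 s to 0.5 s moves the mean counts by less
        than one standard error."""
        m = hiv_regime_model
        a = simulate_population(m, 800, 14400, 1.0, seed=31)
        b = simulate_population(m, 800, 28800, 0.5, seed=32)
        for x, y in ((a.nascent, b.nascent), (a.mature, b.mature)):
            se = np.sqrt(x.std() ** 2 / x.size + y.std() ** 2 / y.size)
            assert abs(x.mean() - y.mean()) < 3 * se

    def test_on_dwell_distribution(self, hiv_regime_model):
        """ON dwell times in the exact simulator are exponential with mean
        1/k_off1 (checked through the dwell fitter)."""
        from convoyquant.synthetic import _gillespie_promoter_path

        m = hiv_regime_model
        rng = np.random.default_rng(9)
        dwells = []
        while len(dwells) < 400:
            path = _gillespie_promoter_path(m, 36000.0, rng)
            dwells.extend(e - s for st, s, e in path[1:-1] if st == "ON")
        fit = fit_dwell(np.asarray(dwells), "mono")
        expect = 1.0 / m.k_off1
        se = expect / np.sqrt(len(dwells))
        assert abs(fit.taus[0] - expect) < 3 * se

    def test_off2_dwell_mixture(self, hiv_regime_model):
        """Pooled OFF2 dwells form the f1-weighted mixture of the OFF2a and
        OFF2b exponentials: the mean matches the closed form and the
        bi-exponential dwell fitter reproduces the mixture mean."""
        m = hiv_regime_model
        rng = np.random.default_rng(10)
        dwells = []
        while len(dwells) < 600:
            path = _gillespie(m, rng)
            dwells.extend(path)
        dwells = np.asarray(dwells)
        expect = m.f1 / m.k_on2a + (1 - m.f1) / m.k_on2b
        sd = np.sqrt(
            m.f1 * 2 / m.k_on2a**2 + (1 - m.f1) * 2 / m.k_on2b**2 - expect**2
        )
        assert abs(dwells.mean() - expect) < 3 * sd / np.sqrt(dwells.size)
        fit = fit_dwell(dwells, "bi", seed=1)
        fitted_mean = float(np.dot(fit.weights, fit.taus))
        assert fitted_mean == pytest.approx(dwells.mean(), rel=0.05)


def _gillespie(m, rng):
    from convoyquant.synthetic import _gillespie_promoter_path

    path = _gillespie_promoter_path(m, 72000.0, rng)
    return [e - s for st, s, e in path[1:-1] if st in ("OFF2a", "OFF2b")]


class TestCompareDistributions:
    def test_identical_samples(self):
        rng = np.random.default_rng(0)
        nasc = rng.poisson(20, 500)
        mat = rng.poisson(400, 500)
        counts = CellCounts(nasc, mat)
        out = compare_distributions(counts, counts)
        assert out["ks_stat"] == 0.0
        assert out["p_mature"] == pytest.approx(1.0)

    def test_ks_statistic_equals_ecdf_oracle(self):
        """Two-sample KS statistic equals the brute-force max ECDF gap on
        seeded sample pairs."""
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = rng.poisson(rng.uniform(5, 400), int(rng.integers(50, 300)))
            b = rng.poisson(rng.uniform(5, 400), int(rng.integers(50, 300)))
            grid = np.unique(np.concatenate([a, b]))
            ecdf_a = np.searchsorted(np.sort(a), grid, side="right") / a.size
            ecdf_b = np.searchsorted(np.sort(b), grid, side="right") / b.size
            oracle = np.max(np.abs(ecdf_a - ecdf_b))
            ks = stats.ks_2samp(a, b).statistic
            assert ks == pytest.approx(oracle, abs=1e-12)

    def test_chi2_defined_for_tied_nascent_counts(self):
        """All-equal values in one sample: KS would be degenerate, but the
        pooled chi-square remains defined."""
        sim = np.zeros(200, dtype=int)
        obs = np.concatenate([np.zeros(150, dtype=int), np.full(50, 3)])
        chi2, p = _chi2_nascent(sim, obs)
        assert np.isfinite(chi2) and 0 <= p <= 1

    def test_empty_sample_rejected(self):
        c = CellCounts(np.array([1]), np.array([2]))
        with pytest.raises(ValueError):
            compare_distributions(c, CellCounts(np.array([]), np.array([])))


class TestGridSearch:
    def test_grid_of_size_one(self, hiv_regime_model):
        from convoyquant import grid_search_fit

        m = hiv_regime_model
        obs = simulate_population(m, 400, 14400, 2.0, seed=40)
        grid = GridSpec(
            inv_k_ini_s=(2.3,), f1=(0.6,), inv_k_on2b_min=(20.0,),
            k_off1_per_s=(1 / 90.0,), inv_k_on1_min=(1.0,),
        )
        sim = SimSettings(n_cells=200, n_steps=7200, dt_s=2.0)
        table, avg = grid_search_fit(grid, obs, sim, seed=41)
        assert len(table) == 1
        assert avg["inv_k_ini_s"] == 2.3
        assert avg["f1"] == 0.6
        assert avg["n_averaged"] == 1.0

    def test_default_grid_is_full_methods_grid(self):
        assert len(GridSpec()) == 8 * 4 * 4 * 4 * 5

    def test_total_simulated_time_accounting(self):
        s = SimSettings()
        assert s.n_cells == 3000
        assert s.total_time_s == 36000.0
        assert s.total_time_h == pytest.approx(10.0)
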