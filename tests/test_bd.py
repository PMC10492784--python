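"""Birth–death core: exact likelihood, Gibbs times, rjMCMC and diagnostics."""

import collections

import numpy as np
import pytest

from paleodiv.bd import TaxonTimes, bd_loglik, rjmcmc_rates, sample_times
from paleodiv.mcmcutil import (McmcRun, combine_replicates, ess, grid_summary,
                               hpd)
from paleodiv.preservation import PreservationModel
from paleodiv.synthetic import simulate_bd, simulate_preservation

from conftest import WINDOW, constant_config


def quadrature_loglik(times, lam_shifts, lam_rates, mu_shifts, mu_rates, window):
    """Independent oracle: midpoint quadrature over elementary intervals
    (every Ts/Te/shift is a breakpoint), N counted directly per interval."""
    old, young = window
    brk = np.unique(np.concatenate([[old, young],
                                    np.clip(times.ts, young, old),
                                    np.clip(times.te, young, old),
                                    np.asarray(lam_shifts, float),
                                    np.asarray(mu_shifts, float)]))
    brk = brk[(brk >= young) & (brk <= old)]
    integral = 0.0
    for a, b in zip(brk[:-1], brk[1:]):  # ascending ages
        mid = 0.5 * (a + b)
        n = np.sum((times.ts >= mid) & (times.te < mid))
        lam = np.asarray(lam_rates)[np.searchsorted(-np.asarray(lam_shifts), -mid)]
        mu = np.asarray(mu_rates)[np.searchsorted(-np.asarray(mu_shifts), -mid)]
        integral += n * (lam + mu) * (b - a)
    ll = -integral
    for t in times.ts[(times.ts < old) & (times.ts > young)]:
        ll += np.log(np.asarray(lam_rates)[np.searchsorted(-np.asarray(lam_shifts), -t)])
    for t in times.te[times.extinct & (times.te < old) & (times.te > young)]:
        ll += np.log(np.asarray(mu_rates)[np.searchsorted(-np.asarray(mu_shifts), -t)])
    return ll


class TestBdLoglik:
    def test_no_lineages_gives_zero(self):
        tt = TaxonTimes(np.empty(0), np.empty(0), np.empty(0, bool))
        assert bd_loglik(tt, [], [0.2], [], [0.1], WINDOW) == 0.0

    def test_constant_rate_closed_form(self, small_history):
        h = small_history
        tt = TaxonTimes(h.ts, h.te, h.extinct)
        lam, mu = 0.23, 0.07
        old, young = WINDOW
        S = ((h.ts < old) & (h.ts > young)).sum()
        E = (h.extinct & (h.te < old) & (h.te > young)).sum()
        L = np.sum(np.clip(h.ts, young, old) - np.clip(h.te, young, old))
        expected = S * np.log(lam) + E * np.log(mu) - (lam + mu) * L
        assert bd_loglik(tt, [], [lam], [], [mu], WINDOW) == pytest.approx(
            expected, abs=1e-9)

    def test_matches_quadrature_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = 20
            ts = rng.uniform(238, 254, n)
            te = ts - rng.uniform(0.5, 10, n)
            te = np.clip(te, 237.0, None)
            tt = TaxonTimes(ts, te, te > 237.0)
            k = rng.integers(0, 3)
            shifts = np.sort(rng.uniform(238, 253, k))[::-1]
            lam_r = rng.uniform(0.05, 0.5, k + 1)
            mu_r = rng.uniform(0.05, 0.5, k + 1)
            got = bd_loglik(tt, shifts, lam_r, shifts, mu_r, WINDOW)
            want = quadrature_loglik(tt, shifts, lam_r, shifts, mu_r, WINDOW)
            assert got == pytest.approx(want, abs=1e-6)

    def test_zero_rate_at_event_is_minus_inf(self):
        tt = TaxonTimes(np.array([250.0]), np.array([240.0]), np.array([True]))
        assert bd_loglik(tt, [], [0.0], [], [0.1], WINDOW) == -np.inf

    def test_extant_lineage_contributes_no_death_factor(self):
        extinct = TaxonTimes(np.array([250.0]), np.array([240.0]), np.array([True]))
        censored = TaxonTimes(np.array([250.0]), np.array([240.0]), np.array([False]))
        diff = (bd_loglik(extinct, [], [0.2], [], [0.1], WINDOW)
                - bd_loglik(censored, [], [0.2], [], [0.1], WINDOW))
        assert diff == pytest.approx(np.log(0.1))


class TestSampleTimes:
    def test_high_q_pins_times_to_occurrences(self):
        occs = [np.array([250.0, 246.0, 243.0]), np.array([249.0, 241.0])]
        model = PreservationModel("HPP", [200.0])
        post = sample_times(occs, model, (0.2, 0.1), WINDOW,
                            McmcRun(iterations=2000, rng_seed=1), fix_q=True)
        assert np.allclose(post.times.ts, [250.0, 249.0], atol=0.05)
        assert np.allclose(post.times.te, [243.0, 241.0], atol=0.05)

    def test_extension_matches_truncated_exponential_mean(self):
        # one lineage far from the window edge: E[ext] ~ 1/(q+mu)
        occs = [np.array([246.0, 245.0, 244.0])]
        q, mu = 2.0, 0.1
        model = PreservationModel("HPP", [q])
        post = sample_times(occs, model, (0.2, mu), WINDOW,
                            McmcRun(iterations=20000, rng_seed=2), fix_q=True)
        ext = post.ts_samples[:, 0] - 246.0
        B = WINDOW[0] - 246.0
        r = q + mu
        expected = 1 / r - B * np.exp(-r * B) / (1 - np.exp(-r * B))
        assert ext.mean() == pytest.approx(expected, rel=0.1)

    def test_coverage_of_true_origination_times(self):
        cfg = constant_config(seed=33, n_seed=40)
        h = simulate_bd(cfg)
        occs = simulate_preservation(h, cfg)
        mask = np.array([o.size > 0 for o in occs])
        keep = [o for o in occs if o.size]
        post = sample_times(keep, PreservationModel("HPP", [1.0]), (0.2, 0.1),
                            WINDOW, McmcRun(iterations=4000, rng_seed=3),
                            extant=~h.extinct[mask])
        lo = np.quantile(post.ts_samples, 0.025, axis=0)
        hi = np.quantile(post.ts_samples, 0.975, axis=0)
        ts_true = h.ts[mask]
        inner = ts_true < WINDOW[0] - 1e-9  # seeds sit on the window edge
        cover = ((ts_true >= lo) & (ts_true <= hi))[inner].mean()
        assert cover == pytest.approx(0.95, abs=0.07)

    def test_times_bracket_occurrences(self, small_dataset):
        _, h, occs, *_ = small_dataset
        keep = [o for o in occs if o.size]
        post = sample_times(keep, PreservationModel("HPP", [1.0]), (0.2, 0.1),
                            WINDOW, McmcRun(iterations=1000, rng_seed=4))
        x_old = np.array([o.max() for o in keep])
        x_young = np.array([o.min() for o in keep])
        assert (post.times.ts > x_old).all()
        assert (post.times.te < x_young + 1e-12).all()


class TestRjmcmc:
    def test_constant_rate_modal_shift_count_zero(self, small_history):
        tt = TaxonTimes(small_history.ts, small_history.te, small_history.extinct)
        lam, mu = rjmcmc_rates(tt, (252.0, 237.0),
                               McmcRun(iterations=20000, rng_seed=5))
        assert collections.Counter(lam.n_shifts).most_common(1)[0][0] == 0
        assert collections.Counter(mu.n_shifts).most_common(1)[0][0] == 0

    def test_pure_birth_recovers_event_rate(self):
        cfg = constant_config(seed=44, lam=0.25, mu=0.0, n_seed=20)
        h = simulate_bd(cfg)
        tt = TaxonTimes(h.ts, h.te, h.extinct)
        lam, _ = rjmcmc_rates(tt, (252.0, 237.0),
                              McmcRun(iterations=20000, rng_seed=6))
        old, young = 252.0, 237.0
        S = ((h.ts < old) & (h.ts > young)).sum()
        L = np.sum(np.clip(h.ts, young, old) - np.clip(h.te, young, old))
        mid = len(lam.grid) // 2
        assert lam.mean[mid] == pytest.approx(S / L, rel=0.10)

    def test_prior_recovery_likelihood_off(self):
        # with the likelihood switched off the chain must sample its priors:
        # Poisson(1) on the shift count, Gamma(2,2) on segment rates
        from scipy.stats import chisquare, kstest, poisson

        tt = TaxonTimes(np.array([250.0]), np.array([240.0]), np.array([True]))
        lam, _ = rjmcmc_rates(tt, (252.0, 237.0),
                              McmcRun(iterations=60000, rng_seed=7, n_samples=5000),
                              likelihood_off=True)
        ks = lam.n_shifts
        kmax = 6
        obs = np.array([np.sum(ks == i) for i in range(kmax)] + [np.sum(ks >= kmax)])
        p = np.array([poisson.pmf(i, 1.0) for i in range(kmax)]
                     + [1 - poisson.cdf(kmax - 1, 1.0)])
        chi2, pval = chisquare(obs, p * obs.sum())
        assert pval > 0.01
        assert kstest(lam.grid_samples[::5, 3], "gamma",
                      args=(2, 0, 0.5)).pvalue > 0.01

    def test_mu_spike_detected_within_2myr(self):
        from paleodiv.synthetic import SimulationConfig

        cfg = SimulationConfig(
            t_start=254, t_end=237, lambda_episodes=[(254, 237, 0.2)],
            mu_episodes=[(254, 246, 0.1), (246, 244, 0.5), (244, 237, 0.1)],
            q_bins=[(254, 237, 1.0)], n_seed_lineages=40, rng_seed=11)
        h = simulate_bd(cfg)
        tt = TaxonTimes(h.ts, h.te, h.extinct)
        _, mu = rjmcmc_rates(tt, (254.0, 237.0),
                             McmcRun(iterations=40000, rng_seed=8))
        shifts = np.concatenate([s for s in mu.shift_ages if s.size])
        assert abs(shifts.mean() - 245.0) <= 2.0

    def test_deterministic_given_seed(self, small_history):
        tt = TaxonTimes(small_history.ts, small_history.te, small_history.extinct)
        runs = [rjmcmc_rates(tt, (252.0, 237.0),
                             McmcRun(iterations=3000, rng_seed=9)) for _ in range(2)]
        assert np.array_equal(runs[0][0].grid_samples, runs[1][0].grid_samples)
        assert np.array_equal(runs[0][1].grid_samples, runs[1][1].grid_samples)


class TestDiagnostics:
    def test_ess_of_white_noise_near_n(self):
        x = np.random.default_rng(1).normal(size=4000)
        assert ess(x) == pytest.approx(4000, rel=0.2)

    def test_ess_constant_chain_warns(self):
        with pytest.warns(UserWarning):
            assert ess(np.ones(100)) == 100

    def test_hpd_matches_equal_tail_for_symmetric(self):
        x = np.random.default_rng(2).normal(size=100_000)
        lo, hi = hpd(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_hpd_shortest_interval_on_skewed(self):
        x = np.random.default_rng(3).exponential(size=100_000)
        lo, hi = hpd(x, 0.90)
        assert lo == pytest.approx(0.0, abs=0.01)
        assert hi < np.quantile(x, 0.95)  # shorter than equal-tail

    def test_combine_identical_runs_is_identity(self):
        s = np.random.default_rng(4).normal(size=(100, 5))
        pooled = combine_replicates([s, s])
        m1, lo1, hi1 = grid_summary(s)
        m2, lo2, hi2 = grid_summary(pooled)
        assert np.allclose(m1, m2) and np.allclose(lo1, lo2) and np.allclose(hi1, hi2)

    def test_combine_rejects_grid_mismatch(self):
        with pytest.raises(ValueError):
            combine_replicates([np.zeros((10, 4)), np.zeros((10, 5))])
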