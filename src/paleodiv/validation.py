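"""Simulation-validation studies: parameter recovery, shift detection,
likelihood exactness, driver recovery, prior sampling, curation exactness,
discrete-bin oracles, spatial properties and preservation model selection.

Each study regenerates its synthetic inputs from scratch under the study
conditions (constant rates λ=0.2, μ=0.1, preservation q=1.0 per lineage-Myr,
datasets of a few hundred genera, Permian–Triassic-scale windows) and
reports summary statistics.  These functions back both the acceptance test
suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import collections

import numpy as np
import pandas as pd
from scipy import stats

from . import bd, curation, diversity, mbd, spatial
from .mcmcutil import McmcRun, combine_replicates, hpd
from .preservation import PreservationModel, select_preservation_model
from .synthetic import (SimulationConfig, simulate_bd, simulate_predictors,
                        simulate_preservation)

WINDOW_SIM = (254.0, 237.0)
WINDOW_ANALYSIS = (252.0, 237.0)


def _constant_config(seed, lam=0.2, mu=0.1, q=1.0, n_seed=30,
                     window=WINDOW_SIM, **kw):
    return SimulationConfig(
        t_start=window[0], t_end=window[1],
        lambda_episodes=[(window[0], window[1], lam)],
        mu_episodes=[(window[0], window[1], mu)],
        q_bins=[(window[0], window[1], q)],
        n_seed_lineages=n_seed, rng_seed=seed, **kw)


def _simulate_sampled(seed, min_genera=120, **kw):
    """Simulate until the sampled dataset is non-degenerate.

    Replicates are conditioned on survival and a minimum sampled size, the
    usual protocol for birth–death recovery studies (collapsed populations
    carry no information about the generating rates).
    """
    attempt = 0
    while True:
        cfg = _constant_config((seed + attempt * 7919) % 2**31, **kw)
        h = simulate_bd(cfg)
        occs = simulate_preservation(h, cfg)
        mask = np.array([o.size > 0 for o in occs])
        if not h.total_extinction and mask.sum() >= min_genera:
            return h, [o for o in occs if o.size], mask
        attempt += 1


# ---------------------------------------------------------------------------
# 1. constant-rate birth–death recovery


def bd_recovery_study(seed: int, n_reps: int = 10, n_time_draws: int = 4,
                      iterations: int = 20_000):
    """Two-step recovery of λ=0.2, μ=0.1 at q=1 on ~200–400-genus datasets.

    Per replicate: Gibbs times, then rjMCMC pooled over posterior time draws;
    reports how many replicates contain the truth in the mid-window 95% HPD.
    """
    lam_cover = mu_cover = 0
    lam_means, mu_means = [], []
    for rep in range(n_reps):
        base = (seed * 1000 + rep * 101) % 2**31
        h, occs, mask = _simulate_sampled(base)
        post = bd.sample_times(occs, PreservationModel("HPP", [1.0]), (0.2, 0.1),
                               WINDOW_SIM, McmcRun(iterations=1500, rng_seed=base + 1),
                               extant=~h.extinct[mask])
        lam_sets, mu_sets = [], []
        idx = np.linspace(0, post.ts_samples.shape[0] - 1, n_time_draws).astype(int)
        for j, di in enumerate(idx):
            tt = bd.TaxonTimes(post.ts_samples[di], post.te_samples[di],
                               post.times.extinct, weights=post.times.weights,
                               exposure_weights=post.times.exposure_weights)
            lam, mu = bd.rjmcmc_rates(tt, WINDOW_ANALYSIS,
                                      McmcRun(iterations=iterations,
                                              rng_seed=base + 10 + j))
            lam_sets.append(lam.grid_samples)
            mu_sets.append(mu.grid_samples)
        pl = combine_replicates(lam_sets)
        pm = combine_replicates(mu_sets)
        mid = pl.shape[1] // 2
        lo, hi = hpd(pl[:, mid])
        lam_cover += lo <= 0.2 <= hi
        lam_means.append(pl[:, mid].mean())
        lo, hi = hpd(pm[:, mid])
        mu_cover += lo <= 0.1 <= hi
        mu_means.append(pm[:, mid].mean())
    return dict(n_reps=n_reps, lambda_covered=int(lam_cover),
                mu_covered=int(mu_cover),
                lambda_posterior_mean=float(np.median(lam_means)),
                mu_posterior_mean=float(np.median(mu_means)))


# ---------------------------------------------------------------------------
# 2. rate-shift detection


def shift_detection_study(seed: int, n_const: int = 20,
                          iterations: int = 20_000):
    """A 5× extinction spike must be located within ±2 Myr; constant-rate
    data must put the modal shift count at zero."""
    base = (seed * 977) % 2**31
    cfg = SimulationConfig(
        t_start=254, t_end=237, lambda_episodes=[(254, 237, 0.2)],
        mu_episodes=[(254, 246, 0.1), (246, 244, 0.5), (244, 237, 0.1)],
        q_bins=[(254, 237, 1.0)], n_seed_lineages=40, rng_seed=base)
    h = simulate_bd(cfg)
    tt = bd.TaxonTimes(h.ts, h.te, h.extinct)
    _, mu = bd.rjmcmc_rates(tt, WINDOW_SIM,
                            McmcRun(iterations=3 * iterations, rng_seed=base + 1))
    shifts = np.concatenate([s for s in mu.shift_ages if s.size])
    location_error = abs(float(shifts.mean()) - 245.0)

    modal_zero = 0
    for s in range(n_const):
        cfg = _constant_config((base + 13 + s) % 2**31)
        h = simulate_bd(cfg)
        tt = bd.TaxonTimes(h.ts, h.te, h.extinct)
        lam, mu = bd.rjmcmc_rates(tt, WINDOW_ANALYSIS,
                                  McmcRun(iterations=iterations, rng_seed=base + 50 + s))
        ml = collections.Counter(lam.n_shifts).most_common(1)[0][0]
        mm = collections.Counter(mu.n_shifts).most_common(1)[0][0]
        modal_zero += (ml == 0) and (mm == 0)
    return dict(shift_location_error_myr=location_error,
                modal_zero_fraction=modal_zero / n_const, n_const=n_const)


# ---------------------------------------------------------------------------
# 3. likelihood exactness


def loglik_exactness_study(seed: int, n_instances: int = 50):
    """Closed-form piecewise likelihood vs independent elementary-interval
    quadrature on random 20-lineage instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    old, young = WINDOW_SIM
    for _ in range(n_instances):
        n = 20
        ts = rng.uniform(young + 1, old, n)
        te = np.clip(ts - rng.uniform(0.5, 10, n), young, None)
        tt = bd.TaxonTimes(ts, te, te > young)
        k = int(rng.integers(0, 4))
        shifts = np.sort(rng.uniform(young + 1, old - 1, k))[::-1]
        lam_r = rng.uniform(0.05, 0.5, k + 1)
        mu_r = rng.uniform(0.05, 0.5, k + 1)
        got = bd.bd_loglik(tt, shifts, lam_r, shifts, mu_r, WINDOW_SIM)

        brk = np.unique(np.concatenate([[old, young], ts, te, shifts]))
        brk = brk[(brk >= young) & (brk <= old)]
        integral = 0.0
        for a, b in zip(brk[:-1], brk[1:]):
            m = 0.5 * (a + b)
            nn = np.sum((ts >= m) & (te < m))
            lam = lam_r[np.searchsorted(-shifts, -m)]
            mu = mu_r[np.searchsorted(-shifts, -m)]
            integral += nn * (lam + mu) * (b - a)
        want = -integral
        for t in ts[(ts < old) & (ts > young)]:
            want += np.log(lam_r[np.searchsorted(-shifts, -t)])
        for t in te[(te > young) & (te < old)]:
            want += np.log(mu_r[np.searchsorted(-shifts, -t)])
        worst = max(worst, abs(got - want))
    return dict(max_abs_error=float(worst), n_instances=n_instances)


# ---------------------------------------------------------------------------
# 4. MBD driver recovery


def mbd_recovery_study(seed: int, n_sims: int = 20, iterations: int = 10_000,
                       g_true: float = 1.5):
    """One signal + nine decoys under the exponential link.

    Datasets are sized like the genus-level occurrence compilations this
    analysis is meant for (roughly 700–1300 genera per clade).
    """
    window = (252.0, 237.0)
    grid = mbd.make_grid(window)
    signal_ok = 0
    decoy_ws = []
    for s in range(n_sims):
        base = (seed * 1000 + s * 37) % 2**31
        preds, lam_t, _, _ = simulate_predictors(grid, 1, 9, rng_seed=base,
                                                 g_lambda=g_true, lambda0=0.1,
                                                 mu0=0.15)
        step = 0.5
        ep = []
        for i in range(int((window[0] - window[1]) / step)):
            a = window[0] - i * step
            ep.append((a, a - step,
                       float(np.interp(a - step / 2, grid[::-1], lam_t[::-1]))))
        cfg = SimulationConfig(t_start=window[0], t_end=window[1],
                               lambda_episodes=ep,
                               mu_episodes=[(window[0], window[1], 0.15)],
                               q_bins=[(window[0], window[1], 1.0)],
                               n_seed_lineages=120, rng_seed=base + 1)
        h = simulate_bd(cfg)
        tt = bd.TaxonTimes(h.ts, h.te, h.extinct)
        series = {n: mbd.PredictorSeries(n, grid, v, grid, v)
                  for n, v in preds.items()}
        res = mbd.fit_mbd(tt, series, window,
                          mcmc=McmcRun(iterations=iterations, rng_seed=base + 2))
        j = res.names.index("signal_0")
        signal_ok += (res.w_lam[j] > 0.5) and (res.g_lam[:, j].mean() > 0)
        dm = [res.w_lam[i] for i, n in enumerate(res.names) if n.startswith("decoy")]
        dm += [res.w_mu[i] for i, n in enumerate(res.names) if n.startswith("decoy")]
        decoy_ws.append(np.mean(dm))
    return dict(signal_recovered_fraction=signal_ok / n_sims,
                decoy_mean_weight=float(np.mean(decoy_ws)), n_sims=n_sims)


# ---------------------------------------------------------------------------
# 5. prior sampling


def prior_sampling_checks(seed: int):
    """Likelihood-off runs must reproduce the Poisson shift-count prior and
    the horseshoe marginal of G."""
    base = (seed * 31) % 2**31
    tt = bd.TaxonTimes(np.array([250.0]), np.array([240.0]), np.array([True]))
    lam, _ = bd.rjmcmc_rates(tt, WINDOW_ANALYSIS,
                             McmcRun(iterations=60_000, rng_seed=base,
                                     n_samples=5000), likelihood_off=True)
    ks = lam.n_shifts
    kmax = 6
    obs = np.array([np.sum(ks == i) for i in range(kmax)] + [np.sum(ks >= kmax)])
    p = np.array([stats.poisson.pmf(i, 1.0) for i in range(kmax)]
                 + [1 - stats.poisson.cdf(kmax - 1, 1.0)])
    _, chi_p = stats.chisquare(obs, p * obs.sum())

    grid = mbd.make_grid(WINDOW_ANALYSIS)
    v = np.random.default_rng(base + 1).random(grid.size)
    series = {"p0": mbd.PredictorSeries("p0", grid, v, grid, v)}
    res = mbd.fit_mbd(tt, series, WINDOW_ANALYSIS,
                      mcmc=McmcRun(iterations=48_000, rng_seed=base + 2,
                                   n_samples=6000), likelihood_off=True)
    g = res.g_lam[::6, 0]  # thin to near-independence for the KS test
    ref = mbd.horseshoe_prior_draws(200_000, np.random.default_rng(base + 3))
    ks_p = stats.ks_2samp(g, ref).pvalue
    return dict(poisson_chisq_p=float(chi_p), horseshoe_ks_p=float(ks_p))


# ---------------------------------------------------------------------------
# 6. curation exactness


def curation_exactness_check(seed: int):
    """Each cleaning rule must remove exactly the injected artefact rows."""
    cfg = _constant_config(seed % 2**31, qualifier_noise_p=0.08,
                           terrestrial_p=0.05, subgenus_p=0.15, outlier_p=0.2,
                           coarse_dating_p=0.1)
    h = simulate_bd(cfg)
    occs = simulate_preservation(h, cfg)
    from .synthetic import emit_occurrence_table

    table, truth = emit_occurrence_table(h, occs, cfg)
    kept, log = curation.clean_occurrences(table)
    # score only the noise rules: the span rule correctly drops coarse-dated
    # rows, which are not injected noise
    noise_rules = {curation.RULE_TERRESTRIAL, curation.RULE_QUALIFIER}
    injected = set(truth.loc[truth.injected_terrestrial
                             | truth.injected_qualifier, "row_id"])
    removed = set(log.loc[log["rule"].isin(noise_rules), "row_id"])
    tp = len(injected & removed)
    recall = tp / len(injected) if injected else 1.0
    precision = tp / len(removed) if removed else 1.0

    # the >10 Myr rule, asserted on the printed example pair
    example = pd.DataFrame([
        dict(genus="Ga", primary_reso="", accepted_genus="Ga", collection_no=1,
             max_ma=273.0, min_ma=259.5, stage="Guadalupian",
             is_international_stage=False, environment="marine",
             lithology1="carbonate", paleolat=0.0, paleolng=0.0),
        dict(genus="Gb", primary_reso="", accepted_genus="Gb", collection_no=2,
             max_ma=227.0, min_ma=208.5, stage="Norian",
             is_international_stage=True, environment="marine",
             lithology1="carbonate", paleolat=0.0, paleolng=0.0),
    ])
    kept2, log2 = curation.clean_occurrences(example)
    rule_ok = (list(kept2["stage"]) == ["Norian"]
               and list(log2["rule"]) == [curation.RULE_SPAN])
    return dict(recall=float(recall), precision=float(precision),
                guadalupian_norian_rule=bool(rule_ok))


# ---------------------------------------------------------------------------
# 7. per-capita and ltt oracles


def per_capita_oracle_check(seed: int):
    """Foote tallies vs brute-force enumeration; ltt vs the truth curve."""
    rng = np.random.default_rng(seed)
    ts = rng.uniform(238, 254, 30)
    te = np.clip(ts - rng.uniform(0.5, 12, 30), 237.0, None)
    tt = bd.TaxonTimes(ts, te, np.ones(30, bool))
    bins = np.array([254.0, 250.0, 246.0, 242.0, 237.0])
    got = diversity.per_capita_rates(diversity.bin_counts(tt, bins))
    worst = 0.0
    for k in range(len(bins) - 1):
        old, young = bins[k], bins[k + 1]
        nbt = nbl = nft = 0
        for s, e in zip(ts, te):  # brute-force crosser enumeration per taxon
            bottom = s >= old > e
            top = s >= young > e
            if bottom and top:
                nbt += 1
            elif bottom and old > e >= young:
                nbl += 1
            elif old > s >= young and top:
                nft += 1
        dt = old - young
        p = -np.log(nbt / (nbt + nft)) / dt if nbt else np.nan
        q = -np.log(nbt / (nbt + nbl)) / dt if nbt else np.nan
        row = got.iloc[k]
        if np.isfinite(p):
            worst = max(worst, abs(row.p - p), abs(row.q - q))
    h = simulate_bd(_constant_config(seed % 2**31))
    tt2 = bd.TaxonTimes(h.ts, h.te, h.extinct)
    grid = np.arange(WINDOW_SIM[0] - 0.25, WINDOW_SIM[1], -0.5)
    curve = diversity.ltt_diversity(tt2, grid)
    direct = np.array([((h.ts >= t) & (h.te < t)).sum() for t in grid])
    ltt_exact = bool(np.array_equal(curve.mean, direct))
    return dict(per_capita_max_abs_error=float(worst), ltt_exact=ltt_exact)


# ---------------------------------------------------------------------------
# 8. spatial properties


def spatial_properties_check(seed: int):
    """MST standardization termination/threshold/variance and planted-region
    recovery by both PAM and network community detection."""
    from sklearn.metrics import adjusted_rand_score

    grid = spatial.HexGrid(2)
    rng = np.random.default_rng(seed)
    per_bin = {}
    for b in range(5):
        n = 40 + 50 * b
        per_bin[b] = pd.DataFrame(dict(
            genus="x",
            paleolat=np.clip(rng.normal(10, 4 + 7 * b, n), -89, 89),
            paleolng=rng.normal(40, 5 + 9 * b, n)))
    _, audit = spatial.mst_standardize(per_bin, grid, threshold="median")
    thr = audit.threshold_km.iloc[0]
    under = bool(((audit.final_length_km <= thr + 1e-9)
                  | (audit.cells_kept == 1)).all())
    non_increasing = bool((audit.final_length_km
                           <= audit.raw_length_km + 1e-9).all())
    var_ratio = float(audit.final_length_km.var() / audit.raw_length_km.var())

    rows = []
    fauna_of = {}
    for fauna, (lat0, lon0) in enumerate([(20, 30), (-30, -120)]):
        for g_i in range(40):
            genus = f"G{fauna}_{g_i}"
            fauna_of[genus] = fauna
            for _ in range(12):
                rows.append(dict(genus=genus,
                                 paleolat=float(np.clip(lat0 + rng.normal(0, 8), -89, 89)),
                                 paleolng=float(lon0 + rng.normal(0, 8))))
    m = spatial.hex_bin(pd.DataFrame(rows), grid=grid)
    truth = np.array([
        int(np.mean([fauna_of[g] for g in m.genera[m.presence[i]]]) > 0.5)
        for i in range(len(m.cell_ids))])
    ra = spatial.regionalize(m)
    return dict(mst_all_bins_under_threshold=under,
                mst_length_non_increasing=non_increasing,
                mst_variance_ratio=var_ratio,
                pam_ari=float(adjusted_rand_score(truth, ra.region_pam)),
                network_ari=float(adjusted_rand_score(truth, ra.region_network)))


# ---------------------------------------------------------------------------
# 9. preservation model selection


def preservation_selection_study(seed: int, n_hpp: int = 50, n_shift: int = 20):
    """HPP data: HPP within 2 score units of the winner; 5× q shift: TPP wins."""
    edges = np.array([254.0, 250.0, 246.0, 242.0, 237.0])
    base = (seed * 211) % 2**31
    hpp_ok = 0
    for s in range(n_hpp):
        cfg = _constant_config((base + s) % 2**31, n_seed=30)
        h = simulate_bd(cfg)
        occs = simulate_preservation(h, cfg)
        mask = np.array([o.size > 0 for o in occs])
        keep = [o for o in occs if o.size]
        _, scores, _ = select_preservation_model(h.ts[mask], h.te[mask], keep,
                                                 bin_edges=edges)
        hpp_ok += scores["HPP"] - min(scores.values()) <= 2.0
    tpp_ok = 0
    for s in range(n_shift):
        cfg = SimulationConfig(t_start=254, t_end=237,
                               lambda_episodes=[(254, 237, 0.2)],
                               mu_episodes=[(254, 237, 0.1)],
                               q_bins=[(254, 246, 0.4), (246, 237, 2.0)],
                               n_seed_lineages=30,
                               rng_seed=(base + 500 + s) % 2**31)
        h = simulate_bd(cfg)
        occs = simulate_preservation(h, cfg)
        mask = np.array([o.size > 0 for o in occs])
        keep = [o for o in occs if o.size]
        best, *_ = select_preservation_model(h.ts[mask], h.te[mask], keep,
                                             bin_edges=edges)
        tpp_ok += best == "TPP"
    return dict(hpp_within_two_fraction=hpp_ok / n_hpp,
                tpp_selected_fraction=tpp_ok / n_shift,
                n_hpp=n_hpp, n_shift=n_shift)
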