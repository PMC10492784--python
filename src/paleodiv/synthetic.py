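"""Synthetic fossil-occurrence data with known ground truth.

The generator emulates the statistical structure of a PBDB-style genus-level
occurrence download: a forward-time birth–death history, an inhomogeneous
Poisson preservation process, censoring of true ages to stage/substage
intervals, Poisson-clustered collections, qualifier noise, bracketed subgenus
names, terrestrial contaminants, carbonate/siliciclastic lithologies and
regionally clustered palaeocoordinates.  Every injected artefact is recorded
in a truth sidecar so curation recall/precision are computable.

Time runs in Ma before present (larger = older); episodes and preservation
bins are half-open ``[older, younger)``; rates are events per lineage-Myr.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stages as _stages

QUALIFIERS = ("cf.", "aff.", "?", "informal", "ex. gr.")


# ---------------------------------------------------------------------------
# configuration and truth containers


@dataclass
class SimulationConfig:
    """Ground-truth settings for one synthetic dataset.

    ``lambda_episodes``/``mu_episodes``/``q_bins`` are lists of
    ``(age_from, age_to, rate)`` with ``age_from > age_to``; together the
    episodes must tile ``[t_end, t_start]`` without gaps or overlap.
    """

    t_start: float
    t_end: float
    lambda_episodes: list
    mu_episodes: list
    q_bins: list
    n_seed_lineages: int = 10
    stage_table_ref: str | None = None
    qualifier_noise_p: float = 0.0
    subgenus_p: float = 0.0
    terrestrial_p: float = 0.0
    outlier_p: float = 0.0
    carbonate_p: float = 0.5
    coarse_dating_p: float = 0.0
    n_regions: int = 4
    mean_collection_size: float = 4.0
    region_inherit_p: float = 0.9
    orders: tuple = ("Spiriferida", "Productida", "Terebratulida", "Rhynchonellida")
    eco_classes: tuple = ("pedicle_attached", "cemented", "reclining", "infaunal")
    rng_seed: int = 0

    def __post_init__(self):
        if not self.t_start > self.t_end >= 0:
            raise ValueError("need t_start > t_end >= 0")
        for name in ("lambda_episodes", "mu_episodes", "q_bins"):
            _check_tiling(getattr(self, name), self.t_start, self.t_end, name)
        for p in ("qualifier_noise_p", "subgenus_p", "terrestrial_p", "outlier_p",
                  "carbonate_p", "coarse_dating_p"):
            v = getattr(self, p)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{p} must be in [0,1], got {v}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


def _check_tiling(episodes, t_start, t_end, name):
    if not episodes:
        raise ValueError(f"{name} is empty")
    eps = sorted(episodes, key=lambda e: -e[0])
    if not np.isclose(eps[0][0], t_start) or not np.isclose(eps[-1][1], t_end):
        raise ValueError(f"{name} must span [{t_end}, {t_start}]")
    for (a, b, r), (c, d, _) in zip(eps, eps[1:]):
        if a <= b or not np.isclose(b, c):
            raise ValueError(f"{name} must tile the window without gaps/overlap")
    if any(r < 0 for *_, r in eps):
        raise ValueError(f"{name} rates must be >= 0")


@dataclass
class TrueHistory:
    """Latent truth of one simulation: per-lineage (Ts, Te) plus labels."""

    ts: np.ndarray
    te: np.ndarray
    extinct: np.ndarray
    region: np.ndarray
    eco_class: np.ndarray
    order: np.ndarray
    total_extinction: bool = False

    def __post_init__(self):
        if self.ts.size and not (self.ts > self.te).all():
            raise ValueError("every lineage needs Ts > Te")

    @property
    def n_lineages(self) -> int:
        return self.ts.size


def _step_rate(episodes):
    """(edges_old_desc, rates) arrays for a piecewise-constant rate."""
    eps = sorted(episodes, key=lambda e: -e[0])
    edges = np.array([e[0] for e in eps] + [eps[-1][1]])
    rates = np.array([e[2] for e in eps])
    return edges, rates


def rate_at(episodes, ages):
    """Evaluate a piecewise-constant ``(from, to, rate)`` series at ``ages``."""
    edges, rates = _step_rate(episodes)
    idx = np.clip(np.searchsorted(-edges, -np.asarray(ages, float), side="right") - 1,
                  0, rates.size - 1)
    return rates[idx]


# ---------------------------------------------------------------------------
# birth–death simulation


def simulate_bd(config: SimulationConfig, rng: np.random.Generator | None = None) -> TrueHistory:
    """Simulate a forward-time birth–death history under piecewise-constant rates.

    Lineages are born at rate λ(t)·N(t) and die at μ(t)·N(t) (Gillespie walk
    from ``t_start`` down to ``t_end``); survivors are truncated at ``t_end``
    and flagged non-extinct.  Total extinction before ``t_end`` sets
    ``total_extinction`` on the returned history instead of raising.
    """
    rng = config.rng() if rng is None else rng
    lam_edges, lam_rates = _step_rate(config.lambda_episodes)
    mu_edges, mu_rates = _step_rate(config.mu_episodes)
    # union of episode boundaries, descending
    edges = np.unique(np.concatenate([lam_edges, mu_edges]))[::-1]

    ts, te, extinct = [], [], []
    region, eco, order = [], [], []
    alive: list[int] = []
    for i in range(config.n_seed_lineages):
        ts.append(config.t_start)
        te.append(np.nan)
        extinct.append(True)
        region.append(rng.integers(config.n_regions))
        eco.append(config.eco_classes[rng.integers(len(config.eco_classes))])
        order.append(config.orders[rng.integers(len(config.orders))])
        alive.append(i)

    t = config.t_start
    total_extinction = False
    while t > config.t_end:
        if not alive:
            total_extinction = True
            break
        lam = lam_rates[min(np.searchsorted(-lam_edges, -t, side="right") - 1, lam_rates.size - 1)]
        mu = mu_rates[min(np.searchsorted(-mu_edges, -t, side="right") - 1, mu_rates.size - 1)]
        next_edge = max((e for e in edges if e < t), default=config.t_end)
        total = len(alive) * (lam + mu)
        if total <= 0:
            t = next_edge
            continue
        wait = rng.exponential(1.0 / total)
        if t - wait <= next_edge:
            t = next_edge
            continue
        t -= wait
        if rng.random() < lam / (lam + mu):  # birth
            parent = alive[rng.integers(len(alive))]
            j = len(ts)
            ts.append(t)
            te.append(np.nan)
            extinct.append(True)
            if rng.random() < config.region_inherit_p:
                region.append(region[parent])
            else:
                region.append(rng.integers(config.n_regions))
            eco.append(eco[parent])
            order.append(order[parent])
            alive.append(j)
        else:  # death
            k = rng.integers(len(alive))
            victim = alive.pop(k)
            te[victim] = t
    for i in alive:
        te[i] = config.t_end
        extinct[i] = False
    return TrueHistory(
        ts=np.array(ts, float),
        te=np.array(te, float),
        extinct=np.array(extinct, bool),
        region=np.array(region, int),
        eco_class=np.array(eco, object),
        order=np.array(order, object),
        total_extinction=total_extinction,
    )


def simulate_preservation(history: TrueHistory, config: SimulationConfig,
                          rng: np.random.Generator | None = None) -> list[np.ndarray]:
    """Draw occurrence ages per lineage from a stepwise-rate Poisson process.

    Returns one (possibly empty) descending-sorted age array per lineage;
    lineages with zero occurrences keep an empty array (they stay in the
    TrueHistory but will be absent from any emitted table).
    """
    rng = np.random.default_rng(config.rng_seed + 1) if rng is None else rng
    q_edges, q_rates = _step_rate(config.q_bins)
    out = []
    for i in range(history.n_lineages):
        ages = []
        for k in range(q_rates.size):
            hi = min(q_edges[k], history.ts[i])
            lo = max(q_edges[k + 1], history.te[i])
            if hi <= lo or q_rates[k] <= 0:
                continue
            n = rng.poisson(q_rates[k] * (hi - lo))
            if n:
                ages.append(rng.uniform(lo, hi, n))
        occ = np.sort(np.concatenate(ages))[::-1] if ages else np.empty(0)
        out.append(occ)
    return out


# ---------------------------------------------------------------------------
# occurrence-table emission (PBDB dialect)


def emit_occurrence_table(history: TrueHistory, occurrences: list[np.ndarray],
                          config: SimulationConfig,
                          stage_table: pd.DataFrame | None = None,
                          rng: np.random.Generator | None = None):
    """Render the simulation as a PBDB-dialect occurrence table plus truth sidecar.

    True ages are censored to substage (or, for coarsely dated collections,
    series) intervals; occurrences are clustered into collections within
    (region x substage x lithology) cells; qualifier noise, bracketed subgenus
    names, terrestrial flags and out-of-range "doubtful" occurrences are
    injected at the configured probabilities.  The sidecar maps every row to
    its clean form (columns ``true_age``, ``clean_genus`` and one boolean per
    injected artefact class).
    """
    rng = np.random.default_rng(config.rng_seed + 2) if rng is None else rng
    stages = _stages.load_stage_table(config.stage_table_ref) if stage_table is None else stage_table
    subs = _stages.substage_table(stages)
    series = _stages.series_table(stages)

    rows = []
    for lin, ages in enumerate(occurrences):
        for a in ages:
            rows.append((lin, float(a), False))
        # deliberate out-of-range occurrences, placed well outside [Te, Ts]
        if ages.size and config.outlier_p > 0 and rng.random() < config.outlier_p:
            span = max(history.ts[lin] - history.te[lin], 1.0)
            bad = history.ts[lin] + span + rng.uniform(5.0, 15.0)
            if bad < stages["max_ma"].max():
                rows.append((lin, float(bad), True))
    if not rows:
        empty = _empty_table()
        return empty, empty.iloc[:0].assign(true_age=[], clean_genus=[])

    raw = pd.DataFrame(rows, columns=["lineage", "true_age", "is_outlier"])

    # substage censoring of each occurrence's true age
    sub_idx = []
    for a in raw["true_age"]:
        row = _stages.interval_for_age(subs, a)
        sub_idx.append(row.name)
    raw["substage_row"] = sub_idx
    raw["lithology1"] = np.where(rng.random(len(raw)) < config.carbonate_p,
                                 "carbonate", "siliciclastic")
    raw["region"] = history.region[raw["lineage"].values]

    # Poisson clustering into collections within (region x substage x lithology)
    coll_ids = np.zeros(len(raw), int)
    next_id = 1
    lat0 = rng.uniform(-60, 60, config.n_regions)
    lon0 = rng.uniform(-150, 150, config.n_regions)
    coll_info = {}
    for key, grp in raw.groupby(["region", "substage_row", "lithology1"], sort=True):
        n_occ = len(grp)
        n_coll = 1 + rng.poisson(max(n_occ / config.mean_collection_size - 1, 0.0))
        assign = rng.integers(n_coll, size=n_occ)
        for j in np.unique(assign):
            cid = next_id
            next_id += 1
            reg = key[0]
            coarse = rng.random() < config.coarse_dating_p
            coll_info[cid] = dict(
                coarse=coarse,
                paleolat=float(np.clip(lat0[reg] + rng.normal(0, 5), -89, 89)),
                paleolng=float(((lon0[reg] + rng.normal(0, 7) + 180) % 360) - 180),
            )
            coll_ids[grp.index[assign == j]] = cid
    raw["collection_no"] = coll_ids

    genus_names = np.array([f"Genus{lin:04d}" for lin in range(history.n_lineages)])
    sub_names = np.array([f"Subgenus{lin:04d}" for lin in range(history.n_lineages)])

    recs = []
    truth = []
    for idx, r in raw.iterrows():
        info = coll_info[r["collection_no"]]
        sub = subs.loc[r["substage_row"]]
        if info["coarse"]:
            srow = _stages.interval_for_age(series, r["true_age"])
            stage_label, max_ma, min_ma, intl = srow["series"], srow["max_ma"], srow["min_ma"], False
        else:
            stage_label, max_ma, min_ma = sub["substage"], sub["max_ma"], sub["min_ma"]
            intl = True
        lin = int(r["lineage"])
        clean = genus_names[lin]
        name = clean
        is_sub = rng.random() < config.subgenus_p
        if is_sub:
            name = f"{clean} ({sub_names[lin]})"
        qual = ""
        is_qual = rng.random() < config.qualifier_noise_p
        if is_qual:
            qual = QUALIFIERS[rng.integers(len(QUALIFIERS))]
        is_terr = rng.random() < config.terrestrial_p
        if r["is_outlier"]:
            # outlier rows look ordinary to the curator: noise classes stay disjoint
            is_qual, is_terr, qual = False, False, ""
        recs.append(dict(
            genus=name, primary_reso=qual, accepted_genus=clean,
            collection_no=int(r["collection_no"]),
            max_ma=float(max_ma), min_ma=float(min_ma), stage=stage_label,
            is_international_stage=bool(intl),
            environment="terrestrial" if is_terr else "marine",
            lithology1=r["lithology1"],
            paleolat=info["paleolat"], paleolng=info["paleolng"],
            order=history.order[lin], **{"class": "Brachiopoda"},
        ))
        truth.append(dict(
            row_id=len(recs) - 1, lineage=lin, true_age=float(r["true_age"]),
            clean_genus=clean, injected_qualifier=bool(is_qual),
            injected_subgenus=bool(is_sub), injected_terrestrial=bool(is_terr),
            injected_outlier=bool(r["is_outlier"]),
            region=int(r["region"]), eco_class=history.eco_class[lin],
        ))
    table = pd.DataFrame(recs)
    sidecar = pd.DataFrame(truth)
    # censoring audit: true (non-outlier) ages must sit inside their interval
    ok = ((sidecar["true_age"] <= table["max_ma"] + 1e-9)
          & (sidecar["true_age"] >= table["min_ma"] - 1e-9))
    assert (ok | sidecar["injected_outlier"]).all(), "censoring violated"
    return table, sidecar


def _empty_table() -> pd.DataFrame:
    cols = ["genus", "primary_reso", "accepted_genus", "collection_no", "max_ma",
            "min_ma", "stage", "is_international_stage", "environment",
            "lithology1", "paleolat", "paleolng", "order", "class"]
    return pd.DataFrame(columns=cols)


def simulate_dataset(config: SimulationConfig):
    """One-call convenience: (history, occurrence ages, table, truth sidecar)."""
    history = simulate_bd(config)
    occs = simulate_preservation(history, config)
    table, sidecar = emit_occurrence_table(history, occs, config)
    return history, occs, table, sidecar


# ---------------------------------------------------------------------------
# predictor curves


def simulate_predictors(grid: np.ndarray, n_signal: int, n_decoy: int,
                        rng_seed: int = 0, g_lambda: float = 1.0,
                        g_mu: float = 0.0, lambda0: float = 0.2, mu0: float = 0.1,
                        roughness: float = 3.0):
    """Smooth autocorrelated predictor curves on a descending age grid.

    The first ``n_signal`` predictors drive the rates through the exponential
    multivariate birth–death link, ``λ(t) = λ0·exp(Σ g·v(t))`` (likewise μ);
    the remaining ``n_decoy`` are pure noise.  Returns
    ``(predictors, lam_true, mu_true, truth)`` where ``predictors`` maps name
    -> values in [0, 1] on ``grid`` and ``truth`` records the generating
    coefficients per predictor.
    """
    grid = np.asarray(grid, float)
    if grid.size < 2 or not (np.diff(grid) < 0).all():
        raise ValueError("grid must be strictly decreasing in age")
    rng = np.random.default_rng(rng_seed)
    preds, truth = {}, {}
    lam = np.full(grid.size, float(lambda0))
    mu = np.full(grid.size, float(mu0))
    for j in range(n_signal + n_decoy):
        v = _smooth_curve(grid.size, rng, roughness)
        name = f"signal_{j}" if j < n_signal else f"decoy_{j - n_signal}"
        preds[name] = v
        if j < n_signal:
            lam = lam * np.exp(g_lambda * v)
            mu = mu * np.exp(g_mu * v)
            truth[name] = dict(g_lambda=g_lambda, g_mu=g_mu)
        else:
            truth[name] = dict(g_lambda=0.0, g_mu=0.0)
    return preds, lam, mu, truth


def _smooth_curve(n: int, rng: np.random.Generator, roughness: float) -> np.ndarray:
    """Gaussian-process-like curve (Gaussian-filtered white noise), min–max
    rescaled to [0, 1].

    The correlation length is window/(10·roughness); the default keeps
    curves smooth like geochemical proxy series (sub-Myr wiggles on a
    multi-Myr window) while leaving independently drawn predictors with
    enough effective degrees of freedom to be mutually distinguishable.
    """
    sigma = max(n / (10.0 * roughness), 2.0)
    k = int(4 * sigma)
    x = np.arange(-k, k + 1)
    kernel = np.exp(-0.5 * (x / sigma) ** 2)
    kernel /= kernel.sum()
    w = rng.normal(0, 1, n + 2 * k)
    s = np.convolve(w, kernel, mode="valid")
    span = s.max() - s.min()
    if span <= 0:
        return np.zeros(n)
    return (s - s.min()) / span


def episodes_to_curve(episodes, grid):
    """Ground-truth rate curve of an episode list on an age grid."""
    return rate_at(episodes, grid)
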