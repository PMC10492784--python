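"""Fossil preservation models: likelihoods and model selection.

Three Poisson sampling models for occurrence ages within each lineage's
(Ts, Te) span:

* ``HPP``  — one homogeneous rate q;
* ``NHPP`` — within-lineage intensity shaped as a symmetric Beta(2,2) hat
  over the span (sampling peaks mid-range), scaled so the integrated
  intensity equals q·duration;
* ``TPP``  — time-variable piecewise-constant q with shifts at stage (or
  series) boundaries.

All likelihoods condition each sampled lineage on having produced at least
one occurrence (the -ln(1 - e^{-Q_i}) term).  Preservation rates carry a
gamma prior with shape 1.5; a rate hyperparameter of 0 means "estimate the
rate from the data" (a vague exponential hyperprior in the Gibbs sampler,
a flat power prior at MAP fitting time).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln


@dataclass
class PreservationModel:
    kind: str  # HPP | NHPP | TPP
    q: np.ndarray  # scalar-like for HPP/NHPP, one per bin for TPP
    bin_edges: np.ndarray | None = None  # ages Ma, strictly decreasing (TPP)
    gamma_prior: tuple = (1.5, 0.0)

    def __post_init__(self):
        self.q = np.atleast_1d(np.asarray(self.q, float))
        if (self.q < 0).any():
            raise ValueError("q must be >= 0")
        if self.kind == "TPP":
            if self.bin_edges is None:
                raise ValueError("TPP needs bin_edges")
            self.bin_edges = np.asarray(self.bin_edges, float)
            if not (np.diff(self.bin_edges) < 0).all():
                raise ValueError("bin_edges must be strictly decreasing")
            if self.q.size != self.bin_edges.size - 1:
                raise ValueError("TPP needs one q per bin")
        elif self.kind in ("HPP", "NHPP"):
            if self.q.size != 1:
                raise ValueError(f"{self.kind} takes a single q")
        else:
            raise ValueError(f"unknown preservation model kind {self.kind!r}")

    @property
    def n_params(self) -> int:
        return self.q.size

    def rate_at(self, ages) -> np.ndarray:
        """Piecewise preservation rate at given ages (TPP) or constant q."""
        ages = np.asarray(ages, float)
        if self.kind != "TPP":
            return np.full(ages.shape, self.q[0])
        idx = np.clip(np.searchsorted(-self.bin_edges, -ages, side="right") - 1,
                      0, self.q.size - 1)
        return self.q[idx]


def bin_overlaps(bin_edges: np.ndarray, ts: np.ndarray, te: np.ndarray) -> np.ndarray:
    """(n_lineages, n_bins) overlap durations of [Te, Ts] with each bin."""
    old = bin_edges[:-1][None, :]
    young = bin_edges[1:][None, :]
    hi = np.minimum(old, ts[:, None])
    lo = np.maximum(young, te[:, None])
    return np.clip(hi - lo, 0.0, None)


def bin_counts_per_lineage(bin_edges: np.ndarray, occs: list[np.ndarray]) -> np.ndarray:
    """(n_lineages, n_bins) occurrence counts per preservation bin."""
    nbins = bin_edges.size - 1
    out = np.zeros((len(occs), nbins), int)
    for i, a in enumerate(occs):
        if a.size == 0:
            continue
        idx = np.clip(np.searchsorted(-bin_edges, -np.asarray(a), side="right") - 1,
                      0, nbins - 1)
        out[i] = np.bincount(idx, minlength=nbins)
    return out


def preservation_loglik(model: PreservationModel, ts: np.ndarray, te: np.ndarray,
                        occs: list[np.ndarray], condition: bool = True) -> float:
    """Log-likelihood of the occurrence ages under the preservation model.

    Raises ``ValueError`` naming the lineage if an occurrence falls outside
    its [Te, Ts] span.  With ``condition=True`` every lineage is conditioned
    on >= 1 occurrence.
    """
    ts = np.asarray(ts, float)
    te = np.asarray(te, float)
    for i, a in enumerate(occs):
        a = np.asarray(a, float)
        if a.size and (a.max() > ts[i] + 1e-9 or a.min() < te[i] - 1e-9):
            raise ValueError(f"occurrence outside [Te, Ts] for lineage {i}")
    d = ts - te
    n = np.array([len(a) for a in occs], float)

    if model.kind == "HPP":
        q = model.q[0]
        Q = q * d
        with np.errstate(divide="ignore"):
            ll = np.where(n > 0, n * np.log(q) if q > 0 else -np.inf, 0.0) - Q
        ll = np.where((n > 0) & (q <= 0), -np.inf, ll)
    elif model.kind == "NHPP":
        q = model.q[0]
        terms = np.zeros(len(occs))
        for i, a in enumerate(occs):
            if len(a) == 0:
                continue
            if q <= 0 or d[i] <= 0:
                terms[i] = -np.inf
                continue
            s = (ts[i] - np.asarray(a, float)) / d[i]
            s = np.clip(s, 1e-12, 1 - 1e-12)
            terms[i] = np.sum(np.log(q * 6.0 * s * (1.0 - s)))
        Q = q * d
        ll = terms - Q
    else:  # TPP
        dt = bin_overlaps(model.bin_edges, ts, te)
        cnt = bin_counts_per_lineage(model.bin_edges, occs)
        Q = dt @ model.q
        with np.errstate(divide="ignore"):
            logq = np.where(model.q > 0, np.log(model.q), -np.inf)
        per_bin = np.where(cnt > 0, cnt * logq[None, :], 0.0)
        ll = per_bin.sum(axis=1) - Q
        ll = np.where(((cnt > 0) & (model.q[None, :] <= 0)).any(axis=1), -np.inf, ll)

    if condition:
        # a sampled lineage with zero integrated intensity is impossible
        with np.errstate(divide="ignore", invalid="ignore"):
            cond = np.log1p(-np.exp(-np.clip(Q, 1e-300, None)))
        ll = np.where(Q > 0, ll - cond, -np.inf)
    return float(np.sum(ll))


def _log_gamma_prior(q: np.ndarray, shape: float, rate: float) -> float:
    q = np.atleast_1d(q)
    if (q <= 0).any():
        return -np.inf
    if rate > 0:
        return float(np.sum(shape * np.log(rate) - gammaln(shape)
                            + (shape - 1) * np.log(q) - rate * q))
    # rate "0": improper power prior q^(shape-1); the data fix the scale
    return float(np.sum((shape - 1) * np.log(q)))


def fit_preservation(kind: str, ts, te, occs, bin_edges=None,
                     gamma_prior=(1.5, 0.0)) -> tuple[PreservationModel, float]:
    """MAP fit of one preservation model at fixed Ts/Te.

    Returns (fitted model, log-posterior at the optimum).
    """
    nq = (len(bin_edges) - 1) if kind == "TPP" else 1
    n_tot = sum(len(a) for a in occs)
    d_tot = float(np.sum(np.asarray(ts) - np.asarray(te)))
    q0 = max(n_tot / max(d_tot, 1e-9), 1e-3)

    def neg(logq):
        q = np.exp(logq)
        m = PreservationModel(kind, q if nq > 1 else q[:1], bin_edges, gamma_prior)
        ll = preservation_loglik(m, ts, te, occs)
        lp = _log_gamma_prior(q, *gamma_prior)
        if not np.isfinite(ll + lp):
            return 1e12
        return -(ll + lp)

    res = minimize(neg, np.full(nq, np.log(q0)), method="L-BFGS-B")
    q_hat = np.exp(res.x)
    model = PreservationModel(kind, q_hat if nq > 1 else q_hat[:1], bin_edges, gamma_prior)
    return model, -float(res.fun)


def select_preservation_model(ts, te, occs, candidates=("HPP", "NHPP", "TPP"),
                              bin_edges=None, gamma_prior=(1.5, 0.0)):
    """Fit each candidate at fixed Ts/Te and pick the best AIC-style score.

    Score = -2·(max log-posterior) + 2·(number of q parameters); the winner is
    the smallest score.  Returns (best kind, {kind: score}, {kind: model}).
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    scores, models = {}, {}
    for kind in candidates:
        edges = bin_edges if kind == "TPP" else None
        if kind == "TPP" and edges is None:
            raise ValueError("TPP candidate needs bin_edges")
        model, lp = fit_preservation(kind, ts, te, occs, edges, gamma_prior)
        scores[kind] = -2.0 * lp + 2.0 * model.n_params
        models[kind] = model
    best = min(scores, key=scores.get)
    return best, scores, models
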