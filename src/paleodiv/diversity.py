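"""Diversity trajectories and discrete-bin (boundary-crosser) rate estimators.

The lineage-through-time diversity counts taxa whose (Ts, Te) interval covers
an age; the per-capita rates of Foote and the three-timer sampling
completeness work on discrete stage bins and serve as cross-checks on the
continuous Bayesian estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bd import TaxonTimes
from .mcmcutil import grid_summary


@dataclass
class DiversityCurve:
    grid: np.ndarray  # ages, descending
    per_replicate: np.ndarray  # (n_replicates, n_grid) integer counts
    mean: np.ndarray
    hpd_lo: np.ndarray
    hpd_hi: np.ndarray


def ltt_diversity(times_sets: list[TaxonTimes] | TaxonTimes,
                  grid: np.ndarray) -> DiversityCurve:
    """Lineage-through-time diversity: #{i : Ts_i >= t > Te_i} on an age grid,
    pooled across replicates."""
    if isinstance(times_sets, TaxonTimes):
        times_sets = [times_sets]
    grid = np.asarray(grid, float)
    counts = np.empty((len(times_sets), grid.size))
    for r, tt in enumerate(times_sets):
        counts[r] = ((tt.ts[None, :] >= grid[:, None])
                     & (tt.te[None, :] < grid[:, None])).sum(axis=1)
    if counts.shape[0] > 1:
        mean, lo, hi = grid_summary(counts)
    else:
        mean = counts[0].astype(float)
        lo = hi = mean
    return DiversityCurve(grid=grid, per_replicate=counts.astype(int),
                          mean=mean, hpd_lo=lo, hpd_hi=hi)


# ---------------------------------------------------------------------------
# discrete-bin tallies


def _ranges_from_records(records: pd.DataFrame):
    """Range-through first/last appearance per genus from an age-resolved table."""
    col = "age" if "age" in records.columns else None
    if col is None:
        mid = (records["max_ma"] + records["min_ma"]) / 2.0
        records = records.assign(age=mid)
    g = records.groupby("genus")["age"]
    return g.max().values, g.min().values, np.array(g.max().index)


def bin_counts(data, bins: np.ndarray) -> pd.DataFrame:
    """Boundary-crosser and three-timer tallies per bin.

    ``data`` is either a :class:`TaxonTimes` (true/estimated ranges) or an
    occurrence DataFrame (range-through first/last appearances, plus
    sampled-in-bin tallies).  ``bins`` are strictly decreasing bin edges
    (ages); bin k spans [bins[k], bins[k+1]).  A taxon crosses a boundary b
    when Ts >= b > Te.  Columns: N_bt, N_bL, N_Ft, N_FL, sib, t3, pt.
    """
    bins = np.asarray(bins, float)
    if not (np.diff(bins) < 0).all():
        raise ValueError("bins must be strictly decreasing")
    if np.any(np.diff(bins) == 0):
        raise ValueError("zero-duration bin")
    if isinstance(data, TaxonTimes):
        fad, lad = data.ts, data.te
        sampled = None
    else:
        fad, lad, genera = _ranges_from_records(data)
        ages = data["age"] if "age" in data.columns else (data["max_ma"] + data["min_ma"]) / 2
        gidx = {g: i for i, g in enumerate(genera)}
        sampled = np.zeros((len(genera), bins.size - 1), bool)
        bin_of = np.clip(np.searchsorted(-bins, -np.asarray(ages), side="right") - 1,
                         0, bins.size - 2)
        for g, k in zip(data["genus"], bin_of):
            sampled[gidx[g], k] = True

    nb = bins.size - 1
    out = []
    for k in range(nb):
        old, young = bins[k], bins[k + 1]
        cross_bottom = (fad >= old) & (lad < old)
        cross_top = (fad >= young) & (lad < young)
        in_bin_f = (fad < old) & (fad >= young)
        in_bin_l = (lad < old) & (lad >= young)
        n_bt = int(np.sum(cross_bottom & cross_top))
        n_bl = int(np.sum(cross_bottom & in_bin_l))
        n_ft = int(np.sum(in_bin_f & cross_top))
        n_fl = int(np.sum(in_bin_f & in_bin_l))
        if sampled is None:
            sib = t3 = pt = 0
        else:
            sib = int(sampled[:, k].sum())
            if 0 < k < nb - 1:
                t3 = int(np.sum(sampled[:, k - 1] & sampled[:, k] & sampled[:, k + 1]))
                pt = int(np.sum(sampled[:, k - 1] & ~sampled[:, k] & sampled[:, k + 1]))
            else:
                t3 = pt = 0
        out.append(dict(bin=k, max_ma=old, min_ma=young, N_bt=n_bt, N_bL=n_bl,
                        N_Ft=n_ft, N_FL=n_fl, sib=sib, t3=t3, pt=pt))
    return pd.DataFrame(out)


def per_capita_rates(counts: pd.DataFrame) -> pd.DataFrame:
    """Foote's per-capita rates per bin.

    p = -ln(N_bt/(N_bt+N_Ft))/Δt, q = -ln(N_bt/(N_bt+N_bL))/Δt; bins with
    N_bt = 0 are reported as missing (NaN), never as 0.
    """
    dt = counts["max_ma"] - counts["min_ma"]
    if (dt <= 0).any():
        raise ValueError("zero-duration bin")
    nbt = counts["N_bt"].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = -np.log(nbt / (nbt + counts["N_Ft"])) / dt
        q = -np.log(nbt / (nbt + counts["N_bL"])) / dt
    p[nbt == 0] = np.nan
    q[nbt == 0] = np.nan
    return counts.assign(p=p, q=q)


def three_timer_completeness(counts: pd.DataFrame):
    """Pooled three-timer completeness 3T/(3T+PT) and corrected richness.

    Returns (completeness, DataFrame with ``corrected_sib``); when the pooled
    3T+PT is zero the completeness (and corrections) are missing.
    """
    if len(counts) < 3:
        raise ValueError("need >= 3 consecutive bins")
    t3 = counts["t3"].sum()
    pt = counts["pt"].sum()
    if t3 + pt == 0:
        comp = np.nan
    else:
        comp = t3 / (t3 + pt)
    corrected = counts["sib"] / comp if np.isfinite(comp) and comp > 0 else \
        pd.Series(np.nan, index=counts.index)
    return comp, counts.assign(corrected_sib=corrected)


def rate_correlation(series_a, series_b, drop_edge_bins: int = 2,
                     method: str = "pearson"):
    """Pairwise-complete correlation of two bin-aligned rate series,
    trimming ``drop_edge_bins`` bins at both ends (edge-effect control)."""
    a = np.asarray(series_a, float)
    b = np.asarray(series_b, float)
    if a.shape != b.shape:
        raise ValueError("series must be bin-aligned")
    if drop_edge_bins:
        a = a[drop_edge_bins:-drop_edge_bins]
        b = b[drop_edge_bins:-drop_edge_bins]
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 5:
        raise ValueError("need >= 5 overlapping bins after trimming")
    if method == "pearson":
        r, p = stats.pearsonr(a[ok], b[ok])
    elif method == "spearman":
        r, p = stats.spearmanr(a[ok], b[ok])
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)
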