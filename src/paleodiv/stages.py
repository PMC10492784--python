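"""Geological stage table: lookup of stage/substage intervals in Ma.

Ages follow the convention used throughout the package: Ma before present,
larger = older, stage intervals half-open ``[max_ma, min_ma)``.  The packaged
default table covers the Kasimovian–Valanginian so that Permian–Jurassic
analysis windows carry buffer stages on both sides.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

_DEFAULT = None


def load_stage_table(path: str | None = None) -> pd.DataFrame:
    """Load a stage table (columns: stage, series, max_ma, min_ma, is_international).

    With ``path=None`` the packaged default table is returned (cached).
    """
    global _DEFAULT
    if path is None:
        if _DEFAULT is None:
            with resources.files("paleodiv.data").joinpath("stages.csv").open() as fh:
                _DEFAULT = _validate(pd.read_csv(fh))
        return _DEFAULT.copy()
    return _validate(pd.read_csv(path))


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    required = {"stage", "series", "max_ma", "min_ma", "is_international"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"stage table missing columns: {sorted(missing)}")
    if not (df["max_ma"] > df["min_ma"]).all():
        raise ValueError("stage table rows must have max_ma > min_ma")
    df = df.sort_values("max_ma", ascending=False).reset_index(drop=True)
    df["is_international"] = df["is_international"].astype(bool)
    return df


def substage_table(stages: pd.DataFrame) -> pd.DataFrame:
    """Divide every stage equally into early and late halves.

    Returns one row per substage with columns stage, substage, max_ma, min_ma.
    """
    rows = []
    for _, r in stages.iterrows():
        mid = 0.5 * (r.max_ma + r.min_ma)
        rows.append((r.stage, f"late {r.stage}", mid, r.min_ma))
        rows.append((r.stage, f"early {r.stage}", r.max_ma, mid))
    out = pd.DataFrame(rows, columns=["stage", "substage", "max_ma", "min_ma"])
    return out.sort_values("max_ma", ascending=False).reset_index(drop=True)


def interval_for_age(table: pd.DataFrame, age: float, label_col: str | None = None):
    """Return the row of ``table`` whose [max_ma, min_ma) interval contains ``age``.

    Raises ``ValueError`` naming the age when no interval covers it.
    """
    hit = table[(table["max_ma"] >= age) & (table["min_ma"] < age)]
    if hit.empty:
        # youngest boundary is inclusive at min edge of the youngest bin
        hit = table[np.isclose(table["min_ma"], age)]
    if hit.empty:
        raise ValueError(f"stage table does not cover age {age} Ma")
    return hit.iloc[0]


def series_table(stages: pd.DataFrame) -> pd.DataFrame:
    """Collapse the stage table to series-level intervals."""
    grp = stages.groupby("series", sort=False).agg(
        max_ma=("max_ma", "max"), min_ma=("min_ma", "min")
    )
    return grp.reset_index().sort_values("max_ma", ascending=False).reset_index(drop=True)


def boundaries_in_window(table: pd.DataFrame, old: float, young: float) -> np.ndarray:
    """Strictly decreasing interval boundaries inside (old, young), edges included."""
    edges = np.unique(np.concatenate([table["max_ma"].values, table["min_ma"].values]))
    edges = edges[(edges <= old) & (edges >= young)]
    edges = np.union1d(edges, [old, young])
    return np.sort(edges)[::-1]
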