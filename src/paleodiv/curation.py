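"""Occurrence curation: cleaning rules, subgenus handling, outlier flags,
age randomization and ecological / PT-group classification.

All filters are deterministic and auditable: ``clean_occurrences`` returns the
kept table together with a rejection log naming the rule that fired for every
dropped row, so kept + rejected always partitions the input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

QUALIFIERS = ("cf.", "aff.", "?", "informal", "ex. gr.", '""')

RULE_UNPARSEABLE = "unparseable_ages"
RULE_AMBIGUOUS = "ambiguous_genus"
RULE_TERRESTRIAL = "terrestrial"
RULE_QUALIFIER = "qualifier_same_genus"
RULE_SPAN = "age_span_gt_max"


@dataclass
class PTSplit:
    """Brachiopod orders that went extinct in vs survived/postdated the PTME."""

    pt_e: frozenset = frozenset(
        {"Spiriferida", "Productida", "Orthotetida", "Orthida", "Dictyonellida"})
    pt_s: frozenset = frozenset(
        {"Lingulida", "Terebratulida", "Athyridida", "Rhynchonellida",
         "Spiriferinida", "Craniida", "Thecideida"})

    def __post_init__(self):
        if self.pt_e & self.pt_s:
            raise ValueError("PT_e and PT_s must be disjoint")


@dataclass
class EcoTable:
    """Lifestyle lookup: genus -> label and/or order -> label, plus roll-ups."""

    genus_to_label: dict = field(default_factory=dict)
    order_to_label: dict = field(default_factory=dict)
    label_to_rollup: dict = field(default_factory=dict)

    def label_for(self, genus: str, order: str | None = None) -> str:
        if genus in self.genus_to_label:
            return self.genus_to_label[genus]
        if order and order in self.order_to_label:
            return self.order_to_label[order]
        return "unknown"


def default_eco_table() -> EcoTable:
    """Packaged lifestyle tables: label roll-ups plus brachiopod order lookup."""
    with resources.files("paleodiv.data").joinpath("eco_classes.csv").open() as fh:
        classes = pd.read_csv(fh)
    with resources.files("paleodiv.data").joinpath("brachiopod_orders.csv").open() as fh:
        orders = pd.read_csv(fh)
    return EcoTable(
        order_to_label=dict(zip(orders["order"], orders["lifestyle"])),
        label_to_rollup=dict(zip(classes["label"], classes["rollup"])),
    )


def default_pt_split() -> PTSplit:
    with resources.files("paleodiv.data").joinpath("brachiopod_orders.csv").open() as fh:
        orders = pd.read_csv(fh)
    return PTSplit(
        pt_e=frozenset(orders.loc[orders.pt_group == "PT_e", "order"]),
        pt_s=frozenset(orders.loc[orders.pt_group == "PT_s", "order"]),
    )


# ---------------------------------------------------------------------------
# cleaning


def clean_occurrences(records: pd.DataFrame, max_span: float = 10.0):
    """Apply the occurrence-cleaning rules; return (kept, rejection_log).

    Rules, in order, one per dropped row (the first that fires is logged):

    * unparseable or inverted max/min ages;
    * ambiguous generic assignment (empty/missing genus); unambiguous genus
      with an open species ("sp.") passes;
    * terrestrial environment;
    * open-nomenclature qualifier (cf., aff., ?, informal, ex. gr.) when the
      primary and accepted genus names agree — when they differ the species
      was re-assigned to another genus and the row is kept;
    * age span strictly greater than ``max_span`` Myr unless the dating is an
      international stage (e.g. a ~15 Myr Guadalupian occurrence is dropped
      but a ~18 Myr Norian one is kept).
    """
    df = records.copy()
    log_rows = []

    ages = df[["max_ma", "min_ma"]].apply(pd.to_numeric, errors="coerce")
    bad_age = ages["max_ma"].isna() | ages["min_ma"].isna() | (
        ages["max_ma"] <= ages["min_ma"])
    genus = df["genus"].fillna("").astype(str).str.strip()
    ambiguous = genus == ""
    terrestrial = df.get("environment", pd.Series("", index=df.index)) \
        .fillna("").str.lower().eq("terrestrial")
    reso = df.get("primary_reso", pd.Series("", index=df.index)).fillna("").astype(str).str.strip()
    accepted = df.get("accepted_genus", genus).fillna("").astype(str)
    base_genus = genus.map(lambda n: strip_subgenus(n, "delete_bracket") if n else n)
    qualifier = reso.isin(QUALIFIERS) & (base_genus == accepted)
    intl = df.get("is_international_stage", pd.Series(True, index=df.index)).fillna(False)
    span = (ages["max_ma"] - ages["min_ma"]) > max_span
    wide = span & ~intl.astype(bool)

    rule = pd.Series("", index=df.index, dtype=object)
    for mask, name in [(bad_age, RULE_UNPARSEABLE), (ambiguous, RULE_AMBIGUOUS),
                       (terrestrial, RULE_TERRESTRIAL), (qualifier, RULE_QUALIFIER),
                       (wide, RULE_SPAN)]:
        rule[mask & (rule == "")] = name
    dropped = rule != ""
    log = pd.DataFrame({"row_id": df.index[dropped], "rule": rule[dropped].values})
    return df[~dropped].copy(), log.reset_index(drop=True)


_SUBGENUS_RE = re.compile(r"^\s*(\S+)\s*\(\s*([^()]+?)\s*\)\s*$")


def strip_subgenus(name: str, mode: str = "delete_bracket",
                   promote: set | None = None) -> str:
    """Resolve a "Genus (Subgenus)" name.

    ``delete_bracket`` keeps the outer genus; ``promote`` keeps the bracketed
    subgenus as the genus when it appears in the user-supplied promotion list
    (otherwise the outer genus is kept).  Names without brackets pass through.
    """
    if not name:
        raise ValueError("empty taxon name")
    if name.count("(") != name.count(")"):
        raise ValueError(f"unbalanced brackets in taxon name: {name!r}")
    m = _SUBGENUS_RE.match(name)
    if not m:
        return name.strip()
    outer, inner = m.group(1), m.group(2)
    if mode == "promote" and promote and inner in promote:
        return inner
    if mode not in ("delete_bracket", "promote"):
        raise ValueError(f"unknown mode {mode!r}")
    return outer


# ---------------------------------------------------------------------------
# stratigraphic-range density outliers


def flag_range_outliers(records: pd.DataFrame, density: float = 0.90) -> pd.Series:
    """Flag occurrences outside the central ``density`` interval of their genus.

    The density estimate is the empirical quantile band of midpoint ages
    (interval (1-d)/2 ... 1-(1-d)/2), per genus; single-occurrence genera are
    never flagged.  Returns a boolean Series aligned with ``records``.
    """
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    mid = (records["max_ma"] + records["min_ma"]) / 2.0
    flags = pd.Series(False, index=records.index)
    if density == 1.0:
        return flags
    lo_q, hi_q = (1 - density) / 2, 1 - (1 - density) / 2
    for _, idx in records.groupby("genus").groups.items():
        if len(idx) < 2:
            continue
        ages = mid.loc[idx]
        lo, hi = ages.quantile([lo_q, hi_q])
        flags.loc[idx] = (ages < lo) | (ages > hi)
    return flags


# ---------------------------------------------------------------------------
# age randomization


def randomize_ages(records: pd.DataFrame, n_replicates: int = 10,
                   rng_seed: int = 0) -> list[pd.DataFrame]:
    """Draw ``n_replicates`` age-resolved copies of the table.

    Per replicate every collection receives one uniform draw from its
    [min_ma, max_ma] interval and all its occurrences share that age
    (column ``age``); replicates differ only by the draws.
    """
    rng = np.random.default_rng(rng_seed)
    colls = records.groupby("collection_no").agg(
        lo=("min_ma", "first"), hi=("max_ma", "first"))
    out = []
    for _ in range(n_replicates):
        u = rng.random(len(colls))
        age = colls["lo"].values + u * (colls["hi"].values - colls["lo"].values)
        lookup = pd.Series(age, index=colls.index)
        rep = records.copy()
        rep["age"] = records["collection_no"].map(lookup)
        out.append(rep)
    return out


# ---------------------------------------------------------------------------
# classification


def assign_ecology(records: pd.DataFrame, table: EcoTable | None = None) -> pd.DataFrame:
    """Attach ``eco_class`` and ``eco_rollup`` columns by pure table lookup."""
    table = default_eco_table() if table is None else table
    out = records.copy()
    orders = out.get("order", pd.Series("", index=out.index)).fillna("")
    base = out["genus"].map(lambda n: strip_subgenus(n) if n else n)
    out["eco_class"] = [table.label_for(g, o) for g, o in zip(base, orders)]
    out["eco_rollup"] = out["eco_class"].map(
        lambda l: table.label_to_rollup.get(l, "unknown"))
    return out


def assign_pt_group(records: pd.DataFrame, split: PTSplit | None = None) -> pd.DataFrame:
    """Attach the PT_e / PT_s group from the brachiopod order.

    Orders in neither set are left unassigned (empty string) with a warning
    column ``pt_unassigned`` set.
    """
    split = default_pt_split() if split is None else split
    out = records.copy()
    orders = out.get("order", pd.Series("", index=out.index)).fillna("")

    def grp(o):
        if o in split.pt_e:
            return "PT_e"
        if o in split.pt_s:
            return "PT_s"
        return ""

    out["pt_group"] = orders.map(grp)
    out["pt_unassigned"] = out["pt_group"] == ""
    return out
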