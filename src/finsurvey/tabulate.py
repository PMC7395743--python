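"""Descriptive tabulation of a trimming ledger.

Turns the per-trimming ledger into the survey's descriptive outputs:
a category count table with percentages, habitat / IUCN conservation
rollups, abundance frequency counts ``f_k`` and the incidence frequency
counts ``Q_k`` over sampling units.  These summaries are the inputs to
the richness estimators, the rarefaction curves and the composition
model.

A sampling unit for incidence data is one vendor visit, i.e. the two
bags purchased from one vendor during one sampling event, pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up

#: ranks that count as "identified" (everything except failed amplifications)
IDENTIFIED_RANKS = ("species", "complex", "genus", "family")
#: ranks identified to the species or species-complex level (diversity analyses)
SPECIES_RANKS = ("species", "complex")


@dataclass
class CountTable:
    """Per-category counts and percentages of identified trimmings.

    ``percent`` uses ``total_identified`` as denominator (trimmings of
    species, complex, genus and family rank), rounded half-up to two
    decimals, the convention of published market-survey tables.
    """

    table: pd.DataFrame  # columns: taxon, rank, count, percent
    total_collected: int
    total_identified: int

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)

    def counts(self, ranks: Sequence[str] = SPECIES_RANKS) -> pd.Series:
        """Per-taxon counts restricted to the given ranks (nonzero only)."""
        sub = self.table[self.table["rank"].isin(ranks) & (self.table["count"] > 0)]
        return sub.set_index("taxon")["count"]


@dataclass
class AbundanceFreq:
    """Abundance frequency summary: per-category counts and f_k.

    ``f_k`` is the number of categories observed exactly k times,
    ``n`` the number of trimmings and ``s_obs`` the number of observed
    categories.  The raw count vector is retained because interpolation
    estimators need it, not just the f_k.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.size == 0 or self.counts.sum() < 1:
            raise ValueError("abundance summary needs at least one observation")
        if (self.counts <= 0).any():
            raise ValueError("all category counts must be positive")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def s_obs(self) -> int:
        return int(self.counts.size)

    def f(self, k: int) -> int:
        """Number of categories with exactly k individuals."""
        return int((self.counts == k).sum())

    @classmethod
    def from_f_counts(cls, f_counts: dict[int, int]) -> "AbundanceFreq":
        """Build from a {k: f_k} mapping (convenience for tests/estimators)."""
        counts = [k for k, fk in f_counts.items() for _ in range(fk)]
        return cls(np.array(sorted(counts, reverse=True)))


@dataclass
class IncidenceFreq:
    """Incidence frequency summary over T sampling units.

    ``incidences`` holds, per observed category, the number of units in
    which it was detected; ``Q_k`` is the number of categories detected
    in exactly k units and ``U`` the total number of incidences.
    """

    incidences: np.ndarray
    n_units: int

    def __post_init__(self) -> None:
        self.incidences = np.asarray(self.incidences, dtype=np.int64)
        if self.n_units < 1:
            raise ValueError("need at least one sampling unit")
        if self.incidences.size == 0:
            raise ValueError("incidence summary needs at least one category")
        if (self.incidences <= 0).any() or (self.incidences > self.n_units).any():
            raise ValueError("incidences must lie in 1..n_units")

    @property
    def t(self) -> int:
        return int(self.n_units)

    @property
    def u(self) -> int:
        return int(self.incidences.sum())

    @property
    def s_obs(self) -> int:
        return int(self.incidences.size)

    def q(self, k: int) -> int:
        """Number of categories detected in exactly k units."""
        return int((self.incidences == k).sum())


@dataclass
class AttributeTable:
    """Per-taxon conservation and ecology attributes.

    IUCN status is one of LC/NT/VU/EN/CR/DD or blank; species complexes
    may carry mixed statuses separated by "/" (e.g. "DD/VU").
    """

    table: pd.DataFrame  # indexed by taxon: iucn, cites, size_class, habitat

    def statuses(self, taxon: str) -> list[str]:
        """IUCN statuses of a taxon; complexes yield one entry per member."""
        if taxon not in self.table.index:
            return []
        raw = self.table.loc[taxon, "iucn"]
        if not isinstance(raw, str) or not raw:
            return []
        return raw.split("/")

    def habitat(self, taxon: str) -> str:
        if taxon not in self.table.index:
            return ""
        value = self.table.loc[taxon, "habitat"]
        return value if isinstance(value, str) else ""


def build_count_table(ledger: pd.DataFrame) -> CountTable:
    """Aggregate a ledger into per-category counts and percentages.

    Unidentified trimmings (failed amplifications) are excluded from the
    percentage denominator but counted in ``total_collected``.
    """
    if len(ledger) == 0:
        raise ValueError("empty ledger")
    for col in ("assigned_taxon", "assignment_rank"):
        if col not in ledger.columns:
            raise ValueError(f"ledger lacks required column {col!r}")
    grouped = (
        ledger.groupby(["assigned_taxon", "assignment_rank"], sort=False)
        .size()
        .reset_index(name="count")
        .rename(columns={"assigned_taxon": "taxon", "assignment_rank": "rank"})
    )
    grouped = grouped.sort_values(["count", "taxon"], ascending=[False, True], kind="mergesort")
    identified = grouped[grouped["rank"].isin(IDENTIFIED_RANKS)]
    total_identified = int(identified["count"].sum())
    if total_identified == 0:
        raise ValueError("no identified trimmings in ledger")
    grouped["percent"] = [
        round_half_up(100.0 * c / total_identified, 2) if r in IDENTIFIED_RANKS else float("nan")
        for c, r in zip(grouped["count"], grouped["rank"])
    ]
    return CountTable(grouped, total_collected=len(ledger), total_identified=total_identified)


def abundance_frequencies(
    table: CountTable, include_ranks: Sequence[str] = SPECIES_RANKS
) -> AbundanceFreq:
    """Abundance frequency counts restricted to the given assignment ranks."""
    bad = set(include_ranks) - set(IDENTIFIED_RANKS)
    if bad:
        raise ValueError(f"unknown ranks: {sorted(bad)}")
    counts = table.counts(include_ranks)
    if counts.empty:
        raise ValueError("no categories left after rank filtering")
    return AbundanceFreq(counts.to_numpy())


def incidence_frequencies(
    ledger: pd.DataFrame,
    include_ranks: Sequence[str] = SPECIES_RANKS,
    unit: str = "vendor",
) -> IncidenceFreq:
    """Incidence frequency counts over sampling units.

    ``unit="vendor"`` (default) pools the two bags of one vendor visit
    into one sampling unit, i.e. the unit key is (event_id, vendor_id);
    ``unit="bag"`` treats each bag as its own unit.
    """
    keys = {"vendor": ["event_id", "vendor_id"], "bag": ["event_id", "vendor_id", "bag_id"]}
    if unit not in keys:
        raise ValueError(f"unit must be one of {sorted(keys)}")
    cols = keys[unit]
    missing = [c for c in cols if c not in ledger.columns]
    if missing:
        raise ValueError(f"ledger lacks unit id column(s): {missing}")
    t = int(ledger.groupby(cols, sort=False).ngroups)
    sub = ledger[ledger["assignment_rank"].isin(include_ranks)]
    if len(sub) == 0:
        raise ValueError("no categories left after rank filtering")
    # a category's incidence = number of units where it appears at least once
    inc = sub.drop_duplicates(subset=cols + ["assigned_taxon"]).groupby("assigned_taxon").size()
    return IncidenceFreq(inc.to_numpy(), n_units=t)


def attribute_rollup(
    table: CountTable,
    attrs: AttributeTable,
    predicate: Callable[[pd.Series], bool],
    ranks: Sequence[str] | None = SPECIES_RANKS,
    decimals: int = 1,
) -> tuple[float, float]:
    """Share of categories and of trimmings matching an attribute predicate.

    Returns ``(category_share_pct, trimming_share_pct)`` where the
    category share is over all categories with count > 0 under the rank
    filter (``ranks=None`` means every identified category) and the
    trimming share divides matching counts by ``total_identified``.

    The predicate receives the attribute row (fields ``iucn``, ``cites``,
    ``size_class``, ``habitat``) with mixed "A/B" statuses already split
    into the list field ``iucn_list``; a taxon missing from the
    attribute table is treated as non-matching.
    """
    use_ranks = list(ranks) if ranks is not None else list(IDENTIFIED_RANKS)
    sub = table.table[(table.table["count"] > 0) & table.table["rank"].isin(use_ranks)]
    n_cat = len(sub)
    if n_cat == 0:
        return (0.0, 0.0)
    match_cats = 0
    match_trims = 0
    for _, row in sub.iterrows():
        taxon = row["taxon"]
        if taxon not in attrs.table.index:
            continue
        arow = attrs.table.loc[taxon].copy()
        iucn = arow.get("iucn", "")
        arow["iucn_list"] = iucn.split("/") if isinstance(iucn, str) and iucn else []
        if predicate(arow):
            match_cats += 1
            match_trims += int(row["count"])
    return (
        round_half_up(100.0 * match_cats / n_cat, decimals),
        round_half_up(100.0 * match_trims / table.total_identified, decimals),
    )


def threatened(row: pd.Series) -> bool:
    """Any-member IUCN threat rule: VU, EN or CR for any complex member."""
    return any(s in ("VU", "EN", "CR") for s in row["iucn_list"])


def oceanic(row: pd.Series) -> bool:
    return row.get("habitat", "") == "Oceanic"


# printed identified totals of the packaged survey table; the Guangzhou
# column's printed counts sum to 1,707 yet every printed percentage uses
# 1,706 (the total stated in the source), an inconsistency in the
# published table that we preserve rather than reconcile
_PRINTED_TOTALS = {
    "guangzhou": {"identified": 1706, "collected": 2000},
    "hongkong": {"identified": 7636, "collected": 7636},
}


def _fixture_frame() -> pd.DataFrame:
    path = resources.files("finsurvey.data") / "guangzhou_hongkong_market_table.csv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, keep_default_na=False)


def load_market_table(market: str = "guangzhou") -> tuple[CountTable, AttributeTable]:
    """Load the packaged Guangzhou / Hong Kong market survey table.

    Returns the CountTable of the requested market (with the printed
    identified total as percentage denominator, so published
    percentages reproduce exactly) and the shared attribute table.
    """
    market = market.lower()
    if market not in _PRINTED_TOTALS:
        raise ValueError("market must be 'guangzhou' or 'hongkong'")
    raw = _fixture_frame()
    col = "count_gz" if market == "guangzhou" else "count_hk"
    totals = _PRINTED_TOTALS[market]
    df = raw[["taxon", "rank", col]].rename(columns={col: "count"}).copy()
    df["count"] = df["count"].astype(int)
    df = df[df["count"] > 0].sort_values(
        ["count", "taxon"], ascending=[False, True], kind="mergesort"
    )
    df["percent"] = [round_half_up(100.0 * c / totals["identified"], 2) for c in df["count"]]
    table = CountTable(
        df[["taxon", "rank", "count", "percent"]],
        total_collected=totals["collected"],
        total_identified=totals["identified"],
    )
    attrs = AttributeTable(
        raw.set_index("taxon")[["iucn", "cites", "size_class", "habitat"]]
    )
    return table, attrs
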