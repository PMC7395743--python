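"""Synthetic market-survey generator.

Emulates the hierarchical sampling design of a retail fin-trimming
survey: repeated sampling events, randomly chosen vendors per event,
two bags per vendor, and a fixed number of trimmings analyzed per bag.
Species shares follow a strongly skewed pool (the default pool is the
observed Guangzhou species/complex composition, ~36% blue shark), and
two realistic nuisance processes are applied per trimming: amplification
failure (default 13.7%) and demotion of a species-level identification
to genus level (default 12.5%, matching the share of genus-only rows in
the survey table).

Vendor-to-vendor heterogeneity is modeled by drawing each vendor's
proportion vector from Dirichlet(theta * pi): small theta gives strongly
clustered bags, theta -> infinity recovers homogeneous multinomial
sampling.  Bags inherit their vendor's proportions.  All randomness
flows from one integer seed through deterministic per-(event, vendor)
substreams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PoolEntry:
    """One species (or complex) in the simulated market pool."""

    taxon: str
    rank: str        # "species" or "complex"
    genus: str
    proportion: float


@dataclass
class MarketSimConfig:
    """Parameters of the synthetic market survey.

    Defaults mirror the survey design the simulator emulates: 10
    sampling events x 10 vendors x 2 bags x 10 analyzed trimmings
    (2,000 trimmings), a 13.7% amplification-failure rate and a 12.5%
    genus-only demotion rate.  ``vendor_heterogeneity`` is the Dirichlet
    concentration multiplier theta; ``math.inf`` gives identical vendors.
    """

    species_pool: Sequence[PoolEntry]
    n_events: int = 10
    vendors_per_event: int = 10
    bags_per_vendor: int = 2
    trimmings_per_bag: int = 10
    vendor_heterogeneity: float = 25.0
    fail_rate: float = 0.137
    genus_only_rate: float = 0.125
    sequences: Mapping[str, str] | None = None  # optional taxon -> reference sequence
    seed: int = 0

    def validate(self) -> None:
        if not self.species_pool:
            raise ValueError("species pool must not be empty")
        total = sum(e.proportion for e in self.species_pool)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"pool proportions must sum to 1 (got {total!r})")
        for name, v in (("n_events", self.n_events), ("vendors_per_event", self.vendors_per_event),
                        ("bags_per_vendor", self.bags_per_vendor),
                        ("trimmings_per_bag", self.trimmings_per_bag)):
            if v < 1:
                raise ValueError(f"{name} must be >= 1")
        for name, v in (("fail_rate", self.fail_rate), ("genus_only_rate", self.genus_only_rate)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not self.vendor_heterogeneity > 0:
            raise ValueError("vendor_heterogeneity must be positive")


@dataclass
class TruthTable:
    """Ground truth behind a simulated ledger, for parameter-recovery tests."""

    vendor_proportions: pd.DataFrame  # index (event_id, vendor_id), one column per taxon
    bag_counts: pd.DataFrame          # index (event_id, vendor_id, bag_id), per-taxon draws


def default_species_pool() -> list[PoolEntry]:
    """Skewed 43-category pool with the observed market species shares."""
    from .tabulate import load_market_table

    table, _ = load_market_table("guangzhou")
    counts = table.counts(("species", "complex"))
    total = counts.sum()
    return [
        PoolEntry(
            taxon=t,
            rank="complex" if "/" in t else "species",
            genus=t.split()[0],
            proportion=c / total,
        )
        for t, c in counts.items()
    ]


def mutate_sequence(seq: str, n_mut: int, seed: int = 0) -> str:
    """Substitute exactly ``n_mut`` positions, never a base for itself.

    The result is at Hamming distance exactly ``n_mut`` from the input.
    """
    if n_mut > len(seq):
        raise ValueError("n_mut exceeds sequence length")
    if n_mut == 0:
        return seq
    rng = np.random.default_rng(seed)
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for pos in positions:
        current = out[pos].upper()
        alternatives = [b for b in "ACGT" if b != current]
        out[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def simulate_market(config: MarketSimConfig) -> tuple[pd.DataFrame, TruthTable]:
    """Simulate a full market survey ledger plus its ground truth.

    The ledger has one row per trimming with columns event_id,
    vendor_id, bag_id, trimming_id, true_taxon, assigned_taxon,
    assignment_rank, and sequence when the config carries reference
    sequences.  Identical configs (including seed) give identical
    output.
    """
    config.validate()
    pool = list(config.species_pool)
    taxa = [e.taxon for e in pool]
    pi = np.array([e.proportion for e in pool])
    theta = config.vendor_heterogeneity
    root = np.random.SeedSequence(config.seed)
    # one substream per (event, vendor), spawned deterministically
    streams = root.spawn(config.n_events * config.vendors_per_event + 1)
    noise_rng = np.random.default_rng(streams[-1])

    rows: list[dict] = []
    vendor_props: dict[tuple, np.ndarray] = {}
    bag_draws: dict[tuple, np.ndarray] = {}
    idx = 0
    for event in range(1, config.n_events + 1):
        for vendor in range(1, config.vendors_per_event + 1):
            rng = np.random.default_rng(streams[idx])
            idx += 1
            if math.isinf(theta):
                props = pi.copy()
            else:
                props = rng.dirichlet(theta * pi + 1e-12)
            vendor_props[(event, vendor)] = props
            for bag in range(1, config.bags_per_vendor + 1):
                counts = rng.multinomial(config.trimmings_per_bag, props)
                bag_draws[(event, vendor, bag)] = counts
                trim = 0
                for sp_idx, c in enumerate(counts):
                    for _ in range(c):
                        trim += 1
                        rows.append(
                            {
                                "event_id": event,
                                "vendor_id": vendor,
                                "bag_id": bag,
                                "trimming_id": trim,
                                "true_taxon": taxa[sp_idx],
                                "_rank": pool[sp_idx].rank,
                                "_genus": pool[sp_idx].genus,
                            }
                        )
    ledger = pd.DataFrame(rows)
    # per-trimming nuisance processes, independent of the hierarchy
    u_fail = noise_rng.random(len(ledger))
    u_genus = noise_rng.random(len(ledger))
    failed = u_fail < config.fail_rate
    demoted = ~failed & (u_genus < config.genus_only_rate)
    assigned = ledger["true_taxon"].copy()
    rank = ledger["_rank"].copy()
    assigned[failed] = "Unidentified"
    rank[failed] = "unidentified"
    assigned[demoted] = ledger.loc[demoted, "_genus"] + " spp."
    rank[demoted] = "genus"
    ledger["assigned_taxon"] = assigned
    ledger["assignment_rank"] = rank
    if config.sequences is not None:
        missing = [t for t in taxa if t not in config.sequences]
        if missing:
            raise ValueError(f"no reference sequence for taxa: {missing}")
        ledger["sequence"] = [
            "" if f else config.sequences[t]
            for t, f in zip(ledger["true_taxon"], failed)
        ]
    ledger = ledger.drop(columns=["_rank", "_genus"])

    truth = TruthTable(
        vendor_proportions=pd.DataFrame(
            {k: v for k, v in vendor_props.items()}, index=taxa
        ).T.rename_axis(["event_id", "vendor_id"]),
        bag_counts=pd.DataFrame(
            {k: v for k, v in bag_draws.items()}, index=taxa
        ).T.rename_axis(["event_id", "vendor_id", "bag_id"]),
    )
    return ledger, truth
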