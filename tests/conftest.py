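"""Shared fixtures: reference mini-barcode sets and simulated surveys.

All sequence fixtures are synthetic: random 150 bp mini-barcodes with
large pairwise distances stand in for per-species COI references, and
the four blacktip-complex members deliberately share one sequence.
"""

from __future__ import annotations

import numpy as np
import pytest

from finsurvey import (
    ComplexTable,
    MarketSimConfig,
    ReferenceDB,
    ReferenceRecord,
    load_market_table,
    simulate_market,
)
from finsurvey.simulate import PoolEntry

BLACKTIP_MEMBERS = (
    "Carcharhinus limbatus",
    "Carcharhinus leiodon",
    "Carcharhinus tilstoni",
    "Carcharhinus amblyrhynchoides",
)

SPECIES_TAXONOMY = {
    # species: (genus, family)
    "Prionace glauca": ("Prionace", "Carcharhinidae"),
    "Carcharhinus falciformis": ("Carcharhinus", "Carcharhinidae"),
    "Carcharhinus leucas": ("Carcharhinus", "Carcharhinidae"),
    "Carcharhinus longimanus": ("Carcharhinus", "Carcharhinidae"),
    "Sphyrna lewini": ("Sphyrna", "Sphyrnidae"),
    "Sphyrna zygaena": ("Sphyrna", "Sphyrnidae"),
    "Isurus oxyrinchus": ("Isurus", "Lamnidae"),
    **{sp: ("Carcharhinus", "Carcharhinidae") for sp in BLACKTIP_MEMBERS},
}


def random_barcode(rng: np.random.Generator, length: int = 150) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def reference_sequences() -> dict[str, str]:
    """One synthetic 150 bp barcode per species; blacktips share one."""
    rng = np.random.default_rng(20240601)
    seqs: dict[str, str] = {}
    blacktip_seq = random_barcode(rng)
    for sp in SPECIES_TAXONOMY:
        if sp in BLACKTIP_MEMBERS:
            seqs[sp] = blacktip_seq
        else:
            seqs[sp] = random_barcode(rng)
    return seqs


def _build_db(seqs: dict[str, str], tag: str) -> ReferenceDB:
    return ReferenceDB(
        records=[
            ReferenceRecord(
                record_id=f"{tag}-{i}",
                sequence=seq,
                species=sp,
                genus=SPECIES_TAXONOMY[sp][0],
                family=SPECIES_TAXONOMY[sp][1],
            )
            for i, (sp, seq) in enumerate(seqs.items())
        ],
        db_tag=tag,
    )


@pytest.fixture(scope="session")
def db_a(reference_sequences) -> ReferenceDB:
    return _build_db(reference_sequences, "A")


@pytest.fixture(scope="session")
def db_b(reference_sequences) -> ReferenceDB:
    return _build_db(reference_sequences, "B")


@pytest.fixture(scope="session")
def blacktip_complexes() -> ComplexTable:
    return ComplexTable(complexes={"Blacktip complex": frozenset(BLACKTIP_MEMBERS)})


@pytest.fixture(scope="session")
def gz_table():
    table, attrs = load_market_table("guangzhou")
    return table, attrs


@pytest.fixture(scope="session")
def default_ledger():
    """Default-design simulated survey (10 x 10 x 2 x 10, seeded)."""
    from finsurvey import default_species_pool

    config = MarketSimConfig(species_pool=default_species_pool(), seed=42)
    return simulate_market(config)


def small_pool(proportions, prefix: str = "Genus") -> list[PoolEntry]:
    """Helper: a pool of dummy species with the given proportions."""
    return [
        PoolEntry(taxon=f"{prefix}{i} species{i}", rank="species",
                  genus=f"{prefix}{i}", proportion=p)
        for i, p in enumerate(proportions)
    ]
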