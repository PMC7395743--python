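"""Two-criterion mini-barcode assignment: distances, matching, ranking rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from finsurvey import (
    MarketSimConfig,
    assign_ledger,
    assign_taxon,
    match_reference,
    mutate_sequence,
    sequence_distance,
    simulate_market,
)
from finsurvey.assign import MatchResult, assign_query

from conftest import BLACKTIP_MEMBERS, SPECIES_TAXONOMY
from finsurvey.simulate import PoolEntry

nt = st.text(alphabet="ACGT", min_size=1, max_size=24)


def brute_force_distance(a: str, b: str) -> int:
    """Independent oracle: try every ungapped offset of the shorter string."""
    if len(a) > len(b):
        a, b = b, a
    best = len(a)
    for off in range(len(b) - len(a) + 1):
        d = sum(
            x != y and x != "N" and y != "N"
            for x, y in zip(a, b[off : off + len(a)])
        )
        best = min(best, d)
    return best


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("ACGT", "ACGT", 0),
        ("ACGT", "ACGA", 1),
        ("ACG", "TACGT", 0),       # shorter slides to a perfect match
        ("ANGT", "ACGT", 0),       # N matches anything
        ("AAAA", "TTTT", 4),
    ],
)
def test_sequence_distance_examples(a, b, expected):
    assert sequence_distance(a, b) == expected
    assert sequence_distance(b, a) == expected


@given(a=nt, b=nt)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_sequence_distance_matches_brute_force(a, b):
    assert sequence_distance(a, b) == brute_force_distance(a, b)
    assert sequence_distance(a, b) == sequence_distance(b, a)


def test_sequence_distance_rejects_empty():
    with pytest.raises(ValueError):
        sequence_distance("", "ACGT")


def test_match_reference_exact_and_ties(db_a, reference_sequences):
    res = match_reference(reference_sequences["Prionace glauca"], db_a)
    assert res.min_distance == 0
    assert res.candidates == {"Prionace glauca"}
    # blacktip members share a sequence: candidate set is all four
    res = match_reference(reference_sequences["Carcharhinus limbatus"], db_a)
    assert res.min_distance == 0
    assert res.candidates == frozenset(BLACKTIP_MEMBERS)


def test_match_reference_order_invariant(db_a, reference_sequences):
    import copy

    query = mutate_sequence(reference_sequences["Sphyrna lewini"], 1, seed=2)
    shuffled = copy.deepcopy(db_a)
    shuffled.records = list(reversed(shuffled.records))
    assert match_reference(query, db_a) == match_reference(query, shuffled)


def test_case_insensitive_assignment(db_a, db_b, blacktip_complexes, reference_sequences):
    seq = reference_sequences["Isurus oxyrinchus"]
    upper = assign_query(seq, db_a, db_b, blacktip_complexes)
    lower = assign_query(seq.lower(), db_a, db_b, blacktip_complexes)
    assert upper == lower
    assert upper.label == "Isurus oxyrinchus"


def test_two_criterion_rule(blacktip_complexes, db_a, db_b):
    # (i)+(ii) satisfied -> species
    a = assign_taxon(
        MatchResult(0, frozenset({"Sphyrna lewini"})),
        MatchResult(0, frozenset({"Sphyrna lewini"})),
        blacktip_complexes,
    )
    assert (a.label, a.rank) == ("Sphyrna lewini", "species")
    # blacktip shared sequence collapses to one complex
    bt = frozenset(BLACKTIP_MEMBERS)
    a = assign_taxon(MatchResult(0, bt), MatchResult(0, bt), blacktip_complexes)
    assert (a.label, a.rank) == ("Blacktip complex", "complex")
    # criterion (i) fails on distance -> genus fallback
    a = assign_taxon(
        MatchResult(3, frozenset({"Carcharhinus leucas"})),
        MatchResult(3, frozenset({"Carcharhinus leucas"})),
        blacktip_complexes,
    )
    assert (a.label, a.rank) == ("Carcharhinus spp.", "genus")
    # databases disagree at species level but share genus -> genus
    a = assign_taxon(
        MatchResult(0, frozenset({"Carcharhinus leucas"})),
        MatchResult(0, frozenset({"Carcharhinus longimanus"})),
        blacktip_complexes,
    )
    assert (a.label, a.rank) == ("Carcharhinus spp.", "genus")
    # same family, different genera -> family
    a = assign_taxon(
        MatchResult(1, frozenset({"Prionace glauca", "Carcharhinus leucas"})),
        MatchResult(1, frozenset({"Prionace glauca", "Carcharhinus leucas"})),
        blacktip_complexes,
        db_a=db_a, db_b=db_b,
    )
    assert (a.label, a.rank) == ("Carcharhinidae", "family")
    # cross-family ambiguity -> unidentified
    a = assign_taxon(
        MatchResult(1, frozenset({"Prionace glauca", "Isurus oxyrinchus"})),
        MatchResult(1, frozenset({"Prionace glauca", "Isurus oxyrinchus"})),
        blacktip_complexes,
        db_a=db_a, db_b=db_b,
    )
    assert a.rank == "unidentified"
    # amplification failure flag wins over everything
    a = assign_taxon(None, None, blacktip_complexes, failed=True)
    assert a.rank == "unidentified"


def test_rank_never_returns_to_species_beyond_two_mismatches(
    db_a, db_b, blacktip_complexes, reference_sequences
):
    """Mutation sweep 0 -> 5: species rank only while distance <= 2."""
    base = reference_sequences["Prionace glauca"]
    for n_mut in range(6):
        query = mutate_sequence(base, n_mut, seed=100 + n_mut)
        result = assign_query(query, db_a, db_b, blacktip_complexes)
        if n_mut <= 2:
            assert result.rank == "species" and result.label == "Prionace glauca"
        else:
            assert result.rank != "species"


def test_high_n_fraction_fails(db_a, db_b, blacktip_complexes, reference_sequences):
    seq = reference_sequences["Prionace glauca"]
    n_tail = "N" * (len(seq) // 3)
    assert assign_query(n_tail + seq[len(n_tail):], db_a, db_b, blacktip_complexes).rank == "unidentified"


def test_round_trip_recovers_all_true_taxa(
    db_a, db_b, blacktip_complexes, reference_sequences
):
    """Clean simulation + <=2 mutations per query -> exact recovery."""
    pool_species = [
        "Prionace glauca", "Carcharhinus falciformis", "Sphyrna lewini",
        "Isurus oxyrinchus", "Carcharhinus leucas",
    ]
    pool = [
        PoolEntry(sp, "species", SPECIES_TAXONOMY[sp][0], 1.0 / len(pool_species))
        for sp in pool_species
    ]
    config = MarketSimConfig(
        species_pool=pool, n_events=2, vendors_per_event=5,
        fail_rate=0.0, genus_only_rate=0.0,
        sequences={sp: reference_sequences[sp] for sp in pool_species}, seed=17,
    )
    ledger, _ = simulate_market(config)
    rng = np.random.default_rng(23)
    ledger["sequence"] = [
        mutate_sequence(s, int(rng.integers(0, 3)), seed=int(rng.integers(2**31)))
        for s in ledger["sequence"]
    ]
    out = assign_ledger(ledger, db_a, db_b, blacktip_complexes)
    assert (out["assigned_taxon"] == out["true_taxon"]).all()
    assert (out["assignment_rank"] == "species").all()
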