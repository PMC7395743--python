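"""Rule-based taxon assignment of COI mini-barcode queries.

Each query is matched against two independent reference sets (tagged A
and B, emulating a GenBank/BLAST search and a BOLD lookup) and assigned
the lowest defensible taxonomic category:

* species (or species complex) when the minimum-distance candidate set
  of reference set A is a single species (after collapsing known
  indistinguishable complexes), at most ``max_species_distance`` (2 bp
  by default) from the query, and reference set B independently returns
  the same unambiguous answer;
* genus when the two criteria are not both met but every candidate
  species shares one genus;
* family when candidates span genera within a single family;
* unidentified otherwise (including amplification failures and queries
  with too many ambiguous bases).

Distances are ungapped mismatch counts: equal-length sequences use the
Hamming distance with N matching anything; a shorter fragment is slid
along a longer reference and the minimum mismatch count over all
offsets is taken.  Indels are not modeled because the mini-barcode
fragments are fixed-length amplicons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

#: queries with more than this fraction of N bases are treated as failed
MAX_N_FRACTION = 0.20
#: maximum mismatches against reference set A for a species-level call
MAX_SPECIES_DISTANCE = 2

_VALID = set("ACGTN")


@dataclass(frozen=True)
class ReferenceRecord:
    """One reference sequence with its taxonomy."""

    record_id: str
    sequence: str
    species: str
    genus: str
    family: str = ""


@dataclass
class ReferenceDB:
    """A set of labeled reference mini-barcodes (db_tag 'A' or 'B')."""

    records: list[ReferenceRecord]
    db_tag: str = "A"

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("reference database must not be empty")
        clean = []
        for i, rec in enumerate(self.records):
            seq = rec.sequence.upper()
            if not seq:
                raise ValueError(f"record {i} ({rec.record_id}): empty sequence")
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(
                    f"record {i} ({rec.record_id}): invalid characters {sorted(bad)}"
                )
            if not rec.species or not rec.genus:
                raise ValueError(f"record {i} ({rec.record_id}): missing taxonomy")
            clean.append(ReferenceRecord(rec.record_id, seq, rec.species, rec.genus, rec.family))
        self.records = clean

    def family_of(self, species: str) -> str:
        for rec in self.records:
            if rec.species == species:
                return rec.family
        return ""


@dataclass
class ComplexTable:
    """Known species complexes: sets of species indistinguishable at the marker."""

    complexes: dict[str, frozenset[str]]  # complex label -> member species

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label, members in self.complexes.items():
            if seen & members:
                raise ValueError(f"complex {label!r} overlaps another complex")
            seen |= members

    def collapse(self, species: Iterable[str]) -> frozenset[str]:
        """Replace species by their complex label wherever applicable."""
        out = set()
        for sp in species:
            for label, members in self.complexes.items():
                if sp in members:
                    out.add(label)
                    break
            else:
                out.add(sp)
        return frozenset(out)

    def is_complex(self, label: str) -> bool:
        return label in self.complexes


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one query against one reference set."""

    min_distance: int
    candidates: frozenset[str]  # species at the minimum distance


@dataclass(frozen=True)
class TaxonAssignment:
    label: str
    rank: str  # species | complex | genus | family | unidentified
    min_distance_a: int | None = None
    min_distance_b: int | None = None
    candidates_a: frozenset[str] = frozenset()
    candidates_b: frozenset[str] = frozenset()


def _to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype="S1")


def sequence_distance(a: str, b: str) -> int:
    """Ungapped mismatch count between two nucleotide strings.

    Equal lengths: Hamming distance, with N matching any base.  Unequal
    lengths: the shorter sequence is slid along the longer and the
    minimum mismatch count over all offsets is returned.  Symmetric.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    sa, sb = _to_array(a), _to_array(b)
    if sa.size > sb.size:
        sa, sb = sb, sa
    short, long = sa, sb
    n_mask = (short == b"N")
    best = short.size
    for off in range(long.size - short.size + 1):
        window = long[off : off + short.size]
        mism = (short != window) & ~n_mask & (window != b"N")
        best = min(best, int(mism.sum()))
        if best == 0:
            break
    return best


def match_reference(query: str, db: ReferenceDB) -> MatchResult:
    """Minimum distance and the species set achieving it.

    Deterministic and independent of record order: ties simply enlarge
    the candidate set.
    """
    best = None
    candidates: set[str] = set()
    for rec in db.records:
        d = sequence_distance(query, rec.sequence)
        if best is None or d < best:
            best = d
            candidates = {rec.species}
        elif d == best:
            candidates.add(rec.species)
    assert best is not None
    return MatchResult(min_distance=best, candidates=frozenset(candidates))


def _shared(values: Iterable[str]) -> str | None:
    vals = {v for v in values if v}
    return next(iter(vals)) if len(vals) == 1 else None


def assign_taxon(
    match_a: MatchResult | None,
    match_b: MatchResult | None,
    complexes: ComplexTable,
    db_a: ReferenceDB | None = None,
    db_b: ReferenceDB | None = None,
    max_species_distance: int = MAX_SPECIES_DISTANCE,
    failed: bool = False,
) -> TaxonAssignment:
    """Apply the two-criterion identification rule.

    Species rank requires (i) reference set A's minimum-distance
    candidates to collapse to one species/complex within
    ``max_species_distance`` mismatches and (ii) reference set B to
    return the same unambiguous answer (no distance threshold on B).
    Failing that, a shared genus gives genus rank, a shared family
    family rank, anything else is unidentified.
    """
    if failed or match_a is None or match_b is None:
        return TaxonAssignment(label="Unidentified", rank="unidentified")
    coll_a = complexes.collapse(match_a.candidates)
    coll_b = complexes.collapse(match_b.candidates)
    common = dict(
        min_distance_a=match_a.min_distance,
        min_distance_b=match_b.min_distance,
        candidates_a=match_a.candidates,
        candidates_b=match_b.candidates,
    )
    if (
        len(coll_a) == 1
        and coll_a == coll_b
        and match_a.min_distance <= max_species_distance
    ):
        label = next(iter(coll_a))
        rank = "complex" if complexes.is_complex(label) else "species"
        return TaxonAssignment(label=label, rank=rank, **common)
    union = match_a.candidates | match_b.candidates
    genus = _shared(sp.split()[0] for sp in union)
    if genus is not None:
        return TaxonAssignment(label=f"{genus} spp.", rank="genus", **common)
    families = set()
    for sp in union:
        fam = ""
        if db_a is not None:
            fam = db_a.family_of(sp)
        if not fam and db_b is not None:
            fam = db_b.family_of(sp)
        families.add(fam)
    family = _shared(families) if "" not in families else None
    if family is not None:
        return TaxonAssignment(label=family, rank="family", **common)
    return TaxonAssignment(label="Unidentified", rank="unidentified", **common)


def assign_query(
    query: str,
    db_a: ReferenceDB,
    db_b: ReferenceDB,
    complexes: ComplexTable,
    max_species_distance: int = MAX_SPECIES_DISTANCE,
) -> TaxonAssignment:
    """Match one query against both reference sets and assign a taxon."""
    seq = query.upper() if query else ""
    if not seq or seq.count("N") / len(seq) > MAX_N_FRACTION:
        return TaxonAssignment(label="Unidentified", rank="unidentified")
    return assign_taxon(
        match_reference(seq, db_a),
        match_reference(seq, db_b),
        complexes,
        db_a=db_a,
        db_b=db_b,
        max_species_distance=max_species_distance,
    )


def assign_ledger(
    ledger,
    db_a: ReferenceDB,
    db_b: ReferenceDB,
    complexes: ComplexTable,
    max_species_distance: int = MAX_SPECIES_DISTANCE,
):
    """Fill assigned_taxon / assignment_rank for every ledger row with a sequence.

    Rows with an empty sequence are marked unidentified (amplification
    failure).  Returns a new DataFrame; the input is not modified.
    """
    if "sequence" not in ledger.columns:
        raise ValueError("ledger has no sequence column to assign from")
    out = ledger.copy()
    cache: dict[str, TaxonAssignment] = {}
    labels, ranks = [], []
    for seq in out["sequence"].fillna(""):
        if seq not in cache:
            cache[seq] = assign_query(seq, db_a, db_b, complexes, max_species_distance)
        a = cache[seq]
        labels.append(a.label)
        ranks.append(a.rank)
    out["assigned_taxon"] = labels
    out["assignment_rank"] = ranks
    return out
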