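"""Readers and writers for ledgers, reference FASTA and complex tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .assign import ComplexTable, ReferenceDB, ReferenceRecord

REQUIRED_LEDGER_COLUMNS = ("event_id", "vendor_id", "bag_id", "trimming_id")
KEY_COLUMNS = list(REQUIRED_LEDGER_COLUMNS)


class LedgerSchemaError(ValueError):
    """A ledger file does not satisfy the expected schema."""


def read_ledger(path: str | Path) -> pd.DataFrame:
    """Read a trimming ledger CSV and validate its schema.

    Requires the hierarchical key columns plus either a ``sequence``
    column or the ``assigned_taxon``/``assignment_rank`` pair.
    Duplicate (event, vendor, bag, trimming) keys are rejected.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise LedgerSchemaError(f"{path}: empty ledger file") from exc
    if len(df) == 0:
        raise LedgerSchemaError(f"{path}: ledger has no rows")
    for col in REQUIRED_LEDGER_COLUMNS:
        if col not in df.columns:
            raise LedgerSchemaError(f"{path}: missing required column {col!r}")
    has_seq = "sequence" in df.columns
    has_assign = "assigned_taxon" in df.columns and "assignment_rank" in df.columns
    if not has_seq and not has_assign:
        raise LedgerSchemaError(
            f"{path}: need a 'sequence' column or 'assigned_taxon'/'assignment_rank'"
        )
    if df.duplicated(subset=KEY_COLUMNS).any():
        dup = df[df.duplicated(subset=KEY_COLUMNS)].iloc[0]
        raise LedgerSchemaError(
            f"{path}: duplicate trimming key {tuple(dup[c] for c in KEY_COLUMNS)}"
        )
    return df


def write_ledger(ledger: pd.DataFrame, path: str | Path) -> None:
    ledger.to_csv(path, index=False)


def read_reference_fasta(path: str | Path, db_tag: str = "A") -> ReferenceDB:
    """Read a reference set from FASTA with ``id|species|genus|family`` headers.

    A trailing ``|db_tag`` field may override ``db_tag``.  Sequences are
    upper-cased; characters outside A/C/G/T/N are rejected.
    """
    path = Path(path)
    records: list[ReferenceRecord] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        fields = rec.description.split("|")
        if len(fields) < 4:
            raise ValueError(
                f"{path}: record {i}: header must be 'id|species|genus|family[|db_tag]', "
                f"got {rec.description!r}"
            )
        rec_id, species, genus, family = (f.strip() for f in fields[:4])
        if len(fields) >= 5 and fields[4].strip():
            db_tag = fields[4].strip()
        records.append(
            ReferenceRecord(
                record_id=rec_id,
                sequence=str(rec.seq).upper(),
                species=species,
                genus=genus,
                family=family,
            )
        )
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return ReferenceDB(records=records, db_tag=db_tag)


def read_complexes(path: str | Path) -> ComplexTable:
    """Read a complexes CSV with columns complex_label, member_species."""
    df = pd.read_csv(path)
    for col in ("complex_label", "member_species"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    table: dict[str, frozenset[str]] = {}
    for label, group in df.groupby("complex_label"):
        table[str(label)] = frozenset(group["member_species"].astype(str))
    return ComplexTable(complexes=table)
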