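"""Construction of All-HLA and 9-HLA reference sequence databases.

The IPD-IMGT/HLA database distributes known HLA allele sequences as
genomic (``*_gen.fasta``) and coding/cDNA (``*_nuc.fasta``) FASTA files
with headers of the form ``HLA:HLA00001 A*01:01:01:01 3503 bp``.  This
module parses those files, pools genomic and cDNA records into one
database, and restricts it either to every locus present (the All-HLA
reference) or to the nine classical loci (the 9-HLA reference) used for
read filtering.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import EmptyReferenceError, InvalidAlleleError
from .nomenclature import AlleleName, parse_allele

logger = logging.getLogger(__name__)

#: The nine classical loci of the restricted reference.
NINE_GENES = frozenset({"A", "B", "C", "DPA1", "DPB1", "DQA1", "DQB1", "DRA", "DRB1"})
CLASS_I_GENES = frozenset({"A", "B", "C"})
CLASS_II_GENES = frozenset({"DPA1", "DPB1", "DQA1", "DQB1", "DRA", "DRB1"})

_VALID_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class ReferenceRecord:
    allele: AlleleName
    sequence: str
    seq_type: str  # "genomic" | "cDNA"


@dataclass
class ReferenceDB:
    """An HLA reference sequence set (pooled genomic + cDNA records)."""

    records: list[ReferenceRecord]
    scope: str = "custom"  # "all_hla" | "nine_hla" | "custom"
    version_label: str = ""
    skipped: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            key = (rec.allele.raw or rec.allele.render(), rec.seq_type)
            if key in seen:
                raise ValueError(f"duplicate reference record {key}")
            seen.add(key)
            if not rec.sequence:
                raise ValueError(f"empty sequence for {rec.allele}")

    def genes(self) -> set[str]:
        return {rec.allele.gene for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def parse_reference_fasta(
    path: str | Path,
    seq_type: str,
    version_label: str = "",
) -> ReferenceDB:
    """Parse one IPD-IMGT/HLA-style FASTA file into a :class:`ReferenceDB`.

    Headers may follow the IPD-IMGT/HLA convention
    ``accession allele-name length bp`` (allele name is the second
    token) or carry a plain allele name as the first token.  Entries
    whose header yields no parseable allele name, or whose sequence
    contains characters outside A/C/G/T/N after uppercasing, are
    skipped with a logged warning and counted in ``skipped``.

    Raises :class:`EmptyReferenceError` if no record parses.
    """
    if seq_type not in ("genomic", "cDNA"):
        raise ValueError(f"seq_type must be 'genomic' or 'cDNA', got {seq_type!r}")
    records: list[ReferenceRecord] = []
    skipped = 0
    seen: set[tuple[str, str]] = set()
    with _open_text(path) as handle:
        for entry in SeqIO.parse(handle, "fasta"):
            allele = _allele_from_header(entry.description)
            if allele is None:
                logger.warning("skipping unparseable FASTA header: %s", entry.description)
                skipped += 1
                continue
            seq = str(entry.seq).upper()
            if not seq or not set(seq) <= _VALID_ALPHABET:
                logger.warning("skipping %s: sequence not over A/C/G/T/N", allele)
                skipped += 1
                continue
            # canonical combined-FASTA headers carry their own type tag
            rec_type = seq_type
            first = entry.description.split()[0]
            if "|" in first and first.rsplit("|", 1)[1] in ("genomic", "cDNA"):
                rec_type = first.rsplit("|", 1)[1]
            key = (allele.raw, rec_type)
            if key in seen:
                logger.warning("skipping duplicate record %s", key)
                skipped += 1
                continue
            seen.add(key)
            records.append(ReferenceRecord(allele, seq, rec_type))
    if not records:
        raise EmptyReferenceError(f"no parseable records in {path}")
    return ReferenceDB(records, scope="custom", version_label=version_label, skipped=skipped)


def _allele_from_header(description: str) -> AlleleName | None:
    tokens = description.split()
    if not tokens:
        return None
    # IPD-IMGT/HLA layout: accession first, allele name second.
    candidates = [tokens[1], tokens[0]] if len(tokens) > 1 else [tokens[0]]
    for tok in candidates:
        # canonical headers from write_fasta carry a "|seq_type" tag
        tok = tok.split("|")[0]
        try:
            allele = parse_allele(tok)
        except InvalidAlleleError:
            continue
        if allele is not None:
            return allele
    return None


def combine(dbs: Sequence[ReferenceDB], version_label: str = "") -> ReferenceDB:
    """Pool several databases (e.g. genomic + cDNA) into one."""
    records = [rec for db in dbs for rec in db.records]
    if not records:
        raise EmptyReferenceError("no records to combine")
    label = version_label or next((db.version_label for db in dbs if db.version_label), "")
    return ReferenceDB(records, scope="custom", version_label=label,
                       skipped=sum(db.skipped for db in dbs))


def restrict_to_genes(db: ReferenceDB, genes: Iterable[str]) -> ReferenceDB:
    """Restrict a database to the given loci, preserving record order.

    When ``genes`` equals the nine classical loci the result is tagged
    with scope ``nine_hla``; otherwise ``custom``.  Raises
    :class:`EmptyReferenceError` if nothing survives.
    """
    wanted = {g.upper() for g in genes}
    if not wanted:
        raise ValueError("genes must be non-empty")
    records = [rec for rec in db.records if rec.allele.gene in wanted]
    if not records:
        raise EmptyReferenceError(f"no records for genes {sorted(wanted)}")
    scope = "nine_hla" if wanted == NINE_GENES else "custom"
    return ReferenceDB(records, scope=scope, version_label=db.version_label)


def as_all_hla(db: ReferenceDB) -> ReferenceDB:
    """Tag a pooled database as the unrestricted All-HLA reference."""
    return replace(db, scope="all_hla")


def write_fasta(db: ReferenceDB, path: str | Path) -> None:
    """Write a combined reference FASTA with ``>alleleName|seq_type`` headers."""
    path = Path(path)
    opener = gzip.open(path, "wt") if path.suffix == ".gz" else open(path, "w")
    with opener as out:
        for rec in db.records:
            out.write(f">{rec.allele.render()}|{rec.seq_type}\n")
            for i in range(0, len(rec.sequence), 60):
                out.write(rec.sequence[i : i + 60] + "\n")
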