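"""Parsers for the four HLA-typing tools' outputs and the generic call TSV.

The ensemble integrates calls from OptiType, Polysolver, ATHLATES and
seq2HLA, each with its own output dialect:

* **OptiType** — a result TSV with columns A1,A2,B1,B2,C1,C2 (class I
  only, no quality metric).
* **Polysolver** — a ``winners.hla.txt`` file with lines like
  ``HLA-A  hla_a_02_01_01  hla_a_03_01`` (underscore-coded alleles; no
  quality metric).
* **seq2HLA** — 4-digit genotype TSVs with per-allele confidence
  p-values; trailing apostrophes mark ambiguous calls.
* **ATHLATES** — a ``.typing.txt`` file whose inferred allelic pair
  carries a score; score 0 means a confidently resolved pair.

Every genotype is normalized to two-field resolution at this boundary.
Sequencing sources are coded N (normal exome), T (tumor exome), R
(tumor RNA-seq).  Class I loci (A, B, C) are typed by all four tools;
class II loci only by ATHLATES and seq2HLA; ATHLATES cannot process
RNA-seq, so ATHLATES×R cells are always failed.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import (
    InvalidAlleleError,
    RowError,
    SchemaError,
    UnsupportedToolError,
)
from .nomenclature import AlleleName, parse_allele, to_two_field
from .reference_db import CLASS_I_GENES, CLASS_II_GENES

logger = logging.getLogger(__name__)

TOOLS = ("ATHLATES", "OptiType", "Polysolver", "seq2HLA")
SOURCES = ("N", "T", "R")
FILTER_LEVELS = ("original", "all_hla", "nine_hla")

#: Tools able to type each HLA class.
CLASS_I_TOOLS = frozenset(TOOLS)
CLASS_II_TOOLS = frozenset({"ATHLATES", "seq2HLA"})

SEQ2HLA_P_THRESHOLD = 0.05


def normalize_tool(tag: str) -> str:
    for tool in TOOLS:
        if tag.lower() == tool.lower():
            return tool
    raise UnsupportedToolError(f"unknown tool tag {tag!r}; expected one of {TOOLS}")


def hla_class(gene: str) -> str:
    """HLA class ('I' or 'II') of a classical locus symbol."""
    gene = gene.upper()
    if gene in CLASS_I_GENES:
        return "I"
    if gene in CLASS_II_GENES:
        return "II"
    raise ValueError(f"{gene!r} is not a classical HLA locus")


def is_applicable(tool: str, source: str, gene: str) -> bool:
    """Whether a (tool, source) cell can produce a call for ``gene``.

    ATHLATES does not work for RNA-seq data; class II loci are typed
    only by ATHLATES and seq2HLA.
    """
    tool = normalize_tool(tool)
    if tool == "ATHLATES" and source == "R":
        return False
    cls = hla_class(gene)
    if cls == "II" and tool not in CLASS_II_TOOLS:
        return False
    return True


@dataclass(frozen=True)
class Genotype:
    """An unordered diploid pair of two-field alleles at one locus.

    ``alleles`` holds 0 (no call), 1 (partial call) or 2 alleles, kept
    sorted so that equality is order-insensitive; a homozygous genotype
    stores the same allele twice.
    """

    gene: str
    alleles: tuple[AlleleName, ...] = ()

    def __post_init__(self) -> None:
        if len(self.alleles) > 2:
            raise ValueError(f"at most 2 alleles per genotype, got {len(self.alleles)}")
        for a in self.alleles:
            if a.gene != self.gene.upper():
                raise ValueError(f"allele {a} does not belong to gene {self.gene}")
        object.__setattr__(self, "gene", self.gene.upper())
        object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))

    def __str__(self) -> str:
        return f"{self.gene}:[{', '.join(map(str, self.alleles)) or 'no call'}]"


@dataclass
class CallRecord:
    """One tool × source × filter-level genotype call for one locus."""

    patient_id: str
    tool: str
    source: str
    filter_level: str
    gene: str
    genotype: Genotype
    quality_value: float | None = None
    quality_class: str = "unavailable"  # confident | not_confident | unavailable
    status: str = "ok"  # ok | failed

    def __post_init__(self) -> None:
        self.tool = normalize_tool(self.tool)
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}, got {self.source!r}")
        if self.filter_level not in FILTER_LEVELS:
            raise ValueError(f"bad filter_level {self.filter_level!r}")
        self.gene = self.gene.upper()
        if self.status == "failed" and self.genotype.alleles:
            raise ValueError("a failed record must carry an empty genotype")
        if self.tool in ("OptiType", "Polysolver") and self.quality_class != "unavailable":
            raise ValueError(f"{self.tool} reports no quality metric")


def _two_field(allele: AlleleName) -> AlleleName:
    return to_two_field(allele)


def _failed_records(
    tool: str, patient_id: str, source: str, filter_level: str, genes: Iterable[str]
) -> list[CallRecord]:
    return [
        CallRecord(patient_id, tool, source, filter_level, g, Genotype(g), status="failed")
        for g in sorted(genes)
    ]


def _default_genes(tool: str) -> list[str]:
    if tool in CLASS_II_TOOLS:
        return sorted(CLASS_I_GENES | CLASS_II_GENES)
    return sorted(CLASS_I_GENES)


# ---------------------------------------------------------------------------
# per-tool dialect parsers


def _parse_optitype(path: Path) -> dict[str, list[AlleleName | None]]:
    """OptiType result TSV: one data row with A1,A2,B1,B2,C1,C2 columns."""
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        rows = list(reader)
    if not rows:
        return {}
    row = rows[0]
    calls: dict[str, list[AlleleName | None]] = {}
    for gene in sorted(CLASS_I_GENES):
        cols = [f"{gene}1", f"{gene}2"]
        if not any(c in row for c in cols):
            continue
        calls[gene] = [
            _safe_parse(row.get(c, ""), "generic") for c in cols
        ]
    return calls


_POLYSOLVER_LINE = re.compile(r"^HLA-(?P<gene>[A-Z0-9]+)\s+(?P<rest>.+)$", re.IGNORECASE)


def _decode_polysolver_allele(token: str) -> AlleleName | None:
    """``hla_a_02_01_01`` -> A*02:01:01 (trailing letter = expression suffix)."""
    parts = token.strip().lower().split("_")
    if len(parts) < 3 or parts[0] != "hla":
        return None
    gene = parts[1]
    fields = parts[2:]
    suffix = ""
    if fields and fields[-1] and fields[-1][-1].isalpha():
        suffix = fields[-1][-1]
        fields[-1] = fields[-1][:-1]
    text = f"{gene.upper()}*{':'.join(fields)}{suffix.upper()}"
    return _safe_parse(text, "generic")


def _parse_polysolver(path: Path) -> dict[str, list[AlleleName | None]]:
    calls: dict[str, list[AlleleName | None]] = {}
    with open(path) as fh:
        for line in fh:
            m = _POLYSOLVER_LINE.match(line.strip())
            if not m:
                continue
            gene = m.group("gene").upper()
            tokens = m.group("rest").split()
            alleles = [_decode_polysolver_allele(t) for t in tokens[:2]]
            calls[gene] = alleles
    return calls


def _parse_seq2hla(path: Path) -> dict[str, tuple[list[AlleleName | None], float | None]]:
    """seq2HLA 4-digit genotype TSV: Locus, Allele 1, Confidence, Allele 2, Confidence.

    The per-gene quality value is the worst (largest) of the two allele
    p-values present; ``NA`` confidences are ignored.
    """
    calls: dict[str, tuple[list[AlleleName | None], float | None]] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#") or row[0].lower() == "locus":
                continue
            gene = row[0].strip().upper()
            a1 = _safe_parse(row[1], "seq2hla") if len(row) > 1 else None
            p1 = _safe_float(row[2]) if len(row) > 2 else None
            a2 = _safe_parse(row[3], "seq2hla") if len(row) > 3 else None
            p2 = _safe_float(row[4]) if len(row) > 4 else None
            pvals = [p for p in (p1, p2) if p is not None]
            calls[gene] = ([a1, a2], max(pvals) if pvals else None)
    return calls


_ATHLATES_PAIR = re.compile(
    r"^(?P<a1>\S+\*\S+)\s+(?P<a2>\S+\*\S+)\s+(?P<score>-?\d+(?:\.\d+)?)\s*$"
)


def _parse_athlates(path: Path) -> dict[str, tuple[list[AlleleName | None], float | None]]:
    """ATHLATES ``.typing.txt``: take the first inferred allelic pair with its score."""
    calls: dict[str, tuple[list[AlleleName | None], float | None]] = {}
    in_pairs = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.lower().startswith("------------ inferred allelic pairs"):
                in_pairs = True
                continue
            if not in_pairs:
                continue
            m = _ATHLATES_PAIR.match(line)
            if not m:
                continue
            a1 = _safe_parse(m.group("a1"), "generic")
            a2 = _safe_parse(m.group("a2"), "generic")
            gene = (a1 or a2).gene if (a1 or a2) else None
            if gene is None or gene in calls:
                continue
            calls[gene] = ([a1, a2], float(m.group("score")))
    return calls


def _safe_parse(text: str, dialect: str) -> AlleleName | None:
    """Parse tolerantly: unparseable fields degrade to no-call."""
    try:
        return parse_allele(text, dialect=dialect)
    except InvalidAlleleError:
        logger.warning("unparseable allele field %r treated as no-call", text)
        return None


def _safe_float(text: str) -> float | None:
    try:
        return float(text)
    except (TypeError, ValueError):
        return None


def _genotype(gene: str, alleles: Sequence[AlleleName | None]) -> Genotype:
    kept = tuple(_two_field(a) for a in alleles if a is not None and a.gene == gene)
    return Genotype(gene, kept)


def ingest_tool_output(
    tool: str,
    path: str | Path,
    patient_id: str,
    source: str,
    filter_level: str,
    expected_genes: Sequence[str] | None = None,
) -> list[CallRecord]:
    """Parse one tool's output file into normalized :class:`CallRecord` s.

    One record is produced per gene found; genes expected of the tool
    but absent from the file (and any empty/missing file) yield
    ``status=failed`` records.  ATHLATES with source R always yields
    failed records, since ATHLATES cannot process RNA-seq data.
    """
    tool = normalize_tool(tool)
    path = Path(path)
    genes = list(expected_genes) if expected_genes is not None else _default_genes(tool)

    if tool == "ATHLATES" and source == "R":
        return _failed_records(tool, patient_id, source, filter_level, genes)
    if not path.exists() or path.stat().st_size == 0:
        return _failed_records(tool, patient_id, source, filter_level, genes)

    records: list[CallRecord] = []
    if tool == "OptiType":
        for gene, alleles in sorted(_parse_optitype(path).items()):
            records.append(
                CallRecord(patient_id, tool, source, filter_level, gene,
                           _genotype(gene, alleles))
            )
    elif tool == "Polysolver":
        for gene, alleles in sorted(_parse_polysolver(path).items()):
            records.append(
                CallRecord(patient_id, tool, source, filter_level, gene,
                           _genotype(gene, alleles))
            )
    elif tool == "seq2HLA":
        for gene, (alleles, pval) in sorted(_parse_seq2hla(path).items()):
            qclass = "unavailable"
            if pval is not None:
                qclass = "confident" if pval < SEQ2HLA_P_THRESHOLD else "not_confident"
            records.append(
                CallRecord(patient_id, tool, source, filter_level, gene,
                           _genotype(gene, alleles), quality_value=pval,
                           quality_class=qclass)
            )
    elif tool == "ATHLATES":
        for gene, (alleles, score) in sorted(_parse_athlates(path).items()):
            qclass = "unavailable"
            if score is not None:
                qclass = "confident" if score == 0 else "not_confident"
            records.append(
                CallRecord(patient_id, tool, source, filter_level, gene,
                           _genotype(gene, alleles), quality_value=score,
                           quality_class=qclass)
            )

    found = {r.gene for r in records}
    missing = [g for g in genes if g.upper() not in found]
    if missing:
        records.extend(_failed_records(tool, patient_id, source, filter_level, missing))
    records.sort(key=lambda r: r.gene)
    return records


# ---------------------------------------------------------------------------
# generic call TSV

GENERIC_COLUMNS = (
    "patient_id", "tool", "source", "filter_level", "gene",
    "allele1", "allele2", "quality_value", "status",
)


def read_generic_calls(path: str | Path) -> list[CallRecord]:
    """Read the canonical interchange TSV into :class:`CallRecord` s.

    Raises :class:`SchemaError` for a missing column and
    :class:`RowError` (with the 1-based line number) for an invalid row.
    """
    records: list[CallRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in GENERIC_COLUMNS:
            if col not in header:
                raise SchemaError(f"generic call TSV is missing column {col!r}")
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(_record_from_row(row))
            except (ValueError, InvalidAlleleError, UnsupportedToolError) as exc:
                raise RowError(lineno, str(exc)) from exc
    return records


def _record_from_row(row: dict) -> CallRecord:
    gene = row["gene"].upper()
    alleles = []
    for col in ("allele1", "allele2"):
        text = (row.get(col) or "").strip()
        allele = parse_allele(text) if text else None
        if allele is not None:
            alleles.append(_two_field(allele))
    qtext = (row.get("quality_value") or "").strip()
    qval = float(qtext) if qtext else None
    status = (row.get("status") or "ok").strip() or "ok"
    if status == "failed":
        alleles = []
    tool = normalize_tool(row["tool"])
    qclass = "unavailable"
    if qval is not None:
        if tool == "ATHLATES":
            qclass = "confident" if qval == 0 else "not_confident"
        elif tool == "seq2HLA":
            qclass = "confident" if qval < SEQ2HLA_P_THRESHOLD else "not_confident"
    return CallRecord(
        patient_id=row["patient_id"],
        tool=tool,
        source=row["source"],
        filter_level=row["filter_level"],
        gene=gene,
        genotype=Genotype(gene, tuple(alleles)),
        quality_value=qval,
        quality_class=qclass,
        status=status,
    )


def write_generic_calls(records: Iterable[CallRecord], path: str | Path) -> None:
    """Write records as the canonical interchange TSV (lossless round-trip)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(GENERIC_COLUMNS)
        for rec in records:
            alleles = [a.render() for a in rec.genotype.alleles]
            alleles += [""] * (2 - len(alleles))
            qval = "" if rec.quality_value is None else repr(rec.quality_value)
            writer.writerow(
                [rec.patient_id, rec.tool, rec.source, rec.filter_level, rec.gene,
                 alleles[0], alleles[1], qval, rec.status]
            )
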