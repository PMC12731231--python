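"""Patient × gene call matrix and unanimous/consensus/ambiguous calling.

Each patient × gene locus receives up to one genotype call per
(tool, sequencing source) cell at each filter level.  With four tools
and three sources (normal exome N, tumor exome T, tumor RNA-seq R) a
class I gene has 11 possible call slots per allele (12 minus the
ATHLATES×R cell, which always fails); a class II gene, typed only by
ATHLATES and seq2HLA, has 5.

For each allele slot the votes across applicable cells are tallied:

* **unanimous** — every applicable cell produced the same allele
  (support = total = expected); the highest-confidence outcome.
* **consensus** — a unique most-frequent (modal) allele exists, but
  support or total falls short of the expected count.
* **ambiguous** — two or more alleles tie for maximal support.
* **no_call** — no cell produced an allele for the slot.

Heterozygous genotypes are split into two slots by sorted order of the
two-field alleles (slot 1 ≤ slot 2); homozygous genotypes fill both
slots with the same allele.  Votes carry equal weight across tools and
sources.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .call_ingest import (
    CallRecord,
    SOURCES,
    TOOLS,
    hla_class,
    is_applicable,
)
from .errors import LookupError_
from .nomenclature import AlleleName

logger = logging.getLogger(__name__)

OUTCOMES = ("unanimous", "consensus", "ambiguous", "no_call")


@dataclass(frozen=True)
class Cell:
    """One (tool, source, filter-level) genotype call inside the matrix."""

    genotype_alleles: tuple[AlleleName, ...]
    status: str
    quality_class: str = "unavailable"
    quality_value: float | None = None

    def slot_allele(self, slot: int) -> AlleleName | None:
        """Allele occupying slot 1 or 2 (sorted order; homozygous fills both)."""
        alleles = self.genotype_alleles
        if self.status != "ok" or not alleles:
            return None
        if len(alleles) == 1:
            # partial call occupies slot 1 only
            return alleles[0] if slot == 1 else None
        return alleles[slot - 1]


@dataclass
class CallMatrix:
    """All calls indexed by (patient, gene) then (tool, source, level)."""

    cells: dict[tuple[str, str], dict[tuple[str, str, str], Cell]] = field(
        default_factory=dict
    )
    tools: set[str] = field(default_factory=set)
    sources: set[str] = field(default_factory=set)

    def patients(self) -> list[str]:
        return sorted({p for p, _ in self.cells})

    def genes(self) -> list[str]:
        return sorted({g for _, g in self.cells})

    def cell(
        self, patient_id: str, gene: str, tool: str, source: str, level: str
    ) -> Cell | None:
        return self.cells.get((patient_id, gene), {}).get((tool, source, level))

    def levels(self) -> set[str]:
        return {key[2] for group in self.cells.values() for key in group}


@dataclass(frozen=True)
class ConsensusResult:
    patient_id: str
    gene: str
    slot: int
    outcome: str
    allele: AlleleName | None
    support: int
    total: int
    expected: int


def build_call_matrix(records: Iterable[CallRecord]) -> CallMatrix:
    """Index call records into a :class:`CallMatrix`.

    Duplicate (patient, gene, tool, source, level) cells are resolved
    last-write-wins with a logged warning.  Failed records occupy their
    cell with an empty genotype so they contribute no-calls.
    """
    matrix = CallMatrix()
    for rec in records:
        group = matrix.cells.setdefault((rec.patient_id, rec.gene), {})
        key = (rec.tool, rec.source, rec.filter_level)
        if key in group:
            logger.warning(
                "duplicate call cell %s for patient %s gene %s; keeping last",
                key, rec.patient_id, rec.gene,
            )
        group[key] = Cell(
            genotype_alleles=rec.genotype.alleles,
            status=rec.status,
            quality_class=rec.quality_class,
            quality_value=rec.quality_value,
        )
        matrix.tools.add(rec.tool)
        matrix.sources.add(rec.source)
    return matrix


def expected_slot_count(
    hla_class: str,
    tools: Iterable[str] = TOOLS,
    sources: Iterable[str] = SOURCES,
) -> int:
    """Number of (tool, source) cells able to call a gene of ``hla_class``.

    With all four tools and all three sources this is 11 for class I
    (ATHLATES cannot process RNA-seq) and 5 for class II (typed only by
    ATHLATES and seq2HLA).
    """
    if hla_class not in ("I", "II"):
        raise ValueError(f"hla_class must be 'I' or 'II', got {hla_class!r}")
    probe_gene = "A" if hla_class == "I" else "DRB1"
    return sum(
        1
        for tool in set(tools)
        for source in set(sources)
        if is_applicable(tool, source, probe_gene)
    )


def consensus_for_slot(
    matrix: CallMatrix,
    patient_id: str,
    gene: str,
    slot: int,
    filter_level: str = "original",
    min_support_fraction: float = 0.0,
) -> ConsensusResult:
    """Tally votes for one allele slot and classify the outcome.

    ``min_support_fraction`` optionally demands modal support of at
    least that fraction of the total votes for a consensus call (the
    default 0 accepts any unique modal allele; ties are always
    ambiguous).  No-calls and failed cells reduce the total but never
    create ambiguity by themselves.
    """
    if (patient_id, gene) not in matrix.cells:
        raise LookupError_(f"no calls for patient {patient_id!r} gene {gene!r}")
    if slot not in (1, 2):
        raise ValueError("slot must be 1 or 2")
    group = matrix.cells[(patient_id, gene)]

    votes: dict[AlleleName, int] = {}
    total = 0
    for (tool, source, level), cell in group.items():
        if level != filter_level or not is_applicable(tool, source, gene):
            continue
        allele = cell.slot_allele(slot)
        if allele is None:
            continue
        total += 1
        votes[allele] = votes.get(allele, 0) + 1

    expected = expected_slot_count(hla_class(gene), matrix.tools or TOOLS,
                                   matrix.sources or SOURCES)

    if total == 0:
        return ConsensusResult(patient_id, gene, slot, "no_call", None, 0, 0, expected)

    top_support = max(votes.values())
    modal = sorted(a for a, n in votes.items() if n == top_support)
    if len(modal) > 1:
        return ConsensusResult(
            patient_id, gene, slot, "ambiguous", None, top_support, total, expected
        )
    allele = modal[0]
    if top_support < min_support_fraction * total:
        return ConsensusResult(
            patient_id, gene, slot, "ambiguous", None, top_support, total, expected
        )
    if top_support == total == expected and len(votes) == 1:
        outcome = "unanimous"
    else:
        outcome = "consensus"
    return ConsensusResult(patient_id, gene, slot, outcome, allele, top_support,
                           total, expected)


def consensus_table(
    matrix: CallMatrix,
    filter_level: str = "original",
    min_support_fraction: float = 0.0,
) -> Iterator[ConsensusResult]:
    """Consensus results for every (patient, gene, slot) in the matrix."""
    for patient_id, gene in sorted(matrix.cells):
        for slot in (1, 2):
            yield consensus_for_slot(
                matrix, patient_id, gene, slot, filter_level, min_support_fraction
            )
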