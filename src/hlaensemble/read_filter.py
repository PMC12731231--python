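"""HLA region-specific read-pair selection with single-end mate rescue.

Paired-end FASTQ reads are tested for membership in the HLA region by
shared k-mers with a reference database (both strands).  A pair is kept
when at least one mate matches; when only one mate matches, the other
is *rescued* so the output stays strictly paired — the behaviour a
downstream HLA typer needs.  k-mer containment (default k=21,
min_shared=1) is a deliberately permissive superset filter: it retains
every read that could align to a known allele, including multimappers.
An external aligner can stand in for the k-mer test via
:func:`matched_names_from_sam`.

Read-reduction bookkeeping distinguishes the *remaining* percentage
(reads kept, relative to input) from the *reduction* percentage
(100 − remaining); the two are easy to conflate when the remaining
fraction is small.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pysam

from .errors import PairingError, UndefinedMetricError, UnusableIndexError
from .reference_db import ReferenceDB

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class FilterSummary:
    """Bookkeeping for one paired-end filtering run."""

    input_pairs: int = 0
    both_matched: int = 0
    r1_only: int = 0
    r2_only: int = 0

    @property
    def rescued_mates(self) -> int:
        return self.r1_only + self.r2_only

    @property
    def output_pairs(self) -> int:
        return self.both_matched + self.r1_only + self.r2_only

    @property
    def remaining_percent(self) -> float:
        if self.input_pairs == 0:
            return 0.0
        return 100.0 * self.output_pairs / self.input_pairs

    @property
    def reduction_percent(self) -> float:
        return 100.0 - self.remaining_percent

    def as_dict(self) -> dict:
        return {
            "input_pairs": self.input_pairs,
            "both_matched": self.both_matched,
            "r1_only": self.r1_only,
            "r2_only": self.r2_only,
            "rescued_mates": self.rescued_mates,
            "output_pairs": self.output_pairs,
            "remaining_percent": self.remaining_percent,
            "reduction_percent": self.reduction_percent,
        }


class KmerIndex:
    """Shared-k-mer membership index over a reference sequence set.

    Holds every k-mer of every reference sequence and of its reverse
    complement, so queries need only enumerate the read's forward
    k-mers.
    """

    def __init__(self, sequences: Iterable[str], k: int = 21):
        if k < 8:
            raise ValueError(f"k must be >= 8, got {k}")
        self.k = k
        self._kmers: set[str] = set()
        usable = 0
        for seq in sequences:
            seq = seq.upper()
            if len(seq) < k:
                continue
            usable += 1
            for strand in (seq, reverse_complement(seq)):
                for i in range(len(strand) - k + 1):
                    self._kmers.add(strand[i : i + k])
        if usable == 0:
            raise UnusableIndexError(f"no reference sequence of length >= k={k}")

    @classmethod
    def from_db(cls, db: ReferenceDB, k: int = 21) -> "KmerIndex":
        return cls((rec.sequence for rec in db.records), k=k)

    def __len__(self) -> int:
        return len(self._kmers)

    def shared_kmers(self, read: str) -> int:
        read = read.upper()
        k = self.k
        if len(read) < k:
            return 0
        return sum(1 for i in range(len(read) - k + 1) if read[i : i + k] in self._kmers)


def read_matches(read: str, index: KmerIndex, min_shared: int = 1) -> bool:
    """True iff the read shares >= ``min_shared`` k-mers with the index.

    Reads shorter than k cannot match and return False.
    """
    if min_shared < 1:
        raise ValueError("min_shared must be >= 1")
    if len(read) < index.k:
        logger.debug("read shorter than k=%d cannot match", index.k)
        return False
    # early exit once the threshold is reached
    read = read.upper()
    k = index.k
    hits = 0
    for i in range(len(read) - k + 1):
        if read[i : i + k] in index._kmers:
            hits += 1
            if hits >= min_shared:
                return True
    return False


# ---------------------------------------------------------------------------
# FASTQ pair streaming


@dataclass(frozen=True)
class FastqRecord:
    name: str
    sequence: str
    quality: str
    comment: str = ""

    def render(self) -> str:
        header = f"@{self.name}"
        if self.comment:
            header += f" {self.comment}"
        return f"{header}\n{self.sequence}\n+\n{self.quality}\n"


def _canonical_name(name: str) -> str:
    # mate suffixes /1 /2 do not distinguish pairs
    if len(name) > 2 and name[-2] == "/" and name[-1] in "12":
        return name[:-2]
    return name


def read_fastq(path: str | Path) -> Iterator[FastqRecord]:
    """Stream FASTQ records (plain or gzip) preserving name/seq/qual."""
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield FastqRecord(
                name=entry.name,
                sequence=entry.sequence,
                quality=entry.quality or "",
                comment=entry.comment or "",
            )


def iter_pairs(
    r1: Iterable[FastqRecord], r2: Iterable[FastqRecord]
) -> Iterator[tuple[FastqRecord, FastqRecord]]:
    """Zip two mate streams, enforcing equal length and name agreement."""
    it1, it2 = iter(r1), iter(r2)
    idx = 0
    while True:
        a = next(it1, None)
        b = next(it2, None)
        if a is None and b is None:
            return
        if a is None or b is None:
            raise PairingError(f"unequal record counts: stream ended at pair index {idx}")
        if _canonical_name(a.name) != _canonical_name(b.name):
            raise PairingError(
                f"read-name mismatch at pair index {idx}: {a.name!r} vs {b.name!r}"
            )
        yield a, b
        idx += 1


def filter_pair_stream(
    pairs: Iterable[tuple[FastqRecord, FastqRecord]],
    matches,
    summary: FilterSummary | None = None,
) -> Iterator[tuple[FastqRecord, FastqRecord]]:
    """Core filter: emit each pair where >= 1 mate satisfies ``matches``.

    ``matches`` is a predicate on the read sequence (or on the record —
    only ``.sequence`` is consulted).  Records pass through verbatim;
    the non-matching mate of a half-matching pair is rescued so output
    stays strictly paired.  Statistics accumulate into ``summary``.
    """
    if summary is None:
        summary = FilterSummary()
    for a, b in pairs:
        summary.input_pairs += 1
        ma = matches(a.sequence)
        mb = matches(b.sequence)
        if ma and mb:
            summary.both_matched += 1
        elif ma:
            summary.r1_only += 1
        elif mb:
            summary.r2_only += 1
        else:
            continue
        yield a, b


def filter_pairs(
    r1_path: str | Path,
    r2_path: str | Path,
    index: KmerIndex,
    out_r1: str | Path,
    out_r2: str | Path,
    min_shared: int = 1,
    matched_names: set[str] | None = None,
) -> FilterSummary:
    """Filter paired FASTQ files against a reference index.

    A pair is written iff at least one mate matches the index (or, when
    ``matched_names`` is given, iff either mate's canonical read name is
    in that set — the external-aligner mode).  Output order is input
    order; records are emitted byte-identical in name, sequence and
    quality.  Returns the :class:`FilterSummary`.
    """
    if matched_names is not None:
        names = {_canonical_name(n) for n in matched_names}

        def record_matches(rec: FastqRecord) -> bool:
            return _canonical_name(rec.name) in names

    else:

        def record_matches(rec: FastqRecord) -> bool:
            return read_matches(rec.sequence, index, min_shared=min_shared)

    summary = FilterSummary()
    pairs = iter_pairs(read_fastq(r1_path), read_fastq(r2_path))
    with _open_out(out_r1) as o1, _open_out(out_r2) as o2:
        for a, b in pairs:
            summary.input_pairs += 1
            ma = record_matches(a)
            mb = record_matches(b)
            if ma and mb:
                summary.both_matched += 1
            elif ma:
                summary.r1_only += 1
            elif mb:
                summary.r2_only += 1
            else:
                continue
            o1.write(a.render())
            o2.write(b.render())
    logger.info(
        "filtered %d pairs -> %d kept (%.2f%% remaining, %d mates rescued)",
        summary.input_pairs,
        summary.output_pairs,
        summary.remaining_percent,
        summary.rescued_mates,
    )
    return summary


def _open_out(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "wt")
    return open(path, "w")


def matched_names_from_sam(sam_path: str | Path) -> set[str]:
    """Collect query names with >= 1 non-unmapped alignment from a SAM file.

    Supports plugging an external aligner into :func:`filter_pairs`
    (``matched_names=``): align the reads to the reference database,
    then treat any read with a mapped record as matching.  Secondary
    and supplementary alignments count, so multimapping reads are
    retained.
    """
    names: set[str] = set()
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for aln in sam:
            if not aln.is_unmapped:
                names.add(_canonical_name(aln.query_name))
    return names


def summarize_reduction(before: int, after: int) -> tuple[float, float]:
    """Return ``(remaining_percent, reduction_percent)`` for a read count drop.

    ``remaining = 100 * after / before``; ``reduction = 100 - remaining``.
    Raises :class:`UndefinedMetricError` when ``before`` is zero.
    """
    if before == 0:
        raise UndefinedMetricError("percentage undefined for zero input reads")
    if not before >= after >= 0:
        raise ValueError(f"need before >= after >= 0, got {before}, {after}")
    remaining = 100.0 * after / before
    return remaining, 100.0 - remaining
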