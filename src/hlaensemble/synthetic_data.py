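"""Fully labeled synthetic inputs for end-to-end testing without downloads.

Real cohort sequencing data of the kind this pipeline consumes is
patient-identifiable and not publicly distributable, so every other
module is exercised against simulations with known truth:

* an HLA-like reference — per-gene random ancestor sequences, each
  allele an ancestor copy with a fixed number of point substitutions,
  named with synthetic two-field names (``A*01:01``, ``A*01:02`` ...);
* a diploid cohort — per patient and gene, a uniformly drawn unordered
  allele pair;
* paired-end reads — uniform fragment starts on each truth haplotype
  plus background pairs of random sequence (guaranteed not to share a
  k-mer with the reference), with per-base substitution errors;
* simulated tool call tables — for each applicable (tool, source) cell
  the truth allele with probability 1−ε per slot, otherwise a uniformly
  chosen different allele of the same gene, with quality values drawn
  consistently with each tool's confident-call rule, and ATHLATES×R
  cells emitted as failed.

Everything is driven by one integer seed; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .call_ingest import (
    CallRecord,
    Genotype,
    SOURCES,
    TOOLS,
    is_applicable,
)
from .errors import ConfigurationError
from .nomenclature import AlleleName
from .read_filter import FastqRecord, KmerIndex, reverse_complement
from .reference_db import ReferenceDB, ReferenceRecord

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Locus symbols assigned to simulated genes, class I first.
_GENE_ORDER = ("A", "B", "C", "DRB1", "DQB1", "DPB1", "DQA1", "DPA1", "DRA")


@dataclass
class SimConfig:
    """Study-condition knobs for the simulator.

    Defaults describe a small but realistic desk-scale cohort: 24
    patients (a typical tumor-sequencing cohort size), five loci (three
    class I, two class II), six alleles per locus diverged from a
    common ancestor by 15 substitutions over 1 kb, 2×100 bp reads at a
    300±30 bp insert with a 0.1% per-base error rate, and a 5% per-slot
    call error rate for the simulated typing tools.
    """

    n_genes: int = 5
    alleles_per_gene: int = 6
    allele_length: int = 1000
    mutations_per_allele: int = 15
    n_patients: int = 24
    read_length: int = 100
    mean_insert: int = 300
    insert_sd: float = 30.0
    base_error_rate: float = 0.001
    pairs_per_haplotype: int = 5
    background_pairs: int = 200
    call_error_rate: float = 0.05
    kmer_k: int = 21
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_genes <= len(_GENE_ORDER):
            raise ConfigurationError(f"n_genes must be in 1..{len(_GENE_ORDER)}")
        if self.mutations_per_allele >= self.allele_length:
            raise ConfigurationError("mutations_per_allele must be < allele_length")
        if self.read_length > self.allele_length:
            raise ConfigurationError("read_length must be <= allele_length")
        if self.mean_insert < self.read_length:
            raise ConfigurationError("mean_insert must be >= read_length")
        if not 0.0 <= self.call_error_rate <= 1.0:
            raise ConfigurationError("call_error_rate must be in [0, 1]")
        if self.call_error_rate > 0 and self.alleles_per_gene < 2:
            raise ConfigurationError(
                "call errors need >= 2 alleles per gene to draw a wrong allele"
            )
        for name in ("alleles_per_gene", "n_patients", "pairs_per_haplotype",
                     "background_pairs"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    @property
    def genes(self) -> tuple[str, ...]:
        return _GENE_ORDER[: self.n_genes]


@dataclass
class SimTruth:
    """Ground-truth labels accompanying a simulated cohort."""

    genotypes: dict[str, dict[str, Genotype]] = field(default_factory=dict)
    read_origins: dict[str, str] = field(default_factory=dict)
    allele_pool: dict[str, list[AlleleName]] = field(default_factory=dict)

    def patients(self) -> list[str]:
        return sorted(self.genotypes)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, n_mut: int) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    positions = rng.choice(len(arr), size=n_mut, replace=False)
    for pos in positions:
        current = arr[pos]
        choices = _BASES[_BASES != current]
        arr[pos] = rng.choice(choices)
    return arr.tobytes().decode()


def _add_read_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    mask = rng.random(len(arr)) < rate
    for pos in np.nonzero(mask)[0]:
        choices = _BASES[_BASES != arr[pos]]
        arr[pos] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_reference(cfg: SimConfig) -> tuple[ReferenceDB, dict[str, str]]:
    """Generate the HLA-like reference set and its per-gene ancestors.

    Each gene's ancestor is an independent uniform-random sequence; each
    allele differs from the ancestor at ``mutations_per_allele`` distinct
    positions.  Allele ``i`` of a gene is named ``GENE*01:0i``.
    """
    rng = np.random.default_rng(cfg.seed)
    ancestors: dict[str, str] = {}
    records: list[ReferenceRecord] = []
    for gene in cfg.genes:
        ancestor = _random_seq(rng, cfg.allele_length)
        ancestors[gene] = ancestor
        for i in range(cfg.alleles_per_gene):
            name = AlleleName(gene=gene, fields=("01", f"{i + 1:02d}"),
                              raw=f"{gene}*01:{i + 1:02d}")
            seq = _mutate(rng, ancestor, cfg.mutations_per_allele)
            records.append(ReferenceRecord(name, seq, "genomic"))
    db = ReferenceDB(records, scope="custom", version_label="synthetic")
    return db, ancestors


def simulate_cohort_reads(
    db: ReferenceDB, cfg: SimConfig
) -> tuple[list[FastqRecord], list[FastqRecord], SimTruth]:
    """Simulate a diploid cohort and its paired-end reads.

    Per patient and gene a genotype is drawn uniformly (with
    replacement, so homozygotes occur); ``pairs_per_haplotype`` read
    pairs are drawn per haplotype allele from uniform fragment starts.
    Background pairs come from random sequence and are rejected (and
    redrawn) if either mate shares a k-mer with the reference, so the
    truth labels are exact.  Read origins are encoded in read names as
    ``...|origin=<allele or background>``.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    by_gene: dict[str, list[ReferenceRecord]] = {}
    for rec in db.records:
        by_gene.setdefault(rec.allele.gene, []).append(rec)

    truth = SimTruth()
    truth.allele_pool = {
        gene: [rec.allele for rec in recs] for gene, recs in by_gene.items()
    }
    r1: list[FastqRecord] = []
    r2: list[FastqRecord] = []
    serial = 0

    def emit_pair(fragment: str, origin: str, patient: str) -> None:
        nonlocal serial
        fwd = fragment[: cfg.read_length]
        rev = reverse_complement(fragment[-cfg.read_length :])
        fwd = _add_read_errors(rng, fwd, cfg.base_error_rate)
        rev = _add_read_errors(rng, rev, cfg.base_error_rate)
        name = f"sim:{patient}:{serial}|origin={origin}"
        qual = "I" * cfg.read_length
        r1.append(FastqRecord(name=name, sequence=fwd, quality=qual))
        r2.append(FastqRecord(name=name, sequence=rev, quality=qual))
        truth.read_origins[name] = origin
        serial += 1

    def draw_fragment_len(limit: int) -> int:
        length = int(round(rng.normal(cfg.mean_insert, cfg.insert_sd)))
        return max(cfg.read_length, min(length, limit))

    for p in range(cfg.n_patients):
        patient = f"P{p + 1:03d}"
        truth.genotypes[patient] = {}
        for gene in cfg.genes:
            recs = by_gene[gene]
            picks = rng.integers(0, len(recs), size=2)
            alleles = tuple(recs[i].allele for i in picks)
            truth.genotypes[patient][gene] = Genotype(gene, alleles)
            for i in picks:
                rec = recs[i]
                for _ in range(cfg.pairs_per_haplotype):
                    frag_len = draw_fragment_len(len(rec.sequence))
                    start = int(rng.integers(0, len(rec.sequence) - frag_len + 1))
                    fragment = rec.sequence[start : start + frag_len]
                    emit_pair(fragment, rec.allele.render(), patient)

    if cfg.background_pairs:
        index = KmerIndex.from_db(db, k=cfg.kmer_k)
        made = 0
        while made < cfg.background_pairs:
            fragment = _random_seq(rng, max(cfg.mean_insert, cfg.read_length))
            fwd = fragment[: cfg.read_length]
            rev = reverse_complement(fragment[-cfg.read_length :])
            if index.shared_kmers(fwd) or index.shared_kmers(rev):
                continue  # reject any accidental reference k-mer collision
            emit_pair(fragment, "background", "background")
            made += 1

    return r1, r2, truth


def simulate_call_tables(
    truth: SimTruth, cfg: SimConfig, filter_level: str = "original"
) -> list[CallRecord]:
    """Simulate the four tools' call tables against a known truth.

    For each applicable (tool, source) cell and gene, each of the two
    genotype slots reports the truth allele with probability
    1−``call_error_rate`` and otherwise a uniformly chosen different
    allele of the same gene.  ATHLATES×R cells are emitted with
    ``status=failed``.  ATHLATES scores and seq2HLA p-values are drawn
    so that their confident-call rules (score == 0; p < 0.05) hold for
    most ok records.
    """
    if not truth.genotypes:
        raise ConfigurationError("empty truth: simulate a cohort first")
    rng = np.random.default_rng(cfg.seed + 2)
    eps = cfg.call_error_rate
    records: list[CallRecord] = []
    for patient in truth.patients():
        for gene, genotype in sorted(truth.genotypes[patient].items()):
            pool = truth.allele_pool[gene]
            for tool in TOOLS:
                for source in SOURCES:
                    if tool == "ATHLATES" and source == "R":
                        records.append(
                            CallRecord(patient, tool, source, filter_level, gene,
                                       Genotype(gene), status="failed")
                        )
                        continue
                    if not is_applicable(tool, source, gene):
                        continue
                    called = []
                    for allele in genotype.alleles:
                        if eps > 0 and rng.random() < eps:
                            wrong = [a for a in pool if a != allele]
                            allele = wrong[int(rng.integers(0, len(wrong)))]
                        called.append(allele)
                    qval: float | None = None
                    qclass = "unavailable"
                    if tool == "ATHLATES":
                        qval = 0.0 if rng.random() < 0.9 else float(rng.integers(1, 6))
                        qclass = "confident" if qval == 0 else "not_confident"
                    elif tool == "seq2HLA":
                        if rng.random() < 0.9:
                            qval = float(rng.uniform(0.0, 0.049))
                        else:
                            qval = float(rng.uniform(0.05, 1.0))
                        qclass = "confident" if qval < 0.05 else "not_confident"
                    records.append(
                        CallRecord(patient, tool, source, filter_level, gene,
                                   Genotype(gene, tuple(called)),
                                   quality_value=qval, quality_class=qclass)
                    )
    return records


def write_fastq(records: Iterable[FastqRecord], path: str | Path) -> None:
    with open(path, "w") as out:
        for rec in records:
            out.write(rec.render())


def write_truth_tsv(truth: SimTruth, path: str | Path) -> None:
    """Write per-patient truth genotypes as a TSV (patient, gene, allele1, allele2)."""
    with open(path, "w") as out:
        out.write("patient_id\tgene\tallele1\tallele2\n")
        for patient in truth.patients():
            for gene, genotype in sorted(truth.genotypes[patient].items()):
                alleles = [a.render() for a in genotype.alleles]
                alleles += [""] * (2 - len(alleles))
                out.write(f"{patient}\t{gene}\t{alleles[0]}\t{alleles[1]}\n")
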