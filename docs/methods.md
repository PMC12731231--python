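# Methods

## Allele nomenclature

Allele names follow the colon-delimited WHO nomenclature
(`GENE*f1:f2[:f3[:f4]][suffix]`). Names are reduced to two fields
(protein-level resolution) at every ingestion boundary, because that is
the resolution at which typing tools are comparable and at which
downstream peptide-based applications operate. Two normalization
decisions are deliberate:

* **Expression suffixes survive reduction and participate in equality**
  (`C*04:09N ≠ C*04:09`). A null or low-expression allele is
  functionally distinct even when its protein fields match, so merging
  them would overstate agreement.
* **Field codes compare numerically** (`A*2:1 == A*02:01`); tools differ
  in zero-padding and a textual comparison would manufacture
  discordance. Rendering preserves the padding seen on input.

One-field names are accepted (some tools emit them on low coverage) but
flagged as under-resolved; they participate in voting like any other
allele value.

## Reference databases

IPD-IMGT/HLA-style genomic and cDNA FASTA files are parsed with
Biopython; the allele name is taken from the second header token
(`HLA:HLA00001 A*01:01:01:01 3503 bp`) with fallback to the first.
Genomic and cDNA records are pooled into one database, since a read may
align to either representation; the pooled set is used unrestricted
(All-HLA) or restricted to the nine classical loci (9-HLA). Sequences
are uppercased; records with characters outside A/C/G/T/N or with
unparseable headers are skipped and counted rather than aborting the
build, because reference releases occasionally contain oddities and a
filter reference is useful even when a handful of records drop out.

## Read filtering with mate rescue

The filter's contract is deliberately permissive: *retain every read
pair that could align to a known HLA allele*, including multimappers —
false positives only cost downstream CPU time, while false negatives
lose genotype evidence. Matching is shared-k-mer containment: the index
holds all k-mers of every reference sequence and its reverse complement
(default k = 21, min_shared = 1), and a read matches when any of its
k-mers is present. k = 21 makes a chance hit against a ~25 Mb two-strand
reference vanishingly rare (4^21 ≈ 4×10^12) while tolerating one
substitution or sequencing error every ~20 bp; min_shared = 1 keeps the
filter a superset of what any aligner would map. An external aligner can
replace the k-mer test (`--aligner-cmd`, SAM on stdout); any
non-unmapped record then counts as a match, so secondary alignments of
multimapping reads are retained.

Mate rescue is performed in a single pass over the two synchronized
FASTQ streams: a pair is emitted when at least one mate matches, so the
unmatched mate is "rescued" by construction and the output remains
strictly paired, in input order, with records byte-identical to input.
This is equivalent to the extract-then-rescue sequence of aligner +
collation tools but cannot desynchronize the mates.

Read-reduction bookkeeping reports both the **remaining** percentage
(100·kept/input) and the **reduction** percentage (100 − remaining)
explicitly, because small remaining fractions are easily misquoted as
reductions.

## Call ingestion and applicability

Each tool's dialect is parsed tolerantly — an unparseable allele field
degrades to a partial or no-call rather than aborting the ensemble,
since one bad field should not discard ten good calls. The dialects:
OptiType result TSV (columns A1..C2, no quality metric), Polysolver
winners file (underscore-coded alleles, `hla_a_02_01` → `A*02:01`;
homozygous output maps to multiplicity 2), seq2HLA four-digit genotype
tables (per-allele p-values; the per-gene quality value is the worst of
the two; trailing ambiguity apostrophes stripped), and ATHLATES typing
files (inferred allelic pair with a score). A canonical TSV
(`patient_id, tool, source, filter_level, gene, allele1, allele2,
quality_value, status`) is the lossless interchange format between
stages.

The applicability map encodes which (tool, source) cells can produce a
call: ATHLATES fails on RNA-seq (always ingested as `status=failed`),
and class II loci are typed only by ATHLATES and seq2HLA. Hence a class
I gene has 11 possible call slots per allele (4 tools × 3 sources − 1)
and a class II gene 5 (2 + 3).

Quality metrics are reduced to a binary classification at ingest:
ATHLATES confident iff score == 0, seq2HLA confident iff p < 0.05,
OptiType/Polysolver unavailable. Retention statistics compare this
binary class rather than raw values, because the raw scores of the two
tools live on incomparable scales; the operationalization is flagged in
the API documentation.

## Consensus calling

Within one filter level, each (patient, gene, allele-slot) tallies one
equal-weight vote per applicable (tool, source) cell. Genotypes are
split into two slots by sorted order of the two-field alleles (slot 1 ≤
slot 2; homozygotes fill both slots). Sorted slotting is deterministic
and symmetric across tools; the alternative — bipartite matching of
each cell's pair against the emerging consensus — was considered and
not adopted as default because it makes the outcome depend on tally
order. Outcomes: *unanimous* when support = total = expected (expected
being the applicability count over the tools and sources present in the
matrix), *consensus* for a unique modal allele otherwise, *ambiguous*
on a tie, *no_call* with zero votes. Failed runs and no-calls shrink
the total but never create ambiguity. An optional
`min_support_fraction` threshold (default 0) demands modal support ≥
that fraction of total votes before accepting a consensus; it is
exposed as a parameter because no single threshold suits every cohort.
Consensus is computed within one filter level at a time; pooling votes
across filter levels would double-count the same underlying reads.

## Metrics

Concordance counts agreement per allele via the maximum multiset
intersection of the two genotypes (0–2 per cell pair), accumulated into
overall / per-patient / per-gene / per-tool groups; cells missing or
failed on either side are excluded from numerator and denominator, and
groups with an empty denominator are reported as undefined rather than
dropped. Note the monotonicity caveat: removing a *fully* discordant
cell (zero matching alleles) can only raise a group's percentage, but
removing a partially matching cell can lower it — the property tests
cover the former.

The diversity ratio for a tool is Σ distinct alleles / number of
(patient, gene, slot) cells with ≥ 1 call, over the tool's applicable
sources. The per-slot denominator is chosen (rather than per patient or
per gene) because it is the only definition under which the ideal value
1 is attainable for heterozygous patients.

## Synthetic data

The simulator emulates the structure the pipeline needs, not HLA
biology: per-gene ancestors are uniform random sequences (default 1 kb)
and alleles differ from their ancestor at a fixed number of positions
(default 15), giving within-gene identity ≈ 97% — enough for reads to
discriminate genes but not so little that alleles collapse. Defaults
describe a desk-scale cohort: 24 patients, 5 loci (A, B, C, DRB1,
DQB1), 6 alleles per locus, 2×100 bp reads at 300±30 bp inserts, 0.1%
per-base error, 5 pairs per haplotype per locus, 200 background pairs,
and a 5% per-slot call error rate with independent errors across cells
(no tool-correlated error model, as no empirical error structure is
available to fit one). Background pairs are random sequence, re-drawn
on any accidental shared k-mer with the reference, so truth labels are
exact. All randomness flows from a single integer seed (stage-specific
child seeds: seed, seed+1, seed+2); identical seeds give byte-identical
FASTA/FASTQ/TSV outputs.

What passing tests on these simulations do **not** show: performance on
real HLA polymorphism (paralogous loci with much higher cross-gene
similarity, exon/intron architecture, RNA-seq splicing), real tool
error patterns (which are correlated with coverage and allele
frequency), or real background genomes (whose HLA-adjacent paralogs
produce borderline matches the random background cannot). The read
filter's retain-everything design is precisely a hedge against those
harder real-data cases.

## Numerical and degenerate-input choices

* Percentages are reported as `None`/flagged when the denominator is
  empty — never silently 0 or 100.
* Ties at any stage resolve by sorted order of the canonical allele
  key (gene, numeric fields, suffix), making every output
  deterministic.
* Empty paired input filters to empty output with a zeroed summary;
  a reference with no sequence of length ≥ k is an error (the index
  would be vacuous).
* Duplicate read names are tolerated (pairing is positional); duplicate
  call-matrix cells are last-write-wins with a warning.

## Known limitations

* The k-mer filter is a desk-scale stand-in for a production aligner;
  for cohort-scale FASTQ files, plug in BWA/minimap2 via
  `--aligner-cmd`.
* G-group/P-group resolution and allele-list ambiguity expansion are
  out of scope; only the first listed allele of an ambiguity string is
  used.
* Novel-allele discovery is impossible by design: the filter keeps only
  reads matching known alleles, so the reference should be the latest
  release.
* Tool output dialects target the commonly distributed layouts of the
  four tools and should be re-validated against the exact versions in
  use.
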