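# hlaensemble

HLA region-specific read filtering and ensemble two-field HLA genotype
calling from multi-source sequencing data.

## The problem

Clinical and research applications such as neoantigen prediction need the
patient's HLA genotype at **two-field resolution** (e.g. `A*02:01` — the
level that distinguishes protein sequences). No single computational HLA
typer is reliable enough on its own, and running several typers on full
exome/RNA-seq FASTQ files is slow. `hlaensemble` implements a two-part
remedy:

1. **HLA region-specific read filtering.** Paired-end FASTQ reads are
   reduced to the small subset that could derive from a known HLA allele,
   by matching against a combined genomic+cDNA allele reference — either
   *All-HLA* (every classical and non-classical locus) or *9-HLA*
   (restricted to the nine classical loci *HLA-A, -B, -C, -DPA1, -DPB1,
   -DQA1, -DQB1, -DRA, -DRB1*). A pair is kept when at least one mate
   matches; the unmatched mate is **rescued** so output stays strictly
   paired. Typing the filtered reads is much faster and yields (nearly)
   the same genotypes.
2. **Ensemble consensus calling.** Two-field genotype calls from four
   typing tools (OptiType, Polysolver, ATHLATES, seq2HLA) applied to three
   sequencing sources per patient (normal exome N, tumor exome T, tumor
   RNA-seq R) are integrated per allele slot. With the tool-by-source
   applicability map (ATHLATES cannot process RNA-seq; class II loci are
   typed only by ATHLATES and seq2HLA) a class I gene has up to **11**
   call slots per allele and a class II gene **5**. An allele called by
   *every* applicable slot is **unanimous** (high confidence); otherwise
   the modal allele is the **consensus**; a tie is **ambiguous**.

The package also computes the associated evaluation statistics:
filtered-vs-original concordance (overall / per patient / per gene / per
tool), the per-tool call **diversity ratio** (mean number of distinct
alleles per patient × gene × slot cell; 1 = perfect internal agreement),
and quality-metric retention for the two tools with explicit quality
scores (ATHLATES pair score, confident iff 0; seq2HLA p-value, confident
iff p < 0.05).

Because real patient-level sequencing data cannot be redistributed, the
package ships a fully labelled simulator (`hlaensemble.synthetic_data`)
that generates an HLA-like reference, a diploid cohort with truth
genotypes, paired-end reads with truth origin labels, and simulated tool
call tables — everything needed to exercise and validate the pipeline
end to end.

## Worked example

Run the simulated end-to-end pipeline (generate a 24-patient cohort,
filter its reads, tally consensus calls, compute metrics):

```bash
hlaensemble run --seed 5 --out-dir demo
```

`demo/summary.json` then contains (abridged):

```json
{
  "consensus_outcomes": {"unanimous": 159, "consensus": 81},
  "diversity_ratios": {
    "ATHLATES": 1.104, "OptiType": 1.125,
    "Polysolver": 1.118, "seq2HLA": 1.171
  },
  "filter": {
    "input_pairs": 1400, "output_pairs": 1200,
    "remaining_percent": 85.71, "rescued_mates": 0
  }
}
```

Reading: of the 240 allele slots (24 patients × 5 genes × 2 slots), 159
were called identically by every applicable tool × source cell
(unanimous) and the remaining 81 resolved to a modal consensus allele at
the default 5% simulated per-call error rate. The read filter kept
exactly the 1200 pairs of HLA origin and discarded all 200 background
pairs (85.71% remaining). Diversity ratios slightly above 1 quantify the
residual between-cell disagreement per tool. The first consensus rows:

```
patient_id  gene  slot  outcome    allele   support  total  expected
P001        A     1     consensus  A*01:03  9        11     11
P001        A     2     consensus  A*01:04  10       11     11
```

Individual stages are available as subcommands — `build-ref`,
`filter-reads`, `ingest`, `consensus`, `concordance`, `ratio`,
`simulate` — and everything is importable as a library
(`from hlaensemble import filter_pairs, build_call_matrix, ...`).

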