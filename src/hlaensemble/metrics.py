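"""Evaluation statistics for filtered-vs-original HLA genotyping.

Three families of statistics:

* **Concordance** — the percentage of allele calls agreeing between
  genotypes derived from HLA-filtered reads and genotypes derived from
  the original unfiltered reads, grouped overall, per patient, per
  gene, or per tool.  Agreement is counted per allele (multiset
  intersection, at most 2 per diploid genotype pair); cells where
  either side failed are excluded from both numerator and denominator.
* **Diversity ratio** — for one tool, the mean number of distinct
  two-field alleles called per patient × gene × allele-slot cell across
  that tool's applicable sequencing sources.  A ratio of exactly 1
  means every cell was internally unanimous; larger values quantify
  call variability.
* **Quality-metric retention** — for the two tools that report a
  quality metric (ATHLATES: allelic-pair score, 0 = confident; seq2HLA:
  prediction p-value, < 0.05 = confident), the percentage of cells
  whose binary quality classification after filtering matches the
  classification of the original-read call.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .call_ingest import Genotype, is_applicable, normalize_tool
from .ensemble import CallMatrix, Cell
from .errors import UndefinedMetricError, UnsupportedToolError

GROUPINGS = ("overall", "per_patient", "per_gene", "per_tool")
QUALITY_TOOLS = ("ATHLATES", "seq2HLA")


@dataclass
class ConcordanceReport:
    grouping: str
    group_key: str
    matched_alleles: int
    compared_alleles: int
    filter_level_compared: str

    @property
    def percent(self) -> float | None:
        """Agreement percentage; ``None`` (flagged) for an empty denominator."""
        if self.compared_alleles == 0:
            return None
        return 100.0 * self.matched_alleles / self.compared_alleles


@dataclass
class DiversityRatio:
    tool: str
    filter_level: str
    distinct_sum: int
    cell_count: int

    @property
    def ratio(self) -> float:
        return self.distinct_sum / self.cell_count


def genotype_match_count(g1: Genotype, g2: Genotype) -> int:
    """Number of agreeing alleles: the maximum multiset intersection.

    0, 1 or 2 for full diploid calls; symmetric in its arguments.
    Raises ``ValueError`` on a gene mismatch.
    """
    if g1.gene != g2.gene:
        raise ValueError(f"cannot compare genotypes of genes {g1.gene} and {g2.gene}")
    c1 = Counter(g1.alleles)
    c2 = Counter(g2.alleles)
    return sum((c1 & c2).values())


def _comparable_cells(matrix: CallMatrix, level: str):
    """Yield (patient, gene, tool, source, original Cell, filtered Cell)."""
    for (patient, gene), group in sorted(matrix.cells.items()):
        seen = sorted({(t, s) for (t, s, _lvl) in group})
        for tool, source in seen:
            orig = group.get((tool, source, "original"))
            filt = group.get((tool, source, level))
            if orig is None or filt is None:
                continue
            if orig.status != "ok" or filt.status != "ok":
                continue
            yield patient, gene, tool, source, orig, filt


def _allele_comparison(orig: Cell, filt: Cell, gene: str) -> tuple[int, int]:
    g1 = Genotype(gene, orig.genotype_alleles)
    g2 = Genotype(gene, filt.genotype_alleles)
    compared = max(len(g1.alleles), len(g2.alleles))
    matched = genotype_match_count(g1, g2)
    return matched, compared


def concordance(
    matrix: CallMatrix, level: str, grouping: str = "overall"
) -> list[ConcordanceReport]:
    """Filtered-vs-original allele concordance at the requested grouping.

    ``level`` names the filter level compared against ``original``
    (``all_hla`` or ``nine_hla``).  Every (patient, gene, tool, source)
    cell with an ok call on both sides contributes up to two compared
    alleles.  Groups that end up with zero comparable alleles are
    reported with an undefined (``None``) percent rather than dropped.
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"grouping must be one of {GROUPINGS}")
    matched: Counter[str] = Counter()
    compared: Counter[str] = Counter()
    keys_seen: set[str] = set()
    for patient, gene, tool, source, orig, filt in _comparable_cells(matrix, level):
        if grouping == "overall":
            key = "overall"
        elif grouping == "per_patient":
            key = patient
        elif grouping == "per_gene":
            key = gene
        else:
            key = tool
        m, c = _allele_comparison(orig, filt, gene)
        matched[key] += m
        compared[key] += c
        keys_seen.add(key)
    if grouping == "overall":
        keys_seen.add("overall")
    return [
        ConcordanceReport(grouping, key, matched[key], compared[key], level)
        for key in sorted(keys_seen)
    ]


def diversity_ratio(matrix: CallMatrix, tool: str, level: str) -> DiversityRatio:
    """Distinct-allele ratio for one tool at one filter level.

    For each (patient, gene, slot) with at least one call across the
    tool's applicable sources, count the distinct two-field alleles;
    the ratio is the sum of those counts divided by the number of such
    cells.  Raises :class:`UndefinedMetricError` when the tool made no
    calls at the level.
    """
    tool = normalize_tool(tool)
    distinct_sum = 0
    cell_count = 0
    for (patient, gene), group in sorted(matrix.cells.items()):
        for slot in (1, 2):
            alleles = set()
            for (t, source, lvl), cell in group.items():
                if t != tool or lvl != level or not is_applicable(t, source, gene):
                    continue
                allele = cell.slot_allele(slot)
                if allele is not None:
                    alleles.add(allele)
            if alleles:
                distinct_sum += len(alleles)
                cell_count += 1
    if cell_count == 0:
        raise UndefinedMetricError(
            f"{tool} made no calls at filter level {level!r}"
        )
    return DiversityRatio(tool, level, distinct_sum, cell_count)


def quality_retention(matrix: CallMatrix, tool: str, level: str) -> float:
    """Percent of cells whose quality classification survives filtering.

    Only ATHLATES and seq2HLA report quality metrics; requesting any
    other tool raises :class:`UnsupportedToolError`.  A cell counts as
    retained when the filtered call's confident/not-confident class
    equals the original call's class.
    """
    tool = normalize_tool(tool)
    if tool not in QUALITY_TOOLS:
        raise UnsupportedToolError(f"{tool} does not report a quality metric")
    retained = 0
    total = 0
    for patient, gene, t, source, orig, filt in _comparable_cells(matrix, level):
        if t != tool:
            continue
        if orig.quality_class == "unavailable" or filt.quality_class == "unavailable":
            continue
        total += 1
        if orig.quality_class == filt.quality_class:
            retained += 1
    if total == 0:
        raise UndefinedMetricError(
            f"no overlapping quality-bearing cells for {tool} at {level!r}"
        )
    return 100.0 * retained / total
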