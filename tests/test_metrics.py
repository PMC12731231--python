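"""Concordance, diversity-ratio, and quality-retention statistics."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from hlaensemble import (
    build_call_matrix,
    concordance,
    diversity_ratio,
    genotype_match_count,
    quality_retention,
)
from hlaensemble.errors import UndefinedMetricError, UnsupportedToolError

from conftest import genotype, rec

ALLELES = ["A*01:01", "A*02:01", "A*03:01", "A*24:02"]


class TestGenotypeMatchCount:
    @pytest.mark.parametrize(
        "g1, g2, expected",
        [
            (("A*02:01", "A*03:01"), ("A*02:01", "A*03:01"), 2),
            (("A*02:01", "A*02:01"), ("A*02:01", "A*03:01"), 1),
            (("A*01:01", "A*24:02"), ("A*02:05", "A*30:01"), 0),
            (("A*02:01",), ("A*02:01", "A*03:01"), 1),
            ((), ("A*02:01", "A*03:01"), 0),
        ],
    )
    def test_multiset_intersection(self, g1, g2, expected):
        assert genotype_match_count(genotype("A", *g1), genotype("A", *g2)) == expected

    def test_gene_mismatch_rejected(self):
        with pytest.raises(ValueError):
            genotype_match_count(genotype("A", "A*02:01"), genotype("B", "B*07:02"))

    @settings(max_examples=500, derandomize=True)
    @given(
        a1=st.lists(st.sampled_from(ALLELES), min_size=0, max_size=2),
        a2=st.lists(st.sampled_from(ALLELES), min_size=0, max_size=2),
    )
    def test_symmetric_and_bounded(self, a1, a2):
        g1, g2 = genotype("A", *a1), genotype("A", *a2)
        n = genotype_match_count(g1, g2)
        assert n == genotype_match_count(g2, g1)
        assert 0 <= n <= 2
        assert n <= min(len(a1), len(a2)) or len(a1) == len(a2) == 0


def _paired_records(filtered_overrides=None):
    """Original + all_hla calls for 1 patient, genes A and B, 5 cells each.

    ``filtered_overrides`` maps (gene, tool, source) -> allele pair used at
    the all_hla level instead of the original call.
    """
    filtered_overrides = filtered_overrides or {}
    cells = [("OptiType", "N"), ("OptiType", "T"), ("OptiType", "R"),
             ("Polysolver", "N"), ("Polysolver", "T")]
    base = {"A": ("A*02:01", "A*03:01"), "B": ("B*07:02", "B*44:02")}
    records = []
    for gene, alleles in base.items():
        for tool, source in cells:
            records.append(rec("P1", tool, source, "original", gene, *alleles))
            filt = filtered_overrides.get((gene, tool, source), alleles)
            records.append(rec("P1", tool, source, "all_hla", gene, *filt))
    return records


class TestConcordance:
    def test_identity_gives_100_percent_for_every_grouping(self):
        matrix = build_call_matrix(_paired_records())
        for grouping in ("overall", "per_patient", "per_gene", "per_tool"):
            for report in concordance(matrix, "all_hla", grouping):
                assert report.percent == pytest.approx(100.0)

    def test_one_changed_allele_out_of_ten_gives_90_percent(self):
        overrides = {("A", "OptiType", "N"): ("A*02:01", "A*11:01")}
        matrix = build_call_matrix(_paired_records(overrides))
        (report,) = concordance(matrix, "all_hla", "per_gene")[:1]  # gene A
        assert report.group_key == "A"
        assert (report.matched_alleles, report.compared_alleles) == (9, 10)
        assert report.percent == pytest.approx(90.0)

    def test_failed_cells_excluded_from_both_sides(self):
        records = _paired_records()
        records.append(rec("P1", "ATHLATES", "N", "original", "A",
                           "A*02:01", "A*03:01"))
        records.append(rec("P1", "ATHLATES", "N", "all_hla", "A", status="failed"))
        matrix = build_call_matrix(records)
        (overall,) = concordance(matrix, "all_hla", "overall")
        assert overall.compared_alleles == 20  # the failed pair adds nothing
        assert overall.percent == pytest.approx(100.0)

    def test_group_with_no_comparable_cells_flagged_undefined(self):
        # original-only records: nothing to compare at all_hla
        records = [rec("P1", "OptiType", "N", "original", "A", "A*02:01")]
        matrix = build_call_matrix(records)
        (overall,) = concordance(matrix, "all_hla", "overall")
        assert overall.compared_alleles == 0
        assert overall.percent is None

    @pytest.mark.parametrize(
        "overrides",
        [
            {("A", "OptiType", "N"): ("A*11:01", "A*26:01")},
            {("A", "OptiType", "N"): ("A*02:01", "A*11:01"),
             ("B", "Polysolver", "T"): ("B*08:01", "B*40:01")},
        ],
    )
    def test_removing_a_discordant_cell_never_decreases_percent(self, overrides):
        # exhaustively drop each discordant cell and recompute from scratch
        full = _paired_records(overrides)
        matrix = build_call_matrix(full)
        (base,) = concordance(matrix, "all_hla", "overall")
        for gene, tool, source in overrides:
            reduced = [
                r for r in full
                if not (r.gene == gene and r.tool == tool and r.source == source)
            ]
            (report,) = concordance(build_call_matrix(reduced), "all_hla", "overall")
            assert report.percent >= base.percent


class TestDiversityRatio:
    def test_internally_unanimous_matrix_has_ratio_exactly_one(self):
        records = []
        for source in ("N", "T", "R"):
            records.append(rec("P1", "seq2HLA", source, "original", "A",
                               "A*02:01", "A*03:01"))
        ratio = diversity_ratio(build_call_matrix(records), "seq2HLA", "original")
        assert ratio.ratio == 1.0
        assert (ratio.distinct_sum, ratio.cell_count) == (2, 2)

    def test_distinct_counts_accumulate_per_slot_cell(self):
        # 4 (patient,gene,slot) cells with distinct counts (1,1,2,1)
        records = []
        for source, a_pair, b_pair in [
            ("N", ("A*02:01", "A*03:01"), ("B*07:02", "B*44:02")),
            ("T", ("A*02:01", "A*03:01"), ("B*07:02", "B*44:02")),
            ("R", ("A*02:01", "A*03:01"), ("B*08:01", "B*44:02")),
        ]:
            records.append(rec("P1", "seq2HLA", source, "original", "A", *a_pair))
            records.append(rec("P1", "seq2HLA", source, "original", "B", *b_pair))
        ratio = diversity_ratio(build_call_matrix(records), "seq2HLA", "original")
        assert (ratio.distinct_sum, ratio.cell_count) == (5, 4)
        assert ratio.ratio == pytest.approx(1.25)

    def test_single_cell_single_call_is_one(self):
        records = [rec("P1", "OptiType", "N", "original", "A", "A*02:01")]
        ratio = diversity_ratio(build_call_matrix(records), "OptiType", "original")
        assert ratio.ratio == 1.0

    def test_no_calls_is_undefined(self):
        records = [rec("P1", "OptiType", "N", "original", "A", "A*02:01")]
        with pytest.raises(UndefinedMetricError):
            diversity_ratio(build_call_matrix(records), "seq2HLA", "original")

    def test_ratio_at_least_one_on_simulated_tables(self, small_cfg, small_cohort):
        from hlaensemble import simulate_call_tables

        _, _, truth = small_cohort
        matrix = build_call_matrix(simulate_call_tables(truth, small_cfg))
        for tool in ("ATHLATES", "OptiType", "Polysolver", "seq2HLA"):
            assert diversity_ratio(matrix, tool, "original").ratio >= 1.0


class TestQualityRetention:
    def _records(self, degrade=0):
        """4 ATHLATES cells; ``degrade`` of them lose confidence on filtering."""
        records = []
        cells = list(itertools.product(("A", "B"), ("N", "T")))
        for i, (gene, source) in enumerate(cells):
            records.append(rec("P1", "ATHLATES", source, "original", gene,
                               f"{gene}*01:01", quality_value=0.0,
                               quality_class="confident"))
            if i < degrade:
                records.append(rec("P1", "ATHLATES", source, "all_hla", gene,
                                   f"{gene}*01:01", quality_value=2.0,
                                   quality_class="not_confident"))
            else:
                records.append(rec("P1", "ATHLATES", source, "all_hla", gene,
                                   f"{gene}*01:01", quality_value=0.0,
                                   quality_class="confident"))
        return records

    def test_full_retention_is_100(self):
        matrix = build_call_matrix(self._records(degrade=0))
        assert quality_retention(matrix, "ATHLATES", "all_hla") == pytest.approx(100.0)

    def test_one_of_four_degrading_gives_75(self):
        matrix = build_call_matrix(self._records(degrade=1))
        assert quality_retention(matrix, "ATHLATES", "all_hla") == pytest.approx(75.0)

    def test_tools_without_quality_metric_rejected(self):
        matrix = build_call_matrix(self._records())
        for tool in ("OptiType", "Polysolver"):
            with pytest.raises(UnsupportedToolError):
                quality_retention(matrix, tool, "all_hla")

    def test_no_overlapping_cells_undefined(self):
        records = [rec("P1", "seq2HLA", "N", "original", "A", "A*02:01",
                       quality_value=0.01, quality_class="confident")]
        matrix = build_call_matrix(records)
        with pytest.raises(UndefinedMetricError):
            quality_retention(matrix, "seq2HLA", "all_hla")
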