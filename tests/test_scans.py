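"""Window tiling, feature partition, reconciliation and the splicing screen."""

import numpy as np
import pandas as pd
import pytest

from imprintscan.model import (
    A_MOTHER,
    B_MOTHER,
    CROSSES,
    Annotation,
    Gene,
    Transcript,
)
from imprintscan.scans import (
    build_feature_units,
    feature_scan,
    partition_totals,
    poe_splicing_scan,
    reconcile,
    significant_features,
    significant_windows,
    tile_windows,
    window_scan,
)


class TestTileWindows:
    def test_three_kb_chromosome(self):
        windows = tile_windows({"chr1": 3000})
        assert [(w.start, w.end) for w in windows] == [
            (0, 1000), (500, 1500), (1000, 2000), (1500, 2500), (2000, 3000),
        ]

    def test_exactly_one_window(self):
        windows = tile_windows({"chr1": 1000})
        assert [(w.start, w.end) for w in windows] == [(0, 1000)]

    def test_short_tail_merged_into_previous(self):
        windows = tile_windows({"chr1": 1300})
        assert [(w.start, w.end) for w in windows] == [(0, 1000), (500, 1300)]

    def test_tiny_chromosome_single_window(self):
        windows = tile_windows({"chr1": 400})
        assert [(w.start, w.end) for w in windows] == [(0, 400)]

    @pytest.mark.parametrize("length", [2000, 3700, 10_000, 12_345])
    def test_interior_positions_covered_twice(self, length):
        windows = tile_windows({"chr1": length})
        last_start = windows[-1].start
        coverage = np.zeros(length, dtype=int)
        for w in windows:
            coverage[w.start : w.end] += 1
        interior = coverage[500 : last_start + 500]
        assert (interior == 2).all()
        assert (coverage >= 1).all()


def _counts_tables(rows_by_cross):
    out = {}
    for cross, rows in rows_by_cross.items():
        df = pd.DataFrame(rows, columns=["chrom", "pos", "r_mat", "r_pat"])
        out[cross] = df
    return out


class TestWindowScan:
    def test_low_coverage_boundary(self):
        tables = _counts_tables(
            {
                A_MOTHER: [("chr1", 100, 6, 3)],  # 9 reads: below the filter
                B_MOTHER: [("chr1", 100, 40, 20)],
            }
        )
        windows = window_scan(tile_windows({"chr1": 1000}), tables, "endosperm")
        assert windows[0].call.call == "low_coverage"

    def test_planted_monoallelic_window(self):
        tables = _counts_tables(
            {
                A_MOTHER: [("chr1", 100, 100, 0)],
                B_MOTHER: [("chr1", 200, 100, 0)],
            }
        )
        windows = window_scan(tile_windows({"chr1": 1000}), tables, "endosperm")
        assert windows[0].call.call == "maternal_imprint"

    def test_null_rejection_rate(self):
        """~5% of well-covered windows fire per cross under the 2:1 null."""
        rng = np.random.default_rng(17)
        n = 2000
        rows_a, rows_b = [], []
        for i in range(n):
            for rows in (rows_a, rows_b):
                m = rng.binomial(100, 2 / 3)
                rows.append(("chr1", 1000 * i + 500, m, 100 - m))
        tables = _counts_tables({A_MOTHER: rows_a, B_MOTHER: rows_b})
        windows = window_scan(
            tile_windows({"chr1": 1000 * n}), tables, "endosperm"
        )
        sig_one_cross = np.mean(
            [w.call.test_a_mother.significant() for w in windows if w.counts[A_MOTHER][0] + w.counts[A_MOTHER][1] >= 10]
        )
        assert 0.03 <= sig_one_cross <= 0.08

    def test_window_totals_double_count_reads(self):
        """Interior SNP reads are counted by exactly two overlapping windows."""
        rng = np.random.default_rng(3)
        rows = [("chr1", int(p), int(m), int(q)) for p, m, q in
                zip(rng.integers(600, 9400, 50), rng.integers(1, 30, 50), rng.integers(1, 30, 50))]
        tables = _counts_tables({A_MOTHER: rows, B_MOTHER: rows})
        windows = window_scan(tile_windows({"chr1": 10_000}), tables, "endosperm")
        total_reads = sum(m + q for _, _, m, q in rows)
        windowed = sum(sum(w.counts[A_MOTHER]) for w in windows)
        assert windowed == 2 * total_reads


def _two_gene_annotation():
    g1 = Gene(
        "gA", "chr1", 1000, 3000,
        [
            Transcript("gA.1", [(1000, 1400), (1800, 2200), (2600, 3000)]),
            Transcript("gA.2", [(1000, 1400), (2600, 3000)]),
        ],
    )
    g2 = Gene("gB", "chr1", 6000, 7000, [Transcript("gB.1", [(6000, 7000)])])
    return Annotation([g1, g2])


class TestFeatureScan:
    def test_partition_conserves_all_reads(self):
        ann = _two_gene_annotation()
        rows = [
            ("chr1", 1200, 30, 10),  # exon of gA
            ("chr1", 1600, 20, 10),  # intron of gA
            ("chr1", 4000, 5, 5),    # intergenic
            ("chr1", 6500, 40, 20),  # exon of gB
        ]
        tables = _counts_tables({A_MOTHER: rows, B_MOTHER: rows})
        totals = partition_totals(ann, tables, {"chr1": 10_000})
        assert totals["exon_union"] + totals["intron"] + totals["intergenic"] == totals["total"]
        assert totals["exon_union"] == 2 * (40 + 60)
        assert totals["intron"] == 2 * 30
        assert totals["intergenic"] == 2 * 10

    def test_isoforms_with_identical_support_collapse(self):
        ann = _two_gene_annotation()
        # SNP only in the shared first exon: gA.1 and gA.2 are indistinguishable
        rows = [("chr1", 1200, 50, 10)]
        tables = _counts_tables({A_MOTHER: rows, B_MOTHER: rows})
        units = feature_scan(ann, tables, "endosperm", {"chr1": 10_000})
        ids = [u.id for u in units if u.kind == "cdna_isoform" and u.gene_id == "gA"]
        assert ids == ["gA.1;gA.2"]

    def test_isoforms_with_distinct_support_stay_separate(self):
        ann = _two_gene_annotation()
        # second SNP in the exon skipped by gA.2
        rows = [("chr1", 1200, 50, 10), ("chr1", 2000, 30, 5)]
        tables = _counts_tables({A_MOTHER: rows, B_MOTHER: rows})
        units = feature_scan(ann, tables, "endosperm", {"chr1": 10_000})
        ids = sorted(
            u.id for u in units if u.kind == "cdna_isoform" and u.gene_id == "gA"
        )
        assert ids == ["gA.1", "gA.2"]

    def test_intergenic_maternal_transcript_recovered(self):
        ann = _two_gene_annotation()
        rows = [("chr1", 4200, 60, 0)]  # between the genes, fully maternal
        tables = _counts_tables({A_MOTHER: rows, B_MOTHER: rows})
        units = feature_scan(ann, tables, "endosperm", {"chr1": 10_000})
        hits = [
            u for u in units
            if u.kind == "intergenic" and u.call.call == "maternal_imprint"
        ]
        assert len(hits) == 1
        assert hits[0].start <= 4200 < hits[0].end

    def test_intron_unit_classified(self):
        ann = _two_gene_annotation()
        rows = [("chr1", 1600, 0, 60), ("chr1", 2400, 0, 40)]  # introns of gA
        tables = _counts_tables({A_MOTHER: rows, B_MOTHER: rows})
        units = feature_scan(ann, tables, "endosperm", {"chr1": 10_000})
        intron = next(u for u in units if u.id == "gA.intron")
        assert intron.call.call == "paternal_imprint"


class TestReconcile:
    def _scanned(self, rows):
        ann = _two_gene_annotation()
        tables = _counts_tables({A_MOTHER: rows, B_MOTHER: rows})
        windows = window_scan(tile_windows({"chr1": 20_000}), tables, "endosperm")
        units = feature_scan(ann, tables, "endosperm", {"chr1": 20_000})
        return windows, units, ann

    def test_window_in_candidate_cdna(self):
        windows, units, ann = self._scanned([("chr1", 6500, 100, 0)])
        report = reconcile(windows, units, ann)
        assert report["n_significant_windows"] >= 1
        assert set(report["window_labels"].values()) == {"overlaps_candidate_feature"}

    def test_far_intergenic_window(self):
        windows, units, ann = self._scanned([("chr1", 15_000, 100, 0)])
        report = reconcile(windows, units, ann)
        # intergenic units are also candidate features, so the window maps to one
        labels = set(report["window_labels"].values())
        assert labels <= {"overlaps_candidate_feature", "intergenic"}
        assert report["n_significant_windows"] == 2  # two overlapping windows

    def test_feature_only_candidate_counted(self):
        # diffuse signal: each window under the gene has <10 reads per cross,
        # but the cDNA aggregates to a significant maternal call
        ann = Annotation(
            [Gene("gB", "chr1", 6000, 9600, [Transcript("gB.1", [(6000, 9600)])])]
        )
        rows = [("chr1", 6100 + 1200 * i, 4, 0) for i in range(3)]
        tables = _counts_tables({A_MOTHER: rows, B_MOTHER: rows})
        windows = window_scan(tile_windows({"chr1": 20_000}), tables, "endosperm")
        units = feature_scan(ann, tables, "endosperm", {"chr1": 20_000})
        report = reconcile(windows, units, ann)
        assert report["n_significant_windows"] == 0
        assert "gB.1" in report["feature_only_candidates"]


class TestPoeSplicingScan:
    def _scan(self, rows):
        ann = _two_gene_annotation()
        tables = _counts_tables({A_MOTHER: rows, B_MOTHER: rows})
        windows = window_scan(tile_windows({"chr1": 10_000}), tables, "endosperm")
        units = feature_scan(ann, tables, "endosperm", {"chr1": 10_000})
        return poe_splicing_scan(units, windows, ann)

    def test_opposite_exon_intron_bias_is_candidate(self):
        rows = [
            ("chr1", 1200, 2, 58),   # exon: paternal
            ("chr1", 2000, 3, 57),   # exon: paternal
            ("chr1", 1600, 55, 5),   # intron: maternal
        ]
        candidates = self._scan(rows)
        assert [c.gene_id for c in candidates] == ["gA"]
        assert any("intron" in p for p in candidates[0].maternal_parts)

    def test_concordant_gene_not_flagged(self):
        rows = [
            ("chr1", 1200, 58, 2),
            ("chr1", 1600, 55, 5),  # intron maternal too
        ]
        assert self._scan(rows) == []

    def test_scan_invariant_to_input_order(self, bundle):
        from imprintscan.counts import GenomeIndex, aggregate_counts, preprocess_and_assign
        from imprintscan.counts import normalize_between_crosses

        genomes = bundle["genomes"]
        index = GenomeIndex(genomes)
        tables = {}
        for cross, reads in bundle["reads"].items():
            assignments, _ = preprocess_and_assign(
                reads, index, genomes.snps, adaptor=bundle["config"].adaptor
            )
            tables[cross] = aggregate_counts(assignments, cross, "endosperm")
        norm, _ = normalize_between_crosses(tables)
        shuffled = {
            c: t.sample(frac=1.0, random_state=1).reset_index(drop=True)
            for c, t in norm.items()
        }
        ann = bundle["annotation"]
        lengths = genomes.chrom_lengths
        u1 = feature_scan(ann, norm, "endosperm", lengths)
        u2 = feature_scan(ann, shuffled, "endosperm", lengths)
        calls1 = {u.id: u.call.call for u in u1}
        calls2 = {u.id: u.call.call for u in u2}
        assert calls1 == calls2


class TestRecoveryOnBundle:
    def test_windows_and_features_agree_on_planted_loci(self, pipeline_report):
        report, _ = pipeline_report
        rec = report["recovery"]
        for cls in ("maternal_imprint", "paternal_imprint"):
            assert rec[cls]["sensitivity"] >= 0.8
        assert rec["false_calls"]["subspecies_called_imprinted"] == 0
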