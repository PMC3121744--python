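"""Read preprocessing, SNP-read assignment, aggregation and normalization."""

import numpy as np
import pandas as pd
import pytest

from imprintscan.counts import (
    GenomeIndex,
    ReadRecord,
    SnpReadAssignment,
    aggregate_counts,
    assign_read,
    filter_read,
    normalize_between_crosses,
    preprocess_and_assign,
    repetitive_fraction,
    revcomp,
    trim_adaptor,
    truncate_embryo,
)
from imprintscan.model import A_MOTHER, B_MOTHER, GenomePair, SnpTable
from imprintscan.synthetic import build_genome_pair

ADAPTOR = "AGATCGGAAGAGCACACGTCT"


class TestTrimAdaptor:
    def test_full_adaptor_suffix_removed(self):
        insert = "ACGTACGTACGTACGTACGTACGTACGTACGTACGT"  # 36-mer
        assert trim_adaptor(insert + ADAPTOR, ADAPTOR) == insert

    def test_no_overlap_unchanged(self):
        read = "CCCCCCCCCCCCCCCCCCCCCCCCCCCC"
        assert trim_adaptor(read, ADAPTOR) == read

    def test_six_base_prefix_overlap_removed(self):
        read = "TTGCATTGCATTGCATTGCATTGCA" + ADAPTOR[:6]
        assert trim_adaptor(read, ADAPTOR) == "TTGCATTGCATTGCATTGCATTGCA"

    def test_overlap_below_minimum_kept(self):
        read = "TTGCATTGCATTGCATTGCATTGCA" + ADAPTOR[:4]
        assert trim_adaptor(read, ADAPTOR) == read

    def test_empty_adaptor_rejected(self):
        with pytest.raises(ValueError):
            trim_adaptor("ACGT", "")


class TestFilterRead:
    def test_seventeen_base_read_is_short(self):
        keep, reason = filter_read("ACGTACGTACGTACGTA")
        assert not keep and reason == "short"

    def test_eighteen_base_read_kept(self):
        keep, _ = filter_read("ACGTAGGTACGTACGTAC")
        assert keep

    def test_pure_dinucleotide_repeat_excluded(self):
        keep, reason = filter_read("AC" * 12)
        assert not keep and reason == "repetitive"

    def test_homopolymer_excluded(self):
        keep, reason = filter_read("A" * 30)
        assert not keep and reason == "repetitive"

    def test_random_reads_rarely_repetitive(self):
        """The tandem-repeat scan leaves typical random 36-mers alone."""
        rng = np.random.default_rng(3)
        fracs = [
            repetitive_fraction("".join(rng.choice(list("ACGT"), size=36)))
            for _ in range(500)
        ]
        assert np.mean([f > 0.5 for f in fracs]) < 0.02

    def test_repetitive_fraction_bounds(self):
        assert repetitive_fraction("") == 0.0
        assert 0.0 <= repetitive_fraction("ACGTACGTAA") <= 1.0


class TestTruncateEmbryo:
    @pytest.mark.parametrize(
        "length,expected", [(75, 36), (36, 36), (20, 20)]
    )
    def test_lengths(self, length, expected):
        seq = ("ACGT" * 20)[:length]
        out = truncate_embryo(seq)
        assert out == seq[:36] and len(out) == expected


def _toy_genomes() -> GenomePair:
    """One 120 bp chromosome with SNPs at 30 and 90, plus a duplicated block."""
    rng = np.random.default_rng(8)
    a = list(rng.choice(list("ACGT"), size=120))
    a[60:80] = a[0:20]  # exact 20 bp duplication (shorter than a read)
    b = a.copy()
    a[30], b[30] = "A", "G"
    a[90], b[90] = "C", "T"
    snps = SnpTable(
        pd.DataFrame(
            [("chr1", 30, "A", "G"), ("chr1", 90, "C", "T")],
            columns=SnpTable.COLUMNS,
        )
    )
    return GenomePair(["chr1"], {"chr1": "".join(a)}, {"chr1": "".join(b)}, snps)


@pytest.fixture(scope="module")
def toy():
    genomes = _toy_genomes()
    return genomes, GenomeIndex(genomes)


class TestAssignRead:
    def test_maternal_allele_a_in_a_mother_cross(self, toy):
        genomes, index = toy
        read = ReadRecord("r1", genomes.seq_a["chr1"][20:56], "endosperm", A_MOTHER)
        out = assign_read(read, index, genomes.snps)
        assert isinstance(out, SnpReadAssignment)
        assert out.origin == "maternal" and out.subspecies_allele == "A"
        assert out.pos == 30

    def test_same_allele_is_paternal_in_reciprocal_cross(self, toy):
        genomes, index = toy
        read = ReadRecord("r1", genomes.seq_a["chr1"][20:56], "endosperm", B_MOTHER)
        out = assign_read(read, index, genomes.snps)
        assert out.origin == "paternal" and out.subspecies_allele == "A"

    def test_strand_symmetry(self, toy):
        genomes, index = toy
        fwd = ReadRecord("r1", genomes.seq_b["chr1"][70:106], "endosperm", A_MOTHER)
        rev = ReadRecord("r1", revcomp(fwd.sequence), "endosperm", A_MOTHER)
        out_f = assign_read(fwd, index, genomes.snps)
        out_r = assign_read(rev, index, genomes.snps)
        assert isinstance(out_f, SnpReadAssignment)
        assert (out_f.pos, out_f.origin, out_f.subspecies_allele) == (
            out_r.pos,
            out_r.origin,
            out_r.subspecies_allele,
        )

    def test_read_without_snp_rejected(self, toy):
        genomes, index = toy
        read = ReadRecord("r1", genomes.seq_a["chr1"][95:115], "endosperm", A_MOTHER)
        assert assign_read(read, index, genomes.snps) == "zero_or_multi_mismatch"

    def test_foreign_sequence_rejected(self, toy):
        genomes, index = toy
        read = ReadRecord("r1", "GATTACAGATTACAGATTACAGATTACA", "endosperm", A_MOTHER)
        assert assign_read(read, index, genomes.snps) == "no_hit"

    def test_read_with_n_rejected(self, toy):
        genomes, index = toy
        seq = genomes.seq_a["chr1"][20:56]
        read = ReadRecord("r1", seq[:10] + "N" + seq[11:], "endosperm", A_MOTHER)
        assert assign_read(read, index, genomes.snps) == "no_hit"

    def test_duplicated_region_is_multi_hit(self, toy):
        genomes, index = toy
        read = ReadRecord("r1", genomes.seq_a["chr1"][0:20], "endosperm", A_MOTHER)
        assert assign_read(read, index, genomes.snps) == "multi_hit"

    def test_two_snp_read_rejected(self):
        genomes = build_genome_pair(1, 2000, 0.0, 1)
        seq = list(genomes.seq_a["chr1"])
        b = seq.copy()
        # plant two SNPs 20 bp apart so a 36-mer can span both
        for pos, alt in ((500, None), (520, None)):
            ref = seq[pos]
            b[pos] = "A" if ref != "A" else "G"
        snps = SnpTable(
            pd.DataFrame(
                [("chr1", 500, seq[500], b[500]), ("chr1", 520, seq[520], b[520])],
                columns=SnpTable.COLUMNS,
            )
        )
        pair = GenomePair(["chr1"], {"chr1": "".join(seq)}, {"chr1": "".join(b)}, snps)
        index = GenomeIndex(pair)
        read = ReadRecord("r1", pair.seq_a["chr1"][495:531], "endosperm", A_MOTHER)
        assert assign_read(read, index, snps) == "multi_snp"

    def test_mismatch_off_snp_rejected(self, toy):
        genomes, index = toy
        seq = list(genomes.seq_a["chr1"][20:56])
        # SNP at offset 10 stays; corrupt a non-SNP base so the perfect hit
        # is lost in A and the B comparison shows a non-SNP mismatch
        pos_in_read = 20
        seq[pos_in_read] = "A" if seq[pos_in_read] != "A" else "C"
        read = ReadRecord("r1", "".join(seq), "endosperm", A_MOTHER)
        out = assign_read(read, index, genomes.snps)
        assert out in ("no_hit", "mismatch_not_snp", "zero_or_multi_mismatch")


class TestAggregate:
    def _assignments(self):
        mk = lambda i, origin: SnpReadAssignment(f"r{i}", "chr1", 30, origin, "A")
        return [mk(i, "maternal") for i in range(3)] + [
            mk(i + 3, "paternal") for i in range(2)
        ]

    def test_counting(self):
        df = aggregate_counts(self._assignments(), A_MOTHER, "endosperm")
        assert len(df) == 1
        assert (df.loc[0, "r_mat_raw"], df.loc[0, "r_pat_raw"]) == (3, 2)

    def test_empty(self):
        df = aggregate_counts([], A_MOTHER, "endosperm")
        assert df.empty

    def test_order_invariance(self):
        a = self._assignments()
        df1 = aggregate_counts(a, A_MOTHER, "endosperm")
        df2 = aggregate_counts(list(reversed(a)), A_MOTHER, "endosperm")
        pd.testing.assert_frame_equal(df1, df2)


def _table(cross, rows):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "r_mat_raw", "r_pat_raw"])
    df["cross_direction"] = cross
    df["tissue"] = "endosperm"
    return df


class TestNormalization:
    def test_equal_totals_identity(self):
        tables = {
            A_MOTHER: _table(A_MOTHER, [("chr1", 10, 30, 20)]),
            B_MOTHER: _table(B_MOTHER, [("chr1", 10, 25, 25)]),
        }
        out, info = normalize_between_crosses(tables)
        assert info["scale_constant"] == pytest.approx(50 / 1e6)
        for cross in tables:
            assert (out[cross]["r_mat"] == out[cross]["r_mat_raw"]).all()
            assert (out[cross]["r_pat"] == out[cross]["r_pat_raw"]).all()

    def test_two_to_one_library_ratio(self):
        """Totals 4M and 2M with C = 3: a raw 10 in the smaller scales to 15."""
        tables = {
            A_MOTHER: _table(A_MOTHER, [("chr1", 10, 4_000_000, 0)]),
            B_MOTHER: _table(
                B_MOTHER, [("chr1", 10, 10, 0), ("chr1", 50, 1_999_990, 0)]
            ),
        }
        out, info = normalize_between_crosses(tables)
        assert info["scale_constant"] == pytest.approx(3.0)
        assert out[B_MOTHER].loc[0, "r_mat"] == 15

    def test_zero_raw_stays_zero(self):
        tables = {
            A_MOTHER: _table(A_MOTHER, [("chr1", 10, 100, 0)]),
            B_MOTHER: _table(B_MOTHER, [("chr1", 10, 0, 50)]),
        }
        out, _ = normalize_between_crosses(tables)
        assert out[A_MOTHER].loc[0, "r_pat"] == 0

    def test_zero_library_total_is_error(self):
        tables = {
            A_MOTHER: _table(A_MOTHER, [("chr1", 10, 1, 1)]),
            B_MOTHER: _table(B_MOTHER, [("chr1", 10, 0, 0)]),
        }
        with pytest.raises(ValueError):
            normalize_between_crosses(tables)

    def test_maternal_fraction_preserved_up_to_rounding(self):
        rng = np.random.default_rng(4)
        rows = [
            ("chr1", int(p), int(m), int(q))
            for p, m, q in zip(
                range(0, 4000, 10),
                rng.integers(0, 80, 400),
                rng.integers(0, 40, 400),
            )
        ]
        tables = {
            A_MOTHER: _table(A_MOTHER, rows),
            B_MOTHER: _table(B_MOTHER, [("chr1", 5, 500, 250)]),
        }
        out, _ = normalize_between_crosses(tables)
        for cross in tables:
            df = out[cross]
            raw_tot = df["r_mat_raw"] + df["r_pat_raw"]
            norm_tot = df["r_mat"] + df["r_pat"]
            keep = (raw_tot > 0) & (norm_tot > 0)
            frac_raw = df.loc[keep, "r_mat_raw"] / raw_tot[keep]
            frac_norm = df.loc[keep, "r_mat"] / norm_tot[keep]
            assert (
                (frac_norm - frac_raw).abs() <= 1.0 / norm_tot[keep] + 1e-12
            ).all()


class TestConservationOnSimulatedReads:
    def test_every_read_in_exactly_one_bucket(self, bundle):
        genomes = bundle["genomes"]
        index = GenomeIndex(genomes)
        for cross, reads in bundle["reads"].items():
            assignments, tally = preprocess_and_assign(
                reads, index, genomes.snps, adaptor=bundle["config"].adaptor
            )
            assert sum(tally.values()) == len(reads)
            assert tally["assigned"] == len(assignments)

    def test_assignment_matches_simulator_oracle(self, bundle):
        """Assigned origin/allele always equal the simulator's planted labels."""
        genomes = bundle["genomes"]
        index = GenomeIndex(genomes)
        reads = bundle["reads"]["A_mother"]
        assignments, _ = preprocess_and_assign(
            reads, index, genomes.snps, adaptor=bundle["config"].adaptor
        )
        assert len(assignments) > 1000
        for a in assignments:
            _, _, origin, allele = a.read_id.split("|")
            assert a.origin == origin and a.subspecies_allele == allele
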