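"""Shared data containers for the imprinting pipeline.

Coordinates are 0-based half-open everywhere inside the package; 1-based
coordinates appear only at the file-format boundary (VCF, GFF3, SNP TSV).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Cross directions: which subspecies provided the egg cell.
A_MOTHER = "A_mother"  # subspecies A female x subspecies B male
B_MOTHER = "B_mother"  # subspecies B female x subspecies A male
CROSSES = (A_MOTHER, B_MOTHER)

ENDOSPERM = "endosperm"
EMBRYO = "embryo"
TISSUES = (ENDOSPERM, EMBRYO)

# Expected maternal read fraction per tissue: the endosperm is triploid
# (2 maternal : 1 paternal genomes), the embryo diploid (1:1).
MATERNAL_FRACTION = {ENDOSPERM: 2.0 / 3.0, EMBRYO: 0.5}

# Classification labels for a profiled feature.
MATERNAL_IMPRINT = "maternal_imprint"
PATERNAL_IMPRINT = "paternal_imprint"
SUBSPECIES_A_BIAS = "subspecies_a_bias"
SUBSPECIES_B_BIAS = "subspecies_b_bias"
UNBIASED = "unbiased"
LOW_COVERAGE = "low_coverage"
ONE_CROSS_CANDIDATE = "one_cross_candidate"
DISCORDANT = "discordant"
IMPRINT_CLASSES = (MATERNAL_IMPRINT, PATERNAL_IMPRINT)
SUBSPECIES_CLASSES = (SUBSPECIES_A_BIAS, SUBSPECIES_B_BIAS)


class SnpTable:
    """Reported SNPs distinguishing the two subspecies.

    Wraps a DataFrame with columns chrom, pos (0-based), allele_a,
    allele_b.  Positions are unique per chromosome and sorted.
    """

    COLUMNS = ["chrom", "pos", "allele_a", "allele_b"]

    def __init__(self, df: pd.DataFrame):
        df = df.loc[:, self.COLUMNS].copy()
        df = df.sort_values(["chrom", "pos"]).reset_index(drop=True)
        if df.duplicated(["chrom", "pos"]).any():
            raise ValueError("duplicate SNP positions within a chromosome")
        if (df["allele_a"] == df["allele_b"]).any():
            raise ValueError("SNP alleles must differ")
        self.df = df
        self._by_chrom = {
            chrom: sub["pos"].to_numpy()
            for chrom, sub in df.groupby("chrom", sort=False)
        }
        self._alleles = {
            (r.chrom, r.pos): (r.allele_a, r.allele_b)
            for r in df.itertuples(index=False)
        }

    def __len__(self) -> int:
        return len(self.df)

    def positions(self, chrom: str) -> np.ndarray:
        """Sorted 0-based SNP positions on one chromosome."""
        return self._by_chrom.get(chrom, np.empty(0, dtype=int))

    def positions_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        pos = self.positions(chrom)
        lo, hi = np.searchsorted(pos, [start, end])
        return pos[lo:hi]

    def alleles_at(self, chrom: str, pos: int) -> tuple[str, str]:
        return self._alleles[(chrom, pos)]

    def is_snp(self, chrom: str, pos: int) -> bool:
        return (chrom, pos) in self._alleles


@dataclass
class GenomePair:
    """Two colinear haploid genome sequences differing only at SNPs."""

    chrom_names: list[str]
    seq_a: dict[str, str]
    seq_b: dict[str, str]
    snps: SnpTable

    def chrom_length(self, chrom: str) -> int:
        return len(self.seq_a[chrom])

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(self.seq_a[c]) for c in self.chrom_names}

    def validate(self) -> None:
        """Check the invariants: equal lengths, mismatches exactly at SNPs."""
        for chrom in self.chrom_names:
            a, b = self.seq_a[chrom], self.seq_b[chrom]
            if len(a) != len(b):
                raise ValueError(f"{chrom}: haplotype lengths differ")
            diff = {i for i in range(len(a)) if a[i] != b[i]}
            listed = set(self.snps.positions(chrom).tolist())
            if diff != listed:
                raise ValueError(f"{chrom}: sequence differences do not match SNP table")
            for pos in listed:
                aa, ab = self.snps.alleles_at(chrom, pos)
                if a[pos] != aa or b[pos] != ab:
                    raise ValueError(f"{chrom}:{pos}: alleles disagree with sequences")


@dataclass
class Transcript:
    """One mRNA isoform: exons as sorted 0-based half-open intervals."""

    id: str
    exons: list[tuple[int, int]]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        ]


@dataclass
class Gene:
    id: str
    chrom: str
    start: int
    end: int
    transcripts: list[Transcript] = field(default_factory=list)

    def exon_union(self) -> list[tuple[int, int]]:
        """Union of exon intervals over all isoforms, merged and sorted."""
        return merge_intervals(
            [iv for t in self.transcripts for iv in t.exons]
        )

    def intron_union(self) -> list[tuple[int, int]]:
        """Gene-span intervals not covered by any isoform's exon."""
        return complement_intervals(self.exon_union(), self.start, self.end)


@dataclass
class Annotation:
    """Gene models for one genome: gene -> mRNA -> exon hierarchy."""

    genes: list[Gene]

    def __post_init__(self):
        self.genes = sorted(self.genes, key=lambda g: (g.chrom, g.start, g.id))

    def by_chrom(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        return out

    def gene_ids(self) -> list[str]:
        return [g.id for g in self.genes]


@dataclass
class GroundTruthLocus:
    """A planted simulation truth used for recovery testing."""

    feature_id: str
    chrom: str
    start: int
    end: int
    truth_class: str
    bias_level: float = 0.5
    mean_depth: float = 35.0
    # For poe_splicing loci: per-sub-feature truth, keyed "exon"/"intron".
    sub_feature_truth: dict[str, str] | None = None
    testable: bool = True


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def complement_intervals(
    intervals: list[tuple[int, int]], start: int, end: int
) -> list[tuple[int, int]]:
    """Intervals of [start, end) not covered by `intervals` (assumed merged)."""
    out = []
    cur = start
    for s, e in intervals:
        if s > cur:
            out.append((cur, min(s, end)))
        cur = max(cur, e)
    if cur < end:
        out.append((cur, end))
    return [(s, e) for s, e in out if e > s and s < end and e > start]
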