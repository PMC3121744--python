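"""Read preprocessing, parental assignment of SNP reads, and count tables.

A "SNP read" aligns perfectly and uniquely to one parental genome, aligns to
the other genome with exactly one mismatch, that mismatch falls on a reported
SNP, and the read covers exactly one reported SNP.  Such a read can be
attributed unambiguously to the subspecies allele it carries, and hence — via
the cross direction — to the maternal or paternal genome.

The assigner here is an exact-match hash index over both parental genomes.
Because the two haplotypes are colinear (equal length, differing only at
SNPs), the homologous location in the other genome is the same coordinate,
and the accept/reject rules above can be evaluated directly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import A_MOTHER, CROSSES, GenomePair, SnpTable

MIN_READ_LENGTH = 18
MAX_REPETITIVE_FRACTION = 0.5
MIN_ADAPTOR_OVERLAP = 5
EMBRYO_TRUNCATION = 36

# Accept/reject buckets for the conservation ledger.
ASSIGNED = "assigned"
REJECT_REASONS = (
    "multi_hit",
    "no_hit",
    "zero_or_multi_mismatch",
    "mismatch_not_snp",
    "multi_snp",
)
FILTER_REASONS = ("short", "repetitive")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadRecord:
    """One sequencing read with its library metadata."""

    id: str
    sequence: str
    tissue: str
    cross_direction: str


@dataclass
class SnpReadAssignment:
    """A read attributed to a parental genome via the SNP it carries."""

    read_id: str
    chrom: str
    pos: int  # 0-based SNP position
    origin: str  # "maternal" | "paternal"
    subspecies_allele: str  # "A" | "B"


def trim_adaptor(seq: str, adaptor: str, min_overlap: int = MIN_ADAPTOR_OVERLAP) -> str:
    """Remove the longest read suffix that exactly matches a prefix of the adaptor.

    Overlaps shorter than `min_overlap` are ignored, so chance matches of a
    few bases do not truncate clean reads.
    """
    if not adaptor:
        raise ValueError("adaptor must be non-empty")
    max_k = min(len(seq), len(adaptor))
    for k in range(max_k, min_overlap - 1, -1):
        if seq.endswith(adaptor[:k]):
            return seq[: len(seq) - k]
    return seq


def repetitive_fraction(seq: str, max_period: int = 3) -> float:
    """Fraction of bases inside tandem repeats of period 1-3.

    A tandem run of period p is a maximal stretch where every base equals
    the base p positions earlier; runs shorter than three repeat units
    (3p bases) are ignored so that chance dinucleotide pairs in random
    sequence do not count as repeats.
    """
    n = len(seq)
    if n == 0:
        return 0.0
    covered = np.zeros(n, dtype=bool)
    for p in range(1, max_period + 1):
        i = p
        run_start = 0
        while i <= n:
            if i < n and seq[i] == seq[i - p]:
                i += 1
                continue
            # run of agreement ended at i; repeat block = [run_start, i)
            if i - run_start >= 3 * p:
                covered[run_start:i] = True
            run_start = i - p + 1
            i += 1
    return float(covered.sum()) / n


def filter_read(seq: str) -> tuple[bool, str | None]:
    """Apply the post-trim read filters.

    Returns (keep, reason): reads shorter than 18 bases are dropped as
    "short"; reads more than half covered by short tandem repeats are
    dropped as "repetitive".
    """
    if len(seq) < MIN_READ_LENGTH:
        return False, "short"
    if repetitive_fraction(seq) > MAX_REPETITIVE_FRACTION:
        return False, "repetitive"
    return True, None


def truncate_embryo(seq: str, cutoff: int = EMBRYO_TRUNCATION) -> str:
    """Keep only the first 36 bases of longer embryo reads.

    Embryo libraries are sequenced longer than endosperm ones; truncating
    makes the multi-SNP exclusion risk comparable between tissues.
    """
    return seq[:cutoff]


class GenomeIndex:
    """Exact-match index of both parental genomes.

    Seeds of length `seed_len` (the minimum read length) are hashed for the
    forward strand of each haplotype; a query checks the read and its
    reverse complement, so both strands are covered.  Perfect full-length
    hits are found by extending seed hits, which is exhaustive because every
    full-read occurrence starts with an indexed seed.
    """

    def __init__(self, genomes: GenomePair, seed_len: int = MIN_READ_LENGTH):
        self.genomes = genomes
        self.seed_len = seed_len
        self._index: dict[str, list[tuple[str, str, int]]] = {}
        for label, seqs in (("A", genomes.seq_a), ("B", genomes.seq_b)):
            for chrom, seq in seqs.items():
                for i in range(len(seq) - seed_len + 1):
                    kmer = seq[i : i + seed_len]
                    self._index.setdefault(kmer, []).append((label, chrom, i))

    def perfect_hits(self, seq: str) -> list[tuple[str, str, int, str]]:
        """All perfect full-length occurrences as (genome, chrom, pos, strand)."""
        hits = []
        for strand, query in (("+", seq), ("-", revcomp(seq))):
            for label, chrom, i in self._index.get(query[: self.seed_len], ()):
                ref = (self.genomes.seq_a if label == "A" else self.genomes.seq_b)[chrom]
                if ref[i : i + len(query)] == query:
                    hits.append((label, chrom, i, strand))
        return hits


def assign_read(
    read: ReadRecord, index: GenomeIndex, snps: SnpTable
) -> SnpReadAssignment | str:
    """Assign a preprocessed read to a parental genome, or return a rejection reason.

    Acceptance requires a unique perfect hit in exactly one genome, exactly
    one mismatch against the homologous span of the other genome, that
    mismatch sitting on a reported SNP, and exactly one reported SNP under
    the read.
    """
    seq = read.sequence
    if "N" in seq:
        return "no_hit"
    hits = index.perfect_hits(seq)
    if not hits:
        return "no_hit"
    if len(hits) > 1:
        # Perfect in both haplotypes at the same spot means no SNP under the
        # read (zero mismatches to the other genome); anything else is a
        # repeat-induced ambiguity.
        locs = {(chrom, pos, strand) for _, chrom, pos, strand in hits}
        genomes_hit = {label for label, *_ in hits}
        if len(locs) == 1 and genomes_hit == {"A", "B"}:
            return "zero_or_multi_mismatch"
        return "multi_hit"
    label, chrom, pos, strand = hits[0]
    query = seq if strand == "+" else revcomp(seq)
    other = (index.genomes.seq_b if label == "A" else index.genomes.seq_a)[chrom]
    span = other[pos : pos + len(query)]
    mismatches = [i for i, (x, y) in enumerate(zip(query, span)) if x != y]
    snp_positions = snps.positions_in(chrom, pos, pos + len(query))
    if len(mismatches) != 1:
        if len(snp_positions) > 1 and all(
            snps.is_snp(chrom, pos + m) for m in mismatches
        ):
            return "multi_snp"
        return "zero_or_multi_mismatch"
    snp_pos = pos + mismatches[0]
    if not snps.is_snp(chrom, snp_pos):
        return "mismatch_not_snp"
    if len(snp_positions) != 1:
        return "multi_snp"
    allele = label
    maternal_allele = "A" if read.cross_direction == A_MOTHER else "B"
    origin = "maternal" if allele == maternal_allele else "paternal"
    return SnpReadAssignment(read.id, chrom, snp_pos, origin, allele)


def preprocess_and_assign(
    reads: list[ReadRecord],
    index: GenomeIndex,
    snps: SnpTable,
    adaptor: str | None = None,
) -> tuple[list[SnpReadAssignment], Counter]:
    """Run trim -> truncate -> filter -> assign over a read library.

    Returns the assignments and a tally over disposition buckets; every
    input read lands in exactly one bucket (conservation).
    """
    assignments: list[SnpReadAssignment] = []
    tally: Counter = Counter()
    for read in reads:
        seq = read.sequence
        if adaptor:
            seq = trim_adaptor(seq, adaptor)
        if read.tissue == "embryo":
            seq = truncate_embryo(seq)
        keep, reason = filter_read(seq)
        if not keep:
            tally[f"filtered_{reason}"] += 1
            continue
        result = assign_read(
            ReadRecord(read.id, seq, read.tissue, read.cross_direction), index, snps
        )
        if isinstance(result, SnpReadAssignment):
            assignments.append(result)
            tally[ASSIGNED] += 1
        else:
            tally[result] += 1
    return assignments, tally


def aggregate_counts(
    assignments: list[SnpReadAssignment], cross_direction: str, tissue: str
) -> pd.DataFrame:
    """Sum assignments to per-SNP maternal/paternal raw counts for one library."""
    rows: dict[tuple[str, int], list[int]] = {}
    for a in assignments:
        counts = rows.setdefault((a.chrom, a.pos), [0, 0])
        counts[0 if a.origin == "maternal" else 1] += 1
    df = pd.DataFrame(
        [
            {"chrom": chrom, "pos": pos, "r_mat_raw": m, "r_pat_raw": p}
            for (chrom, pos), (m, p) in rows.items()
        ],
        columns=["chrom", "pos", "r_mat_raw", "r_pat_raw"],
    )
    df["cross_direction"] = cross_direction
    df["tissue"] = tissue
    return df.sort_values(["chrom", "pos"]).reset_index(drop=True)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(np.int64)


def normalize_between_crosses(
    tables: dict[str, pd.DataFrame]
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Rescale the two crosses' counts to a common library depth.

    Raw counts are converted to reads per million of the cross's total
    assigned SNP reads, then multiplied by a fixed constant C = mean library
    total / 1e6, which returns integers on the scale of the raw data.  Equal
    library totals therefore leave counts unchanged.
    """
    if set(tables) != set(CROSSES):
        raise ValueError(f"need both crosses {CROSSES}, got {sorted(tables)}")
    totals = {
        cross: int(df["r_mat_raw"].sum() + df["r_pat_raw"].sum())
        for cross, df in tables.items()
    }
    if any(t <= 0 for t in totals.values()):
        raise ValueError(f"zero library total: {totals}")
    mean_total = float(np.mean(list(totals.values())))
    out = {}
    for cross, df in tables.items():
        df = df.copy()
        scale = mean_total / totals[cross]  # == 1e6/total * C
        df["r_mat"] = _round_half_up(df["r_mat_raw"].to_numpy() * scale)
        df["r_pat"] = _round_half_up(df["r_pat_raw"].to_numpy() * scale)
        out[cross] = df
    return out, {"library_totals": totals, "scale_constant": mean_total / 1e6}
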