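"""Synthetic reciprocal-cross data with recorded ground truth.

Emulates the study design the analysis assumes: two subspecies genomes
differing at reported SNPs, gene models with isoforms, and one short-read
library per reciprocal cross per tissue.  Endosperm reads are drawn around a
2 maternal : 1 paternal baseline (triploid tissue), embryo reads around 1:1.
Planted loci carry known truth classes — maternal/paternal imprints,
subspecies-biased alleles, biallelic background, low-coverage loci, and
parent-of-origin splicing loci with maternal-favoured introns and
paternal-favoured exons — so the whole pipeline can be scored for recovery.

Sampling model: each locus draws a per-SNP mean depth from a log-normal
across loci (long-tailed, matching a median around 35 reads per SNP in
endosperm and 59 in embryo), each SNP draws a Poisson read count around that
mean, and each read's parental origin is Bernoulli with a class- and
cross-dependent maternal probability.  Reads are exact substrings of the
originating haplotype; a configurable fraction carries a 3' adaptor suffix
to exercise preprocessing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .counts import ReadRecord, revcomp
from .model import (
    A_MOTHER,
    B_MOTHER,
    CROSSES,
    EMBRYO,
    ENDOSPERM,
    MATERNAL_FRACTION,
    Annotation,
    Gene,
    GenomePair,
    GroundTruthLocus,
    SnpTable,
    Transcript,
)

BASES = np.array(list("ACGT"))
DEFAULT_ADAPTOR = "AGATCGGAAGAGCACACGTCT"  # Illumina TruSeq-like 3' adaptor

TRUTH_CLASSES = (
    "maternal_imprint",
    "paternal_imprint",
    "subspecies_a_bias",
    "subspecies_b_bias",
    "biallelic",
    "low_coverage",
    "poe_splicing",
)


@dataclass
class SimConfig:
    """Study-design parameters for one simulated tissue.

    Defaults mirror the surveyed rice endosperm: 36 bp libraries, one per
    reciprocal cross, subspecies SNP density around one SNP per 200 bp in
    transcribed regions, and a long-tailed per-SNP depth distribution with
    median 35.
    """

    tissue: str = ENDOSPERM
    n_chrom: int = 2
    chrom_len: int = 100_000
    snp_rate: float = 0.005
    read_length: int = 36  # embryo libraries use 75 and are truncated to 36
    snp_depth_median: float = 35.0  # median SNP read depth per cross
    snp_depth_sigma: float = 0.5  # log-normal spread of per-locus mean depth
    class_counts: dict[str, int] = field(
        default_factory=lambda: {
            "maternal_imprint": 4,
            "paternal_imprint": 4,
            "subspecies_a_bias": 3,
            "subspecies_b_bias": 3,
            "biallelic": 20,
            "low_coverage": 3,
            "poe_splicing": 2,
        }
    )
    n_intergenic_maternal: int = 1  # maternal loci planted outside annotation
    bias_level: float = 0.95  # favoured-origin read fraction at planted loci
    low_coverage_depth: float = 3.0  # total SNP reads per cross at low-cov loci
    adaptor: str = DEFAULT_ADAPTOR
    adaptor_fraction: float = 0.05
    overdispersion: float = 0.0  # beta-binomial ICC; 0 = pure binomial
    seed: int = 0

    @property
    def baseline_maternal(self) -> float:
        return MATERNAL_FRACTION[self.tissue]

    def __post_init__(self):
        if self.tissue not in MATERNAL_FRACTION:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if self.tissue == EMBRYO and self.read_length == 36:
            self.read_length = 75


def build_genome_pair(
    n_chrom: int, chrom_len: int, snp_rate: float, seed: int
) -> GenomePair:
    """Two colinear random genomes differing at uniformly placed SNPs.

    SNP placement is unconstrained, so some SNP pairs fall within one read
    length of each other and exercise the exactly-one-SNP read filter.
    """
    if not 0 <= snp_rate < 0.1:
        raise ValueError(f"snp_rate must be in [0, 0.1), got {snp_rate}")
    if chrom_len < 2 * 36:
        raise ValueError(f"chrom_len too short: {chrom_len}")
    rng = np.random.default_rng(seed)
    chrom_names = [f"chr{i + 1}" for i in range(n_chrom)]
    seq_a, seq_b = {}, {}
    records = []
    for chrom in chrom_names:
        a = rng.choice(BASES, size=chrom_len)
        b = a.copy()
        n_snps = rng.binomial(chrom_len, snp_rate)
        positions = np.sort(
            rng.choice(chrom_len, size=n_snps, replace=False)
        )
        for pos in positions:
            ref = a[pos]
            alt = rng.choice(BASES[BASES != ref])
            b[pos] = alt
            records.append((chrom, int(pos), str(ref), str(alt)))
        seq_a[chrom] = "".join(a)
        seq_b[chrom] = "".join(b)
    snps = SnpTable(
        pd.DataFrame(records, columns=SnpTable.COLUMNS)
        if records
        else pd.DataFrame(columns=SnpTable.COLUMNS)
    )
    return GenomePair(chrom_names, seq_a, seq_b, snps)


def build_annotation(genomes: GenomePair, seed: int, isoform_fraction: float = 0.3) -> Annotation:
    """Random gene models tiled along each chromosome.

    Genes of 2-5 exons separated by intergenic gaps; a fraction of genes get
    a second exon-skipping isoform so the isoform-collapsing logic is
    exercised.
    """
    rng = np.random.default_rng(seed)
    genes = []
    gid = 0
    for chrom in genomes.chrom_names:
        length = genomes.chrom_length(chrom)
        cursor = int(rng.integers(300, 1200))
        while True:
            n_exons = int(rng.integers(2, 6))
            exons = []
            pos = cursor
            for i in range(n_exons):
                exon_len = int(rng.integers(150, 400))
                exons.append((pos, pos + exon_len))
                pos += exon_len
                if i < n_exons - 1:
                    pos += int(rng.integers(100, 400))
            if pos >= length - 300:
                break
            gid += 1
            gene_id = f"g{gid:04d}"
            transcripts = [Transcript(f"{gene_id}.1", exons)]
            if len(exons) >= 3 and rng.random() < isoform_fraction:
                skip = int(rng.integers(1, len(exons) - 1))
                alt = [e for i, e in enumerate(exons) if i != skip]
                transcripts.append(Transcript(f"{gene_id}.2", alt))
            genes.append(Gene(gene_id, chrom, exons[0][0], exons[-1][1], transcripts))
            cursor = pos + int(rng.integers(500, 2500))
    return Annotation(genes)


def plant_truth(
    genomes: GenomePair, annotation: Annotation, config: SimConfig, seed: int
) -> list[GroundTruthLocus]:
    """Assign truth classes to genes (and optionally intergenic gaps).

    Loci without any SNP in their span cannot be profiled by SNP reads and
    are marked untestable (with a warning), mirroring real genes that carry
    no subspecies polymorphism.
    """
    rng = np.random.default_rng(seed)
    wanted = dict(config.class_counts)
    n_genic = sum(wanted.values())
    if n_genic > len(annotation.genes):
        raise ValueError(
            f"{n_genic} truth loci requested but only {len(annotation.genes)} genes"
        )
    # POE-splicing loci need SNPs in both exons and introns to be observable;
    # reserve eligible genes for them first.
    n_poe = wanted.get("poe_splicing", 0)
    eligible = [
        i
        for i, g in enumerate(annotation.genes)
        if any(
            len(genomes.snps.positions_in(g.chrom, s, e)) > 0 for s, e in g.exon_union()
        )
        and any(
            len(genomes.snps.positions_in(g.chrom, s, e)) > 0 for s, e in g.intron_union()
        )
    ]
    if n_poe > len(eligible):
        raise ValueError(
            f"{n_poe} poe_splicing loci requested but only {len(eligible)} genes "
            "have SNPs in both exons and introns"
        )
    poe_idx = list(rng.permutation(eligible)[:n_poe])
    rest = [i for i in rng.permutation(len(annotation.genes)) if i not in set(poe_idx)]
    other_labels = [
        c for c, n in wanted.items() if c != "poe_splicing" for _ in range(n)
    ]
    order = poe_idx + rest[: len(other_labels)]
    labels = ["poe_splicing"] * n_poe + other_labels
    truth = []
    for idx, truth_class in zip(order, labels):
        gene = annotation.genes[int(idx)]
        depth = _locus_depth(gene, genomes, config, rng)
        locus = GroundTruthLocus(
            feature_id=gene.id,
            chrom=gene.chrom,
            start=gene.start,
            end=gene.end,
            truth_class=truth_class,
            bias_level=(
                config.baseline_maternal if truth_class in ("biallelic", "low_coverage")
                else config.bias_level
            ),
            mean_depth=(
                config.low_coverage_depth if truth_class == "low_coverage" else depth
            ),
            sub_feature_truth=(
                {"intron": "maternal_imprint", "exon": "paternal_imprint"}
                if truth_class == "poe_splicing"
                else None
            ),
        )
        n_snps = len(genomes.snps.positions_in(gene.chrom, gene.start, gene.end))
        if n_snps == 0:
            warnings.warn(f"truth locus {gene.id} contains no SNP; untestable")
            locus.testable = False
        truth.append(locus)
    truth.extend(_plant_intergenic(genomes, annotation, config, rng))
    return truth


def _locus_depth(gene: Gene, genomes: GenomePair, config: SimConfig, rng) -> float:
    """Expected SNP reads per cross for a locus: log-normal mean x SNP count."""
    n_snps = max(1, len(genomes.snps.positions_in(gene.chrom, gene.start, gene.end)))
    per_snp = config.snp_depth_median * float(
        np.exp(rng.normal(0.0, config.snp_depth_sigma))
    )
    return per_snp * n_snps


def _plant_intergenic(genomes, annotation, config, rng) -> list[GroundTruthLocus]:
    out = []
    by_chrom = annotation.by_chrom()
    candidates = []
    for chrom in genomes.chrom_names:
        genes = by_chrom.get(chrom, [])
        prev_end = 0
        for g in genes:
            if g.start - prev_end >= 1500:
                candidates.append((chrom, prev_end + 200, g.start - 200))
            prev_end = max(prev_end, g.end)
    rng.shuffle(candidates)
    for i, (chrom, start, end) in enumerate(candidates[: config.n_intergenic_maternal]):
        end = min(end, start + 1000)
        locus = GroundTruthLocus(
            feature_id=f"ig{i + 1:03d}",
            chrom=chrom,
            start=start,
            end=end,
            truth_class="maternal_imprint",
            bias_level=config.bias_level,
            mean_depth=config.snp_depth_median
            * max(1, len(genomes.snps.positions_in(chrom, start, end))),
        )
        if len(genomes.snps.positions_in(chrom, start, end)) == 0:
            warnings.warn(f"truth locus {locus.feature_id} contains no SNP; untestable")
            locus.testable = False
        out.append(locus)
    return out


def maternal_probability(
    truth_class: str, bias_level: float, baseline: float, cross_direction: str
) -> float:
    """Per-read probability that the maternal allele is sampled.

    Imprint classes favour a parental origin regardless of cross; subspecies
    classes favour a fixed ALLELE, so the maternal probability flips between
    the reciprocal crosses.
    """
    if truth_class == "maternal_imprint":
        return bias_level
    if truth_class == "paternal_imprint":
        return 1.0 - bias_level
    if truth_class == "subspecies_a_bias":
        return bias_level if cross_direction == A_MOTHER else 1.0 - bias_level
    if truth_class == "subspecies_b_bias":
        return bias_level if cross_direction == B_MOTHER else 1.0 - bias_level
    if truth_class in ("biallelic", "low_coverage"):
        return baseline
    raise ValueError(f"no single maternal probability for class {truth_class!r}")


def _sample_p(rng, p: float, rho: float) -> float:
    """Optionally overdispersed per-locus success probability."""
    if rho <= 0 or p in (0.0, 1.0):
        return p
    nu = (1.0 - rho) / rho
    return float(rng.beta(p * nu, (1.0 - p) * nu))


def simulate_cross_reads(
    genomes: GenomePair,
    annotation: Annotation,
    truth: list[GroundTruthLocus],
    config: SimConfig,
    cross_direction: str,
    seed: int,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Simulate one cross's read library plus its per-locus expectations.

    Every emitted read is an exact substring (either strand) of the
    haplotype it originated from, positioned so that it covers the sampled
    SNP.  Read ids record locus, origin and allele, providing the oracle
    labels for assignment-accuracy tests.
    """
    if cross_direction not in CROSSES:
        raise ValueError(f"unknown cross {cross_direction!r}")
    rng = np.random.default_rng(seed)
    maternal_allele = "A" if cross_direction == A_MOTHER else "B"
    reads: list[ReadRecord] = []
    expected = []
    counter = 0
    for locus in truth:
        snp_pos = genomes.snps.positions_in(locus.chrom, locus.start, locus.end)
        if len(snp_pos) == 0:
            continue
        per_snp_mean = locus.mean_depth / len(snp_pos)
        if locus.truth_class == "poe_splicing":
            groups = _poe_snp_groups(locus, annotation, snp_pos)
        else:
            p = _sample_p(
                rng,
                maternal_probability(
                    locus.truth_class, locus.bias_level,
                    config.baseline_maternal, cross_direction,
                ),
                config.overdispersion,
            )
            groups = [(snp_pos, p, locus.truth_class)]
        exp_mat = 0.0
        exp_total = 0.0
        for positions, p_mat_class, sub_class in groups:
            if sub_class == "maternal_imprint" and locus.truth_class == "poe_splicing":
                p_mat = locus.bias_level
            elif sub_class == "paternal_imprint" and locus.truth_class == "poe_splicing":
                p_mat = 1.0 - locus.bias_level
            else:
                p_mat = p_mat_class
            for pos in positions:
                depth = rng.poisson(per_snp_mean)
                exp_mat += per_snp_mean * p_mat
                exp_total += per_snp_mean
                for _ in range(depth):
                    counter += 1
                    is_mat = rng.random() < p_mat
                    allele = (
                        maternal_allele
                        if is_mat
                        else ("B" if maternal_allele == "A" else "A")
                    )
                    seq = _draw_read(genomes, locus.chrom, int(pos), allele, config, rng)
                    origin = "maternal" if is_mat else "paternal"
                    reads.append(
                        ReadRecord(
                            id=f"r{counter:07d}|{locus.feature_id}|{origin}|{allele}",
                            sequence=seq,
                            tissue=config.tissue,
                            cross_direction=cross_direction,
                        )
                    )
        expected.append(
            {
                "feature_id": locus.feature_id,
                "cross_direction": cross_direction,
                "expected_total": exp_total,
                "expected_maternal": exp_mat,
            }
        )
    return reads, pd.DataFrame(expected)


def _poe_snp_groups(locus, annotation, snp_pos):
    """Split a POE-splicing locus's SNPs into exonic and intronic groups."""
    gene = next(g for g in annotation.genes if g.id == locus.feature_id)
    exon_iv = gene.exon_union()
    in_exon = np.array(
        [any(s <= p < e for s, e in exon_iv) for p in snp_pos], dtype=bool
    )
    truth = locus.sub_feature_truth or {}
    return [
        (snp_pos[in_exon], np.nan, truth.get("exon", "paternal_imprint")),
        (snp_pos[~in_exon], np.nan, truth.get("intron", "maternal_imprint")),
    ]


def _draw_read(genomes, chrom, snp_pos, allele, config, rng) -> str:
    """An exact read covering `snp_pos` from the chosen haplotype.

    With probability `adaptor_fraction`, the genomic insert is shortened and
    padded to full read length with the 3' adaptor (the insert still covers
    the SNP so trimming recovers an assignable read).
    """
    seq = (genomes.seq_a if allele == "A" else genomes.seq_b)[chrom]
    length = config.read_length
    insert_len = length
    if config.adaptor and rng.random() < config.adaptor_fraction:
        insert_len = int(rng.integers(22, length - len(config.adaptor) // 2))
    lo = max(0, snp_pos - insert_len + 1)
    hi = min(snp_pos, len(seq) - insert_len)
    start = int(rng.integers(lo, hi + 1)) if hi >= lo else lo
    insert = seq[start : start + insert_len]
    if insert_len < length:
        read = insert + config.adaptor[: length - insert_len]
    else:
        read = insert
    if rng.random() < 0.5:
        # adaptored reads stay forward: the adaptor is a sequencing artefact
        # appended after the (possibly reverse-complemented) insert
        if insert_len == length:
            read = revcomp(read)
        else:
            read = revcomp(insert) + config.adaptor[: length - insert_len]
    return read


def simulate_locus_counts(
    truth: list[GroundTruthLocus], config: SimConfig, seed: int
) -> pd.DataFrame:
    """Per-locus allelic counts for both crosses, skipping read generation.

    The counts-level entry point: each locus/cross draws a Poisson total
    around its mean depth and a binomial (optionally beta-binomial) maternal
    count.  Used for large simulations where individual reads add nothing.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for locus in truth:
        for cross in CROSSES:
            if locus.truth_class == "poe_splicing":
                specs = [
                    ("exon", (locus.sub_feature_truth or {}).get("exon", "paternal_imprint")),
                    ("intron", (locus.sub_feature_truth or {}).get("intron", "maternal_imprint")),
                ]
            else:
                specs = [(None, locus.truth_class)]
            for sub, cls in specs:
                p = _sample_p(
                    rng,
                    maternal_probability(
                        cls, locus.bias_level, config.baseline_maternal, cross
                    ),
                    config.overdispersion,
                )
                total = rng.poisson(locus.mean_depth)
                r_mat = rng.binomial(total, p) if total > 0 else 0
                rows.append(
                    {
                        "feature_id": (
                            locus.feature_id if sub is None else f"{locus.feature_id}:{sub}"
                        ),
                        "sub_feature": sub or "",
                        "truth_class": locus.truth_class,
                        "cross_direction": cross,
                        "tissue": config.tissue,
                        "r_mat_raw": int(r_mat),
                        "r_pat_raw": int(total - r_mat),
                    }
                )
    return pd.DataFrame(rows)


def truth_table(truth: list[GroundTruthLocus]) -> pd.DataFrame:
    rows = []
    for t in truth:
        rows.append(
            {
                "feature_id": t.feature_id,
                "chrom": t.chrom,
                "start": t.start,
                "end": t.end,
                "truth_class": t.truth_class,
                "bias_level": t.bias_level,
                "mean_depth": t.mean_depth,
                "sub_feature_truth": (
                    ";".join(f"{k}={v}" for k, v in sorted(t.sub_feature_truth.items()))
                    if t.sub_feature_truth
                    else ""
                ),
                "testable": t.testable,
            }
        )
    return pd.DataFrame(rows)


def truth_from_table(df: pd.DataFrame) -> list[GroundTruthLocus]:
    out = []
    for r in df.itertuples(index=False):
        sub = None
        if r.sub_feature_truth:
            sub = dict(kv.split("=") for kv in str(r.sub_feature_truth).split(";"))
        out.append(
            GroundTruthLocus(
                feature_id=r.feature_id,
                chrom=r.chrom,
                start=int(r.start),
                end=int(r.end),
                truth_class=r.truth_class,
                bias_level=float(r.bias_level),
                mean_depth=float(r.mean_depth),
                sub_feature_truth=sub,
                testable=bool(r.testable),
            )
        )
    return out


def make_bundle(config: SimConfig):
    """Genomes, annotation, truth and reads for both crosses, in memory."""
    root = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(5)]
    genomes = build_genome_pair(config.n_chrom, config.chrom_len, config.snp_rate, seeds[0])
    annotation = build_annotation(genomes, seeds[1])
    truth = plant_truth(genomes, annotation, config, seeds[2])
    reads = {}
    expected = []
    for cross, seed in zip(CROSSES, seeds[3:5]):
        reads[cross], exp = simulate_cross_reads(
            genomes, annotation, truth, config, cross, seed
        )
        expected.append(exp)
    return genomes, annotation, truth, reads, pd.concat(expected, ignore_index=True)


def emit_fixture_bundle(config: SimConfig, outdir) -> dict:
    """Write a complete simulated input bundle to disk.

    FASTA genomes, SNP TSV and minimal VCF, GFF3 annotation, per-cross
    FASTA read files, the truth table, and the per-locus expected counts;
    all re-readable by the io module.  Returns the path map.
    """
    from pathlib import Path

    from . import io as iomod

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genomes, annotation, truth, reads, expected = make_bundle(config)
    paths = {
        "genome_a": outdir / "genome_a.fasta",
        "genome_b": outdir / "genome_b.fasta",
        "snps_tsv": outdir / "snps.tsv",
        "snps_vcf": outdir / "snps.vcf",
        "annotation": outdir / "annotation.gff3",
        "truth": outdir / "truth.tsv",
        "expected": outdir / "expected_counts.tsv",
    }
    iomod.write_fasta(paths["genome_a"], genomes.seq_a)
    iomod.write_fasta(paths["genome_b"], genomes.seq_b)
    iomod.write_snp_tsv(paths["snps_tsv"], genomes.snps)
    iomod.write_snp_vcf(paths["snps_vcf"], genomes.snps, genomes.chrom_lengths)
    iomod.write_gff3(paths["annotation"], annotation)
    truth_table(truth).to_csv(paths["truth"], sep="\t", index=False)
    expected.to_csv(paths["expected"], sep="\t", index=False)
    for cross, readlist in reads.items():
        p = outdir / f"reads_{config.tissue}_{cross}.fasta"
        iomod.write_reads_fasta(p, readlist)
        paths[f"reads_{cross}"] = p
    return paths
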