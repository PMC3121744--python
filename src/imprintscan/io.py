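"""File formats for the pipeline.

External coordinates follow each format's convention — 1-based inclusive in
the SNP TSV, VCF and GFF3, 0-based half-open in BED — and are converted to
the package-internal 0-based half-open representation at this boundary.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .counts import ReadRecord
from .model import Annotation, Gene, GenomePair, SnpTable, Transcript


# ---------------------------------------------------------------- FASTA/FASTQ

def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_reads_fasta(path, reads: list[ReadRecord]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in reads),
        str(path),
        "fasta",
    )


def write_reads_fastq(path, reads: list[ReadRecord]) -> None:
    """FASTQ export with uniform placeholder qualities."""
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(r.sequence)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_reads(path, tissue: str, cross_direction: str) -> list[ReadRecord]:
    fmt = "fastq" if str(path).endswith(("fastq", "fq")) else "fasta"
    return [
        ReadRecord(rec.id, str(rec.seq).upper(), tissue, cross_direction)
        for rec in SeqIO.parse(str(path), fmt)
    ]


# ------------------------------------------------------------------ SNP table

def write_snp_tsv(path, snps: SnpTable) -> None:
    df = snps.df.copy()
    df["pos"] = df["pos"] + 1  # 1-based in the file
    df.to_csv(path, sep="\t", index=False)


def read_snp_tsv(path) -> SnpTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(SnpTable.COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing SNP columns {sorted(missing)}")
    df["pos"] = df["pos"].astype(int) - 1
    return SnpTable(df)


def write_snp_vcf(path, snps: SnpTable, chrom_lengths: dict[str, int]) -> None:
    """Minimal VCF 4.2 with subspecies A as REF and B as ALT."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in sorted(chrom_lengths.items()):
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in snps.df.itertuples(index=False):
            fh.write(
                f"{r.chrom}\t{r.pos + 1}\t.\t{r.allele_a}\t{r.allele_b}\t.\t.\t.\n"
            )


def read_snp_vcf(path) -> SnpTable:
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if not rec.alts or len(rec.alts) != 1:
                raise ValueError(f"{path}: non-biallelic record at {rec.chrom}:{rec.pos}")
            rows.append((rec.chrom, rec.pos - 1, rec.ref, rec.alts[0]))
    return SnpTable(pd.DataFrame(rows, columns=SnpTable.COLUMNS))


def load_genome_pair(fasta_a, fasta_b, snp_path) -> GenomePair:
    seq_a = read_fasta(fasta_a)
    seq_b = read_fasta(fasta_b)
    if set(seq_a) != set(seq_b):
        raise ValueError("parental genomes name different chromosomes")
    snps = (
        read_snp_vcf(snp_path)
        if str(snp_path).endswith(".vcf")
        else read_snp_tsv(snp_path)
    )
    return GenomePair(sorted(seq_a), seq_a, seq_b, snps)


# ---------------------------------------------------------------------- GFF3

def write_gff3(path, annotation: Annotation) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation.genes:
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t+\t.\tID={g.id}\n"
            )
            for t in g.transcripts:
                fh.write(
                    f"{g.chrom}\tsim\tmRNA\t{t.start + 1}\t{t.end}\t.\t+\t.\t"
                    f"ID={t.id};Parent={g.id}\n"
                )
                for i, (s, e) in enumerate(t.exons, 1):
                    fh.write(
                        f"{g.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t+\t.\t"
                        f"ID={t.id}.exon{i};Parent={t.id}\n"
                    )


def read_gff3(path) -> Annotation:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene"):
        transcripts = []
        for t in db.children(g, featuretype="mRNA", order_by="start"):
            exons = [
                (e.start - 1, e.end)
                for e in db.children(t, featuretype="exon", order_by="start")
            ]
            if not exons:
                raise ValueError(f"{path}: mRNA {t.id} has no exons")
            transcripts.append(Transcript(t.id, exons))
        genes.append(Gene(g.id, g.seqid, g.start - 1, g.end, transcripts))
    return Annotation(genes)


# ----------------------------------------------------------------------- BED

def write_bed(path, intervals: list[tuple[str, int, int, str]]) -> None:
    """BED4: (chrom, start, end, name), 0-based half-open as internal."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            rows.append(
                {
                    "chrom": parts[0],
                    "start": int(parts[1]),
                    "end": int(parts[2]),
                    "name": parts[3] if len(parts) > 3 else "",
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


# ----------------------------------------------------------------- count TSV

COUNT_COLUMNS = ["chrom", "pos", "cross_direction", "tissue", "r_mat_raw", "r_pat_raw"]


def write_count_tsv(path, tables: dict[str, pd.DataFrame]) -> None:
    """Per-SNP raw allelic counts for both crosses (pos written 1-based)."""
    frames = []
    for df in tables.values():
        out = df.loc[:, COUNT_COLUMNS].copy()
        out["pos"] = out["pos"] + 1
        frames.append(out)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_count_tsv(path) -> dict[str, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing count columns {sorted(missing)}")
    df["pos"] = df["pos"].astype(int) - 1
    return {
        cross: sub.reset_index(drop=True)
        for cross, sub in df.groupby("cross_direction")
    }


# ---------------------------------------------------------------------- JSON

def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
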