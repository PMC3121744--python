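"""Orchestration: configuration, the end-to-end run, and reports.

The pipeline runs preprocess -> assign -> normalize -> window scan +
feature scan -> classification -> splicing screen -> downstream
characterization, logging every parameter and conservation check, and
writes candidate tables (full and the strong-bias subset), a BED of
significant windows, and a JSON summary of all tallies.  A counts-only
entry point skips read assignment so any upstream aligner can feed the
statistics.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import counts as counts_mod
from . import downstream as down_mod
from . import io as iomod
from . import scans as scans_mod
from .model import (
    CROSSES,
    ENDOSPERM,
    IMPRINT_CLASSES,
    MATERNAL_FRACTION,
    SUBSPECIES_CLASSES,
)
from .stats import MIN_READS, SIGNIFICANCE_NEGLOG10P

log = logging.getLogger("imprintscan")


@dataclass
class RunConfig:
    """Everything a reproducible run needs; round-trips through YAML."""

    genome_a: str = ""
    genome_b: str = ""
    snps: str = ""
    annotation: str = ""
    reads_a_mother: str = ""
    reads_b_mother: str = ""
    counts: str = ""  # counts-only entry point (skips read assignment)
    truth: str = ""  # optional simulation truth for recovery scoring
    repeats: str = ""  # optional repeat/transposon BED
    go_map: str = ""  # optional gene_id<TAB>term TSV
    tissue: str = ENDOSPERM
    adaptor: str = ""
    min_reads: int = MIN_READS
    neglog10p: float = SIGNIFICANCE_NEGLOG10P
    strong_bias: float = 0.9
    window_width: int = 1000
    window_step: int = 500
    seed: int = 0
    outdir: str = "imprintscan_out"

    def __post_init__(self):
        if self.tissue not in MATERNAL_FRACTION:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if self.min_reads <= 0 or self.neglog10p <= 0 or self.strong_bias <= 0:
            raise ValueError("thresholds must be positive")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    @property
    def expected_maternal_fraction(self) -> float:
        return MATERNAL_FRACTION[self.tissue]


class StageError(RuntimeError):
    """A pipeline stage failed; the message carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[stage {stage}] {cause}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - tag and re-raise
                raise StageError(name, exc) from exc

        return wrapped

    return deco


@_stage("load")
def _load_inputs(config: RunConfig):
    genomes = iomod.load_genome_pair(config.genome_a, config.genome_b, config.snps)
    annotation = iomod.read_gff3(config.annotation)
    return genomes, annotation


@_stage("assign")
def _assign(config: RunConfig, genomes):
    index = counts_mod.GenomeIndex(genomes)
    tables, tallies = {}, {}
    read_paths = {"A_mother": config.reads_a_mother, "B_mother": config.reads_b_mother}
    for cross in CROSSES:
        reads = iomod.read_reads(read_paths[cross], config.tissue, cross)
        assignments, tally = counts_mod.preprocess_and_assign(
            reads, index, genomes.snps, adaptor=config.adaptor or None
        )
        n_binned = sum(tally.values())
        if n_binned != len(reads):
            raise RuntimeError(
                f"{cross}: {len(reads)} reads but {n_binned} dispositions"
            )
        tables[cross] = counts_mod.aggregate_counts(assignments, cross, config.tissue)
        tallies[cross] = dict(tally)
        log.info("%s: %s", cross, dict(tally))
    return tables, tallies


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write all outputs under config.outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("run config: %s", dataclasses.asdict(config))

    genomes, annotation = _load_inputs(config)
    chrom_lengths = genomes.chrom_lengths

    if config.counts:
        raw_tables = iomod.read_count_tsv(config.counts)
        tallies = {cross: {"assigned": int((t["r_mat_raw"] + t["r_pat_raw"]).sum())}
                   for cross, t in raw_tables.items()}
    else:
        raw_tables, tallies = _assign(config, genomes)

    norm_tables, norm_info = counts_mod.normalize_between_crosses(raw_tables)
    log.info("normalization: %s", norm_info)

    windows = scans_mod.tile_windows(
        chrom_lengths, config.window_width, config.window_step
    )
    windows = scans_mod.window_scan(
        windows, norm_tables, config.tissue, config.min_reads, config.neglog10p
    )
    units = scans_mod.feature_scan(
        annotation, norm_tables, config.tissue, chrom_lengths,
        config.min_reads, config.neglog10p,
    )
    partition = scans_mod.partition_totals(annotation, norm_tables, chrom_lengths)
    if partition["exon_union"] + partition["intron"] + partition["intergenic"] != partition["total"]:
        raise StageError("conservation", RuntimeError(f"partition leak: {partition}"))
    log.info("partition conservation: %s", partition)

    overlap = scans_mod.reconcile(windows, units, annotation)
    splicing = scans_mod.poe_splicing_scan(units, windows, annotation)

    feature_table = features_to_frame(units)
    feature_table.to_csv(outdir / "feature_calls.tsv", sep="\t", index=False)
    strong = feature_table[
        feature_table["call"].isin(IMPRINT_CLASSES)
        & (feature_table["combined_bias"] >= config.strong_bias)
    ]
    strong.to_csv(outdir / "feature_calls_strong.tsv", sep="\t", index=False)
    sig_w = scans_mod.significant_windows(windows)
    iomod.write_bed(
        outdir / "significant_windows.bed",
        [(w.chrom, w.start, w.end, w.call.call) for w in sig_w],
    )

    report = {
        "config": dataclasses.asdict(config),
        "read_tallies": tallies,
        "normalization": norm_info,
        "partition": partition,
        "n_windows": len(windows),
        "n_significant_windows": len(sig_w),
        "window_label_counts": overlap["window_label_counts"],
        "n_feature_units": len(units),
        "call_counts": feature_table["call"].value_counts().to_dict(),
        "n_strong_candidates": int(len(strong)),
        "splicing_candidates": [c.summary() for c in splicing],
        "reconcile": {
            k: overlap[k]
            for k in (
                "n_significant_features",
                "feature_only_candidates",
                "direction_counts",
            )
        },
    }

    report["downstream"] = _downstream(config, genomes, annotation, units, sig_w)

    if config.truth:
        from .synthetic import truth_from_table

        truth = truth_from_table(pd.read_csv(config.truth, sep="\t", keep_default_na=False))
        report["recovery"] = recovery_summary(truth, units, splicing)

    iomod.write_json(outdir / "summary.json", report)
    return report


@_stage("downstream")
def _downstream(config, genomes, annotation, units, sig_w):
    imprinted_genes = sorted(
        {
            u.gene_id
            for u in units
            if u.gene_id and u.call and u.call.call in IMPRINT_CLASSES
        }
    )
    mids: dict[str, list[float]] = {}
    for w in sig_w:
        mids.setdefault(w.chrom, []).append(w.midpoint)
    cluster = down_mod.cluster_stats(mids, imprinted_genes, annotation)
    out = {
        "imprinted_genes": imprinted_genes,
        "median_nn_distance": cluster.median_nn_distance,
        "n_within_10kb": cluster.n_within_10kb,
        "fraction_within_10kb": cluster.fraction_within_10kb,
        "micro_clusters": cluster.micro_clusters,
    }
    candidate_seqs = []
    background_seqs = []
    gene_by_id = {g.id: g for g in annotation.genes}
    expressed = {
        u.gene_id
        for u in units
        if u.gene_id
        and u.call
        and all(u.counts[c][0] + u.counts[c][1] >= config.min_reads for c in CROSSES)
    }
    for gid in expressed:
        g = gene_by_id[gid]
        seq = genomes.seq_a[g.chrom][g.start : g.end]
        (candidate_seqs if gid in imprinted_genes else background_seqs).append(seq)
    if candidate_seqs and background_seqs:
        out["gc"] = down_mod.gc_comparison(
            candidate_seqs, candidate_seqs + background_seqs
        )
    if config.repeats and imprinted_genes:
        repeats = iomod.read_bed(config.repeats).rename(columns={"name": "repeat_class"})
        out["repeat_proximity"] = down_mod.repeat_proximity(
            imprinted_genes, annotation.genes, repeats, seed=config.seed
        )
    if config.go_map and imprinted_genes:
        term_map = pd.read_csv(config.go_map, sep="\t", names=["gene_id", "term"])
        background = sorted(expressed | set(imprinted_genes))
        results = down_mod.go_enrichment(imprinted_genes, background, term_map)
        out["go_enrichment"] = [dataclasses.asdict(r) for r in results[:20]]
    return out


def classify_count_frame(
    df: pd.DataFrame,
    tissue: str,
    min_reads: int = MIN_READS,
    threshold: float = SIGNIFICANCE_NEGLOG10P,
    normalize: bool = True,
) -> pd.DataFrame:
    """Classify a per-feature allelic count table (both crosses).

    `df` columns: feature_id, cross_direction, r_mat_raw, r_pat_raw.  When
    `normalize` is set, the two crosses are first rescaled to a common
    library depth.  Returns one row per feature with the combined call.
    """
    from .stats import BiasTest, classify_feature

    tables = {
        cross: sub.reset_index(drop=True)
        for cross, sub in df.groupby("cross_direction")
    }
    if normalize:
        tables, _ = counts_mod.normalize_between_crosses(tables)
    else:
        tables = {
            c: t.assign(r_mat=t["r_mat_raw"], r_pat=t["r_pat_raw"])
            for c, t in tables.items()
        }
    merged = pd.merge(
        tables[CROSSES[0]][["feature_id", "r_mat", "r_pat"]],
        tables[CROSSES[1]][["feature_id", "r_mat", "r_pat"]],
        on="feature_id",
        how="outer",
        suffixes=("_a", "_b"),
    ).fillna(0)
    rows = []
    for r in merged.itertuples(index=False):
        call = classify_feature(
            BiasTest(int(r.r_mat_a), int(r.r_pat_a), tissue, CROSSES[0]),
            BiasTest(int(r.r_mat_b), int(r.r_pat_b), tissue, CROSSES[1]),
            feature_id=r.feature_id,
            min_reads=min_reads,
            threshold=threshold,
        )
        rows.append(
            {
                "feature_id": r.feature_id,
                "call": call.call,
                "combined_bias": call.combined_bias,
                "combined_neglog10p": call.combined_neglog10p,
            }
        )
    return pd.DataFrame(rows)


def features_to_frame(units) -> pd.DataFrame:
    rows = []
    for u in units:
        c = u.call
        ta, tb = c.test_a_mother, c.test_b_mother
        rows.append(
            {
                "feature_id": u.id,
                "kind": u.kind,
                "gene_id": u.gene_id or "",
                "chrom": u.chrom,
                "start": u.start,
                "end": u.end,
                "ambiguous": u.ambiguous,
                "call": c.call,
                "combined_bias": c.combined_bias,
                "combined_neglog10p": c.combined_neglog10p,
                "r_mat_A_mother": ta.r_mat,
                "r_pat_A_mother": ta.r_pat,
                "neglog10p_A_mother": ta.neglog10p,
                "r_mat_B_mother": tb.r_mat,
                "r_pat_B_mother": tb.r_pat,
                "neglog10p_B_mother": tb.neglog10p,
            }
        )
    return pd.DataFrame(rows)


def recovery_summary(truth, units, splicing_candidates) -> dict:
    """Score calls against planted truth: per-class sensitivity + leakage.

    A genic truth locus is recovered when any unit of its gene carries the
    planted call; intergenic loci are matched by interval overlap with
    called intergenic units.
    """
    units_by_gene: dict[str, list] = {}
    intergenic_units = []
    for u in units:
        if u.gene_id:
            units_by_gene.setdefault(u.gene_id, []).append(u)
        elif u.kind == "intergenic":
            intergenic_units.append(u)
    splice_genes = {c.gene_id for c in splicing_candidates}

    per_class: dict[str, dict[str, int]] = {}
    false_calls = {"subspecies_called_imprinted": 0, "biallelic_called_imprinted": 0}
    for t in truth:
        if not t.testable:
            continue
        stats = per_class.setdefault(t.truth_class, {"n": 0, "recovered": 0})
        stats["n"] += 1
        calls = _locus_calls(t, units_by_gene, intergenic_units)
        if t.truth_class in IMPRINT_CLASSES:
            if t.truth_class in calls:
                stats["recovered"] += 1
        elif t.truth_class in SUBSPECIES_CLASSES:
            if t.truth_class in calls:
                stats["recovered"] += 1
            if calls & set(IMPRINT_CLASSES):
                false_calls["subspecies_called_imprinted"] += 1
        elif t.truth_class == "poe_splicing":
            if t.feature_id in splice_genes:
                stats["recovered"] += 1
        elif t.truth_class in ("biallelic", "low_coverage"):
            if calls & set(IMPRINT_CLASSES):
                if t.truth_class == "biallelic":
                    false_calls["biallelic_called_imprinted"] += 1
            else:
                stats["recovered"] += 1  # correctly left uncalled
    out = {
        cls: {
            **v,
            "sensitivity": (v["recovered"] / v["n"]) if v["n"] else float("nan"),
        }
        for cls, v in per_class.items()
    }
    out["false_calls"] = false_calls
    return out


def _locus_calls(t, units_by_gene, intergenic_units) -> set[str]:
    calls = set()
    for u in units_by_gene.get(t.feature_id, []):
        if u.call:
            calls.add(u.call.call)
    if not calls:
        for u in intergenic_units:
            if u.chrom == t.chrom and u.call and any(
                s < t.end and t.start < e for s, e in u.intervals
            ):
                calls.add(u.call.call)
    return calls
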