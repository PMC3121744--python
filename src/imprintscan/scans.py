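"""Genome-wide application of the bias statistics.

Two redundant strategies, as in the survey design: overlapping 1 kb physical
windows stepped every 0.5 kb across the genome (annotation-free), and
annotated features — each transcript isoform independently, per-gene intron
regions, and intergenic intervals.  A read participates through its SNP
position (a single point), so each SNP read lands in exactly two interior
windows and exactly one partition class (exon-union > intron > intergenic),
giving an exact conservation check.  A reconciliation step labels each
significant window by its overlap with the feature analysis, and a final
screen flags genes whose sub-features carry opposite parental calls —
candidate parent-of-origin alternative splicing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    CROSSES,
    IMPRINT_CLASSES,
    MATERNAL_IMPRINT,
    PATERNAL_IMPRINT,
    Annotation,
    complement_intervals,
    merge_intervals,
)
from .stats import MIN_READS, SIGNIFICANCE_NEGLOG10P, BiasTest, ImprintCall, classify_feature

WINDOW_WIDTH = 1000
WINDOW_STEP = 500
INTERGENIC_UNIT_MAX = 10_000


@dataclass
class Window:
    chrom: str
    start: int
    end: int
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    call: ImprintCall | None = None

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class FeatureUnit:
    id: str
    kind: str  # cdna_isoform | intron | intergenic
    chrom: str
    intervals: list[tuple[int, int]]
    gene_id: str | None = None
    ambiguous: bool = False
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    call: ImprintCall | None = None

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        return self.intervals[-1][1]


@dataclass
class SplicingCandidate:
    gene_id: str
    maternal_parts: list[str]
    paternal_parts: list[str]

    def summary(self) -> str:
        return (
            f"{self.gene_id}: maternal={','.join(self.maternal_parts)}"
            f" paternal={','.join(self.paternal_parts)}"
        )


def tile_windows(
    chrom_lengths: dict[str, int],
    width: int = WINDOW_WIDTH,
    step: int = WINDOW_STEP,
) -> list[Window]:
    """Overlapping windows of `width` every `step` along each chromosome.

    The last window absorbs the chromosome tail: a start is only opened
    while at least `step` bases remain, so no window shorter than `step`
    is created and the final window ends at the chromosome end.
    """
    windows = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        if length < 1:
            raise ValueError(f"{chrom}: non-positive length")
        starts = [0] + [s for s in range(step, length, step) if s + step < length]
        for s in starts:
            windows.append(Window(chrom, s, min(s + width, length)))
        if windows and windows[-1].chrom == chrom:
            windows[-1].end = length
    return windows


class _SnpCounts:
    """Per-chromosome sorted arrays of normalized SNP counts for one cross."""

    def __init__(self, table: pd.DataFrame):
        self.by_chrom = {}
        for chrom, sub in table.groupby("chrom", sort=True):
            sub = sub.sort_values("pos")
            self.by_chrom[chrom] = (
                sub["pos"].to_numpy(),
                sub["r_mat"].to_numpy(),
                sub["r_pat"].to_numpy(),
            )

    def sum_in(self, chrom: str, intervals: list[tuple[int, int]]) -> tuple[int, int]:
        if chrom not in self.by_chrom:
            return 0, 0
        pos, mat, pat = self.by_chrom[chrom]
        m = p = 0
        for s, e in intervals:
            lo, hi = np.searchsorted(pos, [s, e])
            m += int(mat[lo:hi].sum())
            p += int(pat[lo:hi].sum())
        return m, p

    def snp_support(self, chrom: str, intervals: list[tuple[int, int]]) -> tuple:
        """Hashable per-SNP (pos, mat, pat) support inside the intervals."""
        if chrom not in self.by_chrom:
            return ()
        pos, mat, pat = self.by_chrom[chrom]
        out = []
        for s, e in intervals:
            lo, hi = np.searchsorted(pos, [s, e])
            out.extend(zip(pos[lo:hi].tolist(), mat[lo:hi].tolist(), pat[lo:hi].tolist()))
        return tuple(sorted(out))


def _classify(
    unit_id: str, counts: dict[str, tuple[int, int]], tissue: str,
    min_reads: int, threshold: float,
) -> ImprintCall:
    tests = {
        cross: BiasTest(counts[cross][0], counts[cross][1], tissue, cross)
        for cross in CROSSES
    }
    return classify_feature(
        tests[CROSSES[0]], tests[CROSSES[1]], feature_id=unit_id,
        min_reads=min_reads, threshold=threshold,
    )


def window_scan(
    windows: list[Window],
    tables: dict[str, pd.DataFrame],
    tissue: str,
    min_reads: int = MIN_READS,
    threshold: float = SIGNIFICANCE_NEGLOG10P,
) -> list[Window]:
    """Sum normalized SNP counts into each window and classify it."""
    counts = {cross: _SnpCounts(tables[cross]) for cross in CROSSES}
    for w in windows:
        w.counts = {
            cross: counts[cross].sum_in(w.chrom, [(w.start, w.end)])
            for cross in CROSSES
        }
        w.call = _classify(
            f"{w.chrom}:{w.start}-{w.end}", w.counts, tissue, min_reads, threshold
        )
    return windows


def build_feature_units(
    annotation: Annotation, chrom_lengths: dict[str, int]
) -> list[FeatureUnit]:
    """Isoform, per-gene intron, and intergenic units from the annotation.

    Overlapping gene models are allowed: a SNP inside two genes contributes
    to both genes' units, which are then flagged ambiguous.
    """
    units: list[FeatureUnit] = []
    by_chrom = annotation.by_chrom()
    for chrom, genes in by_chrom.items():
        spans = [(g.start, g.end) for g in genes]
        overlapped = set()
        for i, (s1, e1) in enumerate(spans):
            for j in range(i + 1, len(spans)):
                s2, e2 = spans[j]
                if s2 >= e1:
                    break
                overlapped.update({genes[i].id, genes[j].id})
        for g in genes:
            amb = g.id in overlapped
            for t in g.transcripts:
                units.append(
                    FeatureUnit(t.id, "cdna_isoform", chrom, list(t.exons), g.id, amb)
                )
            introns = g.intron_union()
            if introns:
                units.append(
                    FeatureUnit(f"{g.id}.intron", "intron", chrom, introns, g.id, amb)
                )
        # intergenic: complement of gene spans, long intervals split at 10 kb
        gaps = complement_intervals(
            merge_intervals(spans), 0, chrom_lengths[chrom]
        )
        k = 0
        for s, e in gaps:
            for piece_start in range(s, e, INTERGENIC_UNIT_MAX):
                k += 1
                piece_end = min(piece_start + INTERGENIC_UNIT_MAX, e)
                units.append(
                    FeatureUnit(
                        f"{chrom}.ig{k:04d}", "intergenic", chrom,
                        [(piece_start, piece_end)],
                    )
                )
    for chrom in chrom_lengths:
        if chrom not in by_chrom:
            units.append(
                FeatureUnit(f"{chrom}.ig0001", "intergenic", chrom,
                            [(0, chrom_lengths[chrom])])
            )
    return units


def partition_totals(
    annotation: Annotation,
    tables: dict[str, pd.DataFrame],
    chrom_lengths: dict[str, int],
) -> dict[str, int]:
    """Allocate every SNP read to exactly one of exon-union/intron/intergenic.

    Precedence exon > intron > intergenic when annotations are nested, so the
    three totals sum exactly to the total normalized SNP reads — the
    conservation check of the reallocation.
    """
    exon_by_chrom: dict[str, list] = {}
    span_by_chrom: dict[str, list] = {}
    for g in annotation.genes:
        exon_by_chrom.setdefault(g.chrom, []).extend(g.exon_union())
        span_by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
    totals = {"exon_union": 0, "intron": 0, "intergenic": 0, "total": 0}
    for cross in CROSSES:
        for chrom, sub in tables[cross].groupby("chrom"):
            pos = sub["pos"].to_numpy()
            reads = (sub["r_mat"] + sub["r_pat"]).to_numpy()
            in_exon = _in_intervals(pos, merge_intervals(exon_by_chrom.get(chrom, [])))
            in_span = _in_intervals(pos, merge_intervals(span_by_chrom.get(chrom, [])))
            totals["exon_union"] += int(reads[in_exon].sum())
            totals["intron"] += int(reads[~in_exon & in_span].sum())
            totals["intergenic"] += int(reads[~in_span].sum())
            totals["total"] += int(reads.sum())
    return totals


def _in_intervals(pos: np.ndarray, intervals: list[tuple[int, int]]) -> np.ndarray:
    if not intervals:
        return np.zeros(len(pos), dtype=bool)
    starts = np.array([s for s, _ in intervals])
    ends = np.array([e for _, e in intervals])
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    ok[ok] &= pos[ok] < ends[idx[ok]]
    return ok


def feature_scan(
    annotation: Annotation,
    tables: dict[str, pd.DataFrame],
    tissue: str,
    chrom_lengths: dict[str, int],
    min_reads: int = MIN_READS,
    threshold: float = SIGNIFICANCE_NEGLOG10P,
) -> list[FeatureUnit]:
    """Classify every annotated feature unit; collapse equivalent isoforms.

    Isoforms of one gene whose per-SNP read support is identical are
    indistinguishable to the data and reported once under a compound id
    ("gene.1;gene.2").
    """
    counts = {cross: _SnpCounts(tables[cross]) for cross in CROSSES}
    units = build_feature_units(annotation, chrom_lengths)
    for u in units:
        u.counts = {
            cross: counts[cross].sum_in(u.chrom, u.intervals) for cross in CROSSES
        }
    units = _collapse_isoforms(units, counts)
    for u in units:
        u.call = _classify(u.id, u.counts, tissue, min_reads, threshold)
    return units


def _collapse_isoforms(units: list[FeatureUnit], counts) -> list[FeatureUnit]:
    out = []
    by_gene: dict[str, list[FeatureUnit]] = {}
    for u in units:
        if u.kind == "cdna_isoform" and u.gene_id:
            by_gene.setdefault(u.gene_id, []).append(u)
        else:
            out.append(u)
    for gene_id, isoforms in by_gene.items():
        if len(isoforms) == 1:
            out.extend(isoforms)
            continue
        groups: dict[tuple, list[FeatureUnit]] = {}
        for u in isoforms:
            key = tuple(
                counts[cross].snp_support(u.chrom, u.intervals) for cross in CROSSES
            )
            groups.setdefault(key, []).append(u)
        for members in groups.values():
            if len(members) == 1:
                out.append(members[0])
            else:
                merged = FeatureUnit(
                    ";".join(sorted(m.id for m in members)),
                    "cdna_isoform",
                    members[0].chrom,
                    merge_intervals([iv for m in members for iv in m.intervals]),
                    gene_id,
                    any(m.ambiguous for m in members),
                    counts=members[0].counts,
                )
                out.append(merged)
    return out


def significant_windows(windows: list[Window]) -> list[Window]:
    return [w for w in windows if w.call and w.call.call in IMPRINT_CLASSES]


def significant_features(units: list[FeatureUnit]) -> list[FeatureUnit]:
    return [u for u in units if u.call and u.call.call in IMPRINT_CLASSES]


def reconcile(
    windows: list[Window],
    units: list[FeatureUnit],
    annotation: Annotation,
    annotation_flank: int = 2000,
) -> dict:
    """Cross-tabulate the two analyses.

    Each significant window is labelled by whether it overlaps a significant
    annotated candidate, merely overlaps (or lies within `annotation_flank`
    of) annotation, or is intergenic; each candidate feature gets its count
    of supporting significant windows, and features with no window support
    are reported as feature-only candidates.
    """
    sig_w = significant_windows(windows)
    sig_f = significant_features(units)
    cand_iv: dict[str, list[tuple[int, int]]] = {}
    for u in sig_f:
        cand_iv.setdefault(u.chrom, []).extend(u.intervals)
    cand_iv = {c: merge_intervals(iv) for c, iv in cand_iv.items()}
    gene_iv = {}
    for g in annotation.genes:
        gene_iv.setdefault(g.chrom, []).append(
            (max(0, g.start - annotation_flank), g.end + annotation_flank)
        )
    gene_iv = {c: merge_intervals(iv) for c, iv in gene_iv.items()}

    window_labels = {}
    for w in sig_w:
        if _overlaps(w, cand_iv.get(w.chrom, [])):
            label = "overlaps_candidate_feature"
        elif _overlaps(w, gene_iv.get(w.chrom, [])):
            label = "overlaps_annotation_only"
        else:
            label = "intergenic"
        window_labels[f"{w.chrom}:{w.start}-{w.end}"] = label

    feature_support = {}
    for u in sig_f:
        n = sum(
            1
            for w in sig_w
            if w.chrom == u.chrom
            and any(w.start < e and s < w.end for s, e in u.intervals)
        )
        feature_support[u.id] = n
    label_counts = pd.Series(list(window_labels.values())).value_counts().to_dict()
    return {
        "window_labels": window_labels,
        "feature_window_support": feature_support,
        "n_significant_windows": len(sig_w),
        "n_significant_features": len(sig_f),
        "window_label_counts": label_counts,
        "feature_only_candidates": sorted(
            fid for fid, n in feature_support.items() if n == 0
        ),
        "direction_counts": {
            "windows": _direction_counts(w.call for w in sig_w),
            "features": _direction_counts(u.call for u in sig_f),
        },
    }


def _overlaps(w: Window, intervals: list[tuple[int, int]]) -> bool:
    return any(w.start < e and s < w.end for s, e in intervals)


def _direction_counts(calls) -> dict[str, int]:
    out = {MATERNAL_IMPRINT: 0, PATERNAL_IMPRINT: 0}
    for c in calls:
        if c and c.call in out:
            out[c.call] += 1
    return out


def poe_splicing_scan(
    units: list[FeatureUnit],
    windows: list[Window],
    annotation: Annotation,
) -> list[SplicingCandidate]:
    """Screen genes for sub-features of mixed imprinting status.

    A gene is a candidate when at least one of its sub-features (an isoform,
    its intron region, or a window fully inside the gene span) is called
    maternally imprinted and at least one other paternally imprinted —
    opposite parental origin of different transcript parts, the signature of
    parent-of-origin-dependent alternative splicing.
    """
    parts: dict[str, dict[str, list[str]]] = {}

    def add(gene_id: str, call: str, part_id: str):
        slot = parts.setdefault(gene_id, {MATERNAL_IMPRINT: [], PATERNAL_IMPRINT: []})
        slot[call].append(part_id)

    for u in units:
        if u.gene_id and u.call and u.call.call in IMPRINT_CLASSES:
            add(u.gene_id, u.call.call, u.id)
    spans = {g.id: (g.chrom, g.start, g.end) for g in annotation.genes}
    for w in windows:
        if not (w.call and w.call.call in IMPRINT_CLASSES):
            continue
        for gid, (chrom, s, e) in spans.items():
            if w.chrom == chrom and w.start >= s and w.end <= e:
                add(gid, w.call.call, f"window:{w.chrom}:{w.start}-{w.end}")
    out = []
    for gene_id in sorted(parts):
        slot = parts[gene_id]
        if slot[MATERNAL_IMPRINT] and slot[PATERNAL_IMPRINT]:
            out.append(
                SplicingCandidate(
                    gene_id, sorted(slot[MATERNAL_IMPRINT]), sorted(slot[PATERNAL_IMPRINT])
                )
            )
    return out
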