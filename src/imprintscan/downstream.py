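"""Characterization of the candidate imprinted set.

Covers the survey's follow-up questions: are imprinted loci physically
clustered (nearest-neighbour distances between significant windows,
micro-clusters of adjacent imprinted genes), do they sit near or among
transposons/repeats more than expressed genes at large (permutation test),
do they differ in GC content (rank-sum), and are any functional categories
over-represented (hypergeometric test against the expressed background).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import Annotation
from .stats import bh_qvalues


@dataclass
class ClusterReport:
    median_nn_distance: float  # bp between significant-window midpoints
    n_within_10kb: int
    fraction_within_10kb: float
    nn_distances: list[float] = field(default_factory=list)
    micro_clusters: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class EnrichmentResult:
    term: str
    k_candidates_with_term: int
    n_candidates: int
    K_background_with_term: int
    N_background: int
    p_value: float
    q_value: float = float("nan")


def cluster_stats(
    window_midpoints: dict[str, list[float]],
    imprinted_gene_ids: list[str],
    annotation: Annotation,
    pair_window: int = 10_000,
    micro_cluster_gap: int = 20_000,
    micro_cluster_intervening: int = 1,
) -> ClusterReport:
    """Spatial clustering of candidates.

    `window_midpoints` maps chromosome -> midpoints of significant windows.
    Nearest-neighbour distances are computed within chromosomes; windows on
    chromosomes with a single candidate have no neighbour and contribute no
    distance.  Micro-clusters are pairs of imprinted genes with at most
    `micro_cluster_intervening` annotated genes between them, or a genomic
    gap of at most `micro_cluster_gap`.
    """
    nn: list[float] = []
    for chrom, mids in window_midpoints.items():
        m = np.sort(np.asarray(mids, dtype=float))
        if len(m) < 2:
            continue
        gaps_prev = np.r_[np.inf, np.diff(m)]
        gaps_next = np.r_[np.diff(m), np.inf]
        nn.extend(np.minimum(gaps_prev, gaps_next).tolist())
    n_close = int(sum(d <= pair_window for d in nn))
    total = sum(len(m) for m in window_midpoints.values())
    report = ClusterReport(
        median_nn_distance=float(np.median(nn)) if nn else float("nan"),
        n_within_10kb=n_close,
        fraction_within_10kb=(n_close / total) if total else 0.0,
        nn_distances=nn,
    )
    report.micro_clusters = _micro_clusters(
        imprinted_gene_ids, annotation, micro_cluster_gap, micro_cluster_intervening
    )
    return report


def _micro_clusters(
    imprinted_gene_ids, annotation, max_gap, max_intervening
) -> list[tuple[str, str]]:
    imprinted = set(imprinted_gene_ids)
    pairs = []
    for chrom, genes in annotation.by_chrom().items():
        idx = {g.id: i for i, g in enumerate(genes)}
        hits = [g for g in genes if g.id in imprinted]
        for a, b in zip(hits, hits[1:]):
            intervening = idx[b.id] - idx[a.id] - 1
            gap = b.start - a.end
            if intervening <= max_intervening or gap <= max_gap:
                pairs.append((a.id, b.id))
    return pairs


def _nearest_distance(point_start, point_end, intervals: np.ndarray) -> float:
    """Distance from interval [start,end) to nearest repeat interval; 0 if overlapping."""
    if intervals.size == 0:
        return float("inf")
    starts, ends = intervals[:, 0], intervals[:, 1]
    overlap = (starts < point_end) & (point_start < ends)
    if overlap.any():
        return 0.0
    left = point_start - ends[ends <= point_start]
    right = starts[starts >= point_end] - point_end
    best = np.inf
    if left.size:
        best = min(best, float(left.min()))
    if right.size:
        best = min(best, float(right.min()))
    return best


def repeat_metrics(
    genes: list, repeats: pd.DataFrame, flank: int = 5_000
) -> pd.DataFrame:
    """Per-gene distance to nearest repeat and repeat-bp density within +/-flank.

    `repeats` columns: chrom, start, end, repeat_class.
    """
    by_chrom = {
        chrom: sub[["start", "end"]].to_numpy()
        for chrom, sub in repeats.groupby("chrom")
    }
    rows = []
    for g in genes:
        iv = by_chrom.get(g.chrom, np.empty((0, 2), dtype=int))
        dist = _nearest_distance(g.start, g.end, iv)
        lo, hi = g.start - flank, g.end + flank
        density = 0
        for s, e in iv:
            density += max(0, min(e, hi) - max(s, lo))
        rows.append(
            {
                "gene_id": g.id,
                "nearest_repeat_bp": dist,
                "repeat_bp_in_flank": density,
            }
        )
    return pd.DataFrame(rows)


def repeat_proximity(
    candidate_ids: list[str],
    all_genes: list,
    repeats: pd.DataFrame,
    flank: int = 5_000,
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict:
    """Permutation comparison of repeat proximity/density, candidates vs all genes.

    The observed statistic is the candidate-set mean (nearest-repeat
    distance, and repeat bp within the flank); the null resamples
    same-size gene sets from all annotated genes.  Two-sided empirical P
    with the +1 correction.  Repeated per repeat class as well.
    """
    metrics = repeat_metrics(all_genes, repeats, flank)
    out = {"overall": _perm_test(metrics, candidate_ids, n_perm, seed)}
    if "repeat_class" in repeats.columns:
        for cls, sub in repeats.groupby("repeat_class"):
            m = repeat_metrics(all_genes, sub, flank)
            out[str(cls)] = _perm_test(m, candidate_ids, n_perm, seed)
    return out


def _perm_test(metrics: pd.DataFrame, candidate_ids, n_perm, seed) -> dict:
    rng = np.random.default_rng(seed)
    is_cand = metrics["gene_id"].isin(set(candidate_ids)).to_numpy()
    n_cand = int(is_cand.sum())
    result = {"n_candidates": n_cand}
    for col in ("nearest_repeat_bp", "repeat_bp_in_flank"):
        values = metrics[col].to_numpy(dtype=float)
        finite = np.isfinite(values)
        if not finite.any() or n_cand == 0:
            result[col] = {"observed": float("nan"), "p_value": float("nan")}
            continue
        values = np.where(finite, values, np.nanmax(values[finite]) if finite.any() else 0)
        obs = float(values[is_cand].mean())
        null = np.empty(n_perm)
        for i in range(n_perm):
            pick = rng.choice(len(values), size=n_cand, replace=False)
            null[i] = values[pick].mean()
        center = float(null.mean())
        p = (1 + np.sum(np.abs(null - center) >= abs(obs - center))) / (n_perm + 1)
        result[col] = {"observed": obs, "null_mean": center, "p_value": float(p)}
    return result


def gc_content(seq: str) -> float:
    """GC fraction of a sequence (N bases excluded from the denominator)."""
    acgt = sum(seq.upper().count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (seq.upper().count("G") + seq.upper().count("C")) / acgt


def gc_comparison(
    candidate_seqs: list[str], background_seqs: list[str]
) -> dict:
    """Rank-sum comparison of GC content, candidates vs background."""
    gc_c = [gc_content(s) for s in candidate_seqs]
    gc_b = [gc_content(s) for s in background_seqs]
    stat, p = sps.mannwhitneyu(gc_c, gc_b, alternative="two-sided")
    return {
        "candidate_median_gc": float(np.median(gc_c)),
        "background_median_gc": float(np.median(gc_b)),
        "statistic": float(stat),
        "p_value": float(p),
    }


def go_enrichment(
    candidate_ids: list[str],
    background_ids: list[str],
    term_map: pd.DataFrame,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of terms in the candidate set.

    The background is the expressed set (features with at least 10 reads);
    candidates must be a subset of it.  `term_map` columns: gene_id, term.
    """
    background = set(background_ids)
    candidates = set(candidate_ids)
    if not candidates <= background:
        raise ValueError("candidates must be a subset of the expressed background")
    tm = term_map[term_map["gene_id"].isin(background)]
    N = len(background)
    n = len(candidates)
    results = []
    for term, sub in tm.groupby("term"):
        genes_with = set(sub["gene_id"])
        K = len(genes_with)
        k = len(genes_with & candidates)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(str(term), k, n, K, N, min(p, 1.0)))
    if results:
        qs = bh_qvalues(np.array([r.p_value for r in results]))
        for r, q in zip(results, qs):
            r.q_value = float(q)
    return sorted(results, key=lambda r: r.p_value)
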