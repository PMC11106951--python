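"""Relating states and peaks to genome features.

TSS meta-profiles (strand-oriented reference-point matrices), state-vs-feature
fold enrichment, emission-rule state labeling, midpoint-based genomic feature
annotation with a fixed priority ladder, and sorted-sweep interval
intersection under half-open arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import GeneModel, GenomicInterval, _effective_strand
from .hmm_segmentation import HMMModel, Segmentation
from .signal_norm import BinnedTrack

LABELS = (
    "TSS Active",
    "TSS Flanking",
    "Bivalent/poised TSS",
    "Putative active enhancer",
    "Putative weak enhancer",
    "Quiescent(low)",
    "Repressed",
    "Weak repressed",
    "Other",
)

CATEGORIES = (
    "Promoter (<=1kb)",
    "Promoter (1-2kb)",
    "Promoter (2-3kb)",
    "5' UTR",
    "3' UTR",
    "Exon",
    "Intron",
    "Downstream",
    "Distal Intergenic",
)


@dataclass
class StateLabel:
    """One functional label per state, with the evidence that produced it."""

    state: int
    label: str
    emission: np.ndarray
    tss_fold: float


@dataclass
class FeatureAnnotation:
    """Genomic-feature category of one interval (decided by its midpoint)."""

    interval: GenomicInterval
    category: str
    nearest_gene: str
    distance_to_tss: int


@dataclass
class LabelThresholds:
    """Emission/TSS-fold cutoffs for the labeling rule ladder."""

    strong: float = 0.5
    weak: float = 0.2
    flank_k4: float = 0.3
    quiescent: float = 0.1
    tss_fold: float = 2.0


# ---------------------------------------------------------------------------
# TSS meta-profile
# ---------------------------------------------------------------------------

def tss_metaprofile(
    track: BinnedTrack, genes: list[GeneModel], flank: int = 3000
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Signal around every TSS, strand-oriented (upstream on the left).

    Returns (column-mean profile, per-gene matrix ordered by row sum
    descending, gene ids in matrix order). Genes whose window would cross a
    chromosome edge get NaN padding and are excluded from column means.
    """
    bs = track.grid.bin_size
    if flank % bs != 0:
        raise ValueError("flank must be a multiple of bin_size")
    half = flank // bs
    width = 2 * half + 1
    rows = np.full((len(genes), width), np.nan)
    for i, g in enumerate(genes):
        chrom = g.interval.chrom
        vals = track.values[chrom]
        center = track.grid.bin_index(g.tss)
        lo, hi = center - half, center + half + 1
        src_lo, src_hi = max(lo, 0), min(hi, len(vals))
        row = np.full(width, np.nan)
        row[src_lo - lo : src_hi - lo] = vals[src_lo:src_hi]
        if _effective_strand(g.strand) == "-":
            row = row[::-1]
        rows[i] = row
    with np.errstate(invalid="ignore"):
        profile = np.nanmean(rows, axis=0) if len(genes) else np.zeros(width)
    order = np.argsort(-np.nansum(rows, axis=1), kind="stable")
    gene_ids = [genes[i].gene_id for i in order]
    return profile, rows[order], gene_ids


# ---------------------------------------------------------------------------
# State-vs-feature fold enrichment
# ---------------------------------------------------------------------------

def _merge_intervals(ivs: list[GenomicInterval]) -> dict[str, np.ndarray]:
    """Union of intervals per chrom as an array of (start, end) rows."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in ivs:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: dict[str, np.ndarray] = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        out: list[list[int]] = []
        for s, e in spans:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.array(out)
    return merged


def _overlap_bp(ivs: list[GenomicInterval], merged: dict[str, np.ndarray]) -> int:
    total = 0
    for iv in ivs:
        spans = merged.get(iv.chrom)
        if spans is None:
            continue
        lo = np.maximum(spans[:, 0], iv.start)
        hi = np.minimum(spans[:, 1], iv.end)
        total += int(np.maximum(hi - lo, 0).sum())
    return total


def state_feature_enrichment(
    seg: Segmentation, features: dict[str, list[GenomicInterval]]
) -> pd.DataFrame:
    """Fold enrichment of every state in every feature set.

    fold = (state bp within feature / feature bp) / (state bp / genome bp);
    0/0 is reported as 0.
    """
    if not features:
        raise ValueError("features must be non-empty")
    genome_bp = sum(seg.grid.chrom_lengths.values())
    states = sorted({s for _, s in seg.segments})
    by_state: dict[int, list[GenomicInterval]] = {s: [] for s in states}
    for iv, s in seg.segments:
        by_state[s].append(iv)
    state_bp = {s: sum(iv.length for iv in by_state[s]) for s in states}

    data = np.zeros((len(states), len(features)))
    for j, (fname, fivs) in enumerate(features.items()):
        merged = _merge_intervals(fivs)
        feat_bp = int(sum((sp[:, 1] - sp[:, 0]).sum() for sp in merged.values()))
        for i, s in enumerate(states):
            if feat_bp == 0 or state_bp[s] == 0:
                data[i, j] = 0.0
                continue
            inside = _overlap_bp(by_state[s], merged)
            data[i, j] = (inside / feat_bp) / (state_bp[s] / genome_bp)
    return pd.DataFrame(data, index=states, columns=list(features))


# ---------------------------------------------------------------------------
# State labeling
# ---------------------------------------------------------------------------

def label_states(
    model: HMMModel,
    tss_fold: np.ndarray | pd.Series,
    thresholds: LabelThresholds | None = None,
) -> list[StateLabel]:
    """Assign a functional label to every state by a first-match rule ladder.

    Rules (in priority order, with default thresholds): bivalent when both
    H3K4me3 and H3K27me3 emissions are high; TSS Active when H3K4me3 and
    H3K27ac are high at TSS-enriched states; TSS Flanking for moderate
    H3K4me3 at TSS-enriched states; enhancers by H3K27ac away from TSSs;
    repressed states by H3K27me3; quiescent when everything is silent.
    """
    th = thresholds or LabelThresholds()
    required = ("H3K4me3", "H3K27ac", "H3K27me3")
    for mark in required:
        if mark not in model.marks:
            raise ValueError(f"mark {mark} required for state labeling")
    k4 = model.emissionprob[:, model.marks.index("H3K4me3")]
    k27ac = model.emissionprob[:, model.marks.index("H3K27ac")]
    k27me3 = model.emissionprob[:, model.marks.index("H3K27me3")]
    tss_fold = np.asarray(tss_fold, dtype=float)
    if tss_fold.shape != (model.n_states,):
        raise ValueError("tss_fold must have one entry per state")

    labels: list[StateLabel] = []
    for k in range(model.n_states):
        e = model.emissionprob[k]
        if k4[k] >= th.strong and k27me3[k] >= th.strong:
            lab = "Bivalent/poised TSS"
        elif k4[k] >= th.strong and k27ac[k] >= th.strong and tss_fold[k] >= th.tss_fold:
            lab = "TSS Active"
        elif k4[k] >= th.flank_k4 and tss_fold[k] >= th.tss_fold:
            lab = "TSS Flanking"
        elif k27ac[k] >= th.strong and tss_fold[k] < th.tss_fold:
            lab = "Putative active enhancer"
        elif th.weak <= k27ac[k] < th.strong and tss_fold[k] < th.tss_fold:
            lab = "Putative weak enhancer"
        elif k27me3[k] >= th.strong:
            lab = "Repressed"
        elif th.weak <= k27me3[k] < th.strong:
            lab = "Weak repressed"
        elif (e < th.quiescent).all():
            lab = "Quiescent(low)"
        else:
            lab = "Other"
        labels.append(StateLabel(k + 1, lab, e.copy(), float(tss_fold[k])))
    return labels


# ---------------------------------------------------------------------------
# Genomic feature annotation (midpoint ladder)
# ---------------------------------------------------------------------------

def _signed_tss_distance(pos: int, gene: GeneModel) -> int:
    """Signed distance to the TSS; positive downstream w.r.t. the strand."""
    if _effective_strand(gene.strand) == "+":
        return pos - gene.tss
    return gene.tss - pos


def annotate_intervals(
    intervals: list[GenomicInterval], genes: list[GeneModel]
) -> tuple[list[FeatureAnnotation], pd.Series]:
    """Assign each interval one feature category by its midpoint.

    Priority ladder: promoter bands (|distance to nearest TSS| within 1 kb /
    1-2 kb / 2-3 kb) > exon > intron > downstream (<= 3 kb past the TES) >
    distal intergenic. UTR categories require transcript-level annotation the
    gene models do not carry and are never assigned here. Returns the
    annotations and a category percentage table summing to 100.
    """
    if not genes:
        raise ValueError("genes must be non-empty")
    if not intervals:
        return [], pd.Series(dtype=float)

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)

    annos: list[FeatureAnnotation] = []
    for iv in intervals:
        mid = iv.midpoint
        cands = by_chrom.get(iv.chrom, [])
        if not cands:
            annos.append(FeatureAnnotation(iv, "Distal Intergenic", "", 0))
            continue
        dists = [(abs(_signed_tss_distance(mid, g)), g) for g in cands]
        dists.sort(key=lambda t: (t[0], t[1].gene_id))
        absd, nearest = dists[0]
        signed = _signed_tss_distance(mid, nearest)
        if absd <= 1000:
            cat = "Promoter (<=1kb)"
        elif absd <= 2000:
            cat = "Promoter (1-2kb)"
        elif absd <= 3000:
            cat = "Promoter (2-3kb)"
        else:
            host = next(
                (g for g in cands
                 if g.interval.start <= mid < g.interval.end),
                None,
            )
            if host is not None:
                in_exon = any(
                    ex.start <= mid < ex.end for ex in (host.exons or [host.interval])
                )
                cat = "Exon" if in_exon else "Intron"
            else:
                downstream = False
                for g in cands:
                    if _effective_strand(g.strand) == "+":
                        if g.interval.end <= mid < g.interval.end + 3000:
                            downstream = True
                            break
                    else:
                        if g.interval.start - 3000 <= mid < g.interval.start:
                            downstream = True
                            break
                cat = "Downstream" if downstream else "Distal Intergenic"
        annos.append(FeatureAnnotation(iv, cat, nearest.gene_id, signed))

    counts = pd.Series([a.category for a in annos]).value_counts()
    percentages = counts / counts.sum() * 100.0
    return annos, percentages


# ---------------------------------------------------------------------------
# Interval intersection (sorted sweep)
# ---------------------------------------------------------------------------

def intersect(
    a: list[GenomicInterval], b: list[GenomicInterval]
) -> tuple[list[tuple[int, int]], int]:
    """All overlapping (i, j) index pairs plus the count of a-intervals hit.

    Overlap means >= 1 bp under half-open arithmetic
    (``a.start < b.end and b.start < a.end``). Sorted sweep per chromosome.
    """
    a_by_chrom: dict[str, list[int]] = {}
    b_by_chrom: dict[str, list[int]] = {}
    for i, iv in enumerate(a):
        a_by_chrom.setdefault(iv.chrom, []).append(i)
    for j, iv in enumerate(b):
        b_by_chrom.setdefault(iv.chrom, []).append(j)

    pairs: list[tuple[int, int]] = []
    for chrom, a_ids in a_by_chrom.items():
        b_ids = b_by_chrom.get(chrom, [])
        if not b_ids:
            continue
        a_ids = sorted(a_ids, key=lambda i: a[i].start)
        b_ids = sorted(b_ids, key=lambda j: b[j].start)
        bi = 0
        active: list[int] = []
        for i in a_ids:
            iv = a[i]
            while bi < len(b_ids) and b[b_ids[bi]].start < iv.end:
                active.append(b_ids[bi])
                bi += 1
            # b-intervals ending at or before iv.start can never overlap
            # this or any later a-interval (a is start-sorted)
            active = [j for j in active if b[j].end > iv.start]
            pairs.extend((i, j) for j in active if b[j].start < iv.end)
    pairs.sort()
    hit = len({i for i, _ in pairs})
    return pairs, hit
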