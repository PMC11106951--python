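"""Broad TSS-state domains and cell-type-specific gene ranking.

Maximal runs of TSS-state bins (states 1/2 by default) become TSS regions; a
region spanning at least ``broad_min`` (4 kb) is a broad domain, the class
associated with cell-identity genes. Expression counts are normalized by
trimmed-mean-of-M-values (TMM) factors; genes are ranked per cell type by a
leave-category-out Welch t-statistic on log2(CPM+1), with the top decile
flagged as cell-type specific.

TMM convention used here: M-values are computed on raw counts (not
depth-normalized counts), so the factor absorbs both sequencing depth and
composition bias, and CPM divides by (geometric-mean library size x factor).
Scaling one sample's counts by c scales its factor by c and leaves its CPM
unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import GeneModel, GenomicInterval
from .hmm_segmentation import Segmentation


@dataclass
class TssRegion:
    """One maximal run of TSS-state bins."""

    interval: GenomicInterval
    states_spanned: set[int]
    genes: list[str] = field(default_factory=list)
    broad_min: int = 4000

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def is_broad(self) -> bool:
        return self.length >= self.broad_min


@dataclass
class SpecificityResult:
    """Per-gene specificity for one target cell type."""

    gene_id: str
    cell_type: str
    t_stat: float
    rank: int
    is_specific: bool


# ---------------------------------------------------------------------------
# TSS regions
# ---------------------------------------------------------------------------

def extract_tss_regions(
    seg: Segmentation,
    tss_states: set[int] | None = None,
    broad_min: int = 4000,
) -> tuple[list[TssRegion], pd.Series, dict[str, float]]:
    """Maximal runs of consecutive TSS-state bins, with a length histogram.

    Runs mixing states 1 and 2 form single regions. Returns the regions, a
    histogram of lengths binned at 1 kb (index = lower kb bound), and a
    summary with region count, broad count and broad percentage.
    """
    if tss_states is not None and not tss_states:
        raise ValueError("tss_states must be non-empty")
    tss_states = tss_states or {1, 2}
    bs = seg.grid.bin_size
    regions: list[TssRegion] = []
    for chrom in seg.grid.chroms:
        path = seg.state_path[chrom]
        mask = np.isin(path, list(tss_states)).astype(np.int8)
        if mask.sum() == 0:
            continue
        edges = np.flatnonzero(np.diff(mask))
        starts = edges[mask[edges + 1] == 1] + 1
        ends = edges[mask[edges] == 1] + 1
        if mask[0] == 1:
            starts = np.concatenate(([0], starts))
        if mask[-1] == 1:
            ends = np.concatenate((ends, [len(mask)]))
        chrom_len = seg.grid.chrom_lengths[chrom]
        for s, e in zip(starts, ends):
            iv = GenomicInterval(chrom, int(s) * bs, min(int(e) * bs, chrom_len))
            regions.append(
                TssRegion(iv, set(np.unique(path[s:e]).tolist()),
                          broad_min=broad_min)
            )
    lengths = pd.Series([r.length for r in regions], dtype=int)
    hist = (lengths // 1000).value_counts().sort_index() if len(lengths) else (
        pd.Series(dtype=int)
    )
    n_broad = int(sum(r.is_broad for r in regions))
    summary = {
        "n_regions": float(len(regions)),
        "n_broad": float(n_broad),
        "pct_broad": 100.0 * n_broad / len(regions) if regions else 0.0,
    }
    return regions, hist, summary


def genes_for_regions(
    regions: list[TssRegion],
    genes: list[GeneModel],
    window: int = 1000,
) -> dict[int, list[str]]:
    """Attach genes whose TSS +/- window overlaps each region (half-open).

    Mutates ``region.genes`` in place and returns {region index: gene ids}.
    """
    from .state_annotation import intersect

    region_ivs = [r.interval for r in regions]
    tss_ivs = [
        GenomicInterval(
            g.interval.chrom,
            max(0, g.tss - window),
            g.tss + window + 1,
            name=g.gene_id,
        )
        for g in genes
    ]
    pairs, _ = intersect(region_ivs, tss_ivs)
    mapping: dict[int, list[str]] = {i: [] for i in range(len(regions))}
    for i, j in pairs:
        mapping[i].append(genes[j].gene_id)
    for i, r in enumerate(regions):
        r.genes = sorted(mapping[i])
    return mapping


def broad_gene_set(regions: list[TssRegion]) -> set[str]:
    """Genes attached to at least one broad region."""
    out: set[str] = set()
    for r in regions:
        if r.is_broad:
            out.update(r.genes)
    return out


# ---------------------------------------------------------------------------
# TMM normalization and CPM
# ---------------------------------------------------------------------------

def tmm_factors(
    counts: pd.DataFrame,
    trim_M: float = 0.30,
    trim_A: float = 0.05,
    ref: str | None = None,
) -> pd.Series:
    """Trimmed-mean-of-M-values factors per sample, geometric mean 1.

    M and A are computed on raw counts against the reference sample (chosen
    automatically as the sample whose upper-quartile count is closest to the
    mean of upper-quartiles). Genes with a zero count in either member of a
    pair are excluded from that pair. M is trimmed by ``trim_M`` and A by
    ``trim_A`` from each tail; the kept M-values are averaged with inverse
    asymptotic-variance (precision) weights.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("a sample has all-zero counts")
    lib = counts.sum(axis=0).astype(float)
    if ref is None:
        uq = counts.apply(lambda col: np.quantile(col, 0.75), axis=0)
        ref = (uq - uq.mean()).abs().idxmin()
    yr = counts[ref].to_numpy(dtype=float)

    log2f = {}
    for sample in counts.columns:
        if sample == ref:
            log2f[sample] = 0.0
            continue
        ys = counts[sample].to_numpy(dtype=float)
        keep = (ys > 0) & (yr > 0)
        ysk, yrk = ys[keep], yr[keep]
        M = np.log2(ysk / yrk)
        A = 0.5 * np.log2(ysk * yrk)
        n = len(M)
        if n == 0:
            raise ValueError(f"no co-expressed genes between {sample} and {ref}")
        rank_M = pd.Series(M).rank().to_numpy()
        rank_A = pd.Series(A).rank().to_numpy()
        keep2 = (
            (rank_M >= n * trim_M)
            & (rank_M <= n * (1 - trim_M))
            & (rank_A >= n * trim_A)
            & (rank_A <= n * (1 - trim_A))
        )
        if not keep2.any():
            keep2 = np.ones(n, dtype=bool)
        w = 1.0 / (
            (lib[sample] - ysk) / (lib[sample] * ysk)
            + (lib[ref] - yrk) / (lib[ref] * yrk)
        )
        log2f[sample] = float(
            np.average(M[keep2], weights=np.maximum(w[keep2], 1e-12))
        )
    factors = pd.Series({s: 2.0 ** v for s, v in log2f.items()})[counts.columns]
    factors /= np.exp(np.log(factors).mean())  # geometric mean 1
    return factors


def cpm(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Counts per million: counts / (geometric-mean library size x factor)."""
    lib = counts.sum(axis=0).astype(float)
    scale = np.exp(np.log(lib).mean())
    return counts / (scale * factors) * 1e6


def call_expressed(
    cpm_mat: pd.DataFrame,
    samples: pd.DataFrame,
    threshold: float = 1.0,
    min_samples: int | None = None,
) -> pd.DataFrame:
    """Expressed iff CPM >= threshold in >= min_samples of a cell type
    (default: all replicates of that type)."""
    out = {}
    for ct, grp in samples.groupby("cell_type"):
        cols = grp["sample_id"].tolist()
        need = min_samples if min_samples is not None else len(cols)
        out[ct] = (cpm_mat[cols] >= threshold).sum(axis=1) >= need
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Specificity ranking
# ---------------------------------------------------------------------------

def welch_t(group1: np.ndarray, group2: np.ndarray) -> float:
    """Welch two-sample t; 0 by convention when both variances and the mean
    difference are zero."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least two samples")
    num = g1.mean() - g2.mean()
    den = math.sqrt(g1.var(ddof=1) / len(g1) + g2.var(ddof=1) / len(g2))
    if den == 0.0:
        return 0.0 if num == 0.0 else math.copysign(math.inf, num)
    return num / den


def specificity_t(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    target_cell_type: str,
    top_fraction: float = 0.10,
    factors: pd.Series | None = None,
    mode: str = "leave-category-out",
) -> list[SpecificityResult]:
    """Rank genes by Welch t on log2(CPM+1): target type vs out-of-category.

    ``leave-category-out`` (default) compares target-type samples against all
    samples whose biological category differs from the target's (other samples
    sharing the category are excluded entirely); ``all-others`` compares
    against every non-target sample. The top ceil(top_fraction * G) genes by
    descending t (ties broken by gene id) are flagged specific.
    """
    if mode not in ("leave-category-out", "all-others"):
        raise ValueError(f"unknown mode {mode!r}")
    meta = samples.set_index("sample_id")
    target_samples = meta.index[meta["cell_type"] == target_cell_type].tolist()
    if len(target_samples) < 2:
        raise ValueError("need >= 2 samples in the target cell type")
    if mode == "leave-category-out":
        target_cat = meta.loc[target_samples[0], "category"]
        other_samples = meta.index[meta["category"] != target_cat].tolist()
    else:
        other_samples = meta.index[meta["cell_type"] != target_cell_type].tolist()
    if len(other_samples) < 2:
        raise ValueError("need >= 2 samples outside the target's category")

    if factors is None:
        factors = tmm_factors(counts)
    logcpm = np.log2(cpm(counts, factors) + 1.0)
    g1 = logcpm[target_samples].to_numpy()
    g2 = logcpm[other_samples].to_numpy()
    n1, n2 = g1.shape[1], g2.shape[1]
    num = g1.mean(axis=1) - g2.mean(axis=1)
    den = np.sqrt(g1.var(axis=1, ddof=1) / n1 + g2.var(axis=1, ddof=1) / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(den == 0.0, np.where(num == 0.0, 0.0,
                                          np.sign(num) * np.inf), num / den)

    df = pd.DataFrame({"gene_id": counts.index, "t": t})
    df = df.sort_values(["t", "gene_id"], ascending=[False, True],
                        kind="stable").reset_index(drop=True)
    n_top = math.ceil(top_fraction * len(df))
    return [
        SpecificityResult(row.gene_id, target_cell_type, float(row.t),
                          i + 1, i < n_top)
        for i, row in enumerate(df.itertuples(index=False))
    ]


def broad_specific_overlap(
    broad_genes: set[str],
    specific: list[SpecificityResult] | set[str],
    annotated_subset: set[str] | None = None,
) -> tuple[int, int, float]:
    """(overlap count, broad total, percentage) of broad genes that are also
    cell-type specific; optionally restricted to an annotated gene subset."""
    if not broad_genes:
        raise ValueError("broad gene set is empty")
    if isinstance(specific, set):
        specific_ids = specific
    else:
        specific_ids = {r.gene_id for r in specific if r.is_specific}
    pool = set(broad_genes)
    if annotated_subset is not None:
        pool &= annotated_subset
    if not pool:
        raise ValueError("no broad genes left after restriction")
    k = len(pool & specific_ids)
    return k, len(pool), 100.0 * k / len(pool)
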