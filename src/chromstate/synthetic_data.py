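"""Synthetic study generator: genome, state paths, mark counts, expression.

Emulates a two-cell-type CUT&RUN + RNA-seq design on a small multi-chromosome
genome: per-cell-type hidden chromatin-state paths over fixed-width bins
(10 states), Poisson per-bin mark counts with state-dependent rates plus a
flat IgG control, Poisson spike-in totals, negative-binomial expression with
replicate structure, planted cell-type-specific genes, and planted broad
(>= 4 kb) TSS-state runs on a "developmental" gene subset. Everything is a
deterministic function of the master seed; per-component generators are
seeded as (seed, fixed offset) so components stay independent.

State vocabulary (ground-truth indices):
  1 TSS Active, 2 TSS Flanking, 3 Bivalent/poised TSS, 4 Putative active
  enhancer, 5 Putative weak enhancer, 6 Repressed, 7 Weak repressed,
  8 Quiescent(low), 9 BRG1-bound, 10 Mixed weak.
Background bins move among states 3..10 with a sticky Markov chain; states
1/2 occur only in planted TSS runs, so planted broad runs are recoverable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import (
    BinGrid,
    GeneModel,
    GenomicInterval,
    write_bed,
    write_gtf_genes,
    write_track,
)
from .signal_norm import BinnedTrack

MARKS = ["H3K4me3", "H3K27ac", "H3K27me3", "BRG1", "IgG"]
CELL_TYPES = ["PFF-like", "PTr2-like"]
CATEGORIES = {"PFF-like": "fibroblast", "PTr2-like": "trophectoderm"}

TSS_ACTIVE, TSS_FLANK = 1, 2
REPRESSED = 6
BACKGROUND_STATES = np.arange(3, 11)
# Relative weights of background states when the chain leaves a state;
# quiescent-dominated so marginal mark frequencies stay sparse (~2-15%).
BACKGROUND_WEIGHTS = {3: 0.04, 4: 0.07, 5: 0.07, 6: 0.08, 7: 0.08,
                      8: 0.55, 9: 0.06, 10: 0.05}

# Poisson mean reads per 200-bp bin per replicate, rows = states 1..10,
# columns = MARKS. IgG is flat and low everywhere.
DEFAULT_STATE_RATES = np.array(
    [
        # K4me3 K27ac K27me3 BRG1  IgG
        [24.0, 18.0, 0.05, 3.0, 0.2],   # 1 TSS Active
        [24.0, 0.3, 0.05, 0.5, 0.2],    # 2 TSS Flanking
        [6.0, 0.2, 8.0, 0.2, 0.2],      # 3 Bivalent/poised TSS
        [0.3, 10.0, 0.05, 6.0, 0.2],    # 4 Putative active enhancer
        [0.2, 7.0, 0.05, 1.0, 0.2],     # 5 Putative weak enhancer
        [0.05, 0.05, 10.0, 0.1, 0.2],   # 6 Repressed
        [0.05, 0.05, 6.0, 0.1, 0.2],    # 7 Weak repressed
        [0.05, 0.05, 0.05, 0.05, 0.2],  # 8 Quiescent(low)
        [0.2, 0.5, 0.05, 8.0, 0.2],     # 9 BRG1-bound
        [0.1, 6.0, 6.0, 0.5, 0.2],      # 10 Mixed weak
    ]
)


@dataclass
class SimulationConfig:
    """Study-design parameters; defaults are the simulated study conditions."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    bin_size: int = 200
    n_genes: int = 400
    n_states: int = 10
    marks: list[str] = field(default_factory=lambda: list(MARKS))
    state_rates: np.ndarray | None = None
    transition_bias: float = 0.96
    n_cell_types: int = 2
    n_reps_cutrun: int = 2
    n_reps_rna: int = 3
    frac_specific_genes: float = 0.10
    specific_log2fc: float = 3.0
    frac_broad_genes: float = 0.05
    frac_broad_specific: float = 0.35  # of broad genes, specific per cell type
    nb_dispersion: float = 0.1
    spikein_mean: float = 5_000.0
    gene_length_range: tuple[int, int] = (600, 3000)
    ordinary_run_bins: tuple[int, int] = (5, 10)   # 1-2 kb at 200 bp
    broad_run_bins: tuple[int, int] = (21, 31)     # 4.2-6.2 kb at 200 bp

    def __post_init__(self) -> None:
        if self.state_rates is None:
            self.state_rates = DEFAULT_STATE_RATES.copy()
        self.state_rates = np.asarray(self.state_rates, dtype=float)
        if self.state_rates.shape != (self.n_states, len(self.marks)):
            raise ValueError("state_rates must be (n_states, n_marks)")
        if (self.state_rates < 0).any():
            raise ValueError("rates must be non-negative")
        for frac in (self.frac_specific_genes, self.frac_broad_genes):
            if not 0 < frac < 1:
                raise ValueError("fractions must be in (0, 1)")
        if not 0 < self.transition_bias < 1:
            raise ValueError("transition_bias must be in (0, 1)")

    @property
    def cell_types(self) -> list[str]:
        return CELL_TYPES[: self.n_cell_types]

    def rng(self, offset: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, offset])


@dataclass
class GroundTruth:
    """Planted structure: per-cell-type state paths and gene subsets."""

    state_path: dict[str, dict[str, np.ndarray]]  # cell type -> chrom -> states
    broad_genes: dict[str, set[str]]
    specific_genes: dict[str, set[str]]


@dataclass
class StudyBundle:
    """Everything one synthetic study produces."""

    config: SimulationConfig
    grid: BinGrid
    genes: list[GeneModel]
    truth: GroundTruth
    tracks: dict[str, dict[str, list[BinnedTrack]]]  # cell -> mark -> reps
    spikein: dict[str, int]  # sample_id -> spike-in reads
    expression: pd.DataFrame  # genes x samples
    samples: pd.DataFrame  # sample_id, cell_type, category
    term_map: dict[str, set[str]]


# ---------------------------------------------------------------------------
# Genome and genes
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig) -> tuple[BinGrid, list[GeneModel]]:
    """Lay out non-overlapping genes with randomized positions and strands.

    Genes are placed one per equal-width slot with a uniformly random offset
    inside the slot, keeping enough clearance that planted TSS-state runs of
    neighbouring genes can never touch. Raises if the slots are too narrow
    for the requested gene count/length.
    """
    chroms = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    grid = BinGrid(bin_size=config.bin_size, chrom_lengths=chroms)
    if config.n_genes == 0:
        return grid, []

    rng = config.rng(11)
    margin = (config.broad_run_bins[1] // 2 + 2) * config.bin_size
    total_len = config.n_chroms * config.chrom_length
    slot = total_len // config.n_genes
    max_gene_len = config.gene_length_range[1]
    if slot < 2 * margin + max_gene_len:
        raise ValueError(
            "genes cannot fit without overlap: reduce n_genes or gene length "
            f"(slot {slot} bp < required {2 * margin + max_gene_len} bp)"
        )
    genes: list[GeneModel] = []
    per_chrom = config.n_genes // config.n_chroms
    extra = config.n_genes % config.n_chroms
    gi = 0
    for ci, chrom in enumerate(chroms):
        n_here = per_chrom + (1 if ci < extra else 0)
        chrom_slot = config.chrom_length // max(n_here, 1)
        if chrom_slot < 2 * margin + max_gene_len:
            raise ValueError("genes cannot fit without overlap on " + chrom)
        for s in range(n_here):
            length = int(rng.integers(config.gene_length_range[0],
                                      config.gene_length_range[1] + 1))
            lo = s * chrom_slot + margin
            hi = (s + 1) * chrom_slot - margin - length
            start = int(rng.integers(lo, hi + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            iv = GenomicInterval(chrom, start, start + length, strand)
            # two exons with one intron when the gene is long enough
            if length >= 900:
                e1 = GenomicInterval(chrom, start, start + length // 3, strand)
                e2 = GenomicInterval(chrom, start + 2 * length // 3,
                                     start + length, strand)
                exons = [e1, e2]
            else:
                exons = [iv]
            genes.append(GeneModel(f"gene{gi:04d}", iv, exons))
            gi += 1
    return grid, genes


# ---------------------------------------------------------------------------
# Hidden state paths
# ---------------------------------------------------------------------------

def _background_chain(rng: np.random.Generator, n: int,
                      transition_bias: float) -> np.ndarray:
    """Sticky Markov chain over background states 3..10."""
    states = BACKGROUND_STATES
    weights = np.array([BACKGROUND_WEIGHTS[s] for s in states])
    weights = weights / weights.sum()
    path = np.empty(n, dtype=np.int64)
    cur = int(rng.choice(states, p=weights))
    stay = rng.random(n) < transition_bias
    for i in range(n):
        if i > 0 and not stay[i]:
            # jump to a *different* state so the realized self-transition
            # frequency matches transition_bias
            w = weights.copy()
            w[states == cur] = 0.0
            cur = int(rng.choice(states, p=w / w.sum()))
        path[i] = cur
    return path


def simulate_state_paths(config: SimulationConfig,
                         genes: list[GeneModel],
                         grid: BinGrid) -> GroundTruth:
    """Plant per-gene TSS-state runs on a shared sticky background chain.

    The background path is shared between cell types; paths differ only at
    planted loci. Ordinary genes get 1-2 kb runs, ``broad`` genes >= 4 kb
    runs (same genes in both cell types), and ``specific`` genes get their
    run in their own cell type but the Repressed state at the same locus in
    the other cell type.
    """
    rng = config.rng(23)
    background = {
        chrom: _background_chain(rng, grid.n_bins(chrom), config.transition_bias)
        for chrom in grid.chroms
    }
    paths = {
        ct: {c: background[c].copy() for c in grid.chroms}
        for ct in config.cell_types
    }

    gene_ids = [g.gene_id for g in genes]
    n_broad = int(round(config.frac_broad_genes * len(genes)))
    n_specific = int(round(config.frac_specific_genes * len(genes)))
    perm = rng.permutation(len(genes))
    broad_list = [gene_ids[i] for i in perm[:n_broad]]
    broad_ids = set(broad_list)
    # a fraction of broad genes is cell-type specific (broad domains mark
    # identity genes), the rest of the specific genes come from non-broad ones
    n_bs = min(int(round(config.frac_broad_specific * n_broad)),
               n_broad // max(len(config.cell_types), 1),
               n_specific // max(len(config.cell_types), 1))
    specific = {ct: set() for ct in config.cell_types}
    for i, ct in enumerate(config.cell_types):
        specific[ct].update(broad_list[i * n_bs : (i + 1) * n_bs])
    n_rest = n_specific - n_bs * len(config.cell_types)
    rest_pool = [gene_ids[i] for i in perm[n_broad : n_broad + n_rest]]
    half = len(rest_pool) // 2
    if config.cell_types:
        specific[config.cell_types[0]].update(rest_pool[:half])
    if len(config.cell_types) > 1:
        specific[config.cell_types[1]].update(rest_pool[half:])

    specific_owner = {
        gid: ct for ct, ids in specific.items() for gid in ids
    }
    for g in genes:
        chrom = g.interval.chrom
        n_bins = grid.n_bins(chrom)
        if g.gene_id in broad_ids:
            run_len = int(rng.integers(config.broad_run_bins[0],
                                       config.broad_run_bins[1] + 1))
        else:
            run_len = int(rng.integers(config.ordinary_run_bins[0],
                                       config.ordinary_run_bins[1] + 1))
        tss_bin = grid.bin_index(g.tss)
        lo = max(0, tss_bin - run_len // 2)
        hi = min(n_bins, lo + run_len)
        # alternate Active core with Flanking edges (both are TSS states)
        run = np.full(hi - lo, TSS_ACTIVE, dtype=np.int64)
        if hi - lo >= 4:
            run[0] = TSS_FLANK
            run[-1] = TSS_FLANK
        owner = specific_owner.get(g.gene_id)
        for ct in config.cell_types:
            if owner is not None and ct != owner:
                paths[ct][chrom][lo:hi] = REPRESSED
            else:
                paths[ct][chrom][lo:hi] = run

    # a broad gene specific to the other cell type is repressed (not broad) here
    broad = {
        ct: {
            gid for gid in broad_ids
            if specific_owner.get(gid) in (None, ct)
        }
        for ct in config.cell_types
    }
    return GroundTruth(state_path=paths, broad_genes=broad,
                       specific_genes=specific)


# ---------------------------------------------------------------------------
# Mark counts and spike-ins
# ---------------------------------------------------------------------------

def simulate_mark_counts(
    config: SimulationConfig, truth: GroundTruth, grid: BinGrid
) -> tuple[dict[str, dict[str, list[BinnedTrack]]], dict[str, int]]:
    """Poisson per-bin counts with state-dependent rates, plus spike-ins.

    Returns ``tracks[cell_type][mark] -> list of replicate BinnedTracks`` and
    Poisson spike-in totals keyed by sample id ``{cell}_{mark}_rep{r}``.
    """
    rng = config.rng(37)
    tracks: dict[str, dict[str, list[BinnedTrack]]] = {}
    spikein: dict[str, int] = {}
    for ct in config.cell_types:
        tracks[ct] = {}
        for m_idx, mark in enumerate(config.marks):
            reps = []
            for r in range(config.n_reps_cutrun):
                values = {}
                for chrom in grid.chroms:
                    rates = config.state_rates[
                        truth.state_path[ct][chrom] - 1, m_idx
                    ]
                    values[chrom] = rng.poisson(rates).astype(float)
                sid = f"{ct}_{mark}_rep{r + 1}"
                reps.append(
                    BinnedTrack(grid=grid, values=values, sample_id=sid, mark=mark)
                )
                spikein[sid] = int(rng.poisson(config.spikein_mean))
            tracks[ct][mark] = reps
    return tracks, spikein


# ---------------------------------------------------------------------------
# Expression and term map
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """NB with var = mu + dispersion * mu^2; Poisson in the dispersion->0 limit."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_expression(
    config: SimulationConfig, truth: GroundTruth, genes: list[GeneModel]
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, set[str]]]:
    """NB expression counts with planted cell-type-specific fold changes.

    Specific genes have mean ``base * 2^specific_log2fc`` in their own cell
    type and ``base`` elsewhere; all other genes share means across types.
    Also emits a term->genes map whose 'developmental_process' term contains
    the broad-marked genes.
    """
    rng = config.rng(53)
    gene_ids = [g.gene_id for g in genes]
    base = rng.lognormal(mean=np.log(300.0), sigma=0.8, size=len(genes))
    owner = {gid: ct for ct, ids in truth.specific_genes.items() for gid in ids}

    samples = []
    for ct in config.cell_types:
        for r in range(config.n_reps_rna):
            samples.append(
                {
                    "sample_id": f"{ct}_rna{r + 1}",
                    "cell_type": ct,
                    "category": CATEGORIES.get(ct, ct),
                }
            )
    samples_df = pd.DataFrame(samples)

    counts = np.empty((len(genes), len(samples)), dtype=np.int64)
    fc = 2.0 ** config.specific_log2fc
    for j, row in samples_df.iterrows():
        mean = base.copy()
        boost = np.array(
            [owner.get(gid) == row["cell_type"] for gid in gene_ids]
        )
        mean[boost] *= fc
        counts[:, j] = _nb_draw(rng, mean, config.nb_dispersion)
    expr = pd.DataFrame(counts, index=gene_ids,
                        columns=samples_df["sample_id"].tolist())

    term_rng = config.rng(71)
    term_map: dict[str, set[str]] = {}
    all_broad = set().union(*truth.broad_genes.values()) if truth.broad_genes else set()
    term_map["developmental_process"] = set(all_broad)
    n_terms = 30
    size_hi = min(40, max(len(gene_ids) // 2, 2))
    size_lo = min(10, size_hi)
    for t in range(n_terms):
        size = int(term_rng.integers(size_lo, size_hi + 1))
        members = term_rng.choice(gene_ids, size=size, replace=False)
        term_map[f"term{t:03d}"] = set(members.tolist())
    return expr, samples_df, term_map


# ---------------------------------------------------------------------------
# Full study + file export
# ---------------------------------------------------------------------------

def simulate_study(config: SimulationConfig) -> StudyBundle:
    """Run every generator stage for one config."""
    grid, genes = simulate_genome(config)
    truth = simulate_state_paths(config, genes, grid)
    tracks, spikein = simulate_mark_counts(config, truth, grid)
    expr, samples, term_map = simulate_expression(config, truth, genes)
    return StudyBundle(config, grid, genes, truth, tracks, spikein,
                       expr, samples, term_map)


def write_study(bundle: StudyBundle, outdir: str | Path) -> Path:
    """Write every artifact as plain text (GTF/BED/bedGraph/TSV/JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gtf_genes(bundle.genes, outdir / "genes.gtf")
    write_bed(
        [
            GenomicInterval(
                g.interval.chrom, g.interval.start, g.interval.end,
                g.interval.strand, g.gene_id,
            )
            for g in bundle.genes
        ],
        outdir / "genes.bed",
    )
    for ct, marks in bundle.tracks.items():
        for mark, reps in marks.items():
            for t in reps:
                write_track(t, outdir / f"counts_{t.sample_id}.bedGraph")
    with open(outdir / "spikein.tsv", "w") as fh:
        fh.write("sample_id\tspikein_reads\n")
        for sid, reads in bundle.spikein.items():
            fh.write(f"{sid}\t{reads}\n")
    bundle.expression.rename_axis("gene_id").to_csv(
        outdir / "expression_counts.tsv", sep="\t"
    )
    bundle.samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    with open(outdir / "terms.tsv", "w") as fh:
        fh.write("term_id\tgene_id\n")
        for term, members in bundle.term_map.items():
            for gid in sorted(members):
                fh.write(f"{term}\t{gid}\n")
    truth_obj = {
        "broad_genes": {ct: sorted(v) for ct, v in bundle.truth.broad_genes.items()},
        "specific_genes": {
            ct: sorted(v) for ct, v in bundle.truth.specific_genes.items()
        },
        "state_path": {
            ct: {c: p.tolist() for c, p in paths.items()}
            for ct, paths in bundle.truth.state_path.items()
        },
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_obj, fh)
    return outdir
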