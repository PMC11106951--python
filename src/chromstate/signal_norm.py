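"""Spike-in normalization, smoothing, and Poisson-background binarization.

CUT&RUN signal is made comparable across samples by scaling each track with
``C / spike-in reads`` (exogenous E. coli reads). Binned counts are then
binarized with a Poisson tail rule: a bin is called present (1) when its
count is improbably high under a background rate taken as the larger of the
track-wide mean and, when an IgG control is supplied, the depth-scaled
control expectation for that bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .genome_io import BinGrid


@dataclass(frozen=True)
class ScaleFactor:
    """Spike-in scale factor: ``factor = constant_C / spikein_reads``."""

    sample_id: str
    spikein_reads: int
    constant_C: float = 10_000.0
    factor: float = field(init=False)

    def __post_init__(self) -> None:
        if self.spikein_reads <= 0:
            raise ValueError(
                f"sample {self.sample_id}: spike-in read count must be positive "
                f"(got {self.spikein_reads}); the spike-in likely failed"
            )
        object.__setattr__(self, "factor", self.constant_C / self.spikein_reads)


@dataclass
class BinnedTrack:
    """Per-bin signal for one sample/mark on a fixed grid."""

    grid: BinGrid
    values: dict[str, np.ndarray]
    sample_id: str = ""
    mark: str = ""

    def __post_init__(self) -> None:
        for chrom in self.grid.chroms:
            if chrom not in self.values:
                raise ValueError(f"track missing chrom {chrom}")
            n = self.grid.n_bins(chrom)
            v = np.asarray(self.values[chrom], dtype=float)
            if v.shape != (n,):
                raise ValueError(
                    f"{chrom}: expected {n} bins, got {v.shape}"
                )
            self.values[chrom] = v

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def concat(self) -> np.ndarray:
        return np.concatenate([self.values[c] for c in self.grid.chroms])


@dataclass
class BinaryMatrix:
    """0/1 mark calls per bin, column order fixed by ``marks``."""

    grid: BinGrid
    marks: list[str]
    calls: dict[str, np.ndarray]  # chrom -> (n_bins, n_marks) uint8
    cell_type: str = ""

    def __post_init__(self) -> None:
        for chrom in self.grid.chroms:
            arr = np.asarray(self.calls[chrom])
            if arr.shape != (self.grid.n_bins(chrom), len(self.marks)):
                raise ValueError(f"{chrom}: call matrix shape mismatch")
            if not np.isin(arr, (0, 1)).all():
                raise ValueError("binary matrix entries must be 0/1")
            self.calls[chrom] = arr.astype(np.uint8)

    def sequences(self) -> list[np.ndarray]:
        """Per-chromosome observation sequences (no transitions across chroms)."""
        return [self.calls[c] for c in self.grid.chroms]


def spikein_scale_factor(
    spikein_reads: int, constant_C: float = 10_000.0, sample_id: str = ""
) -> ScaleFactor:
    """Scale factor C / spike-in reads for one sample."""
    return ScaleFactor(sample_id=sample_id, spikein_reads=int(spikein_reads),
                       constant_C=constant_C)


def normalize_track(
    track: BinnedTrack, sf: ScaleFactor, smooth_bins: int | None = None
) -> BinnedTrack:
    """Scale a track by its spike-in factor, optionally running-mean smoothed.

    ``smooth_bins`` is an odd, centered window (e.g. 3 bins mirrors a 60-bp
    smooth on a 20-bp grid); the window is truncated at chromosome edges so
    edge bins average over the available neighbours only.
    """
    if smooth_bins is not None:
        if smooth_bins < 1:
            raise ValueError("smoothing window must cover at least one bin")
        if smooth_bins % 2 == 0:
            raise ValueError("smoothing window must be odd (centered)")
    out: dict[str, np.ndarray] = {}
    for chrom, vals in track.values.items():
        v = vals * sf.factor
        if smooth_bins is not None and smooth_bins > 1:
            kernel = np.ones(smooth_bins)
            counts = np.convolve(np.ones_like(v), kernel, mode="same")
            v = np.convolve(v, kernel, mode="same") / counts
        out[chrom] = v
    return BinnedTrack(grid=track.grid, values=out,
                       sample_id=track.sample_id, mark=track.mark)


def poisson_threshold(lambda_bg: float, p: float) -> int:
    """Smallest integer x with P(X >= x) <= p for X ~ Poisson(lambda_bg)."""
    if lambda_bg <= 0:
        raise ValueError("lambda_bg must be positive")
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    if p >= 1.0:
        return 0
    # P(X >= x) = sf(x - 1); start near the quantile and walk to the boundary
    x = int(stats.poisson.isf(p, lambda_bg))
    while x > 0 and stats.poisson.sf(x - 1, lambda_bg) <= p:
        x -= 1
    while stats.poisson.sf(x - 1, lambda_bg) > p:
        x += 1
    return x


def binarize(
    tracks: dict[str, list[BinnedTrack]],
    control: list[BinnedTrack] | None = None,
    p: float = 1e-4,
    cell_type: str = "",
    marks: list[str] | None = None,
    control_smooth_bins: int = 75,
) -> BinaryMatrix:
    """Poisson-tail binarization of pooled per-mark counts.

    Replicates of a mark are summed bin-wise before binarization. The per-bin
    background rate is ``max(global mean count/bin, control_bin * signal_total
    / control_total)`` when a pooled control is given, else the global mean.
    The pooled control is running-mean smoothed over ``control_smooth_bins``
    (default 75 bins, 15 kb at 200 bp) first: a shallow control's local
    relative noise is amplified by the signal/control depth ratio, so the
    expectation must be estimated over a regional window. A bin is called 1 iff its count reaches
    ``poisson_threshold(lambda, p)``.
    """
    if marks is None:
        marks = list(tracks)
    grid = next(iter(tracks.values()))[0].grid
    for reps in tracks.values():
        for t in reps:
            if t.grid != grid:
                raise ValueError("all tracks must share one bin grid")
    ctrl_vals = None
    ctrl_total = 0.0
    if control is not None:
        for t in control:
            if t.grid != grid:
                raise ValueError("control grid does not match signal grid")
        ctrl_vals = {}
        for c in grid.chroms:
            pooled_ctrl = np.sum([t.values[c] for t in control], axis=0)
            window = min(control_smooth_bins, len(pooled_ctrl))
            if window > 1:
                kernel = np.ones(window)
                norm = np.convolve(np.ones_like(pooled_ctrl), kernel, "same")
                pooled_ctrl = np.convolve(pooled_ctrl, kernel, "same") / norm
            ctrl_vals[c] = pooled_ctrl
        ctrl_total = float(sum(v.sum() for v in ctrl_vals.values()))

    calls: dict[str, np.ndarray] = {
        c: np.zeros((grid.n_bins(c), len(marks)), dtype=np.uint8)
        for c in grid.chroms
    }
    for m_idx, mark in enumerate(marks):
        pooled = {
            c: np.sum([t.values[c] for t in tracks[mark]], axis=0)
            for c in grid.chroms
        }
        total = float(sum(v.sum() for v in pooled.values()))
        global_mean = total / grid.total_bins
        for chrom in grid.chroms:
            counts = pooled[chrom]
            lam = np.full_like(counts, global_mean, dtype=float)
            if ctrl_vals is not None and ctrl_total > 0:
                lam = np.maximum(lam, ctrl_vals[chrom] * (total / ctrl_total))
            lam = np.maximum(lam, 1e-8)
            # count >= poisson_threshold(lam, p)  <=>  P(X >= count) <= p
            tail = stats.poisson.sf(counts - 1, lam)
            calls[chrom][:, m_idx] = ((counts > 0) & (tail <= p)).astype(np.uint8)
    return BinaryMatrix(grid=grid, marks=list(marks), calls=calls,
                        cell_type=cell_type)


# ---------------------------------------------------------------------------
# ChromHMM-style binarized text I/O
# ---------------------------------------------------------------------------

def write_binarized(binary: BinaryMatrix, outdir: str | Path) -> list[Path]:
    """One text file per chromosome: header 'cellType<TAB>chrom', mark names,
    then tab-separated 0/1 rows."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for chrom in binary.grid.chroms:
        path = outdir / f"{binary.cell_type}_{chrom}_binary.txt"
        with open(path, "w") as fh:
            fh.write(f"{binary.cell_type}\t{chrom}\n")
            fh.write("\t".join(binary.marks) + "\n")
            np.savetxt(fh, binary.calls[chrom], fmt="%d", delimiter="\t")
        paths.append(path)
    return paths


def read_binarized(paths: list[str | Path], grid: BinGrid) -> BinaryMatrix:
    """Read ChromHMM-style binarized text files back into a BinaryMatrix."""
    calls: dict[str, np.ndarray] = {}
    marks: list[str] | None = None
    cell_type = ""
    for path in paths:
        with open(path) as fh:
            cell_type, chrom = fh.readline().rstrip("\n").split("\t")
            file_marks = fh.readline().rstrip("\n").split("\t")
            if marks is None:
                marks = file_marks
            elif marks != file_marks:
                raise ValueError(f"{path}: mark header mismatch")
            data = np.loadtxt(fh, dtype=np.uint8, delimiter="\t", ndmin=2)
        calls[chrom] = data
    assert marks is not None
    return BinaryMatrix(grid=grid, marks=marks, calls=calls, cell_type=cell_type)
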