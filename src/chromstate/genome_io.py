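"""Core genomic types and plain-text readers/writers.

All internal coordinates are 0-based half-open ``[start, end)``. GTF input
(1-based, closed) is converted on read and can be converted back exactly.
Chromosome names are compared by exact string match; no "chr" normalization
is attempted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

log = logging.getLogger("chromstate")

_VALID_STRANDS = ("+", "-", ".")
_warned_unstranded = False


class ParseError(ValueError):
    """Raised for malformed records in BED/GTF/bedGraph input."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional BED name/score."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """1-bp overlap under half-open arithmetic."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def _effective_strand(strand: str) -> str:
    """Unstranded features are treated as '+' where strand is required."""
    global _warned_unstranded
    if strand == ".":
        if not _warned_unstranded:
            log.warning("unstranded feature treated as '+' for TSS-relative math")
            _warned_unstranded = True
        return "+"
    return strand


@dataclass
class GeneModel:
    """A gene span with strand-aware TSS/TES and sorted non-overlapping exons."""

    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = None
        for ex in self.exons:
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(
                    f"gene {self.gene_id}: exon {ex.start}-{ex.end} outside "
                    f"gene span {self.interval.start}-{self.interval.end}"
                )
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = ex.end

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        """Transcription start: 5' end of the gene span."""
        if _effective_strand(self.strand) == "+":
            return self.interval.start
        return self.interval.end - 1

    @property
    def tes(self) -> int:
        """Transcription end: 3' end of the gene span."""
        if _effective_strand(self.strand) == "+":
            return self.interval.end - 1
        return self.interval.start


@dataclass(frozen=True)
class BinGrid:
    """Fixed-width bins over a set of chromosomes; the last bin may be short."""

    bin_size: int
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chrom {chrom} has non-positive length")

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    def n_bins(self, chrom: str) -> int:
        return math.ceil(self.chrom_lengths[chrom] / self.bin_size)

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.chrom_lengths)

    def bin_index(self, pos: int) -> int:
        return pos // self.bin_size

    def bin_interval(self, chrom: str, index: int) -> GenomicInterval:
        start = index * self.bin_size
        end = min(start + self.bin_size, self.chrom_lengths[chrom])
        return GenomicInterval(chrom, start, end)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a 3-6 column BED file (0-based half-open, preserved exactly)."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from e
            if start >= end or start < 0:
                raise ParseError(
                    f"{path}:{lineno}: invalid coordinates start={start} end={end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as e:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from e
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in _VALID_STRANDS:
                raise ParseError(f"{path}:{lineno}: invalid strand {strand!r}")
            intervals.append(GenomicInterval(chrom, start, end, strand, name, score))
    return intervals


def write_bed(
    records: Iterable[GenomicInterval | tuple[GenomicInterval, str]],
    path: str | Path,
) -> None:
    """Write intervals (or (interval, label) pairs) as BED.

    Labeled records emit the label in the name column; round-trips through
    :func:`read_bed`.
    """
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, tuple):
                iv, label = rec
            else:
                iv, label = rec, rec.name
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if label is not None or iv.score is not None or iv.strand != ".":
                cols.append(label if label is not None else ".")
            if iv.score is not None or iv.strand != ".":
                cols.append("." if iv.score is None else _fmt_num(iv.score))
            if iv.strand != ".":
                cols.append(iv.strand)
            fh.write("\t".join(cols) + "\n")


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(x)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _gtf_attributes(raw: str, path, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            continue
        key, value = parts
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf_genes(path: str | Path) -> list[GeneModel]:
    """Read gene models (gene + exon features) from a GTF file.

    GTF 1-based closed coordinates become 0-based half-open (start-1, end).
    One :class:`GeneModel` is returned per ``gene_id``, in order of first
    appearance; exons are attached to their gene, sorted by start.
    """
    genes: dict[str, GenomicInterval] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: fewer than 9 GTF columns")
            chrom, _source, feature, start1, end1, _score, strand, _frame, attr = (
                fields[:9]
            )
            if feature not in ("gene", "exon"):
                continue
            try:
                start, end = int(start1) - 1, int(end1)
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from e
            attrs = _gtf_attributes(attr, path, lineno)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
            iv = GenomicInterval(chrom, start, end, strand if strand in _VALID_STRANDS else ".")
            if feature == "gene":
                if gene_id not in genes:
                    order.append(gene_id)
                genes[gene_id] = iv
            else:
                exons.setdefault(gene_id, []).append(iv)
                if gene_id not in genes:
                    order.append(gene_id)

    models: list[GeneModel] = []
    for gid in order:
        if gid not in genes:
            # exon-only record set: infer gene span from exon extent
            exs = sorted(exons[gid], key=lambda e: e.start)
            genes[gid] = GenomicInterval(
                exs[0].chrom, exs[0].start, exs[-1].end, exs[0].strand
            )
        span = genes[gid]
        exs = sorted(exons.get(gid, []), key=lambda e: e.start)
        models.append(GeneModel(gid, span, exs))
    return models


def write_gtf_genes(models: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models back out as GTF (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for g in models:
            iv = g.interval
            base = (
                f"{iv.chrom}\tchromstate\t{{feat}}\t{{s}}\t{{e}}\t.\t{iv.strand}\t.\t"
                f'gene_id "{g.gene_id}";\n'
            )
            fh.write(base.format(feat="gene", s=iv.start + 1, e=iv.end))
            for ex in g.exons:
                fh.write(base.format(feat="exon", s=ex.start + 1, e=ex.end))


# ---------------------------------------------------------------------------
# Per-bin tracks (bedGraph / TSV)
# ---------------------------------------------------------------------------

def read_track(path: str | Path, grid: BinGrid):
    """Read a bedGraph of per-bin values into a dense :class:`BinnedTrack`.

    Records must align to grid bin boundaries (a record may span several whole
    bins); unlisted bins are zero. Returns a ``signal_norm.BinnedTrack``.
    """
    import numpy as np

    from .signal_norm import BinnedTrack

    values = {c: np.zeros(grid.n_bins(c)) for c in grid.chroms}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: need 4 bedGraph columns")
            chrom = fields[0]
            if chrom not in values:
                raise ParseError(f"{path}:{lineno}: unknown chrom {chrom!r}")
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: malformed record") from e
            bs = grid.bin_size
            chrom_len = grid.chrom_lengths[chrom]
            end_ok = end % bs == 0 or end == chrom_len
            if start % bs != 0 or not end_ok or start >= end:
                raise ParseError(
                    f"{path}:{lineno}: record {start}-{end} crosses a {bs}-bp bin "
                    "boundary; re-bin the input to the grid"
                )
            values[chrom][start // bs : math.ceil(end / bs)] = value
    return BinnedTrack(grid=grid, values=values, sample_id=str(path), mark="")


def write_track(track, path: str | Path) -> None:
    """Write a BinnedTrack as bedGraph (one record per bin, zeros included)."""
    grid = track.grid
    with open(path, "w") as fh:
        for chrom in grid.chroms:
            vals = track.values[chrom]
            bs = grid.bin_size
            chrom_len = grid.chrom_lengths[chrom]
            for i, v in enumerate(vals):
                end = min((i + 1) * bs, chrom_len)
                fh.write(f"{chrom}\t{i * bs}\t{end}\t{_fmt_num(float(v))}\n")
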