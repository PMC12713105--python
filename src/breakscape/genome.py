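"""Genome coordinate primitives shared by every analysis stage.

All coordinates are 0-based half-open (BED convention). A :class:`GenomeBinning`
tiles each chromosome with fixed-width bins; the trailing bin of a chromosome
may be shorter (it is retained, and carries its true length, so binnings are
always partitions of the genome).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "GenomeBinning",
    "GeneRecord",
    "make_bins",
    "median_nucleotide",
    "nearest_tss_distance",
    "overlaps",
    "bins_overlapping",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its TSS and per-condition expression (FPKM).

    The TSS is the 5' end of the gene body: ``start`` for plus-strand genes,
    ``end - 1`` for minus-strand genes.
    """

    gene_id: str
    interval: GenomicInterval
    fpkm_control: float = 0.0
    fpkm_treated: float = 0.0
    is_deg: bool = False

    def __post_init__(self) -> None:
        if self.fpkm_control < 0 or self.fpkm_treated < 0:
            raise ValueError(f"negative FPKM for gene {self.gene_id}")
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id} needs an explicit strand")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1


class GenomeBinning:
    """Fixed-width tiling of a genome.

    Bins are ordered by chromosome (insertion order of ``chrom_sizes``) then
    start coordinate; the index <-> (chrom, start) mapping is a bijection.
    """

    def __init__(self, chrom_sizes: Mapping[str, int], bin_width: int) -> None:
        if bin_width <= 0:
            raise ValueError(f"bin_width must be positive, got {bin_width}")
        if not chrom_sizes:
            raise ValueError("empty genome: no chromosomes given")
        for chrom, size in chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {size}")
        self.chrom_sizes: dict[str, int] = dict(chrom_sizes)
        self.bin_width = int(bin_width)
        self._chrom_offset: dict[str, int] = {}
        self._chrom_nbins: dict[str, int] = {}
        offset = 0
        for chrom, size in self.chrom_sizes.items():
            nb = -(-size // bin_width)  # ceil division: trailing partial bin kept
            self._chrom_offset[chrom] = offset
            self._chrom_nbins[chrom] = nb
            offset += nb
        self.n_bins = offset

    # -- index arithmetic ---------------------------------------------------

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global index of the bin containing base ``pos``."""
        if chrom not in self.chrom_sizes:
            raise KeyError(f"chromosome {chrom} not in binning")
        if not 0 <= pos < self.chrom_sizes[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        return self._chrom_offset[chrom] + pos // self.bin_width

    def bin_interval(self, index: int) -> GenomicInterval:
        chrom, local = self._locate(index)
        start = local * self.bin_width
        end = min(start + self.bin_width, self.chrom_sizes[chrom])
        return GenomicInterval(chrom, start, end)

    def _locate(self, index: int) -> tuple[str, int]:
        if not 0 <= index < self.n_bins:
            raise IndexError(f"bin index {index} out of range")
        for chrom in self.chrom_sizes:
            off = self._chrom_offset[chrom]
            nb = self._chrom_nbins[chrom]
            if off <= index < off + nb:
                return chrom, index - off
        raise IndexError(index)  # pragma: no cover

    def chrom_slice(self, chrom: str) -> slice:
        """Global-index slice covering all bins of one chromosome."""
        off = self._chrom_offset[chrom]
        return slice(off, off + self._chrom_nbins[chrom])

    def n_bins_of(self, chrom: str) -> int:
        return self._chrom_nbins[chrom]

    @property
    def bins(self) -> list[GenomicInterval]:
        return [self.bin_interval(i) for i in range(self.n_bins)]

    def bin_lengths(self) -> np.ndarray:
        """Length in bp of every bin (trailing bins may be short)."""
        out = np.full(self.n_bins, self.bin_width, dtype=np.int64)
        for chrom, size in self.chrom_sizes.items():
            rem = size % self.bin_width
            if rem:
                out[self._chrom_offset[chrom] + self._chrom_nbins[chrom] - 1] = rem
        return out

    def bin_starts(self) -> np.ndarray:
        """Per-bin start coordinate (chromosome-local)."""
        parts = [
            np.arange(self._chrom_nbins[c], dtype=np.int64) * self.bin_width
            for c in self.chrom_sizes
        ]
        return np.concatenate(parts)

    def bin_chroms(self) -> np.ndarray:
        parts = [
            np.repeat(c, self._chrom_nbins[c]) for c in self.chrom_sizes
        ]
        return np.concatenate(parts)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, GenomeBinning)
            and self.chrom_sizes == other.chrom_sizes
            and self.bin_width == other.bin_width
        )

    def __repr__(self) -> str:
        return (
            f"GenomeBinning({len(self.chrom_sizes)} chroms, "
            f"bin_width={self.bin_width}, n_bins={self.n_bins})"
        )


def make_bins(chrom_sizes: Mapping[str, int], bin_width: int = 5000) -> GenomeBinning:
    """Tile a genome with fixed-width bins (default 5 kb)."""
    return GenomeBinning(chrom_sizes, bin_width)


def median_nucleotide(region: GenomicInterval) -> int:
    """Central base of a region; the lower of the two middles for even lengths."""
    return region.start + (len(region) - 1) // 2


def nearest_tss_distance(
    region: GenomicInterval, genes: Sequence[GeneRecord]
) -> int | None:
    """Distance from the region's median nucleotide to the nearest TSS.

    Only genes on the region's chromosome are considered; returns ``None``
    when no gene shares the chromosome (callers exclude such regions).
    """
    if not genes:
        raise ValueError("empty gene list")
    mid = median_nucleotide(region)
    best: int | None = None
    for g in genes:
        if g.chrom != region.chrom:
            continue
        d = abs(g.tss - mid)
        if best is None or d < best:
            best = d
    return best


def nearest_tss_distances(
    binning: GenomeBinning, genes: Sequence[GeneRecord]
) -> np.ndarray:
    """Vectorised nearest-TSS distance for every bin (NaN = no gene on chrom)."""
    if not genes:
        raise ValueError("empty gene list")
    out = np.full(binning.n_bins, np.nan)
    tss_by_chrom: dict[str, list[int]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append(g.tss)
    lengths = binning.bin_lengths()
    starts = binning.bin_starts()
    mids = starts + (lengths - 1) // 2
    for chrom, tss_list in tss_by_chrom.items():
        if chrom not in binning.chrom_sizes:
            continue
        sl = binning.chrom_slice(chrom)
        tss = np.sort(np.asarray(tss_list, dtype=np.int64))
        m = mids[sl]
        idx = np.searchsorted(tss, m)
        left = np.abs(m - tss[np.clip(idx - 1, 0, len(tss) - 1)])
        right = np.abs(tss[np.clip(idx, 0, len(tss) - 1)] - m)
        out[sl] = np.minimum(left, right)
    return out


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Half-open overlap test; cross-chromosome pairs never overlap."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def bins_overlapping(iv: GenomicInterval, binning: GenomeBinning) -> list[int]:
    """Global indices of every bin sharing >= 1 bp with ``iv``."""
    if iv.chrom not in binning.chrom_sizes:
        return []
    size = binning.chrom_sizes[iv.chrom]
    start = min(iv.start, size)
    end = min(iv.end, size)
    if start >= end:
        return []
    off = binning._chrom_offset[iv.chrom]
    first = start // binning.bin_width
    last = (end - 1) // binning.bin_width
    return list(range(off + first, off + last + 1))
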