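"""Readers and writers for the plain-text genomics formats the pipeline uses.

Everything is 0-based half-open on disk and in memory (BED family). Writers
emit deterministic ordering (chromosome, then start) so identical inputs give
byte-identical files.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GeneRecord, GenomeBinning, GenomicInterval

__all__ = [
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_labeled_bed",
    "write_labeled_bed",
    "read_gene_table",
    "write_gene_table",
    "read_bedgraph",
    "write_bedgraph",
    "read_contact_matrix",
    "write_contact_matrix",
    "read_tads",
    "write_tads",
]

GENE_TABLE_COLUMNS = [
    "gene_id",
    "chrom",
    "start",
    "end",
    "strand",
    "fpkm_control",
    "fpkm_treated",
    "deg_flag",
]


def _sorted_intervals(ivs: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(ivs, key=lambda iv: (iv.chrom, iv.start, iv.end))


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        chrom, size = line.split()[:2]
        sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    Path(path).write_text("".join(f"{c}\t{s}\n" for c, s in sizes.items()))


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 intervals; strand taken from column 6 when present."""
    out: list[GenomicInterval] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        strand = f[5] if len(f) >= 6 and f[5] in ("+", "-") else "."
        out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_bed(ivs: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in _sorted_intervals(ivs):
            if iv.strand == ".":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_labeled_bed(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    """BED4+ where column 4 carries a label (chromatin state, repeat subtype)."""
    out: list[tuple[GenomicInterval, str]] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 4:
            raise ValueError(f"labeled BED needs 4 columns, got: {line!r}")
        out.append((GenomicInterval(f[0], int(f[1]), int(f[2])), f[3]))
    return out


def write_labeled_bed(
    items: Iterable[tuple[GenomicInterval, str]], path: str | Path
) -> None:
    ordered = sorted(items, key=lambda t: (t[0].chrom, t[0].start, t[0].end, t[1]))
    with open(path, "w") as fh:
        for iv, label in ordered:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\n")


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Tab-separated GTF-lite gene table (see ``GENE_TABLE_COLUMNS``)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneRecord(
                gene_id=str(row.gene_id),
                interval=GenomicInterval(
                    str(row.chrom), int(row.start), int(row.end), str(row.strand)
                ),
                fpkm_control=float(row.fpkm_control),
                fpkm_treated=float(row.fpkm_treated),
                is_deg=bool(int(row.deg_flag)),
            )
        )
    return genes


def write_gene_table(genes: Sequence[GeneRecord], path: str | Path) -> None:
    rows = [
        (
            g.gene_id,
            g.chrom,
            g.interval.start,
            g.interval.end,
            g.strand,
            f"{g.fpkm_control:.6g}",
            f"{g.fpkm_treated:.6g}",
            int(g.is_deg),
        )
        for g in sorted(genes, key=lambda g: (g.chrom, g.interval.start, g.gene_id))
    ]
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_bedgraph(path: str | Path) -> list[tuple[GenomicInterval, float]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        out.append((GenomicInterval(f[0], int(f[1]), int(f[2])), float(f[3])))
    return out


def write_bedgraph(
    items: Iterable[tuple[GenomicInterval, float]], path: str | Path
) -> None:
    ordered = sorted(items, key=lambda t: (t[0].chrom, t[0].start))
    with open(path, "w") as fh:
        for iv, v in ordered:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{v:.6g}\n")


def bedgraph_to_track(
    items: Sequence[tuple[GenomicInterval, float]], binning: GenomeBinning
) -> np.ndarray:
    """Map bedGraph entries onto a binning (NaN where absent)."""
    vals = np.full(binning.n_bins, np.nan)
    for iv, v in items:
        if iv.chrom not in binning.chrom_sizes:
            continue
        vals[binning.bin_index(iv.chrom, iv.start)] = v
    return vals


# -- sparse contact matrices ------------------------------------------------


def write_contact_matrix(
    triplets: np.ndarray, chrom: str, n_bins: int, resolution: int, path: str | Path
) -> None:
    """Write a symmetric sparse matrix as upper-triangle triplet text.

    ``triplets`` is an (m, 3) integer array of (bin_i, bin_j, count) with
    i <= j; a header sidecar line records the binning.
    """
    tri = np.asarray(triplets, dtype=np.int64)
    order = np.lexsort((tri[:, 1], tri[:, 0])) if len(tri) else []
    with open(path, "w") as fh:
        fh.write(f"# chrom={chrom} n_bins={n_bins} resolution={resolution}\n")
        for i, j, c in tri[order]:
            fh.write(f"{i}\t{j}\t{c}\n")


def read_contact_matrix(path: str | Path) -> tuple[np.ndarray, str, int, int]:
    """Read triplet text; returns (triplets, chrom, n_bins, resolution)."""
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise ValueError(f"{path}: missing '# chrom=... n_bins=... resolution=' header")
    header = dict(kv.split("=") for kv in lines[0][1:].split())
    rows = [tuple(int(x) for x in ln.split("\t")) for ln in lines[1:] if ln.strip()]
    tri = np.asarray(rows, dtype=np.int64).reshape(-1, 3)
    return tri, header["chrom"], int(header["n_bins"]), int(header["resolution"])


def read_tads(path: str | Path) -> list[tuple[GenomicInterval, int]]:
    """TSV TAD calls: chrom, start, end, level (header optional)."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("chrom\t"):
            continue
        f = line.split("\t")
        out.append((GenomicInterval(f[0], int(f[1]), int(f[2])), int(f[3])))
    return out


def write_tads(tads: Iterable[tuple[GenomicInterval, int]], path: str | Path) -> None:
    ordered = sorted(tads, key=lambda t: (t[0].chrom, t[0].start, -t[1]))
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tlevel\n")
        for iv, lvl in ordered:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{lvl}\n")
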