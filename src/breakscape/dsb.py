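"""DSB (double-strand break) enrichment quantification.

Breakpoint sites are counted into fixed genome bins (5 kb by default), each
condition is depth-normalised to CPM, and the per-bin treated/control fold
change ("DSB ratio") is the central statistic. On top of the ratio track the
module implements the stratified analyses used to characterise where
treatment-induced breaks land: distance-to-TSS profiles, ratio-decile classes
versus chromatin state, enhancer proximity, peak/repeat correlations and a
strand-oriented TSS meta-profile.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .genome import (
    GeneRecord,
    GenomeBinning,
    GenomicInterval,
    bins_overlapping,
    nearest_tss_distances,
)

__all__ = [
    "BinnedTrack",
    "DsbRatioTrack",
    "DsbEnrichmentRegion",
    "ChromStateSegment",
    "ENHA_STATES",
    "count_reads_per_bin",
    "dsb_ratio",
    "hypergeom_bin_test",
    "call_enrichment_regions",
    "multiscale_median_smooth",
    "split_ratio_classes",
    "tss_distance_profile",
    "element_fraction_by_class",
    "classify_enhancer_proximity",
    "compare_ratio_by_feature",
    "repeat_subtype_correlation",
    "tss_meta_profile",
]

ENHA_STATES = ("EnhA1", "EnhA2")


@dataclass
class BinnedTrack:
    """One numeric value per genome bin (counts, CPM, ratio, coverage)."""

    binning: GenomeBinning
    values: np.ndarray
    units: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.binning.n_bins,):
            raise ValueError(
                f"track length {self.values.shape} != n_bins {self.binning.n_bins}"
            )

    @property
    def n_bins(self) -> int:
        return self.binning.n_bins


@dataclass
class DsbRatioTrack:
    """Per-bin treated/control fold change with its CPM components."""

    binning: GenomeBinning
    ratio: np.ndarray
    treated_cpm: np.ndarray
    control_cpm: np.ndarray
    pseudocount: float

    @property
    def mean_ratio(self) -> float:
        """Genome-wide arithmetic mean of per-bin ratios."""
        return float(np.mean(self.ratio))

    @property
    def totals_ratio(self) -> float:
        """Ratio of library-normalised totals (alternative genome-wide fold)."""
        return float(np.sum(self.treated_cpm) / np.sum(self.control_cpm))


@dataclass(frozen=True)
class DsbEnrichmentRegion:
    interval: GenomicInterval
    fold: float
    p_value: float
    q_value: float


@dataclass
class ChromStateSegment:
    """Labeled interval from a chromatin-state segmentation (ChromHMM-style)."""

    interval: GenomicInterval
    state: str
    proximity: str = "n/a"  # proximal/distal, EnhA states only


def count_reads_per_bin(
    sites: Sequence[GenomicInterval], binning: GenomeBinning
) -> tuple[BinnedTrack, int]:
    """Count breakpoint sites per bin by their 5' coordinate.

    The 5' breakpoint of a site is its start for +/. strands and ``end - 1``
    for minus-strand records. Sites off any chromosome in the binning are
    skipped; the skip count is returned alongside the track.
    """
    counts = np.zeros(binning.n_bins, dtype=float)
    skipped = 0
    for s in sites:
        pos = s.start if s.strand != "-" else s.end - 1
        if s.chrom not in binning.chrom_sizes or not (
            0 <= pos < binning.chrom_sizes[s.chrom]
        ):
            skipped += 1
            continue
        counts[binning.bin_index(s.chrom, pos)] += 1
    return BinnedTrack(binning, counts, units="raw"), skipped


def dsb_ratio(
    treated: BinnedTrack,
    control: BinnedTrack,
    pseudocount: float = 0.5,
) -> DsbRatioTrack:
    """Per-bin fold change of CPM-normalised DSB signal, treated over control.

    CPM = count / library_total * 1e6; the pseudocount keeps ratios finite at
    zero-count bins and makes the statistic invariant to global library
    scaling.
    """
    if treated.binning != control.binning:
        raise ValueError("treated and control tracks use different binnings")
    t_total = float(np.sum(treated.values))
    c_total = float(np.sum(control.values))
    if t_total <= 0 or c_total <= 0:
        raise ValueError("library sizes must be positive")
    t_cpm = treated.values / t_total * 1e6
    c_cpm = control.values / c_total * 1e6
    ratio = (t_cpm + pseudocount) / (c_cpm + pseudocount)
    return DsbRatioTrack(
        binning=treated.binning,
        ratio=ratio,
        treated_cpm=t_cpm,
        control_cpm=c_cpm,
        pseudocount=pseudocount,
    )


def hypergeom_bin_test(
    k_bin_treated: int, n_bin_total: int, K_treated_total: int, N_grand_total: int
) -> float:
    """Upper-tail hypergeometric P(X >= k) for treated-read excess in a bin.

    Population = all reads of both samples (N), marked = treated reads (K),
    draws = reads falling in the bin (n), successes = treated reads in the
    bin (k).
    """
    k, n, K, N = k_bin_treated, n_bin_total, K_treated_total, N_grand_total
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(
            f"inconsistent margins k={k}, n={n}, K={K}, N={N}"
        )
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def call_enrichment_regions(
    ratio: DsbRatioTrack,
    pvals: np.ndarray,
    q_threshold: float = 0.05,
    fold_threshold: float = 2.0,
) -> list[DsbEnrichmentRegion]:
    """BH-correct per-bin p-values and merge significant adjacent bins.

    A bin is significant when q < ``q_threshold`` and ratio >= ``fold_threshold``;
    maximal runs of adjacent significant bins on the same chromosome become
    one region (fold = max bin ratio, p/q = min over member bins).
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.shape != (ratio.binning.n_bins,):
        raise ValueError("p-value vector not aligned to binning")
    qvals = stats.false_discovery_control(pvals, method="bh")
    sig = (qvals < q_threshold) & (ratio.ratio >= fold_threshold)
    regions: list[DsbEnrichmentRegion] = []
    binning = ratio.binning
    for chrom in binning.chrom_sizes:
        sl = binning.chrom_slice(chrom)
        idx = np.flatnonzero(sig[sl]) + sl.start
        if len(idx) == 0:
            continue
        run_start = idx[0]
        prev = idx[0]
        for i in list(idx[1:]) + [None]:
            if i is not None and i == prev + 1:
                prev = i
                continue
            members = slice(run_start, prev + 1)
            iv = GenomicInterval(
                chrom,
                binning.bin_interval(run_start).start,
                binning.bin_interval(prev).end,
            )
            regions.append(
                DsbEnrichmentRegion(
                    interval=iv,
                    fold=float(np.max(ratio.ratio[members])),
                    p_value=float(np.min(pvals[members])),
                    q_value=float(np.min(qvals[members])),
                )
            )
            if i is not None:
                run_start = prev = i
    return regions


def multiscale_median_smooth(
    raw: BinnedTrack, scales: Sequence[int]
) -> dict[int, BinnedTrack]:
    """Median-smooth a base-resolution track over non-overlapping windows.

    At scale ``k * base`` each output value is the median of the k raw values
    in that window; trailing partial windows use the values available. Window
    boundaries never cross chromosomes. Scale equal to the base width is the
    identity.
    """
    base = raw.binning.bin_width
    out: dict[int, BinnedTrack] = {}
    for scale in scales:
        if scale % base != 0 or scale <= 0:
            raise ValueError(f"scale {scale} is not a positive multiple of {base}")
        k = scale // base
        coarse = GenomeBinning(raw.binning.chrom_sizes, scale)
        vals = np.empty(coarse.n_bins)
        for chrom in raw.binning.chrom_sizes:
            fine = raw.values[raw.binning.chrom_slice(chrom)]
            csl = coarse.chrom_slice(chrom)
            for w in range(csl.stop - csl.start):
                vals[csl.start + w] = np.median(fine[w * k : (w + 1) * k])
        out[scale] = BinnedTrack(coarse, vals, units=raw.units)
    return out


def _descending_order(ratio: DsbRatioTrack, mask: np.ndarray | None = None) -> np.ndarray:
    """Bin indices sorted by descending ratio, ties broken by genomic order."""
    idx = np.arange(ratio.binning.n_bins) if mask is None else np.flatnonzero(mask)
    order = np.lexsort((idx, -ratio.ratio[idx]))
    return idx[order]


def _equal_count_groups(n_items: int, n_groups: int) -> np.ndarray:
    """Group sizes differing by at most one, larger groups first."""
    base, rem = divmod(n_items, n_groups)
    return np.array([base + (1 if g < rem else 0) for g in range(n_groups)])


def split_ratio_classes(ratio: DsbRatioTrack, n_classes: int = 10) -> np.ndarray:
    """Partition bins into equal-count classes by descending DSB ratio.

    Returns a per-bin class label in 1..n_classes; class 1 holds the highest
    ratios. Class sizes differ by at most one (larger classes first).
    """
    n = ratio.binning.n_bins
    if n < n_classes:
        raise ValueError(f"{n} bins cannot form {n_classes} classes")
    order = _descending_order(ratio)
    sizes = _equal_count_groups(n, n_classes)
    labels = np.empty(n, dtype=int)
    pos = 0
    for cls, size in enumerate(sizes, start=1):
        labels[order[pos : pos + size]] = cls
        pos += size
    return labels


@dataclass
class TssDistanceProfile:
    mean_ratio: np.ndarray
    mean_distance: np.ndarray
    spearman_rho: float
    spearman_p: float
    pearson_r: float
    pearson_p: float


def tss_distance_profile(
    ratio: DsbRatioTrack, genes: Sequence[GeneRecord], n_bins: int = 500
) -> TssDistanceProfile:
    """Relate DSB ratio to distance from gene TSSs.

    Genomic bins (regions) are sorted in descending ratio order and grouped
    into ``n_bins`` equal-count groups; per group the mean ratio and mean
    nearest-TSS distance (region median nucleotide to nearest TSS) are
    reported, with Spearman and Pearson correlations over the group pairs.
    Regions on chromosomes without genes are excluded.
    """
    dists = nearest_tss_distances(ratio.binning, genes)
    defined = ~np.isnan(dists)
    n_regions = int(defined.sum())
    if n_regions < n_bins:
        raise ValueError(f"only {n_regions} regions with defined TSS distance")
    order = _descending_order(ratio, defined)
    sizes = _equal_count_groups(n_regions, n_bins)
    mean_ratio = np.empty(n_bins)
    mean_dist = np.empty(n_bins)
    pos = 0
    for g, size in enumerate(sizes):
        sel = order[pos : pos + size]
        mean_ratio[g] = np.mean(ratio.ratio[sel])
        mean_dist[g] = np.mean(dists[sel])
        pos += size
    rho, rho_p = stats.spearmanr(mean_ratio, mean_dist)
    r, r_p = stats.pearsonr(mean_ratio, mean_dist)
    return TssDistanceProfile(
        mean_ratio=mean_ratio,
        mean_distance=mean_dist,
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
        pearson_r=float(r),
        pearson_p=float(r_p),
    )


def bins_with_state(
    states: Iterable[ChromStateSegment],
    binning: GenomeBinning,
    wanted: Sequence[str],
) -> np.ndarray:
    """Boolean mask of bins overlapping (>=1 bp) any segment in ``wanted``."""
    mask = np.zeros(binning.n_bins, dtype=bool)
    wanted_set = set(wanted)
    for seg in states:
        if seg.state in wanted_set:
            for b in bins_overlapping(seg.interval, binning):
                mask[b] = True
    return mask


@dataclass
class ClassElementFractions:
    class_mean_ratio: np.ndarray
    tssa_fraction: np.ndarray
    enha_fraction: np.ndarray
    tssa_spearman: float
    enha_spearman: float


def element_fraction_by_class(
    classes: np.ndarray,
    ratio: DsbRatioTrack,
    states: Sequence[ChromStateSegment],
) -> ClassElementFractions:
    """Fraction of bins per ratio class containing TssA / active enhancers.

    A bin "contains" an element when it overlaps a segment by >=1 bp. The
    Spearman correlation is computed between class mean ratio and fraction.
    """
    binning = ratio.binning
    tssa = bins_with_state(states, binning, ["TssA"])
    enha = bins_with_state(states, binning, list(ENHA_STATES))
    labels = np.unique(classes)
    mean_r = np.array([ratio.ratio[classes == c].mean() for c in labels])
    tssa_f = np.array([tssa[classes == c].mean() for c in labels])
    enha_f = np.array([enha[classes == c].mean() for c in labels])
    def _rho(frac: np.ndarray) -> float:
        if len(labels) < 2 or np.allclose(frac, frac[0]) or np.allclose(
            mean_r, mean_r[0]
        ):
            return float("nan")
        return float(stats.spearmanr(mean_r, frac).statistic)

    return ClassElementFractions(
        class_mean_ratio=mean_r,
        tssa_fraction=tssa_f,
        enha_fraction=enha_f,
        tssa_spearman=_rho(tssa_f),
        enha_spearman=_rho(enha_f),
    )


def classify_enhancer_proximity(
    states: Sequence[ChromStateSegment], window: int = 20000
) -> list[ChromStateSegment]:
    """Mark EnhA segments proximal/distal by TssA edge-to-edge distance.

    An active enhancer is proximal when some TssA segment lies within
    ``window`` bp (edge-to-edge gap; overlap counts as gap 0), else distal.
    Returns new segments; non-EnhA states keep proximity "n/a".
    """
    tssa_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for seg in states:
        if seg.state == "TssA":
            tssa_by_chrom.setdefault(seg.interval.chrom, []).append(
                (seg.interval.start, seg.interval.end)
            )
    for ivs in tssa_by_chrom.values():
        ivs.sort()
    out: list[ChromStateSegment] = []
    for seg in states:
        if seg.state not in ENHA_STATES:
            out.append(ChromStateSegment(seg.interval, seg.state, "n/a"))
            continue
        gap = _min_gap(seg.interval, tssa_by_chrom.get(seg.interval.chrom, []))
        proximity = "proximal" if gap is not None and gap <= window else "distal"
        out.append(ChromStateSegment(seg.interval, seg.state, proximity))
    return out


def _min_gap(iv: GenomicInterval, sorted_ivs: list[tuple[int, int]]) -> int | None:
    best: int | None = None
    for s, e in sorted_ivs:
        if s < iv.end and iv.start < e:
            return 0
        gap = s - iv.end if s >= iv.end else iv.start - e
        if best is None or gap < best:
            best = gap
    return best


@dataclass
class RankSumResult:
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    statistic: float
    p_value: float


def compare_ratio_by_feature(
    ratio: DsbRatioTrack, feature_bins: np.ndarray | set
) -> RankSumResult:
    """Wilcoxon rank-sum of DSB ratio in bins with vs without a feature.

    Two-sided Mann-Whitney U; exact for small untied samples, tie-corrected
    normal approximation otherwise.
    """
    mask = np.zeros(ratio.binning.n_bins, dtype=bool)
    mask[np.asarray(sorted(feature_bins), dtype=int)] = True
    return rank_sum_compare(ratio.ratio[mask], ratio.ratio[~mask])


def rank_sum_compare(a: np.ndarray, b: np.ndarray) -> RankSumResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return RankSumResult(
        n_a=len(a),
        n_b=len(b),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def coverage_fraction(
    intervals: Iterable[GenomicInterval], binning: GenomeBinning
) -> np.ndarray:
    """Per-bin fraction of bases covered by a set of intervals.

    Overlapping intervals within the set are counted once (true coverage).
    """
    covered = np.zeros(binning.n_bins, dtype=float)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        if iv.chrom in binning.chrom_sizes:
            by_chrom.setdefault(iv.chrom, []).append(
                (iv.start, min(iv.end, binning.chrom_sizes[iv.chrom]))
            )
    width = binning.bin_width
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        # merge overlapping intervals so shared bases count once
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        off = binning.chrom_slice(chrom).start
        for s, e in merged:
            first, last = s // width, (e - 1) // width
            for b in range(first, last + 1):
                bs, be = b * width, min((b + 1) * width, binning.chrom_sizes[chrom])
                covered[off + b] += max(0, min(e, be) - max(s, bs))
    return covered / binning.bin_lengths()


def repeat_subtype_correlation(
    ratio: DsbRatioTrack,
    repeats: Sequence[tuple[GenomicInterval, str]],
) -> dict[str, tuple[float, float]]:
    """Spearman correlation of DSB ratio with per-subtype repeat coverage.

    Returns subtype -> (rho, p); (nan, nan) when coverage is constant.
    """
    by_subtype: dict[str, list[GenomicInterval]] = {}
    for iv, subtype in repeats:
        by_subtype.setdefault(subtype, []).append(iv)
    out: dict[str, tuple[float, float]] = {}
    for subtype in sorted(by_subtype):
        cov = coverage_fraction(by_subtype[subtype], ratio.binning)
        if np.allclose(cov, cov[0]):
            out[subtype] = (float("nan"), float("nan"))
            continue
        rho, p = stats.spearmanr(ratio.ratio, cov)
        out[subtype] = (float(rho), float(p))
    return out


def tss_meta_profile(
    sites: Sequence[GenomicInterval],
    genes: Sequence[GeneRecord],
    chrom_sizes: Mapping[str, int],
    flank: int = 5000,
    n_bins: int = 100,
) -> np.ndarray:
    """Average breakpoint density around TSSs, TSS-oriented.

    Windows of +/-``flank`` around each TSS are split into ``n_bins`` equal
    sub-bins; per-gene densities (reads per kb per million mapped reads) are
    orientation-flipped for minus-strand genes and averaged. Genes whose
    window leaves the chromosome are excluded.
    """
    tmp: dict[str, list[int]] = {}
    for s in sites:
        pos = s.start if s.strand != "-" else s.end - 1
        tmp.setdefault(s.chrom, []).append(pos)
    positions = {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in tmp.items()}
    total = sum(len(v) for v in positions.values())
    if total == 0:
        raise ValueError("no breakpoint sites given")
    bin_bp = 2 * flank / n_bins
    edges_rel = np.linspace(-flank, flank, n_bins + 1)
    profile = np.zeros(n_bins)
    n_used = 0
    for g in genes:
        if g.chrom not in chrom_sizes:
            continue
        lo, hi = g.tss - flank, g.tss + flank
        if lo < 0 or hi > chrom_sizes[g.chrom]:
            continue
        pos = positions.get(g.chrom, np.empty(0, dtype=np.int64))
        pos = pos[(pos >= lo) & (pos < hi)]  # half-open window
        counts, _ = np.histogram(pos, bins=g.tss + edges_rel)
        if g.strand == "-":
            counts = counts[::-1]
        profile += counts
        n_used += 1
    if n_used == 0:
        raise ValueError("no eligible genes for the TSS meta-profile")
    # reads per kb per million, averaged over genes
    return profile / n_used / (total / 1e6) / (bin_bp / 1000)
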