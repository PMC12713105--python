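"""Cross-layer integration of DSB, loop, compartment, TAD and expression data.

Gene-level assignments use the TSS throughout: a gene sits in a loop anchor,
compartment bin or TAD when its TSS does.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .dsb import DsbEnrichmentRegion, DsbRatioTrack, rank_sum_compare, RankSumResult
from .genome import GeneRecord, GenomicInterval, bins_overlapping
from .loops import DifferentialLoopSet

__all__ = [
    "CompartmentTrack",
    "genes_in_anchors",
    "expression_dsb_correlation",
    "classify_compartment_bins",
    "deg_compartment_enrichment",
    "tad_level_association",
    "multi_evidence_overlap",
]

COMPARTMENT_CLASSES = ("stableA", "AtoB", "BtoA", "stableB", "undefined")


@dataclass
class GenesInAnchors:
    gained: set[str]
    lost: set[str]

    @property
    def all_ids(self) -> set[str]:
        return self.gained | self.lost


def genes_in_anchors(
    genes: Sequence[GeneRecord], differential: DifferentialLoopSet
) -> GenesInAnchors:
    """Genes whose TSS lies inside a differential-loop anchor interval."""

    def tss_in(anchors: list[GenomicInterval], g: GeneRecord) -> bool:
        return any(
            a.chrom == g.chrom and a.start <= g.tss < a.end for a in anchors
        )

    gained_anchors = [a for lp in differential.gained for a in (lp.anchor1, lp.anchor2)]
    lost_anchors = [a for lp in differential.lost for a in (lp.anchor1, lp.anchor2)]
    return GenesInAnchors(
        gained={g.gene_id for g in genes if tss_in(gained_anchors, g)},
        lost={g.gene_id for g in genes if tss_in(lost_anchors, g)},
    )


@dataclass
class ExpressionDsbCorrelation:
    mean_enrichment: np.ndarray
    mean_expression: np.ndarray
    pearson_r: float
    pearson_p: float
    n_genes: int


def expression_dsb_correlation(
    genes: Sequence[GeneRecord],
    ratio: DsbRatioTrack,
    dsb_regions: Sequence[DsbEnrichmentRegion] = (),
    n_bins: int = 100,
    fpkm_threshold: float = 1.0,
    expression: str = "treated",
) -> ExpressionDsbCorrelation:
    """Binned Pearson correlation between gene expression and DSB enrichment.

    Genes with FPKM > ``fpkm_threshold`` are sorted in descending order of
    DSB enrichment (ratio at the TSS-containing bin), split into ``n_bins``
    equal-count groups, and the Pearson correlation is computed on the group
    means. Returns r = NaN when one side has zero variance.
    """
    fpkm = {
        "treated": lambda g: g.fpkm_treated,
        "control": lambda g: g.fpkm_control,
    }[expression]
    eligible = [g for g in genes if fpkm(g) > fpkm_threshold
                and g.chrom in ratio.binning.chrom_sizes]
    if len(eligible) < n_bins:
        raise ValueError(
            f"only {len(eligible)} genes pass FPKM > {fpkm_threshold}; "
            f"reduce n_bins below {n_bins}"
        )
    enrich = np.array(
        [ratio.ratio[ratio.binning.bin_index(g.chrom, g.tss)] for g in eligible]
    )
    expr = np.array([fpkm(g) for g in eligible])
    order = np.lexsort((np.arange(len(eligible)), -enrich))
    base, rem = divmod(len(eligible), n_bins)
    mean_e = np.empty(n_bins)
    mean_x = np.empty(n_bins)
    pos = 0
    for b in range(n_bins):
        size = base + (1 if b < rem else 0)
        sel = order[pos : pos + size]
        mean_e[b] = enrich[sel].mean()
        mean_x[b] = expr[sel].mean()
        pos += size
    if np.allclose(mean_x, mean_x[0]) or np.allclose(mean_e, mean_e[0]):
        return ExpressionDsbCorrelation(mean_e, mean_x, float("nan"), float("nan"),
                                        len(eligible))
    r, p = stats.pearsonr(mean_e, mean_x)
    return ExpressionDsbCorrelation(mean_e, mean_x, float(r), float(p), len(eligible))


@dataclass
class CompartmentTrack:
    """Per-100 kb-bin PC1 values and the four-way switch classification."""

    bins: list[GenomicInterval]
    pc1_control: np.ndarray
    pc1_treated: np.ndarray
    classes: np.ndarray  # labels from COMPARTMENT_CLASSES

    def switch_fraction(self) -> float:
        defined = self.classes != "undefined"
        if not defined.any():
            return float("nan")
        switching = np.isin(self.classes, ("AtoB", "BtoA"))
        return float(switching.sum() / defined.sum())

    def class_of(self, chrom: str, pos: int) -> str:
        for iv, cls in zip(self.bins, self.classes):
            if iv.chrom == chrom and iv.start <= pos < iv.end:
                return str(cls)
        return "undefined"


def classify_compartment_bins(
    pc1_control: Sequence[tuple[GenomicInterval, float]],
    pc1_treated: Sequence[tuple[GenomicInterval, float]],
) -> CompartmentTrack:
    """Sign-based four-type compartment classification of matched PC1 tracks.

    (+,+) -> stableA, (+,-) -> AtoB, (-,+) -> BtoA, (-,-) -> stableB;
    zero or missing PC1 on either side -> undefined.
    """
    key_c = {(iv.chrom, iv.start, iv.end): v for iv, v in pc1_control}
    key_t = {(iv.chrom, iv.start, iv.end): v for iv, v in pc1_treated}
    if set(key_c) != set(key_t):
        raise ValueError("control and treated PC1 tracks cover different bins")
    bins = sorted(key_c, key=lambda k: (k[0], k[1]))
    pc_c = np.array([key_c[k] for k in bins])
    pc_t = np.array([key_t[k] for k in bins])
    classes = np.empty(len(bins), dtype=object)
    for i, (c, t) in enumerate(zip(pc_c, pc_t)):
        if not np.isfinite(c) or not np.isfinite(t) or c == 0 or t == 0:
            classes[i] = "undefined"
        elif c > 0:
            classes[i] = "stableA" if t > 0 else "AtoB"
        else:
            classes[i] = "BtoA" if t > 0 else "stableB"
    return CompartmentTrack(
        bins=[GenomicInterval(*k) for k in bins],
        pc1_control=pc_c,
        pc1_treated=pc_t,
        classes=classes,
    )


@dataclass
class ClassEnrichment:
    n_class_genes: int
    n_class_degs: int
    expected: float
    p_value: float


def deg_compartment_enrichment(
    degs: set[str],
    genes: Sequence[GeneRecord],
    compartments: CompartmentTrack,
) -> dict[str, ClassEnrichment]:
    """Hypergeometric DEG enrichment per compartment-switch class.

    Each gene is assigned the class of its TSS bin; per class the upper-tail
    hypergeometric p-value for the observed DEG count is computed against the
    gene universe. Empty DEG sets give p = 1 everywhere.
    """
    if not genes:
        raise ValueError("empty gene universe")
    # index compartment bins per chromosome for fast TSS lookup
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for iv, cls in zip(compartments.bins, compartments.classes):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, str(cls)))
    for v in by_chrom.values():
        v.sort()

    def class_at(chrom: str, pos: int) -> str:
        rows = by_chrom.get(chrom, [])
        lo, hi = 0, len(rows)
        while lo < hi:
            mid = (lo + hi) // 2
            s, e, cls = rows[mid]
            if pos < s:
                hi = mid
            elif pos >= e:
                lo = mid + 1
            else:
                return cls
        return "undefined"

    assigned = {g.gene_id: class_at(g.chrom, g.tss) for g in genes}
    N = len(genes)
    K = len(degs & set(assigned))
    out: dict[str, ClassEnrichment] = {}
    for cls in COMPARTMENT_CLASSES:
        members = [gid for gid, c in assigned.items() if c == cls]
        n = len(members)
        k = len(degs & set(members))
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if n else 1.0
        out[cls] = ClassEnrichment(
            n_class_genes=n,
            n_class_degs=k,
            expected=n * K / N if N else float("nan"),
            p_value=p,
        )
    return out


@dataclass
class TadLevelAssociation:
    levels: list[int]
    mean_ratio: dict[int, float]
    mean_fpkm: dict[int, float]
    n_bins: dict[int, int]
    consecutive_ratio_tests: dict[tuple[int, int], RankSumResult]
    consecutive_fpkm_tests: dict[tuple[int, int], RankSumResult]
    ratio_trend_rho: float
    fpkm_trend_rho: float


def tad_level_association(
    tads: Sequence[tuple[GenomicInterval, int]],
    ratio: DsbRatioTrack,
    genes: Sequence[GeneRecord] = (),
    expression: str = "treated",
) -> TadLevelAssociation:
    """DSB ratio and expression as functions of hierarchical TAD level.

    Every genome bin (and gene, via its TSS) is assigned the deepest TAD
    level covering it (level 0 = outside any TAD, excluded). Consecutive
    levels are compared with Wilcoxon rank-sum tests; the Spearman trend is
    computed on per-bin (level, ratio) pairs.
    """
    if not tads:
        raise ValueError("empty TAD list")
    binning = ratio.binning
    level_of_bin = np.zeros(binning.n_bins, dtype=int)
    for iv, level in tads:
        for b in bins_overlapping(iv, binning):
            if level > level_of_bin[b]:
                level_of_bin[b] = level
    fpkm = {
        "treated": lambda g: g.fpkm_treated,
        "control": lambda g: g.fpkm_control,
    }[expression]
    level_of_gene: dict[str, int] = {}
    gene_vals: dict[int, list[float]] = {}
    for g in genes:
        if g.chrom not in binning.chrom_sizes:
            continue
        lvl = max(
            (l for iv, l in tads if iv.chrom == g.chrom and iv.start <= g.tss < iv.end),
            default=0,
        )
        if lvl:
            gene_vals.setdefault(lvl, []).append(fpkm(g))

    levels = sorted(set(level_of_bin[level_of_bin > 0]))
    if not levels:
        raise ValueError("no bin covered by any TAD")
    ratio_by_level = {l: ratio.ratio[level_of_bin == l] for l in levels}
    mean_ratio = {l: float(np.mean(v)) for l, v in ratio_by_level.items()}
    mean_fpkm = {
        l: float(np.mean(gene_vals[l])) if l in gene_vals else float("nan")
        for l in levels
    }
    n_bins = {l: int((level_of_bin == l).sum()) for l in levels}

    ratio_tests: dict[tuple[int, int], RankSumResult] = {}
    fpkm_tests: dict[tuple[int, int], RankSumResult] = {}
    for lo, hi in zip(levels, levels[1:]):
        ratio_tests[(lo, hi)] = rank_sum_compare(
            ratio_by_level[hi], ratio_by_level[lo]
        )
        if lo in gene_vals and hi in gene_vals:
            fpkm_tests[(lo, hi)] = rank_sum_compare(gene_vals[hi], gene_vals[lo])

    covered = level_of_bin > 0
    cov_ratio = ratio.ratio[covered]
    if len(levels) > 1 and not np.allclose(cov_ratio, cov_ratio[0]):
        trend = stats.spearmanr(level_of_bin[covered], cov_ratio)
        ratio_trend = float(trend.statistic)
    else:
        ratio_trend = float("nan")
    gene_pairs = [(l, v) for l, vals in gene_vals.items() for v in vals]
    if len({l for l, _ in gene_pairs}) > 1:
        fpkm_trend = float(
            stats.spearmanr(
                [l for l, _ in gene_pairs], [v for _, v in gene_pairs]
            ).statistic
        )
    else:
        fpkm_trend = float("nan")
    return TadLevelAssociation(
        levels=levels,
        mean_ratio=mean_ratio,
        mean_fpkm=mean_fpkm,
        n_bins=n_bins,
        consecutive_ratio_tests=ratio_tests,
        consecutive_fpkm_tests=fpkm_tests,
        ratio_trend_rho=ratio_trend,
        fpkm_trend_rho=fpkm_trend,
    )


@dataclass
class MultiEvidenceOverlap:
    set_names: list[str]
    exclusive_counts: dict[frozenset, int]
    exclusive_members: dict[frozenset, set[str]]
    candidates: set[str]

    def count(self, *names: str) -> int:
        """Exclusive (upset-style) count for an exact combination of sets."""
        return self.exclusive_counts.get(frozenset(names), 0)


def multi_evidence_overlap(
    sets: Mapping[str, set[str]],
    candidate_combination: Sequence[str] | None = None,
) -> MultiEvidenceOverlap:
    """Upset-style exclusive intersections over named gene sets.

    Every element of the union is assigned to the exact combination of sets
    containing it; ``candidate_combination`` (default: all sets) selects the
    genes present in *at least* those sets as the multi-evidence candidate
    list.
    """
    if len(sets) < 2:
        raise ValueError("need at least two gene sets")
    names = list(sets)
    membership: dict[str, frozenset] = {}
    for gid in set().union(*sets.values()):
        membership[gid] = frozenset(n for n in names if gid in sets[n])
    counts: dict[frozenset, int] = {}
    members: dict[frozenset, set[str]] = {}
    for gid, combo in membership.items():
        counts[combo] = counts.get(combo, 0) + 1
        members.setdefault(combo, set()).add(gid)
    wanted = frozenset(candidate_combination if candidate_combination else names)
    candidates = {gid for gid, combo in membership.items() if wanted <= combo}
    return MultiEvidenceOverlap(
        set_names=names,
        exclusive_counts=counts,
        exclusive_members=members,
        candidates=candidates,
    )
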