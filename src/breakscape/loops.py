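"""Chromatin-loop analysis: differential calling, APA, busy-anchor statistics.

Loops are intra-chromosomal anchor pairs at a fixed resolution (10 kb by
default) carrying the calling probability of an upstream loop caller. A loop
is *differential* when its probability exceeds ``p_high`` in one condition and
falls below ``p_low`` in the other; anchors participating in two or more loops
are *busy* anchors (interaction hubs). Aggregate peak analysis (APA) averages
observed/expected contact submatrices around loop pixels.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .genome import GenomeBinning, GenomicInterval, bins_overlapping

__all__ = [
    "Loop",
    "LoopSet",
    "DifferentialLoopSet",
    "AnchorTable",
    "ApaResult",
    "read_loops",
    "write_loops",
    "match_loops",
    "call_differential_loops",
    "apa",
    "build_anchor_table",
    "busy_anchor_association",
    "dsb_anchor_enrichment",
    "chi2_2x2",
]

Anchor = tuple[str, int]  # (chrom, snapped start)


@dataclass(frozen=True)
class Loop:
    """Two same-chromosome anchors at loop resolution plus a call probability."""

    chrom: str
    start1: int
    start2: int
    probability: float
    resolution: int = 10000
    condition: str = ""

    def __post_init__(self) -> None:
        if self.start1 >= self.start2:
            raise ValueError("anchor1 must lie upstream of anchor2")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability {self.probability} outside [0, 1]")

    @property
    def anchor1(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start1, self.start1 + self.resolution)

    @property
    def anchor2(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start2, self.start2 + self.resolution)

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start1, self.start2)


@dataclass
class LoopSet:
    loops: list[Loop]
    resolution: int = 10000
    condition: str = ""

    def __len__(self) -> int:
        return len(self.loops)

    def __iter__(self):
        return iter(self.loops)

    def by_key(self) -> dict[tuple[str, int, int], Loop]:
        """Last-wins map of snapped anchor pair -> loop."""
        return {lp.key: lp for lp in self.loops}


@dataclass
class DifferentialLoopSet:
    gained: list[Loop]  # high probability in treated, low in control
    lost: list[Loop]  # high probability in control, low in treated
    p_high: float = 0.95
    p_low: float = 0.8

    @property
    def all_loops(self) -> list[Loop]:
        return self.gained + self.lost

    def anchor_intervals(self) -> list[GenomicInterval]:
        return [a for lp in self.all_loops for a in (lp.anchor1, lp.anchor2)]


def _snap(pos: int, resolution: int) -> int:
    return (pos // resolution) * resolution


def read_loops(
    path: str | Path, resolution: int = 10000, condition: str = ""
) -> LoopSet:
    """Read a BEDPE loop list with the calling probability in column 7.

    A name column in position 7 (probability shifted to column 8) is also
    accepted. Anchors are snapped to the resolution grid; inter-chromosomal
    rows are skipped with a warning; malformed rows raise with line numbers.
    """
    loops: list[Loop] = []
    skipped_inter = 0
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        if len(f) < 7:
            raise ValueError(f"{path}:{ln}: BEDPE needs >=7 columns")
        try:
            c1, s1, c2, s2 = f[0], int(f[1]), f[3], int(f[4])
            try:
                prob = float(f[6])
            except ValueError:
                if len(f) < 8:
                    raise
                prob = float(f[7])  # name column present in col 7
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: malformed row ({exc})") from exc
        if not 0.0 <= prob <= 1.0:
            raise ValueError(f"{path}:{ln}: probability {prob} outside [0, 1]")
        if c1 != c2:
            skipped_inter += 1
            continue
        a, b = sorted((_snap(s1, resolution), _snap(s2, resolution)))
        loops.append(Loop(c1, a, b, prob, resolution, condition))
    if skipped_inter:
        warnings.warn(
            f"{path}: skipped {skipped_inter} inter-chromosomal loop rows",
            stacklevel=2,
        )
    return LoopSet(loops, resolution, condition)


def write_loops(loop_set: LoopSet, path: str | Path) -> None:
    res = loop_set.resolution
    ordered = sorted(loop_set.loops, key=lambda lp: lp.key)
    with open(path, "w") as fh:
        for lp in ordered:
            fh.write(
                f"{lp.chrom}\t{lp.start1}\t{lp.start1 + res}"
                f"\t{lp.chrom}\t{lp.start2}\t{lp.start2 + res}"
                f"\t{lp.probability:.6g}\n"
            )


@dataclass
class MatchedLoops:
    """Probability pairs for the union of two conditions' loops.

    Loops absent from one condition carry probability 0 there (an uncalled
    loop has effectively no support).
    """

    keys: list[tuple[str, int, int]]
    prob_a: np.ndarray
    prob_b: np.ndarray
    resolution: int


def union_loops(*loop_sets: LoopSet) -> LoopSet:
    """Distinct loops (by snapped anchor pair) across conditions.

    A loop present in several conditions counts once, keeping the highest
    probability seen; this is the loop universe on which anchor recurrence
    (busy status) is counted.
    """
    if not loop_sets:
        raise ValueError("need at least one loop set")
    res = loop_sets[0].resolution
    best: dict[tuple[str, int, int], Loop] = {}
    for ls in loop_sets:
        if ls.resolution != res:
            raise ValueError("resolution mismatch in union")
        for lp in ls:
            cur = best.get(lp.key)
            if cur is None or lp.probability > cur.probability:
                best[lp.key] = lp
    return LoopSet([best[k] for k in sorted(best)], res, "union")


def match_loops(a: LoopSet, b: LoopSet) -> MatchedLoops:
    """Match loops across conditions by exact snapped anchor-bin identity."""
    if a.resolution != b.resolution:
        raise ValueError(
            f"resolution mismatch: {a.resolution} vs {b.resolution}"
        )
    map_a, map_b = a.by_key(), b.by_key()
    keys = sorted(set(map_a) | set(map_b))
    pa = np.array([map_a[k].probability if k in map_a else 0.0 for k in keys])
    pb = np.array([map_b[k].probability if k in map_b else 0.0 for k in keys])
    return MatchedLoops(keys=keys, prob_a=pa, prob_b=pb, resolution=a.resolution)


def call_differential_loops(
    treated: LoopSet,
    control: LoopSet,
    p_high: float = 0.95,
    p_low: float = 0.8,
) -> DifferentialLoopSet:
    """Probability-threshold differential-loop rule.

    gained: probability > ``p_high`` in treated and < ``p_low`` in control;
    lost: the mirror image. Loops uncalled in a condition count as
    probability 0 there. Inequalities are strict on both sides.
    """
    if p_low >= p_high:
        raise ValueError(f"p_low ({p_low}) must be < p_high ({p_high})")
    m = match_loops(treated, control)
    gained: list[Loop] = []
    lost: list[Loop] = []
    for (chrom, s1, s2), pt, pc in zip(m.keys, m.prob_a, m.prob_b):
        if pt > p_high and pc < p_low:
            gained.append(Loop(chrom, s1, s2, pt, m.resolution, "treated"))
        elif pc > p_high and pt < p_low:
            lost.append(Loop(chrom, s1, s2, pc, m.resolution, "control"))
    return DifferentialLoopSet(gained=gained, lost=lost, p_high=p_high, p_low=p_low)


@dataclass
class ApaResult:
    matrix: np.ndarray  # (2w+1, 2w+1) aggregate observed/expected
    apa_score: float  # center pixel / mean of 3x3 lower-left corner
    n_loops_used: int
    n_loops_dropped: int


def _expected_by_offset(dense: np.ndarray) -> np.ndarray:
    """Mean contact at each diagonal offset, zeros included."""
    n = dense.shape[0]
    exp = np.empty(n)
    for k in range(n):
        exp[k] = np.mean(np.diagonal(dense, offset=k))
    return exp


def apa(
    contacts: Mapping[str, np.ndarray],
    loops: Iterable[Loop],
    window: int = 10,
    min_separation: int | None = None,
) -> ApaResult:
    """Aggregate peak analysis over loop pixels.

    ``contacts`` maps chromosome -> dense symmetric matrix at loop resolution.
    Each usable loop contributes its (2w+1)^2 observed submatrix centred on
    the loop pixel, divided by the genome-wide distance expectation (mean
    contact per diagonal offset). Loops too close to the diagonal
    (separation <= ``min_separation``, default 3w) or to the matrix edge are
    dropped. The score is the centre pixel over the mean of the 3x3
    lower-left corner block (short-distance background).
    """
    if min_separation is None:
        min_separation = 3 * window
    expected = {c: _expected_by_offset(m) for c, m in contacts.items()}
    w = window
    size = 2 * w + 1
    agg = np.zeros((size, size))
    used = dropped = 0
    for lp in loops:
        if lp.chrom not in contacts:
            dropped += 1
            continue
        dense = contacts[lp.chrom]
        n = dense.shape[0]
        i = lp.start1 // lp.resolution
        j = lp.start2 // lp.resolution
        if j - i <= min_separation or i - w < 0 or j + w >= n or i + w >= n or j - w < 0:
            dropped += 1
            continue
        sub = dense[i - w : i + w + 1, j - w : j + w + 1].astype(float)
        offs = np.abs(
            (np.arange(i - w, i + w + 1)[:, None]) - (np.arange(j - w, j + w + 1)[None, :])
        )
        exp = expected[lp.chrom][offs]
        with np.errstate(divide="ignore", invalid="ignore"):
            oe = np.where(exp > 0, sub / exp, 0.0)
        agg += oe
        used += 1
    if used == 0:
        raise ValueError("no usable loops for APA")
    agg /= used
    corner = agg[size - 3 : size, 0:3]  # lower-left: high row index, low column
    score = float(agg[w, w] / np.mean(corner))
    return ApaResult(matrix=agg, apa_score=score, n_loops_used=used, n_loops_dropped=dropped)


@dataclass
class AnchorTable:
    anchors: list[Anchor]
    frequency: np.ndarray
    busy: np.ndarray  # frequency >= busy_min_frequency
    in_differential: np.ndarray
    busy_min_frequency: int = 2

    def __len__(self) -> int:
        return len(self.anchors)


def build_anchor_table(
    loops: Iterable[Loop],
    differential: DifferentialLoopSet | None = None,
    busy_min_frequency: int = 2,
) -> AnchorTable:
    """Deduplicate loop anchors, count recurrence and flag busy anchors.

    Frequency counts loop *endpoints*: a loop contributes to both its anchors,
    so frequencies sum to twice the loop count. Anchors recurring
    ``busy_min_frequency`` (default 2) or more times are busy. When a
    differential set is given, anchors used by any differential loop are
    flagged ``in_differential``.
    """
    freq: dict[Anchor, int] = {}
    for lp in loops:
        for s in (lp.start1, lp.start2):
            freq[(lp.chrom, s)] = freq.get((lp.chrom, s), 0) + 1
    anchors = sorted(freq)
    frequency = np.array([freq[a] for a in anchors], dtype=int)
    diff_anchors: set[Anchor] = set()
    if differential is not None:
        for lp in differential.all_loops:
            diff_anchors.add((lp.chrom, lp.start1))
            diff_anchors.add((lp.chrom, lp.start2))
    in_diff = np.array([a in diff_anchors for a in anchors], dtype=bool)
    return AnchorTable(
        anchors=anchors,
        frequency=frequency,
        busy=frequency >= busy_min_frequency,
        in_differential=in_diff,
        busy_min_frequency=busy_min_frequency,
    )


@dataclass
class Chi2Result:
    table: np.ndarray  # 2x2 observed counts
    statistic: float  # Yates-corrected for 2x2
    statistic_uncorrected: float
    df: int
    p_value: float


def chi2_2x2(table: np.ndarray | Sequence[Sequence[int]]) -> Chi2Result:
    """Chi-square independence test for a 2x2 table.

    The reported statistic uses the Yates continuity correction
    N(max(0, |ad-bc| - N/2))^2 / (r1 r2 c1 c2), matching
    ``scipy.stats.chi2_contingency``'s 2x2 default; the uncorrected
    N(ad-bc)^2 / (r1 r2 c1 c2) is reported alongside. A zero margin yields
    an undefined (NaN) p with the table still returned.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    r1, r2 = t.sum(axis=1)
    c1, c2 = t.sum(axis=0)
    denom = r1 * r2 * c1 * c2
    if denom == 0:
        return Chi2Result(t, float("nan"), float("nan"), 1, float("nan"))
    cross = a * d - b * c
    uncorrected = n * cross**2 / denom
    corrected = n * max(0.0, abs(cross) - n / 2) ** 2 / denom
    p = float(stats.chi2.sf(corrected, df=1))
    return Chi2Result(t, float(corrected), float(uncorrected), 1, p)


def busy_anchor_association(
    loop_universe: LoopSet | Iterable[Loop],
    differential: DifferentialLoopSet,
    busy_min_frequency: int = 2,
    anchors: AnchorTable | None = None,
) -> Chi2Result:
    """Chi-square association between anchor busyness and differential loops.

    The contingency unit is the loop *endpoint* (every loop contributes its
    two anchor occurrences, so counts sum to 2x the loop number): rows are
    busy / normal endpoints — an endpoint is busy when its anchor recurs
    ``busy_min_frequency``-or-more times in the loop universe — and columns
    are whether the endpoint's loop is differential. Counting endpoints
    rather than deduplicated anchors keeps the test calibrated: an anchor
    with many loops is otherwise more likely to touch *some* differential
    loop even when busyness and differential status are independent.
    """
    loop_list = list(loop_universe)
    if anchors is None:
        anchors = build_anchor_table(
            loop_list, differential, busy_min_frequency
        )
    busy_set = {a for a, b in zip(anchors.anchors, anchors.busy) if b}
    diff_keys = {lp.key for lp in differential.all_loops}
    table = np.zeros((2, 2), dtype=int)
    for lp in loop_list:
        is_diff = lp.key in diff_keys
        for s in (lp.start1, lp.start2):
            row = 0 if (lp.chrom, s) in busy_set else 1
            table[row, 0 if is_diff else 1] += 1
    return chi2_2x2(table)


@dataclass
class DsbAnchorEnrichment:
    overlap_bins: int
    chi2: Chi2Result


def dsb_anchor_enrichment(
    dsb_regions: Sequence,  # DsbEnrichmentRegion or GenomicInterval
    differential: DifferentialLoopSet,
    binning: GenomeBinning,
) -> DsbAnchorEnrichment:
    """Genome-bin-level colocalisation of DSB regions and differential anchors.

    Every bin of the genome is cross-classified by (inside a differential
    loop anchor?) x (inside a DSB enrichment region?); the overlap count is
    the number of bins positive for both, tested with a Yates chi-square.
    """
    in_anchor = np.zeros(binning.n_bins, dtype=bool)
    for iv in differential.anchor_intervals():
        for b in bins_overlapping(iv, binning):
            in_anchor[b] = True
    in_dsb = np.zeros(binning.n_bins, dtype=bool)
    for r in dsb_regions:
        iv = getattr(r, "interval", r)
        for b in bins_overlapping(iv, binning):
            in_dsb[b] = True
    table = np.array(
        [
            [np.sum(in_anchor & in_dsb), np.sum(in_anchor & ~in_dsb)],
            [np.sum(~in_anchor & in_dsb), np.sum(~in_anchor & ~in_dsb)],
        ]
    )
    return DsbAnchorEnrichment(overlap_bins=int(table[0, 0]), chi2=chi2_2x2(table))
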