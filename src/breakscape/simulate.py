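"""Synthetic-data generators with planted, recoverable ground truth.

The generators emulate the statistical structure of a folate-deficiency DSB /
Hi-C study: Poisson breakpoint counts whose rate decays with distance from the
nearest TSS and is boosted at active enhancers and by treatment; two-condition
loop lists with calling probabilities, shared ("busy") anchors and planted
differential loops preferentially placed in DSB-hot bins; contact matrices
with power-law distance decay and planted loop peaks; and lognormal expression
coupled to gained/lost loop anchors.

One global seed is split into named substreams so each stage is reproducible
in isolation; a fixed seed makes every output byte-identical across runs.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .dsb import BinnedTrack, ChromStateSegment, ENHA_STATES
from .genome import (
    GeneRecord,
    GenomeBinning,
    GenomicInterval,
    bins_overlapping,
    make_bins,
    nearest_tss_distances,
)
from .loops import Loop, LoopSet

__all__ = [
    "SimulationParams",
    "SyntheticAnnotation",
    "SyntheticTruth",
    "generate_genome",
    "generate_dsb_counts",
    "generate_loops",
    "generate_contacts",
    "generate_expression",
    "generate_tads",
    "generate_compartments",
    "simulate_all",
]

_SUBSTREAMS = {
    "genome": 1,
    "dsb": 2,
    "loops": 3,
    "contacts": 4,
    "expression": 5,
    "tads": 6,
    "compartments": 7,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream of the global seed (stage-level reproducibility)."""
    return np.random.default_rng([_SUBSTREAMS[stream], int(seed)])


@dataclass
class SimulationParams:
    """All knobs of the synthetic study, with defaults defining its conditions.

    Rates are expected reads per bin; ``tss_decay`` is the exponential decay
    length (bp) of the break-signal component away from the nearest TSS
    (``inf`` disables the decay); ``treatment_fold`` scales the
    treatment-induced break excess, which is concentrated near TSSs and in
    regulatory bins (see :func:`generate_dsb_counts`), so the
    treated/control ratio decays continuously with TSS distance and equals
    the fold exactly in regulatory bins.
    """

    seed: int = 0
    # genome layout
    n_chrom: int = 2
    chrom_len: int = 20_000_000
    n_genes: int = 200
    n_enhancers: int = 200
    bin_width: int = 5000
    # DSB rates
    base_rate: float = 40.0  # lambda_0, expected signal reads/bin at d=0
    rate_floor: float = 16.0  # distance-independent baseline reads/bin
    tss_decay: float = 50_000.0  # tau (bp); inf = no distance structure
    enhancer_boost: float = 2.0  # beta, signal multiplier (1 + beta) in EnhA bins
    treatment_fold: float = 5.0  # f
    promoter_fold_sd: float = 0.5  # lognormal sd of per-regulatory-bin fold
    overdispersion: float = 0.0  # gamma-Poisson extra variance (0 = pure Poisson)
    # loops
    loop_n: int = 400
    busy_fraction: float = 0.3
    p_diff_busy: float = 0.4  # pi_b
    p_diff_normal: float = 0.1  # pi_n
    loop_resolution: int = 10_000
    diff_anchor_dsb_weight: float = 0.8  # P(fresh diff anchor drawn DSB-hot)
    min_loop_gap_bins: int = 35
    max_loop_gap_bins: int = 200
    # contacts
    contact_depth: float = 150_000.0  # expected reads per chromosome matrix
    decay_exponent: float = 1.0  # alpha
    peak_factor: float = 3.0  # kappa, loop-pixel intensity multiplier
    # expression
    expr_mu: float = 1.5  # lognormal location (ln FPKM)
    expr_sigma: float = 1.0  # lognormal scale
    expr_noise: float = 0.15  # per-condition multiplicative lognormal noise
    expr_dsb_coupling: float = 0.5  # Gaussian-copula rank coupling to DSB ratio
    loop_effect: float = 1.0  # log2 fold applied at gained/lost anchors

    def validate(self) -> None:
        errs = []
        for name in (
            "base_rate",
            "rate_floor",
            "enhancer_boost",
            "overdispersion",
            "contact_depth",
        ):
            if getattr(self, name) < 0:
                errs.append(f"{name} must be >= 0")
        if self.treatment_fold < 1:
            errs.append("treatment_fold must be >= 1")
        for name in ("p_diff_busy", "p_diff_normal", "busy_fraction",
                     "diff_anchor_dsb_weight"):
            if not 0 <= getattr(self, name) <= 1:
                errs.append(f"{name} must be in [0, 1]")
        for name in ("n_chrom", "chrom_len", "bin_width", "loop_resolution"):
            if getattr(self, name) <= 0:
                errs.append(f"{name} must be positive")
        if self.tss_decay <= 0:
            errs.append("tss_decay must be positive (use inf to disable)")
        if errs:
            raise ValueError("invalid SimulationParams: " + "; ".join(errs))

    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_len for i in range(self.n_chrom)}


@dataclass
class SyntheticAnnotation:
    binning: GenomeBinning
    genes: list[GeneRecord]
    states: list[ChromStateSegment]
    repeats: list[tuple[GenomicInterval, str]]


@dataclass
class DsbTruth:
    rate_control: np.ndarray
    rate_treated: np.ndarray
    regulatory_mask: np.ndarray
    tss_distance: np.ndarray

    @property
    def true_ratio(self) -> np.ndarray:
        return self.rate_treated / self.rate_control


@dataclass
class LoopTruth:
    planted_gained: list[tuple[str, int, int]]
    planted_lost: list[tuple[str, int, int]]
    loop_is_differential: list[bool]
    loop_has_busy_anchor: list[bool]
    peak_factor: float

    @property
    def planted_keys(self) -> set[tuple[str, int, int]]:
        return set(self.planted_gained) | set(self.planted_lost)


@dataclass
class SyntheticTruth:
    """Planted ground truth of one simulated study."""

    dsb: DsbTruth
    loops: LoopTruth | None = None
    deg_up: list[str] = field(default_factory=list)  # genes at gained anchors
    deg_down: list[str] = field(default_factory=list)  # genes at lost anchors

    @property
    def deg_ids(self) -> set[str]:
        return set(self.deg_up) | set(self.deg_down)


# -- genome & annotation ----------------------------------------------------

_TSSA_HALF = 500  # TssA segments are 1 kb centred on the TSS
_ENH_LEN = 1000
_REPEAT_SUBTYPES = ("L1", "L2", "B1")
_EDGE_MARGIN = 10_000  # keep TSS windows clear of chromosome ends


def generate_genome(params: SimulationParams) -> SyntheticAnnotation:
    """Place genes, chromatin-state segments and repeats on a fresh genome.

    Genes are spread uniformly without TSS collisions; every TSS gets a 1 kb
    TssA segment, ``n_enhancers`` 1 kb EnhA1/EnhA2 segments land uniformly in
    non-promoter space, and the remainder of each chromosome is Quies, so the
    state segments partition each chromosome exactly.
    """
    params.validate()
    rng = _rng(params.seed, "genome")
    sizes = params.chrom_sizes()
    binning = make_bins(sizes, params.bin_width)
    footprint = params.n_genes * 2 * _TSSA_HALF + params.n_enhancers * _ENH_LEN
    genome_len = sum(sizes.values())
    if footprint > 0.5 * genome_len:
        raise ValueError(
            f"cannot place {params.n_genes} genes and {params.n_enhancers} "
            f"enhancers on a {genome_len} bp genome (too dense)"
        )

    chroms = list(sizes)
    per_chrom = {c: params.n_genes // params.n_chrom for c in chroms}
    for i in range(params.n_genes % params.n_chrom):
        per_chrom[chroms[i]] += 1

    genes: list[GeneRecord] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    gene_idx = 0
    for chrom in chroms:
        size = sizes[chrom]
        taken: set[int] = set()
        for _ in range(per_chrom[chrom]):
            while True:
                tss = int(rng.integers(_EDGE_MARGIN, size - _EDGE_MARGIN))
                if all(abs(tss - t) > 2 * _TSSA_HALF for t in taken):
                    break
            taken.add(tss)
            body = int(rng.integers(2000, 50_000))
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                start, end = tss, min(tss + body, size)
            else:
                start, end = max(tss + 1 - body, 0), tss + 1
            genes.append(
                GeneRecord(
                    gene_id=f"gene{gene_idx:04d}",
                    interval=GenomicInterval(chrom, start, end, strand),
                )
            )
            occupied[chrom].append((tss - _TSSA_HALF, tss + _TSSA_HALF))
            gene_idx += 1

    states: list[ChromStateSegment] = []
    placed: dict[str, list[tuple[int, int, str]]] = {c: [] for c in chroms}
    for g in genes:
        s = max(0, g.tss - _TSSA_HALF)
        e = min(sizes[g.chrom], g.tss + _TSSA_HALF)
        placed[g.chrom].append((s, e, "TssA"))

    n_enh_per_chrom = {c: params.n_enhancers // params.n_chrom for c in chroms}
    for i in range(params.n_enhancers % params.n_chrom):
        n_enh_per_chrom[chroms[i]] += 1
    for chrom in chroms:
        size = sizes[chrom]
        spans = sorted((s, e) for s, e, _ in placed[chrom])
        for _ in range(n_enh_per_chrom[chrom]):
            for _attempt in range(10_000):
                s = int(rng.integers(0, size - _ENH_LEN))
                e = s + _ENH_LEN
                if not any(s < pe and ps < e for ps, pe in spans):
                    break
            else:
                raise ValueError("enhancer placement impossible (too dense)")
            state = "EnhA1" if rng.random() < 0.5 else "EnhA2"
            placed[chrom].append((s, e, state))
            spans.append((s, e))
            spans.sort()

    for chrom in chroms:
        segs = sorted(placed[chrom])
        pos = 0
        for s, e, state in segs:
            if s > pos:
                states.append(
                    ChromStateSegment(GenomicInterval(chrom, pos, s), "Quies")
                )
            states.append(ChromStateSegment(GenomicInterval(chrom, s, e), state))
            pos = e
        if pos < sizes[chrom]:
            states.append(
                ChromStateSegment(GenomicInterval(chrom, pos, sizes[chrom]), "Quies")
            )

    repeats: list[tuple[GenomicInterval, str]] = []
    n_per_subtype = max(1, genome_len // 100_000)
    for subtype in _REPEAT_SUBTYPES:
        for _ in range(n_per_subtype):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            length = int(rng.integers(200, 2000))
            s = int(rng.integers(0, sizes[chrom] - length))
            repeats.append((GenomicInterval(chrom, s, s + length), subtype))

    return SyntheticAnnotation(binning=binning, genes=genes, states=states,
                               repeats=repeats)


# -- DSB counts -------------------------------------------------------------


def _state_mask(annotation: SyntheticAnnotation, wanted: Sequence[str]) -> np.ndarray:
    mask = np.zeros(annotation.binning.n_bins, dtype=bool)
    wanted_set = set(wanted)
    for seg in annotation.states:
        if seg.state in wanted_set:
            for b in bins_overlapping(seg.interval, annotation.binning):
                mask[b] = True
    return mask


def generate_dsb_counts(
    annotation: SyntheticAnnotation, params: SimulationParams
) -> tuple[BinnedTrack, BinnedTrack, DsbTruth]:
    """Draw per-bin breakpoint counts for control and treated conditions.

    Control rate per bin: floor + base * (1 + boost*enh) * exp(-d_TSS/tau).
    The treatment-induced excess is itself TSS-focused: inside regulatory
    (TssA/EnhA) bins the whole rate is multiplied by ``treatment_fold``,
    and elsewhere the signal component is amplified by a factor that decays
    from ``treatment_fold`` at the TSS to 1 far away (same decay length), so
    the treated/control ratio falls continuously with TSS distance and
    equals the fold exactly in regulatory bins. Counts are Poisson, or
    gamma-Poisson when ``overdispersion`` > 0.
    """
    params.validate()
    rng = _rng(params.seed, "dsb")
    binning = annotation.binning
    if annotation.genes:
        d = nearest_tss_distances(binning, annotation.genes)
        d = np.where(np.isnan(d), np.inf, d)
    else:
        d = np.full(binning.n_bins, np.inf)
    decay = np.exp(-d / params.tss_decay) if np.isfinite(params.tss_decay) else np.ones_like(d)
    decay = np.where(np.isfinite(decay), decay, 0.0)
    enh = _state_mask(annotation, ENHA_STATES)
    reg = enh | _state_mask(annotation, ["TssA"])
    signal = params.base_rate * (1 + params.enhancer_boost * enh) * decay
    lam_c = params.rate_floor + signal
    f = params.treatment_fold
    boost = 1.0 + (f - 1.0) * decay  # induced excess decays with TSS distance
    # per-regulatory-bin break propensity: mean-one lognormal heterogeneity,
    # so individual promoters/enhancers differ while the aggregate fold stays f
    sd = params.promoter_fold_sd
    u = np.ones(binning.n_bins)
    if sd > 0 and f != 1.0:
        u[reg] = rng.lognormal(-(sd**2) / 2, sd, size=int(reg.sum()))
    lam_t = np.where(reg, f * u * lam_c, params.rate_floor + boost * signal)

    def draw(lam: np.ndarray) -> np.ndarray:
        if params.overdispersion > 0:
            shape = 1.0 / params.overdispersion
            lam = rng.gamma(shape, lam / shape)
        return rng.poisson(lam).astype(float)

    control = BinnedTrack(binning, draw(lam_c), units="raw")
    treated = BinnedTrack(binning, draw(lam_t), units="raw")
    truth = DsbTruth(
        rate_control=lam_c, rate_treated=lam_t, regulatory_mask=reg, tss_distance=d
    )
    return control, treated, truth


# -- loops ------------------------------------------------------------------


def _hot_anchor_bins(
    annotation: SyntheticAnnotation, dsb_truth: DsbTruth, params: SimulationParams
) -> dict[str, np.ndarray]:
    """Loop-resolution bin starts in the top decile of true DSB ratio."""
    res = params.loop_resolution
    out: dict[str, np.ndarray] = {}
    ratio = dsb_truth.true_ratio
    all_means: list[np.ndarray] = []
    per_chrom: dict[str, np.ndarray] = {}
    for chrom, size in annotation.binning.chrom_sizes.items():
        sl = annotation.binning.chrom_slice(chrom)
        fine = ratio[sl]
        k = res // annotation.binning.bin_width
        n_coarse = size // res
        means = fine[: n_coarse * k].reshape(n_coarse, k).mean(axis=1)
        per_chrom[chrom] = means
        all_means.append(means)
    cutoff = np.quantile(np.concatenate(all_means), 0.9)
    for chrom, means in per_chrom.items():
        out[chrom] = np.flatnonzero(means >= cutoff) * res
    return out


def generate_loops(
    annotation: SyntheticAnnotation,
    dsb_truth: DsbTruth,
    params: SimulationParams,
) -> tuple[LoopSet, LoopSet, LoopTruth]:
    """Draw a two-condition loop list with hubs and planted differential loops.

    A ``busy_fraction`` of loops reuse an existing anchor (creating hubs); a
    loop is planted differential with probability ``p_diff_busy`` when it uses
    a shared anchor, else ``p_diff_normal``. Stable loops get one probability
    draw ~U(0.95, 1) used in both conditions; a planted loop is high in one
    condition and ~U(0, 0.8) in the other. Fresh anchors of planted loops are
    drawn from top-decile DSB-ratio bins with probability
    ``diff_anchor_dsb_weight``.
    """
    params.validate()
    if params.loop_n < 1:
        raise ValueError("loop_n must be >= 1")
    rng = _rng(params.seed, "loops")
    res = params.loop_resolution
    sizes = annotation.binning.chrom_sizes
    chroms = list(sizes)
    n_bins = {c: sizes[c] // res for c in chroms}
    max_pairs = sum(
        max(0, n_bins[c] - params.min_loop_gap_bins) for c in chroms
    )
    if params.loop_n > max_pairs:
        raise ValueError(
            f"loop_n={params.loop_n} exceeds available anchor pairs ({max_pairs})"
        )
    hot = _hot_anchor_bins(annotation, dsb_truth, params)

    used_anchors: list[tuple[str, int]] = []
    used_set: set[tuple[str, int]] = set()
    used_keys: set[tuple[str, int, int]] = set()
    control_loops: list[Loop] = []
    treated_loops: list[Loop] = []
    truth = LoopTruth([], [], [], [], params.peak_factor)

    def fresh_anchor(chrom: str, want_hot: bool) -> int:
        pool = hot.get(chrom)
        for attempt in range(10_000):
            # fall back to uniform placement once the hot pool looks exhausted
            if want_hot and attempt < 100 and pool is not None and len(pool):
                s = int(pool[int(rng.integers(0, len(pool)))])
            else:
                s = int(rng.integers(0, n_bins[chrom])) * res
            if (chrom, s) not in used_set:
                return s
        raise ValueError("anchor placement failed (loop list too dense)")

    for _ in range(params.loop_n):
        for _attempt in range(10_000):
            reuse = bool(used_anchors) and rng.random() < params.busy_fraction
            p_diff = params.p_diff_busy if reuse else params.p_diff_normal
            is_diff = rng.random() < p_diff
            want_hot = is_diff and rng.random() < params.diff_anchor_dsb_weight
            if reuse:
                chrom, a1 = used_anchors[int(rng.integers(0, len(used_anchors)))]
            else:
                chrom = chroms[int(rng.integers(0, len(chroms)))]
                a1 = fresh_anchor(chrom, want_hot)
            gap = int(
                rng.integers(params.min_loop_gap_bins, params.max_loop_gap_bins + 1)
            )
            a2 = a1 + gap * res
            if a2 >= sizes[chrom] or (chrom, a2) in used_set:
                continue
            key = (chrom, a1, a2)
            if key in used_keys:
                continue
            break
        else:
            raise ValueError("could not place loop (genome too small for loop_n)")

        used_keys.add(key)
        for s in (a1, a2):
            if (chrom, s) not in used_set:
                used_set.add((chrom, s))
            used_anchors.append((chrom, s))

        if is_diff:
            p_hi = float(rng.uniform(0.95, 1.0))
            p_lo = float(rng.uniform(0.0, 0.8))
            gained = rng.random() < 0.5
            p_t, p_c = (p_hi, p_lo) if gained else (p_lo, p_hi)
            (truth.planted_gained if gained else truth.planted_lost).append(key)
        else:
            p_t = p_c = float(rng.uniform(0.95, 1.0))
        truth.loop_is_differential.append(is_diff)
        truth.loop_has_busy_anchor.append(reuse)
        control_loops.append(Loop(chrom, a1, a2, p_c, res, "control"))
        treated_loops.append(Loop(chrom, a1, a2, p_t, res, "treated"))

    return (
        LoopSet(control_loops, res, "control"),
        LoopSet(treated_loops, res, "treated"),
        truth,
    )


# -- contact matrices -------------------------------------------------------


def generate_contacts(
    loops: LoopSet,
    params: SimulationParams,
    chrom_sizes: Mapping[str, int] | None = None,
) -> dict[str, np.ndarray]:
    """Sample symmetric Poisson contact matrices with planted loop peaks.

    Expected count for bin pair (i, j) is c / (|i-j|^alpha + 1), scaled so
    each chromosome's matrix sums to ~``contact_depth`` reads, and multiplied
    by ``peak_factor`` at loop pixels. Returns dense symmetric matrices at
    loop resolution.
    """
    params.validate()
    rng = _rng(params.seed, "contacts")
    res = loops.resolution
    sizes = dict(chrom_sizes) if chrom_sizes is not None else params.chrom_sizes()
    out: dict[str, np.ndarray] = {}
    for chrom, size in sizes.items():
        n = size // res
        offsets = np.arange(n)
        weight = (n - offsets) / (offsets**params.decay_exponent + 1.0)
        c = params.contact_depth / weight.sum()
        peaks: dict[int, list[int]] = {}
        for lp in loops:
            if lp.chrom != chrom:
                continue
            i, j = lp.start1 // res, lp.start2 // res
            peaks.setdefault(j - i, []).append(i)
        dense = np.zeros((n, n), dtype=np.int64)
        for k in range(n):
            lam = np.full(n - k, c / (k**params.decay_exponent + 1.0))
            for i in peaks.get(k, []):
                lam[i] *= params.peak_factor
            counts = rng.poisson(lam)
            idx = np.arange(n - k)
            dense[idx, idx + k] = counts
            dense[idx + k, idx] = counts
        out[chrom] = dense
    return out


def contacts_to_triplets(dense: np.ndarray) -> np.ndarray:
    """Upper-triangle nonzero entries as (i, j, count) rows."""
    iu, ju = np.triu_indices_from(dense)
    vals = dense[iu, ju]
    nz = vals > 0
    return np.column_stack([iu[nz], ju[nz], vals[nz]]).astype(np.int64)


def triplets_to_dense(triplets: np.ndarray, n_bins: int) -> np.ndarray:
    dense = np.zeros((n_bins, n_bins), dtype=np.int64)
    for i, j, v in np.asarray(triplets, dtype=np.int64):
        dense[i, j] = v
        dense[j, i] = v
    return dense


# -- expression -------------------------------------------------------------


def generate_expression(
    annotation: SyntheticAnnotation,
    truth: SyntheticTruth,
    params: SimulationParams,
) -> tuple[list[GeneRecord], SyntheticTruth]:
    """Assign two-condition FPKM to genes, coupled to planted loop changes.

    Baseline FPKM is lognormal(expr_mu, expr_sigma); with
    ``expr_dsb_coupling`` = rho > 0 the baseline is rank-coupled (Gaussian
    copula) to the true DSB ratio at the gene's TSS bin. Genes whose TSS
    falls inside a gained-loop anchor gain ``loop_effect`` log2 units in the
    treated condition, lost anchors the opposite; both conditions then get
    independent multiplicative lognormal noise. The DEG flag marks exactly
    the genes carrying a planted effect.
    """
    params.validate()
    rng = _rng(params.seed, "expression")
    genes = annotation.genes
    n = len(genes)
    res = params.loop_resolution
    gained_anchors: set[tuple[str, int]] = set()
    lost_anchors: set[tuple[str, int]] = set()
    if truth.loops is not None:
        for chrom, s1, s2 in truth.loops.planted_gained:
            gained_anchors.update({(chrom, s1), (chrom, s2)})
        for chrom, s1, s2 in truth.loops.planted_lost:
            lost_anchors.update({(chrom, s1), (chrom, s2)})

    dsb_at_tss = np.array(
        [
            truth.dsb.true_ratio[annotation.binning.bin_index(g.chrom, g.tss)]
            for g in genes
        ]
    )
    eps = rng.normal(size=n)
    rho = params.expr_dsb_coupling
    if rho > 0 and n > 1:
        # Gaussian copula: expression z-score correlated with DSB-ratio rank
        order = np.argsort(np.argsort(dsb_at_tss, kind="stable"), kind="stable")
        z_dsb = _norm_ppf((order + 1) / (n + 1))
        z = rho * z_dsb + np.sqrt(1 - rho**2) * eps
    else:
        z = eps
    baseline = np.exp(params.expr_mu + params.expr_sigma * z)

    new_genes: list[GeneRecord] = []
    deg_up: list[str] = []
    deg_down: list[str] = []
    noise_c = np.exp(rng.normal(0.0, params.expr_noise, size=n))
    noise_t = np.exp(rng.normal(0.0, params.expr_noise, size=n))
    for i, g in enumerate(genes):
        anchor = (g.chrom, (g.tss // res) * res)
        fc = 1.0
        if params.loop_effect != 0 and anchor in gained_anchors:
            fc = 2.0**params.loop_effect
            deg_up.append(g.gene_id)
        elif params.loop_effect != 0 and anchor in lost_anchors:
            fc = 2.0**-params.loop_effect
            deg_down.append(g.gene_id)
        fpkm_c = baseline[i] * noise_c[i]
        fpkm_t = baseline[i] * fc * noise_t[i]
        new_genes.append(
            GeneRecord(
                gene_id=g.gene_id,
                interval=g.interval,
                fpkm_control=fpkm_c,
                fpkm_treated=fpkm_t,
                is_deg=fc != 1.0,
            )
        )
    truth.deg_up = deg_up
    truth.deg_down = deg_down
    return new_genes, truth


def _norm_ppf(q: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    return norm.ppf(q)


# -- TADs & compartments ----------------------------------------------------


def generate_tads(
    params: SimulationParams, resolution: int = 50_000, max_level: int = 3
) -> list[tuple[GenomicInterval, int]]:
    """Hierarchical nested TADs on a 50 kb grid.

    Level-1 domains tile each chromosome (0.5-1.5 Mb); each domain nests a
    smaller level-2 domain with probability 0.6, and so on up to
    ``max_level``.
    """
    rng = _rng(params.seed, "tads")
    out: list[tuple[GenomicInterval, int]] = []
    for chrom, size in params.chrom_sizes().items():
        n = size // resolution
        pos = 0
        while pos < n:
            span = int(rng.integers(10, 31))  # 0.5-1.5 Mb
            end = min(pos + span, n)
            if end - pos >= 3:
                out.append(
                    (GenomicInterval(chrom, pos * resolution, end * resolution), 1)
                )
                s, e = pos, end
                for level in range(2, max_level + 1):
                    if e - s < 6 or rng.random() >= 0.6:
                        break
                    sub_span = max(3, (e - s) // 2)
                    s = s + int(rng.integers(0, e - s - sub_span + 1))
                    e = s + sub_span
                    out.append(
                        (GenomicInterval(chrom, s * resolution, e * resolution), level)
                    )
            pos = end
    return out


def generate_compartments(
    params: SimulationParams, resolution: int = 100_000
) -> list[tuple[GenomicInterval, float, float]]:
    """Smooth PC1 tracks for two conditions with a small switch fraction.

    Returns (bin interval, pc1_control, pc1_treated) rows at 100 kb; the
    treated track is the control plus small smooth noise, so sign flips
    concentrate where PC1 is near zero (a few percent of bins, mirroring the
    stability of real compartments).
    """
    rng = _rng(params.seed, "compartments")
    out: list[tuple[GenomicInterval, float, float]] = []
    kernel = np.ones(9) / 9
    for chrom, size in params.chrom_sizes().items():
        n = size // resolution
        base = np.convolve(rng.normal(size=n + 8), kernel, mode="valid")
        base *= 3.0  # smooth +/- ~1-scale PC1
        wobble = np.convolve(rng.normal(size=n + 8), kernel, mode="valid") * 0.45
        treated = base + wobble
        for i in range(n):
            out.append(
                (
                    GenomicInterval(chrom, i * resolution, (i + 1) * resolution),
                    float(base[i]),
                    float(treated[i]),
                )
            )
    return out


# -- orchestration ----------------------------------------------------------


@dataclass
class SimulationResult:
    params: SimulationParams
    annotation: SyntheticAnnotation
    control_dsb: BinnedTrack
    treated_dsb: BinnedTrack
    control_loops: LoopSet
    treated_loops: LoopSet
    contacts_treated: dict[str, np.ndarray]
    genes: list[GeneRecord]
    tads: list[tuple[GenomicInterval, int]]
    compartments: list[tuple[GenomicInterval, float, float]]
    truth: SyntheticTruth


def simulate_all(
    params: SimulationParams, with_contacts: bool = True
) -> SimulationResult:
    """Run every generator in dependency order under one seed."""
    annotation = generate_genome(params)
    control_dsb, treated_dsb, dsb_truth = generate_dsb_counts(annotation, params)
    control_loops, treated_loops, loop_truth = generate_loops(
        annotation, dsb_truth, params
    )
    truth = SyntheticTruth(dsb=dsb_truth, loops=loop_truth)
    genes, truth = generate_expression(annotation, truth, params)
    annotation.genes = genes
    contacts: dict[str, np.ndarray] = {}
    if with_contacts:
        high = LoopSet(
            [lp for lp in treated_loops if lp.probability > 0.95],
            treated_loops.resolution,
            "treated",
        )
        contacts = generate_contacts(high, params)
    tads = generate_tads(params)
    compartments = generate_compartments(params)
    return SimulationResult(
        params=params,
        annotation=annotation,
        control_dsb=control_dsb,
        treated_dsb=treated_dsb,
        control_loops=control_loops,
        treated_loops=treated_loops,
        contacts_treated=contacts,
        genes=genes,
        tads=tads,
        compartments=compartments,
        truth=truth,
    )


def write_truth_json(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "planted_gained": sorted(map(list, truth.loops.planted_gained))
        if truth.loops
        else [],
        "planted_lost": sorted(map(list, truth.loops.planted_lost))
        if truth.loops
        else [],
        "deg_up": sorted(truth.deg_up),
        "deg_down": sorted(truth.deg_down),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
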