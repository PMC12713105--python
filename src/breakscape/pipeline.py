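"""End-to-end orchestration: simulate -> DSB -> loops -> integrate -> report.

Every stage writes its intermediates in the standard text formats and the run
finishes with a machine-readable JSON report whose numbers are all
recomputable by calling the underlying operations directly. Identical config
and seed give byte-identical outputs.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np

from . import dsb as dsb_mod
from . import integrate as int_mod
from . import io as io_mod
from . import loops as loop_mod
from .config import PipelineConfig, validate_config
from .simulate import (
    SimulationParams,
    SimulationResult,
    contacts_to_triplets,
    simulate_all,
    write_truth_json,
)

__all__ = ["run_pipeline", "RunReport"]

REPORT_SCHEMA_VERSION = 1


class RunReport(dict):
    """JSON-serialisable run report (a dict with a stable serialisation)."""

    def to_json(self) -> str:
        return json.dumps(self, indent=2, sort_keys=True, default=_json_default) + "\n"


def _json_default(obj: Any):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: PipelineConfig | dict,
    sim_params: SimulationParams | None = None,
    outdir: str | Path | None = None,
) -> RunReport:
    """Run the full simulated analysis and write outputs plus a report.

    ``sim_params`` defaults to the study conditions with the config's seed.
    """
    cfg = validate_config(config)
    out = Path(outdir if outdir is not None else cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if sim_params is None:
        sim_params = SimulationParams(
            seed=cfg.seed,
            bin_width=cfg.bin_width,
            loop_resolution=cfg.loop_resolution,
        )
    sim = simulate_all(sim_params)
    report = RunReport(
        schema_version=REPORT_SCHEMA_VERSION,
        config=asdict(cfg),
        sim_params=asdict(sim_params),
    )

    inputs = _write_inputs(sim, out)
    report["input_hashes"] = {name: _sha256(p) for name, p in inputs.items()}
    warnings_list: list[str] = []

    # -- DSB stage ----------------------------------------------------------
    ratio = dsb_mod.dsb_ratio(sim.treated_dsb, sim.control_dsb, cfg.pseudocount)
    t = sim.treated_dsb.values
    n_bin = sim.treated_dsb.values + sim.control_dsb.values
    K = float(t.sum())
    N = float(n_bin.sum())
    from scipy import stats as _st

    pvals = _st.hypergeom.sf(t - 1, int(N), int(K), n_bin.astype(int))
    regions = dsb_mod.call_enrichment_regions(
        ratio, pvals, cfg.q_threshold, cfg.fold_threshold
    )
    classes = dsb_mod.split_ratio_classes(ratio, cfg.n_classes)
    profile = dsb_mod.tss_distance_profile(ratio, sim.genes, cfg.n_ratio_bins)
    states_prox = dsb_mod.classify_enhancer_proximity(
        sim.annotation.states, cfg.enhancer_window
    )
    fractions = dsb_mod.element_fraction_by_class(
        classes, ratio, sim.annotation.states
    )
    enha_bins = dsb_mod.bins_with_state(
        sim.annotation.states, ratio.binning, list(dsb_mod.ENHA_STATES)
    )
    enha_test = dsb_mod.compare_ratio_by_feature(ratio, np.flatnonzero(enha_bins))
    repeat_corr = dsb_mod.repeat_subtype_correlation(ratio, sim.annotation.repeats)
    report["dsb"] = {
        "mean_ratio": ratio.mean_ratio,
        "totals_ratio": ratio.totals_ratio,
        "n_enrichment_regions": len(regions),
        "tss_distance_spearman": profile.spearman_rho,
        "tss_distance_pearson": profile.pearson_r,
        "tssa_fraction_spearman": fractions.tssa_spearman,
        "enha_fraction_spearman": fractions.enha_spearman,
        "enha_vs_none_p": enha_test.p_value,
        "n_proximal_enha": sum(
            1 for s in states_prox if s.proximity == "proximal"
        ),
        "n_distal_enha": sum(1 for s in states_prox if s.proximity == "distal"),
        "repeat_spearman": {k: v[0] for k, v in repeat_corr.items()},
    }

    # -- loop stage ---------------------------------------------------------
    differential = loop_mod.call_differential_loops(
        sim.treated_loops, sim.control_loops, cfg.p_high, cfg.p_low
    )
    union = loop_mod.union_loops(sim.treated_loops, sim.control_loops)
    anchors = loop_mod.build_anchor_table(
        union, differential, cfg.busy_min_frequency
    )
    assoc = loop_mod.busy_anchor_association(
        union, differential, cfg.busy_min_frequency, anchors
    )
    colocal = loop_mod.dsb_anchor_enrichment(regions, differential, ratio.binning)
    apa_result = None
    if sim.contacts_treated:
        high_treated = loop_mod.LoopSet(
            [lp for lp in sim.treated_loops if lp.probability > cfg.p_high],
            cfg.loop_resolution,
        )
        apa_result = loop_mod.apa(
            sim.contacts_treated, high_treated, window=cfg.apa_window
        )
    report["loops"] = {
        "n_gained": len(differential.gained),
        "n_lost": len(differential.lost),
        "n_anchors": len(anchors),
        "n_busy_anchors": int(anchors.busy.sum()),
        "busy_assoc_chi2": assoc.statistic,
        "busy_assoc_p": assoc.p_value,
        "dsb_anchor_overlap_bins": colocal.overlap_bins,
        "dsb_anchor_chi2": colocal.chi2.statistic,
        "dsb_anchor_p": colocal.chi2.p_value,
        "apa_score": apa_result.apa_score if apa_result else None,
        "apa_loops_used": apa_result.n_loops_used if apa_result else 0,
    }

    # -- integration stage --------------------------------------------------
    anchor_genes = int_mod.genes_in_anchors(sim.genes, differential)
    expr_corr = int_mod.expression_dsb_correlation(
        sim.genes, ratio, regions, cfg.n_expr_bins, cfg.fpkm_threshold
    )
    comp = int_mod.classify_compartment_bins(
        [(iv, c) for iv, c, _ in sim.compartments],
        [(iv, t_) for iv, _, t_ in sim.compartments],
    )
    deg_ids = {g.gene_id for g in sim.genes if g.is_deg}
    comp_enrich = int_mod.deg_compartment_enrichment(deg_ids, sim.genes, comp)
    tad_assoc = int_mod.tad_level_association(sim.tads, ratio, sim.genes)
    dsb_gene_ids = _genes_in_regions(sim.genes, regions)
    overlap = int_mod.multi_evidence_overlap(
        {
            "dsb": dsb_gene_ids,
            "loop_anchor": anchor_genes.all_ids,
            "deg": deg_ids,
        },
        candidate_combination=["dsb", "loop_anchor", "deg"],
    )
    report["integration"] = {
        "n_anchor_genes": len(anchor_genes.all_ids),
        "n_anchor_genes_gained": len(anchor_genes.gained),
        "n_anchor_genes_lost": len(anchor_genes.lost),
        "expression_dsb_pearson_r": expr_corr.pearson_r,
        "expression_dsb_pearson_p": expr_corr.pearson_p,
        "compartment_switch_fraction": comp.switch_fraction(),
        "deg_compartment_p": {
            cls: e.p_value for cls, e in comp_enrich.items()
        },
        "tad_levels": tad_assoc.levels,
        "tad_mean_ratio": {str(k): v for k, v in tad_assoc.mean_ratio.items()},
        "tad_ratio_trend_rho": tad_assoc.ratio_trend_rho,
        "n_dsb_genes": len(dsb_gene_ids),
        "n_deg": len(deg_ids),
        "n_candidates": len(overlap.candidates),
        "candidates": sorted(overlap.candidates),
    }
    report["warnings"] = warnings_list

    _write_outputs(sim, cfg, out, ratio, regions, differential, anchors, report)
    return report


def _genes_in_regions(genes, regions) -> set[str]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        by_chrom.setdefault(r.interval.chrom, []).append(
            (r.interval.start, r.interval.end)
        )
    out = set()
    for g in genes:
        for s, e in by_chrom.get(g.chrom, []):
            if s <= g.tss < e:
                out.add(g.gene_id)
                break
    return out


def _write_inputs(sim: SimulationResult, out: Path) -> dict[str, Path]:
    """Write the simulated study in the pipeline's input formats."""
    paths: dict[str, Path] = {}

    def reg(name: str, p: Path) -> Path:
        paths[name] = p
        return p

    io_mod.write_chrom_sizes(
        sim.annotation.binning.chrom_sizes, reg("chrom_sizes", out / "genome.chrom.sizes")
    )
    io_mod.write_gene_table(sim.genes, reg("genes", out / "genes.tsv"))
    io_mod.write_labeled_bed(
        [(s.interval, s.state) for s in sim.annotation.states],
        reg("states", out / "chrom_states.bed"),
    )
    io_mod.write_labeled_bed(
        sim.annotation.repeats, reg("repeats", out / "repeats.bed")
    )
    _write_counts_bedgraph(
        sim.control_dsb, reg("dsb_control", out / "dsb_control.bedgraph")
    )
    _write_counts_bedgraph(
        sim.treated_dsb, reg("dsb_treated", out / "dsb_treated.bedgraph")
    )
    loop_mod.write_loops(sim.control_loops, reg("loops_control", out / "loops_control.bedpe"))
    loop_mod.write_loops(sim.treated_loops, reg("loops_treated", out / "loops_treated.bedpe"))
    for chrom, dense in sim.contacts_treated.items():
        p = reg(f"contacts_{chrom}", out / f"contacts_treated.{chrom}.txt")
        io_mod.write_contact_matrix(
            contacts_to_triplets(dense), chrom, dense.shape[0],
            sim.treated_loops.resolution, p,
        )
    io_mod.write_tads(sim.tads, reg("tads", out / "tads.tsv"))
    io_mod.write_bedgraph(
        [(iv, c) for iv, c, _ in sim.compartments],
        reg("pc1_control", out / "pc1_control.bedgraph"),
    )
    io_mod.write_bedgraph(
        [(iv, t) for iv, _, t in sim.compartments],
        reg("pc1_treated", out / "pc1_treated.bedgraph"),
    )
    write_truth_json(sim.truth, out / "truth.json")
    paths["truth"] = out / "truth.json"
    return paths


def _write_counts_bedgraph(track, path: Path) -> None:
    items = [
        (track.binning.bin_interval(i), float(track.values[i]))
        for i in range(track.binning.n_bins)
    ]
    io_mod.write_bedgraph(items, path)


def _write_outputs(sim, cfg, out, ratio, regions, differential, anchors, report):
    items = [
        (ratio.binning.bin_interval(i), float(ratio.ratio[i]))
        for i in range(ratio.binning.n_bins)
    ]
    io_mod.write_bedgraph(items, out / "dsb_ratio.bedgraph")
    io_mod.write_bed([r.interval for r in regions], out / "dsb_regions.bed")
    loop_mod.write_loops(
        loop_mod.LoopSet(differential.gained, cfg.loop_resolution),
        out / "loops_gained.bedpe",
    )
    loop_mod.write_loops(
        loop_mod.LoopSet(differential.lost, cfg.loop_resolution),
        out / "loops_lost.bedpe",
    )
    with open(out / "anchors.tsv", "w") as fh:
        fh.write("chrom\tstart\tfrequency\tbusy\tin_differential\n")
        for (chrom, s), f, b, d in zip(
            anchors.anchors, anchors.frequency, anchors.busy, anchors.in_differential
        ):
            fh.write(f"{chrom}\t{s}\t{f}\t{int(b)}\t{int(d)}\n")
    (out / "report.json").write_text(report.to_json())
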