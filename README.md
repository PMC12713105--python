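# breakscape

Quantitative analysis linking DNA double-strand-break (DSB) enrichment to
3D-genome reorganisation.

Folate deficiency (modelled with the dihydrofolate-reductase inhibitor
methotrexate, MTX) floods the genome of embryonic stem cells with DSBs, and
those breaks are not uniformly placed: they concentrate near transcription
start sites, at active promoters (TssA) and enhancers (EnhA), and they
co-locate with chromatin loops that appear or disappear between conditions.
`breakscape` is a library + CLI for the statistics behind that kind of study:

- **Per-bin DSB ratios.** Breakpoint sites are counted into fixed genome bins
  (5 kb default), depth-normalised to CPM, and the per-bin fold change
  r_i = (CPM_treated,i + c) / (CPM_control,i + c) (pseudocount c = 0.5) is
  the central statistic, with per-bin hypergeometric enrichment tests
  (population = pooled reads, marked = treated reads, draws = reads in the
  bin), Benjamini–Hochberg correction and adjacent-bin merging into DSB
  enrichment regions.
- **Stratified correlations.** The ratio track is sorted and grouped into
  equal-count bins to relate DSB levels to nearest-TSS distance (500 bins),
  to chromatin-state content across ratio deciles, to enhancer proximity
  (EnhA proximal ⇔ a TssA within 20 kb edge-to-edge), to peak/repeat
  coverage (Spearman), and to expression (genes with FPKM > 1, 100 bins,
  Pearson).
- **Differential chromatin loops.** Loops (10 kb anchors with a caller
  probability) are *gained* when p_treated > 0.95 and p_control < 0.8, and
  *lost* in the mirror case; uncalled loops count as probability 0.
- **Busy anchors and colocalisation.** Anchors used by ≥ 2 loops are hubs
  ("busy"); a Yates-corrected chi-square on loop endpoints tests whether
  hubs preferentially host differential loops, and a genome-bin 2×2 tests
  DSB-region / differential-anchor colocalisation.
- **APA.** Aggregate peak analysis: observed/expected contact submatrices
  around loop pixels are averaged; score = centre / mean of the 3×3
  lower-left corner.
- **Integration.** Genes in differential anchors (by TSS), A/B-compartment
  switch classes (stable A, A→B, B→A, stable B from PC1 signs) with
  hypergeometric DEG enrichment, hierarchical-TAD-level trends, and
  upset-style multi-evidence gene intersection.
- **Synthetic data with planted truth.** A seeded generator emulates the
  whole study — Poisson DSB counts decaying with TSS distance and boosted by
  treatment in regulatory chromatin, two-condition loop lists with hubs and
  planted differential loops in DSB-hot bins, contact matrices with planted
  loop peaks, lognormal expression coupled to gained/lost anchors — so every
  stage can be validated against known ground truth.

## Worked example

```python
from breakscape import (dsb_ratio, call_differential_loops,
                        busy_anchor_association, tss_distance_profile)
from breakscape.loops import union_loops
from breakscape.simulate import SimulationParams, simulate_all

sim = simulate_all(SimulationParams(seed=7), with_contacts=False)
ratio = dsb_ratio(sim.treated_dsb, sim.control_dsb)
profile = tss_distance_profile(ratio, sim.genes, n_bins=500)
diff = call_differential_loops(sim.treated_loops, sim.control_loops)
assoc = busy_anchor_association(
    union_loops(sim.treated_loops, sim.control_loops), diff)

print(f"genome-wide mean DSB ratio: {ratio.mean_ratio:.3f}")
print(f"DSB ratio vs TSS distance (500-bin Spearman): {profile.spearman_rho:.3f}")
print(f"differential loops: {len(diff.gained)} gained, "
      f"{len(diff.lost)} lost of {len(sim.treated_loops)}")
print(f"busy-anchor association: chi2={assoc.statistic:.1f}, "
      f"p={assoc.p_value:.2e}")
```

prints

```
genome-wide mean DSB ratio: 0.847
DSB ratio vs TSS distance (500-bin Spearman): -0.897
differential loops: 32 gained, 44 lost of 400
busy-anchor association: chi2=11.6, p=6.73e-04
```

The Spearman of −0.90 recovers the planted exponential decay of
treatment-induced breaks away from TSSs; 76 of 400 loops cross the
0.95/0.8 probability thresholds (exactly the planted differential set); and
the chi-square shows hub anchors hosting differential loops far more often
than singleton anchors, as planted.

The same analyses run from the shell:

```sh
breakscape run --seed 7 --outdir out/          # full simulated pipeline
breakscape diff --treated t.bedpe --control c.bedpe --out-prefix diffloops
breakscape ratio --treated t.bed --control c.bed \
    --chrom-sizes genome.chrom.sizes --out ratio.bedgraph
```

`breakscape run` writes every intermediate in standard text formats (bedGraph
ratio track, BED regions, BEDPE loop lists, TSV anchor table) plus a
machine-readable `report.json`; identical config + seed gives byte-identical
outputs.

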