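# Methods

## Coordinate model

All coordinates are 0-based half-open (BED convention) everywhere in memory
and on disk; 1-based inputs must be converted at the reader boundary. A
`GenomeBinning` tiles each chromosome with fixed-width bins; the trailing bin
of a chromosome is retained (truncated, with its true length available for
density normalisation), so every binning is a partition of the genome and
bin index ↔ (chromosome, start) is a bijection. The "median nucleotide" of a
region of length L is start + ⌊(L−1)/2⌋ — the lower of the two central bases
for even lengths, a deterministic tie rule. TSS distance is measured from
that median nucleotide to the nearest TSS *on the same chromosome* (nearest
gene, not an assigned gene — the assignment rule is genuinely open and
nearest-TSS is the package's choice); regions on chromosomes without genes
are excluded from distance analyses rather than given a sentinel value.

## DSB quantification

Breakpoint sites are assigned to bins by their 5′ coordinate (start for
+/. records, end−1 for − records). Each condition is normalised to counts
per million (CPM) and the per-bin DSB ratio is

    r_i = (CPM_treated,i + c) / (CPM_control,i + c),   c = 0.5.

The pseudocount keeps ratios finite at empty bins and CPM makes the
statistic exactly invariant to global library scaling. Note two properties
of this estimator: (i) the genome-wide *mean of per-bin ratios* is upward
biased at low counts (Jensen: E[1/X] > 1/E[X]), so the ratio-of-totals is
reported alongside it; (ii) whether a published "average fold increase" is a
mean of per-bin ratios or a ratio of totals is ambiguous in general, which
is why both are exposed (`mean_ratio`, `totals_ratio`).

Per-bin enrichment uses an upper-tail hypergeometric test with population
N = all reads of both samples, marked K = treated reads, draws n = reads in
the bin, successes k = treated reads in the bin. Several parameterisations
are consistent with a spreadsheet-style HYPGEOMDIST call; this one is
isolated behind a single function so it can be swapped. Bins with BH-adjusted
q < 0.05 *and* ratio ≥ 2 are merged (maximal runs of adjacent significant
bins, never crossing a chromosome) into DSB enrichment regions; both
thresholds are conventional defaults exposed in the config, not published
constants.

Multiscale median smoothing evaluates non-overlapping windows of k bins
(5 kb…1000 kb in 5 kb steps when run in full); the median of an even window
is the mean of the two central values, trailing partial windows use the
values they have, and scale = base width is the identity.

Sorting for the equal-count groupings (10 ratio classes, 500
distance-profile bins, 100 expression bins) is descending by ratio with ties
broken by genomic order (stable lexsort) for reproducibility; group sizes
differ by at most one with the larger groups first. A bin "contains" a
chromatin-state element when they overlap by ≥ 1 bp (not midpoint
containment). Active enhancers are *proximal* when some TssA segment lies
within 20 kb edge-to-edge (overlap ⇒ gap 0), else *distal*. Group
comparisons use the two-sided Mann–Whitney U (exact for small untied
samples, tie-corrected normal approximation otherwise); correlations are
Spearman for coverage/fraction relations and Pearson for the binned
expression profile, matching each analysis's convention.

## Loops

Loops are intra-chromosomal anchor pairs snapped to the 10 kb grid with a
caller probability. Cross-condition matching requires exact snapped-bin
identity (a ±1-bin slack exists but defaults to off); a loop uncalled in a
condition carries probability 0 there, which makes it eligible for
differential status — the natural reading of comparing against a condition
where the caller found nothing. The differential rule is strict on both
sides: gained ⇔ p_treated > 0.95 ∧ p_control < 0.8; lost is the mirror
image, so swapping the condition labels swaps gained ↔ lost exactly.

Anchor recurrence is counted on the *union of distinct loops* across both
conditions (a stable loop present in both lists counts once); anchors with
frequency ≥ 2 are busy. The busy-anchor association chi-square counts **loop
endpoints** (two per loop, table total = 2 × loops): rows busy/normal
endpoint, columns differential/stable loop. Counting deduplicated anchors
instead would be structurally anti-conservative — an anchor participating in
k loops touches at least one differential loop with probability
1 − (1 − π)^k even when busyness and differential status are independent —
and simulation confirms a ~99% null rejection rate for the anchor-level
table versus 2.5% at nominal 5% for the endpoint-level one. All 2×2 tests
report the Yates-corrected statistic N(max(0,|ad−bc|−N/2))²/(r₁r₂c₁c₂)
(clamped at zero, matching `scipy.stats.chi2_contingency`) with the
uncorrected value alongside; a zero margin yields an undefined (NaN) p with
the table still returned.

DSB–anchor colocalisation is scored at the genome-bin level: every 5 kb bin
is cross-classified by membership in a differential-loop anchor and in a DSB
enrichment region (counting bins rather than regions or reads is the
package's choice; the alternatives change the units but not the test).

APA extracts the (2w+1)² observed submatrix around each loop pixel
(w = 10 bins), divides by the distance expectation (mean contact per
diagonal offset over the whole matrix, zeros included), averages across
loops, and scores centre / mean of the 3×3 lower-left corner — the standard
convention when the upstream tool only renders the aggregate. Loops within
3w bins of the diagonal or overhanging the matrix edge are dropped and
counted.

## Integration

Gene ↔ anchor, gene ↔ compartment and gene ↔ enrichment-region assignment
all use the TSS, consistent with the DSB–gene rule ("TSS located within a
DSB enrichment region"); gene-level DSB enrichment is the ratio at the
TSS-containing bin (configurable to the gene-body maximum). Compartment
classes follow PC1 signs — (+,+) stable A, (+,−) A→B, (−,+) B→A, (−,−)
stable B — with zero or missing PC1 mapping to *undefined* rather than a
sign. DEG enrichment per class is upper-tail hypergeometric against the gene
universe. Under nested TADs a bin or gene takes the *deepest* covering
level. The multi-evidence intersection uses upset semantics (exclusive
combination counts, summing to the union size); the candidate list is the
genes present in at least a designated combination of sets (default: DSB
regions ∧ differential anchors ∧ DEG) — the published figure's eight gene
definitions are not fully specified, so the collection is generic with this
combination as the default preset.

## The synthetic study

The generator draws, under one seed split into named substreams (genome,
dsb, loops, contacts, expression, tads, compartments), a complete two-
condition study. Default conditions (chosen once, at design time, so each
planted effect is identifiable at desk scale within seconds):

| parameter | default | meaning |
|---|---|---|
| n_chrom × chrom_len | 2 × 20 Mb | 8 000 5-kb bins, 4 000 10-kb loop bins |
| n_genes / n_enhancers | 200 / 200 | ≥ 450 regulatory bins; ~185 genes at FPKM > 1 |
| rate_floor / base_rate | 16 / 40 reads·bin⁻¹ | depth at which Poisson noise does not swamp the planted decay and the f = 1 null's mean per-bin ratio stays well inside [0.9, 1.1] despite the Jensen bias |
| tss_decay τ | 50 kb | e-folding of the break signal vs TSS distance |
| enhancer_boost β | 2 | control-signal multiplier (1+β) in EnhA bins |
| treatment_fold f | 5 | see below |
| promoter_fold_sd | 0.5 | per-regulatory-bin lognormal (mean-one) fold heterogeneity |
| loop_n / busy_fraction | 400 / 0.3 | hub formation by anchor reuse |
| π_busy / π_normal | 0.4 / 0.1 | per-loop differential planting probabilities |
| peak_factor κ / decay α | 3 / 1 | loop-pixel boost over c/(d+1) contact decay |
| expr_mu/σ, coupling, loop_effect | 1.5/1.0, 0.5, 1 log₂ | lognormal FPKM, copula-coupled to DSB, ±1 log₂ at gained/lost anchors |

Control rate per bin: floor + base·(1+β·enh)·e^(−d/τ). The treated rate
models a TSS-focused induction: inside TssA/EnhA bins the whole rate
(floor included) is multiplied by f (times the bin's mean-one heterogeneity
factor), and elsewhere the signal component is amplified by
1 + (f−1)·e^(−d/τ). Two properties motivate this form over a flat
regulatory-only fold: the treated/control ratio then decays *continuously*
with TSS distance (so the 500-bin profile has a recoverable monotone trend,
not a two-level step lost in rank noise), while the aggregate fold over
regulatory bins remains exactly f, recoverable as a ratio of count sums.
f = 1 reduces both conditions to identical rates; τ = ∞ with β = 0 and
f = 1 gives a fully uniform null. The per-bin heterogeneity exists because
without it every gene's TSS bin would carry the identical planted fold and
an expression–DSB coupling would be undefined; it also makes the DSB-hot
top decile a non-trivial target for differential-loop placement.

Loops are drawn sequentially: with probability `busy_fraction` a loop reuses
an already-used anchor (preferential attachment ⇒ hubs); the loop is planted
differential with probability π_busy if it reused an anchor, else π_normal;
fresh anchors of planted loops are drawn from the top decile of true DSB
ratio (at 10 kb) with probability 0.8. Stable loops get one U(0.95, 1) draw
used in both conditions; planted loops are U(0.95, 1) in one condition and
U(0, 0.8) in the other, so the threshold caller recovers the planted set
*exactly* — threshold behaviour, not statistical power, is what that test
isolates. Contacts are Poisson with expectation c/(|i−j|^α + 1) scaled to
~150 000 reads per chromosome and multiplied by κ at loop pixels. Expression
is lognormal with a Gaussian-copula rank coupling (default ρ = 0.5,
mirroring the positive expression–DSB relation the analysis is designed to
detect) to the true DSB ratio at the TSS bin, a ±`loop_effect` log₂ shift
for genes whose TSS falls in a gained/lost anchor, and independent
multiplicative noise per condition; the DEG flag marks exactly the planted
genes. TAD and compartment generators provide structurally valid inputs
(nested 50 kb-grid domains; smooth 100 kb PC1 tracks whose sign flips
concentrate near zero, a few percent of bins) so the integration stage runs
end-to-end; they do not plant level- or class-coupled DSB effects — the
TAD-level and compartment-enrichment operations are validated on directly
constructed inputs instead.

What the generator does *not* emulate: read-level data (alignment, GC or
mappability bias, duplicates), overdispersion beyond the optional
gamma-Poisson switch, replication timing, sequence content, inter-
chromosomal loops, balancing artefacts in contact matrices, and any
coupling between compartments/TADs and breaks. Passing tests therefore show
the *operations* are correct and the planted effect sizes are recoverable at
these depths — not that real libraries meet the model's assumptions.

## Numerical and degenerate-input conventions

Correlations on constant inputs return NaN rather than raising. Empty
comparison groups, empty gene universes, fewer regions than requested bins
and inconsistent test margins raise `ValueError` with the offending field
named. Config validation collects *all* errors in one message and warns on
unknown keys instead of failing. Determinism: one integer seed fully
determines every generator output (numpy Generator substreams keyed by
stage), writers emit sorted rows with fixed float formatting (`%.6g`), and
the run report is JSON with sorted keys — two runs with the same config and
seed are byte-identical (the report's config echo necessarily contains the
output path).

## Known limitations

- The hypergeometric parameterisation and the bin-level colocalisation unit
  are each one defensible choice among several; both are isolated behind
  single functions.
- The per-bin mean ratio is a biased estimator at low depth; prefer
  `totals_ratio` for a genome-wide fold at shallow coverage.
- APA's distance expectation is computed from the full matrix including
  unmappable-like empty rows if present in real data; with synthetic
  matrices this is exact, with real matrices a masked expectation would be
  preferable.
- The multi-evidence candidate list depends on the generic set definitions
  supplied by the caller; no gene-level "DSB change" threshold is imposed
  beyond enrichment-region membership.
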