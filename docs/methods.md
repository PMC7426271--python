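# Methods

This note documents the models, parameter choices, and numerical conventions
behind `chromintegrate`, and what the synthetic-data generator does and does
not emulate.

## Coordinate and overlap conventions

All intervals are 0-based half-open (BED convention). Overlap everywhere
means ≥ 1 shared base: `[0,10)` and `[9,20)` overlap, `[0,10)` and `[10,20)`
do not. The same criterion drives replicate reproducibility, the dual-caller
gate, bivalency, enhancer classes, and CpG assignment. Peak "position" for
distance computations is the interval midpoint `floor((start+end)/2)`; no
summit model is used, so distances are deterministic without signal data.
Nearest-TSS ties break to the lexicographically smaller gene id.

## Synthetic study model

The generator emulates a knockout-vs-control chromatin study in a
replicated design: a point-source DNA-binding factor and a Polycomb-subunit
partner co-occupy CpG-island promoters; the repressive mark H3K27me3 forms
broad domains over factor-bound promoters and gains amplitude in the
knockout; the active mark H3K4me3 sits on most promoters in both genotypes;
RNA counts are negative-binomial with up/down classes linked to binding.

Defaults (all in `SimulationConfig`, units noted):

- genome: 2 chromosomes × 5 Mb, 1000 non-overlapping genes on alternating
  strands; 65% of promoters carry a CpG island (TSS ± 500 bp) plus a small
  intergenic background set.
- binding: 25% of genes factor-bound (peaks 500–2000 bp at the promoter).
  This puts truth-peak bp at ~3% of the toy genome, chosen to match the
  peak density of genome-scale factor profiling (tens of thousands of ~1-kb
  peaks on a mammalian genome ≈ 1%) after the 250-fold genome compression;
  a much denser packing would saturate the percentile caller's top-1%
  threshold, which by construction covers ~1% of nonzero-bin bp.
- co-occupancy: 66% of factor peaks get an overlapping partner peak;
  partner-only peaks are added at unbound CpG promoters.
- enrichment: truth peaks are 8-fold enriched over uniform background;
  fragment midpoints follow the resulting piecewise-constant rate
  (inhomogeneous Poisson), lengths are Gaussian (mean 180 bp, sd 60 bp,
  truncated at 1 bp), matching nucleosomal CUT&RUN fragments.
- knockout effect: the repressive mark's amplitude over bound genes is
  multiplied by 2 in the knockout; the factor's own knockout libraries have
  no truth peaks (background only).
- libraries: 2 replicates per (factor, genotype), 10⁵ fragments each,
  5% spike-in fraction at unit yield.
- expression: 3 RNA replicates per genotype; log-normal baseline means;
  negative-binomial dispersion 0.05 (biological CV ≈ 0.22, typical for
  genetically matched sorted-cell replicates); differentially expressed
  classes (10% up, 6% down) change 6-fold in the knockout, the strong-effect
  regime in which a 3-vs-3 design has power; down genes are drawn
  preferentially (weight 25:1) from bound genes, up genes mildly (1.5:1).

**Spike-in / chromatin-yield coupling.** The true scale factor of a library
is the user-set per-replicate factor multiplied by the genotype's
truth-signal mass ratio (total rate mass relative to wild type for that
factor). A fragment is a spike-in with probability
`spike_in_fraction / true_scale_factor`. A genotype with globally more
target chromatin therefore yields proportionally fewer spike fragments at
fixed depth — precisely the displacement that spike-in normalization
(rescaling by `min(spike)/spike`) undoes. Without this coupling a global
mark gain is unrecoverable at fixed sequencing depth, because the gain
dilutes per-locus coverage exactly as much as it raises the signal share.

Determinism: every stage derives an independent child generator from the
global seed and a fixed per-stage tag (CRC-32 of the stage name), so any
artifact regenerates byte-identically regardless of call order.

What the generator does **not** emulate: sequence content, mappability and
GC structure, fragment-length dependence on occupancy, duplicate structure
beyond exact-coordinate collisions, antibody efficiency differences, and
sample-level batch effects. Passing recovery tests therefore demonstrates
the correctness of the statistical chain, not robustness to artifacts of
real libraries.

## Peak callers

Both callers are minimal, fully specified stand-ins for the broad-domain
and sparse-enrichment callers used in practice; they keep the published
parameterization but use a single testable statistical model each, so exact
agreement with the published tools' outputs is not expected.

*Poisson window/island caller.* Fragment midpoints (count semantics: one
window per fragment) in non-overlapping 200-bp windows; background rate
λ = N·w / (G·f) with effective genome fraction f = 0.86. Windows pass by
Benjamini–Hochberg at the configured FDR over all genome-wide windows;
passing windows separated by ≤ 600 bp join into islands; each island is
re-tested (upper-tail Poisson on its aggregate count against the
length-scaled rate, BH again) and failures are dropped. Island score =
aggregate count, q-value = island BH-adjusted p. BH is used wherever an
FDR-corrected p-value is required.

*Percentile block caller.* Threshold = (100 − p)th percentile of the
**nonzero** bin values of the normalized track (p = 1 high-confidence,
p = 5 low-confidence); peaks are maximal runs of ≥ `min_block_bins` bins
strictly above the threshold (a constant track yields nothing); score =
max bin value. Output is invariant to positive rescaling of the track.
Track bin size defaults to 50 bp (an exposed choice; no canonical value
exists).

*Dual-caller merge.* Broad peaks overlapping any point peak are discarded
as redundant; survivors merge with the point peaks.

## Consensus rule

A replicate's high-confidence peak (FDR 0.05 / top 1%) is *reproducible*
when it overlaps ≥ 1 low-confidence interval (FDR 0.5 / top 5%) in **all**
other replicates (default; `any` is available for sensitivity analysis).
Reproducible peaks are pooled over replicates and merged; peaks are kept
whole, never trimmed to overlap footprints. Factor (sparse-cleavage) assays
are additionally required to overlap the percentile caller's reproducible
set; broad histone ChIP marks are not (`require_secondary` flag), mirroring
the assay-specific practice the pipeline emulates.

## Region classification

Locale: promoter = midpoint within 2 kb of the nearest TSS (TSS-proximal at
10 bp); genic = overlaps a gene span but not promoter-proximal; distal =
neither. Exactly one of the three holds. CpG and enhancer classes use plain
interval overlap; an H3K4me1 interval co-marked by both H3K27ac and
H3K27me3 lands in both enhancer classes (reported with a count).

Five-category taxonomy (strand-ignorant; genome-coordinate left/right), in
priority order 5 → 4 → 3 → 1/2 because absence and knockout-gain are the
most distinctive patterns: with c the factor-peak midpoint, (5) no
active-mark interval midpoint within ± 2 kb in either genotype; (4) KO/WT
mean-track ratio over [c−2kb, c+2kb) ≥ 2; (3) nearest mark midpoint within
± 250 bp of c; (1)/(2) nearest mark midpoint left/right of c. The window
(2 kb), center tolerance (250 bp) and gain fold (2) are exposed parameters;
no canonical thresholds exist for the category boundaries.

## Expression and integration

FPKM = count × 10⁹ / (library total × transcript length bp). TMM: reference
= sample with upper-quartile count fraction closest to the mean; gene-wise
M/A against the reference after library-size scaling; double trim (30% on
M, 5% on A); factor = 2^(precision-weighted mean of retained M) with
delta-method binomial weights; factors normalized to multiply to 1.

The differential test is a deliberate, clearly-labeled simplification of a
mean–variance-modeled linear fit: Welch's t on log₂(TMM-CPM + 0.5) with
per-group variances floored at the global median variance (so zero-spread
genes cannot generate spurious hits; on null simulations the raw
false-positive rate is well below nominal), BH adjustment across expressed
genes only (mean FPKM > 1 in at least one genotype), and status up/down
requiring adjusted p < 0.05 and linear fold-change > 1.5 in either
direction.

Gene-level mark signal is the length-weighted mean normalized track value
over the promoter ± 2 kb (default) or the gene body; windows at chromosome
edges are clipped. MA values use pseudocount c = 1. A gene is "bound" when
≥ 1 consensus peak overlaps its promoter ± 2 kb window (exposed parameter).

The binding×direction test is the two-tailed Fisher exact test under the
probability-mass rule (sum of all fixed-margin tables no more probable than
the observed one), implemented directly on the hypergeometric pmf with a
1 + 10⁻⁹ relative tie tolerance; a zero margin returns p = 1 by convention.
Peak-overlap enrichment uses the upper-tail hypergeometric test. qPCR fold
changes use 2^−ΔΔCt.

## Proteomics scoring

Protein abundance = spectral count × 50 kD / protein size kD. Bait-vs-IgG
comparison is a per-protein Welch two-sample t-test on raw abundances
(zeros dominate IgG rows, so no log by default; `log_transform` applies
log1p); "enriched" requires p < α **and** a higher target mean. All-zero
rows report p = 1. Proteins are ranked enriched-first, then by descending t.
The test flavor (Welch rather than pooled or paired) is a robustness choice
for n = 3 count-derived values and is recorded in the output metadata.

## Numerical choices and degenerate inputs

- Empty fragment sets / all-zero tracks: callers warn and return empty peak
  sets; zero spike counts and zero library totals are errors.
- Zero variance after the floor (identical replicates everywhere): t = 0,
  p = 1.
- Percentile thresholds use the default linear-interpolation percentile;
  strict `>` comparison throughout the block caller.
- Profile matrices resample by exact length-weighted means of the
  piecewise-constant track; out-of-chromosome stretches contribute zero
  signal (anchors near edges are damped, not extrapolated).
- All BH adjustments use the step-up procedure as implemented in
  statsmodels.

## Problem sizes

Defaults were sized so the full pipeline (16 libraries × 10⁵ fragments on a
10-Mb toy genome) runs in a few seconds and the complete test suite —
including 100-run null calibrations of the caller and the DE test and the
exhaustive ≤ 40-total exact-test sweep — in about a minute on one core.

## Known limitations

- The callers are stand-ins: no model-based shift estimation, no
  control-library thresholding, no per-window score aggregation beyond the
  Poisson island model.
- The DE stand-in has conservative null behavior (variance flooring) and
  less power than a moderated linear model at n = 3; the generator's
  6-fold effects are chosen to be in its detectable regime.
- The locale taxonomy is strand-ignorant and midpoint-based; genic vs
  promoter assignment follows a fixed priority, not transcript models.
- Spectral-count scoring is protein-level only; no peptide/PSM modeling.
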