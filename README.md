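# chromintegrate

Integrative analysis of knockout-vs-control chromatin profiling, built for
studies that combine spike-in–normalized CUT&RUN / ChIP-seq of a DNA-binding
factor and histone marks with RNA-seq differential expression and co-IP
mass-spectrometry. The package implements the full statistical chain —
fragment filtering, spike-in scale factors, two peak callers, a
cross-replicate consensus rule, chromatin-region classification, and
binding×expression×proteomics integration — and ships a seeded synthetic-data
generator so every stage is testable end-to-end without external downloads.

## What it computes

**Spike-in normalization.** Each library carries foreign-genome
("spike-in") fragments at a fraction set by the chromatin yield of the
sample. With spike counts *s₁…sₙ*, library *i* is rescaled by
*fᵢ = min(s) / sᵢ* (scale-down only; the lowest-spike library is the
reference). This is what lets a global histone-mark gain in the knockout
survive fixed sequencing depth.

**Peak calling.** Two deliberately simple, fully specified callers:

- *Poisson window/island caller* (broad-mark style): fragment midpoints per
  200-bp window; background rate λ = N·w/(G·0.86); windows passing
  Benjamini–Hochberg at the chosen FDR are joined across gaps ≤ 600 bp and
  each island re-tested on its aggregate count.
- *Percentile block caller* (sparse-enrichment style): maximal runs of bins
  whose normalized signal strictly exceeds the top-1% (high confidence) or
  top-5% (low confidence) threshold of the nonzero bins.

**Consensus.** A high-confidence peak is *reproducible* when it overlaps
(≥1 bp) a low-confidence call in the other replicate(s); factor assays are
additionally required to overlap the percentile caller's reproducible set.

**Classification.** Peak locale (TSS ±10 bp, promoter ±2 kb, genic, distal,
CpG), bivalent domains (H3K27me3 ∩ H3K4me3), active/poised enhancers
(H3K4me1 ∩ H3K27ac / ∩ H3K27me3), and a five-category taxonomy of factor
peaks by the position and knockout response of the nearby active-promoter
mark.

**Integration.** FPKM and TMM normalization, a Welch-on-log-CPM differential
expression test (adjusted *p* < 0.05 and fold-change > 1.5), per-gene mark
MA values M = log₂((KO+c)/(WT+c)), the two-tailed Fisher exact test on the
binding×direction 2×2 table, the hypergeometric peak-overlap test, 2^−ΔΔCt
qPCR quantification, and size-normalized spectral-count scoring
(SC × 50 kD / size kD) with a per-protein Welch test for bait-vs-IgG co-IP.

## Worked example

The numbered drivers under `analysis/` run one simulated study (seed 1,
two chromatin replicates per genotype, 10⁵ fragments/library, truth peaks at
8-fold enrichment, 2-fold knockout gain of the repressive mark at bound
genes):

```bash
python analysis/01_simulate.py
python analysis/02_normalize.py
python analysis/03_call_peaks.py
python analysis/04_consensus_peaks.py
python analysis/05_classify_regions.py
python analysis/06_integrate_expression.py
python analysis/07_score_proteomics.py
```

Key lines the drivers print, and what they mean:

```
repressive-mark libraries: WT scaled by ~0.70 vs KO ~1.00
```
the knockout's globally higher H3K27me3 yield lowers its spike fraction;
normalization scales WT down to match (without this the 2-fold gain is
invisible at fixed depth).

```
ybx1 wt: 241 consensus peaks, recall 0.976, precision 1.000
```
the dual-threshold, dual-caller consensus recovers 97.6% of truth factor
peaks with no false positives.

```
200 bivalent regions; 195 (97.5%) bound by the factor
up genes bound: 29/91 (31.9%); down genes bound: 33/42 (78.6%)
binding x direction Fisher exact: odds 0.128, p = 6.35e-07
repressive-mark M (log2 KO/WT): down genes 0.645, up genes 0.283, all 0.220
```
down-regulated genes are strongly enriched for factor binding at their
promoters, and genes that lose expression gain the repressive mark — the
simulated ground truth links both, and the integration statistics recover
the links.

```
published printed counts (382/604 up, 263/366 down) re-tested: p = 0.0062
```
the one desk-reproducible published statistic: building the 2×2 table from
the printed bound-gene counts and running the exact test reproduces the
published two-tailed *p* (the source prints the 263/366 fraction as 68%,
although it computes to 71.9%; both are surfaced).

The same chain is callable as a library (`chromintegrate.run_pipeline`) and
as a CLI (`chromintegrate run-all --out out/`).

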