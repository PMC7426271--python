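"""Seeded generator of toy genomes, truth occupancy, fragments, and expression.

The generator emulates the statistical structure of a knockout-vs-control
chromatin study in neural progenitors: a DNA-binding factor ("ybx1"-like) and
a Polycomb subunit ("ezh2"-like) co-occupy CpG-island promoters; the repressive
mark H3K27me3 gains signal over factor-bound genes in the knockout; each
sequencing library carries a fixed proportion of foreign-genome spike-in
fragments; and RNA counts are negative-binomial with up/down gene classes
linked to factor binding.

Everything flows deterministically from ``SimulationConfig.seed``: each
operation derives an independent child generator from the global seed and a
stable per-stage tag, so regenerating any one artifact is byte-identical
regardless of call order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .intervals import Gene, GenomeAnnotation, GenomicInterval, PeakSet

__all__ = [
    "SimulationConfig",
    "Library",
    "TruthSet",
    "generate_annotation",
    "generate_truth",
    "simulate_fragments",
    "simulate_expression",
    "ExpressionMatrix",
]

FACTOR_BINDER = "ybx1"      # point-source factor at CpG promoters
FACTOR_PRC2 = "ezh2"        # co-occupying Polycomb subunit
MARK_REPRESSIVE = "h3k27me3"
MARK_ACTIVE = "h3k4me3"
GENOTYPES = ("wt", "ko")
SPIKE_CHROM = "spike_chr1"
SPIKE_GENOME_LENGTH = 1_000_000


class Library(NamedTuple):
    """One sequencing library: (factor/mark, genotype, replicate)."""

    factor: str
    genotype: str
    replicate: int

    @property
    def name(self) -> str:
        return f"{self.factor}_{self.genotype}_rep{self.replicate}"


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic genome and libraries.

    Defaults describe the emulated study: two chromatin replicates and three
    RNA replicates per genotype, 1e5 fragments per library, truth peaks at
    8-fold enrichment over background, a 2-fold repressive-mark gain at bound
    genes in the knockout, ~2/3 factor-PRC2 co-occupancy, and a 5% spike-in
    fraction.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 1000
    cpg_promoter_fraction: float = 0.65
    factors: tuple[str, ...] = (FACTOR_BINDER, FACTOR_PRC2, MARK_REPRESSIVE, MARK_ACTIVE)
    co_occupancy_fraction: float = 0.66
    bound_gene_fraction: float = 0.25
    ko_h3k27me3_gain_fold: float = 2.0
    enrichment_fold: float = 8.0
    spike_in_fraction: float = 0.05
    depth: int = 100_000
    n_replicates: int = 2
    n_rna_replicates: int = 3
    frag_len_mean: float = 180.0
    frag_len_sd: float = 60.0
    nb_dispersion: float = 0.05
    de_fractions: tuple[float, float] = (0.10, 0.06)  # (up, down)
    de_fold: float = 6.0
    # Per-replicate true library scale factors (cycled); None = all 1.0.
    scale_factors: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        for name in ("cpg_promoter_fraction", "co_occupancy_fraction",
                     "bound_gene_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if not (0.0 < self.spike_in_fraction < 1.0):
            raise ValueError("spike_in_fraction must lie in (0,1)")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.ko_h3k27me3_gain_fold < 1.0:
            raise ValueError("ko_h3k27me3_gain_fold must be >= 1")
        if not all(0.0 <= f <= 1.0 for f in self.de_fractions):
            raise ValueError("de_fractions must lie in [0,1]")

    def libraries(self) -> list[Library]:
        libs = []
        for factor in self.factors:
            for genotype in GENOTYPES:
                for rep in range(1, self.n_replicates + 1):
                    libs.append(Library(factor, genotype, rep))
        return libs

    def true_scale_factor(self, library: Library) -> float:
        if self.scale_factors is None:
            return 1.0
        return self.scale_factors[(library.replicate - 1) % len(self.scale_factors)]


@dataclass
class TruthSet:
    """Ground truth used by recovery tests: peaks, gene classes, binding flags."""

    truth_peaks: dict[tuple[str, str], PeakSet]
    gene_classes: dict[str, str]  # gene id -> up | down | unchanged
    bound_flags: dict[str, bool]
    true_scale_factors: dict[Library, float]


def _rng(cfg: SimulationConfig, tag: str) -> np.random.Generator:
    """Child generator derived from the global seed and a stage tag."""
    return np.random.default_rng(
        np.random.SeedSequence([cfg.seed, zlib.crc32(tag.encode())])
    )


def _chrom_names(cfg: SimulationConfig) -> list[str]:
    return [f"chr{i + 1}" for i in range(cfg.n_chroms)]


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def generate_annotation(cfg: SimulationConfig) -> GenomeAnnotation:
    """Non-overlapping genes on alternating strands, CpG islands, enhancer marks.

    Genes are laid out in equal slots along each chromosome with jittered
    starts and lengths, so intergenic space exists everywhere.  CpG islands
    cover ``cpg_promoter_fraction`` of promoters (TSS +/- 500 bp) plus a small
    intergenic background set.  Enhancer-signature interval lists (H3K4me1 /
    H3K27ac) are placed midway between genes.
    """
    rng = _rng(cfg, "annotation")
    chroms = _chrom_names(cfg)
    chrom_sizes = {c: cfg.chrom_length for c in chroms}

    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chroms))
    slot = cfg.chrom_length // per_chrom
    min_gene, max_gene = 2000, min(10_000, slot // 2)
    if slot < 2 * min_gene:
        raise ValueError("genome too small")

    genes: list[Gene] = []
    idx = 0
    for chrom in chroms:
        for j in range(per_chrom):
            if idx >= cfg.n_genes:
                break
            slot_start = j * slot
            glen = int(rng.integers(min_gene, max_gene + 1))
            offset = int(rng.integers(600, slot - glen - 600))
            a = slot_start + offset
            b = a + glen
            strand = "+" if idx % 2 == 0 else "-"
            tss, tes = (a, b - 1) if strand == "+" else (b - 1, a)
            genes.append(Gene(f"g{idx:04d}", chrom, strand, tss, tes, glen))
            idx += 1

    n_cpg = int(round(cfg.cpg_promoter_fraction * len(genes)))
    cpg_gene_idx = rng.choice(len(genes), size=n_cpg, replace=False)
    islands = []
    for gi in sorted(cpg_gene_idx):
        g = genes[gi]
        start = max(0, g.tss - 500)
        end = min(chrom_sizes[g.chrom], g.tss + 500)
        islands.append(GenomicInterval(g.chrom, start, end))
    # background islands away from promoters
    n_bg = max(1, len(genes) // 20)
    for _ in range(n_bg):
        chrom = chroms[int(rng.integers(cfg.n_chroms))]
        start = int(rng.integers(0, cfg.chrom_length - 600))
        islands.append(GenomicInterval(chrom, start, start + 600))
    from .intervals import merge_union

    cpg = merge_union(PeakSet(islands, label="cpg_islands"))

    # enhancer signatures: K4me1 regions between genes; half also K27ac(+)
    k4me1, k27ac = [], []
    for i, g in enumerate(genes):
        if i % 5 != 0:
            continue
        lo, hi = min(g.tss, g.tes), max(g.tss, g.tes)
        center = hi + 3000 + int(rng.integers(0, 1500))
        if center + 800 >= chrom_sizes[g.chrom]:
            continue
        iv = GenomicInterval(g.chrom, center, center + 800)
        k4me1.append(iv)
        if rng.random() < 0.5:
            k27ac.append(GenomicInterval(g.chrom, center + 100, center + 900))
    enhancer_marks = {
        "h3k4me1": PeakSet(k4me1, label="h3k4me1"),
        "h3k27ac": PeakSet(k27ac, label="h3k27ac"),
    }
    return GenomeAnnotation(
        chrom_sizes=chrom_sizes, genes=genes, cpg_islands=cpg,
        enhancer_marks=enhancer_marks,
    )


# ---------------------------------------------------------------------------
# Truth occupancy and gene classes
# ---------------------------------------------------------------------------

def _clip_interval(chrom: str, start: int, end: int, size: int,
                   score: float | None = None) -> GenomicInterval:
    start = max(0, start)
    end = min(size, end)
    return GenomicInterval(chrom, start, max(end, start + 1), score)


def generate_truth(cfg: SimulationConfig, ann: GenomeAnnotation) -> TruthSet:
    """Factor/mark truth peaks, linked gene classes, and library scale factors.

    The binder's peaks sit on CpG promoters of "bound" genes (width 500-2000
    bp).  A ``co_occupancy_fraction`` subset of them gets an overlapping
    PRC2-subunit peak; extra PRC2-only peaks are added elsewhere.  The
    repressive mark has broad domains over bound promoters whose knockout
    amplitude is multiplied by ``ko_h3k27me3_gain_fold``; the active mark sits
    on most promoters in both genotypes.  Down-regulated gene classes are
    drawn preferentially from bound genes.

    Interval ``score`` carries the truth amplitude (relative rate multiplier
    on top of uniform background) used by :func:`simulate_fragments`.
    """
    rng = _rng(cfg, "truth")
    genes = ann.genes
    sizes = ann.chrom_sizes
    amp = cfg.enrichment_fold - 1.0  # extra rate over background inside a peak

    cpg_trees = ann.cpg_islands.trees()

    def promoter_has_cpg(g: Gene) -> bool:
        t = cpg_trees.get(g.chrom)
        return t is not None and t.overlaps(max(0, g.tss - 500), g.tss + 500)

    cpg_genes = [i for i, g in enumerate(genes) if promoter_has_cpg(g)]
    other_genes = [i for i in range(len(genes)) if i not in set(cpg_genes)]
    n_bound = int(round(cfg.bound_gene_fraction * len(genes)))
    # bound genes preferentially at CpG promoters
    take_cpg = min(n_bound, len(cpg_genes))
    bound_idx = list(rng.choice(cpg_genes, size=take_cpg, replace=False))
    if n_bound > take_cpg:
        bound_idx += list(rng.choice(other_genes, size=n_bound - take_cpg, replace=False))
    bound_set = set(int(i) for i in bound_idx)

    binder_peaks, prc2_peaks, k27_wt, k27_ko, k4 = [], [], [], [], []
    for i in sorted(bound_set):
        g = genes[i]
        size = sizes[g.chrom]
        w = int(rng.integers(500, 2001))
        jitter = int(rng.integers(-100, 101))
        c = g.tss + jitter
        binder_peaks.append(_clip_interval(g.chrom, c - w // 2, c - w // 2 + w, size, amp))
        if rng.random() < cfg.co_occupancy_fraction:
            w2 = int(rng.integers(500, 2001))
            shift = int(rng.integers(-w // 4, w // 4 + 1))
            prc2_peaks.append(
                _clip_interval(g.chrom, c + shift - w2 // 2, c + shift - w2 // 2 + w2,
                               size, amp)
            )
        # broad repressive domain over the bound promoter
        w3 = int(rng.integers(3000, 6001))
        k27_wt.append(_clip_interval(g.chrom, c - w3 // 2, c - w3 // 2 + w3, size, amp))
        k27_ko.append(
            _clip_interval(g.chrom, c - w3 // 2, c - w3 // 2 + w3, size,
                           amp * cfg.ko_h3k27me3_gain_fold)
        )

    # PRC2-only peaks at a sample of unbound CpG promoters
    spare = [i for i in cpg_genes if i not in bound_set]
    n_extra = min(len(spare), max(1, n_bound // 3))
    for i in sorted(rng.choice(spare, size=n_extra, replace=False)):
        g = genes[i]
        w = int(rng.integers(500, 2001))
        prc2_peaks.append(
            _clip_interval(g.chrom, g.tss - w // 2, g.tss - w // 2 + w,
                           sizes[g.chrom], amp)
        )

    # active-promoter mark on 80% of genes, both genotypes
    for i, g in enumerate(genes):
        if rng.random() < 0.8:
            w = int(rng.integers(800, 1501))
            k4.append(_clip_interval(g.chrom, g.tss - w // 2, g.tss - w // 2 + w,
                                     sizes[g.chrom], amp))

    truth_peaks = {
        (FACTOR_BINDER, "wt"): PeakSet(binder_peaks, "ybx1_wt_truth"),
        (FACTOR_BINDER, "ko"): PeakSet([], "ybx1_ko_truth"),  # knockout: no binding
        (FACTOR_PRC2, "wt"): PeakSet(prc2_peaks, "ezh2_wt_truth"),
        (FACTOR_PRC2, "ko"): PeakSet(prc2_peaks, "ezh2_ko_truth"),
        (MARK_REPRESSIVE, "wt"): PeakSet(k27_wt, "h3k27me3_wt_truth"),
        (MARK_REPRESSIVE, "ko"): PeakSet(k27_ko, "h3k27me3_ko_truth"),
        (MARK_ACTIVE, "wt"): PeakSet(k4, "h3k4me3_wt_truth"),
        (MARK_ACTIVE, "ko"): PeakSet(k4, "h3k4me3_ko_truth"),
    }

    # gene classes: down preferentially bound, up mildly bound
    up_frac, down_frac = cfg.de_fractions
    n_up = int(round(up_frac * len(genes)))
    n_down = int(round(down_frac * len(genes)))
    all_idx = np.arange(len(genes))
    bound_mask = np.array([i in bound_set for i in all_idx])
    w_down = np.where(bound_mask, 25.0, 1.0)
    down_pick = rng.choice(all_idx, size=n_down, replace=False,
                           p=w_down / w_down.sum()) if n_down else np.array([], int)
    remaining = np.setdiff1d(all_idx, down_pick)
    w_up = np.where(bound_mask[remaining], 1.5, 1.0)
    up_pick = rng.choice(remaining, size=n_up, replace=False,
                         p=w_up / w_up.sum()) if n_up else np.array([], int)

    gene_classes = {g.gene_id: "unchanged" for g in genes}
    for i in down_pick:
        gene_classes[genes[int(i)].gene_id] = "down"
    for i in up_pick:
        gene_classes[genes[int(i)].gene_id] = "up"
    bound_flags = {genes[int(i)].gene_id: bool(bound_mask[int(i)]) for i in all_idx}

    # True library scale factors couple the user-set per-replicate factor with
    # the genotype's chromatin yield: a genotype with globally more truth
    # signal mass recovers proportionally more target (fewer spike) fragments,
    # which is precisely the shift spike-in normalization must undo.
    genome = sum(ann.chrom_sizes.values())

    def signal_mass(factor: str, genotype: str) -> float:
        ps = truth_peaks[(factor, genotype)]
        return genome + sum(iv.length * (iv.score or 0.0) for iv in ps)

    scale = {}
    for lib in cfg.libraries():
        mass_ratio = signal_mass(lib.factor, lib.genotype) / signal_mass(lib.factor, "wt")
        scale[lib] = cfg.true_scale_factor(lib) * mass_ratio
    return TruthSet(truth_peaks, gene_classes, bound_flags, scale)


# ---------------------------------------------------------------------------
# Fragments
# ---------------------------------------------------------------------------

def simulate_fragments(cfg: SimulationConfig, truth: TruthSet, library: Library):
    """Paired-end fragments for one library, tagged by species of origin.

    Each of ``cfg.depth`` fragments is a spike-in with probability
    ``spike_in_fraction / true_scale_factor(library)`` (so libraries with a
    smaller true scale factor carry proportionally more foreign fragments, the
    signal a spike-in normalization must undo).  Target fragment midpoints
    follow an inhomogeneous-Poisson rate: uniform background plus the
    piecewise-constant truth amplitude of the library's (factor, genotype).
    Lengths are Gaussian, truncated at 1 bp.
    """
    from .signal import FragmentSet

    rng = _rng(cfg, f"fragments:{library.name}")
    s = truth.true_scale_factors.get(library, cfg.true_scale_factor(library))
    p_spike = cfg.spike_in_fraction / s
    if not (0.0 < p_spike < 1.0):
        raise ValueError(f"spike probability {p_spike} outside (0,1) for {library}")

    species = np.where(rng.random(cfg.depth) < p_spike, "spike", "target")
    n_spike = int((species == "spike").sum())
    n_target = cfg.depth - n_spike

    chroms = _chrom_names(cfg)
    peaks = truth.truth_peaks.get((library.factor, library.genotype), PeakSet())

    # Build per-chrom piecewise rate segments: (chrom, start, end, rate)
    seg_chrom: list[str] = []
    seg_start: list[int] = []
    seg_end: list[int] = []
    seg_rate: list[float] = []
    by_chrom = peaks.by_chrom()
    for chrom in chroms:
        pos = 0
        for iv in by_chrom.get(chrom, []):
            if iv.start > pos:
                seg_chrom.append(chrom); seg_start.append(pos)
                seg_end.append(iv.start); seg_rate.append(1.0)
            seg_chrom.append(chrom); seg_start.append(iv.start)
            seg_end.append(iv.end); seg_rate.append(1.0 + (iv.score or 0.0))
            pos = iv.end
        if pos < cfg.chrom_length:
            seg_chrom.append(chrom); seg_start.append(pos)
            seg_end.append(cfg.chrom_length); seg_rate.append(1.0)

    starts = np.array(seg_start)
    ends = np.array(seg_end)
    rates = np.array(seg_rate)
    weights = rates * (ends - starts)
    weights = weights / weights.sum()
    seg_pick = rng.choice(len(starts), size=n_target, p=weights)
    mids = starts[seg_pick] + (rng.random(n_target) * (ends - starts)[seg_pick]).astype(int)
    lens = np.maximum(1, rng.normal(cfg.frag_len_mean, cfg.frag_len_sd, n_target)).astype(int)
    f_start = np.maximum(0, mids - lens // 2)
    f_end = np.minimum(cfg.chrom_length, f_start + lens)
    f_start = np.minimum(f_start, f_end - 1)
    t_chroms = np.array(seg_chrom, dtype=object)[seg_pick]

    sp_mids = rng.integers(0, SPIKE_GENOME_LENGTH, n_spike)
    sp_lens = np.maximum(1, rng.normal(cfg.frag_len_mean, cfg.frag_len_sd, n_spike)).astype(int)
    sp_start = np.maximum(0, sp_mids - sp_lens // 2)
    sp_end = np.minimum(SPIKE_GENOME_LENGTH, sp_start + sp_lens)
    sp_start = np.minimum(sp_start, sp_end - 1)

    df = pd.DataFrame(
        {
            "chrom": np.concatenate([t_chroms, np.full(n_spike, SPIKE_CHROM, dtype=object)]),
            "start": np.concatenate([f_start, sp_start]).astype(int),
            "end": np.concatenate([f_end, sp_end]).astype(int),
            "species": np.concatenate(
                [np.full(n_target, "target", dtype=object),
                 np.full(n_spike, "spike", dtype=object)]
            ),
        }
    )
    # interleave back into the original Bernoulli order for reproducibility clarity
    order = np.argsort(np.concatenate([np.flatnonzero(species == "target"),
                                       np.flatnonzero(species == "spike")]),
                       kind="stable")
    df = df.iloc[order].reset_index(drop=True)
    return FragmentSet(df, library)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Gene x sample counts with sample metadata and gene lengths (bp)."""

    counts: pd.DataFrame            # index: gene ids, columns: sample names
    samples: pd.DataFrame           # columns: sample, genotype, replicate
    gene_lengths: pd.Series         # index: gene ids, bp

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError("every sample must have total count > 0")

    def condition_columns(self, genotype: str) -> list[str]:
        m = self.samples[self.samples.genotype == genotype]
        return list(m["sample"])


def simulate_expression(
    cfg: SimulationConfig, truth: TruthSet, ann: GenomeAnnotation | None = None
) -> ExpressionMatrix:
    """Negative-binomial counts with genotype fold-changes for up/down classes.

    Baseline means are log-normal; genes in the up (down) class have their
    knockout mean multiplied (divided) by ``de_fold``.  Differentially
    expressed genes get a floor on baseline mean so the classes are in the
    detectable range.  ``nb_dispersion`` -> 0 recovers the Poisson limit.
    """
    rng = _rng(cfg, "expression")
    gene_ids = list(truth.gene_classes.keys())
    n = len(gene_ids)
    base = rng.lognormal(mean=4.0, sigma=1.0, size=n)
    classes = np.array([truth.gene_classes[g] for g in gene_ids])
    is_de = classes != "unchanged"
    base = np.where(is_de, np.maximum(base, 40.0), base)

    mu_wt = base
    mu_ko = base * np.where(classes == "up", cfg.de_fold,
                            np.where(classes == "down", 1.0 / cfg.de_fold, 1.0))

    def draw(mu: np.ndarray) -> np.ndarray:
        if cfg.nb_dispersion <= 1e-9:
            return rng.poisson(mu)
        r = 1.0 / cfg.nb_dispersion
        p = r / (r + mu)
        return rng.negative_binomial(r, p)

    data = {}
    meta = []
    for genotype, mu in (("wt", mu_wt), ("ko", mu_ko)):
        for rep in range(1, cfg.n_rna_replicates + 1):
            name = f"{genotype}_rep{rep}"
            data[name] = draw(mu)
            meta.append({"sample": name, "genotype": genotype, "replicate": rep})

    counts = pd.DataFrame(data, index=gene_ids)
    if ann is not None:
        lengths = pd.Series(ann.gene_lengths()).reindex(gene_ids)
    else:
        lengths = pd.Series(1000, index=gene_ids, dtype=float)
    return ExpressionMatrix(counts, pd.DataFrame(meta), lengths.astype(float))
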