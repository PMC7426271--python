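"""Genomic-context annotation of peaks, bivalent domains, enhancer classes,
and the five-category active-mark taxonomy of factor-bound peaks.

Categories (strand-ignorant, genome-coordinate left/right):

1. active-promoter mark (H3K4me3) peaks left of the factor peak center;
2. mark peaks right of the center;
3. mark peak at the center (within ``center_tol``);
4. strong knockout gain of the mark over the peak window;
5. no mark peak within the window in either genotype.

Priority is 5 -> 4 -> 3 -> 1/2: absence and knockout gain are the most
distinctive patterns, then centered marks, then flanking direction.
"""

from __future__ import annotations

import pandas as pd

from .intervals import GenomeAnnotation, PeakSet, GenomicInterval, merge_union, nearest_tss
from .signal import SignalTrack, mean_over_interval

__all__ = [
    "annotate_locale",
    "bivalent_regions",
    "enhancer_classes",
    "categorize_peaks",
]


def annotate_locale(peaks: PeakSet, ann: GenomeAnnotation) -> pd.DataFrame:
    """Per-peak locale flags: TSS-proximal, promoter, genic, distal, CpG.

    ``promoter_2kb`` means the peak midpoint lies within 2 kb of the nearest
    TSS (``tss_within_10bp`` within 10 bp); ``genic`` means the peak overlaps
    a gene span without being promoter-proximal; ``distal`` is the remainder.
    Exactly one of promoter/genic/distal holds per peak.
    """
    gene_spans = PeakSet(
        [GenomicInterval(g.chrom, min(g.tss, g.tes), max(g.tss, g.tes) + 1)
         for g in ann.genes]
    )
    gene_trees = gene_spans.trees()
    cpg_trees = ann.cpg_islands.trees()

    rows = []
    for iv in peaks:
        gene_id, dist = nearest_tss(iv, ann)
        tss10 = dist <= 10
        promoter = dist <= 2000
        gtree = gene_trees.get(iv.chrom)
        in_gene = gtree is not None and gtree.overlaps(iv.start, iv.end)
        genic = in_gene and not promoter
        distal = not promoter and not genic
        ctree = cpg_trees.get(iv.chrom)
        cpg = ctree is not None and ctree.overlaps(iv.start, iv.end)
        rows.append(
            {
                "chrom": iv.chrom, "start": iv.start, "end": iv.end,
                "nearest_gene": gene_id, "tss_distance": dist,
                "tss_within_10bp": tss10, "promoter_2kb": promoter,
                "genic": genic, "distal": distal, "cpg": cpg,
            }
        )
    return pd.DataFrame(rows)


def bivalent_regions(k27: PeakSet, k4: PeakSet) -> PeakSet:
    """Union spans of repressive-mark intervals co-occupied by the active mark.

    For every H3K27me3 interval overlapping >= 1 H3K4me3 interval, the span
    from the leftmost to the rightmost coordinate of the overlapping pair(s)
    is emitted; results are merged.
    """
    trees = k4.trees()
    out = []
    for iv in k27:
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        hits = tree.overlap(iv.start, iv.end)
        if not hits:
            continue
        lo = min(iv.start, min(h.begin for h in hits))
        hi = max(iv.end, max(h.end for h in hits))
        out.append(GenomicInterval(iv.chrom, lo, hi))
    return merge_union(PeakSet(out, label="bivalent"))


def enhancer_classes(
    k4me1: PeakSet, k27ac: PeakSet, k27me3: PeakSet
) -> tuple[PeakSet, PeakSet, int]:
    """Active (K4me1+K27ac) and poised (K4me1+K27me3) enhancer intervals.

    An interval co-occupied by all three marks lands in both classes; the
    third return value counts such double-classified intervals.
    """
    ac_trees = k27ac.trees()
    me3_trees = k27me3.trees()
    active, poised = [], []
    both = 0
    for iv in k4me1:
        a = ac_trees.get(iv.chrom)
        p = me3_trees.get(iv.chrom)
        is_active = a is not None and a.overlaps(iv.start, iv.end)
        is_poised = p is not None and p.overlaps(iv.start, iv.end)
        if is_active:
            active.append(iv)
        if is_poised:
            poised.append(iv)
        if is_active and is_poised:
            both += 1
    return (PeakSet(active, "active_enhancers"),
            PeakSet(poised, "poised_enhancers"), both)


def categorize_peaks(
    factor_peaks: PeakSet,
    k4_wt: PeakSet,
    k4_ko: PeakSet,
    k4_tracks: tuple[SignalTrack, SignalTrack],
    window: int = 2000,
    center_tol: int = 250,
    gain_fold: float = 2.0,
) -> pd.DataFrame:
    """Assign each factor peak to one of the five mark-pattern categories.

    With c the factor-peak midpoint: category 5 if no active-mark interval of
    either genotype has its midpoint within +/- ``window`` of c; else 4 if the
    knockout/control mean track ratio over [c-window, c+window) is >=
    ``gain_fold``; else, with s the nearest mark midpoint, 3 if |s-c| <=
    ``center_tol``, 1 if s < c, 2 if s > c.
    """
    wt_track, ko_track = k4_tracks
    if wt_track is None or ko_track is None:
        raise ValueError("both genotype tracks are required")

    mark_mids: dict[str, list[int]] = {}
    for ps in (k4_wt, k4_ko):
        for iv in ps:
            mark_mids.setdefault(iv.chrom, []).append(iv.midpoint)
    mark_mids = {c: sorted(v) for c, v in mark_mids.items()}

    rows = []
    for iv in factor_peaks:
        c = iv.midpoint
        mids = mark_mids.get(iv.chrom, [])
        near = [m for m in mids if abs(m - c) <= window]
        ratio = float("nan")
        offset = None
        if not near:
            cat = 5
        else:
            wt_mean = mean_over_interval(wt_track, iv.chrom, c - window, c + window)
            ko_mean = mean_over_interval(ko_track, iv.chrom, c - window, c + window)
            ratio = ko_mean / wt_mean if wt_mean > 0 else float("inf")
            if ratio >= gain_fold:
                cat = 4
            else:
                s = min(near, key=lambda m: abs(m - c))
                offset = s - c
                if abs(offset) <= center_tol:
                    cat = 3
                elif offset < 0:
                    cat = 1
                else:
                    cat = 2
        rows.append(
            {
                "chrom": iv.chrom, "start": iv.start, "end": iv.end,
                "category": cat, "nearest_mark_offset": offset,
                "ko_wt_ratio": ratio,
            }
        )
    return pd.DataFrame(rows)
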