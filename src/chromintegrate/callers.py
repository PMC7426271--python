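"""Two simplified peak callers: a Poisson window/island caller and a
percentile block caller.

Both are deliberately minimal stand-ins for the broad-domain (SICER-style)
and sparse-enrichment (SEACR-style) callers used in CUT&RUN/ChIP practice:
they keep the published parameterization (200-bp windows, 600-bp gap, 0.86
effective genome fraction; top-1%/top-5% thresholds) but use a single, fully
testable statistical model, so their exact output is not expected to match
the published tools'.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomeAnnotation, GenomicInterval, PeakSet, merge_union, overlap_flags
from .signal import FragmentSet, SignalTrack

__all__ = [
    "CallerConfig",
    "call_windows_poisson",
    "call_percentile_blocks",
    "dual_caller_merge",
]


@dataclass(frozen=True)
class CallerConfig:
    """Shared caller parameters.

    ``window``/``gap``/``effective_genome_fraction`` drive the Poisson
    window-island caller; ``percentile_top``/``min_block_bins`` drive the
    percentile block caller; ``fdr_cutoff`` is the BH threshold for the
    former.
    """

    window: int = 200
    gap: int = 600
    effective_genome_fraction: float = 0.86
    fdr_cutoff: float = 0.05
    percentile_top: float = 1.0
    min_block_bins: int = 1

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.gap < 0:
            raise ValueError("gap must be >= 0")
        if not (0.0 < self.effective_genome_fraction <= 1.0):
            raise ValueError("effective_genome_fraction must lie in (0,1]")
        if not (0.0 < self.fdr_cutoff < 1.0):
            raise ValueError("fdr_cutoff must lie in (0,1)")
        if not (0.0 < self.percentile_top < 100.0):
            raise ValueError("percentile_top must lie in (0,100)")
        if self.min_block_bins < 1:
            raise ValueError("min_block_bins must be >= 1")


def poisson_window_pvalue(k: int | np.ndarray, lam: float) -> np.ndarray:
    """Upper-tail Poisson p-value P(X >= k) at rate lam."""
    return stats.poisson.sf(np.asarray(k) - 1, lam)


def call_windows_poisson(
    f: FragmentSet, ann: GenomeAnnotation, cfg: CallerConfig
) -> PeakSet:
    """Window/island caller with a genome-wide Poisson background.

    Fragment midpoints are counted in non-overlapping windows; the background
    rate is ``total_fragments x window / (genome x effective_genome_fraction)``.
    Windows passing BH at ``fdr_cutoff`` are joined into islands when
    separated by <= ``gap`` bp, and each island is re-tested (BH again) on its
    aggregate count against the island-length-scaled background rate.
    """
    tgt = f.target
    label = f"{f.library.name}:poisson" if f.library else "poisson"
    if len(tgt) == 0:
        warnings.warn("no fragments: returning empty peak set")
        return PeakSet([], label=label)

    window = cfg.window
    genome = sum(ann.chrom_sizes.values())
    lam = len(tgt) * window / (genome * cfg.effective_genome_fraction)

    # per-chrom window counts of fragment midpoints
    chroms = sorted(ann.chrom_sizes)
    counts: dict[str, np.ndarray] = {}
    for chrom in chroms:
        nw = int(np.ceil(ann.chrom_sizes[chrom] / window))
        counts[chrom] = np.zeros(nw, dtype=int)
    for chrom, sub in tgt.groupby("chrom"):
        if chrom not in counts:
            continue
        mids = ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2)
        idx = np.clip(mids // window, 0, len(counts[chrom]) - 1)
        counts[chrom] += np.bincount(idx, minlength=len(counts[chrom]))

    all_counts = np.concatenate([counts[c] for c in chroms])
    pvals = poisson_window_pvalue(all_counts, lam)
    eligible = multipletests(pvals, alpha=cfg.fdr_cutoff, method="fdr_bh")[0]

    # split eligibility back per chromosome and join into islands
    islands: list[tuple[str, int, int]] = []  # (chrom, start, end) in bp
    offset = 0
    max_gap_windows = cfg.gap // window  # windows between eligibles that may be bridged
    for chrom in chroms:
        nw = len(counts[chrom])
        el = np.flatnonzero(eligible[offset: offset + nw])
        offset += nw
        if len(el) == 0:
            continue
        run_start = el[0]
        prev = el[0]
        for w in el[1:]:
            if (w - prev - 1) * window <= cfg.gap and (w - prev - 1) <= max_gap_windows:
                prev = w
            else:
                islands.append((chrom, run_start * window,
                                min((prev + 1) * window, ann.chrom_sizes[chrom])))
                run_start = prev = w
        islands.append((chrom, run_start * window,
                        min((prev + 1) * window, ann.chrom_sizes[chrom])))

    if not islands:
        return PeakSet([], label=label)

    # island significance on aggregate count vs length-scaled rate
    isl_counts = []
    for chrom, start, end in islands:
        w0 = start // window
        w1 = int(np.ceil(end / window))
        isl_counts.append(int(counts[chrom][w0:w1].sum()))
    isl_counts = np.array(isl_counts)
    lengths = np.array([e - s for _, s, e in islands], dtype=float)
    isl_p = stats.poisson.sf(isl_counts - 1, lam * lengths / window)
    reject, qvals, _, _ = multipletests(isl_p, alpha=cfg.fdr_cutoff, method="fdr_bh")

    out = [
        GenomicInterval(chrom, start, end, score=float(k), qvalue=float(min(q, 1.0)))
        for (chrom, start, end), k, q, keep in zip(islands, isl_counts, qvals, reject)
        if keep
    ]
    return PeakSet(out, label=label)


def call_percentile_blocks(track: SignalTrack, cfg: CallerConfig) -> PeakSet:
    """Threshold the track at the top ``percentile_top``% of nonzero bins.

    The threshold is the (100 - percentile_top)th percentile of the nonzero
    bin values; peaks are maximal runs of >= ``min_block_bins`` consecutive
    bins whose value strictly exceeds it (so a constant track yields no
    peaks).  Peak score is the run's maximum bin value.  Invariant to
    multiplying the track by a positive constant.
    """
    nonzero = np.concatenate([arr[arr > 0] for arr in track.values.values()]) \
        if track.values else np.array([])
    label = f"{track.library.name}:percentile" if track.library else "percentile"
    if nonzero.size == 0:
        warnings.warn("all-zero track: returning empty peak set")
        return PeakSet([], label=label)
    threshold = float(np.percentile(nonzero, 100.0 - cfg.percentile_top))

    bs = track.bin_size
    out = []
    for chrom in sorted(track.values):
        arr = track.values[chrom]
        above = arr > threshold
        if not above.any():
            continue
        edges = np.diff(np.concatenate([[0], above.astype(int), [0]]))
        run_starts = np.flatnonzero(edges == 1)
        run_ends = np.flatnonzero(edges == -1)  # exclusive bin index
        for b0, b1 in zip(run_starts, run_ends):
            if b1 - b0 < cfg.min_block_bins:
                continue
            out.append(
                GenomicInterval(chrom, int(b0 * bs), int(b1 * bs),
                                score=float(arr[b0:b1].max()))
            )
    return PeakSet(out, label=label)


def dual_caller_merge(point_peaks: PeakSet, broad_peaks: PeakSet) -> PeakSet:
    """Union of point peaks with broad peaks that hit no point peak.

    A broad peak overlapping any point peak (1-nt criterion) is discarded as
    redundant; survivors are merged with the point peaks.
    """
    hit = overlap_flags(broad_peaks, point_peaks)
    survivors = [iv for iv, h in zip(broad_peaks, hit) if not h]
    combined = PeakSet(list(point_peaks) + survivors, label=point_peaks.label)
    return merge_union(combined)
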