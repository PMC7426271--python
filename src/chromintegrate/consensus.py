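"""Cross-replicate reproducible peaks and the dual-caller consensus pipeline.

A peak is reproducible when it is called at the stringent threshold in one
replicate and supported at the relaxed threshold in the other replicate(s);
the final consensus additionally requires support from a second, independent
caller's reproducible set.  Peaks are always kept whole (never trimmed to
the overlap footprint).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .intervals import PeakSet, merge_union, overlap_flags

__all__ = ["ReplicatePeakCalls", "reproducible_peaks", "consensus_pipeline"]


@dataclass
class ReplicatePeakCalls:
    """Per-replicate (high-confidence, low-confidence) peak calls.

    ``high_conf[r]`` holds the stringent calls of replicate r (e.g. FDR 0.05
    or top 1 percentile), ``low_conf[r]`` the relaxed calls (FDR 0.5 / top 5
    percentile) of the same replicate.
    """

    high_conf: list[PeakSet]
    low_conf: list[PeakSet]
    method: str = ""

    def __post_init__(self) -> None:
        if len(self.high_conf) != len(self.low_conf):
            raise ValueError("high_conf and low_conf must pair up per replicate")

    @property
    def n_replicates(self) -> int:
        return len(self.high_conf)


def reproducible_peaks(calls: ReplicatePeakCalls, mode: str = "all") -> PeakSet:
    """High-confidence peaks supported by low-confidence calls in other replicates.

    For each replicate r, a high-confidence peak is kept when it overlaps at
    least one low-confidence interval in ``all`` (default) or ``any`` other
    replicate.  Kept peaks from every replicate are pooled and merged.
    """
    if mode not in ("all", "any"):
        raise ValueError("mode must be 'all' or 'any'")
    n = calls.n_replicates
    if n == 0:
        raise ValueError("no replicates")
    if n == 1:
        warnings.warn("single replicate: reproducibility rule is a pass-through")
        return merge_union(calls.high_conf[0])

    kept = []
    for r in range(n):
        high = calls.high_conf[r]
        if len(high) == 0:
            continue
        support = []
        for o in range(n):
            if o == r:
                continue
            support.append(overlap_flags(high, calls.low_conf[o]))
        for i, iv in enumerate(high):
            votes = [s[i] for s in support]
            ok = all(votes) if mode == "all" else any(votes)
            if ok:
                kept.append(iv)
    return merge_union(PeakSet(kept, label=f"{calls.method}:reproducible"))


def consensus_pipeline(
    primary_calls: ReplicatePeakCalls,
    secondary_calls: ReplicatePeakCalls,
    mode: str = "all",
    require_secondary: bool = True,
) -> PeakSet:
    """Reproducible primary peaks that also hit the secondary reproducible set.

    ``require_secondary=False`` skips the second-caller intersection (for
    assay types where only the primary caller's reproducibility is demanded).
    """
    r1 = reproducible_peaks(primary_calls, mode=mode)
    if not require_secondary:
        return r1
    r2 = reproducible_peaks(secondary_calls, mode=mode)
    hit = overlap_flags(r1, r2)
    return PeakSet([iv for iv, h in zip(r1, hit) if h],
                   label=f"{primary_calls.method}:consensus")
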