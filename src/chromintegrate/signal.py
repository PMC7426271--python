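"""Fragment filtering, spike-in scale factors, binned coverage, profile matrices.

Spike-in normalization: each library's foreign-genome fragment count measures
its effective depth, so signal is rescaled by ``min(spike counts) / spike
count(library)``.  The library with the fewest spike-in fragments is the
reference (factor 1); all other factors are <= 1, i.e. libraries are only ever
scaled down.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import PeakSet
from .simulate import Library

__all__ = [
    "FragmentSet",
    "SpikeNormFactors",
    "SignalTrack",
    "filter_fragments",
    "spike_scale_factors",
    "coverage_track",
    "profile_matrix",
    "mean_over_interval",
    "write_bedgraph",
]


@dataclass
class FragmentSet:
    """Paired-end fragments (chrom, start, end, species) for one library."""

    df: pd.DataFrame
    library: Library

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "species"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"fragment table must have columns {sorted(required)}")
        if len(self.df) and not (self.df["start"] < self.df["end"]).all():
            raise ValueError("fragments require start < end")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def target(self) -> pd.DataFrame:
        return self.df[self.df["species"] == "target"]

    @property
    def spike_count(self) -> int:
        return int((self.df["species"] == "spike").sum())

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, library: Library) -> "FragmentSet":
        return cls(pd.read_csv(path, sep="\t"), library)


@dataclass
class SpikeNormFactors:
    """Spike-in counts and the derived per-library scale-down factors."""

    spike_counts: dict[Library, int]
    factors: dict[Library, float]


@dataclass
class SignalTrack:
    """Fixed-bin coverage per chromosome, optionally spike-normalized."""

    bin_size: int
    values: dict[str, np.ndarray]
    library: Library | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for chrom, arr in self.values.items():
            if (arr < 0).any():
                raise ValueError(f"negative track values on {chrom}")

    def chrom_length(self, chrom: str) -> int:
        # length implied by the binning (upper bound; exact size not stored)
        return len(self.values[chrom]) * self.bin_size

    def scaled(self, c: float) -> "SignalTrack":
        return SignalTrack(self.bin_size, {k: v * c for k, v in self.values.items()},
                           self.library, self.normalized)

    def __add__(self, other: "SignalTrack") -> "SignalTrack":
        assert self.bin_size == other.bin_size
        keys = set(self.values) | set(other.values)
        out = {}
        for k in keys:
            a = self.values.get(k)
            b = other.values.get(k)
            if a is None:
                out[k] = b.copy()
            elif b is None:
                out[k] = a.copy()
            else:
                n = max(len(a), len(b))
                s = np.zeros(n)
                s[: len(a)] += a
                s[: len(b)] += b
                out[k] = s
        return SignalTrack(self.bin_size, out, self.library, self.normalized)


def filter_fragments(f: FragmentSet, max_len: int = 2000, dedup: bool = True) -> FragmentSet:
    """Keep fragments shorter than ``max_len``; optionally collapse duplicates.

    A fragment of length exactly ``max_len`` is dropped (strictly-shorter
    rule); duplicate (chrom, start, end) rows collapse to a single copy when
    ``dedup`` is set, emulating a redundancy threshold of 1.
    """
    df = f.df
    keep = (df["end"] - df["start"]) < max_len
    df = df[keep]
    if dedup:
        df = df.drop_duplicates(subset=["chrom", "start", "end"])
    return FragmentSet(df.reset_index(drop=True), f.library)


def spike_scale_factors(frag_sets: list[FragmentSet]) -> SpikeNormFactors:
    """factor(lib) = min spike count over libraries / spike count(lib)."""
    counts = {fs.library: fs.spike_count for fs in frag_sets}
    for lib, c in counts.items():
        if c == 0:
            raise ValueError(f"no spike-in fragments in library {lib.name}")
    m = min(counts.values())
    factors = {lib: m / c for lib, c in counts.items()}
    return SpikeNormFactors(counts, factors)


def coverage_track(
    f: FragmentSet,
    chrom_sizes: dict[str, int],
    bin_size: int = 50,
    factor: float = 1.0,
) -> SignalTrack:
    """Binned target-fragment coverage scaled by a normalization factor.

    A fragment contributes 1 to every bin it overlaps by >= 1 bp (coverage
    semantics, as genome-browser tracks use), then all bins are multiplied by
    ``factor``.  Spike-in fragments are excluded.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    values = {
        chrom: np.zeros(int(np.ceil(size / bin_size)))
        for chrom, size in chrom_sizes.items()
    }
    tgt = f.target
    for chrom, sub in tgt.groupby("chrom"):
        if chrom not in values:
            continue
        nb = len(values[chrom])
        size = chrom_sizes[chrom]
        start = np.clip(sub["start"].to_numpy(), 0, size - 1)
        end = np.clip(sub["end"].to_numpy(), 1, size)
        b0 = start // bin_size
        b1 = (end - 1) // bin_size  # inclusive last bin
        diff = np.zeros(nb + 1)
        np.add.at(diff, b0, 1.0)
        np.add.at(diff, b1 + 1, -1.0)
        values[chrom] = np.cumsum(diff[:-1])
    values = {k: v * factor for k, v in values.items()}
    return SignalTrack(bin_size, values, f.library, normalized=(factor != 1.0))


def _track_integral(arr: np.ndarray, bin_size: int, x0: float, x1: float) -> float:
    """Integral (value x bp) of a piecewise-constant track over [x0, x1)."""
    n = len(arr)
    x0 = min(max(x0, 0.0), n * bin_size)
    x1 = min(max(x1, 0.0), n * bin_size)
    if x1 <= x0:
        return 0.0
    cum = np.concatenate([[0.0], np.cumsum(arr) * bin_size])

    def ival(x: float) -> float:
        k = min(int(x // bin_size), n - 1)
        return cum[k] + arr[k] * (x - k * bin_size)

    return ival(x1) - ival(x0)


def mean_over_interval(track: SignalTrack, chrom: str, start: float, end: float) -> float:
    """Length-weighted mean track value over [start, end).

    Out-of-chromosome stretches contribute zero signal but count in the
    denominator, so windows hanging off a chromosome edge are damped rather
    than extrapolated.
    """
    if end <= start:
        raise ValueError("end must exceed start")
    arr = track.values.get(chrom)
    if arr is None:
        return 0.0
    return _track_integral(arr, track.bin_size, start, end) / (end - start)


def profile_matrix(
    track: SignalTrack, anchors: PeakSet, flank: int, n_bins: int
) -> np.ndarray:
    """(n_anchors x n_bins) matrix of signal around anchor midpoints.

    Row i resamples the track over [mid_i - flank, mid_i + flank) into
    ``n_bins`` equal-width bins (length-weighted means); column means give the
    average binding profile.  Bins outside the chromosome read 0.
    """
    if len(anchors) == 0:
        raise ValueError("empty anchor set")
    if n_bins % 2 != 0:
        raise ValueError("n_bins must be even")
    width = 2.0 * flank / n_bins
    mat = np.zeros((len(anchors), n_bins))
    for i, iv in enumerate(anchors):
        arr = track.values.get(iv.chrom)
        if arr is None:
            continue
        left = iv.midpoint - flank
        for j in range(n_bins):
            x0 = left + j * width
            x1 = left + (j + 1) * width
            mat[i, j] = _track_integral(arr, track.bin_size, x0, x1) / width
    return mat


def write_bedgraph(track: SignalTrack, path: str | Path,
                   chrom_sizes: dict[str, int] | None = None) -> None:
    """Fixed-width-bin bedGraph (chrom, start, end, value); zero bins skipped."""
    bs = track.bin_size
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            arr = track.values[chrom]
            limit = chrom_sizes.get(chrom) if chrom_sizes else len(arr) * bs
            for k, v in enumerate(arr):
                if v == 0:
                    continue
                fh.write(f"{chrom}\t{k * bs}\t{min((k + 1) * bs, limit)}\t{v:g}\n")
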