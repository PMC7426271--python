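"""Expression summarization (FPKM, TMM), a differential-expression test,
per-gene mark signal / MA values, and binding-by-expression enrichment tests.

The differential test is a Welch t-test on log2 CPM after TMM normalization
with a global median variance floor — a deliberately simple, documented
substitute for a full mean-variance-modeled linear-model fit, adequate for
the replicated negative-binomial designs this package simulates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomeAnnotation, PeakSet
from .signal import SignalTrack, mean_over_interval
from .simulate import ExpressionMatrix

__all__ = [
    "fpkm",
    "tmm_factors",
    "de_test_standin",
    "gene_mark_signal",
    "ma_values",
    "ContingencyTable2x2",
    "fisher_exact_2x2",
    "hypergeom_overlap",
    "binding_de_summary",
    "bound_genes",
    "ddct",
]

FC_CUTOFF = 1.5
ADJ_P_CUTOFF = 0.05
EXPRESSED_FPKM = 1.0


def fpkm(mat: ExpressionMatrix) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM[g, s] = count x 1e9 / (sample total x gene length in bp).
    """
    lengths = mat.gene_lengths
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    totals = mat.counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("zero sample total")
    return mat.counts * 1e9 / totals / lengths.to_numpy()[:, None]


def tmm_factors(
    mat: ExpressionMatrix, trim_m: float = 0.3, trim_a: float = 0.05
) -> pd.Series:
    """Trimmed-mean-of-M-values scale factors, normalized to multiply to 1.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean upper quartile.  For every other sample, gene-wise
    log-ratios M and mean abundances A (vs the reference, after library-size
    scaling) are doubly trimmed — the top/bottom ``trim_m`` by M and
    ``trim_a`` by A — and the factor is 2 to the precision-weighted mean of
    the retained M values (delta-method binomial weights).
    """
    counts = mat.counts
    if counts.shape[1] < 2:
        raise ValueError("TMM needs >= 2 samples")
    y = counts.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    uq = np.array([np.percentile(y[:, j] / lib[j], 75) for j in range(y.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(y.shape[1])
    for j in range(y.shape[1]):
        if j == ref:
            continue
        ok = (y[:, j] > 0) & (y[:, ref] > 0)
        if ok.sum() == 0:
            continue
        yj, yr = y[ok, j], y[ok, ref]
        nj, nr = lib[j], lib[ref]
        m = np.log2((yj / nj) / (yr / nr))
        a = 0.5 * np.log2((yj / nj) * (yr / nr))
        w = (nj - yj) / (nj * yj) + (nr - yr) / (nr * yr)

        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if keep.sum() == 0 or np.allclose(m, 0):
            factors[j] = 1.0
            continue
        mk, wk = m[keep], w[keep]
        wk = np.where(wk > 0, wk, np.nan)
        inv = 1.0 / wk
        factors[j] = 2.0 ** (np.nansum(mk * inv) / np.nansum(inv))

    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def log_cpm(mat: ExpressionMatrix, prior: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million on TMM-effective library sizes."""
    f = tmm_factors(mat)
    eff = mat.counts.sum(axis=0) * f
    return np.log2(mat.counts / eff * 1e6 + prior)


def de_test_standin(mat: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene Welch t-test on log2 TMM-normalized CPM, with BH adjustment.

    Genes not expressed (mean FPKM <= 1 in both genotypes) are excluded from
    the multiple-testing universe and labeled ``not_expressed``.  A gene is
    ``up``/``down`` (in knockout relative to control) when the BH-adjusted p
    is < 0.05 and the linear fold-change exceeds 1.5 in that direction;
    otherwise ``unchanged``.  Per-group variances are floored at the global
    median variance so zero-variance genes cannot produce spurious hits.
    """
    wt_cols = mat.condition_columns("wt")
    ko_cols = mat.condition_columns("ko")
    if len(wt_cols) < 2 or len(ko_cols) < 2:
        raise ValueError("need >= 2 replicates per genotype")

    fp = fpkm(mat)
    fpkm_wt = fp[wt_cols].mean(axis=1)
    fpkm_ko = fp[ko_cols].mean(axis=1)
    expressed = np.maximum(fpkm_wt, fpkm_ko) > EXPRESSED_FPKM

    lc = log_cpm(mat)
    x = lc[wt_cols].to_numpy()
    z = lc[ko_cols].to_numpy()
    n1, n2 = x.shape[1], z.shape[1]
    m1, m2 = x.mean(axis=1), z.mean(axis=1)
    v1 = x.var(axis=1, ddof=1)
    v2 = z.var(axis=1, ddof=1)
    floor = np.median(np.concatenate([v1, v2]))
    v1 = np.maximum(v1, floor)
    v2 = np.maximum(v2, floor)

    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m2 - m1) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        pvals = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se2 == 0  # zero spread even after the floor: no evidence
    t[degenerate] = 0.0
    pvals[degenerate] = 1.0

    adj = np.full(len(pvals), np.nan)
    exp_idx = np.flatnonzero(expressed.to_numpy())
    if len(exp_idx):
        adj[exp_idx] = multipletests(pvals[exp_idx], method="fdr_bh")[1]

    log2fc = m2 - m1
    status = np.full(len(pvals), "unchanged", dtype=object)
    sig = (adj < ADJ_P_CUTOFF) & (np.abs(log2fc) > np.log2(FC_CUTOFF))
    status[sig & (log2fc > 0)] = "up"
    status[sig & (log2fc < 0)] = "down"
    status[~expressed.to_numpy()] = "not_expressed"

    return pd.DataFrame(
        {
            "gene": mat.counts.index,
            "fpkm_wt": fpkm_wt.to_numpy(),
            "fpkm_ko": fpkm_ko.to_numpy(),
            "log2fc": log2fc,
            "pvalue": pvals,
            "adj_pvalue": adj,
            "status": status,
        }
    ).set_index("gene")


def gene_mark_signal(
    track: SignalTrack, ann: GenomeAnnotation, window: str = "promoter2kb"
) -> pd.Series:
    """Mean normalized mark signal per gene over promoter +/-2 kb or gene body."""
    if window not in ("promoter2kb", "genebody"):
        raise ValueError("window must be 'promoter2kb' or 'genebody'")
    vals = {}
    for g in ann.genes:
        if window == "promoter2kb":
            lo, hi = g.tss - 2000, g.tss + 2000
        else:
            lo, hi = min(g.tss, g.tes), max(g.tss, g.tes) + 1
        size = ann.chrom_sizes[g.chrom]
        lo = max(0, lo)
        hi = min(size, hi)
        vals[g.gene_id] = mean_over_interval(track, g.chrom, lo, hi)
    return pd.Series(vals, name="mark_signal")


def ma_values(
    sig_wt: pd.Series, sig_ko: pd.Series, c: float = 1.0
) -> pd.DataFrame:
    """M = log2((ko+c)/(wt+c)); A = half the sum of the two log2 terms."""
    wt = sig_wt.reindex(sig_ko.index)
    if wt.isna().any():
        raise ValueError("gene universes differ")
    if (wt < 0).any() or (sig_ko < 0).any():
        raise ValueError("negative signal")
    lko = np.log2(sig_ko + c)
    lwt = np.log2(wt + c)
    return pd.DataFrame({"A": 0.5 * (lko + lwt), "M": lko - lwt})


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a,b / c,d: rows = DE direction (up, down), cols = (bound, unbound)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_exact_2x2(t: ContingencyTable2x2) -> tuple[float, float]:
    """Two-tailed Fisher exact test (probability-mass rule): (odds ratio, p).

    p sums the probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's.  A zero margin gives
    p = 1 by convention.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a + b, c + d, a + c, b + d) == 0:
        return np.nan, 1.0
    n1, n2, k = a + b, c + d, a + c
    lo, hi = max(0, k - n2), min(k, n1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n1 + n2, k, n1)
    p_obs = pmf[a - lo]
    # relative tolerance guards against ties lost to floating-point rounding
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-9)].sum())
    odds = a * d / (b * c) if b * c > 0 else np.inf
    return float(odds), min(p, 1.0)


def hypergeom_overlap(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric overlap p-value P(X >= k).

    N: universe size; K: hits in set B; n: size of set A; k: observed overlap.
    """
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError("inconsistent hypergeometric counts")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bound_genes(
    peaks: PeakSet, ann: GenomeAnnotation, promoter_flank: int = 2000
) -> pd.Series:
    """Boolean per gene: does >= 1 peak overlap the promoter +/-flank window?"""
    trees = peaks.trees()
    flags = {}
    for g in ann.genes:
        t = trees.get(g.chrom)
        lo = max(0, g.tss - promoter_flank)
        hi = min(ann.chrom_sizes[g.chrom], g.tss + promoter_flank)
        flags[g.gene_id] = t is not None and t.overlaps(lo, hi)
    return pd.Series(flags, name="bound")


def binding_de_summary(
    de: pd.DataFrame, bound: pd.Series
) -> tuple[ContingencyTable2x2, dict[str, float], tuple[float, float]]:
    """2x2 table (up/down x bound/unbound), per-row bound fractions, Fisher test."""
    up = de.index[de["status"] == "up"]
    down = de.index[de["status"] == "down"]
    if len(up) + len(down) == 0:
        raise ValueError("no differentially expressed genes")
    missing = set(up).union(down) - set(bound.index)
    if missing:
        raise ValueError(f"bound flag missing for {len(missing)} DE genes")
    a = int(bound.loc[up].sum())
    b = len(up) - a
    c = int(bound.loc[down].sum())
    d = len(down) - c
    table = ContingencyTable2x2(a, b, c, d)
    fractions = {
        "up_bound_fraction": a / len(up) if len(up) else float("nan"),
        "down_bound_fraction": c / len(down) if len(down) else float("nan"),
    }
    return table, fractions, fisher_exact_2x2(table)


def ddct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative qPCR fold change by the 2^-ddCt method."""
    for v in (ct_target_sample, ct_ref_sample, ct_target_control, ct_ref_control):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    delta_delta = (ct_target_sample - ct_ref_sample) - (ct_target_control - ct_ref_control)
    return float(2.0 ** (-delta_delta))
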