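"""End-to-end driver: simulate -> normalize -> call -> consensus -> classify
-> integrate, returning a JSON-serializable report of every summary table.

This is the orchestration layer the analysis drivers, the CLI, and the
acceptance checks all share; each stage below is a thin call into the
corresponding module.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import callers, classify, consensus, expression, signal, simulate
from .intervals import PeakSet, fraction_overlapping, merge_union, write_bed
from .simulate import (
    FACTOR_BINDER,
    FACTOR_PRC2,
    GENOTYPES,
    MARK_ACTIVE,
    MARK_REPRESSIVE,
    Library,
    SimulationConfig,
)

__all__ = ["run_pipeline", "recall_precision"]

HIGH_FDR, LOW_FDR = 0.05, 0.5
HIGH_PCT, LOW_PCT = 1.0, 5.0
BIN_SIZE = 50


def recall_precision(called: PeakSet, truth: PeakSet) -> tuple[float, float]:
    """Fraction of truth peaks recovered and of called peaks matching truth."""
    truth = merge_union(truth)
    if len(truth) == 0 or len(called) == 0:
        return 0.0, 0.0
    recall = fraction_overlapping(truth, called)[2]
    precision = fraction_overlapping(called, truth)[2]
    return recall, precision


def _call_library(frags, ann, track):
    """High/low-confidence calls from both callers for one library."""
    poisson_high = callers.call_windows_poisson(
        frags, ann, callers.CallerConfig(fdr_cutoff=HIGH_FDR))
    poisson_low = callers.call_windows_poisson(
        frags, ann, callers.CallerConfig(fdr_cutoff=LOW_FDR))
    pct_high = callers.call_percentile_blocks(
        track, callers.CallerConfig(percentile_top=HIGH_PCT))
    pct_low = callers.call_percentile_blocks(
        track, callers.CallerConfig(percentile_top=LOW_PCT))
    return poisson_high, poisson_low, pct_high, pct_low


def run_pipeline(cfg: SimulationConfig, outdir: str | Path | None = None) -> dict:
    """Run the whole analysis on one simulated study; return the report dict.

    When ``outdir`` is given, consensus BED files, the DE table, and
    ``report.json`` are written there.
    """
    ann = simulate.generate_annotation(cfg)
    truth = simulate.generate_truth(cfg, ann)
    report: dict = {"config": {"seed": cfg.seed, "depth": cfg.depth,
                               "n_replicates": cfg.n_replicates}}

    # --- fragments, spike normalization, tracks, per-library calls ---------
    consensus_sets: dict[tuple[str, str], PeakSet] = {}
    mean_tracks: dict[tuple[str, str], signal.SignalTrack] = {}
    spike_report = {}
    for factor in (FACTOR_BINDER, FACTOR_PRC2, MARK_REPRESSIVE, MARK_ACTIVE):
        libs = [Library(factor, g, r) for g in GENOTYPES
                for r in range(1, cfg.n_replicates + 1)]
        filtered = {
            lib: signal.filter_fragments(simulate.simulate_fragments(cfg, truth, lib))
            for lib in libs
        }
        norm = signal.spike_scale_factors(list(filtered.values()))
        spike_report[factor] = {lib.name: norm.factors[lib] for lib in libs}

        tracks = {
            lib: signal.coverage_track(filtered[lib], ann.chrom_sizes,
                                       BIN_SIZE, norm.factors[lib])
            for lib in libs
        }
        for genotype in GENOTYPES:
            glibs = [l for l in libs if l.genotype == genotype]
            ph, pl, sh, sl = [], [], [], []
            for lib in glibs:
                a, b, c, d = _call_library(filtered[lib], ann, tracks[lib])
                ph.append(a); pl.append(b); sh.append(c); sl.append(d)
            primary = consensus.ReplicatePeakCalls(ph, pl, method="poisson")
            secondary = consensus.ReplicatePeakCalls(sh, sl, method="percentile")
            # percentile-caller gate applies to the sparse-cleavage assays
            # (factor CUT&RUN-style libraries), not the broad histone ChIP marks
            consensus_sets[(factor, genotype)] = consensus.consensus_pipeline(
                primary, secondary,
                require_secondary=factor in (FACTOR_BINDER, FACTOR_PRC2))
            t = tracks[glibs[0]]
            for lib in glibs[1:]:
                t = t + tracks[lib]
            mean_tracks[(factor, genotype)] = t.scaled(1.0 / len(glibs))

    report["spike_factors"] = spike_report
    report["consensus_peak_counts"] = {
        f"{f}_{g}": len(ps) for (f, g), ps in consensus_sets.items()
    }

    # --- recovery vs truth -------------------------------------------------
    recovery = {}
    for (factor, genotype), ps in consensus_sets.items():
        tp = truth.truth_peaks.get((factor, genotype), PeakSet())
        if len(tp) == 0:
            continue
        rec, prec = recall_precision(ps, tp)
        recovery[f"{factor}_{genotype}"] = {"recall": rec, "precision": prec}
    report["truth_recovery"] = recovery

    # --- classification ----------------------------------------------------
    binder = consensus_sets[(FACTOR_BINDER, "wt")]
    locale = classify.annotate_locale(binder, ann)
    report["locale_fractions"] = {
        col: float(locale[col].mean())
        for col in ("tss_within_10bp", "promoter_2kb", "genic", "distal", "cpg")
    }

    k27_wt = consensus_sets[(MARK_REPRESSIVE, "wt")]
    k4_wt = consensus_sets[(MARK_ACTIVE, "wt")]
    k4_ko = consensus_sets[(MARK_ACTIVE, "ko")]
    bivalent = classify.bivalent_regions(k27_wt, k4_wt)
    report["bivalent"] = {"count": len(bivalent)}
    if len(bivalent):
        cnt, tot, frac = fraction_overlapping(bivalent, binder)
        report["bivalent"].update(
            {"bound_by_factor": cnt, "bound_fraction": frac})

    marks = ann.enhancer_marks or {}
    active_enh, poised_enh, both = classify.enhancer_classes(
        marks.get("h3k4me1", PeakSet()), marks.get("h3k27ac", PeakSet()), k27_wt)
    report["enhancers"] = {"active": len(active_enh), "poised": len(poised_enh),
                           "double_classified": both}

    categories = classify.categorize_peaks(
        binder, k4_wt, k4_ko,
        (mean_tracks[(MARK_ACTIVE, "wt")], mean_tracks[(MARK_ACTIVE, "ko")]))
    report["category_counts"] = {
        str(c): int((categories["category"] == c).sum()) for c in range(1, 6)
    }

    # --- expression integration --------------------------------------------
    expr = simulate.simulate_expression(cfg, truth, ann)
    de = expression.de_test_standin(expr)
    status_counts = de["status"].value_counts().to_dict()
    report["de_counts"] = {k: int(v) for k, v in status_counts.items()}

    bound = expression.bound_genes(binder, ann)
    table, fractions, (odds, pval) = expression.binding_de_summary(de, bound)
    report["binding_de"] = {
        "table": {"up_bound": table.a, "up_unbound": table.b,
                  "down_bound": table.c, "down_unbound": table.d},
        **fractions,
        "fisher_odds_ratio": None if np.isnan(odds) else odds,
        "fisher_p": pval,
    }

    sig_wt = expression.gene_mark_signal(mean_tracks[(MARK_REPRESSIVE, "wt")], ann)
    sig_ko = expression.gene_mark_signal(mean_tracks[(MARK_REPRESSIVE, "ko")], ann)
    ma = expression.ma_values(sig_wt, sig_ko)
    down = [g for g, s in truth.gene_classes.items() if s == "down"]
    up = [g for g, s in truth.gene_classes.items() if s == "up"]
    bound_ids = [g for g, f in truth.bound_flags.items() if f]
    report["mark_ma"] = {
        "mean_M_down_genes": float(ma.loc[down, "M"].mean()) if down else None,
        "mean_M_up_genes": float(ma.loc[up, "M"].mean()) if up else None,
        "mean_M_all_genes": float(ma["M"].mean()),
    }
    wt_bound = float(sig_wt.loc[bound_ids].mean())
    ko_bound = float(sig_ko.loc[bound_ids].mean())
    report["k27me3_ko_wt_ratio_bound_genes"] = (
        ko_bound / wt_bound if wt_bound > 0 else None)

    # hypergeometric overlap of binder and PRC2 consensus at promoters
    prc2_bound = expression.bound_genes(consensus_sets[(FACTOR_PRC2, "wt")], ann)
    N = len(bound)
    K = int(prc2_bound.sum())
    n = int(bound.sum())
    k = int((bound & prc2_bound).sum())
    report["binder_prc2_promoter_overlap"] = {
        "universe": N, "prc2_genes": K, "binder_genes": n, "overlap": k,
        "hypergeom_p": expression.hypergeom_overlap(N, K, n, k),
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for (factor, genotype), ps in consensus_sets.items():
            write_bed(ps, outdir / f"consensus_{factor}_{genotype}.bed")
        write_bed(bivalent, outdir / "bivalent_regions.bed")
        de.to_csv(outdir / "de_table.tsv", sep="\t")
        locale.to_csv(outdir / "locale_table.tsv", sep="\t", index=False)
        categories.to_csv(outdir / "category_table.tsv", sep="\t", index=False)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
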