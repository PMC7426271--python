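"""Classify consensus peaks: locale, CpG, bivalency, enhancers, categories.

Reads consensus BEDs from 04_consensus_peaks.py and writes per-peak locale
and category tables plus bivalent/enhancer BEDs under results/classification/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import STUDY, outdir

from chromintegrate import classify, signal, simulate
from chromintegrate.intervals import PeakSet, fraction_overlapping, read_bed, write_bed
from chromintegrate.simulate import MARK_ACTIVE, Library


def mean_track(ann, truth, factor, genotype):
    # scale factors must be computed across BOTH genotypes' libraries so the
    # knockout's chromatin-yield shift is corrected before genotypes compare
    all_libs = [Library(factor, g, r) for g in ("wt", "ko")
                for r in range(1, STUDY.n_replicates + 1)]
    filtered = {
        lib: signal.filter_fragments(simulate.simulate_fragments(STUDY, truth, lib))
        for lib in all_libs
    }
    norm = signal.spike_scale_factors(list(filtered.values()))
    track = None
    n = 0
    for lib, fs in filtered.items():
        if lib.genotype != genotype:
            continue
        t = signal.coverage_track(fs, ann.chrom_sizes, 50, norm.factors[lib])
        track = t if track is None else track + t
        n += 1
    return track.scaled(1.0 / n)


def main() -> None:
    cons = outdir("consensus")
    out = outdir("classification")
    ann = simulate.generate_annotation(STUDY)
    truth = simulate.generate_truth(STUDY, ann)

    binder = read_bed(cons / "consensus_ybx1_wt.bed")
    k27_wt = read_bed(cons / "consensus_h3k27me3_wt.bed")
    k4_wt = read_bed(cons / "consensus_h3k4me3_wt.bed")
    k4_ko = read_bed(cons / "consensus_h3k4me3_ko.bed")

    locale = classify.annotate_locale(binder, ann)
    locale.to_csv(out / "locale_table.tsv", sep="\t", index=False)
    fr = {c: locale[c].mean()
          for c in ("tss_within_10bp", "promoter_2kb", "genic", "distal", "cpg")}
    print("factor peak locale fractions:",
          {k: round(v, 3) for k, v in fr.items()})

    bivalent = classify.bivalent_regions(k27_wt, k4_wt)
    write_bed(bivalent, out / "bivalent_regions.bed")
    if len(bivalent):
        cnt, tot, frac = fraction_overlapping(bivalent, binder)
        print(f"{tot} bivalent regions; {cnt} ({100 * frac:.1f}%) bound by the factor")

    marks = ann.enhancer_marks or {}
    active, poised, both = classify.enhancer_classes(
        marks.get("h3k4me1", PeakSet()), marks.get("h3k27ac", PeakSet()), k27_wt)
    write_bed(active, out / "active_enhancers.bed")
    write_bed(poised, out / "poised_enhancers.bed")
    print(f"{len(active)} active / {len(poised)} poised enhancers "
          f"({both} in both classes)")

    k4_tracks = (mean_track(ann, truth, MARK_ACTIVE, "wt"),
                 mean_track(ann, truth, MARK_ACTIVE, "ko"))
    categories = classify.categorize_peaks(binder, k4_wt, k4_ko, k4_tracks)
    categories.to_csv(out / "category_table.tsv", sep="\t", index=False)
    counts = categories.category.value_counts().sort_index().to_dict()
    print("five-category taxonomy of factor peaks:", counts)


if __name__ == "__main__":
    main()
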