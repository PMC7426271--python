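"""Call peaks per library with both callers at both confidence levels.

Poisson window/island caller at FDR 0.05 (high) and 0.5 (low); percentile
block caller at top 1% (high) and top 5% (low).  BED outputs under
results/peaks/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import STUDY, outdir

from chromintegrate import callers, signal, simulate
from chromintegrate.intervals import write_bed
from chromintegrate.simulate import GENOTYPES, Library


def main() -> None:
    out = outdir("peaks")
    ann = simulate.generate_annotation(STUDY)
    truth = simulate.generate_truth(STUDY, ann)

    for factor in STUDY.factors:
        libs = [Library(factor, g, r) for g in GENOTYPES
                for r in range(1, STUDY.n_replicates + 1)]
        filtered = [
            signal.filter_fragments(simulate.simulate_fragments(STUDY, truth, lib))
            for lib in libs
        ]
        norm = signal.spike_scale_factors(filtered)
        counts = []
        for fs in filtered:
            lib = fs.library
            track = signal.coverage_track(fs, ann.chrom_sizes, 50, norm.factors[lib])
            calls = {
                "poisson_high": callers.call_windows_poisson(
                    fs, ann, callers.CallerConfig(fdr_cutoff=0.05)),
                "poisson_low": callers.call_windows_poisson(
                    fs, ann, callers.CallerConfig(fdr_cutoff=0.5)),
                "percentile_high": callers.call_percentile_blocks(
                    track, callers.CallerConfig(percentile_top=1.0)),
                "percentile_low": callers.call_percentile_blocks(
                    track, callers.CallerConfig(percentile_top=5.0)),
            }
            for name, ps in calls.items():
                write_bed(ps, out / f"{lib.name}_{name}.bed")
            counts.append((lib.name, {k: len(v) for k, v in calls.items()}))
        for name, c in counts:
            print(f"  {name}: {c}")
    print(f"per-library peak calls -> {out}")


if __name__ == "__main__":
    main()
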