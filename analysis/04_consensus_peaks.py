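"""Cross-replicate reproducible peaks and the dual-caller consensus.

Reads the per-library BED calls written by 03_call_peaks.py, applies the
reproducibility rule (high-confidence peaks supported by low-confidence
calls in the other replicate), gates the sparse-assay factors on the
percentile caller's reproducible set, and reports recovery against truth.
Consensus BEDs under results/consensus/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import STUDY, outdir

from chromintegrate import consensus, simulate
from chromintegrate.intervals import read_bed, write_bed
from chromintegrate.pipeline import recall_precision
from chromintegrate.simulate import FACTOR_BINDER, FACTOR_PRC2, GENOTYPES, Library


def main() -> None:
    peaks_dir = outdir("peaks")
    out = outdir("consensus")
    ann = simulate.generate_annotation(STUDY)
    truth = simulate.generate_truth(STUDY, ann)

    for factor in STUDY.factors:
        for genotype in GENOTYPES:
            libs = [Library(factor, genotype, r)
                    for r in range(1, STUDY.n_replicates + 1)]
            primary = consensus.ReplicatePeakCalls(
                [read_bed(peaks_dir / f"{l.name}_poisson_high.bed") for l in libs],
                [read_bed(peaks_dir / f"{l.name}_poisson_low.bed") for l in libs],
                method="poisson",
            )
            secondary = consensus.ReplicatePeakCalls(
                [read_bed(peaks_dir / f"{l.name}_percentile_high.bed") for l in libs],
                [read_bed(peaks_dir / f"{l.name}_percentile_low.bed") for l in libs],
                method="percentile",
            )
            result = consensus.consensus_pipeline(
                primary, secondary,
                require_secondary=factor in (FACTOR_BINDER, FACTOR_PRC2))
            write_bed(result, out / f"consensus_{factor}_{genotype}.bed")
            tp = truth.truth_peaks.get((factor, genotype))
            if tp and len(tp):
                rec, prec = recall_precision(result, tp)
                print(f"  {factor} {genotype}: {len(result)} consensus peaks, "
                      f"recall {rec:.3f}, precision {prec:.3f}")
            else:
                print(f"  {factor} {genotype}: {len(result)} consensus peaks "
                      "(no truth peaks)")
    print(f"consensus peak sets -> {out}")


if __name__ == "__main__":
    main()
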