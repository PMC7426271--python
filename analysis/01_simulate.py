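"""Simulate the study: toy genome, truth occupancy, libraries, counts.

Writes the genome annotation, truth peak BEDs, per-library fragment tables,
and the RNA count matrix under results/simulation/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import STUDY, outdir

from chromintegrate import simulate
from chromintegrate.intervals import write_bed, write_chrom_sizes, write_genes_tsv


def main() -> None:
    out = outdir("simulation")
    ann = simulate.generate_annotation(STUDY)
    truth = simulate.generate_truth(STUDY, ann)

    write_chrom_sizes(ann.chrom_sizes, out / "chrom.sizes")
    write_genes_tsv(ann, out / "genes.tsv")
    write_bed(ann.cpg_islands, out / "cpg_islands.bed")
    for (factor, genotype), ps in truth.truth_peaks.items():
        write_bed(ps, out / f"truth_{factor}_{genotype}.bed")

    n_frag = 0
    for lib in STUDY.libraries():
        fs = simulate.simulate_fragments(STUDY, truth, lib)
        fs.to_tsv(out / f"fragments_{lib.name}.tsv")
        n_frag += len(fs)

    expr = simulate.simulate_expression(STUDY, truth, ann)
    expr.counts.to_csv(out / "counts.tsv", sep="\t", index_label="gene")

    n_bound = sum(truth.bound_flags.values())
    classes = {c: sum(v == c for v in truth.gene_classes.values())
               for c in ("up", "down", "unchanged")}
    print(f"simulated {len(ann.genes)} genes on {len(ann.chrom_sizes)} chromosomes")
    print(f"{n_bound} factor-bound genes; truth gene classes: {classes}")
    print(f"{len(STUDY.libraries())} libraries x {STUDY.depth} fragments "
          f"({n_frag} total) -> {out}")


if __name__ == "__main__":
    main()
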