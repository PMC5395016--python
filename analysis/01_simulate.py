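#!/usr/bin/env python
"""Generate the synthetic study the later steps analyse.

Writes the full dataset (true genome, erroneous assembly, gene models,
short/long reads, optical map, ground truth) under scratch/study/ and a
small truth summary under results/. The study is desk-scale: a 200 kb
single-chromosome genome with the default error and allele counts
scaled down, read libraries mirroring the two re-sequencing datasets
(single-end 36/51 bp and paired-end 76 bp at ~150 bp inserts), long
reads of ~377 bp mean length, and a noisy SwaI optical map.
"""

from pathlib import Path

import pandas as pd

from refgrade import genemodels, sequences
from refgrade.config import SimConfig
from refgrade.optical import write_fragment_lists
from refgrade.readprep import write_fastq
from refgrade.simulate import (
    simulate_long_reads,
    simulate_optical_map,
    simulate_short_reads_paired,
    simulate_short_reads_single,
    simulate_study,
)

OUT = Path("scratch/study")
RESULTS = Path("results")


def config() -> SimConfig:
    return SimConfig(
        seed=42, genome_length=200_000, n_chromosomes=1, n_genes=12,
        n_substitution_errors=20, n_insertion_errors=6, n_deletion_errors=6,
        n_between_sites=6, n_within_sites=6, physical_gap_size=15_000,
    )


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    cfg = config()
    sim = simulate_study(cfg)

    sequences.write_fasta(OUT / "true_genome.fasta", sim.true_genome.chroms.items())
    sequences.write_fasta(OUT / "assembly.fasta", sim.assembly.items())
    genemodels.write_gff3(OUT / "genes.gff3", sim.true_genome.genes)
    sim.truth.write_tsv(OUT / "truth.tsv")
    with open(OUT / "gaps.bed", "w") as fh:
        for g in sim.truth.gaps:
            fh.write(f"{g.chrom}\t{g.start}\t{g.start + g.n_length}\tphysical_gap\n")

    ind1, ind2 = sim.individuals
    n1 = write_fastq(OUT / "ds1.fastq", simulate_short_reads_single(ind1, cfg))
    pairs = simulate_short_reads_paired(ind2, cfg)
    write_fastq(OUT / "ds2_1.fastq", (p[0] for p in pairs))
    write_fastq(OUT / "ds2_2.fastq", (p[1] for p in pairs))
    nl = write_fastq(OUT / "long_reads.fastq", simulate_long_reads(ind1, cfg))
    write_fragment_lists(OUT / "optical_map.tsv", simulate_optical_map(sim.true_genome, cfg))
    cfg.to_yaml(OUT / "config.yaml")

    summary = (
        pd.read_csv(OUT / "truth.tsv", sep="\t")
        .groupby(["category", "type"]).size().rename("count").reset_index()
    )
    summary.to_csv(RESULTS / "01_truth_summary.tsv", sep="\t", index=False)
    print(f"study written to {OUT}: {n1} single-end reads, "
          f"{2 * len(pairs)} paired-end mates, {nl} long reads")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
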