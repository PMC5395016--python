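#!/usr/bin/env python
"""Detect large reference indels from split long-read alignments.

Scans the long-read library against the assembly, keeps read pairs of
unambiguous local hits on one chromosome/strand within 1 Mbp covering
>90% of the read, clusters candidates by breakpoint and size, and
writes corroborated events (>=2 supporting reads) as BED.
"""

from pathlib import Path

import pandas as pd

from refgrade.mapping import GenomeIndex
from refgrade.readprep import read_fastq
from refgrade.sequences import read_fasta
from refgrade.splitread import corroborate_events, scan_long_reads
from refgrade.vcfio import write_bed

IN = Path("scratch/study")
RESULTS = Path("results")


def main() -> None:
    ref = read_fasta(IN / "assembly.fasta")
    index = GenomeIndex(ref)
    events = scan_long_reads(read_fastq(IN / "long_reads.fastq"), index)
    kept = corroborate_events(events, min_support=2)
    write_bed(RESULTS / "05_large_indels.bed", [
        (e.chrom, e.breakpoint,
         e.breakpoint + (e.size if e.event_type == "deletion" else 1),
         f"{e.event_type}:{e.size}:support={e.support}")
        for e in kept
    ])
    truth = pd.read_csv(IN / "truth.tsv", sep="\t")
    large = truth[truth.type.str.startswith("large")]
    print(f"{len(events)} candidate split reads, {len(kept)} corroborated events")
    for e in kept:
        print(f"  {e.chrom}:{e.breakpoint} {e.event_type} {e.size} bp "
              f"(support {e.support})")
    print("injected truth:")
    print(large[["chrom", "pos", "type", "size"]].to_string(index=False))


if __name__ == "__main__":
    main()
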