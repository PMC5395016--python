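#!/usr/bin/env python
"""Map the preprocessed reads and profile the coverage.

Reads are placed with the built-in unique seed-and-extend mapper
(multiple-placement reads are discarded downstream, confidence >=20
retained), written as SAM under scratch/study/, and the per-chromosome
fraction of positions covered at >=1, >=5 and >=10 reads — the
effective-site profile — is written under results/.
"""

from pathlib import Path

import pandas as pd

from refgrade.mapping import (
    GenomeIndex,
    MappingStats,
    estimate_insert_bounds,
    flag_proper_pairs,
    map_reads,
    write_sam,
)
from refgrade.pileup import build_pileup, coverage_profile, merge_pileups
from refgrade.readprep import read_fastq
from refgrade.sequences import read_fasta

IN = Path("scratch/study")
RESULTS = Path("results")


def main() -> None:
    ref = read_fasta(IN / "assembly.fasta")
    index = GenomeIndex(ref)
    stats = {"ds1": MappingStats(), "ds2": MappingStats()}

    rec1 = map_reads(read_fastq(IN / "prepped" / "ds1.fastq"), index, stats["ds1"])
    mates1 = map_reads(read_fastq(IN / "prepped" / "ds2_1.fastq", "mate1"),
                       index, stats["ds2"])
    mates2 = map_reads(read_fastq(IN / "prepped" / "ds2_2.fastq", "mate2"),
                       index, stats["ds2"])
    unpaired = map_reads(read_fastq(IN / "prepped" / "ds2_unpaired.fastq"),
                         index, stats["ds2"])
    pairs = list(zip(mates1, mates2))
    bounds = estimate_insert_bounds(pairs)
    stats["ds2"].proper = sum(flag_proper_pairs(a, b, bounds) for a, b in pairs)
    rec2 = mates1 + mates2 + unpaired
    write_sam(IN / "ds1.sam", rec1, ref)
    write_sam(IN / "ds2.sam", rec2, ref)

    p1 = build_pileup(rec1, ref)
    p2 = build_pileup(rec2, ref)
    pooled = merge_pileups(p1, p2)

    frames = []
    for name, p in (("ds1", p1), ("ds2", p2), ("pooled", pooled)):
        df = coverage_profile(p)
        df.insert(0, "dataset", name)
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(RESULTS / "03_coverage.tsv", sep="\t", index=False)

    mstats = pd.DataFrame([{"library": k, **v.as_row()} for k, v in stats.items()])
    mstats.to_csv(RESULTS / "03_mapping.tsv", sep="\t", index=False)
    print(mstats.to_string(index=False))
    print(table[table.chrom == "total"].to_string(index=False))


if __name__ == "__main__":
    main()
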