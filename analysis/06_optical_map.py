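#!/usr/bin/env python
"""Validate the assembly against the optical map.

Digests the assembly in silico with SwaI, aligns the fragment pattern
against the (noisy) optical map of the true genome by dynamic
programming, classifies map-sequence discordances into the five
classes, and estimates the physical gap size from the unmatched
optical fragments at the annotated gap.
"""

from pathlib import Path

import pandas as pd

from refgrade.optical import (
    AlignParams, align_maps, classify_discordances, digest_in_silico,
    estimate_gap_size, read_fragment_lists,
)
from refgrade.sequences import read_fasta
from refgrade.vcfio import write_bed

IN = Path("scratch/study")
RESULTS = Path("results")


def main() -> None:
    ref = read_fasta(IN / "assembly.fasta")
    maps = {m.map_id: m for m in read_fragment_lists(IN / "optical_map.tsv")}
    gaps: dict[str, list[tuple[int, int]]] = {}
    for line in open(IN / "gaps.bed"):
        chrom, s, e, *_ = line.split("\t")
        gaps.setdefault(chrom, []).append((int(s), int(e)))

    params = AlignParams()
    rows, gap_rows = [], []
    for chrom, seq in ref.items():
        sil = digest_in_silico(seq, map_id=chrom)
        aln = align_maps(sil, maps[chrom], params)
        for d in classify_discordances(aln, gaps.get(chrom, ()), params):
            rows.append((chrom, d.location[0], max(d.location[1], d.location[0] + 1),
                         f"class{d.cls}:{d.magnitude}"))
        for gs, ge in gaps.get(chrom, ()):
            size, supported = estimate_gap_size(aln, (gs, ge), params)
            gap_rows.append({"chrom": chrom, "gap_start": gs,
                             "estimated_bp": size, "map_supported": supported})
    write_bed(RESULTS / "06_discordances.bed", rows)
    gap_df = pd.DataFrame(gap_rows)
    gap_df.to_csv(RESULTS / "06_gap_estimates.tsv", sep="\t", index=False)
    print(f"{len(rows)} discordances")
    for r in rows:
        print(" ", *r)
    print(gap_df.to_string(index=False))


if __name__ == "__main__":
    main()
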