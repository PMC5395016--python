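"""VCF emission for error corrections and allelic sites (via pysam).

Coordinates are 1-based in the emitted file; indel records use the
anchored-base convention (REF/ALT both start at the anchor base).
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pysam

from .classify import ErrorRecord, SiteCall
from .sequences import decode


def _header(assembly: dict[str, np.ndarray]) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for chrom, seq in assembly.items():
        h.contigs.add(chrom, length=len(seq))
    h.info.add("CLASS", 1, "String", "Combined genotype class")
    h.info.add("CAT", 3, "String", "Per-dataset R/N/A/L category (ds1,ds2,pooled)")
    h.info.add("CARRIER", 1, "String", "Carrier individual for within-alleles")
    h.info.add("EFFECT", 1, "String", "Gene-model effect of the substitution")
    h.info.add("ETYPE", 1, "String", "Correction type (snp/insertion/deletion)")
    return h


def write_vcf(
    path,
    assembly: dict[str, np.ndarray],
    error_records: Sequence[ErrorRecord] = (),
    calls: Sequence[SiteCall] = (),
    effects: Optional[dict[tuple, str]] = None,
) -> int:
    """Write corrections and/or classified allelic sites; returns count."""
    hdr = _header(assembly)
    n = 0
    rows = []
    for r in error_records:
        chrom_seq = assembly[r.chrom]
        anchor = decode(chrom_seq[r.position : r.position + 1])
        if r.type == "snp":
            ref, alt = r.ref_allele, r.corrected_allele
        elif r.type == "insertion":
            ref, alt = anchor, anchor + r.corrected_allele
        else:
            ref, alt = anchor + r.ref_allele, anchor
        rows.append((r.chrom, r.position, ref, alt,
                     {"CLASS": "sequencing_error", "ETYPE": r.type}))
    for c in calls:
        alt = c.alleles.get("pooled")
        if alt is None or len(alt) != 1:
            continue
        info = {
            "CLASS": c.combined,
            "CAT": tuple(c.categories.values()),
        }
        if c.carrier:
            info["CARRIER"] = c.carrier
        if effects and (c.chrom, c.position) in effects:
            info["EFFECT"] = effects[(c.chrom, c.position)]
        rows.append((c.chrom, c.position, c.ref_allele, alt, info))
    rows.sort(key=lambda r: (r[0], r[1]))
    with pysam.VariantFile(str(path), "w", header=hdr) as out:
        for chrom, pos, ref, alt, info in rows:
            rec = out.new_record(contig=chrom, start=pos, alleles=(ref, alt))
            for k, v in info.items():
                rec.info[k] = v
            out.write(rec)
            n += 1
    return n


def write_bed(path, intervals: Iterable[tuple[str, int, int, str]]) -> int:
    """Plain BED with a name field."""
    n = 0
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")
            n += 1
    return n
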