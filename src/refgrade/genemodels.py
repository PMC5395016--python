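"""Gene models: container plus GFF3 round trip.

A ``GeneModel`` is a single-transcript protein-coding locus described by
genomic intervals (0-based half-open internally; GFF3 emission is
1-based inclusive). UTR/CDS/intron structure is explicit so that SNP
effect annotation can place a site by interval containment.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path

Interval = tuple[int, int]


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str                       # '+' or '-'
    exons: list[Interval]             # sorted by genomic coordinate
    cds: list[Interval]               # subset of exon space, sorted
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def validate(self) -> None:
        for name, ivs in (("exons", self.exons), ("cds", self.cds)):
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"{self.gene_id}: overlapping {name}")
            for s, e in ivs:
                if e <= s:
                    raise ValueError(f"{self.gene_id}: empty interval in {name}")
        if self.cds and self.cds_length() % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")

    def cds_phases(self) -> list[int]:
        """GFF3 phase per CDS interval, in genomic order."""
        order = self.cds if self.strand == "+" else self.cds[::-1]
        phases, consumed = [], 0
        for s, e in order:
            phases.append((3 - consumed % 3) % 3)
            consumed += e - s
        return phases if self.strand == "+" else phases[::-1]


def write_gff3(path, genes: list[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            g.validate()
            def row(ftype, s, e, phase=".", parent=None, fid=None):
                attrs = []
                if fid:
                    attrs.append(f"ID={fid}")
                if parent:
                    attrs.append(f"Parent={parent}")
                fh.write(
                    "\t".join(
                        [g.chrom, "refgrade", ftype, str(s + 1), str(e),
                         ".", g.strand, str(phase), ";".join(attrs)]
                    ) + "\n"
                )

            mrna_id = g.gene_id + ".1"
            row("gene", g.start, g.end, fid=g.gene_id)
            row("mRNA", g.start, g.end, parent=g.gene_id, fid=mrna_id)
            for s, e in g.exons:
                row("exon", s, e, parent=mrna_id)
            for (s, e), ph in zip(g.cds, g.cds_phases()):
                row("CDS", s, e, phase=ph, parent=mrna_id)
            for s, e in g.utr5:
                row("five_prime_UTR", s, e, parent=mrna_id)
            for s, e in g.utr3:
                row("three_prime_UTR", s, e, parent=mrna_id)


def read_gff3(path) -> list[GeneModel]:
    """Parse a GFF3 file back into GeneModel objects (via gffutils)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for gene in db.features_of_type("gene"):
        for mrna in db.children(gene, featuretype="mRNA"):
            def ivs(ftype):
                return sorted(
                    (f.start - 1, f.end)
                    for f in db.children(mrna, featuretype=ftype)
                )

            genes.append(
                GeneModel(
                    gene_id=gene.id,
                    chrom=gene.seqid,
                    strand=gene.strand,
                    exons=ivs("exon"),
                    cds=ivs("CDS"),
                    utr5=ivs("five_prime_UTR"),
                    utr3=ivs("three_prime_UTR"),
                )
            )
    return genes
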