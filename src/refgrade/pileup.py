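"""Gapped pileups over filtered unique alignments.

Base counts are accumulated per reference column (A/C/G/T/N rows);
1-4 bp insertion/deletion alleles are recorded at the reference base
immediately left of the event and left-normalized against the
reference, so identical events reported at different alignment offsets
collapse onto one anchor. Deletion-spanned columns receive no depth
from the deleted read — the event is counted at its anchor only.

Indel allele frequencies are later computed over *event-spanning*
reads (reads whose alignment covers the event plus a short flank):
reads ending inside or right next to an indel cannot report it and
would otherwise dilute the allele frequency at short read lengths.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .mapping import AlignmentRecord
from .sequences import decode, encode
from .simulate import left_align_indel

INDEL_FLANK = 3   # bp of reference a read must cover beyond an event to vote on it


@dataclass
class PileupColumn:
    chrom: str
    position: int
    ref_base: str
    depth: int
    base_counts: dict[str, int]
    indel_alleles: dict[tuple, int] = field(default_factory=dict)


class Pileup:
    """Per-chromosome base-count matrices plus anchored indel tallies."""

    def __init__(self, reference: dict[str, np.ndarray]):
        self.reference = reference
        self.counts: dict[str, np.ndarray] = {
            c: np.zeros((5, len(s)), dtype=np.uint32) for c, s in reference.items()
        }
        # anchored indels: (chrom, anchor) -> Counter[(kind, length, seq)]
        self.indels: dict[tuple[str, int], Counter] = {}
        self._starts: dict[str, list[int]] = {c: [] for c in reference}
        self._ends: dict[str, list[int]] = {c: [] for c in reference}
        self.aligned_bases = 0
        self.n_records = 0

    # -- construction -------------------------------------------------

    def add_record(self, rec: AlignmentRecord) -> None:
        ref = self.reference[rec.chrom]
        counts = self.counts[rec.chrom]
        codes = encode(rec.seq)
        pos, ridx = rec.start, 0
        for op, ln in rec.cigar:
            if op == "M":
                counts[codes[ridx : ridx + ln], np.arange(pos, pos + ln)] += 1
                self.aligned_bases += ln
                pos += ln
                ridx += ln
            elif op == "I":
                if pos > 0 and 1 <= ln <= 4:
                    anchor, alleles = left_align_indel(ref, pos - 1, "ins",
                                                       codes[ridx : ridx + ln])
                    self._tally(rec.chrom, anchor, ("ins", ln, decode(alleles)))
                ridx += ln
            elif op == "D":
                if pos > 0 and 1 <= ln <= 4:
                    anchor, alleles = left_align_indel(ref, pos - 1, "del",
                                                       ref[pos : pos + ln])
                    self._tally(rec.chrom, anchor, ("del", ln, decode(alleles)))
                pos += ln
            else:  # pragma: no cover
                raise ValueError(f"unexpected cigar op {op}")
        self._starts[rec.chrom].append(rec.start)
        self._ends[rec.chrom].append(pos)
        self.n_records += 1

    def _tally(self, chrom: str, anchor: int, allele: tuple) -> None:
        self.indels.setdefault((chrom, anchor), Counter())[allele] += 1

    def extend(self, records: Iterable[AlignmentRecord]) -> "Pileup":
        for rec in records:
            self.add_record(rec)
        return self

    def finalize(self) -> None:
        for c in self._starts:
            self._starts[c] = np.asarray(self._starts[c], dtype=np.int64)
            self._ends[c] = np.asarray(self._ends[c], dtype=np.int64)

    # -- queries ------------------------------------------------------

    def depth(self, chrom: str) -> np.ndarray:
        return self.counts[chrom].sum(axis=0)

    def spanning_reads(self, chrom: str, start: int, end: int) -> int:
        """Reads whose reference footprint covers [start, end) entirely."""
        s = np.asarray(self._starts[chrom])
        e = np.asarray(self._ends[chrom])
        return int(((s <= start) & (e >= end)).sum())

    def indel_denominator(self, chrom: str, anchor: int, length: int, kind: str) -> int:
        # deletions consume `length` bp of reference; insertions demand the
        # same reference overhang so boundary reads cannot vote either way
        return self.spanning_reads(
            chrom, anchor - INDEL_FLANK + 1, anchor + 1 + length + INDEL_FLANK
        )

    def column(self, chrom: str, position: int) -> PileupColumn:
        col = self.counts[chrom][:, position]
        ref_base = decode(self.reference[chrom][position : position + 1])
        bases = dict(zip("ACGTN", map(int, col)))
        indels = dict(self.indels.get((chrom, position), {}))
        return PileupColumn(chrom, position, ref_base, int(col.sum()), bases, indels)


def build_pileup(
    records: Iterable[AlignmentRecord], reference: dict[str, np.ndarray]
) -> Pileup:
    p = Pileup(reference).extend(
        r for r in records if r.placement == "unique" and r.mapq >= 20
    )
    p.finalize()
    return p


def merge_pileups(a: Pileup, b: Pileup) -> Pileup:
    """Pooled pileup: union of both datasets' retained alignments, re-piled."""
    if a.reference is not b.reference and list(a.reference) != list(b.reference):
        raise ValueError("pileups built on different references")
    out = Pileup(a.reference)
    for c in out.counts:
        out.counts[c] = a.counts[c] + b.counts[c]
    for key, counter in a.indels.items():
        out.indels[key] = counter.copy()
    for key, counter in b.indels.items():
        out.indels.setdefault(key, Counter()).update(counter)
    for c in out._starts:
        out._starts[c] = np.concatenate([np.asarray(a._starts[c]), np.asarray(b._starts[c])])
        out._ends[c] = np.concatenate([np.asarray(a._ends[c]), np.asarray(b._ends[c])])
    out.aligned_bases = a.aligned_bases + b.aligned_bases
    out.n_records = a.n_records + b.n_records
    return out


def coverage_profile(pileup: Pileup, thresholds: tuple[int, ...] = (1, 5, 10)):
    """Fraction of assembly positions with depth >= t, per chromosome and total."""
    import pandas as pd

    rows = []
    totals = {t: 0 for t in thresholds}
    total_len = 0
    for chrom in pileup.counts:
        depth = pileup.depth(chrom)
        L = len(depth)
        row = {"chrom": chrom, "length": L}
        for t in thresholds:
            n = int((depth >= t).sum())
            row[f"ge{t}"] = n
            row[f"ge{t}_frac"] = n / L if L else 0.0
            totals[t] += n
        rows.append(row)
        total_len += L
    total_row = {"chrom": "total", "length": total_len}
    for t in thresholds:
        total_row[f"ge{t}"] = totals[t]
        total_row[f"ge{t}_frac"] = totals[t] / total_len if total_len else 0.0
    rows.append(total_row)
    return pd.DataFrame(rows)
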