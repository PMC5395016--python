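"""Desk-scale read mapping and alignment filtering.

A seed-and-extend mapper sufficient for synthetic genomes: exact k-mer
seeds anchor candidate placements, edlib verifies them with banded
edit-distance alignment, and a read is ``unique`` only when its best
placement strictly beats every other candidate. Exact repeat copies tie
and become ``multiple``. Mapping confidence is 60 for unique placements
and 0 for ties; only the >=20 cutoff downstream is meaningful.

External alignments can be ingested from SAM and produce identical
pileups for identical placements.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import edlib
import numpy as np

from .readprep import Read
from .sequences import decode, encode, revcomp

UNIQUE_MAPQ = 60
TIED_MAPQ = 0
SEED_K = 16
MAX_KMER_HITS = 64
PAD = 8

_CIG_RE = re.compile(r"(\d+)([=XIDM])")


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    """edlib/SAM cigar -> [(op, length)] with =/X collapsed into M."""
    ops: list[tuple[str, int]] = []
    for ln, op in _CIG_RE.findall(cigar):
        op = "M" if op in "=X" else op
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + int(ln))
        else:
            ops.append((op, int(ln)))
    return ops


def canonicalize_cigar(ops: list[tuple[str, int]], max_gap: int = 4) -> list[tuple[str, int]]:
    """Merge same-type indels separated by short match runs.

    Unit gap costs make the placement of a multi-base indel degenerate:
    an aligner may split a 4 bp deletion into 1+3 bp pieces around a
    coincidentally matching base at identical cost. Collapsing splits
    whose intervening match run is at most ``max_gap`` gives every read
    spanning the same event one canonical representation, which
    left-normalization then anchors identically across reads.
    """
    def collapse(seq):
        out: list[tuple[str, int]] = []
        for op, ln in seq:
            if out and out[-1][0] == op:
                out[-1] = (op, out[-1][1] + ln)
            else:
                out.append((op, ln))
        return out

    ops = collapse(ops)
    changed = True
    while changed:
        changed = False
        for i in range(len(ops) - 2):
            t = ops[i][0]
            if (
                t in "ID"
                and ops[i + 1][0] == "M"
                and ops[i + 1][1] <= max_gap
                and ops[i + 2][0] == t
            ):
                merged = (t, ops[i][1] + ops[i + 2][1])
                ops = collapse(ops[:i] + [merged, ops[i + 1]] + ops[i + 3 :])
                changed = True
                break
    return ops


@dataclass(slots=True)
class AlignmentRecord:
    read_id: str
    chrom: str
    start: int                      # 0-based reference start
    strand: str                     # '+' or '-'
    mapq: int
    placement: str                  # unique | multiple | unmapped
    cigar: list                     # [(op, length)], ops M/I/D
    seq: str                        # read sequence in reference orientation
    edit_distance: int = 0
    mate_role: str = "single"
    proper_pair: bool = False

    @property
    def end(self) -> int:
        return self.start + sum(ln for op, ln in self.cigar if op in "MD")

    def consumed_read(self) -> int:
        return sum(ln for op, ln in self.cigar if op in "MI")


@dataclass
class MappingStats:
    total: int = 0
    unique: int = 0
    multiple: int = 0
    unmapped: int = 0
    proper: int = 0

    def as_row(self) -> dict:
        return {
            "reads": self.total,
            "unique": self.unique,
            "multiple": self.multiple,
            "unmapped": self.unmapped,
            "proper_pairs": self.proper,
        }


class GenomeIndex:
    """Exact k-mer index over a set of chromosomes."""

    def __init__(self, chroms: dict[str, np.ndarray], k: int = SEED_K):
        self.k = k
        self.names = list(chroms)
        self.chrom_codes = {n: np.ascontiguousarray(c) for n, c in chroms.items()}
        self.chrom_bytes = {n: decode(c).encode() for n, c in chroms.items()}
        self.offsets = np.zeros(len(self.names) + 1, dtype=np.int64)
        for i, n in enumerate(self.names):
            self.offsets[i + 1] = self.offsets[i] + len(chroms[n])
        concat = np.concatenate([self.chrom_codes[n] for n in self.names])
        self.total = int(self.offsets[-1])

        # base-5 keys (A..T,N as digits) make N-containing k-mers unambiguous
        self._pow4 = 5 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        valid = concat < 4
        kmers = np.zeros(self.total - k + 1, dtype=np.int64)
        ok = np.ones(self.total - k + 1, dtype=bool)
        for i in range(k):
            seg = concat[i : self.total - k + 1 + i]
            kmers = kmers * 5 + seg.astype(np.int64)
            ok &= valid[i : self.total - k + 1 + i]
        # positions crossing chromosome boundaries are invalid seeds
        for b in self.offsets[1:-1]:
            ok[max(0, b - k + 1) : b] = False
        positions = np.flatnonzero(ok)
        keys = kmers[positions]
        order = np.argsort(keys, kind="stable")
        keys_sorted = keys[order]
        pos_sorted = positions[order]
        bounds = np.concatenate(
            [[0], np.flatnonzero(np.diff(keys_sorted)) + 1, [len(keys_sorted)]]
        )
        self._index: dict[int, np.ndarray] = {
            int(keys_sorted[bounds[i]]): pos_sorted[bounds[i] : bounds[i + 1]]
            for i in range(len(bounds) - 1)
        }

    def chrom_of(self, gpos: int) -> tuple[str, int]:
        i = int(np.searchsorted(self.offsets, gpos, side="right")) - 1
        return self.names[i], gpos - int(self.offsets[i])

    def seed_positions(self, codes: np.ndarray, offset: int) -> Optional[np.ndarray]:
        k = self.k
        window = codes[offset : offset + k]
        if len(window) < k:
            return None
        key = int(window.dot(self._pow4))
        hits = self._index.get(key)
        if hits is None or len(hits) > MAX_KMER_HITS:
            return None
        return hits - offset


def _seed_offsets(read_len: int, k: int) -> list[int]:
    if read_len <= k:
        return [0]
    return sorted({0, (read_len - k) // 2, read_len - k})


def _max_edits(read_len: int) -> int:
    return min(8, max(4, read_len // 12))


def map_read(read: Read, index: GenomeIndex) -> AlignmentRecord:
    """Place one read; returns a record with placement in
    {unique, multiple, unmapped}."""
    maxk = _max_edits(len(read))
    k = index.k
    best: Optional[tuple] = None        # (dist, lo, hi, strand, seq, exact_concat_start)
    second_dist = maxk + 1

    for strand, seq in (("+", read.sequence), ("-", revcomp(read.sequence))):
        codes = encode(seq)
        cands: list[int] = []
        for off in _seed_offsets(len(seq), k):
            hits = index.seed_positions(codes, off)
            if hits is not None:
                cands.extend(int(h) for h in hits)
        if not cands:
            continue
        cands = sorted(set(cands))
        # merge candidates shifted against each other by small indels
        merged: list[int] = []
        for c in cands:
            if merged and c - merged[-1] <= PAD:
                continue
            merged.append(c)
        sbytes = seq.encode()
        L = len(seq)
        for c in merged:
            ci = int(np.searchsorted(index.offsets, max(c, 0), side="right")) - 1
            ci = min(max(ci, 0), len(index.names) - 1)
            cs, ce = int(index.offsets[ci]), int(index.offsets[ci + 1])
            lo = max(c - PAD, cs)
            hi = min(c + L + PAD, ce)
            if hi - lo < L - maxk:
                continue
            target = index.chrom_bytes[index.names[ci]][lo - cs : hi - cs]
            exact = None
            if c >= lo and c + L <= hi and target[c - lo : c - lo + L] == sbytes:
                dist = 0
                exact = c
            else:
                res = edlib.align(sbytes, target, mode="HW", task="distance", k=maxk)
                dist = res["editDistance"]
                if dist < 0:
                    continue
            if best is None or dist < best[0]:
                if best is not None:
                    second_dist = min(second_dist, best[0])
                best = (dist, lo, hi, strand, seq, exact)
            elif dist < second_dist:
                second_dist = dist

    if best is None:
        return AlignmentRecord(read.id, "", -1, "+", 0, "unmapped", [], read.sequence,
                               mate_role=read.mate_role)
    dist, lo, hi, strand, seq, exact = best
    if dist >= second_dist:
        return AlignmentRecord(read.id, "", -1, strand, TIED_MAPQ, "multiple", [], seq,
                               mate_role=read.mate_role)
    chrom, cpos_lo = index.chrom_of(lo)
    if exact is not None:
        start = cpos_lo + (exact - lo)
        cigar = [("M", len(seq))]
    else:
        cs = lo - cpos_lo
        target = index.chrom_bytes[chrom][cpos_lo : cpos_lo + (hi - lo)]
        res = edlib.align(seq.encode(), target, mode="HW", task="path", k=dist)
        loc = res["locations"][0]
        start = cpos_lo + loc[0]
        cigar = canonicalize_cigar(parse_cigar(res["cigar"]))
    return AlignmentRecord(read.id, chrom, start, strand, UNIQUE_MAPQ, "unique",
                           cigar, seq, edit_distance=dist, mate_role=read.mate_role)


def map_reads(
    reads: Iterable[Read], index: GenomeIndex, stats: Optional[MappingStats] = None
) -> list[AlignmentRecord]:
    records = []
    for read in reads:
        rec = map_read(read, index)
        records.append(rec)
        if stats is not None:
            stats.total += 1
            if rec.placement == "unique":
                stats.unique += 1
            elif rec.placement == "multiple":
                stats.multiple += 1
            else:
                stats.unmapped += 1
    return records


# ---------------------------------------------------------------------------
# filtering


def estimate_insert_bounds(
    pairs: Iterable[tuple[AlignmentRecord, AlignmentRecord]], n_sample: int = 10_000
) -> tuple[float, float]:
    """Insert bounds as mean +/- 4 sd over the first uniquely mapped pairs."""
    spans = []
    for r1, r2 in pairs:
        if r1.placement == "unique" and r2.placement == "unique" and r1.chrom == r2.chrom:
            span = max(r1.end, r2.end) - min(r1.start, r2.start)
            spans.append(span)
            if len(spans) >= n_sample:
                break
    if not spans:
        return (0.0, float("inf"))
    arr = np.array(spans, dtype=float)
    return (float(arr.mean() - 4 * arr.std()), float(arr.mean() + 4 * arr.std()))


def flag_proper_pairs(
    r1: AlignmentRecord, r2: AlignmentRecord, bounds: tuple[float, float]
) -> bool:
    """Mates proper iff same chromosome, inward orientation, span within bounds."""
    if r1.placement != "unique" or r2.placement != "unique" or r1.chrom != r2.chrom:
        return False
    if r1.strand == r2.strand:
        return False
    fwd, rev = (r1, r2) if r1.strand == "+" else (r2, r1)
    if fwd.start > rev.end:
        return False
    span = max(r1.end, r2.end) - min(r1.start, r2.start)
    proper = bounds[0] <= span <= bounds[1]
    r1.proper_pair = r2.proper_pair = proper
    return proper


def filter_alignments(
    records: Iterable[AlignmentRecord], min_confidence: int = 20
) -> list[AlignmentRecord]:
    """Retain uniquely mapped records with confidence >= threshold."""
    return [
        r
        for r in records
        if r.placement == "unique" and r.mapq >= min_confidence
    ]


# ---------------------------------------------------------------------------
# SAM round trip


def write_sam(path, records: Iterable[AlignmentRecord], chroms: dict[str, np.ndarray]) -> None:
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": len(s)} for n, s in chroms.items()],
    }
    names = list(chroms)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.query_sequence = r.seq
            if r.placement != "unique":
                a.is_unmapped = True
                a.flag |= 4
                out.write(a)
                continue
            a.reference_id = names.index(r.chrom)
            a.reference_start = r.start
            a.mapping_quality = r.mapq
            a.is_reverse = r.strand == "-"
            opmap = {"M": 0, "I": 1, "D": 2}
            a.cigartuples = [(opmap[op], ln) for op, ln in r.cigar]
            a.set_tag("NM", r.edit_distance)
            out.write(a)


def read_sam(path) -> list[AlignmentRecord]:
    import pysam

    records = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for a in fh:
            if a.is_unmapped:
                records.append(
                    AlignmentRecord(a.query_name, "", -1, "+", 0, "unmapped", [],
                                    a.query_sequence or "")
                )
                continue
            opnames = {0: "M", 1: "I", 2: "D", 7: "M", 8: "M"}
            cigar = []
            for op, ln in a.cigartuples:
                name = opnames.get(op)
                if name is None:
                    raise ValueError(f"unsupported cigar op {op} in {a.query_name}")
                if cigar and cigar[-1][0] == name:
                    cigar[-1] = (name, cigar[-1][1] + ln)
                else:
                    cigar.append((name, ln))
            mapq = a.mapping_quality
            records.append(
                AlignmentRecord(
                    a.query_name, a.reference_name, a.reference_start,
                    "-" if a.is_reverse else "+", mapq,
                    "unique" if mapq >= 20 else "multiple",
                    cigar, a.query_sequence or "",
                    edit_distance=a.get_tag("NM") if a.has_tag("NM") else 0,
                )
            )
    return records
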