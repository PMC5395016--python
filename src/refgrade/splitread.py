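"""Large reference indel detection from split long-read alignments.

A long read spanning a large reference error aligns as two local hits.
The event size follows from the hit geometry alone:

    size = (read gap between hits) - (reference gap between hits)

positive sizes are insertions (the reference is missing sequence),
negative sizes deletions (the reference carries extra sequence; the
absolute value is reported). Candidate pairs must be unambiguous, on
the same chromosome and strand, within 1 Mbp of each other, and the
two hits together must cover >90% of the read. Insertion-type errors
arising from collapsed tandem duplications produce hit pairs that
overlap on the reference (negative reference gap); these are accepted
as long as the pair is not a pure rearrangement.

Because the hit pair shares the read, errors that truncate either hit
shift both its read and reference endpoint along the same diagonal, so
the inferred size is robust to endpoint wobble.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .mapping import GenomeIndex
from .readprep import Read
from .sequences import encode, revcomp

SEED_STEP = 4
MIN_HIT_SPAN = 30
MAX_DISTANCE = 1_000_000
MIN_READ_COVERAGE = 0.9
MIN_EVENT_SIZE = 20
BREAKPOINT_WINDOW = 10
TANDEM_MASK_FRACTION = 0.5


@dataclass(slots=True)
class LocalHit:
    read_id: str
    read_start: int
    read_end: int
    chrom: str
    ref_start: int
    ref_end: int
    strand: str
    score: int
    ambiguous: bool = False


@dataclass
class SplitReadEvent:
    read_id: str
    chrom: str
    left: LocalHit
    right: LocalHit
    event_type: str            # insertion | deletion
    size: int                  # absolute size in bp
    breakpoint: int            # reference coordinate of the junction
    distance: int              # |reference gap| between the hits


@dataclass
class CorroboratedEvent:
    chrom: str
    event_type: str
    size: int
    breakpoint: int
    support: int
    read_ids: list[str] = field(default_factory=list)
    short_read_corroborated: Optional[bool] = None


# ---------------------------------------------------------------------------
# repeat screen


def tandem_masked_fraction(seq: str, max_unit: int = 6, min_run: int = 20) -> float:
    """Fraction of the read covered by short-unit tandem repeats."""
    codes = encode(seq)
    n = len(codes)
    if n < min_run:
        return 0.0
    mask = np.zeros(n, dtype=bool)
    for u in range(1, max_unit + 1):
        eq = codes[u:] == codes[:-u]
        run = 0
        for i, same in enumerate(eq):
            run = run + 1 if same else 0
            if run >= min_run - u:
                mask[i - run + 1 : i + 1 + u] = True
    return float(mask.mean())


# ---------------------------------------------------------------------------
# seeded local alignment


def local_align(read: Read, index: GenomeIndex,
                min_span: int = MIN_HIT_SPAN) -> list[LocalHit]:
    """All local hits of one long read, with ambiguity flags."""
    k = index.k
    hits: list[LocalHit] = []
    for strand, seq in (("+", read.sequence), ("-", revcomp(read.sequence))):
        codes = encode(seq)
        seeds: list[tuple[int, int]] = []       # (diag, rpos)
        for rpos in range(0, len(seq) - k + 1, SEED_STEP):
            gpositions = index.seed_positions(codes, rpos)
            if gpositions is None:
                continue
            for g in gpositions:
                seeds.append((int(g), rpos))    # g = concat_pos - rpos = diagonal
        if not seeds:
            continue
        seeds.sort()
        cluster: list[tuple[int, int]] = []

        def flush():
            if not cluster:
                return
            rmin = min(r for _, r in cluster)
            rmax = max(r for _, r in cluster)
            diag = cluster[0][0]
            gstart, gend = diag + rmin, diag + rmax + k
            if gstart < 0 or gend > index.total:
                return
            chrom, cstart = index.chrom_of(gstart)
            chrom2, cend = index.chrom_of(gend - 1)
            if chrom != chrom2:
                return
            span = rmax + k - rmin
            if span >= min_span:
                hits.append(
                    LocalHit(read.id, rmin, rmax + k, chrom, cstart, cend + 1,
                             strand, span)
                )

        prev_diag, prev_r = None, None
        for diag, rpos in seeds:
            if (
                prev_diag is not None
                and diag - prev_diag <= 6
                and (diag != prev_diag or rpos - prev_r <= 60)
            ):
                cluster.append((diag, rpos))
            else:
                flush()
                cluster = [(diag, rpos)]
            prev_diag, prev_r = diag, rpos
        flush()

    # drop hits fully contained in a longer hit on the read
    hits.sort(key=lambda h: -h.score)
    kept: list[LocalHit] = []
    for h in hits:
        if any(
            o.read_start <= h.read_start and h.read_end <= o.read_end
            and o.score > h.score and o.strand == h.strand
            for o in kept
        ):
            continue
        kept.append(h)
    # ambiguity: substantially overlapping hits of comparable score
    for i, h in enumerate(kept):
        for o in kept[i + 1 :]:
            ov = min(h.read_end, o.read_end) - max(h.read_start, o.read_start)
            if ov > 0.8 * min(h.score, o.score) and o.score >= 0.9 * h.score:
                h.ambiguous = o.ambiguous = True
    return sorted(kept, key=lambda h: h.read_start)


# ---------------------------------------------------------------------------
# event detection


def detect_events(
    hits_by_read: dict[str, list[LocalHit]],
    read_lengths: dict[str, int],
    max_distance: int = MAX_DISTANCE,
    min_coverage: float = MIN_READ_COVERAGE,
    min_size: int = MIN_EVENT_SIZE,
) -> list[SplitReadEvent]:
    events = []
    for read_id, hits in hits_by_read.items():
        clean = [h for h in hits if not h.ambiguous]
        if len(clean) < 2:
            continue
        clean = sorted(clean, key=lambda h: -h.score)[:2]
        h1, h2 = sorted(clean, key=lambda h: h.read_start)
        if h1.chrom != h2.chrom or h1.strand != h2.strand:
            continue
        if h2.read_start < h1.read_end - 10:       # overlapping on the read
            continue
        if h2.ref_end <= h1.ref_start:             # pure rearrangement
            continue
        read_gap = h2.read_start - h1.read_end
        ref_gap = h2.ref_start - h1.ref_end
        distance = abs(ref_gap)
        if distance > max_distance:
            continue
        rl = read_lengths[read_id]
        if (h1.score + h2.score) / rl <= min_coverage:
            continue
        size = read_gap - ref_gap
        if abs(size) < min_size:
            continue
        etype = "insertion" if size > 0 else "deletion"
        events.append(
            SplitReadEvent(read_id, h1.chrom, h1, h2, etype, abs(size),
                           breakpoint=h1.ref_end, distance=distance)
        )
    return events


def scan_long_reads(
    reads: Iterable[Read],
    index: GenomeIndex,
    max_distance: int = MAX_DISTANCE,
    min_coverage: float = MIN_READ_COVERAGE,
    min_size: int = MIN_EVENT_SIZE,
) -> list[SplitReadEvent]:
    """local_align + detect_events over a long-read library, skipping
    reads dominated by short-unit tandem repeats."""
    hits_by_read: dict[str, list[LocalHit]] = {}
    lengths: dict[str, int] = {}
    for read in reads:
        if tandem_masked_fraction(read.sequence) > TANDEM_MASK_FRACTION:
            continue
        hits = local_align(read, index)
        if len(hits) >= 2:
            hits_by_read[read.id] = hits
            lengths[read.id] = len(read)
    return detect_events(hits_by_read, lengths, max_distance, min_coverage, min_size)


# ---------------------------------------------------------------------------
# corroboration (automated stand-in for manual candidate curation)


def corroborate_events(
    events: list[SplitReadEvent],
    min_support: int = 2,
    window: int = BREAKPOINT_WINDOW,
    depth: Optional[dict[str, np.ndarray]] = None,
) -> list[CorroboratedEvent]:
    """Cluster events by breakpoint/size and keep clusters seen in at
    least ``min_support`` distinct reads. With a short-read depth
    profile, deletion-type clusters are additionally checked for a
    coverage drop across the removed interval."""
    out: list[CorroboratedEvent] = []
    by_group: dict[tuple[str, str], list[SplitReadEvent]] = {}
    for e in events:
        by_group.setdefault((e.chrom, e.event_type), []).append(e)
    for (chrom, etype), evs in sorted(by_group.items()):
        evs.sort(key=lambda e: (e.breakpoint, e.size))
        cluster: list[SplitReadEvent] = []

        def flush():
            if not cluster:
                return
            reads = sorted({e.read_id for e in cluster})
            if len(reads) < min_support:
                return
            bp = int(np.median([e.breakpoint for e in cluster]))
            size = int(np.median([e.size for e in cluster]))
            ce = CorroboratedEvent(chrom, etype, size, bp, len(reads), reads)
            if depth is not None and etype == "deletion":
                d = depth[chrom]
                inner = d[bp : bp + size]
                flank = np.concatenate(
                    [d[max(0, bp - 500) : bp], d[bp + size : bp + size + 500]]
                )
                ce.short_read_corroborated = bool(
                    len(inner) and len(flank) and inner.mean() < 0.5 * flank.mean()
                )
            out.append(ce)

        for e in evs:
            if cluster and (
                e.breakpoint - cluster[-1].breakpoint > window
                or abs(e.size - cluster[0].size) > window
            ):
                flush()
                cluster = []
            cluster.append(e)
        flush()
    return out
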