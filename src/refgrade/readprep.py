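"""Short-read preprocessing: quality trimming, adapter clipping,
length filtering and paired-end bookkeeping.

The trimming rule scans inward from each read end and discards bases
until two consecutive bases with quality >= Q20 are seen; the surviving
read therefore starts and ends with such a pair. Adapter clipping is
3'-anchored with a documented minimum match and mismatch tolerance
(the trimming order — quality first, adapters second, then the length
filter — follows the protocol this pipeline reproduces). A read pair in
which exactly one mate is discarded demotes the survivor to an
"unpaired" single-end read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np

from .sequences import phred_to_string, string_to_phred

DEFAULT_Q = 20
DEFAULT_MIN_LEN = 32
ADAPTER_MIN_MATCH = 5
ADAPTER_MAX_MISMATCH_FRAC = 0.10


@dataclass(slots=True)
class Read:
    id: str
    sequence: str
    qualities: np.ndarray            # Phred integers, same length as sequence
    mate_role: str = "single"        # single | mate1 | mate2 | unpaired

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"{self.id}: sequence/quality length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PrepStats:
    input_reads: int = 0
    after_quality_trim: int = 0
    after_adapter_trim: int = 0
    after_pairing: int = 0
    unpaired_count: int = 0

    def as_row(self) -> dict:
        return {
            "input_reads": self.input_reads,
            "after_quality_trim": self.after_quality_trim,
            "after_adapter_trim": self.after_adapter_trim,
            "after_pairing": self.after_pairing,
            "unpaired": self.unpaired_count,
        }


def trim_quality(read: Read, q_threshold: int = DEFAULT_Q) -> Optional[Read]:
    """Trim low-quality ends; return None when nothing survives."""
    q = read.qualities
    n = len(q)
    if n < 2:
        return None
    hi = q >= q_threshold
    pair = hi[:-1] & hi[1:]            # pair[i]: positions i, i+1 both high
    idx = np.flatnonzero(pair)
    if idx.size == 0:
        return None
    start, end = int(idx[0]), int(idx[-1]) + 2
    if start == 0 and end == n:
        return read
    return Read(read.id, read.sequence[start:end], q[start:end], read.mate_role)


def _adapter_hit(seq: str, adapter: str) -> Optional[int]:
    """Leftmost 3'-anchored adapter occurrence start, or None."""
    n, m = len(seq), len(adapter)
    # cheap screen: any tolerated hit leaves one of the first two adapter
    # 5-mers intact (mismatch budget in the first 10 bases is at most 1)
    if adapter[:5] not in seq and adapter[5:10] not in seq:
        return None
    max_frac = ADAPTER_MAX_MISMATCH_FRAC
    for s in range(0, n - ADAPTER_MIN_MATCH + 1):
        overlap = min(m, n - s)
        limit = int(overlap * max_frac)
        mismatches = 0
        for a, b in zip(seq[s : s + overlap], adapter[:overlap]):
            if a != b:
                mismatches += 1
                if mismatches > limit:
                    break
        else:
            return s
    return None


def clip_adapter(read: Read, adapters: Iterable[str]) -> Read:
    """Truncate the read before the leftmost adapter occurrence."""
    cut = len(read)
    for adapter in adapters:
        hit = _adapter_hit(read.sequence, adapter.upper())
        if hit is not None:
            cut = min(cut, hit)
    if cut == len(read):
        return read
    return Read(read.id, read.sequence[:cut], read.qualities[:cut], read.mate_role)


def filter_length(read: Optional[Read], min_len: int = DEFAULT_MIN_LEN) -> bool:
    return read is not None and len(read) >= min_len


def preprocess_read(
    read: Read,
    adapters: Iterable[str],
    q_threshold: int = DEFAULT_Q,
    min_len: int = DEFAULT_MIN_LEN,
) -> Optional[Read]:
    """Full per-read pipeline; None means discarded."""
    trimmed = trim_quality(read, q_threshold)
    if trimmed is None:
        return None
    clipped = clip_adapter(trimmed, adapters)
    if not filter_length(clipped, min_len):
        return None
    return clipped


def pair_bookkeeping(
    mate1: Optional[Read], mate2: Optional[Read]
) -> tuple[Optional[Read], ...]:
    """Demote lone survivors of a pair to 'unpaired'."""
    if mate1 is not None and mate2 is not None:
        return (mate1, mate2)
    survivor = mate1 if mate1 is not None else mate2
    if survivor is None:
        return ()
    demoted = Read(survivor.id, survivor.sequence, survivor.qualities, "unpaired")
    return (demoted,)


def preprocess_single(
    reads: Iterable[Read],
    adapters: Iterable[str],
    q_threshold: int = DEFAULT_Q,
    min_len: int = DEFAULT_MIN_LEN,
    stats: Optional[PrepStats] = None,
) -> Iterator[Read]:
    adapters = [a.upper() for a in adapters]
    for read in reads:
        if stats is not None:
            stats.input_reads += 1
        trimmed = trim_quality(read, q_threshold)
        if trimmed is None:
            continue
        if stats is not None:
            stats.after_quality_trim += 1
        clipped = clip_adapter(trimmed, adapters)
        if not filter_length(clipped, min_len):
            continue
        if stats is not None:
            stats.after_adapter_trim += 1
            stats.after_pairing += 1
        yield clipped


def preprocess_pairs(
    pairs: Iterable[tuple[Read, Read]],
    adapters: Iterable[str],
    q_threshold: int = DEFAULT_Q,
    min_len: int = DEFAULT_MIN_LEN,
    stats: Optional[PrepStats] = None,
) -> Iterator[tuple[Optional[Read], ...]]:
    """Yield surviving pairs or demoted unpaired singletons."""
    adapters = [a.upper() for a in adapters]
    for m1, m2 in pairs:
        if stats is not None:
            stats.input_reads += 2
        out = []
        n_qtrim = 0
        for mate in (m1, m2):
            trimmed = trim_quality(mate, q_threshold)
            if trimmed is not None:
                n_qtrim += 1
                clipped = clip_adapter(trimmed, adapters)
                out.append(clipped if filter_length(clipped, min_len) else None)
            else:
                out.append(None)
        result = pair_bookkeeping(out[0], out[1])
        if stats is not None:
            stats.after_quality_trim += n_qtrim
            stats.after_adapter_trim += sum(r is not None for r in out)
            stats.after_pairing += len(result)
            if len(result) == 1:
                stats.unpaired_count += 1
        if result:
            yield result


# ---------------------------------------------------------------------------
# FASTQ I/O (Phred+33)

def write_fastq(path, reads: Iterable[Read]) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{phred_to_string(r.qualities)}\n")
            n += 1
    return n


def read_fastq(path, mate_role: str = "single") -> Iterator[Read]:
    import pysam

    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            yield Read(rec.name, rec.sequence, string_to_phred(rec.quality), mate_role)
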