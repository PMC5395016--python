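"""Low-level sequence utilities shared across the pipeline.

Sequences are held in two interchangeable forms: Python strings over
``ACGTN`` and numpy ``uint8`` code arrays (A=0, C=1, G=2, T=3, N=4).
The code-array form is what the simulator, mapper and pileup engine
operate on; strings appear only at file boundaries.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGTN"
A, C, G, T, N = range(5)

_ENCODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)

# complement of codes 0..4 (N -> N)
_COMP = np.array([T, G, C, A, N], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """String -> uint8 code array (unknown characters become N)."""
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """uint8 code array -> string."""
    return _DECODE[codes].tobytes().decode()


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes[::-1]]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def gc_fraction(codes: np.ndarray) -> float:
    acgt = codes < 4
    if not acgt.any():
        return 0.0
    return float(((codes == C) | (codes == G)).sum() / acgt.sum())


def write_fasta(path, records, width: int = 70) -> None:
    """Write ``(name, sequence)`` pairs; sequence may be str or code array."""
    with open(path, "w") as fh:
        for name, seq in records:
            if isinstance(seq, np.ndarray):
                seq = decode(seq)
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, np.ndarray]:
    """FASTA -> ordered dict of name -> code array (via pysam/htslib)."""
    import pysam

    out: dict[str, np.ndarray] = {}
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            out[rec.name] = encode(rec.sequence)
    return out


def phred_to_string(quals: np.ndarray) -> str:
    return (quals.astype(np.uint8) + 33).tobytes().decode()


def string_to_phred(qual: str) -> np.ndarray:
    return np.frombuffer(qual.encode(), dtype=np.uint8).astype(np.int16) - 33
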