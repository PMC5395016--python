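"""SNP effect annotation, assembly correction, gap placeholders and
assembly/genome-size accounting.

Effects of biallelic substitutions are classified against gene models
into six groups — Nonsense, Missense, Silent, UTR, Intron, Intergenic —
by interval containment and, inside CDS, by strand-aware codon
substitution under the standard code. The site-level effect is the most
severe across overlapping transcripts (severity in the order listed).

Corrections are applied by splicing: substitutions in place, insertion
errors filled with the individuals' bases, deletion errors (extra
assembly bases) removed; an offset map converts coordinates between the
old and corrected assemblies and is exact outside corrected intervals.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from .classify import ErrorRecord
from .genemodels import GeneModel
from .sequences import decode, encode

EFFECTS = ("Nonsense", "Missense", "Silent", "UTR", "Intron", "Intergenic")
_SEVERITY = {e: i for i, e in enumerate(EFFECTS)}


@dataclass
class EffectCall:
    chrom: str
    position: int
    ref_allele: str
    alt_allele: str
    effect: str
    transcript_effects: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# effect annotation


def _within(ivs: Sequence[tuple[int, int]], pos: int) -> bool:
    return any(s <= pos < e for s, e in ivs)


def _codon_effect(gene: GeneModel, pos: int, ref: str, alt: str,
                  chrom_seq: np.ndarray) -> str:
    """Effect of a CDS substitution via codon comparison."""
    cds = gene.cds if gene.strand == "+" else gene.cds[::-1]
    coding_pos = 0
    hit = None
    for s, e in cds:
        if s <= pos < e:
            offset = (pos - s) if gene.strand == "+" else (e - 1 - pos)
            hit = coding_pos + offset
        coding_pos += e - s
    if hit is None:  # pragma: no cover
        raise ValueError("position not in CDS")
    if coding_pos % 3 != 0:
        raise ValueError(f"{gene.gene_id}: invalid CDS frame")

    parts = [decode(chrom_seq[s:e]) for s, e in gene.cds]
    coding = "".join(parts)
    if gene.strand == "-":
        coding = str(Seq(coding).reverse_complement())
    ref_c, alt_c = ref, alt
    if gene.strand == "-":
        ref_c = str(Seq(ref).complement())
        alt_c = str(Seq(alt).complement())
    if coding[hit] != ref_c:
        raise ValueError(
            f"{gene.gene_id}: reference base mismatch at CDS position {hit}"
        )
    ci = hit // 3
    codon = coding[3 * ci : 3 * ci + 3]
    new_codon = codon[: hit % 3] + alt_c + codon[hit % 3 + 1 :]
    old_aa = str(Seq(codon).translate())
    new_aa = str(Seq(new_codon).translate())
    if new_aa == old_aa:
        return "Silent"
    if new_aa == "*" and old_aa != "*":
        return "Nonsense"
    return "Missense"       # includes start-loss and stop-loss


def annotate_effect(
    chrom: str, position: int, ref: str, alt: str,
    genes: Sequence[GeneModel], assembly: dict[str, np.ndarray],
) -> EffectCall:
    """Six-way effect of a biallelic substitution."""
    per_tx: dict[str, str] = {}
    for gene in genes:
        if gene.chrom != chrom or not (gene.start <= position < gene.end):
            continue
        if _within(gene.cds, position):
            eff = _codon_effect(gene, position, ref, alt, assembly[chrom])
        elif _within(gene.utr5, position) or _within(gene.utr3, position) or _within(
            gene.exons, position
        ):
            eff = "UTR"
        else:
            eff = "Intron"   # includes splice-region positions
        per_tx[gene.gene_id] = eff
    site_effect = (
        min(per_tx.values(), key=_SEVERITY.__getitem__) if per_tx else "Intergenic"
    )
    return EffectCall(chrom, position, ref, alt, site_effect, per_tx)


def effect_breakdown(calls: Iterable[EffectCall]):
    import pandas as pd

    counts = {e: 0 for e in EFFECTS}
    for c in calls:
        counts[c.effect] += 1
    total = sum(counts.values())
    return pd.DataFrame(
        [
            {"effect": e, "count": n, "percent": round(100 * n / total, 1) if total else 0.0}
            for e, n in counts.items()
        ]
    )


# ---------------------------------------------------------------------------
# corrections


class OffsetMap:
    """Piecewise old<->new coordinate conversion for one chromosome."""

    def __init__(self):
        self._old: list[int] = [0]
        self._new: list[int] = [0]

    def add_breakpoint(self, old_pos: int, new_pos: int) -> None:
        self._old.append(old_pos)
        self._new.append(new_pos)

    def to_new(self, old_pos: int) -> int:
        i = bisect.bisect_right(self._old, old_pos) - 1
        return self._new[i] + (old_pos - self._old[i])

    def to_old(self, new_pos: int) -> int:
        i = bisect.bisect_right(self._new, new_pos) - 1
        return self._old[i] + (new_pos - self._new[i])

    def write_chain(self, fh, chrom: str) -> None:
        for o, n in zip(self._old, self._new):
            fh.write(f"{chrom}\t{o}\t{n}\n")


def apply_corrections(
    assembly: dict[str, np.ndarray], records: Sequence[ErrorRecord]
) -> tuple[dict[str, np.ndarray], dict[str, OffsetMap]]:
    """Correct the assembly; returns (corrected, per-chromosome offset map).

    ``snp``: base replaced in place. ``insertion``: the individuals'
    bases are inserted after the anchor. ``deletion``: ``size`` assembly
    bases after the anchor are removed.
    """
    by_chrom: dict[str, list[ErrorRecord]] = {c: [] for c in assembly}
    for r in records:
        by_chrom[r.chrom].append(r)
    corrected: dict[str, np.ndarray] = {}
    offsets: dict[str, OffsetMap] = {}
    for chrom, seq in assembly.items():
        recs = sorted(by_chrom[chrom], key=lambda r: r.position)
        spans = []
        for r in recs:
            s = r.position if r.type == "snp" else r.position + 1
            e = s + (r.size if r.type in ("snp", "deletion") else 0)
            spans.append((s, max(e, s + (1 if r.type == "snp" else 0)), r))
        for (s1, e1, r1), (s2, e2, r2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(
                    f"overlapping correction records at {chrom}:{r1.position} and {chrom}:{r2.position}"
                )
        parts: list[np.ndarray] = []
        om = OffsetMap()
        prev = 0
        new_len = 0
        for r in recs:
            if r.type == "snp":
                parts.append(seq[prev : r.position])
                new_len += r.position - prev
                parts.append(encode(r.corrected_allele))
                new_len += 1
                prev = r.position + 1
            elif r.type == "insertion":
                parts.append(seq[prev : r.position + 1])
                new_len += r.position + 1 - prev
                ins = encode(r.corrected_allele)
                parts.append(ins)
                new_len += len(ins)
                prev = r.position + 1
                om.add_breakpoint(prev, new_len)
            elif r.type == "deletion":
                parts.append(seq[prev : r.position + 1])
                new_len += r.position + 1 - prev
                prev = r.position + 1 + r.size
                om.add_breakpoint(prev, new_len)
            else:
                raise ValueError(f"unknown correction type {r.type}")
        parts.append(seq[prev:])
        corrected[chrom] = np.concatenate(parts) if parts else seq.copy()
        offsets[chrom] = om
    return corrected, offsets


# ---------------------------------------------------------------------------
# gap placeholders


def insert_gap_placeholders(
    assembly: dict[str, np.ndarray],
    gaps: Sequence[tuple[str, int, str]],
    physical_n: int = 1000,
    telomere_n: int = 1000,
) -> dict[str, np.ndarray]:
    """Insert N runs: 1,000 Ns at each physical gap coordinate; telomeric
    gaps add an N run at the stated chromosome end ('start' or 'end')."""
    edits: dict[str, list[tuple[int, str]]] = {c: [] for c in assembly}
    for chrom, pos, kind in gaps:
        edits[chrom].append((pos, kind))
    out: dict[str, np.ndarray] = {}
    for chrom, seq in assembly.items():
        pieces: list[np.ndarray] = []
        prev = 0
        prepend = any(k == "telomere_start" for _, k in edits[chrom])
        append = any(k == "telomere_end" for _, k in edits[chrom])
        for pos, kind in sorted(e for e in edits[chrom] if e[1] == "physical"):
            pieces.append(seq[prev:pos])
            pieces.append(np.full(physical_n, 4, dtype=np.uint8))
            prev = pos
        pieces.append(seq[prev:])
        body = np.concatenate(pieces)
        if prepend:
            body = np.concatenate([np.full(telomere_n, 4, dtype=np.uint8), body])
        if append:
            body = np.concatenate([body, np.full(telomere_n, 4, dtype=np.uint8)])
        out[chrom] = body
    return out


# ---------------------------------------------------------------------------
# accounting


@dataclass
class AssemblyAccount:
    sequence_length: int
    gap_totals: dict[str, int]          # estimation source -> total gap bp
    rdna_bp: int = 0
    telomeric_gaps: int = 0

    def totals(self) -> dict[str, int]:
        return {src: self.sequence_length + g for src, g in self.gap_totals.items()}

    def genome_sizes(self) -> dict[str, int]:
        return {src: t + self.rdna_bp for src, t in self.totals().items()}

    def coverage(self) -> dict[str, float]:
        return {
            src: self.sequence_length / g for src, g in self.genome_sizes().items() if g
        }


def account_assembly(account: AssemblyAccount) -> dict:
    """Totals, genome-size range (Mbp, 1 decimal) and coverage range
    (%, 1 decimal)."""
    totals = account.totals()
    sizes = account.genome_sizes()
    cov = account.coverage()
    report = {
        "sequence_length_bp": account.sequence_length,
        "total_assembly_size_bp": totals,
        "genome_size_bp": sizes,
        "genome_size_mbp": {s: round(v / 1e6, 1) for s, v in sizes.items()},
        "coverage_percent": {s: round(100 * v, 1) for s, v in cov.items()},
    }
    if sizes:
        lo, hi = min(sizes.values()), max(sizes.values())
        report["genome_size_range_mbp"] = (round(lo / 1e6, 1), round(hi / 1e6, 1))
        report["coverage_range_percent"] = (
            round(100 * account.sequence_length / hi, 1),
            round(100 * account.sequence_length / lo, 1),
        )
    return report


def gigabases(read_counts_and_lengths: Sequence[tuple[int, int]]) -> float:
    """Total Gbp of a library set, at 1 decimal."""
    total = sum(n * ln for n, ln in read_counts_and_lengths)
    return round(total / 1e9, 1)


# ---------------------------------------------------------------------------
# report bundle


def summarize_run(
    prep_stats: dict,
    mapping_stats: dict,
    coverage_df,
    class_counts: dict,
    effective_sites: int,
    effect_calls: Optional[Iterable[EffectCall]] = None,
) -> dict:
    """Tables mirroring the published layouts: per-library preprocessing
    counts with percentages, mapping outcomes, per-chromosome coverage,
    class counts with per-10 kb rates, and the effect breakdown."""
    import pandas as pd

    from .classify import compute_rate

    prep_rows = []
    for lib, st in prep_stats.items():
        row = {"library": lib, **st.as_row()}
        base = max(row["input_reads"], 1)
        for key in ("after_quality_trim", "after_adapter_trim", "after_pairing"):
            row[key + "_pct"] = round(100 * row[key] / base, 1)
        prep_rows.append(row)
    map_rows = []
    for lib, st in mapping_stats.items():
        row = {"library": lib, **st.as_row()}
        base = max(row["reads"], 1)
        for key in ("unique", "multiple", "unmapped"):
            row[key + "_pct"] = round(100 * row[key] / base, 1)
        map_rows.append(row)
    class_rows = [
        {
            "class": cls,
            "count": n,
            "rate_per_10kb": compute_rate(n, effective_sites)
            if cls not in ("reference",)
            else "",
        }
        for cls, n in sorted(class_counts.items())
    ]
    report = {
        "preprocessing": pd.DataFrame(prep_rows),
        "mapping": pd.DataFrame(map_rows),
        "coverage": coverage_df,
        "classes": pd.DataFrame(class_rows),
    }
    if effect_calls is not None:
        report["effects"] = effect_breakdown(effect_calls)
    return report
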