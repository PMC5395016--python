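"""Per-site classification of re-sequencing evidence against the assembly.

Every effective site (pooled depth >= 10) is first categorized per
dataset as reference type (R), non-reference type (N), allelic (A) or
low depth (L), using inclusive frequency thresholds: R when >=80% of
reads match the assembly base, N when >=80% are discordant, A when two
alleles each have >=40% support, L below the depth floor. Sites
matching none of the rules (e.g. 70/30) are an "unresolved precursor"
(U) — the published rules genuinely leave that region undefined.

The per-dataset categories of the two individuals and of the pooled
alignments are then combined into the five published genotype classes
(reference / sequencing error / allele within an individual / allelic
difference between individuals / low depth) plus "unresolved". The
combination table is a documented reconstruction — see docs/methods.md
— since only its inputs and outputs are published. 1-4 bp indel alleles
run through the same thresholds with the anchored indel as the
non-reference allele.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .pileup import Pileup
from .simulate import TruthTable

R, N, A, L, U, X = range(6)          # X: not assessable (assembly base is N)
CAT_NAMES = {R: "R", N: "N", A: "A", L: "L", U: "U", X: "X"}

REF_FRAC = 0.8
ALLELE_FRAC = 0.4
MIN_DEPTH = 10
_EPS = 1e-9

CLASSES = (
    "reference",
    "sequencing_error",
    "allele_within",
    "allele_between",
    "low_depth",
    "unresolved",
)


@dataclass
class SiteCall:
    chrom: str
    position: int
    ref_allele: str
    categories: dict[str, str]            # ds1/ds2/pooled -> R/N/A/L/U
    alleles: dict[str, Optional[str]]     # supporting non-reference allele per set
    frequencies: dict[str, float]
    combined: str
    carrier: Optional[str] = None         # allele_within carrier individual
    low_confidence: bool = False


@dataclass(frozen=True)
class ErrorRecord:
    chrom: str
    position: int
    type: str                             # snp | insertion | deletion
    ref_allele: str
    corrected_allele: str
    size: int


@dataclass
class ClassificationResult:
    effective_sites: int
    class_counts: Counter = field(default_factory=Counter)
    calls: list[SiteCall] = field(default_factory=list)
    error_records: list[ErrorRecord] = field(default_factory=list)
    indel_calls: list[SiteCall] = field(default_factory=list)

    def rate(self, which: str) -> float:
        return compute_rate(self.class_counts[which], self.effective_sites)


# ---------------------------------------------------------------------------
# per-dataset categories


def _ge(count, depth, frac):
    return count + _EPS >= frac * depth


def classify_site(column, min_depth: int = MIN_DEPTH,
                  ref_frac: float = REF_FRAC, allele_frac: float = ALLELE_FRAC) -> str:
    """R/N/A/L/U category of one pileup column (single-column API)."""
    depth = column.depth
    if depth < min_depth:
        return "L"
    ref_count = column.base_counts.get(column.ref_base, 0)
    if _ge(ref_count, depth, ref_frac):
        return "R"
    if _ge(depth - ref_count, depth, ref_frac):
        return "N"
    top2 = sorted(column.base_counts.values(), reverse=True)[:2]
    if len(top2) == 2 and _ge(top2[1], depth, allele_frac):
        return "A"
    return "U"


def classify_columns(counts: np.ndarray, ref_codes: np.ndarray,
                     min_depth: int = MIN_DEPTH, ref_frac: float = REF_FRAC,
                     allele_frac: float = ALLELE_FRAC):
    """Vectorized R/N/A/L/U/X categories for one chromosome.

    Returns (categories uint8, alt base codes int8) where alt is the
    majority non-reference base (-1 when depth is zero).
    """
    Lcols = counts.shape[1]
    depth = counts.sum(axis=0, dtype=np.int64)
    cols = np.arange(Lcols)
    ref_count = counts[ref_codes, cols].astype(np.int64)
    disc = depth - ref_count
    part = np.partition(counts, 3, axis=0).astype(np.int64)
    top2 = part[3]

    is_L = depth < min_depth
    is_R = _ge(ref_count, depth, ref_frac)
    is_N = _ge(disc, depth, ref_frac)
    is_A = _ge(top2, depth, allele_frac) & (depth > 0)
    cat = np.select([is_L, is_R, is_N, is_A], [L, R, N, A], default=U).astype(np.uint8)
    cat[ref_codes >= 4] = X

    masked = counts.astype(np.int64).copy()
    masked[ref_codes, cols] = -1
    alt = masked.argmax(axis=0).astype(np.int8)
    alt[depth == 0] = -1
    return cat, alt


# ---------------------------------------------------------------------------
# combining the three datasets

_DEFER = {R: "reference", N: "sequencing_error", A: "allele_within",
          L: "low_depth", U: "unresolved", X: "unresolved"}


def combine_datasets(cat1: int, cat2: int, catp: int,
                     allele1: Optional[str], allele2: Optional[str],
                     allelep: Optional[str],
                     ds_names: tuple[str, str] = ("ds1", "ds2"),
                     pooled_alt_count: int = 0):
    """Combined genotype class from the three per-dataset categories.

    Returns (combined_class, carrier, low_confidence).
    """
    indef = {L, U, X}
    if cat1 in indef and cat2 in indef:
        if cat1 == L and cat2 == L and catp == L:
            return "low_depth", None, False
        cls = _DEFER[catp]
        return cls, None, cls == "sequencing_error"
    if cat1 in indef or cat2 in indef:
        # one informative dataset: defer to the pooled set, cross-checked
        xcat, xall, xname = (
            (cat2, allele2, ds_names[1]) if cat1 in indef else (cat1, allele1, ds_names[0])
        )
        if xcat == A:
            if catp == N:
                return "unresolved", None, False
            if pooled_alt_count >= 2 and xall is not None and (
                allelep is None or xall == allelep or catp in (R, U)
            ):
                return "allele_within", xname, False
            return "unresolved", None, False
        if catp == R:
            return ("reference", None, False) if xcat == R else ("unresolved", None, False)
        if catp == N:
            if xcat == N and xall == allelep:
                return "sequencing_error", None, True
            return "unresolved", None, False
        if catp == A:
            return "allele_within", None, False
        if catp == L:
            return "low_depth", None, False
        return "unresolved", None, False

    # both individuals informative
    if cat1 == R and cat2 == R:
        return "reference", None, False
    if cat1 == N and cat2 == N:
        if allele1 == allele2 and allele1 is not None:
            return "sequencing_error", None, False
        return "unresolved", None, False
    if {cat1, cat2} == {R, N}:
        # the pooled set is a mixture whose category only reflects the
        # depth ratio; any non-reference pooled reading is consistent
        if catp in (A, N, U):
            carrier = ds_names[0] if cat1 == N else ds_names[1]
            return "allele_between", carrier, False
        return "unresolved", None, False
    if cat1 == A and cat2 == A:
        if allele1 == allele2:
            return "allele_within", "both", False
        return "unresolved", None, False
    if A in (cat1, cat2):
        other = cat2 if cat1 == A else cat1
        if other == N:
            return "unresolved", None, False
        carrier = ds_names[0] if cat1 == A else ds_names[1]
        if pooled_alt_count >= 2:
            return "allele_within", carrier, False
        return "unresolved", None, False
    return "unresolved", None, False


# ---------------------------------------------------------------------------
# whole-study SNV classification


def classify_snv_sites(
    p1: Pileup, p2: Pileup, pooled: Pileup,
    ds_names: tuple[str, str] = ("NIAS_like", "CSHL_like"),
    min_depth: int = MIN_DEPTH,
) -> ClassificationResult:
    from .sequences import BASES

    effective_total = 0
    result = ClassificationResult(effective_sites=0)
    for chrom, ref in p1.reference.items():
        c1, c2, cp = p1.counts[chrom], p2.counts[chrom], pooled.counts[chrom]
        dp = cp.sum(axis=0, dtype=np.int64)
        d1 = c1.sum(axis=0, dtype=np.int64)
        d2 = c2.sum(axis=0, dtype=np.int64)
        if (dp < np.maximum(d1, d2)).any():
            raise ValueError("pooled depth below an individual dataset's depth")
        cat1, alt1 = classify_columns(c1, ref, min_depth)
        cat2, alt2 = classify_columns(c2, ref, min_depth)
        catp, altp = classify_columns(cp, ref, min_depth)
        effective = (dp >= min_depth) & (ref < 4)
        effective_total += int(effective.sum())

        interesting = effective & (
            (catp != R) | np.isin(cat1, (N, A, U)) | np.isin(cat2, (N, A, U))
        )
        n_interesting = int(interesting.sum())
        result.class_counts["reference"] += int(effective.sum()) - n_interesting

        cols = np.flatnonzero(interesting)
        for pos in cols:
            pos = int(pos)
            a1 = BASES[alt1[pos]] if alt1[pos] >= 0 else None
            a2 = BASES[alt2[pos]] if alt2[pos] >= 0 else None
            ap = BASES[altp[pos]] if altp[pos] >= 0 else None
            pooled_alt = int(cp[altp[pos], pos]) if altp[pos] >= 0 else 0
            combined, carrier, lowconf = combine_datasets(
                int(cat1[pos]), int(cat2[pos]), int(catp[pos]),
                a1, a2, ap, ds_names, pooled_alt,
            )
            result.class_counts[combined] += 1
            call = SiteCall(
                chrom, pos, BASES[int(ref[pos])],
                categories={
                    ds_names[0]: CAT_NAMES[int(cat1[pos])],
                    ds_names[1]: CAT_NAMES[int(cat2[pos])],
                    "pooled": CAT_NAMES[int(catp[pos])],
                },
                alleles={ds_names[0]: a1, ds_names[1]: a2, "pooled": ap},
                frequencies={
                    "pooled_alt": pooled_alt / dp[pos] if dp[pos] else 0.0,
                    "pooled_ref": int(cp[ref[pos], pos]) / dp[pos] if dp[pos] else 0.0,
                },
                combined=combined, carrier=carrier, low_confidence=lowconf,
            )
            result.calls.append(call)
            if combined == "sequencing_error" and ap is not None:
                result.error_records.append(
                    ErrorRecord(chrom, pos, "snp", BASES[int(ref[pos])], ap, 1)
                )
    result.effective_sites = effective_total
    return result


# ---------------------------------------------------------------------------
# small indels


def call_small_indels(
    p1: Pileup, p2: Pileup, pooled: Pileup,
    ds_names: tuple[str, str] = ("NIAS_like", "CSHL_like"),
    min_depth: int = MIN_DEPTH,
    min_pooled_support: int = 2,
) -> tuple[list[ErrorRecord], list[SiteCall]]:
    """1-4 bp indel errors and allelic indel sites.

    The anchored indel is treated as the non-reference allele and run
    through the same R/N/A/L thresholds; frequencies use the number of
    event-spanning reads as denominator.
    """
    errors: list[ErrorRecord] = []
    allelic: list[SiteCall] = []
    for (chrom, anchor), counter in sorted(pooled.indels.items()):
        # support is pooled over inserted/deleted sequences of one length:
        # a sequencing error inside an inserted run must not split the allele
        groups: dict[tuple[str, int], int] = Counter()
        for (kind, ln, seq), n in counter.items():
            groups[(kind, ln)] += n
        for (kind, ln), pooled_support in sorted(groups.items()):
            if pooled_support < min_pooled_support:
                continue
            seq_votes = Counter(
                {s: n for (k2, l2, s), n in counter.items() if (k2, l2) == (kind, ln)}
            )
            seq = seq_votes.most_common(1)[0][0]

            def group_support(p: Pileup) -> int:
                c = p.indels.get((chrom, anchor))
                if not c:
                    return 0
                return sum(n for (k2, l2, _), n in c.items() if (k2, l2) == (kind, ln))

            def category(p: Pileup):
                denom = p.indel_denominator(chrom, anchor, ln, kind)
                sup = min(group_support(p), denom)
                ref_sup = max(denom - sum(p.indels.get((chrom, anchor), Counter()).values()), 0)
                if denom < min_depth:
                    return L, sup, denom
                if _ge(sup, denom, REF_FRAC):
                    return N, sup, denom
                if _ge(ref_sup, denom, REF_FRAC):
                    return R, sup, denom
                if _ge(sup, denom, ALLELE_FRAC) and _ge(ref_sup, denom, ALLELE_FRAC):
                    return A, sup, denom
                return U, sup, denom

            cat1, sup1, den1 = category(p1)
            cat2, sup2, den2 = category(p2)
            catp, supp, denp = category(pooled)
            token = f"{kind}{ln}"
            combined, carrier, lowconf = combine_datasets(
                cat1, cat2, catp, token if sup1 else None, token if sup2 else None,
                token if supp else None, ds_names, pooled_alt_count=supp,
            )
            ref_arr = pooled.reference[chrom]
            from .sequences import BASES, decode

            anchor_base = BASES[int(ref_arr[anchor])]
            if combined == "sequencing_error":
                if kind == "ins":     # assembly missing bases: insert them
                    errors.append(ErrorRecord(chrom, anchor, "insertion",
                                              anchor_base, seq, ln))
                else:                 # assembly carries extra bases: delete them
                    deleted = decode(ref_arr[anchor + 1 : anchor + 1 + ln])
                    errors.append(ErrorRecord(chrom, anchor, "deletion",
                                              deleted, "", ln))
            elif combined in ("allele_within", "allele_between"):
                allelic.append(
                    SiteCall(
                        chrom, anchor, anchor_base,
                        categories={
                            ds_names[0]: CAT_NAMES[cat1],
                            ds_names[1]: CAT_NAMES[cat2],
                            "pooled": CAT_NAMES[catp],
                        },
                        alleles={ds_names[0]: token, ds_names[1]: token, "pooled": token},
                        frequencies={"pooled_alt": supp / denp if denp else 0.0},
                        combined=combined, carrier=carrier, low_confidence=lowconf,
                    )
                )
    return errors, allelic


def correction_span(r: ErrorRecord) -> tuple[int, int]:
    """Assembly interval a correction record touches."""
    if r.type == "snp":
        return (r.position, r.position + 1)
    if r.type == "deletion":
        return (r.position + 1, r.position + 1 + r.size)
    return (r.position + 1, r.position + 1)      # insertion: a point


def drop_overlapping_records(records) -> tuple[list[ErrorRecord], list[ErrorRecord]]:
    """Greedy conflict resolution before corrections are applied.

    Calls at adjacent coordinates can touch overlapping assembly
    intervals (e.g. a substitution call inside a called deletion); the
    larger event wins, ties go to the leftmost. Returns (kept, dropped).
    """
    kept: list[ErrorRecord] = []
    dropped: list[ErrorRecord] = []
    last_end: dict[str, int] = {}
    for r in sorted(records, key=lambda r: (r.chrom, correction_span(r)[0], -r.size)):
        s, e = correction_span(r)
        if s < last_end.get(r.chrom, -1):
            dropped.append(r)
            continue
        kept.append(r)
        last_end[r.chrom] = max(e, s + 1)
    return kept, dropped


# ---------------------------------------------------------------------------
# rates


def compute_rate(count: int, effective_sites: int) -> float:
    """Events per 10,000 nucleotides, at the reported precision
    (2 decimals, 4 when below 0.01)."""
    if effective_sites <= 0:
        return 0.0
    rate = count / effective_sites * 10_000
    return round(rate, 4) if rate < 0.01 else round(rate, 2)


# ---------------------------------------------------------------------------
# scoring against simulation truth


@dataclass
class RecoveryMetrics:
    error_sensitivity: float
    error_precision: float
    within_sensitivity: float
    between_sensitivity: float
    n_true_errors: int
    n_called_errors: int
    cross_class_confusions: int


def compare_with_truth(result: ClassificationResult,
                       indel_errors: list[ErrorRecord],
                       truth: TruthTable) -> RecoveryMetrics:
    """Sensitivity/precision of error recovery and allele-class separation."""
    true_small = {
        (e.chrom, e.pos): e
        for e in truth.assembly_errors
        if e.type in ("substitution", "insertion", "deletion")
    }
    called = {(r.chrom, r.position): r for r in result.error_records}
    for r in indel_errors:
        called[(r.chrom, r.position)] = r

    tp = 0
    for key, te in true_small.items():
        cr = called.get(key)
        if cr is None:
            continue
        if te.type == "substitution" and cr.type == "snp" and cr.corrected_allele == te.true_allele:
            tp += 1
        elif te.type == "insertion" and cr.type == "insertion" and cr.corrected_allele == te.true_allele:
            tp += 1
        elif te.type == "deletion" and cr.type == "deletion" and cr.size == te.size:
            tp += 1
    n_called = len(called)

    by_pos = {(c.chrom, c.position): c for c in result.calls}
    within_hit = sum(
        1
        for s in truth.within_sites
        if (c := by_pos.get((s.chrom, s.pos))) is not None
        and c.combined == "allele_within"
        and (c.carrier in (s.carrier, None, "both"))
    )
    between_hit = sum(
        1
        for s in truth.between_sites
        if (c := by_pos.get((s.chrom, s.pos))) is not None and c.combined == "allele_between"
    )
    confusions = 0
    for s in truth.within_sites + truth.between_sites:
        c = by_pos.get((s.chrom, s.pos))
        if c is not None and c.combined == "sequencing_error":
            confusions += 1
    for key in true_small:
        c = by_pos.get(key)
        if c is not None and c.combined in ("allele_within", "allele_between"):
            confusions += 1

    n_true = len(true_small)
    return RecoveryMetrics(
        error_sensitivity=tp / n_true if n_true else 1.0,
        error_precision=tp / n_called if n_called else 1.0,
        within_sensitivity=within_hit / len(truth.within_sites) if truth.within_sites else 1.0,
        between_sensitivity=between_hit / len(truth.between_sites) if truth.between_sites else 1.0,
        n_true_errors=n_true,
        n_called_errors=len(called),
        cross_class_confusions=confusions,
    )
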