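"""Synthetic study generator.

Builds a toy "true" genome (the genome the sequenced individuals
actually carry), derives an erroneous assembly from it by injecting
substitution errors, 1-4 bp indel errors, large (>=100 bp) indel errors
and N-filled physical gaps, creates two diploid individuals carrying
homozygous between-individual differences and heterozygous
within-individual sites, and samples short reads, long reads and a
noisy optical (restriction) map — all with a recorded ground truth so
every downstream stage of the pipeline can be scored.

Conventions:

* "insertion" error: the assembly is MISSING bases the individuals
  carry (a correction must insert them). Large insertion errors are
  modelled as collapsed tandem duplications — the individuals carry two
  adjacent copies of a unit, the assembly only one — because that is
  the only large-insertion geometry a split-alignment detector with a
  read-coverage rule can recover from ~377 bp reads.
* "deletion" error: the assembly carries extra bases absent from the
  individuals (a correction must delete them).
* Truth positions are 0-based assembly coordinates; small-indel truth
  anchors are left-normalized against the assembly so they can be
  compared directly with pileup-derived calls.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from .config import SimConfig
from .genemodels import GeneModel
from .readprep import Read
from .sequences import BASES, decode, encode, revcomp_codes

# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class AssemblyError:
    chrom: str
    pos: int                  # 0-based assembly coordinate (anchor for indels)
    type: str                 # substitution | insertion | deletion | large_insertion | large_deletion
    ref_allele: str           # what the assembly says
    true_allele: str          # what the individuals carry
    size: int


@dataclass(frozen=True)
class AlleleSite:
    chrom: str
    pos: int                  # assembly coordinate
    true_pos: int             # true-genome coordinate
    ref_allele: str
    alt_allele: str
    carrier: str              # individual name; for between sites, the alt carrier


@dataclass(frozen=True)
class GapRecord:
    chrom: str
    start: int                # assembly coordinate of the N run
    n_length: int             # placeholder length (1,000 Ns)
    true_size: int            # size of the missing true sequence


@dataclass
class TruthTable:
    assembly_errors: list[AssemblyError] = field(default_factory=list)
    between_sites: list[AlleleSite] = field(default_factory=list)
    within_sites: list[AlleleSite] = field(default_factory=list)
    gaps: list[GapRecord] = field(default_factory=list)

    def validate_disjoint(self) -> None:
        seen: set[tuple[str, int]] = set()
        for rec in (*self.assembly_errors, *self.between_sites, *self.within_sites):
            key = (rec.chrom, rec.pos)
            if key in seen:
                raise ValueError(f"truth categories collide at {key}")
            seen.add(key)

    def write_tsv(self, path) -> None:
        import pandas as pd

        rows = [
            dict(category="assembly_error", chrom=e.chrom, pos=e.pos, type=e.type,
                 ref=e.ref_allele, alt=e.true_allele, size=e.size, carrier="")
            for e in self.assembly_errors
        ]
        rows += [
            dict(category="between", chrom=s.chrom, pos=s.pos, type="snp",
                 ref=s.ref_allele, alt=s.alt_allele, size=1, carrier=s.carrier)
            for s in self.between_sites
        ]
        rows += [
            dict(category="within", chrom=s.chrom, pos=s.pos, type="snp",
                 ref=s.ref_allele, alt=s.alt_allele, size=1, carrier=s.carrier)
            for s in self.within_sites
        ]
        rows += [
            dict(category="gap", chrom=g.chrom, pos=g.start, type="gap",
                 ref="", alt="", size=g.true_size, carrier="")
            for g in self.gaps
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class TrueGenome:
    chroms: dict[str, np.ndarray]
    repeat_intervals: dict[str, list[tuple[int, int]]]
    dup_loci: list[tuple[str, int, int]]     # (chrom, start of first copy, unit size)
    genes: list[GeneModel]

    def length(self) -> int:
        return sum(len(c) for c in self.chroms.values())


@dataclass
class Individual:
    name: str
    haplotypes: list[dict[str, np.ndarray]]   # exactly two


@dataclass
class SimulatedStudy:
    config: SimConfig
    true_genome: TrueGenome
    assembly: dict[str, np.ndarray]
    truth: TruthTable
    individuals: tuple[Individual, Individual]


# ---------------------------------------------------------------------------
# helpers


class _Space:
    """Tracks blocked intervals on one chromosome for site placement."""

    def __init__(self, length: int, blocked: list[tuple[int, int]], end_margin: int = 1000):
        merged: list[tuple[int, int]] = []
        blocked = sorted(
            [(max(0, s), min(length, e)) for s, e in blocked]
            + [(0, min(end_margin, length)), (max(0, length - end_margin), length)]
        )
        for s, e in blocked:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        self.length = length
        self.starts = [s for s, _ in merged]
        self.ends = [e for _, e in merged]

    def is_free(self, s: int, e: int) -> bool:
        if s < 0 or e > self.length:
            return False
        i = bisect.bisect_right(self.starts, s) - 1
        if i >= 0 and self.ends[i] > s:
            return False
        if i + 1 < len(self.starts) and self.starts[i + 1] < e:
            return False
        return True

    def block(self, s: int, e: int) -> None:
        i = bisect.bisect_left(self.starts, s)
        self.starts.insert(i, s)
        self.ends.insert(i, e)


def _place(rng, space: _Space, span: int, margin: int, tries: int = 2000,
           predicate=None) -> int:
    for _ in range(tries):
        s = int(rng.integers(0, space.length - span))
        if space.is_free(s - margin, s + span + margin) and (
            predicate is None or predicate(s)
        ):
            space.block(s - margin, s + span + margin)
            return s
    raise RuntimeError("insufficient placeable space for requested events")


def left_align_indel(ref: np.ndarray, anchor: int, kind: str, alleles: np.ndarray):
    """Left-normalize an anchored indel against a reference code array.

    For a deletion, ``alleles`` are the deleted reference bases at
    ``[anchor+1, anchor+1+k)``. For an insertion, ``alleles`` are the
    inserted bases placed after ``anchor``. Returns (anchor, alleles).
    """
    alleles = np.asarray(alleles, dtype=np.uint8).copy()
    k = len(alleles)
    if kind == "del":
        while anchor > 0 and ref[anchor + k] == ref[anchor]:
            anchor -= 1
        alleles = ref[anchor + 1 : anchor + 1 + k].copy()
    elif kind == "ins":
        while anchor > 0 and ref[anchor] == alleles[-1]:
            alleles = np.concatenate(([alleles[-1]], alleles[:-1]))
            anchor -= 1
    else:
        raise ValueError(kind)
    return anchor, alleles


def _other_base(rng, base: int) -> int:
    return int((base + rng.integers(1, 4)) % 4)


# ---------------------------------------------------------------------------
# genome


def simulate_genome(config: SimConfig) -> TrueGenome:
    rng = config.rng("genome")
    gc = config.gc_fraction
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    n_chrom = config.n_chromosomes
    base_len = config.genome_length // n_chrom
    chroms: dict[str, np.ndarray] = {}
    repeat_intervals: dict[str, list[tuple[int, int]]] = {}
    names = [f"chr{i + 1:02d}" for i in range(n_chrom)]
    for name in names:
        chroms[name] = rng.choice(4, size=base_len, p=p).astype(np.uint8)
        repeat_intervals[name] = []

    # exact repeat copies: sampled units pasted elsewhere on the same chromosome
    target = config.repeat_fraction * config.genome_length
    placed = 0.0
    lo, hi = config.repeat_unit_range
    attempts = 0
    while placed < target and attempts < 10_000:
        attempts += 1
        name = names[int(rng.integers(n_chrom))]
        seq = chroms[name]
        unit = int(rng.integers(lo, hi + 1))
        if len(seq) < 4 * unit:
            continue
        src = int(rng.integers(0, len(seq) - unit))
        dst = int(rng.integers(0, len(seq) - unit))
        zones = repeat_intervals[name]
        def clash(s, e):
            return any(s < ze + 100 and e > zs - 100 for zs, ze in zones)
        if abs(dst - src) < unit + 100 or clash(src, src + unit) or clash(dst, dst + unit):
            continue
        seq[dst : dst + unit] = seq[src : src + unit]
        zones.extend([(src, src + unit), (dst, dst + unit)])
        placed += 2 * unit
    for name in names:
        repeat_intervals[name].sort()

    # tandem-duplication loci consumed by large insertion-type errors
    dup_loci: list[tuple[str, int, int]] = []
    K = config.large_insertion_size
    for i in range(config.n_large_insertions):
        name = names[int(rng.integers(n_chrom))]
        seq = chroms[name]
        space = _Space(len(seq), repeat_intervals[name])
        t = _place(rng, space, 2 * K, margin=500)
        seq[t + K : t + 2 * K] = seq[t : t + K]
        dup_loci.append((name, t, K))

    genes = _simulate_genes(config, rng, chroms)
    return TrueGenome(chroms, repeat_intervals, dup_loci, genes)


def _simulate_genes(config: SimConfig, rng, chroms) -> list[GeneModel]:
    genes: list[GeneModel] = []
    names = list(chroms)
    taken: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    for gi in range(config.n_genes):
        # structure along the transcription direction
        utr5 = int(rng.integers(100, 301))
        utr3 = int(rng.integers(100, 301))
        n_cds = int(rng.integers(2, 5))
        cds_lens = [int(rng.integers(150, 601)) for _ in range(n_cds)]
        excess = sum(cds_lens) % 3
        cds_lens[-1] -= excess
        introns = [int(rng.integers(100, 501)) for _ in range(n_cds + 1)]
        span = utr5 + utr3 + sum(cds_lens) + sum(introns)

        chrom = names[int(rng.integers(len(names)))]
        L = len(chroms[chrom])
        if span + 2000 > L:
            raise ValueError("gene longer than chromosome")
        placed = False
        for _ in range(200):
            s = int(rng.integers(1000, L - span - 1000))
            if all(s >= e + 200 or s + span <= b - 200 for b, e in taken[chrom]):
                placed = True
                break
        if not placed:
            continue
        taken[chrom].append((s, s + span))

        strand = "+" if rng.random() < 0.5 else "-"
        # genomic layout left->right; for '-' the 5'UTR sits at the right end
        blocks: list[tuple[str, int]] = [("utr5", utr5), ("intron", introns[0])]
        for i, cl in enumerate(cds_lens):
            blocks.append(("cds", cl))
            blocks.append(("intron", introns[i + 1]))
        blocks.append(("utr3", utr3))
        if strand == "-":
            blocks = blocks[::-1]
        pos = s
        exons, cds, u5, u3 = [], [], [], []
        for kind, ln in blocks:
            iv = (pos, pos + ln)
            if kind != "intron":
                exons.append(iv)
            if kind == "cds":
                cds.append(iv)
            elif kind == "utr5":
                u5.append(iv)
            elif kind == "utr3":
                u3.append(iv)
            pos += ln
        genes.append(GeneModel(f"gene{gi + 1:03d}", chrom, strand, exons, cds, u5, u3))
    return genes


# ---------------------------------------------------------------------------
# assembly errors, allele sites


def inject_assembly_errors(
    true_genome: TrueGenome, config: SimConfig
) -> tuple[dict[str, np.ndarray], TruthTable]:
    """Derive the erroneous assembly and the full ground-truth table.

    Also allocates the between-/within-individual allele site positions
    (so that all truth categories stay disjoint); the allele edits
    themselves are applied by :func:`simulate_individuals`.
    """
    rng = config.rng("errors")
    names = list(true_genome.chroms)
    spaces = {
        n: _Space(
            len(true_genome.chroms[n]),
            [(s - 150, e + 150) for s, e in true_genome.repeat_intervals[n]]
            + [(t - 500, t + 2 * k + 500) for c, t, k in true_genome.dup_loci if c == n],
        )
        for n in names
    }

    # events in true-genome coordinates: (chrom, tpos, kind, payload)
    events: dict[str, list[tuple[int, str, object]]] = {n: [] for n in names}

    def rand_chrom():
        return names[int(rng.integers(len(names)))]

    # large events: >=10 kb from one another, modest margin to point sites
    large_positions: dict[str, list[int]] = {n: [] for n in names}
    for chrom, t, k in true_genome.dup_loci[: config.n_large_insertions]:
        events[chrom].append((t, "large_ins", k))
        large_positions[chrom].append(t)

    def far_from_large(c):
        return lambda s: all(abs(s - p) >= 10_000 for p in large_positions[c])

    for _ in range(config.n_large_deletions):
        c = rand_chrom()
        t = _place(rng, spaces[c], 1, margin=300, predicate=far_from_large(c))
        events[c].append((t, "large_del", config.large_deletion_size))
        large_positions[c].append(t)
    for _ in range(config.n_physical_gaps):
        c = rand_chrom()
        g = config.physical_gap_size
        t = _place(rng, spaces[c], g, margin=300, predicate=far_from_large(c))
        events[c].append((t, "gap", g))
        large_positions[c].append(t)

    def point_sites(n_sites, kind, payload_fn):
        for _ in range(n_sites):
            c = rand_chrom()
            t = _place(rng, spaces[c], 8, margin=50)
            events[c].append((t, kind, payload_fn()))

    point_sites(config.n_substitution_errors, "sub", lambda: None)
    point_sites(config.n_insertion_errors, "ins_err", lambda: int(rng.integers(1, 5)))
    point_sites(config.n_deletion_errors, "del_err", lambda: int(rng.integers(1, 5)))
    point_sites(config.n_between_sites, "between", lambda: None)
    point_sites(config.n_within_sites, "within", lambda: None)

    truth = TruthTable()
    assembly: dict[str, np.ndarray] = {}
    for chrom in names:
        seq = true_genome.chroms[chrom]
        parts: list[np.ndarray] = []
        new_len = 0
        prev = 0
        pending_alleles: list[tuple[int, int, str]] = []  # (true_pos, asm_pos, kind)

        def emit(upto):
            nonlocal new_len, prev
            parts.append(seq[prev:upto])
            new_len += upto - prev
            prev = upto

        for t, kind, payload in sorted(events[chrom]):
            if kind == "sub":
                emit(t)
                alt = _other_base(rng, int(seq[t]))
                parts.append(np.array([alt], dtype=np.uint8))
                truth.assembly_errors.append(
                    AssemblyError(chrom, new_len, "substitution",
                                  BASES[alt], BASES[int(seq[t])], 1)
                )
                new_len += 1
                prev = t + 1
            elif kind == "ins_err":       # assembly missing k true bases
                k = payload
                emit(t + 1)
                truth.assembly_errors.append(
                    AssemblyError(chrom, new_len - 1, "insertion",
                                  BASES[int(seq[t])], decode(seq[t + 1 : t + 1 + k]), k)
                )
                prev = t + 1 + k
            elif kind == "del_err":       # assembly carries k extra bases
                k = payload
                emit(t + 1)
                extra = rng.integers(0, 4, size=k).astype(np.uint8)
                truth.assembly_errors.append(
                    AssemblyError(chrom, new_len - 1, "deletion",
                                  decode(extra), "", k)
                )
                parts.append(extra)
                new_len += k
            elif kind == "large_ins":     # collapsed tandem copy
                k = payload
                emit(t + k)
                truth.assembly_errors.append(
                    AssemblyError(chrom, new_len - 1, "large_insertion",
                                  BASES[int(seq[t + k - 1])],
                                  decode(seq[t + k : t + 2 * k]), k)
                )
                prev = t + 2 * k
            elif kind == "large_del":
                k = payload
                emit(t + 1)
                extra = rng.integers(0, 4, size=k).astype(np.uint8)
                truth.assembly_errors.append(
                    AssemblyError(chrom, new_len - 1, "large_deletion",
                                  "", "", k)
                )
                parts.append(extra)
                new_len += k
            elif kind == "gap":
                g = payload
                emit(t)
                truth.gaps.append(GapRecord(chrom, new_len, 1000, g))
                parts.append(np.full(1000, 4, dtype=np.uint8))   # Ns
                new_len += 1000
                prev = t + g
            elif kind in ("between", "within"):
                emit(t + 1)
                pending_alleles.append((t, new_len - 1, kind))
            else:  # pragma: no cover
                raise AssertionError(kind)
        emit(len(seq))
        assembly[chrom] = np.concatenate(parts) if parts else seq.copy()

        # materialize allele truth records (alleles assigned here, applied later)
        for t, apos, kind in pending_alleles:
            ref_base = BASES[int(seq[t])]
            alt = BASES[_other_base(rng, int(seq[t]))]
            carrier = "NIAS_like" if rng.random() < 0.5 else "CSHL_like"
            rec = AlleleSite(chrom, apos, t, ref_base, alt, carrier)
            (truth.between_sites if kind == "between" else truth.within_sites).append(rec)

    _normalize_indel_truth(assembly, truth)
    truth.validate_disjoint()
    return assembly, truth


def _normalize_indel_truth(assembly, truth: TruthTable) -> None:
    normalized = []
    for e in truth.assembly_errors:
        if e.type == "insertion":
            anchor, alleles = left_align_indel(
                assembly[e.chrom], e.pos, "ins", encode(e.true_allele)
            )
            normalized.append(
                AssemblyError(e.chrom, anchor, e.type,
                              BASES[int(assembly[e.chrom][anchor])],
                              decode(alleles), e.size)
            )
        elif e.type == "deletion":
            anchor, alleles = left_align_indel(
                assembly[e.chrom], e.pos, "del", encode(e.ref_allele)
            )
            normalized.append(
                AssemblyError(e.chrom, anchor, e.type, decode(alleles), "", e.size)
            )
        else:
            normalized.append(e)
    truth.assembly_errors = normalized


def simulate_individuals(
    true_genome: TrueGenome, truth: TruthTable, config: SimConfig
) -> tuple[Individual, Individual]:
    """Two diploid individuals: between sites homozygous-different,
    within sites heterozygous in exactly the recorded carrier."""
    ind = {
        name: Individual(
            name,
            [
                {c: s.copy() for c, s in true_genome.chroms.items()},
                {c: s.copy() for c, s in true_genome.chroms.items()},
            ],
        )
        for name in ("NIAS_like", "CSHL_like")
    }
    for site in truth.between_sites:
        alt = encode(site.alt_allele)[0]
        for hap in ind[site.carrier].haplotypes:
            hap[site.chrom][site.true_pos] = alt
    for site in truth.within_sites:
        alt = encode(site.alt_allele)[0]
        ind[site.carrier].haplotypes[1][site.chrom][site.true_pos] = alt
    return ind["NIAS_like"], ind["CSHL_like"]


# ---------------------------------------------------------------------------
# reads


def _qualities(rng, n: int, lengths: np.ndarray, config: SimConfig) -> list[np.ndarray]:
    t5 = rng.geometric(config.low_quality_tail_prob, size=n) - 1
    t3 = rng.geometric(config.low_quality_tail_prob, size=n) - 1
    quals = []
    for i in range(n):
        rl = int(lengths[i])
        q = np.full(rl, config.quality_mean, dtype=np.int16)
        a = min(int(t5[i]), rl // 3)
        b = min(int(t3[i]), rl // 3)
        if a:
            q[:a] = rng.integers(2, 16, size=a)
        if b:
            q[rl - b :] = rng.integers(2, 16, size=b)
        quals.append(q)
    return quals


def _apply_errors(rng, codes: np.ndarray, rate: float) -> np.ndarray:
    n_err = rng.binomial(len(codes), rate)
    if n_err:
        pos = rng.choice(len(codes), size=n_err, replace=False)
        codes = codes.copy()
        codes[pos] = (codes[pos] + rng.integers(1, 4, size=n_err)) % 4
    return codes


def _chrom_choice(rng, haps: list[dict[str, np.ndarray]], n: int):
    names = list(haps[0])
    lengths = np.array([len(haps[0][c]) for c in names], dtype=float)
    ci = rng.choice(len(names), size=n, p=lengths / lengths.sum())
    return names, ci


def simulate_short_reads_single(
    individual: Individual, config: SimConfig, rng=None
) -> list[Read]:
    """Single-end library (dataset 1): mixed 36/51 bp reads."""
    rng = rng or config.rng(f"reads_se_{individual.name}")
    haps = individual.haplotypes
    G = sum(len(s) for s in haps[0].values())
    mean_len = float(np.mean(config.ds1_read_lengths))
    n = int(config.ds1_depth * G / mean_len)
    lengths = np.array(config.ds1_read_lengths)[
        rng.integers(0, len(config.ds1_read_lengths), size=n)
    ]
    names, ci = _chrom_choice(rng, haps, n)
    hap_i = rng.integers(0, 2, size=n)
    strands = rng.random(n) < 0.5
    quals = _qualities(rng, n, lengths, config)
    reads = []
    for i in range(n):
        chrom = names[int(ci[i])]
        seq = haps[int(hap_i[i])][chrom]
        rl = int(lengths[i])
        start = int(rng.integers(0, len(seq) - rl))
        codes = seq[start : start + rl]
        if strands[i]:
            codes = revcomp_codes(codes)
        codes = _apply_errors(rng, codes, config.read_error_rate)
        rid = f"ds1_{i}"
        reads.append(Read(rid, decode(codes), quals[i], "single"))
    return reads


def simulate_short_reads_paired(
    individual: Individual, config: SimConfig, rng=None
) -> list[tuple[Read, Read]]:
    """Paired-end library (dataset 2): 76 bp mates, insert ~150 bp,
    with occasional short inserts that read through into the adapter."""
    rng = rng or config.rng(f"reads_pe_{individual.name}")
    haps = individual.haplotypes
    G = sum(len(s) for s in haps[0].values())
    rl = config.ds2_read_length
    n = int(config.ds2_depth * G / (2 * rl))
    names, ci = _chrom_choice(rng, haps, n)
    hap_i = rng.integers(0, 2, size=n)
    flip = rng.random(n) < 0.5
    inserts = rng.normal(config.insert_mean, config.insert_sd, size=n).astype(int)
    short = rng.random(n) < config.adapter_readthrough_fraction
    inserts[short] = rng.integers(40, rl, size=int(short.sum()))
    inserts = np.clip(inserts, 36, None)
    adapter = encode(config.adapter)
    lengths = np.full(2 * n, rl)
    quals = _qualities(rng, 2 * n, lengths, config)
    pairs = []
    for i in range(n):
        chrom = names[int(ci[i])]
        seq = haps[int(hap_i[i])][chrom]
        ins = int(min(inserts[i], len(seq) - 1))
        start = int(rng.integers(0, len(seq) - ins))
        frag = seq[start : start + ins]
        if flip[i]:
            frag = revcomp_codes(frag)
        def mate(codes_fwd):
            if len(codes_fwd) >= rl:
                return codes_fwd[:rl]
            pad = rl - len(codes_fwd) - len(adapter)
            tail = adapter if pad <= 0 else np.concatenate(
                [adapter, rng.integers(0, 4, size=pad).astype(np.uint8)]
            )
            return np.concatenate([codes_fwd, tail])[:rl]
        m1 = _apply_errors(rng, mate(frag), config.read_error_rate)
        m2 = _apply_errors(rng, mate(revcomp_codes(frag)), config.read_error_rate)
        rid = f"ds2_{i}"
        pairs.append(
            (
                Read(rid, decode(m1), quals[2 * i], "mate1"),
                Read(rid, decode(m2), quals[2 * i + 1], "mate2"),
            )
        )
    return pairs


def simulate_long_reads(
    individual: Individual, config: SimConfig, rng=None
) -> list[Read]:
    """Long single-end reads (mean length ~377 bp)."""
    rng = rng or config.rng(f"reads_long_{individual.name}")
    haps = individual.haplotypes
    G = sum(len(s) for s in haps[0].values())
    n = int(config.long_read_depth * G / config.long_read_mean_length)
    lengths = rng.normal(
        config.long_read_mean_length, config.long_read_sd_length, size=n
    ).astype(int)
    lengths = np.clip(lengths, config.long_read_min_length, None)
    names, ci = _chrom_choice(rng, haps, n)
    hap_i = rng.integers(0, 2, size=n)
    strands = rng.random(n) < 0.5
    reads = []
    for i in range(n):
        chrom = names[int(ci[i])]
        seq = haps[int(hap_i[i])][chrom]
        rl = int(min(lengths[i], len(seq) - 1))
        start = int(rng.integers(0, len(seq) - rl))
        codes = seq[start : start + rl]
        if strands[i]:
            codes = revcomp_codes(codes)
        codes = _apply_errors(rng, codes, config.long_read_error_rate)
        q = np.full(rl, config.quality_mean, dtype=np.int16)
        reads.append(Read(f"lr_{i}", decode(codes), q, "single"))
    return reads


# ---------------------------------------------------------------------------
# optical map


def simulate_optical_map(true_genome: TrueGenome, config: SimConfig, rng=None):
    """Noisy optical map of the true genome, one map per chromosome."""
    from .optical import RestrictionMap, digest_in_silico

    rng = rng or config.rng("optical")
    maps = []
    for chrom, seq in true_genome.chroms.items():
        exact = digest_in_silico(seq, map_id=chrom)
        frags = np.asarray(exact.fragments, dtype=np.int64)
        # missing cuts: merge neighbours
        if len(frags) > 1:
            keep = rng.random(len(frags) - 1) >= config.optical_missing_cut_prob
            bounds = np.concatenate([[0], np.flatnonzero(keep) + 1])
            frags = np.add.reduceat(frags, bounds)
        # extra cuts: split fragments
        out = []
        for f in frags:
            if f > 2 and rng.random() < config.optical_extra_cut_prob:
                u = rng.uniform(0.1, 0.9)
                out.extend([int(f * u), f - int(f * u)])
            else:
                out.append(int(f))
        frags = np.array(out, dtype=np.int64)
        # multiplicative sizing noise
        if config.optical_cv > 0:
            frags = np.maximum(
                1, np.round(frags * rng.normal(1.0, config.optical_cv, size=len(frags)))
            ).astype(np.int64)
        frags = frags[frags >= config.optical_min_fragment]
        maps.append(RestrictionMap(map_id=chrom, fragments=list(map(int, frags)), source="optical"))
    return maps


# ---------------------------------------------------------------------------
# orchestration


def simulate_study(config: SimConfig) -> SimulatedStudy:
    true_genome = simulate_genome(config)
    assembly, truth = inject_assembly_errors(true_genome, config)
    ind1, ind2 = simulate_individuals(true_genome, truth, config)
    return SimulatedStudy(config, true_genome, assembly, truth, (ind1, ind2))
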