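"""In-silico restriction digestion and optical-map concordance.

Sequences are digested with SwaI (recognition ATTTAAAT, blunt cut after
position 4) and the resulting ordered fragment-length list is aligned
against an optical map by dynamic programming. A matched block pairs a
run of up to ``max_merge`` in-silico fragments with a run of optical
fragments (runs longer than one absorb missing/extra cuts); fragments
can also be skipped (left unmatched). Block scores reward size
agreement relative to the sizing error model (sd = cv x length) and
penalize merges; skipping carries a flat per-fragment penalty. Ties
prefer fewer merged fragments, then the leftmost structure.

Discordances between the two maps fall into five classes: (1) an
annotated physical gap, (2) a missed/extra fragment of at least 5 kb,
(3) a significant size difference in a matched block, (4) multiple
different cut sites in one area, (5) multiple different cut sites plus
multiple unmatched fragments with non-comparable totals (possible
misassembly). Sub-5 kb missed/extra/size events are suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .sequences import decode

SWAI_SITE = "ATTTAAAT"
SWAI_CUT_OFFSET = 4

MIN_EVENT_BP = 5000
CLASS4_WINDOW = 100_000


@dataclass
class RestrictionMap:
    map_id: str
    fragments: list[int]
    source: str = "in_silico"            # in_silico | optical
    cut_positions: Optional[list[int]] = None   # sequence coords of cuts

    def total(self) -> int:
        return int(sum(self.fragments))

    def boundaries(self) -> list[int]:
        """Fragment start coordinates (requires cut positions or cumsum)."""
        if self.cut_positions is not None:
            return [0] + list(self.cut_positions)
        return [0] + list(np.cumsum(self.fragments)[:-1])


@dataclass
class AlignParams:
    cv: float = 0.05
    max_merge: int = 3
    match_bonus: float = 5.0
    # a merged fragment reflects a missed/extra cut; at a cut-error
    # probability of ~2% the log-odds cost is about -ln(0.02) ~ 3.9
    merge_penalty: float = 3.0
    skip_penalty: float = 3.0
    min_sigma: float = 500.0     # sizing-error floor for small fragments


@dataclass
class Block:
    s_range: tuple[int, int]     # in-silico fragment index run [i, j)
    o_range: tuple[int, int]     # optical fragment index run
    s_sum: int
    o_sum: int

    @property
    def size_diff(self) -> int:
        return self.o_sum - self.s_sum

    @property
    def n_merged(self) -> int:
        return (self.s_range[1] - self.s_range[0]) + (self.o_range[1] - self.o_range[0]) - 2


@dataclass
class MapAlignment:
    silico: RestrictionMap
    optical: RestrictionMap
    blocks: list[Block]
    unmatched_silico: list[tuple[int, int]]      # index runs
    unmatched_optical: list[tuple[int, int]]
    score: float
    walk: list[tuple] = field(default_factory=list)   # ordered items


@dataclass
class Discordance:
    cls: int
    location: tuple[int, int]    # assembly coordinates of the affected region
    magnitude: int               # bp
    detail: str = ""
    suggestion: str = ""


# ---------------------------------------------------------------------------
# digestion


def digest_in_silico(
    sequence: Union[str, np.ndarray],
    recognition: str = SWAI_SITE,
    cut_offset: int = SWAI_CUT_OFFSET,
    map_id: str = "map",
) -> RestrictionMap:
    """Non-overlapping restriction digest; N runs never match the site."""
    if isinstance(sequence, np.ndarray):
        sequence = decode(sequence)
    seq = sequence.upper()
    cuts: list[int] = []
    i = seq.find(recognition)
    while i != -1:
        cuts.append(i + cut_offset)
        i = seq.find(recognition, i + len(recognition))
    bounds = [0] + cuts + [len(seq)]
    frags = [b - a for a, b in zip(bounds, bounds[1:]) if b > a]
    return RestrictionMap(map_id, frags, "in_silico", cut_positions=cuts)


# ---------------------------------------------------------------------------
# alignment scoring


def block_score(s_sum: float, o_sum: float, n_s: int, n_o: int, p: AlignParams) -> float:
    sigma = max(p.cv * max(s_sum, o_sum), p.min_sigma)
    chi2 = ((s_sum - o_sum) / sigma) ** 2
    return p.match_bonus - p.merge_penalty * (n_s + n_o - 2) - chi2


def align_maps(
    silico: RestrictionMap, optical: RestrictionMap, params: Optional[AlignParams] = None
) -> MapAlignment:
    """Optimal-score order-preserving alignment by dynamic programming."""
    p = params or AlignParams()
    s = list(silico.fragments)
    o = list(optical.fragments)
    n, m = len(s), len(o)
    if n == 0 or m == 0:
        raise ValueError("maps must be non-empty")
    cs = np.concatenate([[0], np.cumsum(s)])
    co = np.concatenate([[0], np.cumsum(o)])

    NEG = (-np.inf, 0)
    # dp value: (score, -merged_fragments); back: (kind, a, b)
    dp = [[NEG] * (m + 1) for _ in range(n + 1)]
    back: list[list[Optional[tuple]]] = [[None] * (m + 1) for _ in range(n + 1)]
    dp[0][0] = (0.0, 0)
    for i in range(n + 1):
        for j in range(m + 1):
            if dp[i][j][0] == -np.inf:
                continue
            cur = dp[i][j]
            # transitions enumerated in fixed order; strict improvement keeps
            # the earliest (leftmost) structure on exact ties
            if i < n:
                cand = (cur[0] - p.skip_penalty, cur[1])
                if cand > dp[i + 1][j]:
                    dp[i + 1][j] = cand
                    back[i + 1][j] = ("skip_s", i, j)
            if j < m:
                cand = (cur[0] - p.skip_penalty, cur[1])
                if cand > dp[i][j + 1]:
                    dp[i][j + 1] = cand
                    back[i][j + 1] = ("skip_o", i, j)
            for a in range(1, min(p.max_merge, n - i) + 1):
                for b in range(1, min(p.max_merge, m - j) + 1):
                    sc = block_score(
                        cs[i + a] - cs[i], co[j + b] - co[j], a, b, p
                    )
                    cand = (cur[0] + sc, cur[1] - (a + b - 2))
                    if cand > dp[i + a][j + b]:
                        dp[i + a][j + b] = cand
                        back[i + a][j + b] = ("block", i, j, a, b)

    # backtrack
    walk: list[tuple] = []
    i, j = n, m
    while (i, j) != (0, 0):
        step = back[i][j]
        if step is None:
            raise RuntimeError("alignment backtrack failed")
        if step[0] == "skip_s":
            walk.append(("skip_s", step[1]))
            i, j = step[1], step[2]
        elif step[0] == "skip_o":
            walk.append(("skip_o", step[2]))
            i, j = step[1], step[2]
        else:
            _, bi, bj, a, b = step
            walk.append(("block", bi, bj, a, b))
            i, j = bi, bj
    walk.reverse()

    blocks: list[Block] = []
    un_s: list[tuple[int, int]] = []
    un_o: list[tuple[int, int]] = []
    for item in walk:
        if item[0] == "block":
            _, bi, bj, a, b = item
            blocks.append(
                Block((bi, bi + a), (bj, bj + b),
                      int(cs[bi + a] - cs[bi]), int(co[bj + b] - co[bj]))
            )
        elif item[0] == "skip_s":
            idx = item[1]
            if un_s and un_s[-1][1] == idx:
                un_s[-1] = (un_s[-1][0], idx + 1)
            else:
                un_s.append((idx, idx + 1))
        else:
            idx = item[1]
            if un_o and un_o[-1][1] == idx:
                un_o[-1] = (un_o[-1][0], idx + 1)
            else:
                un_o.append((idx, idx + 1))
    return MapAlignment(silico, optical, blocks, un_s, un_o, dp[n][m][0], walk)


# ---------------------------------------------------------------------------
# discordance classification


@dataclass
class _Region:
    """Maximal run of consecutive unmatched fragments (either map)."""
    interval: tuple[int, int]       # assembly coordinates
    s_mass: int = 0
    o_mass: int = 0
    n_s: int = 0
    n_o: int = 0


@dataclass
class _BlockFeature:
    interval: tuple[int, int]
    diff: int                       # optical minus in-silico size
    merges: int                     # extra fragments absorbed in the block
    significant: bool               # size difference beyond sizing noise


def _walk_features(alignment: MapAlignment, params: AlignParams, min_event: int):
    """Linear pass over the walk -> ordered regions and block features."""
    sb = alignment.silico.boundaries()
    s_len = alignment.silico.fragments
    o_len = alignment.optical.fragments
    items: list = []
    open_region: Optional[_Region] = None
    next_silico = 0                 # assembly coordinate of the next silico fragment

    def close():
        nonlocal open_region
        if open_region is not None:
            items.append(open_region)
            open_region = None

    for item in alignment.walk:
        if item[0] == "block":
            close()
            _, bi, bj, a, b = item
            start = sb[bi]
            end = sb[bi + a - 1] + s_len[bi + a - 1]
            s_sum = sum(s_len[bi : bi + a])
            o_sum = sum(o_len[bj : bj + b])
            diff = o_sum - s_sum
            items.append(
                _BlockFeature((start, end), diff, a + b - 2, abs(diff) >= min_event)
            )
            next_silico = end
        elif item[0] == "skip_s":
            idx = item[1]
            start, end = sb[idx], sb[idx] + s_len[idx]
            if open_region is None:
                open_region = _Region((start, end))
            else:
                open_region.interval = (open_region.interval[0], end)
            open_region.s_mass += s_len[idx]
            open_region.n_s += 1
            next_silico = end
        else:
            idx = item[1]
            if open_region is None:
                open_region = _Region((next_silico, next_silico))
            open_region.o_mass += o_len[idx]
            open_region.n_o += 1
    close()
    return items


@dataclass
class _Locus:
    """Adjacent discordant items merged into one candidate locus."""
    interval: tuple[int, int]
    s_mass: int = 0
    o_mass: int = 0
    n_s: int = 0
    n_o: int = 0
    diffs: list = field(default_factory=list)     # block size excesses
    merges: int = 0
    significant: bool = False

    def absorb(self, it) -> None:
        self.interval = (min(self.interval[0], it.interval[0]),
                         max(self.interval[1], it.interval[1]))
        if isinstance(it, _Region):
            self.s_mass += it.s_mass
            self.o_mass += it.o_mass
            self.n_s += it.n_s
            self.n_o += it.n_o
        else:
            self.diffs.append(it.diff)
            self.merges += it.merges
            self.significant |= it.significant


def _discordant_loci(alignment: MapAlignment, params: AlignParams,
                     min_event: int) -> list[_Locus]:
    items = _walk_features(alignment, params, min_event)
    loci: list[_Locus] = []
    cur: Optional[_Locus] = None
    for it in items:
        discordant = isinstance(it, _Region) or it.merges > 0 or it.significant
        if discordant:
            if cur is None:
                cur = _Locus(it.interval)
                loci.append(cur)
            cur.absorb(it)
        else:
            cur = None
    return loci


def classify_discordances(
    alignment: MapAlignment,
    gap_annotations: Sequence[tuple[int, int]] = (),
    params: Optional[AlignParams] = None,
    min_event: int = MIN_EVENT_BP,
) -> list[Discordance]:
    """Assign each discordant locus exactly one of the five classes."""
    p = params or AlignParams()
    loci = _discordant_loci(alignment, p, min_event)
    out: list[Discordance] = []

    def overlaps_gap(iv):
        return any(iv[0] <= ge and iv[1] >= gs for gs, ge in gap_annotations)

    cut_candidates: list[_Locus] = []
    for lc in loci:
        excess = lc.o_mass + sum(d for d in lc.diffs if d > 0)
        if overlaps_gap(lc.interval):
            out.append(
                Discordance(1, lc.interval, excess,
                            detail="physical gap; size from unmatched optical fragments")
            )
            continue
        comparable = abs(lc.s_mass - lc.o_mass) <= 0.1 * max(lc.s_mass, lc.o_mass, 1)
        region_mass = max(lc.s_mass, lc.o_mass)
        if lc.n_s == 1 and lc.n_o == 1:
            # one fragment unmatched on each side at the same locus: the
            # same fragment with a large size difference
            if abs(lc.s_mass - lc.o_mass) >= min_event:
                out.append(
                    Discordance(3, lc.interval, abs(lc.s_mass - lc.o_mass),
                                detail="significant size difference")
                )
            else:
                cut_candidates.append(lc)
        elif (
            lc.n_s + lc.n_o >= 3 and lc.n_s >= 1 and lc.n_o >= 1
            and not comparable and lc.s_mass + lc.o_mass >= min_event
        ):
            out.append(
                Discordance(5, lc.interval, lc.s_mass + lc.o_mass,
                            detail="multiple different cut sites and unmatched fragments",
                            suggestion="inspect tiling path for possible misassembly")
            )
        elif lc.n_s >= 1 and lc.n_o >= 1 and comparable:
            cut_candidates.append(lc)       # rearranged cuts, matching totals
        elif region_mass >= min_event:
            which = "missed" if lc.s_mass >= lc.o_mass else "extra"
            out.append(
                Discordance(2, lc.interval, region_mass, detail=f"{which} fragment",
                            suggestion="check for a clone extending into this region")
            )
        elif lc.significant:
            out.append(
                Discordance(3, lc.interval, sum(abs(d) for d in lc.diffs),
                            detail="significant size difference")
            )
        elif lc.merges or lc.n_s + lc.n_o:
            cut_candidates.append(lc)

    # class 4: >=2 remaining cut-site disagreements within a window
    i = 0
    while i < len(cut_candidates):
        j = i
        while (
            j + 1 < len(cut_candidates)
            and cut_candidates[j + 1].interval[0] - cut_candidates[j].interval[1]
            <= CLASS4_WINDOW
        ):
            j += 1
        if j > i:
            span = (cut_candidates[i].interval[0], cut_candidates[j].interval[1])
            mag = sum(sum(abs(d) for d in c.diffs) for c in cut_candidates[i : j + 1])
            out.append(
                Discordance(4, span, mag,
                            detail="multiple different cut sites in the same area")
            )
        i = j + 1
    out.sort(key=lambda d: d.location)
    return out


def estimate_gap_size(alignment: MapAlignment, gap_location: tuple[int, int],
                      params: Optional[AlignParams] = None) -> tuple[int, bool]:
    """Gap size from the unmatched optical fragments at the gap location
    (plus the optical excess of any block the gap aligned inside).

    Returns (size_bp, supported); ``supported`` is False when the map
    shows nothing at the gap.
    """
    p = params or AlignParams()
    gs, ge = gap_location
    total = 0
    for lc in _discordant_loci(alignment, p, MIN_EVENT_BP):
        s, e = lc.interval
        if s <= ge and e >= gs:
            total += lc.o_mass + sum(d for d in lc.diffs if d > 0)
    return total, total > 0


# ---------------------------------------------------------------------------
# fragment-list I/O (one map per line: map_id <tab> length <tab> length ...)


def write_fragment_lists(path, maps: Sequence[RestrictionMap]) -> None:
    with open(path, "w") as fh:
        for m in maps:
            fh.write("\t".join([m.map_id, *map(str, m.fragments)]) + "\n")


def read_fragment_lists(path, source: str = "optical") -> list[RestrictionMap]:
    maps = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            maps.append(RestrictionMap(parts[0], [int(x) for x in parts[1:]], source))
    return maps
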