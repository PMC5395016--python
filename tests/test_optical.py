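"""In-silico digestion, map alignment DP vs brute force, discordances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from refgrade.optical import (
    AlignParams,
    RestrictionMap,
    align_maps,
    block_score,
    classify_discordances,
    digest_in_silico,
    estimate_gap_size,
    read_fragment_lists,
    write_fragment_lists,
)

SITE = "ATTTAAAT"


def seq_without_site(n, seed=0):
    rng = np.random.default_rng(seed)
    while True:
        s = "".join(rng.choice(list("ACGT"), size=n))
        if SITE not in s:
            return s


class TestDigest:
    def test_no_site_single_full_length_fragment(self):
        s = seq_without_site(5_000)
        m = digest_in_silico(s)
        assert m.fragments == [5_000]

    def test_cut_offset_arithmetic(self):
        # one site starting at 0-based 3,996: blunt cut after 4 bases
        s = seq_without_site(10_000)
        s = s[:3_996] + SITE + s[3_996 + 8 :]
        if SITE in (s[:3_996] + "X" + s[4_004:]):  # paranoia: a second site
            pytest.skip("accidental second site")
        m = digest_in_silico(s)
        assert m.fragments == [4_000, 6_000]
        # string-split oracle
        assert s[:4_000].endswith("ATTT") and s[4_000:].startswith("AAAT")

    def test_two_sites_three_fragments_conserve_length(self):
        s = seq_without_site(9_000, seed=1)
        s = s[:2_000] + SITE + s[2_008:5_000] + SITE + s[5_008:]
        m = digest_in_silico(s)
        assert len(m.fragments) == 3
        assert sum(m.fragments) == len(s)

    def test_n_runs_never_match(self):
        s = "ATTT" + "N" * 4 + seq_without_site(100, seed=2)
        m = digest_in_silico(s)
        assert len(m.fragments) == 1

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=400))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_conservation_for_arbitrary_sequences(self, s):
        m = digest_in_silico(s)
        assert sum(m.fragments) == len(s)


def brute_force_alignment(s, o, p: AlignParams):
    """Independent oracle: enumerate every order-preserving alignment."""
    best = {}

    def rec(i, j, score, merges, blocks):
        if i == len(s) and j == len(o):
            key = (score, -merges)
            if "best" not in best or key > best["best"][0]:
                best["best"] = (key, list(blocks))
            return
        if i < len(s):
            rec(i + 1, j, score - p.skip_penalty, merges, blocks)
        if j < len(o):
            rec(i, j + 1, score - p.skip_penalty, merges, blocks)
        for a in range(1, min(p.max_merge, len(s) - i) + 1):
            for b in range(1, min(p.max_merge, len(o) - j) + 1):
                sc = block_score(sum(s[i : i + a]), sum(o[j : j + b]), a, b, p)
                blocks.append(((i, i + a), (j, j + b)))
                rec(i + a, j + b, score + sc, merges + (a + b - 2), blocks)
                blocks.pop()

    rec(0, 0, 0.0, 0, [])
    return best["best"]


class TestAlignMaps:
    def test_identical_maps_align_one_to_one(self):
        frags = [50_000, 30_000, 70_000]
        aln = align_maps(RestrictionMap("s", frags), RestrictionMap("o", list(frags)))
        assert len(aln.blocks) == 3
        assert all(b.n_merged == 0 for b in aln.blocks)
        assert aln.unmatched_silico == [] and aln.unmatched_optical == []

    def test_missing_cut_merges_two_fragments(self):
        sil = RestrictionMap("s", [50_000, 12_000, 18_000])
        opt = RestrictionMap("o", [50_000, 30_000])
        aln = align_maps(sil, opt)
        assert [(b.s_range, b.o_range) for b in aln.blocks] == [
            ((0, 1), (0, 1)),
            ((1, 3), (1, 2)),
        ]
        assert aln.unmatched_silico == [] and aln.unmatched_optical == []

    def test_absent_optical_fragment_left_unmatched(self):
        sil = RestrictionMap("s", [40_000, 6_000, 50_000])
        opt = RestrictionMap("o", [40_000, 50_000])
        aln = align_maps(sil, opt)
        assert aln.unmatched_silico == [(1, 2)]

    def test_dp_equals_brute_force_on_small_maps(self):
        rng = np.random.default_rng(5)
        p = AlignParams()
        for _ in range(40):
            n, m = int(rng.integers(1, 9)), int(rng.integers(1, 9))
            s = [int(rng.integers(2_000, 80_000)) for _ in range(n)]
            o = [int(rng.integers(2_000, 80_000)) for _ in range(m)]
            aln = align_maps(RestrictionMap("s", s), RestrictionMap("o", o), p)
            (bscore, bneg_merges), bblocks = brute_force_alignment(s, o, p)
            merges = sum(b.n_merged for b in aln.blocks)
            assert aln.score == pytest.approx(bscore, abs=1e-9)
            assert merges == -bneg_merges
            assert [(b.s_range, b.o_range) for b in aln.blocks] == bblocks


class TestDiscordances:
    def aln_for(self, sil, opt, **kw):
        p = AlignParams(**kw)
        return align_maps(sil, opt, p), p

    def test_unmatched_region_on_annotated_gap_is_class_1(self):
        sil = RestrictionMap("s", [40_000, 3_000, 50_000])
        opt = RestrictionMap("o", [40_000, 22_000, 50_000])
        aln, p = self.aln_for(sil, opt)
        ds = classify_discordances(aln, gap_annotations=[(41_000, 42_000)], params=p)
        assert [d.cls for d in ds] == [1]

    def test_extra_six_kb_optical_fragment_is_class_2(self):
        sil = RestrictionMap("s", [40_000, 50_000])
        opt = RestrictionMap("o", [40_000, 6_000, 50_000])
        aln, p = self.aln_for(sil, opt)
        ds = classify_discordances(aln, params=p)
        assert [d.cls for d in ds] == [2]
        assert ds[0].magnitude == 6_000

    def test_matched_block_size_jump_is_class_3(self):
        sil = RestrictionMap("s", [40_000, 10_000, 50_000])
        opt = RestrictionMap("o", [40_000, 16_000, 50_000])
        aln, p = self.aln_for(sil, opt)
        ds = classify_discordances(aln, params=p)
        assert [d.cls for d in ds] == [3]
        assert ds[0].magnitude == 6_000

    def test_sub_five_kb_event_suppressed(self):
        sil = RestrictionMap("s", [40_000, 50_000])
        opt = RestrictionMap("o", [40_000, 4_000, 50_000])
        aln, p = self.aln_for(sil, opt)
        assert classify_discordances(aln, params=p) == []

    def test_zero_noise_round_trip_no_discordances(self, small_sim):
        from refgrade.simulate import simulate_optical_map

        cfg = small_sim.config
        cfg0 = type(cfg)(**{**cfg.__dict__,
                            "optical_cv": 0.0, "optical_missing_cut_prob": 0.0,
                            "optical_extra_cut_prob": 0.0, "optical_min_fragment": 0})
        maps = {m.map_id: m for m in simulate_optical_map(small_sim.true_genome, cfg0)}
        for chrom, seq in small_sim.true_genome.chroms.items():
            sil = digest_in_silico(seq, map_id=chrom)
            aln = align_maps(sil, maps[chrom])
            assert classify_discordances(aln) == []


class TestGapEstimate:
    def test_unmatched_optical_fragments_sum(self):
        sil = RestrictionMap("s", [40_000, 1_000, 50_000])
        opt = RestrictionMap("o", [40_000, 9_000, 8_000, 50_000])
        aln = align_maps(sil, opt)
        assert aln.unmatched_optical, "construction should leave optical runs unmatched"
        size, supported = estimate_gap_size(aln, (40_000, 41_000))
        assert supported and size == sum(
            aln.optical.fragments[i]
            for s, e in aln.unmatched_optical
            for i in range(s, e)
        ) > 0

    def test_absent_evidence_flagged_unsupported(self):
        frags = [40_000, 30_000]
        aln = align_maps(RestrictionMap("s", frags), RestrictionMap("o", list(frags)))
        size, supported = estimate_gap_size(aln, (39_000, 40_000))
        assert (size, supported) == (0, False)


class TestNoiseRobustness:
    def test_extra_fragment_detection_sensitivity(self):
        """>=5 kb injected extra fragments found as class 2 in >=90% of
        noisy simulated maps (cv 0.05, cut error rates 0.02)."""
        from refgrade.config import SimConfig
        from refgrade.simulate import simulate_genome, simulate_optical_map

        cfg = SimConfig(seed=11, genome_length=500_000, n_chromosomes=1,
                        n_genes=5, n_physical_gaps=0, n_large_insertions=0,
                        n_large_deletions=0)
        g = simulate_genome(cfg)
        sil = digest_in_silico(g.chroms["chr01"], map_id="chr01")
        rng = np.random.default_rng(123)
        p = AlignParams(cv=cfg.optical_cv)
        hits = 0
        n = 100
        for _ in range(n):
            (om,) = simulate_optical_map(g, cfg, rng=rng)
            frags = list(om.fragments)
            extra = int(rng.integers(6_000, 9_000))
            frags.insert(int(rng.integers(1, len(frags))), extra)
            om.fragments = frags
            ds = classify_discordances(align_maps(sil, om, p), params=p)
            if any(d.cls == 2 and abs(d.magnitude - extra) < 3_000 for d in ds):
                hits += 1
        assert hits / n >= 0.9


def test_fragment_list_round_trip(tmp_path):
    maps = [RestrictionMap("m1", [100, 200, 300]), RestrictionMap("m2", [5_000])]
    path = tmp_path / "maps.tsv"
    write_fragment_lists(path, maps)
    back = read_fragment_lists(path)
    assert [(m.map_id, m.fragments) for m in back] == [
        ("m1", [100, 200, 300]), ("m2", [5_000])
    ]
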