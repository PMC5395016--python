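"""Synthetic-data generator: determinism, truth bookkeeping, read sampling."""

import numpy as np
import pytest

from refgrade.config import SimConfig
from refgrade.sequences import decode, encode, gc_fraction, revcomp
from refgrade.simulate import (
    inject_assembly_errors,
    simulate_genome,
    simulate_individuals,
    simulate_long_reads,
    simulate_optical_map,
    simulate_short_reads_single,
    simulate_study,
)


def plain_config(**kw):
    base = dict(
        seed=3, genome_length=60_000, n_chromosomes=1, repeat_fraction=0.0,
        n_substitution_errors=0, n_insertion_errors=0, n_deletion_errors=0,
        n_large_insertions=0, n_large_deletions=0, n_physical_gaps=0,
        n_between_sites=0, n_within_sites=0, n_genes=3,
    )
    base.update(kw)
    return SimConfig(**base)


class TestGenome:
    def test_no_repeats_means_no_duplicate_50mer(self):
        g = simulate_genome(plain_config())
        seq = decode(next(iter(g.chroms.values())))
        seen = set()
        for i in range(0, len(seq) - 50, 7):
            k = seq[i : i + 50]
            assert k not in seen
            seen.add(k)

    def test_same_seed_is_byte_identical(self):
        cfg = plain_config(repeat_fraction=0.1)
        a = simulate_genome(cfg)
        b = simulate_genome(plain_config(repeat_fraction=0.1))
        for c in a.chroms:
            assert np.array_equal(a.chroms[c], b.chroms[c])

    def test_gc_fraction_matches_target(self):
        cfg = plain_config(genome_length=1_000_000, gc_fraction=0.5)
        g = simulate_genome(cfg)
        gc = gc_fraction(np.concatenate(list(g.chroms.values())))
        assert 0.49 <= gc <= 0.51

    def test_gene_models_are_valid_and_disjoint(self):
        g = simulate_genome(plain_config(n_genes=5))
        for gene in g.genes:
            gene.validate()
        by_chrom = {}
        for gene in g.genes:
            by_chrom.setdefault(gene.chrom, []).append((gene.start, gene.end))
        for ivs in by_chrom.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert s2 >= e1


class TestInjectErrors:
    def test_zero_errors_identity(self):
        cfg = plain_config()
        g = simulate_genome(cfg)
        assembly, truth = inject_assembly_errors(g, cfg)
        assert not truth.assembly_errors
        for c in g.chroms:
            assert np.array_equal(assembly[c], g.chroms[c])

    def test_substitution_diff_recovers_truth_exactly(self):
        cfg = plain_config(n_substitution_errors=10)
        g = simulate_genome(cfg)
        assembly, truth = inject_assembly_errors(g, cfg)
        # brute-force diff of equal-length sequences
        diffs = {
            (c, int(i))
            for c in g.chroms
            for i in np.flatnonzero(assembly[c] != g.chroms[c])
        }
        recorded = {(e.chrom, e.pos) for e in truth.assembly_errors}
        assert diffs == recorded
        for e in truth.assembly_errors:
            assert e.ref_allele != e.true_allele
            assert decode(assembly[e.chrom][e.pos : e.pos + 1]) == e.ref_allele

    def test_large_deletion_length_bookkeeping(self):
        cfg = plain_config(n_large_deletions=1, large_deletion_size=500)
        g = simulate_genome(cfg)
        assembly, truth = inject_assembly_errors(g, cfg)
        c = truth.assembly_errors[0].chrom
        assert len(assembly[c]) == len(g.chroms[c]) + 500

    def test_large_insertion_is_collapsed_tandem_copy(self):
        cfg = plain_config(n_large_insertions=1, large_insertion_size=150)
        g = simulate_genome(cfg)
        assembly, truth = inject_assembly_errors(g, cfg)
        (e,) = truth.assembly_errors
        assert e.type == "large_insertion" and e.size == 150
        c = e.chrom
        assert len(assembly[c]) == len(g.chroms[c]) - 150

    def test_categories_disjoint(self):
        cfg = plain_config(n_substitution_errors=8, n_insertion_errors=3,
                           n_deletion_errors=3, n_between_sites=4, n_within_sites=4)
        g = simulate_genome(cfg)
        _, truth = inject_assembly_errors(g, cfg)
        truth.validate_disjoint()


class TestIndividuals:
    def test_no_variants_equal_true_genome(self):
        cfg = plain_config()
        g = simulate_genome(cfg)
        _, truth = inject_assembly_errors(g, cfg)
        i1, i2 = simulate_individuals(g, truth, cfg)
        for ind in (i1, i2):
            for hap in ind.haplotypes:
                for c in g.chroms:
                    assert np.array_equal(hap[c], g.chroms[c])

    def test_between_sites_are_homozygous_consensus_diffs(self):
        cfg = plain_config(n_between_sites=5)
        g = simulate_genome(cfg)
        _, truth = inject_assembly_errors(g, cfg)
        i1, i2 = simulate_individuals(g, truth, cfg)
        c = next(iter(g.chroms))
        # each individual's haplotypes agree with themselves (homozygous)
        assert np.array_equal(i1.haplotypes[0][c], i1.haplotypes[1][c])
        assert np.array_equal(i2.haplotypes[0][c], i2.haplotypes[1][c])
        diffs = set(map(int, np.flatnonzero(i1.haplotypes[0][c] != i2.haplotypes[0][c])))
        assert diffs == {s.true_pos for s in truth.between_sites}

    def test_within_site_heterozygous_only_in_carrier(self):
        cfg = plain_config(n_within_sites=1)
        g = simulate_genome(cfg)
        _, truth = inject_assembly_errors(g, cfg)
        i1, i2 = simulate_individuals(g, truth, cfg)
        (site,) = truth.within_sites
        carrier = i1 if site.carrier == i1.name else i2
        other = i2 if carrier is i1 else i1
        c = site.chrom
        hap_diffs = np.flatnonzero(carrier.haplotypes[0][c] != carrier.haplotypes[1][c])
        assert list(hap_diffs) == [site.true_pos]
        assert np.array_equal(other.haplotypes[0][c], other.haplotypes[1][c])


class TestReads:
    def test_error_free_reads_are_exact_substrings(self):
        cfg = plain_config(read_error_rate=0.0, ds1_depth=2.0,
                           low_quality_tail_prob=0.01)
        g = simulate_genome(cfg)
        _, truth = inject_assembly_errors(g, cfg)
        i1, _ = simulate_individuals(g, truth, cfg)
        hap = decode(i1.haplotypes[0]["chr01"])
        for read in simulate_short_reads_single(i1, cfg)[:200]:
            assert read.sequence in hap or revcomp(read.sequence) in hap

    def test_target_depth_within_five_percent(self):
        cfg = plain_config(genome_length=200_000, ds1_depth=12.0, read_error_rate=0.0)
        g = simulate_genome(cfg)
        _, truth = inject_assembly_errors(g, cfg)
        i1, _ = simulate_individuals(g, truth, cfg)
        reads = simulate_short_reads_single(i1, cfg)
        total = sum(len(r) for r in reads)
        depth = total / 200_000
        assert abs(depth - 12.0) / 12.0 < 0.05

    def test_long_read_mean_length_near_377(self):
        cfg = plain_config(genome_length=500_000, long_read_depth=4.0)
        g = simulate_genome(cfg)
        _, truth = inject_assembly_errors(g, cfg)
        i1, _ = simulate_individuals(g, truth, cfg)
        reads = simulate_long_reads(i1, cfg)
        mean = np.mean([len(r) for r in reads])
        assert abs(mean - 377) / 377 < 0.05


class TestOpticalSim:
    def noiseless(self, **kw):
        base = dict(optical_cv=0.0, optical_missing_cut_prob=0.0,
                    optical_extra_cut_prob=0.0, optical_min_fragment=0)
        base.update(kw)
        return plain_config(**base)

    def test_zero_noise_equals_exact_digest(self):
        from refgrade.optical import digest_in_silico

        cfg = self.noiseless()
        g = simulate_genome(cfg)
        (m,) = simulate_optical_map(g, cfg)
        exact = digest_in_silico(g.chroms["chr01"], map_id="chr01")
        assert m.fragments == exact.fragments

    def test_missing_cut_prob_one_gives_single_fragment(self):
        cfg = self.noiseless(optical_missing_cut_prob=1.0)
        g = simulate_genome(cfg)
        (m,) = simulate_optical_map(g, cfg)
        assert m.fragments == [len(g.chroms["chr01"])]

    def test_zero_noise_conserves_length(self):
        cfg = self.noiseless(genome_length=150_000)
        g = simulate_genome(cfg)
        (m,) = simulate_optical_map(g, cfg)
        assert sum(m.fragments) == len(g.chroms["chr01"])

    def test_sizing_cv_reproduced(self):
        cfg = plain_config(genome_length=100_000, optical_missing_cut_prob=0.0,
                           optical_extra_cut_prob=0.0, optical_min_fragment=0,
                           optical_cv=0.05)
        g = simulate_genome(cfg)
        from refgrade.optical import digest_in_silico

        exact = np.array(digest_in_silico(g.chroms["chr01"]).fragments, dtype=float)
        rng = np.random.default_rng(0)
        rel = []
        for _ in range(max(1, 1000 // max(len(exact), 1))):
            (m,) = simulate_optical_map(g, cfg, rng=rng)
            rel.extend(np.array(m.fragments) / exact - 1)
        sd = np.std(rel)
        assert abs(sd - 0.05) / 0.05 < 0.2


def test_full_study_determinism(small_config, small_sim):
    again = simulate_study(small_config)
    for c in small_sim.assembly:
        assert np.array_equal(again.assembly[c], small_sim.assembly[c])
    assert again.truth.assembly_errors == small_sim.truth.assembly_errors
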