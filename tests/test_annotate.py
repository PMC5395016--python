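"""Effect annotation, assembly correction, gaps and size accounting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from refgrade.annotate import (
    AssemblyAccount,
    account_assembly,
    annotate_effect,
    apply_corrections,
    gigabases,
    insert_gap_placeholders,
)
from refgrade.classify import ErrorRecord
from refgrade.genemodels import GeneModel, read_gff3, write_gff3
from refgrade.sequences import decode, encode


def toy_gene_plus(prefix=30, cds_seq="ATGTGGGCTTAA", suffix=30):
    """Single-exon plus-strand gene flanked by UTRs on a toy chromosome."""
    chrom = "G" * prefix + "AAAAA" + cds_seq + "CCCCC" + "G" * suffix
    cds_start = prefix + 5
    gene = GeneModel(
        "g1", "chr01", "+",
        exons=[(prefix, prefix + 5), (cds_start, cds_start + len(cds_seq)),
               (cds_start + len(cds_seq), cds_start + len(cds_seq) + 5)],
        cds=[(cds_start, cds_start + len(cds_seq))],
        utr5=[(prefix, prefix + 5)],
        utr3=[(cds_start + len(cds_seq), cds_start + len(cds_seq) + 5)],
    )
    return {"chr01": encode(chrom)}, gene, cds_start


class TestEffects:
    def test_intergenic_outside_all_transcripts(self):
        asm, gene, _ = toy_gene_plus()
        call = annotate_effect("chr01", 2, "G", "A", [gene], asm)
        assert call.effect == "Intergenic"

    def test_codon_changes_on_plus_strand(self):
        asm, gene, cds0 = toy_gene_plus()          # codons ATG TGG GCT TAA
        # TGG -> TAG: nonsense
        assert annotate_effect("chr01", cds0 + 4, "G", "A", [gene], asm).effect == "Nonsense"
        # GCT -> GTT: missense
        assert annotate_effect("chr01", cds0 + 7, "C", "T", [gene], asm).effect == "Missense"
        # GCT -> GCC: silent
        assert annotate_effect("chr01", cds0 + 8, "T", "C", [gene], asm).effect == "Silent"

    def test_utr_and_intron_positions(self):
        asm, gene, cds0 = toy_gene_plus()
        assert annotate_effect("chr01", gene.start + 1, "A", "C", [gene], asm).effect == "UTR"
        intron_gene = GeneModel(
            "g2", "chr01", "+",
            exons=[(10, 20), (40, 52)], cds=[(40, 52)], utr5=[(10, 20)],
        )
        asm2 = {"chr01": encode("A" * 100)}
        asm2["chr01"][40:52] = encode("ATGTGGGCTTAA")
        assert annotate_effect("chr01", 30, "A", "C", [intron_gene], asm2).effect == "Intron"

    def test_minus_strand_complementation(self):
        # coding strand ATG TGG TAA on the minus strand: genomic sequence is
        # its reverse complement; a genomic C->T is coding G->A
        coding = "ATGTGGTAA"
        from refgrade.sequences import revcomp

        chrom = "G" * 20 + revcomp(coding) + "G" * 20
        gene = GeneModel("gm", "chr01", "-", exons=[(20, 29)], cds=[(20, 29)])
        asm = {"chr01": encode(chrom)}
        # genomic position of coding TGG's G2: coding index 4 -> genomic 20 + (9-1-4)
        gpos = 20 + (9 - 1 - 4)
        ref = decode(asm["chr01"][gpos : gpos + 1])
        assert ref == "C"
        call = annotate_effect("chr01", gpos, "C", "T", [gene], asm)
        assert call.effect == "Nonsense"          # TGG -> TAG on coding strand

    def test_site_effect_is_most_severe_across_transcripts(self):
        asm, gene, cds0 = toy_gene_plus()
        other = GeneModel("g3", "chr01", "+",
                          exons=[(gene.start, gene.end)], cds=[],
                          utr5=[(gene.start, gene.end)])
        call = annotate_effect("chr01", cds0 + 4, "G", "A", [gene, other], asm)
        assert call.effect == "Nonsense"
        assert call.transcript_effects == {"g1": "Nonsense", "g3": "UTR"}

    def test_reference_mismatch_raises(self):
        asm, gene, cds0 = toy_gene_plus()
        with pytest.raises(ValueError):
            annotate_effect("chr01", cds0 + 4, "T", "A", [gene], asm)


class TestGff3RoundTrip:
    def test_written_models_read_back_identical(self, tmp_path, small_sim):
        path = tmp_path / "genes.gff3"
        genes = small_sim.true_genome.genes
        write_gff3(path, genes)
        back = read_gff3(path)
        assert len(back) == len(genes)
        for a, b in zip(sorted(genes, key=lambda g: g.gene_id),
                        sorted(back, key=lambda g: g.gene_id)):
            assert (a.chrom, a.strand, a.exons, a.cds) == (b.chrom, b.strand, b.exons, b.cds)


class TestCorrections:
    def test_substitutions_only_keep_length(self):
        asm = {"chr01": encode("ACGTACGTACGT")}
        recs = [ErrorRecord("chr01", 3, "snp", "T", "A", 1)]
        out, _ = apply_corrections(asm, recs)
        assert len(out["chr01"]) == 12
        assert decode(out["chr01"]) == "ACGAACGTACGT"

    def test_deletion_type_error_fills_two_bases(self):
        # assembly missing 2 bp the individuals carry: insertion record
        asm = {"chr01": encode("ACGTACGT")}
        recs = [ErrorRecord("chr01", 3, "insertion", "T", "GG", 2)]
        out, om = apply_corrections(asm, recs)
        assert decode(out["chr01"]) == "ACGTGGACGT"
        assert len(out["chr01"]) == 8 + 2

    def test_extra_bases_removed(self):
        asm = {"chr01": encode("ACGTTTACGT")}
        recs = [ErrorRecord("chr01", 3, "deletion", "TT", "", 2)]
        out, _ = apply_corrections(asm, recs)
        assert decode(out["chr01"]) == "ACGTACGT"

    def test_overlapping_records_rejected(self):
        asm = {"chr01": encode("ACGTACGTACGT")}
        recs = [
            ErrorRecord("chr01", 3, "deletion", "AC", "", 2),
            ErrorRecord("chr01", 4, "snp", "C", "A", 1),
        ]
        with pytest.raises(ValueError, match="overlapping"):
            apply_corrections(asm, recs)

    def test_full_synthetic_round_trip_restores_true_genome(self, small_sim):
        """Applying the truth table's own small corrections makes the
        assembly byte-identical to the true genome outside large events."""
        recs = []
        for e in small_sim.truth.assembly_errors:
            if e.type == "substitution":
                recs.append(ErrorRecord(e.chrom, e.pos, "snp", e.ref_allele,
                                        e.true_allele, 1))
            elif e.type == "insertion":
                recs.append(ErrorRecord(e.chrom, e.pos, "insertion", "",
                                        e.true_allele, e.size))
            elif e.type == "deletion":
                recs.append(ErrorRecord(e.chrom, e.pos, "deletion", e.ref_allele,
                                        "", e.size))
        corrected, om = apply_corrections(small_sim.assembly, recs)
        for rec in recs:
            new_pos = om[rec.chrom].to_new(rec.position)
            true_chrom = small_sim.true_genome.chroms[rec.chrom]
            got = corrected[rec.chrom][new_pos : new_pos + 5]
            # corrected window must occur in the true genome
            assert decode(got) in decode(true_chrom)

    @given(st.lists(st.integers(0, 900), min_size=0, max_size=8, unique=True))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_offset_map_round_trip_identity(self, positions):
        rng = np.random.default_rng(0)
        asm = {"chr01": rng.integers(0, 4, size=1000).astype(np.uint8)}
        positions = sorted(positions)
        recs = []
        last_end = -10
        for p in positions:
            if p - last_end < 6:
                continue
            kind = ["snp", "insertion", "deletion"][p % 3]
            if kind == "snp":
                ref = decode(asm["chr01"][p : p + 1])
                alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
                recs.append(ErrorRecord("chr01", p, "snp", ref, alt, 1))
            elif kind == "insertion":
                recs.append(ErrorRecord("chr01", p, "insertion", "", "AC", 2))
            else:
                recs.append(ErrorRecord("chr01", p, "deletion",
                                        decode(asm["chr01"][p + 1 : p + 3]), "", 2))
            last_end = p + 3
        corrected, om = apply_corrections(asm, recs)
        edited = set()
        for r in recs:
            edited.update(range(r.position - 1, r.position + r.size + 2))
        m = om["chr01"]
        for old in range(0, 1000, 13):
            if old in edited:
                continue
            assert m.to_old(m.to_new(old)) == old


class TestGapPlaceholders:
    def test_physical_gap_inserts_exactly_1000_ns(self):
        asm = {"chr01": encode("ACGT" * 100)}
        out = insert_gap_placeholders(asm, [("chr01", 200, "physical")])
        assert len(out["chr01"]) == 400 + 1000
        assert (out["chr01"][200:1200] == 4).all()

    def test_telomeric_gap_at_chromosome_end(self):
        asm = {"chr01": encode("ACGT" * 10)}
        out = insert_gap_placeholders(asm, [("chr01", 0, "telomere_end")])
        assert (out["chr01"][-1000:] == 4).all()

    def test_zero_gaps_unchanged(self):
        asm = {"chr01": encode("ACGT")}
        out = insert_gap_placeholders(asm, [])
        assert decode(out["chr01"]) == "ACGT"


class TestAccounting:
    def account(self):
        return AssemblyAccount(
            sequence_length=373_173_519,
            gap_totals={"cytological": 9_598_219, "optical": 7_290_600},
            rdna_bp=3_700_000,
        )

    def test_total_assembly_sizes(self):
        rep = account_assembly(self.account())
        assert rep["total_assembly_size_bp"]["cytological"] == 382_771_738
        assert rep["total_assembly_size_bp"]["optical"] == 380_464_119

    def test_genome_size_range(self):
        rep = account_assembly(self.account())
        assert rep["genome_size_range_mbp"] == (384.2, 386.5)

    def test_coverage_range(self):
        rep = account_assembly(self.account())
        assert rep["coverage_range_percent"] == (96.6, 97.1)

    def test_zero_gaps_full_coverage(self):
        rep = account_assembly(AssemblyAccount(1_000_000, {"only": 0}, 0))
        assert rep["total_assembly_size_bp"]["only"] == 1_000_000
        assert rep["coverage_percent"]["only"] == 100.0

    @given(
        st.integers(10_000, 10**9),
        st.dictionaries(st.sampled_from(["a", "b", "c"]), st.integers(0, 10**8),
                        min_size=1),
        st.integers(0, 10**7),
    )
    @settings(deadline=None, max_examples=80, derandomize=True)
    def test_accounting_identities(self, seq_len, gaps, rdna):
        acc = AssemblyAccount(seq_len, gaps, rdna)
        for src, total in acc.totals().items():
            assert total == seq_len + gaps[src]
            assert acc.genome_sizes()[src] == total + rdna
            assert acc.coverage()[src] == pytest.approx(seq_len / (total + rdna))

    def test_library_gigabases(self):
        from refgrade.study_constants import CSHL_LIBRARIES, NIAS_LIBRARIES

        assert gigabases(NIAS_LIBRARIES) == 5.6
        assert gigabases(CSHL_LIBRARIES) == 20.4


class TestSummarize:
    def test_report_counts_equal_recounts(self, small_study):
        from refgrade.annotate import summarize_run

        rep = summarize_run(
            small_study.prep_stats, small_study.mapping_stats,
            small_study.coverage, dict(small_study.snv.class_counts),
            small_study.snv.effective_sites,
        )
        classes = rep["classes"].set_index("class")["count"].to_dict()
        assert classes == {k: int(v) for k, v in small_study.snv.class_counts.items()}
        prep = rep["preprocessing"].set_index("library")
        for lib, st_ in small_study.prep_stats.items():
            assert prep.loc[lib, "input_reads"] == st_.input_reads

    def test_empty_inputs_do_not_crash(self):
        from refgrade.annotate import summarize_run
        import pandas as pd

        rep = summarize_run({}, {}, pd.DataFrame(), {}, 0)
        assert rep["classes"].empty
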