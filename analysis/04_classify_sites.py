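#!/usr/bin/env python
"""Classify every effective site and call 1-4 bp indel errors.

Builds the two per-individual pileups and the pooled pileup from the
SAM files, runs the R/N/A/L classification and the dataset combination
into the five genotype classes, annotates allelic SNPs against the gene
models, scores the calls against the simulation ground truth, and
emits a VCF of corrections and allelic sites plus a class/rate table.
"""

from pathlib import Path

import pandas as pd

from refgrade.annotate import annotate_effect, effect_breakdown
from refgrade.classify import (
    call_small_indels, classify_snv_sites, compare_with_truth, compute_rate,
)
from refgrade.genemodels import read_gff3
from refgrade.mapping import read_sam
from refgrade.pileup import build_pileup, merge_pileups
from refgrade.sequences import read_fasta
from refgrade.vcfio import write_vcf

IN = Path("scratch/study")
RESULTS = Path("results")


def main() -> None:
    ref = read_fasta(IN / "assembly.fasta")
    p1 = build_pileup(read_sam(IN / "ds1.sam"), ref)
    p2 = build_pileup(read_sam(IN / "ds2.sam"), ref)
    pooled = merge_pileups(p1, p2)

    snv = classify_snv_sites(p1, p2, pooled)
    indel_errors, allelic_indels = call_small_indels(p1, p2, pooled)

    genes = read_gff3(IN / "genes.gff3")
    allele_calls = [c for c in snv.calls if c.combined.startswith("allele")]
    effect_calls = []
    effects = {}
    for c in allele_calls:
        alt = c.alleles.get("pooled")
        if alt and len(alt) == 1:
            call = annotate_effect(c.chrom, c.position, c.ref_allele, alt, genes, ref)
            effect_calls.append(call)
            effects[(c.chrom, c.position)] = call.effect
    write_vcf(RESULTS / "04_calls.vcf", ref,
              snv.error_records + indel_errors, allele_calls, effects)

    rows = [
        {"class": cls, "count": n,
         "rate_per_10kb": compute_rate(n, snv.effective_sites) if cls != "reference" else ""}
        for cls, n in sorted(snv.class_counts.items())
    ]
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "04_classes.tsv", sep="\t", index=False)

    truth_rows = pd.read_csv(IN / "truth.tsv", sep="\t")
    # score against truth (the simulator's table has everything needed)
    from refgrade.simulate import AlleleSite, AssemblyError, GapRecord, TruthTable

    truth = TruthTable()
    for _, r in truth_rows.iterrows():
        if r.category == "assembly_error":
            truth.assembly_errors.append(AssemblyError(
                r.chrom, int(r.pos), r.type, str(r.ref) if pd.notna(r.ref) else "",
                str(r.alt) if pd.notna(r.alt) else "", int(r["size"])))
        elif r.category in ("between", "within"):
            site = AlleleSite(r.chrom, int(r.pos), -1, str(r.ref), str(r.alt),
                              str(r.carrier))
            (truth.between_sites if r.category == "between" else truth.within_sites).append(site)
    metrics = compare_with_truth(snv, indel_errors, truth)

    print(table.to_string(index=False))
    print(f"effective sites: {snv.effective_sites}")
    print(f"error recovery: sensitivity {metrics.error_sensitivity:.3f}, "
          f"precision {metrics.error_precision:.3f}; "
          f"within {metrics.within_sensitivity:.2f}, "
          f"between {metrics.between_sensitivity:.2f}, "
          f"confusions {metrics.cross_class_confusions}")
    bd = effect_breakdown(effect_calls)
    bd.to_csv(RESULTS / "04_effects.tsv", sep="\t", index=False)
    print(bd.to_string(index=False))


if __name__ == "__main__":
    main()
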