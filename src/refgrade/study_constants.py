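"""Published inputs of the rice Nipponbare reference-improvement study.

These are the printed per-chromosome lengths, effective-site counts,
library read counts and headline tallies that the accounting and rate
arithmetic consume as inputs. The chromosome-length total (Table-level
sum) and the post-correction genome size are carried as independent
published constants; they differ slightly and are not reconciled here.
"""

# per-chromosome pseudomolecule lengths (bp)
CHROM_LENGTHS = {
    "chr01": 43_270_899,
    "chr02": 35_937_247,
    "chr03": 36_413_819,
    "chr04": 35_502_790,
    "chr05": 29_958_438,
    "chr06": 31_248_789,
    "chr07": 29_697_629,
    "chr08": 28_443_027,
    "chr09": 23_012_721,
    "chr10": 23_208_246,
    "chr11": 29_021_139,
    "chr12": 27_531_905,
}

# effective sites (depth >= 10, pooled datasets) per chromosome
EFFECTIVE_SITES = {
    "chr01": 38_175_168,
    "chr02": 32_148_332,
    "chr03": 33_082_516,
    "chr04": 29_153_050,
    "chr05": 25_327_281,
    "chr06": 26_594_708,
    "chr07": 25_438_043,
    "chr08": 24_024_380,
    "chr09": 19_739_054,
    "chr10": 19_732_853,
    "chr11": 24_546_522,
    "chr12": 22_891_243,
}

# short-read libraries: (number of reads, read length bp)
NIAS_LIBRARIES = [(70_387_992, 36), (60_164_564, 51)]
CSHL_LIBRARIES = [(269_062_790, 76)]

# headline tallies
SNP_ERRORS = 3_447
INSERTION_ERRORS = 642
DELETION_ERRORS = 797
ALLELIC_SITES = 6_433
BETWEEN_INDIVIDUAL_SITES = 250

# assembly accounting (bp)
POST_CORRECTION_GENOME_SIZE = 373_173_519
GAP_TOTAL_CYTOLOGICAL = 9_598_219        # FISH-based estimate
GAP_TOTAL_OPTICAL = 7_290_600
RDNA_ALLOWANCE = 3_700_000
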