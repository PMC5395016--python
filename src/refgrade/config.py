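"""Simulation configuration.

``SimConfig`` pins every knob of the synthetic study: the toy genome, the
errors injected into the "assembly", the two re-sequenced individuals,
the short- and long-read libraries and the optical (restriction) map.
All randomness flows from the mandatory ``seed``; there is no hidden
global RNG anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

ILLUMINA_ADAPTERS = (
    "GATCGGAAGAGCGGTTCAGCAGGAATGCCGAG",
    "ACACTCTTTCCCTACACGACGCTCTTCCGATCT",
)


@dataclass
class SimConfig:
    seed: int

    # genome
    genome_length: int = 1_000_000
    n_chromosomes: int = 2
    gc_fraction: float = 0.44
    repeat_fraction: float = 0.10
    repeat_unit_range: tuple[int, int] = (200, 2000)

    # assembly errors (reference wrong, individuals right)
    n_substitution_errors: int = 100
    n_insertion_errors: int = 25   # assembly MISSING 1-4 bp
    n_deletion_errors: int = 25    # assembly carries 1-4 extra bp
    n_large_insertions: int = 1    # assembly missing >=100 bp (collapsed tandem copy)
    n_large_deletions: int = 1     # assembly carries >=100 extra bp
    large_insertion_size: int = 200
    large_deletion_size: int = 500
    n_physical_gaps: int = 1       # true sequence replaced by a 1,000-N placeholder
    physical_gap_size: int = 20_000

    # individuals
    n_between_sites: int = 20      # homozygous-different between the two individuals
    n_within_sites: int = 20       # heterozygous within exactly one individual

    # short reads: ds1 single-end (36/51 bp mix), ds2 paired-end 76 bp
    # raw sampled depth; preprocessing and unique-mapping losses leave the
    # pooled pileup at ~40x mapped depth, the condition the study states
    ds1_read_lengths: tuple[int, ...] = (36, 51)
    ds1_depth: float = 26.0
    ds2_read_length: int = 76
    ds2_depth: float = 26.0
    insert_mean: float = 150.0
    insert_sd: float = 20.0
    read_error_rate: float = 0.005
    adapter: str = ILLUMINA_ADAPTERS[1]
    adapter_readthrough_fraction: float = 0.02
    quality_mean: int = 38
    low_quality_tail_prob: float = 0.3   # geometric low-Q tail at each read end

    # long reads
    long_read_mean_length: float = 377.0
    long_read_sd_length: float = 120.0
    long_read_min_length: int = 50
    long_read_depth: float = 8.0
    long_read_error_rate: float = 0.005

    # optical map
    optical_cv: float = 0.05
    optical_missing_cut_prob: float = 0.02
    optical_extra_cut_prob: float = 0.02
    optical_min_fragment: int = 500

    # gene models
    n_genes: int = 40

    def __post_init__(self) -> None:
        probs = dict(
            gc_fraction=self.gc_fraction,
            repeat_fraction=self.repeat_fraction,
            read_error_rate=self.read_error_rate,
            adapter_readthrough_fraction=self.adapter_readthrough_fraction,
            low_quality_tail_prob=self.low_quality_tail_prob,
            optical_cv=self.optical_cv,
            optical_missing_cut_prob=self.optical_missing_cut_prob,
            optical_extra_cut_prob=self.optical_extra_cut_prob,
            long_read_error_rate=self.long_read_error_rate,
        )
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in ("ds1_depth", "ds2_depth", "long_read_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if min(self.ds1_read_lengths) < 32 or self.ds2_read_length < 32:
            raise ValueError("short-read lengths must be >= 32 bp")
        if self.genome_length < self.n_chromosomes * 1000:
            raise ValueError("genome too short for requested chromosome count")

    def rng(self, stream: str) -> np.random.Generator:
        """Named, independent RNG stream derived from the master seed."""
        import zlib

        ss = np.random.SeedSequence([self.seed, zlib.crc32(stream.encode())])
        return np.random.default_rng(ss)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("repeat_unit_range", "ds1_read_lengths"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)
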