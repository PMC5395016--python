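"""End-to-end orchestration of the synthetic re-sequencing study.

Each stage is importable on its own; ``run_error_study`` chains them:
simulate -> preprocess -> map -> pileup -> classify -> correct, and
exposes the recovery metrics against the simulation ground truth.
Separate entry points run the split-read large-indel stage and the
optical-map validation stage on the same simulated study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .annotate import apply_corrections, OffsetMap
from .classify import (
    ClassificationResult,
    ErrorRecord,
    RecoveryMetrics,
    call_small_indels,
    classify_snv_sites,
    compare_with_truth,
)
from .config import ILLUMINA_ADAPTERS, SimConfig
from .mapping import (
    GenomeIndex,
    MappingStats,
    estimate_insert_bounds,
    flag_proper_pairs,
    map_reads,
)
from .optical import (
    AlignParams,
    Discordance,
    MapAlignment,
    align_maps,
    classify_discordances,
    digest_in_silico,
    estimate_gap_size,
)
from .pileup import Pileup, build_pileup, coverage_profile, merge_pileups
from .readprep import PrepStats, Read, preprocess_pairs, preprocess_single
from .simulate import SimulatedStudy, simulate_long_reads, simulate_optical_map, simulate_study
from .splitread import CorroboratedEvent, corroborate_events, scan_long_reads


@dataclass
class StudyOutcome:
    sim: SimulatedStudy
    prep_stats: dict[str, PrepStats]
    mapping_stats: dict[str, MappingStats]
    pileups: dict[str, Pileup]
    coverage: "object"
    snv: ClassificationResult
    indel_errors: list[ErrorRecord]
    allelic_indels: list
    metrics: RecoveryMetrics
    corrected: dict[str, np.ndarray]
    offsets: dict[str, OffsetMap]
    applied_records: list[ErrorRecord] = field(default_factory=list)
    prepped_reads: dict[str, list[Read]] = field(default_factory=dict)

    @property
    def all_error_records(self) -> list[ErrorRecord]:
        return sorted(
            self.snv.error_records + self.indel_errors,
            key=lambda r: (r.chrom, r.position),
        )


def prepare_datasets(sim: SimulatedStudy):
    """Simulate and preprocess both short-read libraries."""
    from .simulate import simulate_short_reads_paired, simulate_short_reads_single

    config = sim.config
    adapters = [config.adapter, *ILLUMINA_ADAPTERS]
    ind1, ind2 = sim.individuals
    stats = {"ds1": PrepStats(), "ds2": PrepStats()}
    ds1 = list(preprocess_single(
        simulate_short_reads_single(ind1, config), adapters, stats=stats["ds1"]
    ))
    ds2: list[Read] = []
    ds2_pairs: list[tuple[Read, Read]] = []
    for result in preprocess_pairs(
        simulate_short_reads_paired(ind2, config), adapters, stats=stats["ds2"]
    ):
        if len(result) == 2:
            ds2_pairs.append(result)  # type: ignore[arg-type]
        ds2.extend(result)
    return {"ds1": ds1, "ds2": ds2, "ds2_pairs": ds2_pairs}, stats


def map_and_pile(reads: dict, index: GenomeIndex, assembly: dict[str, np.ndarray],
                 pairs: Optional[list] = None):
    """Map each dataset, flag proper pairs, and build per-dataset pileups."""
    mapping_stats = {"ds1": MappingStats(), "ds2": MappingStats()}
    rec1 = map_reads(reads["ds1"], index, mapping_stats["ds1"])
    rec2 = map_reads(reads["ds2"], index, mapping_stats["ds2"])
    if pairs:
        by_id: dict[str, dict[str, object]] = {}
        for r in rec2:
            by_id.setdefault(r.read_id, {})[r.mate_role] = r
        mate_pairs = [
            (d["mate1"], d["mate2"]) for d in by_id.values()
            if "mate1" in d and "mate2" in d
        ]
        bounds = estimate_insert_bounds(mate_pairs)
        for r1, r2 in mate_pairs:
            if flag_proper_pairs(r1, r2, bounds):
                mapping_stats["ds2"].proper += 1
    p1 = build_pileup(rec1, assembly)
    p2 = build_pileup(rec2, assembly)
    return {"ds1": p1, "ds2": p2, "pooled": merge_pileups(p1, p2)}, mapping_stats


def run_error_study(config: SimConfig, sim: Optional[SimulatedStudy] = None) -> StudyOutcome:
    sim = sim or simulate_study(config)
    reads, prep_stats = prepare_datasets(sim)
    index = GenomeIndex(sim.assembly)
    pileups, mapping_stats = map_and_pile(reads, index, sim.assembly,
                                          pairs=reads["ds2_pairs"])
    coverage = coverage_profile(pileups["pooled"])
    snv = classify_snv_sites(pileups["ds1"], pileups["ds2"], pileups["pooled"])
    indel_errors, allelic_indels = call_small_indels(
        pileups["ds1"], pileups["ds2"], pileups["pooled"]
    )
    metrics = compare_with_truth(snv, indel_errors, sim.truth)
    from .classify import drop_overlapping_records

    kept, _dropped = drop_overlapping_records(snv.error_records + indel_errors)
    corrected, offsets = apply_corrections(sim.assembly, kept)
    return StudyOutcome(
        sim=sim, prep_stats=prep_stats, mapping_stats=mapping_stats,
        pileups=pileups, coverage=coverage, snv=snv,
        indel_errors=indel_errors, allelic_indels=allelic_indels,
        metrics=metrics, corrected=corrected, offsets=offsets,
        applied_records=kept,
        prepped_reads={"ds1": reads["ds1"], "ds2": reads["ds2"]},
    )


def residual_errors_after_correction(outcome: StudyOutcome) -> int:
    """Fixed-point check: re-map the same preprocessed reads to the
    corrected assembly and count sequencing-error calls at the lifted
    coordinates of the applied corrections."""
    index = GenomeIndex(outcome.corrected)
    rec1 = map_reads(outcome.prepped_reads["ds1"], index)
    rec2 = map_reads(outcome.prepped_reads["ds2"], index)
    p1 = build_pileup(rec1, outcome.corrected)
    p2 = build_pileup(rec2, outcome.corrected)
    pooled = merge_pileups(p1, p2)
    snv = classify_snv_sites(p1, p2, pooled)
    indel_errors, _ = call_small_indels(p1, p2, pooled)

    corrected_sites = {
        (r.chrom, outcome.offsets[r.chrom].to_new(r.position))
        for r in outcome.applied_records
    }
    residual = sum(
        1 for r in snv.error_records if (r.chrom, r.position) in corrected_sites
    )
    residual += sum(
        1 for r in indel_errors if (r.chrom, r.position) in corrected_sites
    )
    return residual


# ---------------------------------------------------------------------------
# split-read stage


@dataclass
class SplitReadOutcome:
    events: list
    corroborated: list[CorroboratedEvent]
    matched_truth: dict[tuple, Optional[CorroboratedEvent]]


def run_split_read_stage(
    sim: SimulatedStudy,
    min_support: int = 2,
    depth: Optional[dict[str, np.ndarray]] = None,
) -> SplitReadOutcome:
    """Long-read simulation, split-alignment scan and corroboration,
    scored against the injected large events."""
    config = sim.config
    reads = simulate_long_reads(sim.individuals[0], config)
    index = GenomeIndex(sim.assembly)
    events = scan_long_reads(reads, index)
    corroborated = corroborate_events(events, min_support=min_support, depth=depth)

    matched: dict[tuple, Optional[CorroboratedEvent]] = {}
    for te in sim.truth.assembly_errors:
        if te.type not in ("large_insertion", "large_deletion"):
            continue
        want = "insertion" if te.type == "large_insertion" else "deletion"
        best = None
        for ce in corroborated:
            if ce.chrom == te.chrom and ce.event_type == want:
                if abs(ce.size - te.size) <= 10 and abs(ce.breakpoint - te.pos) <= 2 * te.size + 100:
                    best = ce
                    break
        matched[(te.chrom, te.pos, te.type, te.size)] = best
    return SplitReadOutcome(events, corroborated, matched)


# ---------------------------------------------------------------------------
# optical stage


@dataclass
class OpticalOutcome:
    alignments: dict[str, MapAlignment]
    discordances: dict[str, list[Discordance]]
    gap_estimates: dict[tuple[str, int], tuple[int, bool]]


def run_optical_stage(sim: SimulatedStudy, params: Optional[AlignParams] = None) -> OpticalOutcome:
    """Digest the assembly, align against the simulated optical map of
    the true genome, classify discordances and estimate gap sizes."""
    config = sim.config
    params = params or AlignParams(cv=max(config.optical_cv, 0.01))
    optical_maps = {m.map_id: m for m in simulate_optical_map(sim.true_genome, config)}
    alignments = {}
    discordances = {}
    gap_estimates = {}
    gaps_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in sim.truth.gaps:
        gaps_by_chrom.setdefault(g.chrom, []).append((g.start, g.start + g.n_length))
    for chrom, seq in sim.assembly.items():
        silico = digest_in_silico(seq, map_id=chrom)
        optical = optical_maps[chrom]
        if not optical.fragments or not silico.fragments:
            continue
        aln = align_maps(silico, optical, params)
        alignments[chrom] = aln
        discordances[chrom] = classify_discordances(
            aln, gaps_by_chrom.get(chrom, ()), params
        )
        for g in sim.truth.gaps:
            if g.chrom == chrom:
                gap_estimates[(chrom, g.start)] = estimate_gap_size(
                    aln, (g.start, g.start + g.n_length)
                )
    return OpticalOutcome(alignments, discordances, gap_estimates)
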