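"""End-to-end orchestration of synthetic capture experiments.

Chains the stages — genome simulation, variant planting, capture design,
lane simulation, lane-level filtering, lane merging, consensus genotyping,
capture metrics, concordance scoring and gene reporting — into one
deterministic run driven by a :class:`exocap.config.RunConfig`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from . import capmetrics, concordance, genereport, genotype, lanefilter
from .config import RunConfig
from .intervals import IntervalSet
from .simulate import (
    CaptureDesign,
    DiploidTruth,
    SimulatedGenome,
    SimulatedLane,
    design_capture,
    plant_variants,
    simulate_genome,
    simulate_lane,
)

__all__ = ["ExperimentResult", "run_experiment", "write_report", "subseed"]

_MOD = 2_147_483_647  # keep derived seeds below 2^31


def subseed(seed: int, k: int) -> int:
    """Deterministic stream of sub-seeds from one master seed."""
    return (seed * 1_000_003 + 7919 * (k + 1)) % _MOD


@dataclass
class ExperimentResult:
    """Everything one synthetic capture experiment produced."""

    config: RunConfig
    genome: SimulatedGenome
    truth: DiploidTruth
    design: CaptureDesign
    lanes: List[SimulatedLane]
    lane_results: List[lanefilter.LaneResult]
    merged_mates: List[lanefilter.MateRecord]
    calls: List[genotype.GenotypeCall]
    track: capmetrics.DepthTrack
    coverage: capmetrics.CoverageReport
    uniformity: capmetrics.UniformityHistogram
    insert_dist: Optional[capmetrics.InsertSizeDistribution]
    enrichment: List[float]
    gold_variant: concordance.GoldStandard
    gold_comprehensive: concordance.GoldStandard
    report_variant: concordance.ConcordanceReport
    report_comprehensive: concordance.ConcordanceReport
    gene_models: List[genereport.GeneModel]
    gene_rows: List[genereport.GeneCoverageRow]


def run_experiment(config: RunConfig, seed: Optional[int] = None) -> ExperimentResult:
    """Simulate a capture experiment and push it through the full pipeline.

    ``seed`` overrides ``config.seed``.  The same (config, seed) always
    produces identical results.
    """
    base = config.seed if seed is None else seed
    sim = config.simulation
    pipe = config.pipeline

    genome = simulate_genome(sim.chrom_lengths, sim.gc_fraction, seed=subseed(base, 0))
    truth = plant_variants(
        genome, sim.snv_rate, sim.het_fraction, sim.transition_prob, seed=subseed(base, 1)
    )
    design = design_capture(
        genome,
        n_targets=sim.n_targets,
        target_length_mean=sim.target_length_mean,
        target_length_sd=sim.target_length_sd,
        probe_margin=sim.probe_margin,
        untargeted_fraction=sim.untargeted_fraction,
        seed=subseed(base, 2),
    )
    profile = sim.library_profile()

    lanes, lane_results, enrichment = [], [], []
    insert_lengths = []
    for k in range(sim.n_lanes):
        lane = simulate_lane(
            genome, truth, design, profile, sim.n_pairs,
            seed=subseed(base, 10 + k), name_prefix=f"lane{k}",
        )
        res = lanefilter.run_lane(lane, design, pipe)
        lanes.append(lane)
        lane_results.append(res)
        enrichment.append(capmetrics.enrichment_score(res.stats))
        insert_lengths.append(res.stats.insert_lengths)

    merged = genotype.merge_lanes([r.mates for r in lane_results])
    priors = genotype.PriorModel(het=pipe.het_prior, hom_alt=pipe.hom_alt_prior)
    calls = genotype.call_genotypes(
        merged, genome, design.target, priors=priors, min_quality=pipe.call_min_quality
    )

    track = capmetrics.depth_track(merged, design.target, genome.lengths)
    coverage, uniformity = capmetrics.coverage_report(track, pipe.breadth_thresholds)
    all_inserts = np.concatenate(insert_lengths) if insert_lengths else np.array([], dtype=int)
    insert_dist = (
        capmetrics.insert_size_distribution(all_inserts) if all_inserts.size else None
    )

    gold_variant = concordance.gold_standard_from_truth(
        truth, design.target, genome, flavor="variant_focused"
    )
    gold_comprehensive = concordance.gold_standard_from_truth(
        truth, design.target, genome, flavor="comprehensive"
    )
    report_variant = (
        concordance.concordance_report(calls, gold_variant) if len(gold_variant) else None
    )
    report_comprehensive = concordance.concordance_report(calls, gold_comprehensive)

    gene_models = genereport.simulate_gene_models(design, seed=subseed(base, 3))
    gene_rows = genereport.gene_coverage_report(gene_models, design.target, calls)

    return ExperimentResult(
        config=config, genome=genome, truth=truth, design=design,
        lanes=lanes, lane_results=lane_results, merged_mates=merged, calls=calls,
        track=track, coverage=coverage, uniformity=uniformity,
        insert_dist=insert_dist, enrichment=enrichment,
        gold_variant=gold_variant, gold_comprehensive=gold_comprehensive,
        report_variant=report_variant, report_comprehensive=report_comprehensive,
        gene_models=gene_models, gene_rows=gene_rows,
    )


def write_report(result: ExperimentResult, out_dir: str | Path) -> None:
    """Write the lane-level and sample-level report files of one run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chrom_lengths = result.genome.lengths

    for k, res in enumerate(result.lane_results):
        res.stats.write_tsv(out / f"lane{k}_stats.tsv")
        res.write_sam(out / f"lane{k}_filtered.sam", chrom_lengths)
    with open(out / "enrichment.tsv", "w") as fh:
        fh.write("lane\tenrichment_score\n")
        for k, e in enumerate(result.enrichment):
            fh.write(f"{k}\t{e:.6f}\n")

    result.coverage.write_tsv(out / "coverage.tsv")
    result.uniformity.write_tsv(out / "uniformity.tsv")
    if result.insert_dist is not None:
        result.insert_dist.write_tsv(out / "insert_sizes.tsv")
    result.track.write_bedgraph(out / "depth.bedgraph")

    genotype.write_vcf(result.calls, out / "calls.vcf")
    result.gold_variant.write_tsv(out / "gold_variant_focused.tsv")
    result.gold_comprehensive.write_tsv(out / "gold_comprehensive.tsv")
    if result.report_variant is not None:
        result.report_variant.write_tsv(out / "concordance_variant_focused.tsv")
    result.report_comprehensive.write_tsv(out / "concordance_comprehensive.tsv")

    genereport.write_refflat(result.gene_models, out / "genes.refflat")
    genereport.write_gene_report(result.gene_rows, out / "gene_coverage.tsv")

    from .intervals import write_bed

    write_bed(result.design.target, out / "target.bed")
    write_bed(result.design.probes, out / "probes.bed")
    result.truth.write_vcf(out / "truth.vcf")
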