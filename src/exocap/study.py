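"""Replicated evaluation study: pooled genotyping-quality metrics.

Runs the full pipeline on several independently seeded synthetic capture
experiments under one configuration (by default the package's study
conditions: 2 Mb genome, ~400 exon-like targets, SNV rate 1e-3, 60%
heterozygous, gel-sized inserts, 0.5% base-error rate, 10% duplicates, 12%
off-probe pairs) and pools the counts into five headline metrics:

* ``variant_focused_concordance_pct`` — percent of variant-focused
  gold-standard positions (the planted in-target variants) that received a
  confident call matching truth;
* ``variant_fdr_pct`` — percent of confident variant calls at comprehensive
  gold positions whose true genotype is not a variant;
* ``het_call_disagreement_pct`` — percent of confident heterozygous calls at
  variant-focused gold positions whose true genotype differs;
* ``variant_sensitivity_pct`` — percent of true variants that received a
  confident variant call;
* ``comprehensive_concordance_pct`` — percent of called comprehensive gold
  positions (every target base, mostly homozygous-reference) whose call
  matches truth.

The FDR is scored against the comprehensive standard because a purely
variant-focused standard contains no non-variant positions, making its FDR
structurally zero.  Each metric carries the pooled denominator ``n``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Dict, List, Optional

from .concordance import ConcordanceReport
from .config import RunConfig
from .pipeline import run_experiment, subseed

__all__ = ["ReplicateSummary", "StudyResult", "replicate_study"]


@dataclass
class ReplicateSummary:
    """Per-replicate evidence kept after the experiment itself is discarded."""

    seed: int
    n_pairs: int
    enrichment: List[float]
    truth_on_probe_fraction: float
    n_truth_duplicates: int
    n_duplicates_removed: int
    n_after_dedup: int
    mean_depth: float
    breadth: Dict[int, float]
    target_bases: int
    uniformity_total: int
    insert_mode: int
    insert_median: float
    n_transitions: int
    n_transversions: int
    report_variant: ConcordanceReport
    report_comprehensive: ConcordanceReport


@dataclass
class StudyResult:
    """Replicate summaries plus pooled metrics ``{name: {value, n}}``."""

    replicates: List[ReplicateSummary]
    metrics: Dict[str, Dict[str, float]]


def _summarize(seed: int, config: RunConfig) -> ReplicateSummary:
    from .concordance import _TRANSITIONS  # shared transition definition

    result = run_experiment(config, seed=seed)
    if result.report_variant is None:
        raise ValueError(
            f"replicate seed {seed}: no planted variants inside the target; "
            "increase genome size or snv_rate"
        )
    ts = tv = 0
    for c in result.calls:
        for alt in c.alt_alleles:
            if frozenset((c.ref, alt)) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    return ReplicateSummary(
        seed=seed,
        n_pairs=sum(len(lane) for lane in result.lanes),
        enrichment=list(result.enrichment),
        truth_on_probe_fraction=(
            sum(p.on_probe for lane in result.lanes for p in lane.pairs)
            / sum(len(lane) for lane in result.lanes)
        ),
        n_truth_duplicates=sum(lane.n_duplicates for lane in result.lanes),
        n_duplicates_removed=sum(
            r.stats.n_duplicates_removed for r in result.lane_results
        ),
        n_after_dedup=sum(r.stats.n_after_dedup for r in result.lane_results),
        mean_depth=result.coverage.mean_depth,
        breadth=dict(result.coverage.breadth),
        target_bases=result.coverage.target_bases,
        uniformity_total=result.uniformity.total,
        insert_mode=result.insert_dist.mode,
        insert_median=result.insert_dist.median,
        n_transitions=ts,
        n_transversions=tv,
        report_variant=result.report_variant,
        report_comprehensive=result.report_comprehensive,
    )


def replicate_study(
    seed: int,
    n_replicates: int = 3,
    config: Optional[RunConfig] = None,
) -> StudyResult:
    """Run ``n_replicates`` independently seeded experiments and pool counts.

    Replicate seeds are derived deterministically from ``seed``; the defaults
    of :class:`exocap.config.RunConfig` define the study conditions.
    Experiments are processed one at a time so memory stays bounded.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    cfg = copy.deepcopy(config) if config is not None else RunConfig()

    summaries = [
        _summarize(subseed(seed, 1000 + r), cfg) for r in range(n_replicates)
    ]

    def pooled(num: int, den: int) -> float:
        return 100.0 * num / den if den else 0.0

    vf = [s.report_variant for s in summaries]
    comp = [s.report_comprehensive for s in summaries]

    n_vf_gold = sum(r.n_gold for r in vf)
    n_vf_match = sum(r.n_called - r.n_disagree for r in vf)
    n_gold_variants = sum(r.n_gold_variants for r in vf)
    n_detected = sum(r.n_variants_detected for r in vf)
    n_het_calls = sum(r.n_het_calls_at_gold for r in vf)
    n_het_disagree = sum(r.n_het_call_disagreements for r in vf)
    n_variant_calls = sum(r.n_variant_calls_at_gold for r in comp)
    n_false_variant = sum(r.n_false_variant_calls for r in comp)
    n_comp_called = sum(r.n_called for r in comp)
    n_comp_match = sum(r.n_called - r.n_disagree for r in comp)

    metrics = {
        "variant_focused_concordance_pct": {
            "value": pooled(n_vf_match, n_vf_gold), "n": n_vf_gold,
        },
        "variant_fdr_pct": {
            "value": pooled(n_false_variant, n_variant_calls), "n": n_variant_calls,
        },
        "het_call_disagreement_pct": {
            "value": pooled(n_het_disagree, n_het_calls), "n": n_het_calls,
        },
        "variant_sensitivity_pct": {
            "value": pooled(n_detected, n_gold_variants), "n": n_gold_variants,
        },
        "comprehensive_concordance_pct": {
            "value": pooled(n_comp_match, n_comp_called), "n": n_comp_called,
        },
    }
    return StudyResult(replicates=summaries, metrics=metrics)
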