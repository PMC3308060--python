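"""Gold-standard construction and genotype-concordance metrics.

Two flavors of gold standard are supported, mirroring the two kinds of
trusted genotype sets used to benchmark capture genotyping:

* ``variant_focused`` — mostly (here: exclusively) non-reference genotypes,
  like an array-genotyping panel that targets polymorphic positions by
  design;
* ``comprehensive`` — every confidently genotyped position, the large
  majority homozygous-reference, like a deep whole-genome sequencing call
  set.

The report computes, over gold-standard positions:

* percent genotyped — gold positions that received a confident call;
* genotype disagreement — percent of the called genotypes that disagree with
  the gold genotype (called-positions denominator);
* variant sensitivity — percent of gold positions with a variant genotype
  that were called as variants;
* variant FDR — percent of variant calls at gold positions whose gold
  genotype is not a variant;
* the heterozygous-specific versions of both, plus the disagreement rate of
  heterozygous calls;
* the transition/transversion ratio of the called variants.

"Called as variant" means a confident call whose genotype contains at least
one non-reference allele; a het called hom-alt therefore counts as a detected
variant but a discordant genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .genotype import GenotypeCall
from .intervals import IntervalSet
from .simulate import DiploidTruth, SimulatedGenome

__all__ = [
    "GoldStandard",
    "ConcordanceReport",
    "build_gold_standard",
    "gold_standard_from_truth",
    "concordance_report",
    "ts_tv_ratio",
]

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


@dataclass
class GoldEntry:
    chrom: str
    pos: int  # 0-based
    ref: str
    genotype: Tuple[str, str]  # sorted allele pair

    @property
    def is_variant(self) -> bool:
        return any(a != self.ref for a in self.genotype)

    @property
    def is_het(self) -> bool:
        return self.genotype[0] != self.genotype[1]


@dataclass
class GoldStandard:
    """Trusted genotypes at a set of positions."""

    entries: List[GoldEntry]
    flavor: str  # "variant_focused" | "comprehensive"

    def __post_init__(self) -> None:
        if self.flavor not in ("variant_focused", "comprehensive"):
            raise ValueError("flavor must be 'variant_focused' or 'comprehensive'")
        self.by_pos: Dict[Tuple[str, int], GoldEntry] = {
            (e.chrom, e.pos): e for e in self.entries
        }
        if len(self.by_pos) != len(self.entries):
            raise ValueError("gold-standard positions must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    def write_tsv(self, path: str | Path) -> None:
        """TSV with 1-based positions: chrom, pos, ref, genotype (e.g. A/G)."""
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tref\tgenotype\n")
            for e in sorted(self.entries, key=lambda e: (e.chrom, e.pos)):
                fh.write(f"{e.chrom}\t{e.pos + 1}\t{e.ref}\t{'/'.join(e.genotype)}\n")

    @classmethod
    def read_tsv(cls, path: str | Path, flavor: str = "comprehensive") -> "GoldStandard":
        entries = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("chrom"):
                raise ValueError(f"{path}: expected header 'chrom\\tpos\\tref\\tgenotype'")
            for line in fh:
                chrom, pos, ref, gt = line.rstrip("\n").split("\t")
                alleles = tuple(sorted(gt.split("/")))
                entries.append(GoldEntry(chrom, int(pos) - 1, ref, alleles))  # type: ignore[arg-type]
        return cls(entries=entries, flavor=flavor)


def build_gold_standard(
    calls: Sequence[GenotypeCall],
    min_quality: float = 100.0,
    flavor: str = "comprehensive",
) -> GoldStandard:
    """Collect high-confidence calls (consensus quality >= ``min_quality``,
    default 100) into a gold standard; the ``variant_focused`` flavor keeps
    only non-hom-ref genotypes."""
    entries = []
    for c in calls:
        if c.qc < min_quality:
            continue
        if flavor == "variant_focused" and not c.is_variant:
            continue
        entries.append(GoldEntry(c.chrom, c.pos, c.ref, c.alleles))
    return GoldStandard(entries=entries, flavor=flavor)


def gold_standard_from_truth(
    truth: DiploidTruth,
    target: IntervalSet,
    genome: SimulatedGenome,
    flavor: str = "variant_focused",
) -> GoldStandard:
    """Gold standard built from simulator truth, restricted to the target.

    ``variant_focused``: the planted variants inside the target.
    ``comprehensive``: every target position with its true genotype (mostly
    homozygous-reference).
    """
    entries: List[GoldEntry] = []
    if flavor == "variant_focused":
        for v in truth.variants:
            if target.contains(v.chrom, v.pos):
                entries.append(GoldEntry(v.chrom, v.pos, v.ref, v.alleles))
    else:
        for chrom, pos in target.positions():
            ref = genome.base_at(chrom, pos)
            entries.append(GoldEntry(chrom, pos, ref, truth.genotype_at(chrom, pos, ref)))
    return GoldStandard(entries=entries, flavor=flavor)


@dataclass
class ConcordanceReport:
    """Genotyping performance against one gold standard (percent scale)."""

    n_gold: int
    n_called: int
    pct_genotyped: float
    n_disagree: int
    pct_disagree: float  # of called gold positions
    n_gold_variants: int
    n_variants_detected: int
    variant_sensitivity_pct: float
    n_variant_calls_at_gold: int
    n_false_variant_calls: int
    variant_fdr_pct: float
    n_gold_hets: int
    n_hets_detected: int
    het_sensitivity_pct: float
    n_het_calls_at_gold: int
    n_false_het_calls: int
    het_fdr_pct: float
    n_het_call_disagreements: int
    het_call_disagreement_pct: float
    ts_tv: Optional[float]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            for k, v in vars(self).items():
                fh.write(f"{k}\t{'' if v is None else v}\n")


def concordance_report(
    calls: Sequence[GenotypeCall], gold: GoldStandard
) -> ConcordanceReport:
    """Score confident calls against a gold standard, restricted to gold
    positions.  ``calls`` should already carry the pipeline's consensus-
    quality filter (>= 50 by default upstream).

    Disagreement uses a called-positions denominator: uncalled gold positions
    lower percent-genotyped, not accuracy.
    """
    if len(gold) == 0:
        raise ValueError("empty gold standard")
    call_at: Dict[Tuple[str, int], GenotypeCall] = {}
    for c in calls:
        key = (c.chrom, c.pos)
        if key in gold.by_pos:
            call_at[key] = c

    n_called = len(call_at)
    n_disagree = 0
    n_gold_variants = n_variants_detected = 0
    n_variant_calls = n_false_variant = 0
    n_gold_hets = n_hets_detected = 0
    n_het_calls = n_false_het = n_het_disagree = 0

    for key, entry in gold.by_pos.items():
        call = call_at.get(key)
        if entry.is_variant:
            n_gold_variants += 1
            if call is not None and call.is_variant:
                n_variants_detected += 1
        if entry.is_het:
            n_gold_hets += 1
            if call is not None and call.is_het:
                n_hets_detected += 1
        if call is None:
            continue
        disagrees = call.alleles != entry.genotype
        if disagrees:
            n_disagree += 1
        if call.is_variant:
            n_variant_calls += 1
            if not entry.is_variant:
                n_false_variant += 1
        if call.is_het:
            n_het_calls += 1
            if not entry.is_het:
                n_false_het += 1
            if disagrees:
                n_het_disagree += 1

    def pct(num: int, den: int) -> float:
        return 100.0 * num / den if den else 0.0

    variant_calls = [c for c in call_at.values() if c.is_variant]
    try:
        tstv: Optional[float] = ts_tv_ratio(variant_calls)
    except ValueError:
        tstv = None

    return ConcordanceReport(
        n_gold=len(gold),
        n_called=n_called,
        pct_genotyped=pct(n_called, len(gold)),
        n_disagree=n_disagree,
        pct_disagree=pct(n_disagree, n_called),
        n_gold_variants=n_gold_variants,
        n_variants_detected=n_variants_detected,
        variant_sensitivity_pct=pct(n_variants_detected, n_gold_variants),
        n_variant_calls_at_gold=n_variant_calls,
        n_false_variant_calls=n_false_variant,
        variant_fdr_pct=pct(n_false_variant, n_variant_calls),
        n_gold_hets=n_gold_hets,
        n_hets_detected=n_hets_detected,
        het_sensitivity_pct=pct(n_hets_detected, n_gold_hets),
        n_het_calls_at_gold=n_het_calls,
        n_false_het_calls=n_false_het,
        het_fdr_pct=pct(n_false_het, n_het_calls),
        n_het_call_disagreements=n_het_disagree,
        het_call_disagreement_pct=pct(n_het_disagree, n_het_calls),
        ts_tv=tstv,
    )


def ts_tv_ratio(variant_calls: Iterable[GenotypeCall]) -> float:
    """Transition/transversion ratio of called variants.

    Transitions are A<->G and C<->T; each non-reference allele of a genotype
    contributes once.  Raises if no transversions were observed (the ratio is
    undefined).
    """
    ts = tv = 0
    for c in variant_calls:
        for alt in c.alt_alleles:
            if frozenset((c.ref, alt)) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if tv == 0:
        raise ValueError("Ts/Tv undefined: no transversions observed")
    return ts / tv
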