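"""Gene-level coverage accounting and coding-effect classification.

Gene models come from the UCSC refFlat dialect (geneName, name, chrom,
strand, txStart, txEnd, cdsStart, cdsEnd, exonCount, exonStarts, exonEnds;
0-based half-open, exon lists comma-separated).  For coverage accounting the
CDS exons of all transcripts sharing a gene name are collapsed to their
union; effect classification uses each transcript's own reading frame.

The gene report answers two questions per gene: how much of its coding
sequence the capture design targets at all, and for how much of it the
pipeline could confidently call genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from Bio.Seq import Seq

from .genotype import GenotypeCall
from .intervals import EmptyIntervalSetError, GenomicInterval, IntervalSet, fraction_contained
from .simulate import SimulatedGenome

__all__ = [
    "GeneModel",
    "GeneCoverageRow",
    "read_refflat",
    "write_refflat",
    "gene_coverage_report",
    "coding_effect",
    "RefFlatParseError",
    "simulate_gene_models",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class RefFlatParseError(ValueError):
    """A refFlat line could not be parsed; the message names the line number."""


@dataclass
class GeneModel:
    """One transcript: CDS exons plus the frame anchored at the CDS start.

    ``frame_ok`` flags models whose concatenated CDS length is divisible by
    three; models failing this are flagged, never silently classified.
    ``coding`` is False for non-coding transcripts (cdsStart == cdsEnd).
    """

    name: str
    transcript: str
    chrom: str
    strand: str  # '+' | '-'
    cds_exons: List[GenomicInterval] = field(default_factory=list)
    tx_start: int = 0
    tx_end: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        self.cds_exons = sorted(self.cds_exons)
        for a, b in zip(self.cds_exons, self.cds_exons[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.transcript}: overlapping CDS exons")

    @property
    def coding(self) -> bool:
        return bool(self.cds_exons)

    @property
    def cds_length(self) -> int:
        return sum(len(iv) for iv in self.cds_exons)

    @property
    def frame_ok(self) -> bool:
        return self.coding and self.cds_length % 3 == 0

    def cds_interval_set(self) -> IntervalSet:
        return IntervalSet.from_intervals(self.cds_exons, label=self.name)

    def cds_index_of(self, pos: int) -> Optional[int]:
        """0-based index of a genomic position within the spliced CDS, in
        translation order (respecting strand); None if outside the CDS."""
        offset = 0
        exons = self.cds_exons if self.strand == "+" else list(reversed(self.cds_exons))
        for iv in exons:
            if iv.start <= pos < iv.end:
                if self.strand == "+":
                    return offset + (pos - iv.start)
                return offset + (iv.end - 1 - pos)
            offset += len(iv)
        return None

    def genomic_position_of(self, cds_index: int) -> int:
        exons = self.cds_exons if self.strand == "+" else list(reversed(self.cds_exons))
        offset = 0
        for iv in exons:
            if cds_index < offset + len(iv):
                k = cds_index - offset
                return iv.start + k if self.strand == "+" else iv.end - 1 - k
            offset += len(iv)
        raise IndexError("CDS index out of range")


# ---------------------------------------------------------------------------
# refFlat I/O


def read_refflat(path: str | Path) -> List[GeneModel]:
    """Parse a refFlat table into gene models; exon intervals are clipped to
    [cdsStart, cdsEnd).  Non-coding transcripts yield empty CDS (flagged via
    ``coding``)."""
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 11:
                raise RefFlatParseError(
                    f"{path}:{lineno}: expected 11 tab-separated columns, got {len(f)}"
                )
            try:
                gene, tx, chrom, strand = f[0], f[1], f[2], f[3]
                tx_start, tx_end = int(f[4]), int(f[5])
                cds_start, cds_end = int(f[6]), int(f[7])
                n_exons = int(f[8])
                starts = [int(x) for x in f[9].rstrip(",").split(",") if x]
                ends = [int(x) for x in f[10].rstrip(",").split(",") if x]
            except ValueError as exc:
                raise RefFlatParseError(f"{path}:{lineno}: {exc}") from exc
            if len(starts) != n_exons or len(ends) != n_exons:
                raise RefFlatParseError(f"{path}:{lineno}: exonCount mismatch")
            cds = []
            for s, e in zip(starts, ends):
                cs, ce = max(s, cds_start), min(e, cds_end)
                if cs < ce:
                    cds.append(GenomicInterval(chrom, cs, ce))
            models.append(
                GeneModel(name=gene, transcript=tx, chrom=chrom, strand=strand,
                          cds_exons=cds, tx_start=tx_start, tx_end=tx_end)
            )
    return models


def write_refflat(models: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            exons = m.cds_exons
            starts = ",".join(str(iv.start) for iv in exons) + ","
            ends = ",".join(str(iv.end) for iv in exons) + ","
            cds_start = exons[0].start if exons else m.tx_start
            cds_end = exons[-1].end if exons else m.tx_start
            fh.write(
                "\t".join(
                    [m.name, m.transcript, m.chrom, m.strand,
                     str(m.tx_start or cds_start), str(m.tx_end or cds_end),
                     str(cds_start), str(cds_end), str(len(exons)), starts, ends]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# coverage report


@dataclass
class GeneCoverageRow:
    """Per-gene coding length, percent of coding bases inside the capture
    target, and percent with a confident genotype call."""

    gene: str
    coding_length: int
    pct_targeted: float
    pct_genotyped: float


def gene_coverage_report(
    models: Sequence[GeneModel],
    target: IntervalSet,
    calls: Sequence[GenotypeCall],
) -> List[GeneCoverageRow]:
    """Per gene name (transcripts collapsed to the union of their CDS exons):
    percent of coding bases in the capture target and percent with a call."""
    if not models:
        raise ValueError("no gene models")
    per_gene: Dict[str, List[GenomicInterval]] = {}
    for m in models:
        per_gene.setdefault(m.name, []).extend(m.cds_exons)
    called = {(c.chrom, c.pos) for c in calls}
    rows = []
    for gene in sorted(per_gene):
        cds = IntervalSet.from_intervals(per_gene[gene], label=gene)
        length = cds.total_bases
        if length == 0:
            rows.append(GeneCoverageRow(gene, 0, 0.0, 0.0))
            continue
        pct_target = 100.0 * fraction_contained(cds, target)
        n_called = sum(1 for chrom, pos in cds.positions() if (chrom, pos) in called)
        rows.append(
            GeneCoverageRow(gene, length, pct_target, 100.0 * n_called / length)
        )
    return rows


def write_gene_report(rows: Sequence[GeneCoverageRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tGeneLength\tpct_coding_targeted\tpct_coding_genotyped\n")
        for r in rows:
            fh.write(f"{r.gene}\t{r.coding_length}\t{r.pct_targeted:.2f}\t{r.pct_genotyped:.2f}\n")


# ---------------------------------------------------------------------------
# coding-effect classification


def coding_effect(
    variant: Tuple[int, str, str],
    model: GeneModel,
    genome: SimulatedGenome,
) -> str:
    """Classify a substitution ``(position, ref, alt)`` against one
    transcript: 'synonymous', 'non-synonymous' (stop gain/loss folded in) or
    'non-coding'.  Positions are genomic 0-based; alleles are reference-
    strand.  Raises if ``ref`` mismatches the genome."""
    pos, ref, alt = variant
    if genome.base_at(model.chrom, pos) != ref:
        raise ValueError(
            f"reference allele {ref!r} does not match genome at {model.chrom}:{pos}"
        )
    ci = model.cds_index_of(pos)
    if ci is None:
        return "non-coding"
    if not model.frame_ok:
        raise ValueError(f"{model.transcript}: CDS length not divisible by 3")
    codon_start = 3 * (ci // 3)
    within = ci % 3
    codon = []
    for k in range(3):
        gpos = model.genomic_position_of(codon_start + k)
        base = genome.base_at(model.chrom, gpos)
        codon.append(base if model.strand == "+" else _COMPLEMENT[base])
    alt_cds = alt if model.strand == "+" else _COMPLEMENT[alt]
    alt_codon = list(codon)
    alt_codon[within] = alt_cds
    aa_ref = str(Seq("".join(codon)).translate())
    aa_alt = str(Seq("".join(alt_codon)).translate())
    return "synonymous" if aa_ref == aa_alt else "non-synonymous"


def most_severe_effect(
    variant: Tuple[int, str, str],
    models: Sequence[GeneModel],
    genome: SimulatedGenome,
) -> str:
    """Across transcripts: non-synonymous > synonymous > non-coding."""
    rank = {"non-coding": 0, "synonymous": 1, "non-synonymous": 2}
    best = "non-coding"
    for m in models:
        if not m.coding:
            continue
        eff = coding_effect(variant, m, genome)
        if rank[eff] > rank[best]:
            best = eff
    return best


def effect_summary(
    calls: Sequence[GenotypeCall],
    models: Sequence[GeneModel],
    genome: SimulatedGenome,
) -> Dict[str, int]:
    """Tabulate called variants by zygosity and coding effect (synonymous /
    non-synonymous), transcript multiplicity resolved to the most severe."""
    by_chrom: Dict[str, List[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    out = {
        "het_synonymous": 0, "het_non_synonymous": 0, "het_non_coding": 0,
        "hom_synonymous": 0, "hom_non_synonymous": 0, "hom_non_coding": 0,
    }
    for c in calls:
        if not c.is_variant:
            continue
        cands = [
            m for m in by_chrom.get(c.chrom, [])
            if any(iv.start <= c.pos < iv.end for iv in m.cds_exons)
        ]
        for alt in c.alt_alleles:
            if cands:
                eff = most_severe_effect((c.pos, c.ref, alt), cands, genome)
            else:
                eff = "non-coding"
            zyg = "het" if c.is_het else "hom"
            out[f"{zyg}_{eff.replace('-', '_')}"] += 1
    return out


# ---------------------------------------------------------------------------
# synthetic gene models over a capture design


def simulate_gene_models(
    design,
    exons_per_gene: int = 3,
    seed: int = 0,
) -> List[GeneModel]:
    """Group consecutive simulated target features into multi-exon genes with
    random strands; the last exon is trimmed by 0-2 bases so every CDS length
    is divisible by three.  Untargeted features become genes absent from the
    probe design, emulating genes a capture kit does not cover."""
    import numpy as np

    rng = np.random.default_rng(seed)
    targets = design.all_targets
    models: List[GeneModel] = []
    i = 0
    g = 0
    while i < len(targets):
        chunk = [t for t in targets[i : i + exons_per_gene] if t.chrom == targets[i].chrom]
        i += len(chunk)
        g += 1
        total = sum(len(t) for t in chunk)
        trim = total % 3
        last = chunk[-1]
        exons = list(chunk[:-1]) + [GenomicInterval(last.chrom, last.start, last.end - trim)]
        strand = "+" if rng.random() < 0.5 else "-"
        name = f"GENE{g:04d}"
        models.append(
            GeneModel(
                name=name, transcript=f"{name}.1", chrom=last.chrom, strand=strand,
                cds_exons=exons, tx_start=exons[0].start, tx_end=exons[-1].end,
            )
        )
    return models
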