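"""Synthetic hybrid-capture experiment generator with known truth.

Emulates, at desk scale, the ingredients of a solution exome-capture
experiment: a random reference genome, planted diploid SNVs (heterozygous and
homozygous-alternate), an exon-like target/probe design, paired-end libraries
with either a narrow gel-excision insert-size distribution (150-250 bp,
peaking at 200 bp) or a broad bead-selection distribution (~100 bp extending
beyond 300 bp), configurable off-probe pair fraction, PCR duplicates,
adapter read-through for inserts shorter than the read length, and
Phred-scaled base errors.

Truth alignments are emitted directly — the generator knows the true locus of
every fragment — so the downstream pipeline can be exercised without an
external aligner; real aligner output can be substituted through the same
SAM interface.  Everything is deterministic per (seed, configuration).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import truncnorm

from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "SimulatedGenome",
    "Variant",
    "DiploidTruth",
    "CaptureDesign",
    "InsertModel",
    "LibraryProfile",
    "SimulatedPair",
    "SimulatedLane",
    "simulate_genome",
    "plant_variants",
    "design_capture",
    "simulate_lane",
    "TRUSEQ_ADAPTER_R1",
    "TRUSEQ_ADAPTER_R2",
]

# Illumina TruSeq adapter starts, as read through at the 3' end of R1/R2.
TRUSEQ_ADAPTER_R1 = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
TRUSEQ_ADAPTER_R2 = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGT"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTNacgtn", b"TGCANtgcan"):
    _COMP[_a] = _b


def seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def revcomp(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr[::-1]]


# ---------------------------------------------------------------------------
# genome


@dataclass
class SimulatedGenome:
    """A reference genome as per-chromosome uint8 ASCII arrays (A/C/G/T)."""

    sequences: Dict[str, np.ndarray]
    seed: int = 0

    @property
    def lengths(self) -> Dict[str, int]:
        return {c: int(len(s)) for c, s in self.sequences.items()}

    def base_at(self, chrom: str, pos: int) -> str:
        return chr(self.sequences[chrom][pos])

    def subsequence(self, chrom: str, start: int, end: int) -> str:
        return array_to_seq(self.sequences[chrom][start:end])

    def gc_fraction(self, chrom: str) -> float:
        s = self.sequences[chrom]
        return float(((s == ord("G")) | (s == ord("C"))).mean())

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.sequences):
                fh.write(f">{chrom}\n")
                seq = array_to_seq(self.sequences[chrom])
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    @classmethod
    def read_fasta(cls, path: str | Path) -> "SimulatedGenome":
        from Bio import SeqIO

        sequences = {
            rec.id: seq_to_array(str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")
        }
        return cls(sequences=sequences, seed=-1)


def simulate_genome(
    chrom_lengths: Mapping[str, int], gc_fraction: float = 0.41, seed: int = 0
) -> SimulatedGenome:
    """Generate i.i.d. random chromosomes with the requested GC content.

    Chromosomes must be at least 1 kb — shorter sequences cannot host a
    capture design.  Deterministic per seed.
    """
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    probs = [at, gc, gc, at]  # A C G T
    sequences = {}
    for chrom, n in chrom_lengths.items():
        n = int(n)
        if n < 1000:
            raise ValueError(f"chromosome {chrom!r} shorter than 1 kb ({n})")
        sequences[chrom] = _BASES[rng.choice(4, size=n, p=probs)]
    return SimulatedGenome(sequences=sequences, seed=seed)


# ---------------------------------------------------------------------------
# variants

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    genotype: str  # "het" | "hom"
    haplotype: int = 0  # which haplotype carries the alt allele when het

    @property
    def alleles(self) -> Tuple[str, str]:
        """Sorted diploid allele pair."""
        if self.genotype == "hom":
            return (self.alt, self.alt)
        return tuple(sorted((self.ref, self.alt)))  # type: ignore[return-value]


@dataclass
class DiploidTruth:
    """Planted diploid SNVs: positions, alleles and phase are exactly known."""

    variants: List[Variant]
    seed: int = 0

    def __post_init__(self) -> None:
        self.by_pos: Dict[Tuple[str, int], Variant] = {
            (v.chrom, v.pos): v for v in self.variants
        }
        if len(self.by_pos) != len(self.variants):
            raise ValueError("variant positions must be unique")

    def __len__(self) -> int:
        return len(self.variants)

    def genotype_at(self, chrom: str, pos: int, ref: str) -> Tuple[str, str]:
        v = self.by_pos.get((chrom, pos))
        if v is None:
            return (ref, ref)
        return v.alleles

    def haplotypes(self, genome: SimulatedGenome) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
        """The two haplotype sequences implied by the planted variants."""
        haps = {}
        for chrom, seq in genome.sequences.items():
            h0, h1 = seq.copy(), seq.copy()
            haps[chrom] = (h0, h1)
        for v in self.variants:
            h0, h1 = haps[v.chrom]
            alt = ord(v.alt)
            if v.genotype == "hom":
                h0[v.pos] = alt
                h1[v.pos] = alt
            else:
                (h0 if v.haplotype == 0 else h1)[v.pos] = alt
        return haps

    def write_vcf(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ttruth\n")
            for v in sorted(self.variants, key=lambda v: (v.chrom, v.pos)):
                gt = "0/1" if v.genotype == "het" else "1/1"
                fh.write(
                    f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gt}\n"
                )


def plant_variants(
    genome: SimulatedGenome,
    snv_rate: float,
    het_fraction: float = 0.6,
    transition_prob: float = 2.0 / 3.0,
    seed: int = 0,
) -> DiploidTruth:
    """Plant SNVs at rate ``snv_rate`` per base; a ``het_fraction`` share are
    heterozygous (phase assigned at planting so all lanes of a sample share
    haplotypes); alternates are transitions with probability
    ``transition_prob`` (default 2/3, i.e. Ts/Tv expectation 2.0)."""
    for name, val in [("snv_rate", snv_rate), ("het_fraction", het_fraction),
                      ("transition_prob", transition_prob)]:
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    variants: List[Variant] = []
    for chrom in sorted(genome.sequences):
        seq = genome.sequences[chrom]
        positions = np.flatnonzero(rng.random(len(seq)) < snv_rate)
        for pos in positions:
            ref = chr(seq[pos])
            if rng.random() < transition_prob:
                alt = _TRANSITION[ref]
            else:
                alt = _TRANSVERSIONS[ref][rng.integers(2)]
            het = rng.random() < het_fraction
            variants.append(
                Variant(
                    chrom=chrom,
                    pos=int(pos),
                    ref=ref,
                    alt=alt,
                    genotype="het" if het else "hom",
                    haplotype=int(rng.integers(2)) if het else 0,
                )
            )
    return DiploidTruth(variants=variants, seed=seed)


# ---------------------------------------------------------------------------
# capture design


@dataclass
class CaptureDesign:
    """Intended target vs probe span.  A configurable fraction of target
    features carries no probes, emulating genes absent from a kit design."""

    target: IntervalSet
    probes: IntervalSet
    probed_targets: List[GenomicInterval]
    untargeted_targets: List[GenomicInterval]
    probe_margin: int = 0
    annotation: Optional[list] = None  # list[GeneModel], attached on demand

    @property
    def all_targets(self) -> List[GenomicInterval]:
        return sorted(self.probed_targets + self.untargeted_targets)


def design_capture(
    genome: SimulatedGenome,
    n_targets: int,
    target_length_mean: float = 150.0,
    target_length_sd: float = 35.0,
    min_target_length: int = 60,
    probe_margin: int = 0,
    untargeted_fraction: float = 0.0,
    min_gap: int = 300,
    seed: int = 0,
) -> CaptureDesign:
    """Place ``n_targets`` non-overlapping exon-like features (mean length
    ~150 bp, the genome-wide average exon length) and tile probes over all but
    an ``untargeted_fraction`` of them, each probe extending ``probe_margin``
    bases into the flanks."""
    if not 0.0 <= untargeted_fraction <= 1.0:
        raise ValueError("untargeted_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    chroms = sorted(genome.sequences)
    lens = np.array([len(genome.sequences[c]) for c in chroms], dtype=float)
    counts = rng.multinomial(n_targets, lens / lens.sum())

    targets: List[GenomicInterval] = []
    for chrom, k in zip(chroms, counts):
        if k == 0:
            continue
        chrom_len = len(genome.sequences[chrom])
        lengths = np.maximum(
            np.rint(rng.normal(target_length_mean, target_length_sd, size=k)),
            min_target_length,
        ).astype(int)
        needed = int(lengths.sum()) + (k + 1) * min_gap
        extra = chrom_len - needed
        if extra < 0:
            raise ValueError(
                f"genome too small: chromosome {chrom} ({chrom_len} bp) cannot "
                f"host {k} targets of mean length {target_length_mean}"
            )
        gaps = min_gap + rng.multinomial(extra, np.full(k + 1, 1.0 / (k + 1)))
        pos = 0
        for i in range(k):
            pos += int(gaps[i])
            targets.append(GenomicInterval(chrom, pos, pos + int(lengths[i])))
            pos += int(lengths[i])

    untargeted_mask = rng.random(len(targets)) < untargeted_fraction
    probed = [t for t, u in zip(targets, untargeted_mask) if not u]
    untargeted = [t for t, u in zip(targets, untargeted_mask) if u]

    chrom_lengths = genome.lengths
    probe_tuples = []
    for t in probed:
        s = max(0, t.start - probe_margin)
        e = min(chrom_lengths[t.chrom], t.end + probe_margin)
        probe_tuples.append((t.chrom, s, e))
    return CaptureDesign(
        target=IntervalSet.from_intervals(targets, label="intended-target"),
        probes=IntervalSet.from_tuples(probe_tuples, label="probes"),
        probed_targets=probed,
        untargeted_targets=untargeted,
        probe_margin=probe_margin,
    )


# ---------------------------------------------------------------------------
# library profile


@dataclass(frozen=True)
class InsertModel:
    """Insert-length distribution: ``gel`` = truncated normal (tight
    excision-based selection), ``bead`` = min-clipped lognormal (relaxed
    small-fragment exclusion)."""

    kind: str  # "gel" | "bead"
    mean: float = 200.0  # gel: normal mean; bead: median
    sd: float = 25.0  # gel: normal sd; bead: sigma of log
    minimum: int = 150
    maximum: int = 250  # gel only

    def __post_init__(self) -> None:
        if self.kind not in ("gel", "bead"):
            raise ValueError("insert model kind must be 'gel' or 'bead'")
        if self.minimum <= 0:
            raise ValueError("insert minimum must be positive")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "gel":
            a = (self.minimum - self.mean) / self.sd
            b = (self.maximum - self.mean) / self.sd
            vals = truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=n, random_state=rng)
        else:
            vals = np.exp(rng.normal(np.log(self.mean), self.sd, size=n))
            for _ in range(100):
                low = vals < self.minimum
                if not low.any():
                    break
                vals[low] = np.exp(rng.normal(np.log(self.mean), self.sd, size=int(low.sum())))
            vals = np.maximum(vals, self.minimum)
        return np.rint(vals).astype(np.int64)


def gel_insert_model(mean: float = 200.0, sd: float = 25.0, minimum: int = 150,
                     maximum: int = 250) -> InsertModel:
    return InsertModel("gel", mean=mean, sd=sd, minimum=minimum, maximum=maximum)


def bead_insert_model(median: float = 190.0, sigma: float = 0.4,
                      minimum: int = 100) -> InsertModel:
    return InsertModel("bead", mean=median, sd=sigma, minimum=minimum, maximum=0)


@dataclass(frozen=True)
class LibraryProfile:
    """Sequencing-library configuration for one lane."""

    read_length: int = 76
    insert_model: InsertModel = field(default_factory=gel_insert_model)
    error_rate: float = 0.005
    duplicate_rate: float = 0.0
    off_probe_fraction: float = 0.0
    adapter1: str = TRUSEQ_ADAPTER_R1
    adapter2: str = TRUSEQ_ADAPTER_R2
    ambiguous_fraction: float = 0.0  # pairs planted in repeat-like sequence (MQ 0)
    anchor_bases: int = 20  # min per-mate probe overlap of captured fragments

    def __post_init__(self) -> None:
        for name in ("error_rate", "duplicate_rate", "off_probe_fraction", "ambiguous_fraction"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")

    @classmethod
    def gel(cls, **kw) -> "LibraryProfile":
        return cls(insert_model=gel_insert_model(), **kw)

    @classmethod
    def bead(cls, **kw) -> "LibraryProfile":
        return cls(insert_model=bead_insert_model(), **kw)

    @classmethod
    def nimblegen_like(cls, **kw) -> "LibraryProfile":
        """Gel-sized library with the on-probe fraction centred in the
        87.20-90.27% enrichment band."""
        kw.setdefault("off_probe_fraction", 1.0 - 0.8874)
        return cls(insert_model=gel_insert_model(), **kw)

    @classmethod
    def agilent_like(cls, **kw) -> "LibraryProfile":
        """Bead-sized library with the on-probe fraction centred in the
        69.25-71.50% enrichment band."""
        kw.setdefault("off_probe_fraction", 1.0 - 0.7038)
        return cls(insert_model=bead_insert_model(), **kw)


def _quality_model(error_rate: float) -> Tuple[float, float, int, int, float]:
    """Two-state (high/low) per-base quality model whose mixture mean equals
    ``error_rate``.  Returns (e_high, e_low, q_high, q_low, p_low)."""
    if error_rate <= 0.0:
        return 0.0, 0.0, 40, 40, 0.0
    p_low = 0.15
    e_low = min(0.1, 4.0 * error_rate)
    e_high = max(1e-4, (error_rate - p_low * e_low) / (1.0 - p_low))
    q_high = int(np.clip(np.rint(-10.0 * np.log10(e_high)), 2, 40))
    q_low = int(np.clip(np.rint(-10.0 * np.log10(e_low)), 2, 40))
    return e_high, e_low, q_high, q_low, p_low


# ---------------------------------------------------------------------------
# lane simulation


@dataclass
class SimulatedPair:
    """One sequenced read pair with full provenance.

    ``r1``/``q1`` are read-space (5'->3' as sequenced); r1 is the forward
    mate, r2 the reverse mate (its genomic segment reverse-complemented).
    ``errors1``/``errors2`` record (read offset, observed base) for every
    planted sequencing error, so each read is reconstructible from
    (haplotype, coordinates, errors).
    """

    name: str
    chrom: str
    insert_start: int
    insert_end: int
    haplotype: int
    on_probe: bool
    mapq: int
    is_duplicate: bool
    duplicate_of: Optional[str]
    r1: np.ndarray
    q1: np.ndarray
    r2: np.ndarray
    q2: np.ndarray
    errors1: Tuple[Tuple[int, str], ...] = ()
    errors2: Tuple[Tuple[int, str], ...] = ()

    @property
    def insert_length(self) -> int:
        return self.insert_end - self.insert_start


@dataclass
class SimulatedLane:
    """One lane of simulated paired-end capture data plus its truth."""

    pairs: List[SimulatedPair]
    genome: SimulatedGenome
    truth: DiploidTruth
    design: CaptureDesign
    profile: LibraryProfile
    seed: int

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n_duplicates(self) -> int:
        return sum(p.is_duplicate for p in self.pairs)

    @property
    def n_off_probe(self) -> int:
        return sum(not p.on_probe for p in self.pairs)

    def truth_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "name": [p.name for p in self.pairs],
                "chrom": [p.chrom for p in self.pairs],
                "insert_start": [p.insert_start for p in self.pairs],
                "insert_end": [p.insert_end for p in self.pairs],
                "insert_length": [p.insert_length for p in self.pairs],
                "haplotype": [p.haplotype for p in self.pairs],
                "on_probe": [p.on_probe for p in self.pairs],
                "is_duplicate": [p.is_duplicate for p in self.pairs],
                "duplicate_of": [p.duplicate_of or "" for p in self.pairs],
                "mapq": [p.mapq for p in self.pairs],
            }
        )

    def write_truth_table(self, path: str | Path) -> None:
        self.truth_table().to_csv(path, sep="\t", index=False)

    def write_fastq(self, path_r1: str | Path, path_r2: str | Path) -> None:
        with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
            for p in self.pairs:
                f1.write(
                    f"@{p.name}/1\n{array_to_seq(p.r1)}\n+\n"
                    f"{''.join(chr(q + 33) for q in p.q1)}\n"
                )
                f2.write(
                    f"@{p.name}/2\n{array_to_seq(p.r2)}\n+\n"
                    f"{''.join(chr(q + 33) for q in p.q2)}\n"
                )

    def write_truth_sam(self, path: str | Path) -> None:
        """True alignments: positions, strands and mapping qualities the
        generator planted.  Adapter read-through bases appear soft-clipped."""
        import pysam

        chroms = sorted(self.genome.sequences)
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": len(self.genome.sequences[c])} for c in chroms],
        }
        tid = {c: i for i, c in enumerate(chroms)}
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for p in self.pairs:
                R = self.profile.read_length
                L = p.insert_length
                n_aln = min(R, L)
                pad = R - n_aln
                for mate_idx in (1, 2):
                    a = pysam.AlignedSegment(out.header)
                    a.query_name = p.name
                    a.reference_id = tid[p.chrom]
                    a.next_reference_id = tid[p.chrom]
                    a.mapping_quality = p.mapq
                    is_r2 = mate_idx == 2
                    a.flag = (
                        0x1 | 0x2 | (0x10 if is_r2 else 0x20) | (0x80 if is_r2 else 0x40)
                    )
                    if not is_r2:
                        a.reference_start = p.insert_start
                        a.next_reference_start = max(p.insert_start, p.insert_end - n_aln)
                        a.cigarstring = f"{n_aln}M{pad}S" if pad else f"{n_aln}M"
                        a.query_sequence = array_to_seq(p.r1)
                        a.query_qualities = list(p.q1)
                        a.template_length = L
                    else:
                        a.reference_start = max(p.insert_start, p.insert_end - n_aln)
                        a.next_reference_start = p.insert_start
                        a.cigarstring = f"{pad}S{n_aln}M" if pad else f"{n_aln}M"
                        # SAM stores reverse-strand reads reference-forward
                        a.query_sequence = array_to_seq(revcomp(p.r2))
                        a.query_qualities = list(p.q2[::-1])
                        a.template_length = -L
                    out.write(a)


def _apply_errors(
    read: np.ndarray, rng: np.random.Generator, e_high: float, e_low: float,
    q_high: int, q_low: int, p_low: float,
) -> Tuple[np.ndarray, List[Tuple[int, str]]]:
    n = len(read)
    quals = np.full(n, q_high, dtype=np.uint8)
    if p_low > 0.0:
        low = rng.random(n) < p_low
        quals[low] = q_low
        e = np.where(low, e_low, e_high)
    else:
        e = np.full(n, e_high)
    errors: List[Tuple[int, str]] = []
    if e_high > 0.0 or e_low > 0.0:
        hit = np.flatnonzero(rng.random(n) < e)
        for i in hit:
            old = read[i]
            choices = _BASES[_BASES != old]
            new = choices[rng.integers(len(choices))]
            read[i] = new
            errors.append((int(i), chr(new)))
    return quals, errors


def simulate_lane(
    genome: SimulatedGenome,
    truth: DiploidTruth,
    design: CaptureDesign,
    profile: LibraryProfile,
    n_pairs: int,
    seed: int = 0,
    name_prefix: str = "sim",
) -> SimulatedLane:
    """Simulate one lane of ``n_pairs`` read pairs.

    On-probe fragments are placed so both mates overlap a probe by at least
    ``profile.anchor_bases`` (a captured fragment hybridised to the probe);
    off-probe fragments are placed uniformly in probe-free sequence.  A
    ``duplicate_rate`` share of pairs are PCR re-emissions of earlier
    fragments with independently re-sampled errors.  Any pair whose
    (chrom, start, end, orientation) key repeats an earlier pair is flagged a
    duplicate in the truth table — coordinate identity is the definition of a
    PCR copy here, so coincidental collisions are flagged too.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    R = profile.read_length
    rng = np.random.default_rng(seed)
    haps = truth.haplotypes(genome)
    chrom_lengths = genome.lengths
    min_chrom = min(chrom_lengths.values())
    if profile.insert_model.minimum >= min_chrom:
        raise ValueError("insert minimum exceeds chromosome length")

    n_dup = int(rng.binomial(n_pairs, profile.duplicate_rate))
    n_orig = max(1, n_pairs - n_dup)
    n_dup = n_pairs - n_orig

    # probe features for weighted placement
    probe_list = [(iv.chrom, iv.start, iv.end) for iv in design.probes]
    if not probe_list and profile.off_probe_fraction < 1.0:
        raise ValueError("design has no probes; only off-probe pairs can be simulated")
    probe_w = None
    if probe_list:
        w = np.array([e - s for _, s, e in probe_list], dtype=float)
        probe_w = w / w.sum()

    chroms = sorted(chrom_lengths)
    chrom_w = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    chrom_w /= chrom_w.sum()

    off_mask = rng.random(n_orig) < profile.off_probe_fraction
    inserts = profile.insert_model.sample(rng, n_orig)
    hap_choice = rng.integers(0, 2, size=n_orig)
    amb_mask = rng.random(n_orig) < profile.ambiguous_fraction
    anchor = profile.anchor_bases

    frags: List[Tuple[str, int, int, int, int]] = []  # chrom, start, end, hap, mapq
    for i in range(n_orig):
        L = int(inserts[i])
        if off_mask[i]:
            for _ in range(200):
                c = chroms[int(rng.choice(len(chroms), p=chrom_w))]
                L_eff = min(L, chrom_lengths[c] - 1)
                s = int(rng.integers(0, chrom_lengths[c] - L_eff + 1))
                if design.probes.overlap_bases(c, s, s + L_eff) == 0:
                    break
            frags.append((c, s, s + L_eff, int(hap_choice[i]), 0 if amb_mask[i] else 60))
        else:
            pc, ps, pe = probe_list[int(rng.choice(len(probe_list), p=probe_w))]
            # both mates must reach the probe, so a short probe can only
            # capture fragments from the short tail of the insert
            # distribution; resample rather than clamp so placements and
            # coordinates stay diverse (a point clamp would make every
            # fragment of a short probe a coordinate duplicate)
            bound = min((pe - ps) + 2 * (R - anchor), chrom_lengths[pc])
            L_eff = L
            for _ in range(200):
                if L_eff <= bound:
                    break
                L_eff = int(profile.insert_model.sample(rng, 1)[0])
            else:
                L_eff = bound
            L_eff = max(L_eff, min(R, chrom_lengths[pc]))
            lo = max(ps + anchor - R, 0)
            hi = min(pe - anchor - L_eff + R, chrom_lengths[pc] - L_eff)
            if hi < lo:
                s = min(max((ps + pe) // 2 - L_eff // 2, 0), chrom_lengths[pc] - L_eff)
            else:
                s = int(rng.integers(lo, hi + 1))
            frags.append((pc, s, s + L_eff, int(hap_choice[i]), 0 if amb_mask[i] else 60))

    # PCR duplicates re-emit an existing fragment (same molecule, same mapq)
    dup_src = rng.integers(0, n_orig, size=n_dup)
    order = rng.permutation(n_orig + n_dup)
    qm = _quality_model(profile.error_rate)
    ad1 = seq_to_array(profile.adapter1)
    ad2 = seq_to_array(profile.adapter2)

    on_probe_flags = [not off_mask[i] for i in range(n_orig)]
    pairs: List[SimulatedPair] = []
    seen: Dict[Tuple[str, int, int], str] = {}
    width = len(str(n_orig + n_dup))
    for rank, idx in enumerate(order):
        src = int(idx) if idx < n_orig else int(dup_src[idx - n_orig])
        chrom, s, e, hap, mapq = frags[src]
        L = e - s
        hseq = haps[chrom][hap]
        n_aln = min(R, L)

        r1 = hseq[s : s + n_aln].copy()
        if n_aln < R:
            fill = np.resize(ad1, R - n_aln)
            r1 = np.concatenate([r1, fill])
        q1, err1 = _apply_errors(r1, rng, *qm)

        r2 = revcomp(hseq[e - n_aln : e])
        if n_aln < R:
            fill = np.resize(ad2, R - n_aln)
            r2 = np.concatenate([r2, fill])
        q2, err2 = _apply_errors(r2, rng, *qm)

        name = f"{name_prefix}:{rank:0{width}d}"
        key = (chrom, s, e)
        first = seen.get(key)
        pairs.append(
            SimulatedPair(
                name=name,
                chrom=chrom,
                insert_start=s,
                insert_end=e,
                haplotype=hap,
                on_probe=on_probe_flags[src],
                mapq=mapq,
                is_duplicate=first is not None,
                duplicate_of=first,
                r1=r1,
                q1=q1,
                r2=r2,
                q2=q2,
                errors1=tuple(err1),
                errors2=tuple(err2),
            )
        )
        if first is None:
            seen[key] = name
    return SimulatedLane(
        pairs=pairs, genome=genome, truth=truth, design=design, profile=profile, seed=seed
    )
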