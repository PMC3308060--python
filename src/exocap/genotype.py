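"""Sample-level processing: lane merging, pileup and consensus genotyping.

The caller is a naive-Bayes diploid consensus model: at each target position
the observed bases (from reads that survived lane filtering, with their
post-collapse Phred qualities) are treated as independent draws from the two
alleles of a diploid genotype; for observation b with error probability e,

    P(b | allele a) = 1 - e       if b == a
                      e / 3       otherwise
    P(b | genotype a1/a2) = (P(b|a1) + P(b|a2)) / 2

Posteriors over the ten diploid genotypes (hom-ref, three hom-alt, three
ref/alt het, three alt/alt het) combine these likelihoods with configurable
priors; the consensus quality is the Phred of the probability that the
maximum-posterior genotype is wrong, q_c = -10 log10 (1 - posterior), capped
at 255.  Calls are filtered at q_c >= 50 by default (a 1e-5 probability of an
incorrect genotype).

Only substitutions are modeled: indel-bearing reads were removed upstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.special import logsumexp

from .intervals import IntervalSet
from .lanefilter import MateRecord
from .simulate import SimulatedGenome

__all__ = [
    "PriorModel",
    "GenotypeCall",
    "phred",
    "unphred",
    "merge_lanes",
    "call_genotypes",
    "genotype_column",
    "write_vcf",
    "read_vcf_calls",
]

_MAX_QC = 255.0

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_LETTERS = "ACGT"

# diploid genotype space: 4 homozygous columns then the 6 unordered het pairs
_HET_PAIRS: List[Tuple[int, int]] = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
_N_GT = 10


def phred(p: float, maximum: float = _MAX_QC) -> float:
    """Phred scale: q = -10 log10 p; p = 0 is capped at ``maximum``."""
    if p < 0 or p > 1:
        raise ValueError("probability must be in [0, 1]")
    if p == 0:
        return maximum
    return min(-10.0 * math.log10(p), maximum)


def unphred(q: float) -> float:
    """Inverse Phred: p = 10^(-q/10)."""
    if q < 0:
        raise ValueError("Phred quality must be non-negative")
    return 10.0 ** (-q / 10.0)


@dataclass(frozen=True)
class PriorModel:
    """Genotype priors: total heterozygous and homozygous-alternate mass
    (remaining mass on hom-ref; each class split evenly over its three
    genotypes; the three alt/alt hets get the tiny product prior since they
    require two non-reference alleles)."""

    het: float = 1e-3
    hom_alt: float = 5e-4

    def __post_init__(self) -> None:
        if not (self.het > 0 and self.hom_alt > 0 and self.het + self.hom_alt < 1):
            raise ValueError("priors must be positive and sum below 1")

    def log_priors_for_ref(self, ref_code: int) -> np.ndarray:
        p = np.empty(_N_GT)
        nonref_het_each = self.het * self.hom_alt / 3.0
        p[:4] = self.hom_alt / 3.0
        p[ref_code] = 1.0 - self.het - self.hom_alt - 3 * nonref_het_each
        for k, (i, j) in enumerate(_HET_PAIRS):
            p[4 + k] = self.het / 3.0 if ref_code in (i, j) else nonref_het_each
        return np.log(p)

    def preference_order(self, ref_code: int) -> List[int]:
        """Tie-break order: hom-ref, then ref/alt hets (alt ascending), then
        hom-alts (ascending), then alt/alt hets (ascending)."""
        ref_hets = [4 + k for k, (i, j) in enumerate(_HET_PAIRS) if ref_code in (i, j)]
        homs = [a for a in range(4) if a != ref_code]
        nonref_hets = [4 + k for k, (i, j) in enumerate(_HET_PAIRS) if ref_code not in (i, j)]
        return [ref_code, *ref_hets, *homs, *nonref_hets]


_GT_ALLELES: List[Tuple[int, int]] = [(a, a) for a in range(4)] + _HET_PAIRS


@dataclass(frozen=True)
class GenotypeCall:
    """A diploid consensus genotype call at one reference position."""

    chrom: str
    pos: int  # 0-based
    ref: str
    alleles: Tuple[str, str]  # sorted
    qc: float  # Phred-scaled consensus quality
    depth: int

    @property
    def is_variant(self) -> bool:
        return any(a != self.ref for a in self.alleles)

    @property
    def is_het(self) -> bool:
        return self.alleles[0] != self.alleles[1]

    @property
    def alt_alleles(self) -> Tuple[str, ...]:
        """Each non-reference allele once."""
        return tuple(sorted({a for a in self.alleles if a != self.ref}))


def merge_lanes(
    lanes: Sequence[Sequence[MateRecord]],
    references: Optional[Sequence[Mapping[str, int]]] = None,
) -> List[MateRecord]:
    """Merge filtered lanes of one sample: multiset union of records,
    coordinate-sorted.  If per-lane reference dictionaries are supplied they
    must be identical."""
    if references is not None:
        first = dict(references[0])
        for ref in references[1:]:
            if dict(ref) != first:
                raise ValueError("lanes were aligned to different reference sets")
    merged: List[MateRecord] = []
    for lane in lanes:
        merged.extend(lane)
    merged.sort(key=lambda m: (m.chrom, m.start))
    return merged


# ---------------------------------------------------------------------------
# pileup sufficient statistics


@dataclass
class PileupStats:
    """Per-target-position sufficient statistics of the observation model.

    For each target base (flat index) and base letter: sums of log(1-e),
    log(e/3) and log((1 - 2e/3)/2) over the observations of that letter, plus
    the total log(e/3) and the observation count.
    """

    s_match: np.ndarray  # (L, 4)
    s_miss: np.ndarray  # (L, 4)
    s_het: np.ndarray  # (L, 4)
    t_miss: np.ndarray  # (L,)
    depth: np.ndarray  # (L,)


def pileup_statistics(
    mates: Iterable[MateRecord],
    target: IntervalSet,
    chrom_lengths: Mapping[str, int],
    chunk: int = 20000,
) -> PileupStats:
    loc = target.locator(chrom_lengths)
    L = target.total_bases
    s_match = np.zeros((L, 4))
    s_miss = np.zeros((L, 4))
    s_het = np.zeros((L, 4))
    t_miss = np.zeros(L)
    depth = np.zeros(L, dtype=np.int64)

    idx_buf: List[np.ndarray] = []
    code_buf: List[np.ndarray] = []
    qual_buf: List[np.ndarray] = []

    def flush() -> None:
        if not idx_buf:
            return
        idx = np.concatenate(idx_buf)
        code = np.concatenate(code_buf)
        q = np.concatenate(qual_buf).astype(float)
        idx_buf.clear()
        code_buf.clear()
        qual_buf.clear()
        e = np.clip(10.0 ** (-q / 10.0), 1e-7, 0.75)
        np.add.at(s_match, (idx, code), np.log1p(-e))
        l_miss = np.log(e / 3.0)
        np.add.at(s_miss, (idx, code), l_miss)
        np.add.at(s_het, (idx, code), np.log(0.5 * (1.0 - 2.0 * e / 3.0)))
        np.add.at(t_miss, idx, l_miss)
        np.add.at(depth, idx, 1)

    pending = 0
    for m in mates:
        lut = loc.get(m.chrom)
        if lut is None:
            continue
        for rs, re_, ro in m.aligned_blocks():
            n = re_ - rs
            idx = lut[rs:re_]
            code = _CODE[m.bases[ro : ro + n]]
            keep = (idx >= 0) & (code < 4)
            if not keep.any():
                continue
            idx_buf.append(idx[keep])
            code_buf.append(code[keep])
            qual_buf.append(np.asarray(m.quals[ro : ro + n])[keep])
            pending += int(keep.sum())
            if pending >= chunk:
                flush()
                pending = 0
    flush()
    return PileupStats(s_match, s_miss, s_het, t_miss, depth)


def _log_likelihoods(stats: PileupStats) -> np.ndarray:
    """(L, 10) genotype log-likelihoods from the sufficient statistics."""
    L = stats.depth.shape[0]
    ll = np.empty((L, _N_GT))
    t = stats.t_miss
    for a in range(4):
        ll[:, a] = stats.s_match[:, a] + t - stats.s_miss[:, a]
    for k, (i, j) in enumerate(_HET_PAIRS):
        ll[:, 4 + k] = (
            stats.s_het[:, i] + stats.s_het[:, j] + t - stats.s_miss[:, i] - stats.s_miss[:, j]
        )
    return ll


def _posteriors(
    ll: np.ndarray, ref_codes: np.ndarray, priors: PriorModel
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Posterior matrix plus, per position, the preferred-order argmax.

    Returns (posteriors (L, 10), best column index (L,), posterior of best).
    Ties in the maximum break toward hom-ref, then per the documented
    lexicographic preference.
    """
    logpost = np.array(ll)
    best_col = np.zeros(ll.shape[0], dtype=np.int64)
    for r in range(4):
        rows = np.flatnonzero(ref_codes == r)
        if rows.size == 0:
            continue
        logpost[rows] += priors.log_priors_for_ref(r)
        order = np.array(priors.preference_order(r))
        sub = logpost[rows][:, order]
        best_col[rows] = order[np.argmax(sub, axis=1)]
    norm = logsumexp(logpost, axis=1, keepdims=True)
    post = np.exp(logpost - norm)
    p_best = post[np.arange(post.shape[0]), best_col]
    return post, best_col, p_best


def _target_coordinates(target: IntervalSet) -> Tuple[List[str], np.ndarray, np.ndarray]:
    """chrom list, per-position chrom index and genomic position, in flat order."""
    chroms: List[str] = []
    ci: List[np.ndarray] = []
    pos: List[np.ndarray] = []
    for chrom in target.chroms:
        arr = target.arrays(chrom)
        k = len(chroms)
        chroms.append(chrom)
        for s, e in arr:
            pos.append(np.arange(s, e, dtype=np.int64))
            ci.append(np.full(int(e - s), k, dtype=np.int64))
    if pos:
        return chroms, np.concatenate(ci), np.concatenate(pos)
    return chroms, np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)


def _reference_codes(
    reference: Union[SimulatedGenome, Mapping[str, np.ndarray]],
    chroms: List[str],
    ci: np.ndarray,
    pos: np.ndarray,
) -> np.ndarray:
    seqs = reference.sequences if isinstance(reference, SimulatedGenome) else reference
    codes = np.empty(len(pos), dtype=np.int64)
    for k, chrom in enumerate(chroms):
        rows = ci == k
        if chrom not in seqs:
            raise KeyError(f"reference does not cover chromosome {chrom!r}")
        codes[rows] = _CODE[np.asarray(seqs[chrom])[pos[rows]]]
    if (codes > 3).any():
        raise ValueError("reference contains a non-ACGT base inside the target")
    return codes


def call_genotypes(
    mates: Iterable[MateRecord],
    reference: Union[SimulatedGenome, Mapping[str, np.ndarray]],
    target: IntervalSet,
    priors: PriorModel = PriorModel(),
    min_quality: float = 50.0,
) -> List[GenotypeCall]:
    """Call consensus genotypes at every target position with at least one
    observation; emit calls with consensus quality >= ``min_quality``
    (pass 0 for all-sites output)."""
    if isinstance(reference, SimulatedGenome):
        chrom_lengths = reference.lengths
    else:
        chrom_lengths = {c: len(s) for c, s in reference.items()}
    stats = pileup_statistics(mates, target, chrom_lengths)
    chroms, ci, pos = _target_coordinates(target)
    if len(pos) == 0:
        return []
    ref_codes = _reference_codes(reference, chroms, ci, pos)
    ll = _log_likelihoods(stats)
    _post, best_col, p_best = _posteriors(ll, ref_codes, priors)
    qc = -10.0 * np.log10(np.clip(1.0 - p_best, 10.0 ** (-_MAX_QC / 10.0), 1.0))
    qc = np.minimum(qc, _MAX_QC)

    emit = (stats.depth > 0) & (qc >= min_quality)
    calls: List[GenotypeCall] = []
    for i in np.flatnonzero(emit):
        a1, a2 = _GT_ALLELES[best_col[i]]
        alleles = tuple(sorted((_LETTERS[a1], _LETTERS[a2])))
        calls.append(
            GenotypeCall(
                chrom=chroms[ci[i]],
                pos=int(pos[i]),
                ref=_LETTERS[ref_codes[i]],
                alleles=alleles,  # type: ignore[arg-type]
                qc=float(round(qc[i], 2)),
                depth=int(stats.depth[i]),
            )
        )
    return calls


def genotype_column(
    ref: str,
    bases: Sequence[str],
    quals: Sequence[float],
    priors: PriorModel = PriorModel(),
) -> Tuple[Tuple[str, str], float, np.ndarray]:
    """Genotype a single pileup column through the same model core as
    :func:`call_genotypes`.  Returns (alleles, consensus quality, posterior
    vector over the 10 genotypes)."""
    if len(bases) != len(quals):
        raise ValueError("bases and qualities differ in length")
    L = 1
    stats = PileupStats(
        s_match=np.zeros((L, 4)),
        s_miss=np.zeros((L, 4)),
        s_het=np.zeros((L, 4)),
        t_miss=np.zeros(L),
        depth=np.array([len(bases)], dtype=np.int64),
    )
    for b, q in zip(bases, quals):
        code = int(_CODE[ord(b)])
        if code > 3:
            raise ValueError(f"non-ACGT observation {b!r}")
        e = float(np.clip(10.0 ** (-float(q) / 10.0), 1e-7, 0.75))
        stats.s_match[0, code] += math.log1p(-e)
        stats.s_miss[0, code] += math.log(e / 3.0)
        stats.s_het[0, code] += math.log(0.5 * (1.0 - 2.0 * e / 3.0))
        stats.t_miss[0] += math.log(e / 3.0)
    ref_code = int(_CODE[ord(ref)])
    if ref_code > 3:
        raise ValueError(f"non-ACGT reference base {ref!r}")
    ll = _log_likelihoods(stats)
    post, best_col, p_best = _posteriors(ll, np.array([ref_code]), priors)
    a1, a2 = _GT_ALLELES[int(best_col[0])]
    alleles = tuple(sorted((_LETTERS[a1], _LETTERS[a2])))
    qc = phred(max(1.0 - float(p_best[0]), 10.0 ** (-_MAX_QC / 10.0)))
    return alleles, qc, post[0]  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# VCF-subset I/O


def write_vcf(calls: Sequence[GenotypeCall], path: str | Path, sample: str = "sample",
              all_sites: bool = False) -> None:
    """Write calls as a VCF subset (QUAL = consensus quality, INFO DP=depth).
    Homozygous-reference calls are emitted as ALT="." records only with
    ``all_sites=True``."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth used">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for c in sorted(calls, key=lambda c: (c.chrom, c.pos)):
            alts = list(c.alt_alleles)
            if not alts and not all_sites:
                continue
            alt_field = ",".join(alts) if alts else "."
            order = [c.ref] + alts
            gt = "/".join(str(order.index(a)) for a in c.alleles)
            fh.write(
                f"{c.chrom}\t{c.pos + 1}\t.\t{c.ref}\t{alt_field}\t{c.qc:g}\tPASS\t"
                f"DP={c.depth}\tGT\t{gt}\n"
            )


def read_vcf_calls(path: str | Path) -> List[GenotypeCall]:
    """Read a VCF subset written by :func:`write_vcf` back into calls."""
    calls = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, pos, _id, ref, alt, qual = f[0], int(f[1]) - 1, f[2], f[3], f[4], f[5]
            depth = 0
            for kv in f[7].split(";"):
                if kv.startswith("DP="):
                    depth = int(kv[3:])
            order = [ref] + ([] if alt == "." else alt.split(","))
            gt = f[9].split(":")[0]
            alleles = tuple(sorted(order[int(i)] for i in gt.split("/")))
            calls.append(
                GenotypeCall(chrom=chrom, pos=pos, ref=ref, alleles=alleles,  # type: ignore[arg-type]
                             qc=float(qual), depth=depth)
            )
    return calls
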