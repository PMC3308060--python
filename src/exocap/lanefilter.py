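"""Lane-level read-pair processing.

Seven steps are applied to each lane of paired-end capture data, in order:

1. adapter clipping — mates are aligned against each other (one
   reverse-complemented); an implied insert shorter than the read length
   means the 3' ends ran into the library adapters and both reads are
   truncated to the insert length;
2. pair mapping quality — the minimum of the two mates' mapping qualities
   (Phred scale, q_m = -10 log10 P with P the probability the reported locus
   is wrong; aligner maximum 60);
3. proper-pair classification — mates on one reference, oriented toward each
   other, outer span at most 1,000 bp (inclusive);
4. PCR-duplicate removal — one representative per identical
   (reference, outer start, outer end, orientation) coordinate key;
5. probe filtering — keep pairs with the maximal mapping quality (equality
   with 60, not a >= threshold) whose mates each overlap a probe region by
   at least 20 aligned bases;
6. overlap collapsing — where the two mates overlap on the reference, the
   overlap is trimmed from the lower-quality mate and the retained base
   qualities are recalibrated (agreement: summed Phred, capped; disagreement:
   higher-quality base at the quality difference); reads whose alignment
   contains an insertion or deletion are dropped;
7. on-target base counting.

All thresholds are configurable; the defaults reproduce the published
pipeline settings (span 1000, probe overlap 20, required MQ 60, quality cap
60).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .intervals import IntervalSet
from .simulate import SimulatedLane, array_to_seq, revcomp, seq_to_array

__all__ = [
    "MateRecord",
    "ReadPairRecord",
    "LaneStats",
    "LaneResult",
    "clip_adapters",
    "classify_pair",
    "pair_mapping_quality",
    "remove_duplicates",
    "probe_filter",
    "collapse_pair",
    "run_lane",
    "write_sam",
    "read_sam_mates",
]

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def _cigar_ops(cigar: str) -> List[Tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if not ops or sum(n for n, _ in ops) == 0:
        raise ValueError(f"unparsable CIGAR {cigar!r}")
    return ops


@dataclass
class MateRecord:
    """One aligned mate, reference-oriented (bases/qualities follow the
    reference forward strand, SAM convention)."""

    chrom: str
    start: int  # 0-based reference start of the aligned portion
    strand: str  # '+' or '-'
    cigar: str
    bases: np.ndarray  # uint8 ASCII
    quals: np.ndarray  # integer Phred
    mapq: int

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError("bases and qualities differ in length")
        if not 0 <= self.mapq <= 255:
            raise ValueError("mapping quality out of range")

    @property
    def has_indel(self) -> bool:
        return any(op in "ID" for _, op in _cigar_ops(self.cigar))

    def aligned_blocks(self) -> List[Tuple[int, int, int]]:
        """(ref_start, ref_end, read_offset) for each match block."""
        blocks = []
        ref = self.start
        read = 0
        for n, op in _cigar_ops(self.cigar):
            if op in "M=X":
                blocks.append((ref, ref + n, read))
                ref += n
                read += n
            elif op in "IS":
                read += n
            elif op in "DN":
                ref += n
        return blocks

    @property
    def end(self) -> int:
        """Reference end (exclusive) of the aligned portion."""
        ref = self.start
        for n, op in _cigar_ops(self.cigar):
            if op in "M=XDN":
                ref += n
        return ref

    def probe_overlap(self, probes: IntervalSet) -> int:
        return sum(
            probes.overlap_bases(self.chrom, s, e) for s, e, _ in self.aligned_blocks()
        )


@dataclass
class ReadPairRecord:
    """One aligned read pair."""

    name: str
    mate1: MateRecord
    mate2: MateRecord

    @property
    def pair_mapq(self) -> int:
        return pair_mapping_quality(self.mate1.mapq, self.mate2.mapq)

    @property
    def outer_start(self) -> int:
        return min(self.mate1.start, self.mate2.start)

    @property
    def outer_end(self) -> int:
        return max(self.mate1.end, self.mate2.end)

    @property
    def span(self) -> int:
        """Outer template span in bases."""
        return self.outer_end - self.outer_start

    def coordinate_key(self) -> Tuple[str, int, int, Tuple[str, str]]:
        left, right = sorted(
            (self.mate1, self.mate2), key=lambda m: (m.start, m.end)
        )
        return (self.mate1.chrom, self.outer_start, self.outer_end,
                (left.strand, right.strand))


def pair_mapping_quality(q1: int, q2: int) -> int:
    """Pair mapping quality: the minimum of the two mates' qualities."""
    return min(q1, q2)


# ---------------------------------------------------------------------------
# step 1: adapter clipping


def clip_adapters(
    bases1: np.ndarray,
    quals1: np.ndarray,
    bases2: np.ndarray,
    quals2: np.ndarray,
    adapter1: str = "",
    adapter2: str = "",
    min_overlap: int = 10,
    max_mismatch_rate: float = 0.1,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, Optional[int], bool]:
    """Mutual-overlap adapter clipping of one read pair (read-space inputs).

    The two reads are compared against each other after reverse-complementing
    read 2, over every candidate insert length; gapless.  A candidate is
    scored ``overlap - 4 * mismatches`` and accepted if its mismatch rate is
    at most ``max_mismatch_rate`` over at least ``min_overlap`` bases.  If the
    winning insert length is shorter than the read length, the 3' flanks are
    checked against the library adapters (when provided) and both reads are
    truncated to the insert length.

    Returns (bases1, quals1, bases2, quals2, inferred insert length or None,
    whether clipping occurred).
    """
    if min_overlap < 5:
        raise ValueError("min_overlap must be >= 5")
    a = np.asarray(bases1)
    b = revcomp(np.asarray(bases2))  # b covers genomic [L - len2, L)
    n1, n2 = len(a), len(b)
    best_L, best_score, best_rate = None, 0, 1.0
    for L in range(min_overlap, n1 + n2 - min_overlap + 1):
        g0 = max(0, L - n2)
        g1 = min(n1, L)
        o = g1 - g0
        if o < min_overlap:
            continue
        mm = int((a[g0:g1] != b[g0 - (L - n2) : g1 - (L - n2)]).sum())
        rate = mm / o
        if rate > max_mismatch_rate:
            continue
        score = o - 4 * mm
        if score > best_score or (score == best_score and best_L is not None and L > best_L):
            best_L, best_score, best_rate = L, score, rate
    if best_L is None:
        return bases1, quals1, bases2, quals2, None, False
    L = best_L
    if L >= max(n1, n2):
        # mates overlap on the reference (or not at all); nothing to clip here
        return bases1, quals1, bases2, quals2, L, False
    # short insert: confirm the flanking bases look like adapter before cutting
    for read, adapter in ((bases1, adapter1), (bases2, adapter2)):
        if not adapter:
            continue
        flank = read[L:]
        m = min(len(flank), len(adapter), 12)
        if m >= 4:
            ad = seq_to_array(adapter)[:m]
            if (flank[:m] != ad).sum() / m > max(max_mismatch_rate, 1.0 / m):
                return bases1, quals1, bases2, quals2, L, False
    return bases1[:L], quals1[:L], bases2[:L], quals2[:L], L, True


# ---------------------------------------------------------------------------
# step 3: proper pairs

PROPER = "proper"


def classify_pair(pair: ReadPairRecord, max_span: int = 1000) -> str:
    """'proper' or 'improper:<reason>'.

    Proper means: both mates mapped to the same reference, on opposite
    strands with the forward-strand mate leftmost (mates oriented toward each
    other), and the outer span at most ``max_span`` bases (inclusive).
    """
    m1, m2 = pair.mate1, pair.mate2
    if m1.chrom is None or m2.chrom is None:
        return "improper:unmapped"
    if m1.chrom != m2.chrom:
        return "improper:different-chrom"
    if m1.strand == m2.strand:
        return "improper:same-strand"
    fw = m1 if m1.strand == "+" else m2
    rv = m2 if fw is m1 else m1
    if fw.start > rv.start or fw.end > rv.end:
        return "improper:wrong-orientation"
    if pair.span > max_span:
        return "improper:span"
    return PROPER


# ---------------------------------------------------------------------------
# step 4: duplicate removal


def remove_duplicates(
    pairs: Sequence[ReadPairRecord],
) -> Tuple[List[ReadPairRecord], List[ReadPairRecord]]:
    """Keep one representative per coordinate key
    (reference, outer start, outer end, orientation).

    Two or more pairs aligned at identical coordinates are PCR copies of one
    original insert; the representative is the pair with the highest summed
    base quality (ties: first in input order).  Returns (retained, removed),
    each in input order.
    """
    best: Dict[tuple, Tuple[int, float]] = {}
    sums = []
    for i, p in enumerate(pairs):
        s = float(p.mate1.quals.sum() + p.mate2.quals.sum())
        sums.append(s)
        key = p.coordinate_key()
        cur = best.get(key)
        if cur is None or s > cur[1]:
            best[key] = (i, s)
    keep_idx = {i for i, _ in best.values()}
    retained = [p for i, p in enumerate(pairs) if i in keep_idx]
    removed = [p for i, p in enumerate(pairs) if i not in keep_idx]
    return retained, removed


# ---------------------------------------------------------------------------
# step 5: probe filtering


def probe_filter(
    pairs: Sequence[ReadPairRecord],
    probes: IntervalSet,
    min_overlap: int = 20,
    required_mq: int = 60,
) -> List[ReadPairRecord]:
    """Keep pairs whose pair mapping quality equals ``required_mq`` and whose
    mates each overlap the probe set by at least ``min_overlap`` aligned
    bases.  Whole reads are kept once the overlap test is met (no trimming to
    probe boundaries)."""
    out = []
    for p in pairs:
        if p.pair_mapq != required_mq:
            continue
        if p.mate1.probe_overlap(probes) < min_overlap:
            continue
        if p.mate2.probe_overlap(probes) < min_overlap:
            continue
        out.append(p)
    return out


# ---------------------------------------------------------------------------
# step 6: overlap collapsing


def collapse_pair(
    pair: ReadPairRecord, quality_cap: int = 60
) -> Tuple[List[MateRecord], int]:
    """Collapse the reference overlap of a proper pair and recalibrate.

    Reads whose CIGAR contains insertions or deletions are dropped (read, not
    pair).  If the surviving mates overlap on the reference, the overlapping
    segment is trimmed from the mate with the lower summed base quality in the
    overlap (tie: mate 2), so no reference base is covered twice by the pair;
    at formerly-overlapping positions of the retained mate, agreement raises
    the quality to min(q_kept + q_trimmed, cap) and disagreement keeps the
    higher-quality base at quality max(q_high - q_low, 0).

    Returns (surviving mates, number of reads dropped for indels).
    """
    mates = []
    dropped = 0
    for m in (pair.mate1, pair.mate2):
        if m.has_indel:
            dropped += 1
        else:
            mates.append(m)
    if len(mates) < 2:
        return mates, dropped

    m1, m2 = mates
    os_, oe = max(m1.start, m2.start), min(m1.end, m2.end)
    if os_ >= oe:
        return mates, dropped

    # pure-match alignment assumed past this point (indel reads already gone,
    # soft clips removed at construction)
    def seg(m: MateRecord) -> Tuple[np.ndarray, np.ndarray]:
        i = os_ - m.start
        return m.bases[i : i + (oe - os_)], m.quals[i : i + (oe - os_)]

    b1, q1 = seg(m1)
    b2, q2 = seg(m2)
    if float(q1.sum()) >= float(q2.sum()):
        winner, loser, wb, wq, lb, lq = m1, m2, b1, q1, b2, q2
    else:
        winner, loser, wb, wq, lb, lq = m2, m1, b2, q2, b1, q1

    agree = wb == lb
    new_b = np.where(agree | (wq >= lq), wb, lb)
    new_q = np.where(
        agree,
        np.minimum(wq.astype(np.int64) + lq.astype(np.int64), quality_cap),
        np.abs(wq.astype(np.int64) - lq.astype(np.int64)),
    )
    wi = os_ - winner.start
    winner.bases = winner.bases.copy()
    winner.quals = winner.quals.astype(np.int64).copy()
    winner.bases[wi : wi + (oe - os_)] = new_b
    winner.quals[wi : wi + (oe - os_)] = new_q
    winner.cigar = f"{len(winner.bases)}M"

    # trim the overlap (the loser's 3' portion) off the loser
    if loser.start >= os_ and loser.end <= oe:
        out = [winner]  # loser entirely inside the overlap
    elif loser.start < os_:
        n = os_ - loser.start
        trimmed = replace(
            loser,
            cigar=f"{n}M",
            bases=loser.bases[:n].copy(),
            quals=loser.quals[:n].copy(),
        )
        out = [winner, trimmed] if winner.start <= trimmed.start else [trimmed, winner]
    else:
        n = loser.end - oe
        trimmed = replace(
            loser,
            start=oe,
            cigar=f"{n}M",
            bases=loser.bases[-n:].copy(),
            quals=loser.quals[-n:].copy(),
        )
        out = [winner, trimmed] if winner.start <= trimmed.start else [trimmed, winner]
    return out, dropped


# ---------------------------------------------------------------------------
# step 7 + orchestration


@dataclass
class LaneStats:
    """Counts entering/surviving each lane-level step plus on-target bases."""

    n_pairs_in: int = 0
    n_pairs_clipped: int = 0
    n_proper: int = 0
    improper_reasons: Counter = field(default_factory=Counter)
    n_after_dedup: int = 0
    n_duplicates_removed: int = 0
    n_on_probe: int = 0
    n_reads_dropped_indel: int = 0
    n_pairs_final: int = 0
    bases_on_target: int = 0
    total_final_bases: int = 0
    insert_lengths: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))

    def to_rows(self) -> List[Tuple[str, object]]:
        rows: List[Tuple[str, object]] = [
            ("pairs_in", self.n_pairs_in),
            ("pairs_adapter_clipped", self.n_pairs_clipped),
            ("proper_pairs", self.n_proper),
        ]
        rows += [(f"improper_{k.split(':', 1)[1]}", v) for k, v in sorted(self.improper_reasons.items())]
        rows += [
            ("after_duplicate_removal", self.n_after_dedup),
            ("duplicates_removed", self.n_duplicates_removed),
            ("on_probe_pairs", self.n_on_probe),
            ("reads_dropped_indel", self.n_reads_dropped_indel),
            ("pairs_final", self.n_pairs_final),
            ("bases_on_target", self.bases_on_target),
            ("total_final_bases", self.total_final_bases),
        ]
        return rows

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("statistic\tvalue\n")
            for k, v in self.to_rows():
                fh.write(f"{k}\t{v}\n")


@dataclass
class LaneResult:
    """Filtered lane: surviving collapsed mates plus per-step statistics."""

    mates: List[MateRecord]
    pairs: List[ReadPairRecord]
    stats: LaneStats

    def write_sam(self, path: str | Path, chrom_lengths: Dict[str, int]) -> None:
        write_sam(self.mates, path, chrom_lengths, stats=self.stats)


@dataclass
class _RawPair:
    name: str
    r1: np.ndarray
    q1: np.ndarray
    r2: np.ndarray
    q2: np.ndarray
    # per-mate alignment: chrom, ref_start, ref_end, strand, mapq
    aln1: Tuple[str, int, int, str, int]
    aln2: Tuple[str, int, int, str, int]


def _raw_pairs_from_lane(lane: SimulatedLane) -> Iterable[_RawPair]:
    R = lane.profile.read_length
    for p in lane.pairs:
        n_aln = min(R, p.insert_length)
        yield _RawPair(
            name=p.name,
            r1=p.r1, q1=p.q1.astype(np.int64),
            r2=p.r2, q2=p.q2.astype(np.int64),
            aln1=(p.chrom, p.insert_start, p.insert_start + n_aln, "+", p.mapq),
            aln2=(p.chrom, p.insert_end - n_aln, p.insert_end, "-", p.mapq),
        )


def _read_fastq(path: str | Path) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    out: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            name = header[1:].split()[0]
            if name.endswith("/1") or name.endswith("/2"):
                name = name[:-2]
            out[name] = (
                seq_to_array(seq),
                np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int64) - 33,
            )
    return out


def _raw_pairs_from_files(
    fastq1: str | Path, fastq2: str | Path, alignments: str | Path
) -> List[_RawPair]:
    import pysam

    reads1 = _read_fastq(fastq1)
    reads2 = _read_fastq(fastq2)
    if set(reads1) != set(reads2):
        raise ValueError("read IDs differ between the two FASTQ files")
    alns: Dict[str, Dict[int, Tuple[str, int, int, str, int]]] = {}
    with pysam.AlignmentFile(str(alignments), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            mate = 2 if rec.is_read2 else 1
            alns.setdefault(rec.query_name, {})[mate] = (
                rec.reference_name,
                int(rec.reference_start),
                int(rec.reference_end),
                "-" if rec.is_reverse else "+",
                int(rec.mapping_quality),
            )
    out = []
    for name in reads1:
        rec = alns.get(name)
        if rec is None or 1 not in rec or 2 not in rec:
            raise ValueError(f"read pair {name!r} in FASTQ has no paired alignment")
        r1, q1 = reads1[name]
        r2, q2 = reads2[name]
        out.append(_RawPair(name=name, r1=r1, q1=q1, r2=r2, q2=q2,
                            aln1=rec[1], aln2=rec[2]))
    return out


def _mate_from_clipped(
    aln: Tuple[str, int, int, str, int], read: np.ndarray, quals: np.ndarray
) -> MateRecord:
    chrom, rs, re_, strand, mapq = aln
    n_aligned = min(len(read), re_ - rs)
    if strand == "+":
        bases = read[:n_aligned]
        q = quals[:n_aligned]
        start = rs
    else:
        bases = revcomp(read[:n_aligned])
        q = quals[:n_aligned][::-1]
        start = re_ - n_aligned
    return MateRecord(
        chrom=chrom, start=start, strand=strand, cigar=f"{n_aligned}M",
        bases=np.ascontiguousarray(bases), quals=np.ascontiguousarray(q).astype(np.int64),
        mapq=mapq,
    )


def run_lane(
    lane: Union[SimulatedLane, Tuple[str, str, str]],
    design,
    config=None,
) -> LaneResult:
    """Run lane-level steps 1-7 on a simulated lane or on
    ``(fastq_r1, fastq_r2, alignments_sam)`` file paths.

    ``design`` provides the probe set (``.probes``) and the intended target
    (``.target``); ``config`` is a :class:`exocap.config.PipelineConfig`
    (defaults used when omitted).  Deterministic.
    """
    from .config import PipelineConfig

    cfg = config or PipelineConfig()
    if isinstance(lane, SimulatedLane):
        raws = list(_raw_pairs_from_lane(lane))
        adapter1, adapter2 = lane.profile.adapter1, lane.profile.adapter2
    else:
        raws = _raw_pairs_from_files(*lane)
        adapter1, adapter2 = cfg.adapter1, cfg.adapter2

    stats = LaneStats(n_pairs_in=len(raws))

    # step 1: adapter clipping; step 2: pair records with min-of-two MQ
    pairs: List[ReadPairRecord] = []
    for rp in raws:
        b1, q1, b2, q2, _insert, clipped = clip_adapters(
            rp.r1, rp.q1, rp.r2, rp.q2, adapter1, adapter2,
            min_overlap=cfg.clip_min_overlap,
            max_mismatch_rate=cfg.clip_max_mismatch_rate,
        )
        if clipped:
            stats.n_pairs_clipped += 1
        pairs.append(
            ReadPairRecord(
                name=rp.name,
                mate1=_mate_from_clipped(rp.aln1, b1, q1),
                mate2=_mate_from_clipped(rp.aln2, b2, q2),
            )
        )

    # step 3: proper pairs
    proper: List[ReadPairRecord] = []
    for p in pairs:
        status = classify_pair(p, max_span=cfg.max_span)
        if status == PROPER:
            proper.append(p)
        else:
            stats.improper_reasons[status] += 1
    stats.n_proper = len(proper)

    # step 4: duplicates
    unique, removed = remove_duplicates(proper)
    stats.n_after_dedup = len(unique)
    stats.n_duplicates_removed = len(removed)

    # step 5: probe + mapping-quality filter
    on_probe = probe_filter(
        unique, design.probes, min_overlap=cfg.min_probe_overlap,
        required_mq=cfg.required_mq,
    )
    stats.n_on_probe = len(on_probe)
    stats.insert_lengths = np.array([p.span for p in on_probe], dtype=np.int64)

    # step 6: overlap collapsing
    final_mates: List[MateRecord] = []
    final_pairs: List[ReadPairRecord] = []
    for p in on_probe:
        mates, dropped = collapse_pair(p, quality_cap=cfg.quality_cap)
        stats.n_reads_dropped_indel += dropped
        if mates:
            final_pairs.append(p)
            final_mates.extend(mates)
    stats.n_pairs_final = len(final_pairs)

    # step 7: bases on target
    target = design.target
    stats.bases_on_target = int(
        sum(
            target.overlap_bases(m.chrom, s, e)
            for m in final_mates
            for s, e, _ in m.aligned_blocks()
        )
    )
    stats.total_final_bases = int(sum(len(m.bases) for m in final_mates))

    final_mates.sort(key=lambda m: (m.chrom, m.start))
    return LaneResult(mates=final_mates, pairs=final_pairs, stats=stats)


# ---------------------------------------------------------------------------
# SAM I/O for filtered output


def write_sam(
    mates: Sequence[MateRecord],
    path: str | Path,
    chrom_lengths: Dict[str, int],
    stats: Optional[LaneStats] = None,
) -> None:
    """Write collapsed mates as single-end SAM records; filtering provenance
    goes into @CO header lines."""
    import pysam

    chroms = sorted(chrom_lengths)
    header: Dict[str, object] = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(chrom_lengths[c])} for c in chroms],
    }
    if stats is not None:
        header["CO"] = [f"exocap lanefilter {k}={v}" for k, v in stats.to_rows()]
    tid = {c: i for i, c in enumerate(chroms)}
    ordered = sorted(mates, key=lambda m: (tid[m.chrom], m.start))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, m in enumerate(ordered):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"collapsed:{i}"
            a.reference_id = tid[m.chrom]
            a.reference_start = m.start
            a.mapping_quality = m.mapq
            a.cigarstring = m.cigar
            a.flag = 16 if m.strand == "-" else 0
            a.query_sequence = array_to_seq(m.bases)
            a.query_qualities = [min(int(q), 93) for q in m.quals]
            out.write(a)


def read_sam_mates(path: str | Path) -> List[MateRecord]:
    """Read a filtered SAM back into MateRecords (single-end convention)."""
    import pysam

    mates = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            mates.append(
                MateRecord(
                    chrom=rec.reference_name,
                    start=int(rec.reference_start),
                    strand="-" if rec.is_reverse else "+",
                    cigar=rec.cigarstring,
                    bases=seq_to_array(rec.query_sequence),
                    quals=np.array(rec.query_qualities, dtype=np.int64),
                    mapq=int(rec.mapping_quality),
                )
            )
    return mates
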