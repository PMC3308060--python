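"""Capture-performance metrics.

Coverage breadth and depth over the intended target, depth-uniformity
histograms, enrichment scores (the fraction of properly mapped pairs that
also map to probe regions), insert-size distributions, replicate depth
correlation and the no-waste raw-data-for-depth model for whole-genome
comparison.

Depth counts post-collapse read bases: a read pair contributes at most one
observation per reference position, matching what the genotype caller sees.
Mean depth alone is a poor summary of capture data — breadth at a depth
threshold (default 1x and 20x, the reliable-variant-detection level) is the
primary metric, and the uniformity histogram shows the full distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .intervals import IntervalSet
from .lanefilter import LaneStats, MateRecord, ReadPairRecord

__all__ = [
    "DepthTrack",
    "CoverageReport",
    "UniformityHistogram",
    "depth_track",
    "coverage_report",
    "enrichment_score",
    "insert_size_distribution",
    "InsertSizeDistribution",
    "depth_correlation",
    "raw_data_for_depth",
]


@dataclass
class DepthTrack:
    """Per-base collapsed read depth over a target interval set, stored in
    the target's flat-index coordinate system."""

    target: IntervalSet
    depth: np.ndarray  # int array, length target.total_bases

    def __post_init__(self) -> None:
        if len(self.depth) != self.target.total_bases:
            raise ValueError("depth array length must equal target size")
        if (self.depth < 0).any():
            raise ValueError("depths must be non-negative")

    def __add__(self, other: "DepthTrack") -> "DepthTrack":
        if other.target != self.target:
            raise ValueError("depth tracks cover different targets")
        return DepthTrack(self.target, self.depth + other.depth)

    @property
    def mean(self) -> float:
        return float(self.depth.mean()) if len(self.depth) else 0.0

    def write_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            i = 0
            for iv in self.target:
                seg = self.depth[i : i + len(iv)]
                # run-length encode constant-depth stretches
                change = np.flatnonzero(np.diff(seg)) + 1
                bounds = np.concatenate([[0], change, [len(seg)]])
                for a, b in zip(bounds[:-1], bounds[1:]):
                    fh.write(f"{iv.chrom}\t{iv.start + a}\t{iv.start + b}\t{int(seg[a])}\n")
                i += len(iv)


def depth_track(
    mates: Iterable[MateRecord],
    target: IntervalSet,
    chrom_lengths: Mapping[str, int],
) -> DepthTrack:
    """Per-base count of aligned (collapsed) read bases over target positions."""
    loc = target.locator(chrom_lengths)
    depth = np.zeros(target.total_bases, dtype=np.int64)
    for m in mates:
        lut = loc.get(m.chrom)
        if lut is None:
            continue
        for rs, re_, _ro in m.aligned_blocks():
            idx = lut[rs:re_]
            idx = idx[idx >= 0]
            if idx.size:
                np.add.at(depth, idx, 1)
    return DepthTrack(target=target, depth=depth)


@dataclass
class CoverageReport:
    """Breadth of target coverage at depth thresholds plus mean depth."""

    mean_depth: float
    breadth: Dict[int, float]  # threshold -> fraction of target bases >= threshold
    bases_at_threshold: Dict[int, int]
    target_bases: int

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("threshold\tbases\tbreadth\n")
            fh.write(f"0\t{self.target_bases}\t1.0\n")
            for t in sorted(self.breadth):
                fh.write(f"{t}\t{self.bases_at_threshold[t]}\t{self.breadth[t]:.6f}\n")


@dataclass
class UniformityHistogram:
    """Counts of target bases at depth 0, 1, ..., max_bin; the last bin is
    open-ended (>= max_bin)."""

    counts: np.ndarray
    max_bin: int = 300

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("depth\tbases\n")
            for d, c in enumerate(self.counts[:-1]):
                fh.write(f"{d}\t{int(c)}\n")
            fh.write(f">={self.max_bin}\t{int(self.counts[-1])}\n")


def coverage_report(
    track: DepthTrack,
    thresholds: Sequence[int] = (1, 20),
    max_bin: int = 300,
) -> Tuple[CoverageReport, UniformityHistogram]:
    """Breadth@d (fraction of target bases with depth >= d) for each
    threshold, mean depth, and the depth-uniformity histogram."""
    n = len(track.depth)
    if n == 0:
        raise ValueError("empty target")
    thresholds = sorted(int(t) for t in thresholds)
    if any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive")
    breadth, bases = {}, {}
    for t in thresholds:
        b = int((track.depth >= t).sum())
        bases[t] = b
        breadth[t] = b / n
    clipped = np.minimum(track.depth, max_bin)
    counts = np.bincount(clipped, minlength=max_bin + 1)
    report = CoverageReport(
        mean_depth=track.mean, breadth=breadth, bases_at_threshold=bases, target_bases=n
    )
    return report, UniformityHistogram(counts=counts, max_bin=max_bin)


def enrichment_score(stats: LaneStats) -> float:
    """Fraction of properly mapped, non-duplicate pairs that also mapped to
    probe regions — the primary capture-specificity measure."""
    if stats.n_after_dedup == 0:
        raise ValueError("enrichment score undefined: no proper pairs")
    return stats.n_on_probe / stats.n_after_dedup


@dataclass
class InsertSizeDistribution:
    """1-bp-binned insert-length histogram of proper pairs with summaries."""

    counts: np.ndarray  # index = insert length in bp
    n: int
    mode: int
    median: float
    q05: float
    q95: float

    def pdf(self) -> np.ndarray:
        """Probability-distribution normalization of the histogram."""
        return self.counts / self.counts.sum()

    def write_tsv(self, path: str | Path) -> None:
        pdf = self.pdf()
        with open(path, "w") as fh:
            fh.write("insert_length\tpairs\tpdf\n")
            for l in np.flatnonzero(self.counts):
                fh.write(f"{l}\t{int(self.counts[l])}\t{pdf[l]:.6g}\n")


def insert_size_distribution(pairs_or_lengths) -> InsertSizeDistribution:
    """Insert lengths (outer template spans) of proper pairs, binned at 1 bp.

    Accepts an iterable of :class:`ReadPairRecord` or of integer lengths.
    """
    lengths = np.array(
        [p.span if isinstance(p, ReadPairRecord) else int(p) for p in pairs_or_lengths],
        dtype=np.int64,
    )
    if lengths.size == 0:
        raise ValueError("no proper pairs")
    counts = np.bincount(lengths)
    return InsertSizeDistribution(
        counts=counts,
        n=int(lengths.size),
        mode=int(np.argmax(counts)),
        median=float(np.median(lengths)),
        q05=float(np.quantile(lengths, 0.05)),
        q95=float(np.quantile(lengths, 0.95)),
    )


def depth_correlation(a: DepthTrack, b: DepthTrack, method: str = "pearson") -> float:
    """Correlation of per-base target depth between two captures of the same
    target (replicate consistency), zero-depth bases included."""
    if a.target != b.target:
        raise ValueError("depth tracks cover different targets")
    if np.ptp(a.depth) == 0 or np.ptp(b.depth) == 0:
        raise ValueError("depth correlation undefined for a constant track")
    if method == "pearson":
        return float(np.corrcoef(a.depth, b.depth)[0, 1])
    if method == "spearman":
        from scipy.stats import spearmanr

        return float(spearmanr(a.depth, b.depth).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def raw_data_for_depth(depth: float, genome_size_gb: float = 3.0) -> float:
    """Raw sequence (Gb) needed for a mean genome depth, under the optimistic
    no-waste model: genome size times desired depth."""
    if depth < 0:
        raise ValueError("depth must be non-negative")
    return depth * genome_size_gb


# ---------------------------------------------------------------------------
# optional plots (mirroring the usual insert-size / uniformity figures)


def plot_insert_size_distribution(dist: InsertSizeDistribution, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(np.arange(len(dist.counts)), dist.pdf())
    ax.set_xlabel("insert length (bp)")
    ax.set_ylabel("PDF")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_uniformity(hist: UniformityHistogram, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(np.arange(len(hist.counts)), hist.counts)
    ax.set_xlabel("depth")
    ax.set_ylabel("target bases")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
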