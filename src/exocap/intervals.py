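"""Genomic interval arithmetic and BED I/O.

Every target/probe/gene computation in the package runs on :class:`IntervalSet`,
a normalized (sorted, pairwise-disjoint, adjacent-merged) collection of
half-open genomic intervals.  Coordinates are 0-based half-open throughout, the
BED convention; 1-based formats (SAM positions, gold-standard TSVs) are
converted at the I/O boundary.

Interval sets have *base-set* semantics: two abutting intervals are the same
set of bases as one merged interval, so normalization merges them and all
derived quantities (sizes, fractions) are invariant under fragmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping

import numpy as np

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "read_bed",
    "write_bed",
    "intersect",
    "union",
    "fraction_contained",
    "complement_within",
    "BedParseError",
    "EmptyIntervalSetError",
]


class BedParseError(ValueError):
    """A BED line could not be parsed; the message names the line number."""


class EmptyIntervalSetError(ValueError):
    """An operation that is undefined on an empty interval set was requested."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start


def _merge_sorted(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping or abutting sorted intervals (vectorised sweep)."""
    if starts.size == 0:
        return starts, ends
    # new run starts wherever an interval begins strictly after the running max end
    run_end = np.maximum.accumulate(ends)
    new_run = np.ones(starts.size, dtype=bool)
    new_run[1:] = starts[1:] > run_end[:-1]
    idx = np.flatnonzero(new_run)
    merged_starts = starts[idx]
    merged_ends = np.empty_like(merged_starts)
    merged_ends[:-1] = run_end[idx[1:] - 1]
    merged_ends[-1] = run_end[-1]
    return merged_starts, merged_ends


class IntervalSet:
    """A normalized set of genomic bases, stored per-chromosome as sorted,
    disjoint ``(start, end)`` arrays.

    Construct with :meth:`from_intervals` / :meth:`from_tuples` /
    :func:`read_bed`; instances are immutable in spirit (operations return new
    sets).
    """

    def __init__(self, by_chrom: Mapping[str, np.ndarray] | None = None, label: str = ""):
        # by_chrom maps chrom -> int64 array of shape (n, 2), already normalized
        self._by_chrom: Dict[str, np.ndarray] = {}
        if by_chrom:
            for chrom, arr in by_chrom.items():
                arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
                if arr.size:
                    self._by_chrom[chrom] = arr
        self.label = label

    # -- construction -----------------------------------------------------

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval], label: str = "") -> "IntervalSet":
        return cls.from_tuples(((iv.chrom, iv.start, iv.end) for iv in intervals), label=label)

    @classmethod
    def from_tuples(cls, tuples: Iterable[tuple[str, int, int]], label: str = "") -> "IntervalSet":
        per: Dict[str, List[tuple[int, int]]] = {}
        for chrom, start, end in tuples:
            GenomicInterval(chrom, int(start), int(end))  # validate
            per.setdefault(chrom, []).append((int(start), int(end)))
        by_chrom = {}
        for chrom, pairs in per.items():
            arr = np.array(sorted(pairs), dtype=np.int64)
            s, e = _merge_sorted(arr[:, 0], arr[:, 1])
            by_chrom[chrom] = np.column_stack([s, e])
        return cls(by_chrom, label=label)

    @classmethod
    def empty(cls, label: str = "") -> "IntervalSet":
        return cls({}, label=label)

    # -- basic queries ----------------------------------------------------

    @property
    def chroms(self) -> List[str]:
        return sorted(self._by_chrom)

    def arrays(self, chrom: str) -> np.ndarray:
        """The (n, 2) start/end array for one chromosome (empty if absent)."""
        return self._by_chrom.get(chrom, np.empty((0, 2), dtype=np.int64))

    @property
    def total_bases(self) -> int:
        return int(sum((arr[:, 1] - arr[:, 0]).sum() for arr in self._by_chrom.values()))

    def __len__(self) -> int:
        return sum(arr.shape[0] for arr in self._by_chrom.values())

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in self.chroms:
            for start, end in self._by_chrom[chrom]:
                yield GenomicInterval(chrom, int(start), int(end))

    def __bool__(self) -> bool:
        return len(self) > 0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if set(self._by_chrom) != set(other._by_chrom):
            return False
        return all(np.array_equal(self._by_chrom[c], other._by_chrom[c]) for c in self._by_chrom)

    def __repr__(self) -> str:
        lab = f" {self.label!r}" if self.label else ""
        return f"<IntervalSet{lab}: {len(self)} intervals, {self.total_bases} bases>"

    def contains(self, chrom: str, pos: int) -> bool:
        """Is the single base ``chrom:pos`` in the set?"""
        arr = self._by_chrom.get(chrom)
        if arr is None:
            return False
        i = int(np.searchsorted(arr[:, 0], pos, side="right")) - 1
        return i >= 0 and pos < arr[i, 1]

    def overlap_bases(self, chrom: str, start: int, end: int) -> int:
        """Number of bases of [start, end) that lie in the set."""
        arr = self._by_chrom.get(chrom)
        if arr is None or start >= end:
            return 0
        lo = int(np.searchsorted(arr[:, 1], start, side="right"))
        hi = int(np.searchsorted(arr[:, 0], end, side="left"))
        if lo >= hi:
            return 0
        s = np.maximum(arr[lo:hi, 0], start)
        e = np.minimum(arr[lo:hi, 1], end)
        return int(np.maximum(e - s, 0).sum())

    # -- set algebra -------------------------------------------------------

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        by_chrom = {}
        for chrom in self._by_chrom:
            a = self._by_chrom[chrom]
            b = other._by_chrom.get(chrom)
            if b is None:
                continue
            out = _intersect_arrays(a, b)
            if out.size:
                by_chrom[chrom] = out
        return IntervalSet(by_chrom)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        tuples = [(c, int(s), int(e)) for c in self.chroms for s, e in self._by_chrom[c]]
        tuples += [(c, int(s), int(e)) for c in other.chroms for s, e in other._by_chrom[c]]
        return IntervalSet.from_tuples(tuples)

    def difference(self, other: "IntervalSet") -> "IntervalSet":
        """Bases of self not in other."""
        by_chrom = {}
        for chrom, a in self._by_chrom.items():
            b = other._by_chrom.get(chrom)
            out = a if b is None else _difference_arrays(a, b)
            if out.size:
                by_chrom[chrom] = out
        return IntervalSet(by_chrom)

    def expand(self, margin: int, chrom_lengths: Mapping[str, int] | None = None) -> "IntervalSet":
        """Each interval widened by ``margin`` on both sides (clipped to chrom)."""
        tuples = []
        for chrom, arr in self._by_chrom.items():
            limit = chrom_lengths.get(chrom) if chrom_lengths else None
            for s, e in arr:
                ns = max(0, int(s) - margin)
                ne = int(e) + margin
                if limit is not None:
                    ne = min(ne, limit)
                tuples.append((chrom, ns, ne))
        return IntervalSet.from_tuples(tuples)

    def locator(self, chrom_lengths: Mapping[str, int]) -> Dict[str, np.ndarray]:
        """Per-chromosome arrays mapping genomic position -> flat index into the
        set's bases (-1 off-set).  Flat indices run chromosome by chromosome in
        sorted order, interval by interval — the coordinate system used by
        depth tracks and the pileup engine."""
        out: Dict[str, np.ndarray] = {}
        offset = 0
        for chrom in self.chroms:
            n = int(chrom_lengths[chrom])
            lut = np.full(n, -1, dtype=np.int64)
            for s, e in self._by_chrom[chrom]:
                lut[s:e] = np.arange(offset, offset + (e - s))
                offset += int(e - s)
            out[chrom] = lut
        return out

    def positions(self) -> Iterator[tuple[str, int]]:
        """All (chrom, pos) bases in flat-index order."""
        for chrom in self.chroms:
            for s, e in self._by_chrom[chrom]:
                for p in range(int(s), int(e)):
                    yield chrom, p


def _intersect_arrays(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def _difference_arrays(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = []
    j = 0
    for s, e in a:
        cur = int(s)
        while j < len(b) and b[j, 1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k, 0] < e:
            if b[k, 0] > cur:
                out.append((cur, int(b[k, 0])))
            cur = max(cur, int(b[k, 1]))
            k += 1
        if cur < e:
            out.append((cur, int(e)))
    return np.array(out, dtype=np.int64).reshape(-1, 2)


# -- module-level operations ----------------------------------------------


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Bases present in both sets."""
    return a.intersect(b)


def union(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Bases present in either set."""
    return a.union(b)


def complement_within(universe: IntervalSet, a: IntervalSet) -> IntervalSet:
    """Bases of ``universe`` not in ``a``."""
    return universe.difference(a)


def fraction_contained(a: IntervalSet, b: IntervalSet) -> float:
    """Fraction of a's bases that are also in b (e.g. fraction of one kit's
    target contained in another's, or of a gene's CDS inside a capture target).

    Raises :class:`EmptyIntervalSetError` if ``a`` is empty — the fraction is
    undefined.
    """
    total = a.total_bases
    if total == 0:
        raise EmptyIntervalSetError("fraction_contained undefined for empty set")
    return a.intersect(b).total_bases / total


# -- BED I/O ----------------------------------------------------------------

_HEADER_PREFIXES = ("track", "browser", "#")


def read_bed(path: str | Path, label: str = "", strict_chrom_names: bool = True) -> IntervalSet:
    """Read a BED file (3+ tab-separated columns, 0-based half-open) into a
    normalized IntervalSet.  ``track``/``browser``/comment header lines are
    skipped.  With ``strict_chrom_names=False``, bare numeric names are mapped
    to ``chrN`` (explicit opt-in; silent aliasing hides input errors).
    """
    path = Path(path)
    tuples: List[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_HEADER_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space-separated input
                fields = line.split()
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = fields[0]
            if not strict_chrom_names and not chrom.startswith("chr"):
                chrom = f"chr{chrom}"
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if not (0 <= start < end):
                raise BedParseError(f"{path}:{lineno}: invalid interval {start}-{end}")
            tuples.append((chrom, start, end))
    return IntervalSet.from_tuples(tuples, label=label or path.stem)


def write_bed(ivs: IntervalSet, path: str | Path) -> None:
    """Write sorted, merged BED3 records."""
    with open(path, "w") as fh:
        for iv in ivs:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
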