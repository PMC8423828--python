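"""Genome-arithmetic primitives for archaic-fragment comparisons.

All coordinates are 0-based, half-open (BED convention).  The operations
mirror the interval-toolkit semantics used for group-level fragment
comparisons: union-merge of many individuals' fragments ("joined region
fragments"), total shared/private sequence between two joined sets,
whole-fragment shared/private classification against the other group's
joined set (any-overlap, >= 1 bp), and per-1-kb archaic frequency (number
of distinct individuals covering each window of the joined set).

Book-ended intervals (end == start) merge, matching ``bedtools merge``
defaults; book-ended intervals do NOT count as overlapping for
intersection or classification (half-open semantics).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd


class GenomicInterval(NamedTuple):
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


class BedParseError(ValueError):
    """A malformed interval record (start >= end or negative start)."""


class IntervalSet:
    """Intervals grouped by chromosome, sorted by start.

    Not necessarily merged; :func:`merge_intervals` returns a merged set
    (non-overlapping, non-book-ended).
    """

    def __init__(self, by_chrom: Mapping[str, np.ndarray] | None = None):
        self._by_chrom: dict[str, np.ndarray] = {}
        if by_chrom:
            for chrom, arr in by_chrom.items():
                arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
                self._validate(chrom, arr)
                order = np.lexsort((arr[:, 1], arr[:, 0]))
                self._by_chrom[chrom] = arr[order]

    @staticmethod
    def _validate(chrom: str, arr: np.ndarray) -> None:
        bad = (arr[:, 0] < 0) | (arr[:, 0] >= arr[:, 1])
        if bad.any():
            s, e = arr[bad][0]
            raise BedParseError(f"malformed interval {chrom}:{s}-{e} (need 0 <= start < end)")

    @classmethod
    def from_tuples(cls, intervals: Iterable[tuple[str, int, int]]) -> "IntervalSet":
        grouped: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            grouped.setdefault(str(chrom), []).append((int(start), int(end)))
        return cls({c: np.array(v, dtype=np.int64) for c, v in grouped.items()})

    # -- introspection -------------------------------------------------

    @property
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def arrays(self, chrom: str) -> np.ndarray:
        return self._by_chrom.get(chrom, np.empty((0, 2), dtype=np.int64))

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in self.chroms:
            for start, end in self._by_chrom[chrom]:
                yield GenomicInterval(chrom, int(start), int(end))

    def __len__(self) -> int:
        return sum(a.shape[0] for a in self._by_chrom.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if self.chroms != other.chroms:
            return False
        return all(np.array_equal(self._by_chrom[c], other._by_chrom[c]) for c in self.chroms)

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals on {len(self._by_chrom)} chrom(s), {self.total_bp} bp)"

    @property
    def total_bp(self) -> int:
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in self._by_chrom.values()))

    def lengths(self) -> np.ndarray:
        """Per-interval lengths in bp (chromosome order, then start order)."""
        parts = [self._by_chrom[c][:, 1] - self._by_chrom[c][:, 0] for c in self.chroms]
        return np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)

    def is_merged(self) -> bool:
        for arr in self._by_chrom.values():
            if arr.shape[0] > 1 and (arr[1:, 0] <= arr[:-1, 1]).any():
                return False
        return True

    def contains_position(self, chrom: str, pos0: int) -> bool:
        """Membership of a 0-based position (set should be merged)."""
        arr = self.arrays(chrom)
        if arr.shape[0] == 0:
            return False
        i = int(np.searchsorted(arr[:, 0], pos0, side="right")) - 1
        return i >= 0 and pos0 < arr[i, 1]


def merge_intervals(*sets: IntervalSet) -> IntervalSet:
    """Union-merge one or more interval sets.

    Overlapping and book-ended (end == start) intervals coalesce; the output
    is sorted and non-overlapping per chromosome.
    """
    chroms = sorted({c for s in sets for c in s.chroms})
    out: dict[str, np.ndarray] = {}
    for chrom in chroms:
        arr = np.concatenate([s.arrays(chrom) for s in sets])
        arr = arr[np.argsort(arr[:, 0], kind="stable")]
        merged: list[list[int]] = []
        for start, end in arr:
            if merged and start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], int(end))
            else:
                merged.append([int(start), int(end)])
        out[chrom] = np.array(merged, dtype=np.int64)
    return IntervalSet(out)


def intersect_total(a: IntervalSet, b: IntervalSet) -> tuple[IntervalSet, int]:
    """Overlap segments of two merged sets and the total shared bp.

    ``shared_bp`` is symmetric; private bp of either side is
    ``total_bp - shared_bp``.
    """
    segments: dict[str, np.ndarray] = {}
    shared = 0
    for chrom in a.chroms:
        x, y = a.arrays(chrom), b.arrays(chrom)
        if x.shape[0] == 0 or y.shape[0] == 0:
            continue
        i = j = 0
        segs: list[tuple[int, int]] = []
        while i < x.shape[0] and j < y.shape[0]:
            lo = max(x[i, 0], y[j, 0])
            hi = min(x[i, 1], y[j, 1])
            if lo < hi:
                segs.append((int(lo), int(hi)))
                shared += int(hi - lo)
            if x[i, 1] <= y[j, 1]:
                i += 1
            else:
                j += 1
        if segs:
            segments[chrom] = np.array(segs, dtype=np.int64)
    return IntervalSet(segments), shared


def _overlap_counts(starts: np.ndarray, ends: np.ndarray, qstart, qend) -> np.ndarray:
    """Number of (merged, sorted) intervals overlapping each query by >= 1 bp."""
    return np.searchsorted(starts, np.asarray(qend), side="left") - np.searchsorted(
        ends, np.asarray(qstart), side="right"
    )


def classify_individual_fragments(
    ind: IntervalSet, other_joined: IntervalSet
) -> tuple[IntervalSet, IntervalSet]:
    """Partition an individual's fragments into (shared, private) whole fragments.

    A fragment is shared iff it overlaps the other group's joined set by at
    least 1 bp; fragments are kept whole, and the partition covers the input
    exactly.
    """
    shared: dict[str, np.ndarray] = {}
    private: dict[str, np.ndarray] = {}
    for chrom in ind.chroms:
        frags = ind.arrays(chrom)
        joined = other_joined.arrays(chrom)
        if joined.shape[0] == 0:
            mask = np.zeros(frags.shape[0], dtype=bool)
        else:
            mask = _overlap_counts(joined[:, 0], joined[:, 1], frags[:, 0], frags[:, 1]) > 0
        if mask.any():
            shared[chrom] = frags[mask]
        if (~mask).any():
            private[chrom] = frags[~mask]
    return IntervalSet(shared), IntervalSet(private)


def window_frequency(
    joined: IntervalSet,
    individuals: Sequence[IntervalSet],
    window_bp: int = 1000,
    count: str = "individuals",
) -> pd.DataFrame:
    """Archaic frequency per window of the joined set.

    The joined blocks are tiled into ``window_bp`` segments (the last segment
    of a block may be shorter).  ``count="individuals"`` counts DISTINCT
    individuals with >= 1 overlapping fragment per window (the quantity
    interpreted as archaic allele frequency); ``count="overlaps"`` counts raw
    overlap events, as the interval toolkit's ``-c`` flag would.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if count not in ("individuals", "overlaps"):
        raise ValueError("count must be 'individuals' or 'overlaps'")
    rows_chrom: list[str] = []
    starts_all: list[np.ndarray] = []
    ends_all: list[np.ndarray] = []
    counts_all: list[np.ndarray] = []
    for chrom in joined.chroms:
        blocks = joined.arrays(chrom)
        wstarts, wends = [], []
        for bs, be in blocks:
            edges = np.arange(bs, be, window_bp, dtype=np.int64)
            wstarts.append(edges)
            wends.append(np.minimum(edges + window_bp, be))
        ws = np.concatenate(wstarts) if wstarts else np.empty(0, dtype=np.int64)
        we = np.concatenate(wends) if wends else np.empty(0, dtype=np.int64)
        total = np.zeros(ws.shape[0], dtype=np.int64)
        for ind in individuals:
            frags = ind.arrays(chrom)
            if frags.shape[0] == 0:
                continue
            merged = ind if ind.is_merged() else merge_intervals(ind)
            frags = merged.arrays(chrom)
            n = _overlap_counts(frags[:, 0], frags[:, 1], ws, we)
            total += (n > 0).astype(np.int64) if count == "individuals" else n
        rows_chrom.extend([chrom] * ws.shape[0])
        starts_all.append(ws)
        ends_all.append(we)
        counts_all.append(total)
    return pd.DataFrame(
        {
            "chrom": rows_chrom,
            "start": np.concatenate(starts_all) if starts_all else [],
            "end": np.concatenate(ends_all) if ends_all else [],
            "count": np.concatenate(counts_all) if counts_all else [],
        }
    )


def downsample_individuals(
    sets: Mapping[str, IntervalSet], k: int, seed: int
) -> dict[str, IntervalSet]:
    """Seeded uniform choice of ``k`` individuals (without replacement).

    Used to balance group sizes before joined-set comparisons.
    """
    names = sorted(sets)
    if k > len(names):
        raise ValueError(f"cannot downsample {len(names)} individuals to {k}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(names), size=k, replace=False)
    return {names[i]: sets[names[i]] for i in sorted(chosen)}


# -- BED I/O ----------------------------------------------------------------


def read_bed(path) -> IntervalSet:
    """Read a BED3+ file (trailing columns tolerated, '#' comments skipped)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
        names=["chrom", "start", "end"], dtype={0: str},
    )
    try:
        return IntervalSet.from_tuples(df.itertuples(index=False, name=None))
    except BedParseError as err:
        raise BedParseError(f"{path}: {err}") from err


def write_bed(intervals: IntervalSet | Iterable[GenomicInterval], path, extra=None) -> None:
    """Write intervals as BED3 (plus optional extra columns, row-aligned)."""
    rows = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(rows):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if extra is not None:
                cols.extend(str(x) for x in extra[i])
            fh.write("\t".join(cols) + "\n")


def write_frequency_bed(freq: pd.DataFrame, path) -> None:
    """Write a window-frequency table as BED4 (chrom, start, end, count)."""
    freq[["chrom", "start", "end", "count"]].to_csv(path, sep="\t", header=False, index=False)
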