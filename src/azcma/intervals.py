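"""Normalised half-open genomic interval sets.

``IntervalSet`` stores, per chromosome, a sorted ``(n, 2)`` integer array of
0-based half-open ``[start, end)`` intervals with overlapping and touching
intervals merged.  This is the common currency for H3K9me3 blocks,
pericentromeric regions, peak post-processing and stratum bookkeeping.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np


def _normalize(pairs: np.ndarray) -> np.ndarray:
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    if pairs.size == 0:
        return pairs
    if (pairs[:, 1] <= pairs[:, 0]).any():
        raise ValueError("intervals must satisfy end > start")
    if (pairs[:, 0] < 0).any():
        raise ValueError("negative interval start")
    pairs = pairs[np.argsort(pairs[:, 0], kind="stable")]
    merged: list[list[int]] = [list(pairs[0])]
    for s, e in pairs[1:]:
        if s <= merged[-1][1]:  # overlap or touching -> merge
            merged[-1][1] = max(merged[-1][1], int(e))
        else:
            merged.append([int(s), int(e)])
    return np.asarray(merged, dtype=np.int64)


class IntervalSet:
    """Per-chromosome sets of disjoint, sorted half-open intervals."""

    def __init__(self, intervals: dict[str, np.ndarray | list] | None = None):
        self._ivals: dict[str, np.ndarray] = {}
        for chrom, pairs in (intervals or {}).items():
            arr = _normalize(np.asarray(pairs))
            if arr.size:
                self._ivals[chrom] = arr

    # -- construction ------------------------------------------------------
    @classmethod
    def from_pairs(cls, triples: Iterable[tuple[str, int, int]]) -> "IntervalSet":
        """Build from an iterable of ``(chrom, start, end)``."""
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in triples:
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        return cls(by_chrom)

    # -- basic accessors ---------------------------------------------------
    @property
    def chroms(self) -> list[str]:
        return sorted(self._ivals)

    def intervals(self, chrom: str) -> np.ndarray:
        return self._ivals.get(chrom, np.empty((0, 2), dtype=np.int64))

    def __iter__(self):
        for chrom in self.chroms:
            for s, e in self._ivals[chrom]:
                yield chrom, int(s), int(e)

    def __len__(self) -> int:
        return sum(len(v) for v in self._ivals.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if set(self._ivals) != set(other._ivals):
            return False
        return all(np.array_equal(self._ivals[c], other._ivals[c]) for c in self._ivals)

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals, {self.total_bp} bp)"

    @property
    def total_bp(self) -> int:
        return int(sum((v[:, 1] - v[:, 0]).sum() for v in self._ivals.values()))

    def bp_on(self, chrom: str) -> int:
        v = self.intervals(chrom)
        return int((v[:, 1] - v[:, 0]).sum()) if v.size else 0

    # -- set algebra -------------------------------------------------------
    def union(self, other: "IntervalSet") -> "IntervalSet":
        out: dict[str, list] = {}
        for chrom in set(self._ivals) | set(other._ivals):
            out[chrom] = list(self.intervals(chrom)) + list(other.intervals(chrom))
        return IntervalSet(out)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom in set(self._ivals) & set(other._ivals):
            a, b = self._ivals[chrom], other._ivals[chrom]
            i = j = 0
            acc: list[tuple[int, int]] = []
            while i < len(a) and j < len(b):
                lo = max(a[i, 0], b[j, 0])
                hi = min(a[i, 1], b[j, 1])
                if lo < hi:
                    acc.append((int(lo), int(hi)))
                if a[i, 1] <= b[j, 1]:
                    i += 1
                else:
                    j += 1
            if acc:
                out[chrom] = acc
        return IntervalSet(out)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom, a in self._ivals.items():
            b = other.intervals(chrom)
            acc: list[tuple[int, int]] = []
            for s, e in a:
                cur = int(s)
                for bs, be in b:
                    if be <= cur or bs >= e:
                        continue
                    if bs > cur:
                        acc.append((cur, int(bs)))
                    cur = max(cur, int(be))
                    if cur >= e:
                        break
                if cur < e:
                    acc.append((cur, int(e)))
            if acc:
                out[chrom] = acc
        return IntervalSet(out)

    def complement(self, chrom_lengths: dict[str, int]) -> "IntervalSet":
        full = IntervalSet({c: [(0, n)] for c, n in chrom_lengths.items()})
        return full.subtract(self)

    # -- queries -----------------------------------------------------------
    def contains_positions(self, chrom: str, pos0: np.ndarray) -> np.ndarray:
        """Boolean membership of 0-based positions."""
        pos0 = np.asarray(pos0, dtype=np.int64)
        v = self.intervals(chrom)
        if not v.size:
            return np.zeros(pos0.shape, dtype=bool)
        idx = np.searchsorted(v[:, 0], pos0, side="right") - 1
        ok = idx >= 0
        res = np.zeros(pos0.shape, dtype=bool)
        res[ok] = pos0[ok] < v[idx[ok], 1]
        return res

    def overlaps_windows(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """True for each window ``[start, end)`` that overlaps any interval."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        v = self.intervals(chrom)
        if not v.size:
            return np.zeros(starts.shape, dtype=bool)
        # overlap iff some interval with iv_start < end has iv_end > start
        idx = np.searchsorted(v[:, 0], ends, side="left") - 1
        ok = idx >= 0
        res = np.zeros(starts.shape, dtype=bool)
        res[ok] = v[idx[ok], 1] > starts[ok]
        return res

    def overlap_bp_windows(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Overlap length in bp of each window with the set."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        v = self.intervals(chrom)
        out = np.zeros(starts.shape, dtype=np.int64)
        if not v.size:
            return out
        # cumulative covered bp up to coordinate x
        edges = v.ravel()
        cum = np.concatenate([[0], np.cumsum(v[:, 1] - v[:, 0])])

        def covered_upto(x):
            k = np.searchsorted(edges, x, side="left")
            inside = k % 2 == 1  # x falls inside interval k//2
            base = cum[(k + 1) // 2]
            corr = np.where(inside, v[np.minimum(k // 2, len(v) - 1), 1] - x, 0)
            return base - corr

        return covered_upto(ends) - covered_upto(starts)

    # -- peak post-processing helpers -------------------------------------
    def filter_min_length(self, min_len: int) -> "IntervalSet":
        out = {}
        for chrom, v in self._ivals.items():
            keep = v[(v[:, 1] - v[:, 0]) >= min_len]
            if keep.size:
                out[chrom] = keep
        return IntervalSet(out)

    def merge_close(self, max_gap: int) -> "IntervalSet":
        """Merge consecutive intervals separated by a gap strictly below ``max_gap``."""
        out: dict[str, list[list[int]]] = {}
        for chrom, v in self._ivals.items():
            acc = [list(v[0])]
            for s, e in v[1:]:
                if s - acc[-1][1] < max_gap:
                    acc[-1][1] = int(e)
                else:
                    acc.append([int(s), int(e)])
            out[chrom] = acc
        return IntervalSet(out)
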