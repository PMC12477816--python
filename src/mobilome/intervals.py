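"""Interval algebra on 0-based half-open genomic coordinates.

All coordinates inside the package are 0-based half-open ``[start, end)``.
Conversion from 1-based formats happens only at the I/O boundary
(:mod:`mobilome.formats`).  Interval sets are represented as ``(n, 2)``
integer numpy arrays, which keeps set operations (union, subtraction,
intersection length) exact and fast without an external interval library.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Interval",
    "as_array",
    "merge",
    "total_length",
    "subtract",
    "intersect_length",
    "intersect",
    "complement",
    "coverage_in_windows",
    "per_interval_overlap",
]


@dataclass(frozen=True)
class Interval:
    """One labelled genomic interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def as_array(intervals) -> np.ndarray:
    """Coerce a list of (start, end) pairs / Interval objects to an (n,2) int array."""
    if isinstance(intervals, np.ndarray):
        arr = intervals.astype(np.int64, copy=False).reshape(-1, 2)
    else:
        rows = []
        for iv in intervals:
            if isinstance(iv, Interval):
                rows.append((iv.start, iv.end))
            else:
                rows.append((int(iv[0]), int(iv[1])))
        arr = np.asarray(rows, dtype=np.int64).reshape(-1, 2)
    if arr.size and (arr[:, 0] >= arr[:, 1]).any():
        raise ValueError("intervals must satisfy start < end")
    return arr


def merge(intervals) -> np.ndarray:
    """Union of intervals: sorted, non-overlapping, non-abutting (n,2) array."""
    arr = as_array(intervals)
    if arr.shape[0] == 0:
        return arr
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    out_s = [arr[0, 0]]
    out_e = [arr[0, 1]]
    for s, e in arr[1:]:
        if s <= out_e[-1]:
            if e > out_e[-1]:
                out_e[-1] = e
        else:
            out_s.append(s)
            out_e.append(e)
    return np.column_stack([out_s, out_e]).astype(np.int64)


def total_length(intervals) -> int:
    m = merge(intervals)
    if m.shape[0] == 0:
        return 0
    return int((m[:, 1] - m[:, 0]).sum())


def subtract(a, b) -> np.ndarray:
    """Set difference a \\ b.  Both are interval sets on one chromosome."""
    a = merge(a)
    b = merge(b)
    if a.shape[0] == 0 or b.shape[0] == 0:
        return a
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < b.shape[0] and b[j, 1] <= cur:
            j += 1
        k = j
        while k < b.shape[0] and b[k, 0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    if not out:
        return np.empty((0, 2), dtype=np.int64)
    return np.asarray(out, dtype=np.int64)


def intersect(a, b) -> np.ndarray:
    """Set intersection of two interval sets on one chromosome."""
    a = merge(a)
    b = merge(b)
    out = []
    i = j = 0
    while i < a.shape[0] and j < b.shape[0]:
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    if not out:
        return np.empty((0, 2), dtype=np.int64)
    return np.asarray(out, dtype=np.int64)


def intersect_length(a, b) -> int:
    x = intersect(a, b)
    if x.shape[0] == 0:
        return 0
    return int((x[:, 1] - x[:, 0]).sum())


def complement(intervals, chrom_length: int) -> np.ndarray:
    """Bases of [0, chrom_length) not covered by the interval set."""
    return subtract(np.array([[0, chrom_length]], dtype=np.int64), intervals)


def coverage_in_windows(intervals, window_edges: np.ndarray) -> np.ndarray:
    """Covered bp of a merged interval set within each window.

    ``window_edges`` is a sorted 1-D array of n+1 edges defining n abutting
    windows.  Uses the cumulative-coverage function so that the per-window
    bp sum equals the total covered bp exactly.
    """
    m = merge(intervals)
    edges = np.asarray(window_edges, dtype=np.int64)

    def cum(x):
        # covered bp of the set in [0, x)
        if m.shape[0] == 0:
            return np.zeros_like(x)
        starts, ends = m[:, 0], m[:, 1]
        cumlen = np.concatenate([[0], np.cumsum(ends - starts)])
        idx = np.searchsorted(ends, x, side="left")
        full = cumlen[idx]
        partial = np.where(
            idx < len(starts), np.maximum(0, x - starts[np.minimum(idx, len(starts) - 1)]), 0
        )
        partial = np.where(idx < len(starts), np.minimum(partial, ends[np.minimum(idx, len(starts) - 1)] - starts[np.minimum(idx, len(starts) - 1)]), 0)
        return full + partial

    c = cum(edges)
    return np.diff(c)


def per_interval_overlap(queries, subject) -> np.ndarray:
    """Overlap bp of each query interval with a subject interval set.

    ``queries`` is an (n,2) array (need not be disjoint); ``subject`` is
    merged internally.  Returns an int array of length n.
    """
    q = as_array(queries)
    m = merge(subject)
    if q.shape[0] == 0:
        return np.zeros(0, dtype=np.int64)
    if m.shape[0] == 0:
        return np.zeros(q.shape[0], dtype=np.int64)
    starts, ends = m[:, 0], m[:, 1]
    cumlen = np.concatenate([[0], np.cumsum(ends - starts)])

    def cum(x):
        idx = np.searchsorted(ends, x, side="left")
        safe = np.minimum(idx, len(starts) - 1)
        partial = np.clip(x - starts[safe], 0, ends[safe] - starts[safe])
        partial = np.where(idx < len(starts), partial, 0)
        return cumlen[idx] + partial

    return (cum(q[:, 1]) - cum(q[:, 0])).astype(np.int64)
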