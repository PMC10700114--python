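"""Interval algebra for callable-site masks.

Coordinates are 0-based half-open throughout the package; conversion to and
from the 1-based conventions of VCF and the multihetsep format happens at
the I/O boundary, never here.
"""
from __future__ import annotations

from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["CallableMask"]


def _normalize(intervals: Iterable[tuple[int, int]]) -> np.ndarray:
    """Sort and merge overlapping/adjacent intervals into an (n, 2) array."""
    pairs = sorted((int(s), int(e)) for s, e in intervals)
    arr = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    if arr.size == 0:
        return arr
    if (arr[:, 1] <= arr[:, 0]).any():
        raise ValueError("intervals must satisfy end > start")
    if (arr[:, 0] < 0).any():
        raise ValueError("negative coordinate in interval set")
    merged = [[arr[0, 0], arr[0, 1]]]
    for s, e in arr[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], int(e))
        else:
            merged.append([int(s), int(e)])
    return np.asarray(merged, dtype=np.int64)


def _subtract_arrays(a: np.ndarray, b: np.ndarray) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in a:
        cur = int(s)
        for bs, be in b:
            if be <= cur:
                continue
            if bs >= e:
                break
            if bs > cur:
                out.append((cur, int(bs)))
            cur = max(cur, int(be))
            if cur >= e:
                break
        if cur < e:
            out.append((cur, int(e)))
    return out


def _intersect_arrays(a: np.ndarray, b: np.ndarray) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((int(s), int(e)))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return out


class CallableMask:
    """Per-contig sorted, disjoint, half-open intervals of callable positions.

    The mask defines the denominator of every per-site diversity estimate:
    a position contributes to heterozygosity only if it lies inside the mask.
    """

    def __init__(self, intervals: Mapping[str, Iterable[tuple[int, int]]] | None = None):
        self._ivals: dict[str, np.ndarray] = {}
        if intervals:
            for contig, ivs in intervals.items():
                arr = _normalize(ivs)
                if arr.size:
                    self._ivals[str(contig)] = arr

    # -- construction -----------------------------------------------------
    @classmethod
    def from_bed(cls, path) -> "CallableMask":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["contig", "start", "end"])
        grouped: dict[str, list[tuple[int, int]]] = {}
        for row in df.itertuples(index=False):
            grouped.setdefault(str(row.contig), []).append((int(row.start), int(row.end)))
        return cls(grouped)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CallableMask":
        grouped: dict[str, list[tuple[int, int]]] = {}
        for row in df.itertuples(index=False):
            grouped.setdefault(str(row.contig), []).append((int(row.start), int(row.end)))
        return cls(grouped)

    # -- inspection -------------------------------------------------------
    @property
    def contigs(self) -> list[str]:
        return sorted(self._ivals)

    def intervals(self, contig: str) -> np.ndarray:
        return self._ivals.get(contig, np.empty((0, 2), dtype=np.int64))

    def bp(self, contig: str | None = None) -> int:
        if contig is not None:
            arr = self.intervals(contig)
            return int((arr[:, 1] - arr[:, 0]).sum()) if arr.size else 0
        return sum(self.bp(c) for c in self._ivals)

    @property
    def total_callable_bp(self) -> int:
        return self.bp()

    def contains(self, contig: str, pos: int) -> bool:
        """Membership of a single 0-based position."""
        arr = self.intervals(contig)
        if not arr.size:
            return False
        i = int(np.searchsorted(arr[:, 0], pos, side="right")) - 1
        return i >= 0 and pos < arr[i, 1]

    def overlap_bp(self, contig: str, start: int, end: int) -> int:
        """Number of masked positions in [start, end)."""
        arr = self.intervals(contig)
        if not arr.size or end <= start:
            return 0
        lo = np.minimum(np.maximum(arr[:, 0], start), end)
        hi = np.minimum(np.maximum(arr[:, 1], start), end)
        return int((hi - lo).sum())

    # -- algebra ----------------------------------------------------------
    def subtract(self, other: "CallableMask") -> "CallableMask":
        out: dict[str, list[tuple[int, int]]] = {}
        for contig, arr in self._ivals.items():
            out[contig] = _subtract_arrays(arr, other.intervals(contig))
        return CallableMask(out)

    def intersect(self, other: "CallableMask") -> "CallableMask":
        out: dict[str, list[tuple[int, int]]] = {}
        for contig, arr in self._ivals.items():
            out[contig] = _intersect_arrays(arr, other.intervals(contig))
        return CallableMask(out)

    def restrict_to_contigs(self, contigs: Iterable[str]) -> "CallableMask":
        keep = set(contigs)
        return CallableMask({c: arr for c, arr in self._ivals.items() if c in keep})

    # -- export -----------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [(c, int(s), int(e)) for c in self.contigs for s, e in self.intervals(c)]
        return pd.DataFrame(rows, columns=["contig", "start", "end"])

    def to_bed(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", header=False, index=False)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CallableMask):
            return NotImplemented
        if set(self._ivals) != set(other._ivals):
            return False
        return all(np.array_equal(self._ivals[c], other._ivals[c]) for c in self._ivals)

    def __repr__(self) -> str:
        return f"CallableMask({len(self._ivals)} contigs, {self.total_callable_bp} bp)"
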