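"""Genomic interval arithmetic.

Coordinates follow two conventions:

* **GFF3 coordinates** are 1-based and inclusive on both ends, so the
  interval ``(1, 9)`` covers nine nucleotides.
* **Internal coordinates** are 0-based half-open, the convention used for
  all interval arithmetic here (off-by-one safe: length is ``end - start``).

Public functions accept GFF3 coordinates unless stated otherwise; the
:class:`IntervalSet` container works in internal coordinates.
"""

from __future__ import annotations

from typing import Iterable, Iterator


def to_internal(start: int, end: int) -> tuple[int, int]:
    """Convert a 1-based inclusive (GFF3) interval to 0-based half-open."""
    if start > end:
        raise ValueError(f"invalid interval: start {start} > end {end}")
    if start < 1:
        raise ValueError(f"invalid interval: start {start} < 1")
    return start - 1, end


def to_gff3(start0: int, end0: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive."""
    return start0 + 1, end0


def merge(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge 0-based half-open intervals into sorted, disjoint, non-adjacent runs.

    Book-ended intervals (``(0, 5)`` and ``(5, 9)``) are fused into one.
    """
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if s > e:
            raise ValueError(f"invalid interval: start {s} > end {e}")
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


class IntervalSet:
    """Disjoint sorted intervals per sequence, 0-based half-open internally.

    Supports incremental addition, union length, and membership queries.
    """

    def __init__(self) -> None:
        self._raw: dict[str, list[tuple[int, int]]] = {}
        self._merged: dict[str, list[tuple[int, int]]] | None = None

    def add(self, seqid: str, start0: int, end0: int) -> None:
        if start0 > end0 or start0 < 0:
            raise ValueError(f"invalid interval: [{start0}, {end0})")
        self._raw.setdefault(seqid, []).append((start0, end0))
        self._merged = None

    def add_gff3(self, seqid: str, start: int, end: int) -> None:
        """Add an interval given in 1-based inclusive coordinates."""
        self.add(seqid, *to_internal(start, end))

    def _materialize(self) -> dict[str, list[tuple[int, int]]]:
        if self._merged is None:
            self._merged = {k: merge(v) for k, v in self._raw.items()}
        return self._merged

    def intervals(self, seqid: str) -> list[tuple[int, int]]:
        return self._materialize().get(seqid, [])

    def seqids(self) -> list[str]:
        return sorted(self._raw)

    def union_length(self) -> int:
        """Total number of distinct positions covered, over all sequences."""
        return sum(
            e - s for ivs in self._materialize().values() for s, e in ivs
        )

    def __contains__(self, item: tuple[str, int]) -> bool:
        seqid, pos = item
        for s, e in self._materialize().get(seqid, []):
            if s <= pos < e:
                return True
            if s > pos:
                break
        return False

    def positions(self, seqid: str) -> Iterator[int]:
        """Iterate covered positions on one sequence (small inputs only)."""
        for s, e in self._materialize().get(seqid, []):
            yield from range(s, e)

    def __len__(self) -> int:
        return sum(len(v) for v in self._materialize().values())


def interval_union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Number of distinct nucleotide positions covered by 1-based inclusive intervals.

    All intervals are taken to lie on a single sequence.

    >>> interval_union_length([(1, 9), (5, 13), (1, 13), (27, 33), (22, 27)])
    25
    """
    internal = [to_internal(s, e) for s, e in intervals]
    return sum(e - s for s, e in merge(internal))
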