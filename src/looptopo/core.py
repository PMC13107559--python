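"""Genomic coordinate primitives: intervals, paired-anchor loops, genomes.

All coordinates are 0-based, half-open ``[start, end)`` — the BED convention.
An interval of length L covers exactly L bases.  Any 1-based input dialect
must be converted at the I/O boundary, never downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger("looptopo")

VALID_STRANDS = ("+", "-", ".")


class TransInteractionError(ValueError):
    """Raised for inter-chromosomal (trans) loops, which are unsupported."""


@dataclass(frozen=True)
class Interval:
    """A 0-based half-open genomic span on a named chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name (non-empty).
    start : int
        Start position, 0-based inclusive, >= 0.
    end : int
        End position, exclusive, > start.
    strand : str
        One of ``+``, ``-``, ``.`` (default unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Floor midpoint, ``(start + end) // 2``."""
        return (self.start + self.end) // 2

    def expanded(self, slack: int) -> "Interval":
        """Interval padded by ``slack`` bp on both sides (floored at 0)."""
        if slack < 0:
            raise ValueError("slack must be >= 0")
        return replace(self, start=max(0, self.start - slack), end=self.end + slack)

    def clipped(self, chrom_size: int) -> "Interval":
        """Clip to ``[0, chrom_size)``; raises if nothing remains."""
        return replace(self, start=max(0, self.start), end=min(self.end, chrom_size))


def intervals_overlap(a: Interval, b: Interval, slack: int = 0) -> bool:
    """True iff ``a`` expanded by ``slack`` intersects ``b`` by >= 1 bp.

    Symmetric in its arguments; intervals on different chromosomes never
    overlap.  With ``slack=0`` touching half-open intervals do NOT overlap.
    """
    if slack < 0:
        raise ValueError("slack must be >= 0")
    if a.chrom != b.chrom:
        return False
    return (a.start - slack) < b.end and b.start < (a.end + slack)


@dataclass
class Loop:
    """An ordered pair of anchors with per-condition contact counts.

    Used for both structural (CTCF) loops and regulatory (H3K27ac)
    interactions.  After :func:`canonicalize_loop`, ``anchorL`` lies
    left of ``anchorR`` on the same chromosome.
    """

    id: str
    anchorL: Interval
    anchorR: Interval
    counts: dict[str, int] = field(default_factory=dict)
    strength: float = 0.0

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise ValueError("strength must be non-negative")
        for cond, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for condition {cond!r}")

    @property
    def chrom(self) -> str:
        return self.anchorL.chrom

    def anchor_distance(self) -> int:
        """Distance between anchor midpoints (canonical loop assumed)."""
        return self.anchorR.midpoint - self.anchorL.midpoint


def canonicalize_loop(raw: Loop) -> Loop:
    """Order anchors left-to-right by start.  Idempotent; id preserved.

    Raises
    ------
    TransInteractionError
        If the anchors lie on different chromosomes.
    """
    if raw.anchorL.chrom != raw.anchorR.chrom:
        raise TransInteractionError(
            f"trans interaction {raw.id!r}: anchors on "
            f"{raw.anchorL.chrom} and {raw.anchorR.chrom}"
        )
    if (raw.anchorL.start, raw.anchorL.end) <= (raw.anchorR.start, raw.anchorR.end):
        return raw
    return replace(raw, anchorL=raw.anchorR, anchorR=raw.anchorL)


def loop_span(l: Loop, mode: str = "midpoint") -> Interval:
    """The genomic span subtended by a canonical loop.

    ``mode="outer"`` -> ``[anchorL.start, anchorR.end)``;
    ``mode="midpoint"`` -> ``[mid(anchorL), mid(anchorR))`` with floor
    midpoints.  Midpoint is the default everywhere: it avoids counting
    anchor width twice in containment tests.
    """
    if mode == "outer":
        return Interval(l.chrom, l.anchorL.start, l.anchorR.end)
    if mode == "midpoint":
        lo, hi = l.anchorL.midpoint, l.anchorR.midpoint
        if hi <= lo:
            # overlapping anchors can invert midpoints; degrade to the
            # minimal 1-bp span at the left midpoint
            lo, hi = min(lo, hi), min(lo, hi) + 1
        return Interval(l.chrom, lo, hi)
    raise ValueError(f"unknown span mode {mode!r}")


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome name -> length (bp).  All lengths must be positive."""

    chrom_sizes: Mapping[str, int]

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive size")

    @property
    def total(self) -> int:
        return sum(self.chrom_sizes.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_sizes


def merge_intervals(spans: Iterable[Interval]) -> list[Interval]:
    """Union of spans as a sorted list of disjoint intervals per chromosome."""
    by_chrom: dict[str, list[Interval]] = {}
    for s in spans:
        by_chrom.setdefault(s.chrom, []).append(s)
    merged: list[Interval] = []
    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom], key=lambda s: (s.start, s.end))
        cur_start, cur_end = items[0].start, items[0].end
        for s in items[1:]:
            if s.start <= cur_end:
                cur_end = max(cur_end, s.end)
            else:
                merged.append(Interval(chrom, cur_start, cur_end))
                cur_start, cur_end = s.start, s.end
        merged.append(Interval(chrom, cur_start, cur_end))
    return merged


def union_coverage(spans: Sequence[Interval], genome: GenomeSpec) -> float:
    """Fraction of the genome covered by the union of ``spans``.

    Overlapping spans are counted once.  Spans extending beyond their
    chromosome end are clipped with a logged warning; spans on unknown
    chromosomes are rejected.
    """
    clipped: list[Interval] = []
    for s in spans:
        if s.chrom not in genome:
            raise ValueError(f"span on unknown chromosome {s.chrom!r}")
        size = genome.chrom_sizes[s.chrom]
        if s.end > size or s.start < 0:
            logger.warning(
                "span %s:%d-%d clipped to chromosome bounds [0, %d)",
                s.chrom, s.start, s.end, size,
            )
            if s.start >= size:
                continue
            s = s.clipped(size)
        clipped.append(s)
    if not clipped:
        return 0.0
    covered = sum(m.width for m in merge_intervals(clipped))
    return covered / genome.total


class LoopIndex:
    """Per-chromosome index over loop outer spans for candidate retrieval.

    Backed by sorted numpy arrays; a query returns every loop whose outer
    span, padded by ``pad``, intersects the query window.  Exactness versus
    the exhaustive double loop is asserted in the test-suite.
    """

    def __init__(self, loops: Sequence[Loop]):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[Loop]]] = {}
        grouped: dict[str, list[Loop]] = {}
        for l in loops:
            grouped.setdefault(l.chrom, []).append(l)
        for chrom, items in grouped.items():
            items.sort(key=lambda l: (l.anchorL.start, l.anchorR.end))
            starts = np.array([l.anchorL.start for l in items], dtype=np.int64)
            ends = np.array([l.anchorR.end for l in items], dtype=np.int64)
            self._by_chrom[chrom] = (starts, ends, items)

    def query(self, chrom: str, start: int, end: int, pad: int = 0) -> list[Loop]:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return []
        starts, ends, items = entry
        mask = (starts < end + pad) & (ends > start - pad)
        return [items[i] for i in np.flatnonzero(mask)]

    def __len__(self) -> int:
        return sum(len(v[2]) for v in self._by_chrom.values())
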