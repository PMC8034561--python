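"""Gene segments, heterogeneity encodings and closed enumeration.

A *segment* ``(s, l)`` is a run of ``l`` consecutive variants starting at
1-based position ``s`` within a gene's ordered variant list.  Its
*heterogeneity encoding* is the elementwise OR over the segment's columns:
a sample carries the pattern if any variant in the run is present (allelic
heterogeneity).  Two segments from network-adjacent genes combine by a
second OR into the interaction encoding (locus heterogeneity).

Segments are enumerated in *closed* form: a segment whose encoding equals
that of one of its immediate length-``l-1`` sub-segments is redundant and
suppressed.  Under the OR semantics, equality with an immediate sub-segment
is necessary and sufficient for equality with any deeper sub-segment, so
checking the two immediate ones suffices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .stats import ClassPartition

__all__ = [
    "Segment",
    "Encoding",
    "SegmentInteraction",
    "encode_segment",
    "combine",
    "enumerate_closed_segments",
    "enumerate_interactions",
    "PruneSet",
]


@dataclass(frozen=True)
class Segment:
    """A run of consecutive variants within one gene.

    ``start`` is 1-based within the gene's ordered column list; ``length``
    counts variants, at least 1.
    """

    gene_id: str
    start: int
    length: int

    def __post_init__(self):
        if self.start < 1 or self.length < 1:
            raise ValueError("segment requires start >= 1 and length >= 1")

    @property
    def end(self) -> int:
        """Last covered 1-based position (inclusive)."""
        return self.start + self.length - 1

    def contains(self, other: "Segment") -> bool:
        return self.start <= other.start and other.end <= self.end


@dataclass(frozen=True)
class Encoding:
    """Binary pattern encoding with per-covariate-class supports."""

    bits: np.ndarray
    support_per_class: np.ndarray

    @property
    def support(self) -> int:
        return int(self.support_per_class.sum())


@dataclass(frozen=True)
class SegmentInteraction:
    """A pair of segments from two distinct genes plus the OR-combined encoding."""

    seg1: Segment
    seg2: Segment
    encoding: Encoding

    def __post_init__(self):
        if self.seg1.gene_id == self.seg2.gene_id:
            raise ValueError("interaction segments must come from distinct genes")


def _check_segment(n_cols: int, segment: Segment) -> None:
    if segment.end > n_cols:
        raise IndexError(
            f"segment ({segment.start},{segment.length}) exceeds the "
            f"{n_cols} variants of gene {segment.gene_id}"
        )


def encode_segment(gene_columns: np.ndarray, segment: Segment,
                   partition: ClassPartition) -> Encoding:
    """OR the segment's columns into a single binary encoding.

    ``gene_columns`` is the ``n x m`` binary sub-matrix of the gene's mapped
    variants, ordered by genomic position.
    """
    gene_columns = np.asarray(gene_columns)
    _check_segment(gene_columns.shape[1], segment)
    bits = gene_columns[:, segment.start - 1: segment.end].max(axis=1).astype(np.uint8)
    return Encoding(bits, partition.supports(bits))


def combine(enc1: Encoding, enc2: Encoding, partition: ClassPartition) -> Encoding:
    """Elementwise maximum of two encodings (commutative, idempotent)."""
    if enc1.bits.shape != enc2.bits.shape:
        raise ValueError("encodings must have equal length")
    bits = np.maximum(enc1.bits, enc2.bits)
    return Encoding(bits, partition.supports(bits))


def enumerate_closed_segments(
    gene_id: str,
    gene_columns: np.ndarray,
    partition: ClassPartition,
) -> list[tuple[Segment, Encoding]]:
    """All closed segments of one gene, ordered by start, then by length.

    Encodings are grown incrementally (extend by one column via OR).  A
    segment ``(s, l)`` with ``l > 1`` is suppressed iff its encoding equals
    the encoding of ``(s, l-1)`` or of ``(s+1, l-1)``.
    """
    cols = np.asarray(gene_columns, dtype=np.uint8)
    if cols.ndim != 2 or cols.shape[1] < 1:
        raise ValueError("gene must have at least one variant column")
    m = cols.shape[1]
    out: dict[tuple[int, int], Encoding] = {}
    prev = [cols[:, s] for s in range(m)]  # encodings of length-1 segments
    for s in range(m):
        out[(s + 1, 1)] = Encoding(prev[s].copy(), partition.supports(prev[s]))
    for l in range(2, m + 1):
        cur = []
        for s in range(m - l + 1):
            enc = prev[s] | cols[:, s + l - 1]
            cur.append(enc)
            closed = (not np.array_equal(enc, prev[s])) and (
                not np.array_equal(enc, prev[s + 1])
            )
            if closed:
                out[(s + 1, l)] = Encoding(enc, partition.supports(enc))
        prev = cur
    keys = sorted(out)
    return [(Segment(gene_id, s, l), out[(s, l)]) for s, l in keys]


class PruneSet:
    """Roots of pruned subtrees of the interaction search space.

    When a pattern proves prunable, every *super*-interaction -- both
    segments containing the root's segments -- is excluded from the
    remaining enumeration of the edge without ever being materialised.
    """

    def __init__(self):
        self._roots: list[tuple[int, int, int, int]] = []
        self.n_skipped = 0

    def add(self, seg1: Segment, seg2: Segment) -> None:
        self._roots.append((seg1.start, seg1.end, seg2.start, seg2.end))

    def covers(self, seg1: Segment, seg2: Segment) -> bool:
        s1, e1, s2, e2 = seg1.start, seg1.end, seg2.start, seg2.end
        for r1s, r1e, r2s, r2e in self._roots:
            if s1 <= r1s and r1e <= e1 and s2 <= r2s and r2e <= e2:
                return True
        return False


def enumerate_interactions(
    segments1: Sequence[tuple[Segment, Encoding]],
    segments2: Sequence[tuple[Segment, Encoding]],
    max_len: int | None = None,
    skip: PruneSet | None = None,
) -> Iterator[tuple[Segment, Encoding, Segment, Encoding]]:
    """Cartesian product of two genes' closed segments, sub-patterns first.

    Pairs are yielded in ascending total length ``l1 + l2`` (ties broken by
    ``(s1, l1, s2, l2)``), a topological order of the containment relation:
    every super-interaction appears after all of its sub-interactions, which
    lets a prunability verdict on a pattern remove its whole subtree via
    ``skip`` before any member is materialised.  ``max_len`` restricts the
    per-segment length; ``max_len=1`` reduces the search to single-variant
    (SNP-pair) interactions.
    """
    if max_len is not None and max_len < 1:
        raise ValueError("max_len must be >= 1")

    def eligible(segs):
        return [se for se in segs if max_len is None or se[0].length <= max_len]

    pairs = [
        (a[0].length + b[0].length, a[0].start, a[0].length, b[0].start, b[0].length, a, b)
        for a in eligible(segments1)
        for b in eligible(segments2)
    ]
    pairs.sort(key=lambda t: t[:6])
    for *_key, (seg1, enc1), (seg2, enc2) in pairs:
        if skip is not None and skip.covers(seg1, seg2):
            skip.n_skipped += 1
            continue
        yield seg1, enc1, seg2, enc2
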