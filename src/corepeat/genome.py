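"""Core genomic coordinate types and strand-aware interval arithmetic.

All coordinates are 0-based half-open (BED convention). GTF-style 1-based
inclusive inputs are converted on read by :mod:`corepeat.io`. Every distance,
radius and orientation rule used by the downstream enrichment and peak
statistics is defined here, in one place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

STRANDS = ("+", "-", ".")

REPEAT_CLASSES = ("LINE", "LTR", "SINE", "Satellite", "DNA", "Other")


class IntervalError(ValueError):
    """Raised when an interval or interval operation violates its contract."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a named chromosome.

    ``start`` is 0-based inclusive, ``end`` exclusive; zero-length intervals
    are invalid. ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise IntervalError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise IntervalError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise IntervalError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the intervals share at least one base on the same chrom."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        """Number of shared bases (0 when disjoint or on different chroms)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Gene:
    """A gene with its transcript-union span and optional evolutionary labels.

    ``conservation`` is the fraction of the gene scored as conserved across
    placental mammals (``None`` when unscored); ``lca_clade`` is the clade of
    the gene's last common ancestor (e.g. ``Mus_musculus`` for lineage-specific
    "new" genes).
    """

    id: str
    symbol: str
    span: GenomicInterval
    biotype: str = "protein_coding"
    conservation: Optional[float] = None
    lca_clade: Optional[str] = None

    def __post_init__(self) -> None:
        if self.span.strand not in ("+", "-"):
            raise IntervalError(f"gene {self.id}: strand must be + or -")
        if self.conservation is not None and not (0.0 <= self.conservation <= 1.0):
            raise ValueError(f"gene {self.id}: conservation outside [0, 1]")


@dataclass(frozen=True)
class RepeatInstance:
    """An annotated repeat copy (one genomic integrant of a named family).

    ``divergence`` is percent mismatch from the family consensus, a proxy for
    the integrant's age; ``None`` when not annotated.
    """

    span: GenomicInterval
    family: str
    repclass: str
    divergence: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError("repeat family must be non-empty")
        if self.repclass not in REPEAT_CLASSES:
            raise ValueError(
                f"repclass must be one of {REPEAT_CLASSES}, got {self.repclass!r}"
            )
        if self.divergence is not None and not (0.0 <= self.divergence <= 100.0):
            raise ValueError(f"divergence outside [0, 100]: {self.divergence}")

    @property
    def length(self) -> int:
        return self.span.length


@dataclass(frozen=True)
class Peak:
    """A ChIP peak interval with its sample label and optional score."""

    span: GenomicInterval
    sample: str = ""
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.score is not None and self.score < 0:
            raise ValueError("peak score must be non-negative")


def interval_distance(a: GenomicInterval, b: GenomicInterval) -> float:
    """Gap in bases between two intervals.

    Returns 0 when they share at least one base (and 0 for abutting
    intervals, whose gap is zero without overlap), the distance between the
    nearest edges otherwise, and ``inf`` when the chromosomes differ.
    Symmetric in its arguments.
    """
    if a.chrom != b.chrom:
        return math.inf
    if a.start < b.end and b.start < a.end:
        return 0.0
    if a.end <= b.start:
        return float(b.start - a.end)
    return float(a.start - b.end)


def within_radius(anchor: GenomicInterval, query: GenomicInterval, w: int) -> bool:
    """True iff ``query`` lies within ``w`` bases of ``anchor``.

    At ``w == 0`` at least one shared base is required ("intersection"):
    abutting intervals (gap 0, no shared base) do not count at w=0 but do at
    any positive w. Monotone non-decreasing in ``w``.
    """
    if w < 0:
        raise IntervalError(f"radius must be >= 0, got {w}")
    if w == 0:
        return anchor.overlaps(query)
    return interval_distance(anchor, query) <= w


def upstream_region(
    gene: Gene, length: int, chrom_len: int
) -> Optional[GenomicInterval]:
    """The ``length``-bp region immediately upstream of the gene's 5' end.

    For a + strand gene this is ``[start-length, start)``; for - strand,
    ``[end, end+length)``; clipped to ``[0, chrom_len)``. Returns ``None``
    when clipping leaves nothing (gene flush against the chromosome edge);
    callers exclude such genes from upstream tallies.
    """
    if length <= 0:
        raise ValueError("upstream length must be > 0")
    if gene.span.strand == "+":
        start, end = max(0, gene.span.start - length), gene.span.start
    else:
        start, end = gene.span.end, min(chrom_len, gene.span.end + length)
    if start >= end:
        return None
    return GenomicInterval(gene.span.chrom, start, end, gene.span.strand)


def relative_orientation(gene: Gene, repeat: RepeatInstance) -> str:
    """Orientation of a repeat relative to a gene: sense, antisense or unknown.

    ``sense`` when the repeat strand equals the gene strand, ``unknown`` when
    the repeat is unstranded (excluded from orientation-bias tables).
    """
    if repeat.span.strand == ".":
        return "unknown"
    return "sense" if repeat.span.strand == gene.span.strand else "antisense"
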