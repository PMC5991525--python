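"""Repeat-proximity enrichment of gene sets and the upstream-LTR orientation test.

The central computation: for a gene set and a repeat filter (class, family
list, size, full-length rule), flag each gene for the presence of a
qualifying repeat within a distance window, compare against a background
gene set with a one-sided Fisher test, and report fold enrichment per
window. Also: L1 array statistics (multiple qualifying repeats per gene) and
the sense-orientation bias of LTRs upstream of a gene set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from intervaltree import IntervalTree

from .genome import (
    Gene,
    GenomicInterval,
    RepeatInstance,
    relative_orientation,
    upstream_region,
    within_radius,
)
from .genesets import GeneSet, _resolve
from .io import RepeatFamilyInfo
from .stats import ContingencyTable2x2, fisher_one_sided

#: fraction of the family consensus length an LTR-class copy must reach to
#: count as full-length
FULL_LENGTH_LTR_FRACTION = 0.9


@dataclass(frozen=True)
class RepeatFilter:
    """Selector for repeat instances by class, family, size and completeness.

    ``min_length`` is a strict lower bound (a copy of exactly ``min_length``
    bases is excluded). ``full_length_only`` applies the LTR completeness
    rule: an LTR-class copy qualifies only when its length reaches 90% of the
    family consensus length (LINEs use ``min_length`` for the same purpose).
    At least one selector must be active.
    """

    classes: Optional[frozenset] = None
    families: Optional[frozenset] = None
    min_length: int = 0
    full_length_only: bool = False

    def __post_init__(self) -> None:
        if (
            self.classes is None
            and self.families is None
            and self.min_length == 0
            and not self.full_length_only
        ):
            raise ValueError("RepeatFilter needs at least one active selector")
        if self.min_length < 0:
            raise ValueError("min_length must be >= 0")

    def matches(
        self,
        repeat: RepeatInstance,
        family_info: Optional[Dict[str, RepeatFamilyInfo]] = None,
    ) -> bool:
        if self.classes is not None and repeat.repclass not in self.classes:
            return False
        if self.families is not None and repeat.family not in self.families:
            return False
        if self.min_length and not repeat.length > self.min_length:
            return False
        if self.full_length_only and repeat.repclass == "LTR":
            info = (family_info or {}).get(repeat.family)
            if info is None or info.consensus_length is None:
                return False
            if repeat.length < FULL_LENGTH_LTR_FRACTION * info.consensus_length:
                return False
        return True


@dataclass(frozen=True)
class EnrichmentResult:
    """One set-vs-background comparison at one distance window."""

    window: int
    filter: RepeatFilter
    set_positive: int
    set_total: int
    bg_positive: int
    bg_total: int
    fold: float
    p: float
    fold_is_infinite: bool = False


def select_full_length(
    repeats: Iterable[RepeatInstance],
    filt: RepeatFilter,
    family_info: Optional[Dict[str, RepeatFamilyInfo]] = None,
) -> List[RepeatInstance]:
    """Repeat instances passing the filter (size/completeness rules included)."""
    return [r for r in repeats if filt.matches(r, family_info)]


def _build_tree(repeats: Sequence[RepeatInstance]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for i, r in enumerate(repeats):
        trees.setdefault(r.span.chrom, IntervalTree()).addi(
            r.span.start, r.span.end, i
        )
    return trees


def _count_near(
    gene: Gene, trees: Dict[str, IntervalTree], w: int
) -> int:
    """Number of indexed repeats within radius ``w`` of the gene span."""
    tree = trees.get(gene.span.chrom)
    if tree is None:
        return 0
    if w == 0:
        # intersection: >=1 shared base
        return len(tree.overlap(gene.span.start, gene.span.end))
    # widen the tree query by one base so repeats at distance exactly w are
    # retrieved; within_radius below is the authoritative rule
    hits = tree.overlap(max(0, gene.span.start - w - 1), gene.span.end + w + 1)
    count = 0
    for h in hits:
        iv = GenomicInterval(gene.span.chrom, h.begin, h.end)
        if within_radius(gene.span, iv, w):
            count += 1
    return count


def genes_with_repeat(
    gs: GeneSet,
    genes_by_id: Dict[str, Gene],
    repeats: Sequence[RepeatInstance],
    filt: RepeatFilter,
    w: int,
    family_info: Optional[Dict[str, RepeatFamilyInfo]] = None,
) -> Tuple[int, Dict[str, int]]:
    """Per-gene counts of qualifying repeats within radius ``w``.

    Returns ``(number of genes with >= 1 qualifying repeat, {gene_id: count})``.
    """
    selected = select_full_length(repeats, filt, family_info)
    trees = _build_tree(selected)
    counts = {g.id: _count_near(g, trees, w) for g in _resolve(gs, genes_by_id)}
    return sum(1 for c in counts.values() if c > 0), counts


def enrichment_vs_background(
    gs: GeneSet,
    bg: GeneSet,
    genes_by_id: Dict[str, Gene],
    repeats: Sequence[RepeatInstance],
    filt: RepeatFilter,
    windows: Sequence[int] = (0, 5_000, 20_000),
    family_info: Optional[Dict[str, RepeatFamilyInfo]] = None,
) -> List[EnrichmentResult]:
    """Repeat-presence enrichment of a gene set over a background per window.

    Builds, at each window, the 2x2 table (set vs background) x (gene has a
    qualifying repeat vs not) and tests one-sided for over-representation in
    the set. Fold is the ratio of per-gene presence fractions; a background
    with zero positives yields an infinity-flagged fold (p still computed).
    """
    results = []
    for w in windows:
        sp, _ = genes_with_repeat(gs, genes_by_id, repeats, filt, w, family_info)
        bp, _ = genes_with_repeat(bg, genes_by_id, repeats, filt, w, family_info)
        st, bt = len(gs), len(bg)
        p = fisher_one_sided(ContingencyTable2x2(a=sp, b=st - sp, c=bp, d=bt - bp))
        if bp == 0:
            fold, inf = math.inf, True
            if sp == 0:
                fold, inf = float("nan"), False
        else:
            fold, inf = (sp / st) / (bp / bt), False
        results.append(
            EnrichmentResult(
                window=w, filter=filt, set_positive=sp, set_total=st,
                bg_positive=bp, bg_total=bt, fold=fold, p=p, fold_is_infinite=inf,
            )
        )
    return results


def fraction_with_any(
    gs: GeneSet,
    genes_by_id: Dict[str, Gene],
    repeats: Sequence[RepeatInstance],
    filters: Sequence[RepeatFilter],
    w: int = 20_000,
    family_info: Optional[Dict[str, RepeatFamilyInfo]] = None,
) -> float:
    """Fraction of genes flagged by at least one of several repeat filters."""
    flagged = set()
    for filt in filters:
        _, counts = genes_with_repeat(gs, genes_by_id, repeats, filt, w, family_info)
        flagged.update(g for g, c in counts.items() if c > 0)
    return len(flagged) / len(gs) if len(gs) else float("nan")


def l1_array_fraction(
    gs: GeneSet,
    genes_by_id: Dict[str, Gene],
    repeats: Sequence[RepeatInstance],
    filt: RepeatFilter,
    w: int = 20_000,
    min_count: int = 2,
    family_info: Optional[Dict[str, RepeatFamilyInfo]] = None,
) -> float:
    """Among genes with >= 1 qualifying repeat, the fraction with >= ``min_count``.

    Measures how often flanking L1s occur in arrays rather than alone.
    """
    _, counts = genes_with_repeat(gs, genes_by_id, repeats, filt, w, family_info)
    flagged = [c for c in counts.values() if c > 0]
    if not flagged:
        return float("nan")
    return sum(1 for c in flagged if c >= min_count) / len(flagged)


def orientation_bias(
    gs: GeneSet,
    bg: GeneSet,
    genes_by_id: Dict[str, Gene],
    ltrs: Sequence[RepeatInstance],
    chrom_sizes: Dict[str, int],
    upstream_len: int = 3_000,
) -> Dict[str, object]:
    """Sense-orientation bias of LTRs in the upstream regions of a gene set.

    Collects every stranded LTR-class instance overlapping the
    ``upstream_len``-bp region upstream of each gene (instances pooled across
    genes, not majority-voted per gene), counts sense vs antisense relative
    to the gene, and runs a one-sided Fisher test for sense over-representation
    in the set versus the background. Genes whose upstream region is clipped
    away (chromosome edge) are excluded.
    """
    ltr_only = [r for r in ltrs if r.repclass == "LTR" and r.span.strand != "."]
    trees = _build_tree(ltr_only)

    def tally(geneset: GeneSet) -> Tuple[int, int]:
        sense = antisense = 0
        for g in _resolve(geneset, genes_by_id):
            region = upstream_region(g, upstream_len, chrom_sizes[g.span.chrom])
            if region is None:
                continue
            tree = trees.get(region.chrom)
            if tree is None:
                continue
            for h in tree.overlap(region.start, region.end):
                orient = relative_orientation(g, ltr_only[h.data])
                if orient == "sense":
                    sense += 1
                elif orient == "antisense":
                    antisense += 1
        return sense, antisense

    s_sense, s_anti = tally(gs)
    b_sense, b_anti = tally(bg)
    p = fisher_one_sided(
        ContingencyTable2x2(a=s_sense, b=s_anti, c=b_sense, d=b_anti)
    )
    return {
        "set_sense": s_sense,
        "set_antisense": s_anti,
        "bg_sense": b_sense,
        "bg_antisense": b_anti,
        "sense_fraction_set": (
            s_sense / (s_sense + s_anti) if s_sense + s_anti else float("nan")
        ),
        "sense_fraction_bg": (
            b_sense / (b_sense + b_anti) if b_sense + b_anti else float("nan")
        ),
        "p": p,
    }
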