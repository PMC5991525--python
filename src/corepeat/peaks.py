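"""ChIP peak statistics.

Reproducible-peak filtering from replicate and input peak sets, the peak
clustering fraction, histone-mark overlap at two stringencies, peak-to-repeat
assignment, family-level IP/input binding enrichment, and binned consensus
coverage profiles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome import Gene, GenomicInterval, Peak, RepeatInstance
from .genesets import GeneSet
from .enrichment import RepeatFilter, genes_with_repeat


@dataclass(frozen=True)
class PeakAssignment:
    """A peak's repeat assignment: young L1, inactive L1, other repeat or none."""

    peak: Peak
    category: str
    repeat: Optional[RepeatInstance] = None

    def __post_init__(self) -> None:
        if self.category in ("young_L1", "inactive_L1") and self.repeat is None:
            raise ValueError(f"category {self.category} requires a repeat")


def _interval_tree(items: Sequence) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for i, item in enumerate(items):
        span = item.span if hasattr(item, "span") else item
        trees.setdefault(span.chrom, IntervalTree()).addi(span.start, span.end, i)
    return trees


def _overlaps_any(span: GenomicInterval, trees: Dict[str, IntervalTree]) -> bool:
    tree = trees.get(span.chrom)
    return bool(tree is not None and tree.overlap(span.start, span.end))


def reproducible_peaks(
    rep1: Sequence[Peak], rep2: Sequence[Peak], input_peaks: Sequence[Peak]
) -> List[Peak]:
    """Peaks present in both replicates and absent from the input control.

    A rep1 peak is kept when it overlaps (>= 1 bp) at least one rep2 peak and
    no input peak; output coordinates are the rep1 intervals. Any-overlap is
    used for both the replicate requirement and the input subtraction.
    """
    if not rep1 or not rep2:
        warnings.warn("empty replicate peak set; no reproducible peaks")
        return []
    rep2_trees = _interval_tree(rep2)
    input_trees = _interval_tree(input_peaks)
    return [
        p
        for p in rep1
        if _overlaps_any(p.span, rep2_trees) and not _overlaps_any(p.span, input_trees)
    ]


def cluster_fraction(peaks: Sequence[Peak], d: int = 50_000) -> float:
    """Fraction of peaks whose nearest other peak lies within ``d`` bases.

    Distance is the edge gap (0 for overlapping peaks); a single peak has no
    neighbour and scores 0. Invariant under coordinate translation and
    chromosome relabeling.
    """
    n = len(peaks)
    if n == 0:
        return float("nan")
    if n == 1:
        return 0.0
    by_chrom: Dict[str, List[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.span.chrom, []).append(p)
    clustered = 0
    for chrom_peaks in by_chrom.values():
        if len(chrom_peaks) == 1:
            continue
        chrom_peaks.sort(key=lambda p: (p.span.start, p.span.end))
        ends_running = np.maximum.accumulate([p.span.end for p in chrom_peaks])
        for i, p in enumerate(chrom_peaks):
            # nearest peak to the left: gap to the running-max end so far
            near = i > 0 and p.span.start - ends_running[i - 1] <= d
            if not near:
                # starts are sorted, so the right-side gap grows monotonically
                for q in chrom_peaks[i + 1 :]:
                    if q.span.start - p.span.end > d:
                        break
                    near = True
                    break
            if near:
                clustered += 1
    return clustered / n


def mark_overlap(
    peaks: Sequence[Peak],
    marks: Sequence[GenomicInterval],
    mode: str = "any",
    min_frac: float = 0.8,
) -> Tuple[float, List[bool]]:
    """Fraction of peaks overlapping a mark set at one of two stringencies.

    ``any``: at least one shared base with any mark. ``frac``: the union of
    mark bases must cover at least ``min_frac`` of the peak (coverage is
    measured relative to the peak, not the mark). Returns the fraction and
    the per-peak flags.
    """
    if mode not in ("any", "frac"):
        raise ValueError(f"mode must be 'any' or 'frac', got {mode!r}")
    trees = _interval_tree(marks)
    flags = []
    for p in peaks:
        tree = trees.get(p.span.chrom)
        hits = tree.overlap(p.span.start, p.span.end) if tree is not None else set()
        if mode == "any":
            flags.append(bool(hits))
            continue
        if not hits:
            flags.append(False)
            continue
        segs = sorted(
            (max(h.begin, p.span.start), min(h.end, p.span.end)) for h in hits
        )
        covered, cur_lo, cur_hi = 0, segs[0][0], segs[0][1]
        for lo, hi in segs[1:]:
            if lo > cur_hi:
                covered += cur_hi - cur_lo
                cur_lo, cur_hi = lo, hi
            else:
                cur_hi = max(cur_hi, hi)
        covered += cur_hi - cur_lo
        flags.append(covered / p.span.length >= min_frac)
    frac = float(np.mean(flags)) if flags else float("nan")
    return frac, flags


def assign_peaks(
    peaks: Sequence[Peak],
    repeats: Sequence[RepeatInstance],
    young_families: Sequence[str],
    inactive_families: Sequence[str],
) -> Tuple[List[PeakAssignment], Dict[str, int]]:
    """Assign each peak to the repeat it overlaps most.

    Categories: ``young_L1`` / ``inactive_L1`` when the best-overlapping
    repeat's family is in the corresponding list, ``other_repeat`` for any
    other overlap, ``no_repeat`` otherwise. Ties on overlap length break in
    favour of young over inactive, then by input order.
    """
    young, inactive = set(young_families), set(inactive_families)

    def rank(r: RepeatInstance) -> int:
        if r.family in young:
            return 0
        if r.family in inactive:
            return 1
        return 2

    trees = _interval_tree(repeats)
    assignments = []
    summary = {"young_L1": 0, "inactive_L1": 0, "other_repeat": 0, "no_repeat": 0}
    for p in peaks:
        tree = trees.get(p.span.chrom)
        hits = tree.overlap(p.span.start, p.span.end) if tree is not None else set()
        if not hits:
            assignments.append(PeakAssignment(peak=p, category="no_repeat"))
            summary["no_repeat"] += 1
            continue
        best = None
        best_key = None
        for h in sorted(hits, key=lambda h: h.data):
            r = repeats[h.data]
            key = (-p.span.overlap_length(r.span), rank(r))
            if best_key is None or key < best_key:
                best, best_key = r, key
        if best.family in young:
            cat = "young_L1"
        elif best.family in inactive:
            cat = "inactive_L1"
        else:
            cat = "other_repeat"
        assignments.append(PeakAssignment(peak=p, category=cat, repeat=best))
        summary[cat] += 1
    return assignments, summary


def rpkm(
    counts: pd.Series, lengths: pd.Series, total_mapped: float, pseudocount: float = 0.5
) -> pd.Series:
    """Reads per kilobase per million mapped reads, with a pseudocount."""
    return 1e9 * (counts + pseudocount) / (lengths * total_mapped)


def binding_enrichment(
    ip_counts: pd.DataFrame,
    input_counts: pd.DataFrame,
    consensus_lengths: pd.Series,
    threshold: float = 4.0,
    pseudocount: float = 0.5,
    total_mapped: Optional[Dict[str, float]] = None,
) -> pd.DataFrame:
    """Per-family IP/input RPKM enrichment with a selection at ``threshold``.

    Replicate columns are RPKM-normalized (to each replicate's total mapped
    reads and the family consensus length) then averaged within IP and input;
    the enrichment ratio is averaged-IP over averaged-input, with
    ``pseudocount`` reads added to every family in both samples first. The
    selection is inclusive (ratio >= threshold). Depth-scale invariant.

    ``total_mapped`` maps column names to each library's total mapped reads
    (the genome-wide total, of which the table's families are a part); when
    omitted, column sums are used, which is only appropriate when the table
    covers essentially all mapped reads.
    """
    fams = ip_counts.index
    if not fams.equals(input_counts.index):
        raise ValueError("IP and input tables must share the same family universe")
    lengths = consensus_lengths.reindex(fams)
    if lengths.isna().any():
        missing = list(fams[lengths.isna()])[:5]
        raise ValueError(f"missing consensus lengths for {missing}")

    def mean_rpkm(df: pd.DataFrame) -> pd.Series:
        cols = [
            rpkm(
                df[c],
                lengths,
                total_mapped[c] if total_mapped is not None else df[c].sum(),
                pseudocount,
            )
            for c in df.columns
        ]
        return pd.concat(cols, axis=1).mean(axis=1)

    ip = mean_rpkm(ip_counts)
    ti = mean_rpkm(input_counts)
    ratio = ip / ti
    return pd.DataFrame(
        {
            "ip_rpkm": ip,
            "input_rpkm": ti,
            "ratio": ratio,
            "selected": ratio >= threshold,
        }
    )


def flanking_binding_fraction(
    gs: GeneSet,
    genes_by_id: Dict[str, Gene],
    bound_repeats: Sequence[RepeatInstance],
    inactive_families: Sequence[str],
    w: int = 20_000,
) -> Dict[str, float]:
    """Fractions of genes with a bound inactive L1 or an ERVK within ``w`` bp.

    ``bound_repeats`` are repeat instances established (e.g. by peak
    assignment) to be occupied by the ChIPped factor.
    """
    out = {}
    filt_inactive = RepeatFilter(families=frozenset(inactive_families))
    n_inactive, _ = genes_with_repeat(gs, genes_by_id, bound_repeats, filt_inactive, w)
    out["bound_inactive_L1"] = n_inactive / len(gs) if len(gs) else float("nan")
    ervk = [r for r in bound_repeats if r.family.upper().startswith(("IAP", "ETN", "ERVK"))]
    if ervk:
        filt_ervk = RepeatFilter(families=frozenset(r.family for r in ervk))
        n_ervk, _ = genes_with_repeat(gs, genes_by_id, ervk, filt_ervk, w)
        out["ERVK"] = n_ervk / len(gs) if len(gs) else float("nan")
    else:
        out["ERVK"] = 0.0 if len(gs) else float("nan")
    return out


def consensus_profile(
    coverage: Sequence[float], n_bins: int = 20
) -> Tuple[np.ndarray, float]:
    """Binned coverage profile along a consensus, and the 3'/5' half ratio.

    The per-position coverage is averaged within ``n_bins`` equal bins and
    normalized to the profile mean; the ratio is mean coverage of the second
    (3') half over the first (5') half, ``inf`` when the 5' half is empty.
    A ratio above 1 indicates binding concentrated toward the 3' end.
    """
    cov = np.asarray(coverage, dtype=float)
    if cov.ndim != 1 or cov.size < n_bins:
        raise ValueError("coverage must be 1-D with at least n_bins positions")
    if np.any(cov < 0):
        raise ValueError("coverage must be non-negative")
    edges = np.linspace(0, cov.size, n_bins + 1).astype(int)
    bins = np.array([cov[lo:hi].mean() for lo, hi in zip(edges[:-1], edges[1:])])
    mean = cov.mean()
    norm_bins = bins / mean if mean > 0 else bins
    half = cov.size // 2
    first = cov[:half].mean()
    second = cov[half:].mean() if cov.size % 2 == 0 else cov[cov.size - half :].mean()
    ratio = math.inf if first == 0 and second > 0 else (
        second / first if first > 0 else float("nan")
    )
    return norm_bins, float(ratio)
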