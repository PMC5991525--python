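"""Family-level repeat expression analysis.

Derepression testing of repeat families against control samples, the
intersection that defines co-repressed families, read-fraction summaries per
treatment group, and the evolutionary-age and divergence classifiers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome import RepeatInstance
from .io import RepeatFamilyInfo
from .stats import nb_test


@dataclass(frozen=True)
class FamilySet:
    """A labeled set of repeat-family names."""

    label: str
    families: frozenset

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("FamilySet label must be non-empty")

    def __len__(self) -> int:
        return len(self.families)


def collapse_duplicates(counts: pd.DataFrame, how: str = "sum") -> pd.DataFrame:
    """Collapse identically named features by summing (default) or averaging."""
    if not counts.index.duplicated().any():
        return counts
    grouped = counts.groupby(level=0, sort=False)
    if how == "sum":
        return grouped.sum()
    if how == "mean":
        return grouped.mean().round().astype(int)
    raise ValueError(f"unknown duplicate rule {how!r}")


def derepressed_families(
    counts: pd.DataFrame,
    condition: Sequence[str],
    reference: str,
    label: str,
    fold_min: float = 2.0,
    alpha: float = 0.05,
    use_adjusted: bool = True,
    duplicate_rule: str = "sum",
) -> Tuple[FamilySet, pd.DataFrame]:
    """Families up-regulated more than ``fold_min``-fold at significance ``alpha``.

    The fold threshold is strict (fold > fold_min); significance uses the
    BH-adjusted p by default (``use_adjusted=False`` switches to the raw p).
    An empty selection is a valid, empty family set.
    """
    counts = collapse_duplicates(counts, duplicate_rule)
    de = nb_test(counts, condition, reference)
    crit = de["padj"] if use_adjusted else de["p"]
    selected = de.index[
        (de["log2fc"] > np.log2(fold_min)) & (crit <= alpha) & crit.notna()
    ]
    return FamilySet(label=label, families=frozenset(selected)), de


def corepressed(set_a: FamilySet, set_b: FamilySet) -> FamilySet:
    """Families present in both sets (co-repressed by both factors)."""
    return FamilySet(
        label=f"{set_a.label}&{set_b.label}",
        families=set_a.families & set_b.families,
    )


def percent_reads_repeats(
    repeat_mapped: Sequence[int],
    total_mapped: Sequence[int],
    groups: Sequence[str],
) -> pd.DataFrame:
    """Percent of mapped reads assigned to repeats, summarized per group.

    Returns one row per group with the mean percentage and its spread:
    standard deviation for n >= 3 replicates, standard error of the mean for
    n == 2, NaN for a single replicate.
    """
    repeat_mapped = np.asarray(repeat_mapped, dtype=float)
    total_mapped = np.asarray(total_mapped, dtype=float)
    if np.any(repeat_mapped > total_mapped):
        raise ValueError("repeat-mapped reads exceed total mapped reads")
    if np.any(total_mapped <= 0):
        raise ValueError("total mapped reads must be positive")
    pct = 100.0 * repeat_mapped / total_mapped
    df = pd.DataFrame({"group": list(groups), "percent": pct})
    rows = []
    for grp, sub in df.groupby("group", sort=False):
        vals = sub["percent"].to_numpy()
        n = len(vals)
        if n >= 3:
            spread, kind = float(np.std(vals, ddof=1)), "sd"
        elif n == 2:
            spread, kind = float(np.std(vals, ddof=1) / math.sqrt(n)), "sem"
        else:
            spread, kind = float("nan"), "none"
        rows.append(
            {"group": grp, "n": n, "mean_percent": float(vals.mean()),
             "spread": spread, "spread_kind": kind}
        )
    return pd.DataFrame(rows)


def classify_family_ages(
    fams: FamilySet,
    family_info: Dict[str, RepeatFamilyInfo],
    cutoff_myr: float,
) -> Tuple[float, pd.DataFrame]:
    """Fraction of families strictly younger than ``cutoff_myr``.

    Families without an age are excluded (with a warning) from both the
    numerator and denominator; a family exactly at the cutoff counts as not
    under it.
    """
    rows = []
    for fam in sorted(fams.families):
        info = family_info.get(fam)
        age = info.age_myr if info is not None else None
        if age is None:
            warnings.warn(f"family {fam!r} has no age; excluded from age classification")
            continue
        rows.append({"family": fam, "age_myr": age, "under_cutoff": age < cutoff_myr})
    table = pd.DataFrame(rows, columns=["family", "age_myr", "under_cutoff"])
    frac = float(table["under_cutoff"].mean()) if len(table) else float("nan")
    return frac, table


def mean_divergence(
    instances: Iterable[RepeatInstance],
    families: Optional[Iterable[str]] = None,
) -> pd.Series:
    """Arithmetic mean percent divergence per family.

    Instances without a divergence value are skipped; families with no scored
    instance are omitted from the result.
    """
    wanted = set(families) if families is not None else None
    acc: Dict[str, List[float]] = {}
    for r in instances:
        if wanted is not None and r.family not in wanted:
            continue
        if r.divergence is None:
            continue
        acc.setdefault(r.family, []).append(r.divergence)
    out = {fam: float(np.mean(v)) for fam, v in acc.items()}
    return pd.Series(out, name="mean_divergence").sort_index()
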