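"""Gene-set derivation and gene-level evolutionary statistics.

Co-repressed gene sets from differential-expression results, uniform random
gene backgrounds, peak-proximity fractions, the conservation split, and the
last-common-ancestor (gene age) enrichment test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import Gene, Peak, within_radius
from .stats import ContingencyTable2x2, bh_adjust, fisher_one_sided


@dataclass(frozen=True)
class GeneSet:
    """An ordered, labeled collection of gene ids."""

    label: str
    gene_ids: tuple

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("GeneSet label must be non-empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("GeneSet gene_ids contain duplicates")

    def __len__(self) -> int:
        return len(self.gene_ids)


def _resolve(gs: GeneSet, genes_by_id: Dict[str, Gene]) -> List[Gene]:
    missing = [g for g in gs.gene_ids if g not in genes_by_id]
    if missing:
        raise KeyError(f"gene ids not in annotation: {missing[:5]}")
    return [genes_by_id[g] for g in gs.gene_ids]


def upregulated_genes(
    de: pd.DataFrame, label: str, fold_min: float = 2.0, fdr: float = 0.05
) -> GeneSet:
    """Genes up-regulated strictly more than ``fold_min``-fold at padj <= ``fdr``."""
    sel = de.index[
        (de["log2fc"] > np.log2(fold_min)) & (de["padj"] <= fdr) & de["padj"].notna()
    ]
    return GeneSet(label=label, gene_ids=tuple(sel))


def corepressed_genes(set_a: GeneSet, set_b: GeneSet) -> GeneSet:
    """Intersection of two gene sets, keeping the first set's order."""
    in_b = set(set_b.gene_ids)
    return GeneSet(
        label=f"{set_a.label}&{set_b.label}",
        gene_ids=tuple(g for g in set_a.gene_ids if g in in_b),
    )


def random_gene_sets(
    universe: Sequence[Gene],
    n: int = 100,
    k: int = 3,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    exclude: Optional[Iterable[str]] = None,
) -> List[GeneSet]:
    """``k`` gene sets of ``n`` genes sampled uniformly without replacement.

    Sets are drawn independently of each other (disjointness across sets is
    not enforced, matching a "three random gene groups" design). ``exclude``
    removes gene ids (typically the test set itself) from the sampling
    universe, so a small universe does not contaminate the background.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    excluded = set(exclude) if exclude is not None else set()
    ids = [g.id for g in universe if g.id not in excluded]
    if n > len(ids):
        raise ValueError(f"cannot sample {n} genes from a universe of {len(ids)}")
    return [
        GeneSet(
            label=f"random_{i + 1}",
            gene_ids=tuple(rng.choice(ids, size=n, replace=False)),
        )
        for i in range(k)
    ]


def pool_gene_sets(sets: Sequence[GeneSet], label: str = "background") -> GeneSet:
    """Pool several sets into one background (duplicates collapsed, order kept)."""
    seen, pooled = set(), []
    for gs in sets:
        for g in gs.gene_ids:
            if g not in seen:
                seen.add(g)
                pooled.append(g)
    return GeneSet(label=label, gene_ids=tuple(pooled))


def peak_proximity_fraction(
    gs: GeneSet,
    genes_by_id: Dict[str, Gene],
    peaks: Sequence[Peak],
    w: int = 20_000,
) -> float:
    """Fraction of genes with at least one peak within ``w`` bp of the gene span."""
    genes = _resolve(gs, genes_by_id)
    if not genes:
        return float("nan")
    hits = 0
    for g in genes:
        if any(within_radius(g.span, p.span, w) for p in peaks):
            hits += 1
    return hits / len(genes)


def conservation_split(
    gs: GeneSet, genes_by_id: Dict[str, Gene], threshold: float = 0.8
) -> Dict[str, float]:
    """Split a gene set into conserved (score >= threshold, inclusive) and not.

    Genes without a conservation score are excluded and reported in the
    ``n_unscored`` count; fractions are over scored genes only.
    """
    genes = _resolve(gs, genes_by_id)
    scored = [g for g in genes if g.conservation is not None]
    n_unscored = len(genes) - len(scored)
    if n_unscored:
        warnings.warn(f"{gs.label}: {n_unscored} genes lack conservation scores")
    n_cons = sum(1 for g in scored if g.conservation >= threshold)
    n = len(scored)
    return {
        "n_scored": n,
        "n_unscored": n_unscored,
        "n_conserved": n_cons,
        "n_nonconserved": n - n_cons,
        "conserved_fraction": n_cons / n if n else float("nan"),
        "nonconserved_fraction": (n - n_cons) / n if n else float("nan"),
    }


def conservation_enrichment(
    gs: GeneSet,
    bg: GeneSet,
    genes_by_id: Dict[str, Gene],
    threshold: float = 0.8,
) -> Dict[str, float]:
    """One-sided Fisher test for over-representation of non-conserved genes in the set."""
    s = conservation_split(gs, genes_by_id, threshold)
    b = conservation_split(bg, genes_by_id, threshold)
    table = ContingencyTable2x2(
        a=s["n_nonconserved"], b=s["n_conserved"],
        c=b["n_nonconserved"], d=b["n_conserved"],
    )
    return {
        "set_nonconserved_fraction": s["nonconserved_fraction"],
        "bg_nonconserved_fraction": b["nonconserved_fraction"],
        "p": fisher_one_sided(table),
        "table": (table.a, table.b, table.c, table.d),
    }


def lca_enrichment(
    gs: GeneSet,
    genes_by_id: Dict[str, Gene],
    genome_counts: Dict[str, int],
) -> pd.DataFrame:
    """Per-clade enrichment of last-common-ancestor labels against the genome.

    For every clade a 2x2 one-sided Fisher test (set vs rest-of-genome x
    clade vs not), BH-adjusted across clades. ``genome_counts`` holds the
    genome-wide number of genes per clade (the set is assumed drawn from that
    genome and is subtracted to form the rest-of-genome column). Unlabeled
    genes are excluded with a warning.
    """
    genes = _resolve(gs, genes_by_id)
    labeled = [g for g in genes if g.lca_clade is not None]
    if len(labeled) < len(genes):
        warnings.warn(f"{gs.label}: {len(genes) - len(labeled)} genes lack LCA labels")
    n_set = len(labeled)
    set_counts = pd.Series([g.lca_clade for g in labeled]).value_counts().to_dict()
    n_genome = sum(genome_counts.values())
    rows = []
    for clade in sorted(genome_counts):
        a = int(set_counts.get(clade, 0))
        rest_clade = max(0, genome_counts[clade] - a)
        rest_total = n_genome - n_set
        table = ContingencyTable2x2(
            a=a, b=n_set - a, c=rest_clade, d=rest_total - rest_clade
        )
        rows.append(
            {
                "clade": clade,
                "set_count": a,
                "set_fraction": a / n_set if n_set else float("nan"),
                "genome_fraction": genome_counts[clade] / n_genome,
                "p": fisher_one_sided(table),
            }
        )
    out = pd.DataFrame(rows)
    out["padj"] = bh_adjust(out["p"])
    return out


def biotype_fraction(gs: GeneSet, genes_by_id: Dict[str, Gene]) -> float:
    """Fraction of genes in the set annotated as protein-coding."""
    genes = _resolve(gs, genes_by_id)
    if not genes:
        return float("nan")
    return sum(1 for g in genes if g.biotype == "protein_coding") / len(genes)
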