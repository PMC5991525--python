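"""End-to-end orchestration on a synthetic study with planted ground truth.

``run_pipeline`` simulates an annotated genome, two knockdown expression
experiments (a TRIM28-like and a HUSH-like factor), and a replicate ChIP
experiment; then runs every analysis stage — repeat-family derepression and
co-repression, co-repressed gene sets, repeat-proximity enrichment against
random backgrounds, gene conservation/ancestry statistics, upstream-LTR
orientation bias, and the full suite of peak statistics — and writes TSV
artifacts plus a machine-readable JSON summary keyed by analysis name.

Everything is deterministic given ``PipelineConfig.seed``.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .enrichment import (
    RepeatFilter,
    enrichment_vs_background,
    fraction_with_any,
    l1_array_fraction,
    orientation_bias,
)
from .genesets import (
    GeneSet,
    biotype_fraction,
    conservation_enrichment,
    corepressed_genes,
    lca_enrichment,
    peak_proximity_fraction,
    pool_gene_sets,
    random_gene_sets,
    upregulated_genes,
)
from .io import write_bed, write_counts, write_gene_table, write_repeats
from .peaks import (
    assign_peaks,
    binding_enrichment,
    cluster_fraction,
    flanking_binding_fraction,
    mark_overlap,
    reproducible_peaks,
)
from .repeats import (
    FamilySet,
    classify_family_ages,
    corepressed,
    derepressed_families,
    mean_divergence,
)
from .simulate import (
    ERVK_FAMILIES,
    SATELLITE_FAMILIES,
    SimConfig,
    simulate_annotation,
    simulate_counts,
    simulate_peaks,
)
from .stats import nb_test

log = logging.getLogger(__name__)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return "inf" if math.isinf(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_pipeline(
    cfg: PipelineConfig,
    outdir,
    sim: Optional[SimConfig] = None,
) -> Dict:
    """Run every stage on a simulated study and write artifacts to ``outdir``.

    Returns the summary dictionary (also written as ``summary.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if sim is None:
        sim = SimConfig(seed=cfg.seed)
    log.info("pipeline v%s seed=%d fold>%g fdr<=%g windows=%s", __version__,
             cfg.seed, cfg.fold, cfg.fdr, cfg.windows)

    # ---- annotation ------------------------------------------------------
    bundle, truth = simulate_annotation(sim)
    genes_by_id = {g.id: g for g in bundle.genes}
    write_gene_table(outdir / "genes.tsv", bundle.genes, seed=cfg.seed)
    write_repeats(outdir / "repeats.tsv", bundle.repeats, seed=cfg.seed)
    target_ids = truth["target_gene_ids"]

    # ---- gene-level differential expression (two factors) ---------------
    gene_ids = [g.id for g in bundle.genes]
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 10]))
    extra_a = rng.choice(
        [g for g in gene_ids if g not in set(target_ids)], size=30, replace=False
    )
    extra_b = rng.choice(
        [g for g in gene_ids if g not in set(target_ids) | set(extra_a)],
        size=25, replace=False,
    )
    planted_a = {g: 3.0 for g in list(target_ids) + list(extra_a)}
    planted_b = {g: 3.0 for g in list(target_ids) + list(extra_b)}
    sim_a = SimConfig(seed=cfg.seed * 2 + 101, planted_log2fc=planted_a)
    sim_b = SimConfig(seed=cfg.seed * 2 + 202, planted_log2fc=planted_b)
    counts_a, truth_a = simulate_counts(sim_a, gene_ids)
    counts_b, truth_b = simulate_counts(sim_b, gene_ids)
    cond = truth_a["condition"]
    de_a = nb_test(counts_a, cond, "control")
    de_b = nb_test(counts_b, cond, "control")
    de_a.to_csv(outdir / "de_genes_factorA.tsv", sep="\t")
    de_b.to_csv(outdir / "de_genes_factorB.tsv", sep="\t")

    set_a = upregulated_genes(de_a, "factorA", cfg.fold, cfg.fdr)
    set_b = upregulated_genes(de_b, "factorB", cfg.fold, cfg.fdr)
    coset = corepressed_genes(set_a, set_b)
    recovered = len(set(coset.gene_ids) & set(target_ids))
    pd.Series(coset.gene_ids).to_csv(
        outdir / "corepressed_genes.tsv", sep="\t", index=False, header=["gene_id"]
    )

    # ---- random backgrounds and gene-level statistics --------------------
    bg_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    rand_sets = random_gene_sets(
        bundle.genes, n=cfg.n_random_background, k=cfg.n_random_sets, rng=bg_rng,
        exclude=coset.gene_ids,
    )
    background = pool_gene_sets(rand_sets)

    cons = conservation_enrichment(
        coset, background, genes_by_id, cfg.conservation_threshold
    )
    genome_counts = (
        pd.Series([g.lca_clade for g in bundle.genes]).value_counts().to_dict()
    )
    lca = lca_enrichment(coset, genes_by_id, genome_counts)
    lca.to_csv(outdir / "lca_enrichment.tsv", sep="\t", index=False)

    # ---- repeat-proximity enrichment -------------------------------------
    young_filter = RepeatFilter(families=frozenset(cfg.young_l1_families))
    line_5kb = RepeatFilter(classes=frozenset({"LINE"}), min_length=cfg.full_length_min)
    satellite = RepeatFilter(classes=frozenset({"Satellite"}))
    enr_young = enrichment_vs_background(
        coset, background, genes_by_id, bundle.repeats, young_filter,
        cfg.windows, bundle.family_info,
    )
    enr_rows = [
        {
            "filter": "young_L1", "window": e.window, "set_positive": e.set_positive,
            "set_total": e.set_total, "bg_positive": e.bg_positive,
            "bg_total": e.bg_total, "fold": e.fold, "p": e.p,
        }
        for e in enr_young
    ]
    pd.DataFrame(enr_rows).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    frac_any = fraction_with_any(
        coset, genes_by_id, bundle.repeats, [young_filter, satellite],
        max(cfg.windows), bundle.family_info,
    )
    arrays = l1_array_fraction(
        coset, genes_by_id, bundle.repeats, young_filter, max(cfg.windows),
        family_info=bundle.family_info,
    )

    # ---- orientation bias -------------------------------------------------
    orient = orientation_bias(
        coset, background, genes_by_id, bundle.repeats, bundle.chrom_sizes,
        cfg.upstream_len,
    )

    # ---- repeat-family derepression ---------------------------------------
    families = sorted(bundle.family_info)
    fam_planted = {f: 2.8 for f in cfg.young_l1_families}
    fam_planted.update({f: 3.8 for f in SATELLITE_FAMILIES})
    fam_a = dict(fam_planted, **{f: 3.0 for f in ERVK_FAMILIES})
    sim_fa = SimConfig(seed=cfg.seed * 2 + 303, planted_log2fc=fam_a)
    sim_fb = SimConfig(seed=cfg.seed * 2 + 404, planted_log2fc=fam_planted)
    fam_counts_a, _ = simulate_counts(sim_fa, families, mean_count=500.0)
    fam_counts_b, _ = simulate_counts(sim_fb, families, mean_count=500.0)
    fams_a, fam_de_a = derepressed_families(
        fam_counts_a, cond, "control", "factorA", cfg.fold, cfg.fdr,
        cfg.use_adjusted_for_families,
    )
    fams_b, fam_de_b = derepressed_families(
        fam_counts_b, cond, "control", "factorB", cfg.fold, cfg.fdr,
        cfg.use_adjusted_for_families,
    )
    cofams = corepressed(fams_a, fams_b)
    fam_de_a.to_csv(outdir / "de_families_factorA.tsv", sep="\t")
    fam_de_b.to_csv(outdir / "de_families_factorB.tsv", sep="\t")

    l1_cofams = cofams.families & {
        f for f, i in bundle.family_info.items() if i.repclass == "LINE"
    }
    age_results = {}
    for cutoff in cfg.age_cutoffs_myr:
        frac, _ = classify_family_ages(
            FamilySet(label="coL1", families=frozenset(l1_cofams)),
            bundle.family_info, cutoff,
        )
        age_results[f"under_{cutoff:g}_myr"] = frac
    div = mean_divergence(bundle.repeats, cfg.young_l1_families)

    # ---- ChIP peaks --------------------------------------------------------
    peak_sets, peak_truth = simulate_peaks(sim, bundle)
    for name in ("rep1", "rep2", "input"):
        write_bed(outdir / f"peaks_{name}.bed", peak_sets[name], seed=cfg.seed)
    write_bed(outdir / "h3k9me3.bed", peak_sets["h3k9me3"], seed=cfg.seed)
    repro = reproducible_peaks(
        peak_sets["rep1"], peak_sets["rep2"], peak_sets["input"]
    )
    write_bed(outdir / "peaks_reproducible.bed", repro, seed=cfg.seed)
    clus = cluster_fraction(repro, cfg.cluster_d)
    ov_any, _ = mark_overlap(repro, peak_sets["h3k9me3"], "any")
    ov_frac, _ = mark_overlap(repro, peak_sets["h3k9me3"], "frac", 0.8)
    proximity_set = peak_proximity_fraction(coset, genes_by_id, repro, max(cfg.windows))
    proximity_bg = peak_proximity_fraction(background, genes_by_id, repro, max(cfg.windows))
    assignments, assign_summary = assign_peaks(
        repro, bundle.repeats, cfg.young_l1_families, cfg.inactive_l1_families
    )
    bound = [a.repeat for a in assignments if a.repeat is not None]
    flank_bound = flanking_binding_fraction(
        coset, genes_by_id, bound, cfg.inactive_l1_families, max(cfg.windows)
    )

    # family-level IP/input binding enrichment
    tethered = list(ERVK_FAMILIES) + list(cfg.inactive_l1_families)
    sim_chip = SimConfig(
        seed=cfg.seed * 2 + 505,
        planted_log2fc={f: math.log2(6.0) for f in tethered},
    )
    chip_counts, chip_truth = simulate_counts(
        sim_chip, families, depths=(1.0, 1.0, 1.0, 1.0), n_control=2,
        mean_count=500.0,
    )
    consensus = pd.Series(
        {f: bundle.family_info[f].consensus_length for f in families}
    )
    # totals are the genome-wide mapped reads per library (equal depths here),
    # not the repeat-only column sums
    benr = binding_enrichment(
        chip_counts[["treat_1", "treat_2"]],
        chip_counts[["ctrl_1", "ctrl_2"]],
        consensus, cfg.binding_ratio,
        total_mapped={c: 1e6 for c in chip_counts.columns},
    )
    benr.to_csv(outdir / "binding_enrichment.tsv", sep="\t")
    write_counts(outdir / "chip_family_counts.tsv", chip_counts, seed=cfg.seed)

    summary = {
        "version": __version__,
        "seed": cfg.seed,
        "gene_sets": {
            "factorA_upregulated": len(set_a),
            "factorB_upregulated": len(set_b),
            "corepressed": len(coset),
            "planted_targets": len(target_ids),
            "planted_targets_recovered": recovered,
            "protein_coding_fraction": biotype_fraction(coset, genes_by_id),
        },
        "conservation": cons,
        "lca_mus_musculus": _jsonable(
            lca.set_index("clade").loc["Mus_musculus"].to_dict()
        )
        if "Mus_musculus" in set(lca["clade"])
        else None,
        "young_l1_enrichment": enr_rows,
        "fraction_with_l1_or_satellite": frac_any,
        "l1_array_fraction": arrays,
        "orientation_bias": orient,
        "repeat_families": {
            "factorA_derepressed": sorted(fams_a.families),
            "factorB_derepressed": sorted(fams_b.families),
            "corepressed": sorted(cofams.families),
            "l1_age_fractions": age_results,
            "young_l1_mean_divergence": div.to_dict(),
        },
        "chip_peaks": {
            "n_rep1": len(peak_sets["rep1"]),
            "n_reproducible": len(repro),
            "n_true_planted": peak_truth["n_true_peaks"],
            "cluster_fraction": clus,
            "peak_within_20kb_fraction_set": proximity_set,
            "peak_within_20kb_fraction_background": proximity_bg,
            "h3k9me3_overlap_any": ov_any,
            "h3k9me3_overlap_frac80": ov_frac,
            "assignment": assign_summary,
            "binding_selected": sorted(benr.index[benr["selected"]]),
            "binding_planted": sorted(tethered),
            "flanking_bound_fractions": flank_bound,
        },
    }
    summary = _jsonable(summary)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
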