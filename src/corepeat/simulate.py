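"""Synthetic annotations, count matrices and ChIP peak sets with known truth.

The generator emulates the data structure the analysis assumes: a small
multi-chromosome genome carrying genes with biotype/conservation/ancestry
labels, repeat instances of named LINE-1, ERVK, satellite and LTR families,
negative-binomial count tables with planted derepression, and replicate ChIP
peak sets tethered to ERVK/inactive-L1 copies with planted clustering and
H3K9me3 overlap. A subset of "target" genes receives planted young-L1 flank
enrichment and a planted sense-orientation bias of upstream LTRs, so every
downstream statistic has a ground truth to recover.

Default effect sizes follow the biological regime the pipeline is built for:
7-fold young-L1 flank enrichment at target genes, 69% sense bias of their
upstream LTRs, 34% H3K9me3 overlap of true peaks, and ~1000 tethered peaks
genome-wide. Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome import Gene, GenomicInterval, Peak, RepeatInstance
from .io import AnnotationBundle, RepeatFamilyInfo

YOUNG_L1_FAMILIES = ("L1Md_F", "L1Md_F2", "L1Md_F3", "L1Md_A", "L1Md_T")
INACTIVE_L1_FAMILIES = (
    "L1_Rod",
    "L1MB7",
    "L1_Mur1",
    "L1_Mur2",
    "L1_Mur3",
    "Lx8",
    "Lx9",
    "Lx10",
)
ERVK_FAMILIES = ("IAPEz", "ETnERV")
SATELLITE_FAMILIES = ("GSAT_MM", "SYNREP_MM")
LTR_FAMILIES = ("RLTR10", "MT2_Mm", "ORR1A0")

#: divergence accumulates at roughly this percent per Myr in the simulator
DIVERGENCE_RATE = 0.75

LCA_CLADES = ("Mus_musculus", "Rodentia", "Mammalia", "Vertebrata")


def default_family_info() -> Dict[str, RepeatFamilyInfo]:
    """Shipped family metadata: young L1s < 5 Myr, inactive L1s >= 13 Myr.

    Ages are plausible placeholders for testing the age classifiers and are
    user-replaceable via the family-info TSV.
    """
    ages_young = {"L1Md_T": 1.5, "L1Md_A": 2.0, "L1Md_F2": 3.0, "L1Md_F": 3.5, "L1Md_F3": 4.5}
    ages_inactive = {
        "L1_Rod": 13.5,
        "L1_Mur1": 14.0,
        "L1_Mur2": 15.0,
        "L1_Mur3": 16.0,
        "Lx8": 18.0,
        "Lx9": 20.0,
        "Lx10": 22.0,
        "L1MB7": 30.0,
    }
    info: Dict[str, RepeatFamilyInfo] = {}
    for fam, age in ages_young.items():
        info[fam] = RepeatFamilyInfo(fam, "LINE", age, True, 6500)
    for fam, age in ages_inactive.items():
        info[fam] = RepeatFamilyInfo(fam, "LINE", age, False, 6000)
    for fam, age in zip(ERVK_FAMILIES, (6.0, 8.0)):
        info[fam] = RepeatFamilyInfo(fam, "LTR", age, True, 5500)
    for fam, age in zip(SATELLITE_FAMILIES, (10.0, 25.0)):
        info[fam] = RepeatFamilyInfo(fam, "Satellite", age, False, 234)
    for fam, age in zip(LTR_FAMILIES, (4.0, 9.0, 35.0)):
        info[fam] = RepeatFamilyInfo(fam, "LTR", age, False, 500)
    return info


def _default_rates() -> Dict[str, float]:
    rates: Dict[str, float] = {}
    rates.update({f: 0.8e-6 for f in YOUNG_L1_FAMILIES})
    rates.update({f: 1.2e-6 for f in INACTIVE_L1_FAMILIES})
    rates.update({f: 2e-6 for f in ERVK_FAMILIES})
    rates.update({f: 2e-6 for f in SATELLITE_FAMILIES})
    rates.update({f: 5e-6 for f in LTR_FAMILIES})
    return rates


@dataclass
class SimConfig:
    """Parameters of the synthetic study; all randomness flows from ``seed``."""

    seed: int
    n_chroms: int = 5
    chrom_len: int = 30_000_000
    n_genes: int = 500
    target_fraction: float = 0.2
    repeat_rates: Dict[str, float] = field(default_factory=_default_rates)
    planted_enrichment_fold: float = 7.0
    flank_width: int = 20_000
    nb_dispersion: float = 0.1
    planted_log2fc: Dict[str, float] = field(default_factory=dict)
    peak_tether_prob: float = 0.9
    h3k9me3_overlap_prob: float = 0.34
    sense_bias: float = 0.69
    upstream_ltr_per_kb: float = 2.0
    upstream_len: int = 3000
    nonconserved_prob_target: float = 0.41
    nonconserved_prob_background: float = 0.14
    coding_prob_target: float = 0.72
    coding_prob_background: float = 0.80
    lca_probs_background: Tuple[float, ...] = (0.009, 0.09, 0.55, 0.351)
    lca_probs_target: Tuple[float, ...] = (0.118, 0.20, 0.45, 0.232)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("target_fraction", "peak_tether_prob", "h3k9me3_overlap_prob", "sense_bias"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if any(r <= 0 for r in self.repeat_rates.values()):
            raise ValueError("repeat rates must be positive")
        if self.planted_enrichment_fold < 1:
            raise ValueError("planted_enrichment_fold must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")

    def rng(self, stream: int) -> np.random.Generator:
        """An independent deterministic stream per simulator stage."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


def _place_genes(cfg: SimConfig, rng: np.random.Generator) -> List[GenomicInterval]:
    """Uniform non-overlapping gene spans via uniform-spacing placement."""
    per_chrom = np.full(cfg.n_chroms, cfg.n_genes // cfg.n_chroms)
    per_chrom[: cfg.n_genes % cfg.n_chroms] += 1
    spans: List[GenomicInterval] = []
    for ci in range(cfg.n_chroms):
        n = int(per_chrom[ci])
        lengths = np.clip(
            rng.lognormal(np.log(10_000), 0.6, size=n), 2_000, 60_000
        ).astype(int)
        free = cfg.chrom_len - int(lengths.sum())
        if free <= 0:
            raise ValueError("gene density saturates the chromosome")
        cuts = np.sort(rng.integers(0, free + 1, size=n))
        starts = cuts + np.concatenate(([0], np.cumsum(lengths[:-1])))
        strands = rng.choice(["+", "-"], size=n)
        for s, l, st in zip(starts, lengths, strands):
            spans.append(GenomicInterval(f"chr{ci + 1}", int(s), int(s + l), str(st)))
    return spans


def _repeat_length(fam: str, info: RepeatFamilyInfo, rng: np.random.Generator) -> int:
    if info.repclass == "LINE":
        if rng.random() < 0.3:  # full-length copy
            return int(np.clip(rng.normal(info.consensus_length, 300), 5_100, 8_000))
        return int(np.clip(rng.lognormal(np.log(1_200), 0.8), 150, 4_900))
    if info.repclass == "Satellite":
        return int(rng.integers(200, 2_000))
    # LTR class: near-consensus or truncated
    frac = rng.uniform(0.85, 1.05) if rng.random() < 0.5 else rng.uniform(0.3, 0.8)
    return max(80, int(info.consensus_length * frac))


def _divergence(info: RepeatFamilyInfo, rng: np.random.Generator) -> float:
    age = info.age_myr if info.age_myr is not None else 10.0
    sd = 0.5 if age < 5 else 2.0
    return float(np.clip(rng.normal(age * DIVERGENCE_RATE, sd), 0.05, 60.0))


def _make_instance(
    chrom: str,
    start: int,
    fam: str,
    info: RepeatFamilyInfo,
    chrom_len: int,
    rng: np.random.Generator,
    max_len: Optional[int] = None,
) -> RepeatInstance:
    length = _repeat_length(fam, info, rng)
    if max_len is not None:
        length = min(length, max_len)
    end = min(start + length, chrom_len)
    strand = str(rng.choice(["+", "-"]))
    return RepeatInstance(
        span=GenomicInterval(chrom, start, max(end, start + 1), strand),
        family=fam,
        repclass=info.repclass,
        divergence=_divergence(info, rng),
    )


def simulate_annotation(cfg: SimConfig) -> Tuple[AnnotationBundle, dict]:
    """Generate genes and repeats with planted young-L1 flank enrichment.

    Genes are placed uniformly without overlap; repeats follow an independent
    per-family Poisson process, with young-L1 density multiplied by
    ``planted_enrichment_fold`` inside the +/- ``flank_width`` flanks of
    target genes. LTR instances are additionally planted in each gene's
    upstream region with a sense-orientation probability of ``sense_bias``
    (target genes) or 0.5 (others). The truth record lists target genes and
    planted repeat provenance.
    """
    info = default_family_info()
    unknown = [f for f in cfg.repeat_rates if f not in info]
    if unknown:
        raise ValueError(f"repeat_rates name unknown families: {unknown}")
    mean_len = 2_000.0
    if sum(cfg.repeat_rates.values()) * mean_len > 0.5:
        raise ValueError("repeat densities imply overlap saturation")

    rng = cfg.rng(0)
    spans = _place_genes(cfg, rng)
    n_target = int(round(cfg.n_genes * cfg.target_fraction))
    target_idx = set(rng.choice(cfg.n_genes, size=n_target, replace=False).tolist())

    genes: List[Gene] = []
    for i, span in enumerate(spans):
        is_target = i in target_idx
        p_nc = cfg.nonconserved_prob_target if is_target else cfg.nonconserved_prob_background
        conserved = rng.random() >= p_nc
        conservation = float(rng.uniform(0.8, 1.0) if conserved else rng.uniform(0.0, 0.8))
        coding_p = cfg.coding_prob_target if is_target else cfg.coding_prob_background
        biotype = "protein_coding" if rng.random() < coding_p else "other"
        lca_p = cfg.lca_probs_target if is_target else cfg.lca_probs_background
        lca = str(rng.choice(LCA_CLADES, p=np.asarray(lca_p) / np.sum(lca_p)))
        genes.append(
            Gene(
                id=f"gene{i:04d}",
                symbol=f"Gene{i:04d}",
                span=span,
                biotype=biotype,
                conservation=conservation,
                lca_clade=lca,
            )
        )

    chrom_sizes = {f"chr{c + 1}": cfg.chrom_len for c in range(cfg.n_chroms)}
    target_ids = [genes[i].id for i in sorted(target_idx)]

    # target-gene flank regions (clipped, per chromosome) for planted enrichment
    flanks: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chrom_sizes}
    for i in sorted(target_idx):
        sp = spans[i]
        flanks[sp.chrom].append(
            (max(0, sp.start - cfg.flank_width), min(cfg.chrom_len, sp.end + cfg.flank_width))
        )

    repeats: List[RepeatInstance] = []
    planted_flank = 0
    for fam in sorted(cfg.repeat_rates):
        rate = cfg.repeat_rates[fam]
        fi = info[fam]
        # genome-wide baseline
        for ci in range(cfg.n_chroms):
            chrom = f"chr{ci + 1}"
            n = rng.poisson(rate * cfg.chrom_len)
            for start in sorted(rng.integers(0, cfg.chrom_len - 1, size=n).tolist()):
                repeats.append(_make_instance(chrom, start, fam, fi, cfg.chrom_len, rng))
        # planted extra copies in target flanks for young L1 families
        if fam in YOUNG_L1_FAMILIES and cfg.planted_enrichment_fold > 1:
            extra_rate = (cfg.planted_enrichment_fold - 1) * rate
            for chrom, regions in flanks.items():
                for lo, hi in regions:
                    n = rng.poisson(extra_rate * (hi - lo))
                    for start in sorted(rng.integers(lo, hi - 1, size=n).tolist()) if n else []:
                        repeats.append(
                            _make_instance(chrom, start, fam, fi, cfg.chrom_len, rng)
                        )
                        planted_flank += 1

    # planted upstream LTRs with orientation bias
    upstream_truth = {"target": [0, 0], "background": [0, 0]}  # [sense, antisense]
    ltr_fams = list(LTR_FAMILIES)
    for i, g in enumerate(genes):
        region_len = cfg.upstream_len
        if g.span.strand == "+":
            lo, hi = max(0, g.span.start - region_len), g.span.start
        else:
            lo, hi = g.span.end, min(cfg.chrom_len, g.span.end + region_len)
        if hi - lo < 200:
            continue
        n = rng.poisson(cfg.upstream_ltr_per_kb * (hi - lo) / 1000.0)
        is_target = i in target_idx
        p_sense = cfg.sense_bias if is_target else 0.5
        group = "target" if is_target else "background"
        for _ in range(n):
            fam = str(rng.choice(ltr_fams))
            fi = info[fam]
            length = min(max(80, int(fi.consensus_length * rng.uniform(0.5, 1.0))), hi - lo)
            start = int(rng.integers(lo, hi - length)) if hi - length > lo else lo
            sense = rng.random() < p_sense
            strand = g.span.strand if sense else ("-" if g.span.strand == "+" else "+")
            upstream_truth[group][0 if sense else 1] += 1
            repeats.append(
                RepeatInstance(
                    span=GenomicInterval(g.span.chrom, start, start + length, strand),
                    family=fam,
                    repclass="LTR",
                    divergence=_divergence(fi, rng),
                )
            )

    bundle = AnnotationBundle(
        genes=genes, repeats=repeats, family_info=info, chrom_sizes=chrom_sizes
    )
    truth = {
        "target_gene_ids": target_ids,
        "n_planted_flank_young_l1": planted_flank,
        "upstream_ltr_counts": upstream_truth,
        "young_families": list(YOUNG_L1_FAMILIES),
        "inactive_families": list(INACTIVE_L1_FAMILIES),
    }
    return bundle, truth


def simulate_counts(
    cfg: SimConfig,
    features: Sequence[str],
    depths: Sequence[float] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0),
    n_control: int = 3,
    mean_count: float = 200.0,
) -> Tuple[pd.DataFrame, dict]:
    """Negative-binomial count table with planted fold changes.

    Per-feature base means are lognormal around ``mean_count``; treatment
    samples (the columns after the first ``n_control``) have their means
    multiplied by ``2**planted_log2fc[feature]`` where planted. ``depths``
    scale each sample's library size and are recovered by the size-factor
    estimator. NB draws use the gamma-Poisson mixture with dispersion
    ``nb_dispersion`` (Poisson in the dispersion -> 0 limit).
    """
    rng = cfg.rng(1)
    features = list(features)
    n_samples = len(depths)
    if not (0 < n_control < n_samples):
        raise ValueError("need at least one control and one treatment sample")
    base = rng.lognormal(np.log(mean_count), 1.0, size=len(features))
    lfc = np.array([cfg.planted_log2fc.get(f, 0.0) for f in features])
    cols = [f"ctrl_{i + 1}" for i in range(n_control)] + [
        f"treat_{i + 1}" for i in range(n_samples - n_control)
    ]
    mat = np.empty((len(features), n_samples), dtype=int)
    alpha = cfg.nb_dispersion
    for j, depth in enumerate(depths):
        mu = base * depth
        if j >= n_control:
            mu = mu * np.power(2.0, lfc)
        if alpha < 1e-8:
            mat[:, j] = rng.poisson(mu)
        else:
            lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
            mat[:, j] = rng.poisson(lam)
    counts = pd.DataFrame(mat, index=pd.Index(features, name="feature"), columns=cols)
    truth = {
        "planted": {f: x for f, x in cfg.planted_log2fc.items() if f in features},
        "base_means": dict(zip(features, base.tolist())),
        "condition": ["control"] * n_control + ["treatment"] * (n_samples - n_control),
        "depths": list(depths),
    }
    return counts, truth


def simulate_peaks(
    cfg: SimConfig,
    bundle: AnnotationBundle,
    peak_width: Tuple[int, int] = (300, 800),
    jitter: int = 200,
    spurious_fraction: float = 0.1,
    n_input_peaks: int = 60,
    n_background_marks: int = 100,
    mark_pad: int = 500,
) -> Tuple[dict, dict]:
    """Replicate ChIP peak sets tethered to ERVK/inactive-L1 copies.

    Each tether candidate (an ERVK or inactive-L1 instance) carries a true
    peak with probability ``peak_tether_prob``; replicates see the true peak
    with independent uniform(0, ``jitter``) endpoint noise. A fraction
    ``h3k9me3_overlap_prob`` of true peaks is co-placed with an H3K9me3
    interval padded by ``mark_pad`` (guaranteeing both any-overlap and 80%
    overlap); background marks and per-replicate spurious peaks and
    input-only peaks are added on top.

    Returns ``({"rep1", "rep2", "input", "h3k9me3"}, truth)``.
    """
    rng = cfg.rng(2)
    chrom_sizes = bundle.chrom_sizes
    candidates = [
        r
        for r in bundle.repeats
        if r.family in ERVK_FAMILIES or r.family in INACTIVE_L1_FAMILIES
    ]
    true_peaks: List[GenomicInterval] = []
    marked_flags: List[bool] = []
    marks: List[GenomicInterval] = []
    for r in candidates:
        if rng.random() >= cfg.peak_tether_prob:
            continue
        width = int(rng.integers(*peak_width))
        center = (r.span.start + r.span.end) // 2
        size = chrom_sizes[r.span.chrom]
        start = int(np.clip(center - width // 2, 0, size - width - 1))
        iv = GenomicInterval(r.span.chrom, start, start + width)
        true_peaks.append(iv)
        marked = rng.random() < cfg.h3k9me3_overlap_prob
        marked_flags.append(marked)
        if marked:
            marks.append(
                GenomicInterval(
                    iv.chrom,
                    max(0, iv.start - mark_pad),
                    min(size, iv.end + mark_pad),
                )
            )

    def jittered(iv: GenomicInterval, sample: str) -> Peak:
        if jitter == 0:
            return Peak(span=iv, sample=sample)
        ds = int(rng.integers(0, jitter + 1)) * int(rng.choice([-1, 1]))
        de = int(rng.integers(0, jitter + 1)) * int(rng.choice([-1, 1]))
        size = chrom_sizes[iv.chrom]
        start = int(np.clip(iv.start + ds, 0, size - 2))
        end = int(np.clip(iv.end + de, start + 1, size))
        return Peak(span=GenomicInterval(iv.chrom, start, end), sample=sample)

    def uniform_peaks(n: int, sample: str) -> List[Peak]:
        out = []
        chroms = sorted(chrom_sizes)
        for _ in range(n):
            chrom = str(rng.choice(chroms))
            width = int(rng.integers(*peak_width))
            start = int(rng.integers(0, chrom_sizes[chrom] - width))
            out.append(
                Peak(span=GenomicInterval(chrom, start, start + width), sample=sample)
            )
        return out

    n_spurious = int(round(spurious_fraction * len(true_peaks)))
    rep1 = [jittered(iv, "rep1") for iv in true_peaks] + uniform_peaks(n_spurious, "rep1")
    rep2 = [jittered(iv, "rep2") for iv in true_peaks] + uniform_peaks(n_spurious, "rep2")
    input_peaks = uniform_peaks(n_input_peaks, "input")
    for _ in range(n_background_marks):
        chrom = str(rng.choice(sorted(chrom_sizes)))
        width = int(rng.integers(500, 2000))
        start = int(rng.integers(0, chrom_sizes[chrom] - width))
        marks.append(GenomicInterval(chrom, start, start + width))

    peaks = {"rep1": rep1, "rep2": rep2, "input": input_peaks, "h3k9me3": marks}
    truth = {
        "n_candidates": len(candidates),
        "n_true_peaks": len(true_peaks),
        "true_peaks": true_peaks,
        "marked_fraction": (
            float(np.mean(marked_flags)) if marked_flags else 0.0
        ),
        "n_spurious_per_replicate": n_spurious,
    }
    return peaks, truth
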