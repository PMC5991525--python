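# Methods

`corepeat` reimplements, as a tested library, the genomic side of a
repeat-aware co-repression analysis: given gene and repeat annotations,
count tables, and ChIP peak sets, it asks which retrotransposon families are
derepressed when a silencing factor is removed, which genes are co-repressed
by two factors, whether those genes sit in neighborhoods enriched for young
LINE-1 (L1) elements, whether the LTRs immediately upstream of them are
biased toward the sense orientation, and how a factor's ChIP peaks relate to
repeats and to H3K9me3 heterochromatin. Because the real measurements come
from genome-scale sequencing, the package ships a synthetic-genome generator
that plants every effect it is designed to detect, so all statistics can be
validated against a known truth.

## Coordinates and interval rules

All coordinates are 0-based half-open (BED convention); GTF input is
converted on read. The distance between two intervals is the gap between
their nearest edges — 0 for overlapping *and* for abutting intervals — and
infinite across chromosomes. The radius rule used by every proximity
statistic is: at window `w = 0` a repeat must share at least one base with
the gene span ("intersection"); at `w > 0` a gap of exactly `w` still
counts. Radii are measured from the full gene body (transcript-union span),
not the TSS; repeats partially inside a window count. Upstream regions are
the `L` bases 5' of the gene span on its own strand, clipped at chromosome
edges; a gene with no upstream room is excluded from upstream tallies. An
LTR is *sense* to a gene when the strands agree; unstranded LTRs are
excluded from orientation tables.

## Statistics

**Fisher exact tests.** Every enrichment question is reduced to a 2×2 table
with rows (test set, background) and columns (positive, negative). The
one-sided p is the upper-tail hypergeometric probability of the observed or
greater over-representation in the test group (computed via
`scipy.stats.hypergeom`); the two-sided p uses the minimum-likelihood rule
(sum of all tables no more probable than the observed, the convention of R's
`fisher.test`). Tables with an empty margin return p = 1 with a warning;
underflow is floored at 1e-300. Multiple testing uses Benjamini–Hochberg
step-up (statsmodels).

**Negative-binomial differential test.** Counts are normalized by
median-of-ratios size factors (geometric-mean reference, restricted to
features positive in all samples, factors rescaled to geometric mean 1;
total-count fallback with a warning). The log2 fold change is computed on
group means of normalized counts with a 0.5 pseudocount; ">2-fold" is
strict. The per-feature NB dispersion is estimated by method of moments from
the pooled within-group variance and then *moderated*: the estimates are
sorted by base mean and replaced by a centered rolling mean (window 101),
floored at 0.01. Moderation matters: with 3 vs 3 samples a raw per-feature
estimate has ~4 degrees of freedom of noise and a normal-reference Wald test
becomes badly anti-conservative (empirical type I ≈ 0.12); a rolling
*median* is also biased low because the estimates are right-skewed. With the
mean-trend the Wald z

    z = [ln(μ̂_t + 0.5) − ln(μ̂_c + 0.5)] / sqrt((1/μ̂_t + α̂)/n_t + (1/μ̂_c + α̂)/n_c)

is close to N(0,1) under the null (measured type I 0.04–0.06 across seeds at
the default simulation conditions) while retaining full power for planted
4-fold effects (≥90% recall at padj ≤ 0.05 among 2000 features). The price
is the assumption of a smooth mean–dispersion relationship; features with
genuinely outlying dispersion are tested anti-conservatively. There is no
GLM machinery: exactly two groups, no covariates, no independent filtering,
no outlier replacement. With one sample per group the fold change is
reported and p is NaN.

Repeat families are called *derepressed* when fold > 2 at BH-adjusted
p ≤ 0.05 by default; whether the family-level threshold uses adjusted or raw
p is a config switch (`use_adjusted_for_families`), since either convention
is defensible and they differ only in borderline calls. *Co-repressed*
families/genes are plain set intersections.

**RPKM binding enrichment.** Family-level ChIP enrichment is
RPKM(IP)/RPKM(input) with 0.5 reads added to every family in both samples,
replicates averaged after per-library normalization, selection inclusive at
≥4. Totals must be each library's genome-wide mapped reads, passed
explicitly; column sums of a repeat-only table are incorrect whenever bound
families dominate the IP.

**Peak statistics.** Reproducible peaks are replicate-1 peaks with ≥1 bp
overlap in replicate 2 and no overlap with any input peak; replicate-1
coordinates are kept (counts stay well defined; merging is not attempted).
The clustering fraction is the fraction of peaks whose nearest other peak
lies within 50 kb (edge-gap distance). Mark overlap is reported at two
stringencies: any shared base, or ≥80% of the *peak* covered by the union of
mark intervals (coverage measured relative to the peak, not the mark).
Peak-to-repeat assignment takes the repeat with the largest overlap; exact
ties prefer young over inactive L1 families, then input order. The consensus
coverage profile averages per-position coverage in 20 equal bins normalized
to the profile mean; the 3'/5' ratio is mean coverage of the second half
over the first (a linear ramp gives exactly 3).

## The synthetic study

`simulate_annotation` builds, by default, a 150 Mb genome (5 × 30 Mb)
carrying 500 non-overlapping genes (lengths lognormal around 10 kb) placed
with uniform spacings; 100 of them ("targets") emulate a co-repressed gene
set. Repeats are independent per-family Poisson processes — no nesting or
fragmentation, which the interval statistics do not need — over 20 named
families: five young L1 families (L1Md_F/F2/F3/A/T; ages < 5 Myr, active),
eight inactive L1 families (L1_Rod, L1MB7, L1_Mur1–3, Lx8–10; ages ≥
13 Myr), two ERVK families, two satellites, and three LTR families. Instance
divergence is drawn around `0.75 %/Myr × family age`, so young families
average ~1–3% divergence; L1 lengths are a 30/70 mixture of full-length
(> 5 kb) and truncated copies.

Planted effects, with defaults chosen to match the regime the pipeline is
built for:

- **Flank enrichment:** inside ± 20 kb of target genes, young-L1 density is
  multiplied by 7. The genome is large enough that these flanks are only
  ~3.5% of it; in earlier, smaller drafts the flanks covered a quarter of
  the genome and planted repeats spilled into background genes, a regime the
  emulated study (≈100 targets among ~20k genes) does not have.
- **Upstream LTR orientation:** each gene's 3 kb upstream region receives
  LTR instances at 2/kb; for target genes they are sense with probability
  0.69, otherwise 0.5. With 100 targets this yields ~600 LTRs per group, so
  the sense fraction is estimated to ±0.02 (1σ).
- **Counts:** gamma–Poisson (NB) draws with dispersion 0.1, lognormal base
  means, per-sample depth factors, and planted log2 fold changes applied to
  the treatment group.
- **Peaks:** every ERVK or inactive-L1 instance tethers a true peak
  (300–800 bp) with probability 0.9 (~1800 true peaks at default scale);
  replicates see it with ±≤200 bp endpoint jitter; 34% of true peaks are
  co-placed with an H3K9me3 interval padded by 500 bp (guaranteeing both
  overlap stringencies); 10% spurious peaks per replicate and 60 input-only
  peaks are added, plus 100 background marks.

Everything derives from a single integer seed through independent
`SeedSequence` streams; identical seeds give byte-identical output files.

**What the generator does not emulate:** repeat nesting/fragmentation,
sequence content (no FASTA or reads), mappability and GC biases, expression
correlation between neighboring genes, chromatin-domain structure, and any
dependence between the expression, annotation, and ChIP layers beyond the
planted effects. Passing tests therefore demonstrate that the statistics
recover planted effects under the stated model, not that the model captures
every property of real sequencing data.

## Recovery behavior worth knowing

The enrichment fold reported for a gene set is a ratio of per-gene
*presence* fractions, while the generator plants a *density* fold. Presence
compresses density: with baseline per-gene intensity λ the expected recovery
is (1 − e^(−7λ))/(1 − e^(−λ)) < 7, about 4.5–5.5 at the default λ ≈ 0.05.
This is inherent to 2×2 presence tables, not an estimator defect; the
flank-density ratio, measured directly, recovers 7 ± 2. Recovery tests
assert geometric means over several fixed seeds because a single
hundred-gene draw has Poisson noise comparable to the tolerance widths.

ChIP replicate counts in the binding-enrichment recovery test use NB
dispersion 0.05 — tighter than the expression default, reflecting that IP
duplicates from the same chromatin are technical-scale replicates; at
dispersion 0.1 a true 6-fold family is missed (ratio < 4) about 10% of the
time, which no selection rule can repair.

Null p-values of the Fisher-based enrichment and orientation tests are
*super-uniform* (discrete, conservative); calibration tests bound the
empirical CDF above by the uniform plus binomial noise rather than applying
a two-sided uniformity test.

## Degenerate inputs and tie rules

Empty gene sets and empty peak lists return NaN fractions; an empty
derepressed-family selection is an empty set, not an error. A family age
exactly at a cutoff counts as *not* under it (strict <); conservation
exactly at 0.8 counts as conserved (inclusive ≥, "at least"); fold
thresholds are strict (> 2), the binding-ratio threshold inclusive (≥ 4). A
background with zero positives yields an infinity-flagged fold with the p
still computed. Duplicate feature names in count tables are summed by
default (averaging is available). p-values are floored at 1e-300.

## Configuration

All thresholds live in `PipelineConfig` (YAML-serializable, validated on
construction): fold > 2, FDR 0.05, windows 0/5/20 kb, cluster distance
50 kb, upstream 3 kb, conservation 0.8, binding ratio 4, full-length L1
> 5 kb, age cutoffs 3 and 5 Myr, and the young/inactive family lists.
"Full-length LTR" is length ≥ 90% of the family consensus (configurable);
full-length L1 is the strict > 5 kb size rule.
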