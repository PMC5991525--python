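# corepeat

Repeat-aware co-repression analysis for regulatory genomics.

Heterochromatin factors such as TRIM28 and the HUSH complex silence
retrotransposons, and genes lying near young transposon copies can inherit
that silencing. Analyses of this biology keep answering the same handful of
questions: which repeat families are derepressed when a factor is depleted;
which genes are co-repressed by two factors; whether those genes' 
neighborhoods are enriched for young LINE-1 (L1) elements relative to random
genes; whether the LTRs directly upstream of them sit in the sense
orientation (suggesting promoter capture); and how a factor's ChIP peaks
cluster, overlap H3K9me3, and distribute over young versus inactive L1s.
`corepeat` implements that whole toolkit as a tested Python library with a
CLI, plus a synthetic-genome generator that plants every effect the
statistics are meant to detect — so the entire pipeline can be validated
end-to-end against a known ground truth on a laptop.

## The statistics at its core

Every enrichment question becomes a 2×2 table — rows (gene set, background),
columns (has feature, lacks feature) — tested with the one-sided Fisher
exact test, p = P(X ≥ a) for X hypergeometric on the table margins; multiple
tests are corrected by Benjamini–Hochberg. Proximity uses edge-gap distance
on 0-based half-open intervals: at window w = 0 a repeat must intersect the
gene span, at w > 0 a gap ≤ w counts.

Differential expression of repeat families (and genes) uses a
self-contained negative-binomial Wald test: median-of-ratios size factors,
log2 fold change on pseudocounted group means, method-of-moments dispersion
moderated by a mean-rank rolling trend, and

    z = Δln(μ̂ + 0.5) / sqrt((1/μ̂_t + α̂)/n_t + (1/μ̂_c + α̂)/n_c)

ChIP binding per family is the IP/input RPKM ratio (pseudocount 0.5,
replicates averaged, selection at ≥ 4-fold); peak statistics include
reproducible-peak filtering (in both replicates, absent from input),
nearest-neighbor clustering at 50 kb, H3K9me3 overlap at "any" and "≥80% of
peak" stringencies, and largest-overlap assignment of peaks to young or
inactive L1 families. See `docs/methods.md` for the full model, defaults
and tie rules.

## Worked example

Simulate a study (150 Mb genome, 500 genes of which 100 are "co-repressed"
targets with 7× young-L1 flank enrichment and 69%-sense upstream LTRs), then
run the two central analyses:

```python
from corepeat.simulate import SimConfig, simulate_annotation, simulate_counts, YOUNG_L1_FAMILIES
from corepeat.genesets import GeneSet, pool_gene_sets, random_gene_sets
from corepeat.enrichment import RepeatFilter, enrichment_vs_background, orientation_bias
from corepeat.repeats import derepressed_families

cfg = SimConfig(seed=1)
bundle, truth = simulate_annotation(cfg)
genes_by_id = {g.id: g for g in bundle.genes}
targets = GeneSet("corepressed", tuple(truth["target_gene_ids"]))
background = pool_gene_sets(random_gene_sets(
    bundle.genes, n=100, k=3, seed=8, exclude=targets.gene_ids))

filt = RepeatFilter(families=frozenset(YOUNG_L1_FAMILIES))
for r in enrichment_vs_background(targets, background, genes_by_id,
                                  bundle.repeats, filt):
    print(f"w={r.window:>6}  set {r.set_positive}/{r.set_total}  "
          f"bg {r.bg_positive}/{r.bg_total}  fold={r.fold:.2f}  p={r.p:.2e}")

res = orientation_bias(targets, background, genes_by_id,
                       bundle.repeats, bundle.chrom_sizes)
print(f"sense LTRs upstream: {res['sense_fraction_set']:.1%} vs "
      f"{res['sense_fraction_bg']:.1%} (p={res['p']:.2e})")

counts, ct = simulate_counts(
    SimConfig(seed=2, planted_log2fc={f: 2.8 for f in YOUNG_L1_FAMILIES}),
    sorted(bundle.family_info), mean_count=500.0)
fams, de = derepressed_families(counts, ct["condition"], "control", "kd")
print("derepressed families:", sorted(fams.families))
```

prints

```
w=     0  set 25/100  bg 15/235  fold=3.92  p=4.91e-06
w=  5000  set 46/100  bg 21/235  fold=5.15  p=1.16e-13
w= 20000  set 78/100  bg 51/235  fold=3.59  p=2.95e-22
sense LTRs upstream: 69.4% vs 48.9% (p=4.98e-18)
derepressed families: ['L1Md_A', 'L1Md_F', 'L1Md_F2', 'L1Md_F3', 'L1Md_T']
```

Reading it: target genes are 3.6–5.2× more likely than pooled random genes
to have a young L1 nearby at every window (Fisher one-sided p down to
1e-22); their upstream LTRs are 69% sense versus ~50% in the background
(recovering the planted bias); and exactly the five young L1 families whose
derepression was planted at ~7-fold come out of the NB test at fold > 2,
padj ≤ 0.05. The `fold` column is a ratio of per-gene presence fractions,
which compresses the planted 7× *density* — see `docs/methods.md`.

The same stages are scriptable from the shell:

```bash
corepeat simulate --seed 1 --outdir fixture/
corepeat peaks --rep1 fixture/peaks_rep1.bed --rep2 fixture/peaks_rep2.bed \
         --input fixture/peaks_input.bed --marks fixture/h3k9me3.bed --out repro.bed
corepeat report --seed 1 --outdir report/   # full pipeline + summary.json
```

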