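"""Repeat-proximity enrichment, filters, and the upstream-LTR orientation test."""

import math

import pytest

from corepeat.genome import Gene, GenomicInterval, RepeatInstance, within_radius
from corepeat.genesets import GeneSet, pool_gene_sets, random_gene_sets
from corepeat.enrichment import (
    RepeatFilter,
    enrichment_vs_background,
    fraction_with_any,
    genes_with_repeat,
    l1_array_fraction,
    orientation_bias,
    select_full_length,
)
from corepeat.io import RepeatFamilyInfo
from corepeat.simulate import (
    YOUNG_L1_FAMILIES,
    SimConfig,
    simulate_annotation,
)


def rep(start, end, family="L1Md_T", repclass="LINE", chrom="chr1", strand="+"):
    return RepeatInstance(
        span=GenomicInterval(chrom, start, end, strand), family=family, repclass=repclass
    )


def gene(gid, start, end, chrom="chr1", strand="+"):
    return Gene(id=gid, symbol=gid, span=GenomicInterval(chrom, start, end, strand))


class TestRepeatFilter:
    def test_needs_a_selector(self):
        with pytest.raises(ValueError):
            RepeatFilter()

    def test_min_length_is_strict(self):
        filt = RepeatFilter(classes=frozenset({"LINE"}), min_length=5000)
        assert filt.matches(rep(0, 5001))
        assert not filt.matches(rep(0, 5000))
        assert not filt.matches(rep(0, 4000))

    def test_family_filter(self):
        filt = RepeatFilter(families=frozenset(YOUNG_L1_FAMILIES))
        assert filt.matches(rep(0, 100, family="L1Md_A"))
        assert not filt.matches(rep(0, 100, family="Lx8"))

    def test_full_length_ltr_rule(self):
        info = {"IAPEz": RepeatFamilyInfo("IAPEz", "LTR", 6.0, True, 1000)}
        filt = RepeatFilter(classes=frozenset({"LTR"}), full_length_only=True)
        assert filt.matches(rep(0, 950, family="IAPEz", repclass="LTR"), info)
        assert not filt.matches(rep(0, 500, family="IAPEz", repclass="LTR"), info)

    def test_select_full_length(self):
        reps = [rep(0, 5001), rep(6000, 11000), rep(12000, 13000)]
        filt = RepeatFilter(classes=frozenset({"LINE"}), min_length=5000)
        assert select_full_length(reps, filt) == [reps[0]]


class TestGenesWithRepeat:
    def test_length_filter_excludes_short_l1(self):
        genes = {"g1": gene("g1", 10_000, 20_000)}
        reps = [rep(12_000, 16_000)]  # 4 kb, below the 5 kb bar
        filt = RepeatFilter(classes=frozenset({"LINE"}), min_length=5000)
        n, flags = genes_with_repeat(
            GeneSet("s", ("g1",)), genes, reps, filt, w=20_000
        )
        assert n == 0 and flags["g1"] == 0

    def test_matches_brute_force_oracle(self, small_bundle):
        bundle, _ = small_bundle
        by_id = {g.id: g for g in bundle.genes}
        gs = GeneSet("s", tuple(g.id for g in bundle.genes))
        filt = RepeatFilter(families=frozenset(YOUNG_L1_FAMILIES))
        selected = [r for r in bundle.repeats if r.family in YOUNG_L1_FAMILIES]
        for w in (0, 5_000, 20_000):
            _, flags = genes_with_repeat(gs, by_id, bundle.repeats, filt, w)
            for gid in gs.gene_ids:
                brute = sum(
                    1 for r in selected if within_radius(by_id[gid].span, r.span, w)
                )
                assert flags[gid] == brute


class TestEnrichment:
    def test_identical_set_and_background_is_null(self, small_bundle):
        bundle, _ = small_bundle
        by_id = {g.id: g for g in bundle.genes}
        gs = GeneSet("s", tuple(g.id for g in bundle.genes[:40]))
        bg = GeneSet("b", gs.gene_ids)
        filt = RepeatFilter(families=frozenset(YOUNG_L1_FAMILIES))
        for res in enrichment_vs_background(gs, bg, by_id, bundle.repeats, filt):
            if res.set_positive > 0:
                assert res.fold == pytest.approx(1.0)
            assert res.p >= 0.5

    def test_positives_monotone_over_windows(self, small_bundle):
        bundle, _ = small_bundle
        by_id = {g.id: g for g in bundle.genes}
        gs = GeneSet("s", tuple(g.id for g in bundle.genes[:40]))
        bg = GeneSet("b", tuple(g.id for g in bundle.genes[40:]))
        filt = RepeatFilter(classes=frozenset({"LINE"}))
        res = enrichment_vs_background(gs, bg, by_id, bundle.repeats, filt)
        pos = [r.set_positive for r in res]
        assert pos == sorted(pos)

    def test_zero_background_flagged_infinite(self):
        genes = {
            "s1": gene("s1", 10_000, 12_000),
            "b1": gene("b1", 100_000, 102_000),
        }
        reps = [rep(10_500, 11_000)]
        res = enrichment_vs_background(
            GeneSet("s", ("s1",)), GeneSet("b", ("b1",)), genes, reps,
            RepeatFilter(classes=frozenset({"LINE"})), windows=[0],
        )[0]
        assert res.fold_is_infinite and math.isinf(res.fold)
        assert 0 < res.p <= 1

    def test_fold_scale_free_under_duplication(self, small_bundle):
        bundle, _ = small_bundle
        by_id = dict({g.id: g for g in bundle.genes})
        filt = RepeatFilter(families=frozenset(YOUNG_L1_FAMILIES))
        gs = GeneSet("s", tuple(g.id for g in bundle.genes[:30]))
        bg = GeneSet("b", tuple(g.id for g in bundle.genes[30:]))
        base = enrichment_vs_background(gs, bg, by_id, bundle.repeats, filt, [5_000])[0]
        # duplicate every gene under a new id and every repeat instance
        dup_by_id = dict(by_id)
        for g in bundle.genes:
            dup_by_id[g.id + "_dup"] = Gene(
                id=g.id + "_dup", symbol=g.symbol, span=g.span, biotype=g.biotype
            )
        gs2 = GeneSet("s", gs.gene_ids + tuple(i + "_dup" for i in gs.gene_ids))
        bg2 = GeneSet("b", bg.gene_ids + tuple(i + "_dup" for i in bg.gene_ids))
        doubled = enrichment_vs_background(
            gs2, bg2, dup_by_id, list(bundle.repeats) * 2, filt, [5_000]
        )[0]
        assert doubled.fold == pytest.approx(base.fold)


class TestFractionAndArrays:
    def test_single_filter_reduces_to_presence_fraction(self, small_bundle):
        bundle, _ = small_bundle
        by_id = {g.id: g for g in bundle.genes}
        gs = GeneSet("s", tuple(g.id for g in bundle.genes[:40]))
        filt = RepeatFilter(classes=frozenset({"LINE"}))
        n, _ = genes_with_repeat(gs, by_id, bundle.repeats, filt, 20_000)
        assert fraction_with_any(gs, by_id, bundle.repeats, [filt]) == n / len(gs)

    def test_disjoint_filters_cover_everything(self):
        genes = {"g1": gene("g1", 0, 1000), "g2": gene("g2", 5000, 6000)}
        reps = [rep(100, 300), rep(5100, 5300, family="GSAT_MM", repclass="Satellite")]
        gs = GeneSet("s", ("g1", "g2"))
        filts = [
            RepeatFilter(classes=frozenset({"LINE"})),
            RepeatFilter(classes=frozenset({"Satellite"})),
        ]
        assert fraction_with_any(gs, genes, reps, filts, w=0) == 1.0

    @pytest.mark.parametrize("per_gene,expected", [(1, 0.0), (3, 1.0)])
    def test_array_fraction_extremes(self, per_gene, expected):
        genes = {f"g{i}": gene(f"g{i}", i * 100_000, i * 100_000 + 10_000) for i in range(5)}
        reps = []
        for i in range(5):
            for j in range(per_gene):
                base = i * 100_000 + 1_000 + j * 2_000
                reps.append(rep(base, base + 1_000))
        gs = GeneSet("s", tuple(genes))
        filt = RepeatFilter(classes=frozenset({"LINE"}))
        assert l1_array_fraction(gs, genes, reps, filt) == expected

    def test_array_fraction_against_counting_oracle(self, small_bundle):
        bundle, _ = small_bundle
        by_id = {g.id: g for g in bundle.genes}
        gs = GeneSet("s", tuple(g.id for g in bundle.genes))
        filt = RepeatFilter(families=frozenset(YOUNG_L1_FAMILIES))
        _, counts = genes_with_repeat(gs, by_id, bundle.repeats, filt, 20_000)
        flagged = [c for c in counts.values() if c > 0]
        expected = sum(1 for c in flagged if c >= 2) / len(flagged)
        assert l1_array_fraction(gs, by_id, bundle.repeats, filt) == pytest.approx(expected)


class TestOrientationBias:
    def _setup(self, set_strands, bg_strands):
        genes, ltrs = {}, []
        sizes = {"chr1": 10_000_000}
        for i, strands in enumerate([set_strands, bg_strands]):
            for j, s in enumerate(strands):
                gid = f"{'s' if i == 0 else 'b'}{j}"
                start = (i * 200 + j) * 40_000 + 10_000
                genes[gid] = gene(gid, start, start + 5_000, strand="+")
                ltrs.append(
                    rep(start - 2_000, start - 1_500, family="RLTR10",
                        repclass="LTR", strand=s)
                )
        gs = GeneSet("set", tuple(k for k in genes if k.startswith("s")))
        bg = GeneSet("bg", tuple(k for k in genes if k.startswith("b")))
        return gs, bg, genes, ltrs, sizes

    def test_all_sense_in_both_groups_is_null(self):
        gs, bg, genes, ltrs, sizes = self._setup(["+"] * 10, ["+"] * 10)
        res = orientation_bias(gs, bg, genes, ltrs, sizes)
        assert res["p"] == 1.0

    def test_extreme_split_closed_form(self):
        gs, bg, genes, ltrs, sizes = self._setup(["+"] * 10, ["-"] * 10)
        res = orientation_bias(gs, bg, genes, ltrs, sizes)
        assert res["p"] == pytest.approx(1 / math.comb(20, 10), rel=1e-9)
        assert res["sense_fraction_set"] == 1.0
        assert res["sense_fraction_bg"] == 0.0

    def test_unstranded_ltrs_excluded(self):
        gs, bg, genes, ltrs, sizes = self._setup(["+"] * 5, ["-"] * 5)
        ltrs.append(rep(8_000, 8_400, family="RLTR10", repclass="LTR", strand="."))
        res = orientation_bias(gs, bg, genes, ltrs, sizes)
        assert res["set_sense"] + res["set_antisense"] == 5

    def test_planted_bias_recovered(self):
        cfg = SimConfig(seed=71)
        bundle, truth = simulate_annotation(cfg)
        by_id = {g.id: g for g in bundle.genes}
        gs = GeneSet("targets", tuple(truth["target_gene_ids"]))
        bg = pool_gene_sets(
            random_gene_sets(bundle.genes, n=100, k=3, seed=4, exclude=gs.gene_ids)
        )
        res = orientation_bias(gs, bg, by_id, bundle.repeats, bundle.chrom_sizes)
        assert res["set_sense"] + res["set_antisense"] >= 300
        assert res["sense_fraction_set"] == pytest.approx(0.69, abs=0.05)
        assert res["p"] < 0.05
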