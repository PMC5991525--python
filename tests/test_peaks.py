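"""Peak statistics: reproducibility, clustering, mark overlap, assignment, binding."""

import math

import numpy as np
import pandas as pd
import pytest

from corepeat.genome import GenomicInterval, Peak, RepeatInstance
from corepeat.genesets import GeneSet
from corepeat.peaks import (
    assign_peaks,
    binding_enrichment,
    cluster_fraction,
    consensus_profile,
    flanking_binding_fraction,
    mark_overlap,
    reproducible_peaks,
)
from corepeat.simulate import SimConfig, simulate_counts
from conftest import brute_overlap_length, random_intervals


def peak(start, end, chrom="chr1", sample="rep1"):
    return Peak(span=GenomicInterval(chrom, start, end), sample=sample)


def rep(start, end, family="Lx8", repclass="LINE", chrom="chr1"):
    return RepeatInstance(
        span=GenomicInterval(chrom, start, end, "+"), family=family, repclass=repclass
    )


class TestReproduciblePeaks:
    def test_kept_when_in_both_replicates(self):
        out = reproducible_peaks([peak(0, 100)], [peak(50, 150, sample="rep2")], [])
        assert [p.span for p in out] == [GenomicInterval("chr1", 0, 100)]

    def test_removed_when_in_input(self):
        out = reproducible_peaks(
            [peak(0, 100)], [peak(50, 150, sample="rep2")], [peak(90, 200, sample="ti")]
        )
        assert out == []

    def test_empty_replicate_warns(self):
        with pytest.warns(UserWarning):
            assert reproducible_peaks([], [peak(0, 10)], []) == []

    def test_matches_brute_force_triple_overlap(self):
        rng = np.random.default_rng(81)
        r1 = [Peak(span=s, sample="rep1") for s in random_intervals(rng, 120)]
        r2 = [Peak(span=s, sample="rep2") for s in random_intervals(rng, 120)]
        ti = [Peak(span=s, sample="ti") for s in random_intervals(rng, 40)]
        out = reproducible_peaks(r1, r2, ti)
        brute = [
            p
            for p in r1
            if any(p.span.overlaps(q.span) for q in r2)
            and not any(p.span.overlaps(q.span) for q in ti)
        ]
        assert out == brute

    def test_output_subset_of_rep1_and_disjoint_from_input(self):
        rng = np.random.default_rng(82)
        r1 = [Peak(span=s, sample="rep1") for s in random_intervals(rng, 100)]
        r2 = [Peak(span=s, sample="rep2") for s in random_intervals(rng, 100)]
        ti = [Peak(span=s, sample="ti") for s in random_intervals(rng, 30)]
        out = reproducible_peaks(r1, r2, ti)
        assert set(id(p) for p in out) <= set(id(p) for p in r1)
        for p in out:
            assert not any(p.span.overlaps(q.span) for q in ti)


class TestClusterFraction:
    def test_simple_example(self):
        peaks = [peak(0, 1000), peak(30_000, 31_000), peak(200_000, 201_000)]
        assert cluster_fraction(peaks, d=50_000) == pytest.approx(2 / 3)

    def test_single_peak(self):
        assert cluster_fraction([peak(0, 1000)]) == 0.0

    def test_translation_and_relabel_invariance(self):
        rng = np.random.default_rng(83)
        starts = np.sort(rng.integers(0, 5_000_000, size=200))
        peaks_a = [peak(int(s), int(s) + 500) for s in starts]
        base = cluster_fraction(peaks_a, d=40_000)
        shifted = [peak(int(s) + 1_000_000, int(s) + 1_000_500, chrom="chrX") for s in starts]
        assert cluster_fraction(shifted, d=40_000) == base

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(84)
        ivs = random_intervals(rng, 150, max_pos=200_000, max_len=800)
        peaks = [Peak(span=s) for s in ivs]
        d = 3_000
        frac = cluster_fraction(peaks, d=d)
        from corepeat.genome import interval_distance

        brute = np.mean(
            [
                any(
                    interval_distance(p.span, q.span) <= d
                    for q in peaks
                    if q is not p
                )
                for p in peaks
            ]
        )
        assert frac == pytest.approx(brute)

    def test_poisson_analytic_limit(self):
        # homogeneous Poisson peaks: P(neighbour within d) = 1 - exp(-2 lambda d)
        rng = np.random.default_rng(85)
        lam, length, d = 1e-5, 50_000_000, 30_000
        starts = np.sort(rng.integers(0, length, size=rng.poisson(lam * length)))
        peaks = [peak(int(s), int(s) + 200) for s in starts]
        expected = 1 - math.exp(-2 * lam * d)
        assert cluster_fraction(peaks, d=d) == pytest.approx(expected, abs=0.03)


class TestMarkOverlap:
    def test_any_vs_fractional(self):
        peaks = [peak(0, 1000)]
        marks = [GenomicInterval("chr1", 900, 2000)]
        assert mark_overlap(peaks, marks, "any")[0] == 1.0
        assert mark_overlap(peaks, marks, "frac", 0.8)[0] == 0.0  # only 10% covered

    def test_identical_interval_true_in_both_modes(self):
        peaks = [peak(100, 600)]
        marks = [GenomicInterval("chr1", 100, 600)]
        assert mark_overlap(peaks, marks, "any")[0] == 1.0
        assert mark_overlap(peaks, marks, "frac", 0.8)[0] == 1.0

    def test_union_coverage_across_split_marks(self):
        peaks = [peak(0, 1000)]
        marks = [GenomicInterval("chr1", 0, 450), GenomicInterval("chr1", 500, 950)]
        # 900 of 1000 bases covered by the union
        assert mark_overlap(peaks, marks, "frac", 0.85)[0] == 1.0
        assert mark_overlap(peaks, marks, "frac", 0.95)[0] == 0.0

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(86)
        peaks = [Peak(span=s) for s in random_intervals(rng, 60, max_pos=5_000, max_len=300)]
        marks = random_intervals(rng, 40, max_pos=5_000, max_len=300)
        _, flags_any = mark_overlap(peaks, marks, "any")
        _, flags_frac = mark_overlap(peaks, marks, "frac", 0.8)
        for p, fa, ff in zip(peaks, flags_any, flags_frac):
            covered = len(
                set(range(p.span.start, p.span.end))
                & set().union(*(range(m.start, m.end) for m in marks))
            )
            assert fa == (covered > 0)
            assert ff == (covered / p.span.length >= 0.8)

    def test_any_dominates_fractional(self):
        rng = np.random.default_rng(87)
        peaks = [Peak(span=s) for s in random_intervals(rng, 100)]
        marks = random_intervals(rng, 50)
        assert mark_overlap(peaks, marks, "any")[0] >= mark_overlap(peaks, marks, "frac", 0.8)[0]


class TestAssignPeaks:
    YOUNG = ["L1Md_T", "L1Md_A"]
    INACTIVE = ["Lx8", "L1_Rod"]

    def test_young_assignment(self):
        reps = [rep(0, 6000, family="L1Md_T")]
        _, summary = assign_peaks([peak(100, 500)], reps, self.YOUNG, self.INACTIVE)
        assert summary["young_L1"] == 1

    def test_no_overlap(self):
        _, summary = assign_peaks([peak(100, 500)], [rep(10_000, 16_000)], self.YOUNG, self.INACTIVE)
        assert summary["no_repeat"] == 1

    def test_largest_overlap_wins(self):
        # inactive Lx8 overlaps 600 bp, young L1Md_A only 300 bp
        reps = [rep(0, 600, family="Lx8"), rep(700, 1000, family="L1Md_A")]
        assignments, summary = assign_peaks([peak(0, 1000)], reps, self.YOUNG, self.INACTIVE)
        assert summary["inactive_L1"] == 1
        assert assignments[0].repeat.family == "Lx8"

    def test_equal_overlap_prefers_young(self):
        reps = [rep(0, 300, family="Lx8"), rep(700, 1000, family="L1Md_A")]
        _, summary = assign_peaks([peak(0, 1000)], reps, self.YOUNG, self.INACTIVE)
        assert summary["young_L1"] == 1

    def test_overlap_lengths_match_per_base_oracle(self):
        rng = np.random.default_rng(88)
        reps = [
            RepeatInstance(span=s, family="Lx8", repclass="LINE")
            for s in random_intervals(rng, 50, max_pos=4_000, max_len=200)
        ]
        peaks = [Peak(span=s) for s in random_intervals(rng, 50, max_pos=4_000, max_len=200)]
        assignments, _ = assign_peaks(peaks, reps, self.YOUNG, self.INACTIVE)
        for a in assignments:
            if a.repeat is None:
                assert all(brute_overlap_length(a.peak.span, r.span) == 0 for r in reps)
            else:
                best = max(brute_overlap_length(a.peak.span, r.span) for r in reps)
                assert brute_overlap_length(a.peak.span, a.repeat.span) == best


class TestBindingEnrichment:
    def _tables(self, ip, ti, lengths=None):
        fams = list(ip)
        ipc = pd.DataFrame({"ip1": pd.Series(ip), "ip2": pd.Series(ip)})
        tic = pd.DataFrame({"ti1": pd.Series(ti), "ti2": pd.Series(ti)})
        lengths = pd.Series(lengths or {f: 1000 for f in fams})
        return ipc, tic, lengths

    def test_fourfold_threshold_inclusive(self):
        # selection is ratio >= 4 on the pseudocounted RPKM ratio; "f" sits a
        # hair above the boundary, "g" a hair below, "h" far below
        ipc, tic, lengths = self._tables(
            {"f": 802, "g": 800, "h": 200}, {"f": 200, "g": 200, "h": 200}
        )
        out = binding_enrichment(
            ipc, tic, lengths,
            total_mapped={c: 1000 for c in ["ip1", "ip2", "ti1", "ti2"]},
        )
        assert out["ratio"].to_numpy() == pytest.approx([4.0, 4.0, 1.0], rel=5e-3)
        assert (out["selected"] == (out["ratio"] >= 4.0)).all()
        assert bool(out.loc["f", "selected"]) and not bool(out.loc["g", "selected"])

    def test_equal_samples_ratio_one(self):
        ipc, tic, lengths = self._tables({"f": 500, "g": 100}, {"f": 500, "g": 100})
        out = binding_enrichment(ipc, tic, lengths)
        assert out["ratio"].to_numpy() == pytest.approx([1.0, 1.0])

    def test_depth_scaling_invariance(self):
        ipc, tic, lengths = self._tables({"f": 640, "g": 100}, {"f": 80, "g": 100})
        base = binding_enrichment(ipc, tic, lengths)["ratio"]
        scaled = binding_enrichment(ipc * 10, tic * 10, lengths)["ratio"]
        assert scaled.to_numpy() == pytest.approx(base.to_numpy(), rel=0.05)

    def test_planted_sixfold_families_recovered(self):
        # 22 tethered families at true 6-fold among 80, at 1e6 mapped reads
        tethered = [f"T{i}" for i in range(22)]
        others = [f"N{i}" for i in range(58)]
        cfg = SimConfig(
            seed=89, nb_dispersion=0.05,
            planted_log2fc={f: math.log2(6.0) for f in tethered},
        )
        counts, truth = simulate_counts(
            cfg, tethered + others, depths=(1.0,) * 4, n_control=2, mean_count=500.0
        )
        lengths = pd.Series({f: 5000 for f in tethered + others})
        out = binding_enrichment(
            counts[["treat_1", "treat_2"]], counts[["ctrl_1", "ctrl_2"]], lengths,
            total_mapped={c: 1e6 for c in counts.columns},
        )
        selected = set(out.index[out["selected"]])
        assert len(selected & set(tethered)) >= 20
        assert len(selected - set(tethered)) <= 2


class TestFlankingBinding:
    def test_extremes(self):
        genes = {
            "g1": __import__("corepeat.genome", fromlist=["Gene"]).Gene(
                id="g1", symbol="g1", span=GenomicInterval("chr1", 50_000, 60_000, "+")
            )
        }
        gs = GeneSet("s", ("g1",))
        near = [rep(52_000, 58_000, family="Lx8"), rep(65_000, 70_000, family="IAPEz", repclass="LTR")]
        far = [rep(2_000_000, 2_006_000, family="Lx8")]
        res_near = flanking_binding_fraction(gs, genes, near, ["Lx8"], w=20_000)
        assert res_near["bound_inactive_L1"] == 1.0 and res_near["ERVK"] == 1.0
        res_far = flanking_binding_fraction(gs, genes, far, ["Lx8"], w=20_000)
        assert res_far["bound_inactive_L1"] == 0.0 and res_far["ERVK"] == 0.0


class TestConsensusProfile:
    def test_uniform_coverage(self):
        bins, ratio = consensus_profile(np.ones(1000))
        assert bins == pytest.approx(np.ones(20))
        assert ratio == 1.0

    def test_second_half_only(self):
        cov = np.concatenate([np.zeros(500), np.full(500, 4.0)])
        bins, ratio = consensus_profile(cov)
        assert math.isinf(ratio)
        assert bins[:10] == pytest.approx(np.zeros(10))
        assert bins[10:] == pytest.approx(np.full(10, 2.0))

    def test_linear_ramp_ratio_exactly_three(self):
        cov = 2.0 * np.arange(1000) + 1.0
        _, ratio = consensus_profile(cov)
        assert ratio == 3.0
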