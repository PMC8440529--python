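"""Gain/loss calls, GII, WGD permutation test, CNV clonality and Jaccard ITH."""

import itertools
import math

import numpy as np
import pytest

from mrith.cnv import (
    bin_events,
    call_gain_loss,
    classify_cnv_clonality,
    cnv_ith,
    detect_wgd,
    genome_instability_index,
    jaccard_distance,
    call_events,
)
from mrith.core_io import AUTOSOME_BP

from conftest import make_segment


class TestGainLoss:
    def test_single_gain_against_diploid(self):
        seg = make_segment(total_cn=3.0, major_cn=2, minor_cn=1)
        assert call_gain_loss(seg, ploidy=2.0) == "gain"

    def test_neutral(self):
        assert call_gain_loss(make_segment(), ploidy=2.0) == "neutral"

    def test_loss(self):
        seg = make_segment(total_cn=1.0, major_cn=1, minor_cn=0)
        # log2(1/2) = -1 < log2(1.5/2) = -0.415
        assert call_gain_loss(seg, ploidy=2.0) == "loss"

    def test_thresholds_are_ploidy_relative(self):
        seg = make_segment(total_cn=3.0, major_cn=2, minor_cn=1)
        assert call_gain_loss(seg, ploidy=4.0) == "neutral"
        # exactly at the loss boundary: not a loss (strict <)
        seg2 = make_segment(total_cn=3.0, major_cn=2, minor_cn=1)
        assert call_gain_loss(seg2, ploidy=4.0) != "loss"

    def test_zero_total_is_loss(self):
        seg = make_segment(total_cn=0.0, major_cn=0, minor_cn=0)
        assert call_gain_loss(seg, ploidy=2.0) == "loss"


class TestGii:
    def test_no_events(self):
        assert genome_instability_index([]) == 0.0

    def test_whole_genome_gained(self):
        segs = []
        from mrith.core_io import AUTOSOMES, CONTIGS

        for c in AUTOSOMES:
            segs.append(
                make_segment(chrom=c, start=1, end=CONTIGS[c], total_cn=4.0,
                             major_cn=3, minor_cn=1)
            )
        events = call_events(segs, ploidy=2.0)
        assert genome_instability_index(events) == pytest.approx(1.0)

    def test_arithmetic(self):
        segs = [
            make_segment(chrom="1", start=1, end=150_000_000, total_cn=4.0,
                         major_cn=3, minor_cn=1),
            make_segment(chrom="2", start=1, end=150_000_000, total_cn=1.0,
                         major_cn=1, minor_cn=0),
        ]
        events = call_events(segs, ploidy=2.0)
        gii = genome_instability_index(events, genome_size_bp=3_000_000_000)
        assert gii == pytest.approx(0.1, rel=1e-6)


def _uniform_genome(major, minor, n_chroms=22):
    from mrith.core_io import AUTOSOMES, CONTIGS

    return [
        make_segment(chrom=c, start=1, end=CONTIGS[c],
                     total_cn=float(major + minor), major_cn=major, minor_cn=minor)
        for c in AUTOSOMES[:n_chroms]
    ]


class TestWgd:
    def test_fully_doubled_genome_called(self):
        res = detect_wgd(_uniform_genome(2, 2), n_sim=200, seed=0)
        assert res.observed_statistic == pytest.approx(1.0)
        assert res.ploidy_class == "tetraploid"
        assert res.is_wgd

    def test_diploid_genome_not_called(self):
        res = detect_wgd(_uniform_genome(1, 1), n_sim=200, seed=0)
        assert res.observed_statistic == 0.0
        assert not res.is_wgd

    def test_no_autosomes_undefined(self):
        seg = make_segment(chrom="X", start=1, end=1000)
        assert detect_wgd([seg], n_sim=10, seed=0) is None

    def test_p_matches_bruteforce_permutation_oracle(self, rng):
        """Monte-Carlo p agrees with an independent permutation simulation."""
        from mrith.core_io import AUTOSOMES, CONTIGS

        segs = []
        majors = [2, 2, 2, 1, 1, 2, 1, 2, 2, 1]
        for i, c in enumerate(AUTOSOMES[:10]):
            m = majors[i]
            segs.append(
                make_segment(chrom=c, start=1, end=CONTIGS[c],
                             total_cn=float(m + 1), major_cn=m, minor_cn=1)
            )
        res = detect_wgd(segs, n_sim=2000, seed=123)

        lengths = np.array([s.length for s in segs], dtype=float)
        doubled = np.array([s.major_cn >= 2 for s in segs], dtype=float)
        genome = lengths.sum()
        observed = float(lengths @ doubled / genome)
        oracle_rng = np.random.default_rng(999)
        hits = 0
        n_oracle = 4000
        for _ in range(n_oracle):
            stat = float(lengths @ oracle_rng.permutation(doubled) / genome)
            if stat >= observed - 1e-12:
                hits += 1
        p_oracle = (1 + hits) / (n_oracle + 1)
        se = math.sqrt(p_oracle * (1 - p_oracle) * (1 / 2000 + 1 / n_oracle))
        assert abs(res.p_value - p_oracle) <= 4 * se + 1e-3

    def test_deterministic_given_seed(self):
        segs = _uniform_genome(2, 1)
        r1 = detect_wgd(segs, n_sim=500, seed=7)
        r2 = detect_wgd(segs, n_sim=500, seed=7)
        assert r1 == r2


class TestCnvClonality:
    def test_gain_everywhere_clonal(self):
        ev = {"R1": {("1", 0, "gain")}, "R2": {("1", 0, "gain")}, "R3": {("1", 0, "gain")}}
        out = classify_cnv_clonality(ev)
        assert out[("1", 0, "gain")] == "clonal"

    def test_gain_in_one_region_subclonal(self):
        ev = {"R1": {("1", 0, "gain")}, "R2": set(), "R3": set()}
        assert classify_cnv_clonality(ev)[("1", 0, "gain")] == "subclonal"

    def test_loss_with_loh_elsewhere_is_clonal(self):
        ev = {
            "R1": {("5", 2, "loss")},
            "R2": {("5", 2, "loss")},
            "R3": set(),
        }
        loh = {"R1": set(), "R2": set(), "R3": {("5", 2)}}
        assert classify_cnv_clonality(ev, loh)[("5", 2, "loss")] == "clonal"

    def test_single_region_rejected(self):
        with pytest.raises(ValueError):
            classify_cnv_clonality({"R1": set()})


class TestCnvIth:
    def test_identical_sets_zero(self):
        s = {("1", 0, "gain"), ("2", 3, "loss")}
        assert cnv_ith({"R1": set(s), "R2": set(s), "R3": set(s)}) == 0.0

    def test_pairwise_disjoint_one(self):
        ev = {"R1": {("1", 0, "gain")}, "R2": {("2", 0, "gain")}, "R3": {("3", 0, "gain")}}
        assert cnv_ith(ev) == 1.0

    def test_hand_enumeration(self):
        a, b, c = "a", "b", "c"
        ev = {"R1": {a, b}, "R2": {b, c}, "R3": {a, b}}
        # d(R1,R2)=2/3, d(R1,R3)=0, d(R2,R3)=2/3 -> mean 4/9
        assert cnv_ith(ev) == pytest.approx(4 / 9)

    def test_single_region_missing(self):
        assert cnv_ith({"R1": {1}}) is None

    def test_empty_pairs_contribute_zero(self):
        assert cnv_ith({"R1": set(), "R2": set(), "R3": {1}}) == pytest.approx(2 / 3)

    def test_invariant_under_relabeling(self, rng):
        universe = list(range(6))
        sets = {
            f"R{i}": set(rng.choice(universe, size=rng.integers(0, 5), replace=False).tolist())
            for i in range(1, 4)
        }
        base = cnv_ith(sets)
        relabeled = {"A": sets["R3"], "B": sets["R1"], "C": sets["R2"]}
        assert cnv_ith(relabeled) == pytest.approx(base)

    def test_exhaustive_small_systems_match_oracle(self):
        """All 3-region systems over a 2-element universe vs itertools oracle."""
        universe = ["x", "y"]
        subsets = [frozenset(s) for r in range(3) for s in itertools.combinations(universe, r)]
        for sa, sb, sc in itertools.product(subsets, repeat=3):
            got = cnv_ith({"R1": set(sa), "R2": set(sb), "R3": set(sc)})
            pairs = [(sa, sb), (sa, sc), (sb, sc)]
            dists = [
                0.0 if not (p | q) else 1 - len(p & q) / len(p | q)
                for p, q in pairs
            ]
            assert got == pytest.approx(sum(dists) / 3)


class TestBinEvents:
    def test_segment_spanning_bins(self):
        seg = make_segment(start=5_000_000, end=25_000_000, total_cn=3.0,
                           major_cn=2, minor_cn=1)
        events, loh = bin_events([seg], ploidy=2.0, bin_size=10_000_000)
        assert events == {("1", 0, "gain"), ("1", 1, "gain"), ("1", 2, "gain")}
        assert loh == set()

    def test_loh_bins_tracked(self):
        seg = make_segment(start=1, end=9_999_999, total_cn=2.0,
                           major_cn=2, minor_cn=0)
        events, loh = bin_events([seg], ploidy=2.0)
        assert loh == {("1", 0)}
        assert events == set()  # copy-neutral LOH is not a gain or loss
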