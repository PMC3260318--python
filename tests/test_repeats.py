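"""Repeat finders against brute-force oracles and planted truth."""

import numpy as np
import pytest

import mtstruct as M
from mtstruct._seq import revcomp, seq_to_array
from mtstruct.model import ChromosomeSeq, GenomeModel, RepeatCopy, RepeatPair
from mtstruct.repeats import per_base_match_counts


# ---------------------------------------------------------------------------
# Independent oracle: shift-and-run enumeration of maximal exact pairs on a
# single circular chromosome. O(n^2) but entirely unrelated to the
# seed-and-extend path it checks.
# ---------------------------------------------------------------------------

def _circular_runs(eq: np.ndarray):
    """Maximal runs of True on a circular boolean vector (never all-True)."""
    n = len(eq)
    idx = np.nonzero(~eq)[0]
    runs = []
    for a, b in zip(idx, np.roll(idx, -1)):
        start = (a + 1) % n
        ln = (b - a - 1) % n
        if ln > 0:
            runs.append((start, ln))
    return runs


def exact_pairs_oracle(seq: str, min_len: int) -> set:
    n = len(seq)
    arr = seq_to_array(seq)
    rc = seq_to_array(revcomp(seq))
    found = set()

    def canonical(i1, l1, i2, l2, inverted):
        e1 = (i1 + l1) % n or n
        e2 = (i2 + l2) % n or n
        a, b = sorted([(i1, e1), (i2, e2)])
        if a == b and inverted:
            return None  # palindromic self-interval
        if a == b:
            return None
        sa = "+"
        sb = "-" if inverted else "+"
        return (("chr1", a[0], a[1], sa), ("chr1", b[0], b[1], sb), l1)

    for d in range(1, n):
        eq = arr == np.roll(arr, -d)
        if eq.all():
            continue
        for start, ln in _circular_runs(eq):
            if ln < min_len:
                continue
            key = canonical(start, ln, (start + d) % n, ln, False)
            if key:
                found.add(key)
    for d in range(n):
        eq = arr == np.roll(rc, -d)
        if eq.all():
            continue
        for start, ln in _circular_runs(eq):
            if ln < min_len:
                continue
            j = (start + d) % n  # start in RC coordinates
            ref_start = (n - (j + ln)) % n
            key = canonical(start, ln, ref_start, ln, True)
            if key:
                found.add(key)
    return found


def catalog_keys(catalog) -> set:
    return {
        (
            (p.copy_a.chrom, p.copy_a.start, p.copy_a.end, p.copy_a.strand),
            (p.copy_b.chrom, p.copy_b.start, p.copy_b.end, p.copy_b.strand),
            p.aligned_length,
        )
        for p in catalog
    }


class TestFindExactRepeats:
    def test_smallest_tandem_duplication_linear(self):
        g = GenomeModel({"chr1": ChromosomeSeq("chr1", "ACGTACGT", circular=False)})
        cat = M.find_exact_repeats(g, 4)
        assert len(cat) == 1
        p = cat.pairs[0]
        assert (p.copy_a.start, p.copy_a.end) == (0, 4)
        assert (p.copy_b.start, p.copy_b.end) == (4, 8)
        assert p.identity == 100.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        from mtstruct._seq import random_seq

        seq = random_seq(np.random.default_rng(seed), 2_000)
        g = GenomeModel({"chr1": ChromosomeSeq("chr1", seq)})
        got = catalog_keys(M.find_exact_repeats(g, 8))
        want = exact_pairs_oracle(seq, 8)
        assert got == want

    def test_planted_boundaries_exact(self):
        plan = M.RepeatFamilyPlan(
            "f", 2, 400, placements=[("chr1", 3_000), ("chr1", 12_000)]
        )
        g = M.generate_genome(1, [20_000], repeat_plan=[plan], seed=4)
        cat = M.find_exact_repeats(g, 30)
        big = [p for p in cat if p.aligned_length >= 400]
        assert len(big) == 1
        # maximal match contains the planted interval, extended by at most a
        # couple of chance-matching flank bases
        p = big[0]
        assert p.copy_a.start <= 3_000 and p.copy_a.end >= 3_400
        assert p.aligned_length <= 410

    def test_cross_chromosome_and_inverted(self):
        plans = [
            M.RepeatFamilyPlan(
                "x", 2, 120, placements=[("chr1", 1_000), ("chr2", 4_000)]
            ),
            M.RepeatFamilyPlan(
                "inv", 2, 90, orientation="inverted",
                placements=[("chr1", 5_000), ("chr1", 8_000)],
            ),
        ]
        g = M.generate_genome(2, [10_000, 8_000], repeat_plan=plans, seed=12)
        cat = M.find_exact_repeats(g, 30)
        cross = [p for p in cat if p.cross_chromosome]
        inv = [p for p in cat if p.inverted]
        assert len(cross) == 1 and cross[0].aligned_length >= 120
        assert len(inv) == 1 and inv[0].aligned_length >= 90

    def test_empty_and_repeat_free(self):
        g = M.generate_genome(1, [5_000], seed=1)
        assert len(M.find_exact_repeats(g, 25)) == 0
        with pytest.raises(ValueError):
            M.find_exact_repeats(g, 1)


class TestFindRepeatPairs:
    def test_perfect_30bp_scores_exactly_30(self):
        g = M.plant_duplicate_pair(30, 10_000, 2_000, 6_000, seed=3)
        cat = M.find_repeat_pairs(g)
        assert len(cat) == 1
        p = cat.pairs[0]
        assert p.raw_score == 30
        assert p.aligned_length == 30
        assert p.identity == 100.0

    def test_detection_floor_is_30bp(self):
        """Guard-flanked perfect duplicates: 29 bp invisible, 30 bp reported."""
        for length, expected in ((29, 0), (30, 1)):
            g = M.plant_duplicate_pair(length, 10_000, 2_000, 6_000, seed=5)
            hits = [
                p
                for p in M.find_repeat_pairs(g)
                if {p.copy_a.start, p.copy_b.start} == {2_000, 6_000}
            ]
            assert len(hits) == expected

    def test_planted_identity_recovered(self):
        plan = M.RepeatFamilyPlan(
            "f", 2, 100, identity=0.96, placements=[("chr1", 2_000), ("chr1", 6_000)]
        )
        hits = []
        for seed in (5, 15, 25, 35):
            g = M.generate_genome(1, [10_000], repeat_plan=[plan], seed=seed)
            cat = M.find_repeat_pairs(g)
            assert len(cat) == 1
            hits.append(cat.pairs[0].identity)
        # local alignment may trim terminal mismatches, which can only push
        # the measured identity up, never down below planted - 1 point
        assert all(95.0 <= h <= 100.0 for h in hits)
        assert np.mean(hits) == pytest.approx(96.0, abs=1.5)

    def test_determinism(self):
        plan = M.RepeatFamilyPlan(
            "f", 3, 300, identity=0.97,
            placements=[("chr1", 1_000), ("chr1", 5_000), ("chr1", 9_000)],
        )
        g = M.generate_genome(1, [15_000], repeat_plan=[plan], seed=2)
        assert catalog_keys(M.find_repeat_pairs(g)) == catalog_keys(
            M.find_repeat_pairs(g)
        )

    def test_four_copies_give_six_pairs(self):
        plan = M.RepeatFamilyPlan(
            "f", 4, 500,
            placements=[("chr1", i) for i in (2_000, 8_000, 14_000, 20_000)],
        )
        g = M.generate_genome(1, [26_000], repeat_plan=[plan], seed=8)
        assert len(M.find_repeat_pairs(g)) == 6
        assert len(M.find_exact_repeats(g, 30)) == 6

    def test_exact_pairs_subsumed_by_scored_pairs(self):
        plan = M.RepeatFamilyPlan(
            "f", 2, 250, placements=[("chr1", 2_000), ("chr1", 8_000)]
        )
        g = M.generate_genome(1, [14_000], repeat_plan=[plan], seed=10)
        exact = [p for p in M.find_exact_repeats(g, 30)]
        scored = list(M.find_repeat_pairs(g))
        for e in exact:
            cover = [
                s
                for s in scored
                if s.copy_a.chrom == e.copy_a.chrom
                and s.copy_a.start <= e.copy_a.start
                and s.copy_a.end >= e.copy_a.end
                and s.identity == 100.0
            ]
            assert cover, f"exact pair {e} not covered"

    def test_word_size_larger_than_genome(self):
        g = GenomeModel({"chr1": ChromosomeSeq("chr1", "ACGTAC", circular=False)})
        assert len(M.find_repeat_pairs(g)) == 0


class TestCoverageAndDepth:
    def test_repeat_free_genome(self):
        g = M.generate_genome(1, [8_000], seed=1)
        cat = M.find_exact_repeats(g, 30)
        assert M.repeat_coverage(g, cat).fraction == 0.0
        curve = M.repeat_depth_curve(g, cat)
        assert (curve["cumulative_fraction"] == 1.0).all()

    def test_two_disjoint_kb_copies_cover_20_percent(self):
        g = M.plant_duplicate_pair(1_000, 10_000, 1_000, 5_000, seed=2)
        cat = M.find_exact_repeats(g, 30)
        cov = M.repeat_coverage(g, cat, min_len=100)
        assert cov.fraction == pytest.approx(0.20, abs=0.002)

    def test_four_copy_block_yintercept(self):
        plan = M.RepeatFamilyPlan(
            "f", 4, 1_000,
            placements=[("chr1", i) for i in (1_000, 6_000, 11_000, 16_000)],
        )
        g = M.generate_genome(1, [20_000], repeat_plan=[plan], seed=3)
        cat = M.find_exact_repeats(g, 200)
        curve = M.repeat_depth_curve(g, cat)
        assert curve["cumulative_fraction"].iloc[0] == pytest.approx(0.80, abs=0.005)
        assert curve["cumulative_fraction"].iloc[-1] == 1.0
        assert curve["cumulative_fraction"].is_monotonic_increasing

    def test_per_base_counts_match_interval_membership_oracle(self):
        plan = M.RepeatFamilyPlan(
            "f", 3, 600, placements=[("chr1", 500), ("chr1", 4_000), ("chr1", 9_000)]
        )
        g = M.generate_genome(1, [14_000], repeat_plan=[plan], seed=6)
        cat = M.find_exact_repeats(g, 200)
        counts = per_base_match_counts(g, cat)["chr1"]
        oracle = np.zeros(14_000, dtype=int)
        for p in cat:
            for c in (p.copy_a, p.copy_b):
                if c.end > c.start:
                    oracle[c.start : c.end] += 1
                else:
                    oracle[c.start :] += 1
                    oracle[: c.end] += 1
        assert (counts == oracle).all()

    def test_coverage_monotone_in_thresholds(self):
        plan = M.RepeatFamilyPlan(
            "f", 2, 400, identity=0.96, placements=[("chr1", 1_000), ("chr1", 6_000)]
        )
        g = M.generate_genome(1, [12_000], repeat_plan=[plan], seed=7)
        cat = M.find_repeat_pairs(g)
        f = [
            M.repeat_coverage(g, cat, min_len=l, min_identity=i).fraction
            for l, i in [(0, 0), (100, 0), (100, 90), (100, 99), (1_000, 0)]
        ]
        assert f[0] >= f[1] >= f[2] >= f[3]
        assert f[1] >= f[4]


class TestPairStatistics:
    def test_pairs_not_copies(self):
        plan = M.RepeatFamilyPlan(
            "f", 4, 500,
            placements=[("chr1", i) for i in (2_000, 8_000, 14_000, 20_000)],
        )
        g = M.generate_genome(1, [26_000], repeat_plan=[plan], seed=8)
        st = M.pair_statistics(M.find_exact_repeats(g, 30))
        assert st["n_pairs"] == 6

    def test_perfect_plants_are_identity_point_mass(self):
        plan = M.RepeatFamilyPlan(
            "f", 2, 500, placements=[("chr1", 1_000), ("chr1", 5_000)]
        )
        g = M.generate_genome(1, [10_000], repeat_plan=[plan], seed=9)
        st = M.pair_statistics(M.find_repeat_pairs(g), min_len_for_identity=300)
        assert len(st["identities"]) == 1
        assert st["identities"][0] == 100.0

    def test_summed_pair_length_can_exceed_genome_length(self):
        plan = M.RepeatFamilyPlan(
            "f", 6, 1_000,
            placements=[("chr1", 2_000 * i + 500) for i in range(6)],
        )
        g = M.generate_genome(1, [13_000], repeat_plan=[plan], seed=10)
        st = M.pair_statistics(M.find_exact_repeats(g, 30))
        assert st["n_pairs"] == 15
        assert st["total_pair_length"] > g.total_length


class TestSymmetry:
    def test_pair_canonicalization_order_independent(self):
        a = RepeatCopy("chr1", 100, 200, "+")
        b = RepeatCopy("chr1", 500, 600, "+")
        assert RepeatPair(a, b, 100, 100.0, 100) == RepeatPair(b, a, 100, 100.0, 100)
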