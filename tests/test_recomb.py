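"""Recombination assay: worked-example arithmetic, eligibility filters,
mixture recovery, the reversed-orientation control, and structure reports."""

import numpy as np
import pandas as pd
import pytest

import mtstruct as M
from mtstruct.model import LibraryWindow, RepeatCopy, RepeatPair
from mtstruct.recomb import EligibilityOptions, SupportCounts

from conftest import binomial_3se


class TestRecombinantFrequency:
    def test_worked_example(self):
        """505+481 reference and 8+12 recombinant pairs -> 20/1006 ~ 2%."""
        f = M.recombinant_frequency((505, 481, 8, 12))
        assert f == pytest.approx(20 / 1006)
        assert round(f, 4) == 0.0199
        assert M.frequency_percent(f) == 2

    def test_degenerate_counts(self):
        assert M.recombinant_frequency((10, 20, 0, 0)) == 0.0
        assert M.recombinant_frequency((7, 7, 7, 7)) == 0.5
        assert M.recombinant_frequency((0, 0, 0, 0)) is None

    def test_invariant_under_copy_relabel(self):
        a = M.recombinant_frequency(SupportCounts(100, 80, 5, 3))
        b = M.recombinant_frequency(SupportCounts(80, 100, 3, 5))
        assert a == b


class TestFilterAssayable:
    def _catalog(self, pairs):
        return M.RepeatCatalog(list(pairs))

    def test_short_and_divergent_pairs_excluded(self, window):
        g = M.generate_genome(1, [100_000], seed=1)
        short = RepeatPair(
            RepeatCopy("chr1", 1_000, 1_040), RepeatCopy("chr1", 50_000, 50_040),
            40, 100.0, 40,
        )
        divergent = RepeatPair(
            RepeatCopy("chr1", 2_000, 2_100), RepeatCopy("chr1", 60_000, 60_100),
            100, 92.0, 60,
        )
        df = M.filter_assayable(self._catalog([short, divergent]), window, g)
        assert list(df["reason"]) == ["min_length", "min_identity"]

    def test_close_copies_excluded_by_separation(self, window):
        g = M.generate_genome(1, [100_000], seed=1)
        close = RepeatPair(
            RepeatCopy("chr1", 1_000, 1_100), RepeatCopy("chr1", 3_100, 3_200),
            100, 100.0, 100,
        )
        df = M.filter_assayable(self._catalog([close]), window, g)
        assert df["reason"].iloc[0] == "separation"

    def test_isolated_pair_eligible(self, window):
        g = M.generate_genome(1, [100_000], seed=1)
        iso = RepeatPair(
            RepeatCopy("chr1", 10_000, 11_000), RepeatCopy("chr1", 40_000, 41_000),
            1_000, 100.0, 1_000,
        )
        df = M.filter_assayable(self._catalog([iso]), window, g)
        assert bool(df["eligible"].iloc[0])

    def test_correlated_larger_pair_excluded(self, window):
        g = M.generate_genome(1, [200_000], seed=1)
        focal = RepeatPair(
            RepeatCopy("chr1", 50_000, 50_100), RepeatCopy("chr1", 120_000, 120_100),
            100, 100.0, 100,
        )
        bigger = RepeatPair(
            RepeatCopy("chr1", 52_000, 54_000), RepeatCopy("chr1", 122_000, 124_000),
            2_000, 100.0, 2_000,
        )
        df = M.filter_assayable(self._catalog([focal, bigger]), window, g)
        assert df["reason"].iloc[0] == "correlated_larger_pair"
        off = M.filter_assayable(
            self._catalog([focal, bigger]), window, g,
            EligibilityOptions(correlated_rule=False),
        )
        assert off["reason"].iloc[0] != "correlated_larger_pair"

    def test_adjacency_rule(self, window):
        g = M.generate_genome(1, [200_000], seed=1)
        focal = RepeatPair(
            RepeatCopy("chr1", 50_000, 50_100), RepeatCopy("chr1", 120_000, 120_100),
            100, 100.0, 100,
        )
        neighbour = RepeatPair(
            RepeatCopy("chr1", 50_150, 50_800), RepeatCopy("chr1", 160_000, 160_650),
            650, 100.0, 650,
        )
        opts = EligibilityOptions(adjacency_rule=True, correlated_rule=False)
        df = M.filter_assayable(self._catalog([focal, neighbour]), window, g, opts)
        assert df["reason"].iloc[0] == "adjacent_large_repeat"

    def test_short_pair_subsampling_is_seeded(self, window):
        g = M.generate_genome(1, [500_000], seed=1)
        pairs = [
            RepeatPair(
                RepeatCopy("chr1", 10_000 + 14_000 * i, 10_100 + 14_000 * i),
                RepeatCopy("chr1", 10_000 + 14_000 * i + 7_000, 10_100 + 14_000 * i + 7_000),
                100, 100.0, 100,
            )
            for i in range(30)
        ]
        opts = EligibilityOptions(subsample_short=(0.05, 200, 7))
        df1 = M.filter_assayable(self._catalog(pairs), window, g, opts)
        df2 = M.filter_assayable(self._catalog(pairs), window, g, opts)
        assert (df1["reason"] == df2["reason"]).all()
        assert (df1["reason"] == "subsampled_out").sum() >= 20


class TestCountSupport:
    def test_reference_only_reads_give_zero_recombinant(
        self, assay_genome, assay_pair, labelled_mixtures, window
    ):
        c = M.count_conformation_support(
            assay_pair, labelled_mixtures[0.0], window, assay_genome
        )
        assert c.r1 == 0 and c.r2 == 0
        assert c.c1 >= 50 and c.c2 >= 50

    def test_equal_mixture_recovers_half(
        self, assay_genome, assay_pair, labelled_mixtures, window
    ):
        c = M.count_conformation_support(
            assay_pair, labelled_mixtures[0.5], window, assay_genome
        )
        f = M.recombinant_frequency(c)
        assert c.total >= 200
        assert abs(f - 0.5) < binomial_3se(0.5, c.total)

    def test_repeat_exceeding_window_is_undefined(self, assay_genome, window):
        giant = RepeatPair(
            RepeatCopy("chr1", 0, 7_000), RepeatCopy("chr1", 100_000, 107_000),
            7_000, 100.0, 7_000,
        )
        df = pd.DataFrame(
            columns=[
                "read_id", "chrom1", "pos1", "len1", "strand1", "nm1",
                "chrom2", "pos2", "len2", "strand2", "nm2", "status", "label", "span",
            ]
        )
        with pytest.raises(M.AssayUndefinedError):
            M.count_conformation_support(giant, df, window, assay_genome)

    def test_counts_invariant_under_copy_swap(
        self, assay_genome, assay_pair, labelled_mixtures, window
    ):
        lab = labelled_mixtures[0.25]
        c = M.count_conformation_support(assay_pair, lab, window, assay_genome)
        swapped = RepeatPair(
            assay_pair.copy_b, assay_pair.copy_a,
            assay_pair.aligned_length, assay_pair.identity, assay_pair.raw_score,
        )
        c2 = M.count_conformation_support(swapped, lab, window, assay_genome)
        assert M.recombinant_frequency(c) == M.recombinant_frequency(c2)

    def test_min_support_gate(self, assay_genome, assay_pair, window):
        empty = pd.DataFrame(
            {
                "read_id": [], "chrom1": [], "pos1": [], "len1": [], "strand1": [],
                "nm1": [], "chrom2": [], "pos2": [], "len2": [], "strand2": [],
                "nm2": [], "status": [], "label": [], "span": [],
            }
        )
        a = M.assay_repeat(assay_pair, empty, window, assay_genome)
        assert not a.eligible and a.exclusion_reason == "min_support"
        assert a.frequency is None


class TestReversedControl:
    def test_control_floor_is_zero_without_chimeras(
        self, assay_genome, assay_pair, labelled_mixtures, window
    ):
        """Direct-repeat recombination at any weight leaves the control at
        the chimera floor, which is exactly zero in chimera-free data."""
        for wt in (0.0, 0.5):
            c = M.reversed_control(
                assay_pair, labelled_mixtures[wt], window, assay_genome
            )
            assert M.recombinant_frequency(c) < 0.01
            assert c.r1 + c.r2 == 0

    def test_control_recovers_inverted_recombination(
        self, assay_genome, assay_pair, labelled_inverted_mixture, window
    ):
        direct = M.count_conformation_support(
            assay_pair, labelled_inverted_mixture, window, assay_genome
        )
        ctrl = M.reversed_control(
            assay_pair, labelled_inverted_mixture, window, assay_genome
        )
        f_direct = M.recombinant_frequency(direct)
        f_ctrl = M.recombinant_frequency(ctrl)
        assert f_direct < 0.01
        assert abs(f_ctrl - 0.3) < binomial_3se(0.3, ctrl.total)


class TestMixtureRecovery:
    def test_frequency_tracks_weight(
        self, assay_genome, assay_pair, labelled_mixtures, window
    ):
        """Estimated recombinant frequency follows the planted mixing
        weight across the whole range (the primary quantitative surface)."""
        for wt, lab in labelled_mixtures.items():
            c = M.count_conformation_support(assay_pair, lab, window, assay_genome)
            f = M.recombinant_frequency(c)
            assert c.total >= 200
            assert abs(f - wt) <= binomial_3se(wt, c.total), (wt, f, c)


class TestAutonomy:
    def test_disjoint_circles_all_autonomous(self, window):
        g = M.generate_genome(3, [20_000, 25_000, 30_000], seed=30)
        cat = M.find_exact_repeats(g, 30)
        reports = M.chromosome_autonomy(g, cat, [])
        assert all(r.autonomous for r in reports)
        assert all(r.vacuous for r in reports)

    def test_fused_mixture_breaks_autonomy(self, window, library):
        plans = [
            M.RepeatFamilyPlan(
                "shared", 2, 5_000, placements=[("chr1", 10_000), ("chr2", 12_000)]
            )
        ]
        g = M.generate_genome(2, [40_000, 40_000], repeat_plan=plans, seed=31)
        cat = M.find_exact_repeats(g, 30)
        big = [p for p in cat if p.aligned_length >= 5_000]
        reports = M.chromosome_autonomy(g, cat, [])
        assert big and all(not r.autonomous for r in reports)


@pytest.fixture(scope="module")
def even_simulation(window):
    g = M.generate_genome(3, [25_000, 25_000, 25_000], seed=33)
    lib = M.library_3kb(error_rate=0.0, duplicate_rate=0.0)
    reads = M.simulate_read_pairs([(g, 1.0)], lib, 12_000, seed=34)
    df = M.map_reads(reads.reads1, reads.reads2, g)
    return g, M.classify(M.deduplicate(df), window, g)


class TestDepthAndCollapse:
    def test_uniform_simulation_is_even(self, even_simulation):
        g, lab = even_simulation
        df, fold = M.depth_evenness(lab, g)
        assert fold == pytest.approx(1.0, abs=0.1)

    def test_doubled_chromosome_doubles_depth(self, window):
        from mtstruct.model import GenomeModel

        g = M.generate_genome(3, [25_000, 25_000, 25_000], seed=33)
        extra = GenomeModel({"chr1": g["chr1"]})
        lib = M.library_3kb(error_rate=0.0, duplicate_rate=0.0)
        reads = M.simulate_read_pairs([(g, 0.75), (extra, 0.25)], lib, 12_000, seed=35)
        df = M.map_reads(reads.reads1, reads.reads2, g)
        lab = M.classify(M.deduplicate(df), window, g)
        table, fold = M.depth_evenness(lab, g)
        assert fold == pytest.approx(2.0, abs=0.25)

    def test_gc_of_all_at_chromosome_is_zero(self):
        from mtstruct.model import ChromosomeSeq

        c = ChromosomeSeq("x", "ATATATAT")
        assert c.gc == 0.0

    def test_clean_circle_has_no_collapse_flags(self, even_simulation):
        g, lab = even_simulation
        assert len(M.collapse_diagnostics(lab, g)) == 0

    def test_collapsed_tandem_is_flagged(self, window):
        from mtstruct._seq import random_seq
        from mtstruct.model import ChromosomeSeq, GenomeModel

        bg = random_seq(np.random.default_rng(36), 40_000)
        unit = bg[10_000:14_000]
        true_g = GenomeModel(
            {"chr1": ChromosomeSeq("chr1", bg[:10_000] + unit + unit + bg[14_000:])}
        )
        ref_g = GenomeModel({"chr1": ChromosomeSeq("chr1", bg)})
        lib = M.library_3kb(error_rate=0.0, duplicate_rate=0.0)
        reads = M.simulate_read_pairs([(true_g, 1.0)], lib, 12_000, seed=37)
        df = M.map_reads(reads.reads1, reads.reads2, ref_g)
        lab = M.classify(M.deduplicate(df), window, ref_g)
        flags = M.collapse_diagnostics(lab, ref_g)
        assert len(flags) > 0
        assert flags["start"].min() >= 8_000 and flags["end"].max() <= 16_000

    def test_true_subcircle_not_flagged(self, assay_genome, assay_variant, window):
        """A genuine autonomous subcircle mapped against itself shows
        neither excess depth nor boundary-clustered inconsistent pairs."""
        lib = M.library_3kb(error_rate=0.0, duplicate_rate=0.0)
        reads = M.simulate_read_pairs([(assay_variant, 1.0)], lib, 8_000, seed=38)
        df = M.map_reads(reads.reads1, reads.reads2, assay_variant)
        lab = M.classify(M.deduplicate(df), window, assay_variant)
        assert len(M.collapse_diagnostics(lab, assay_variant)) == 0
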