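import itertools
import math

import numpy as np
import pytest

from foundercnv.formats import GeneticMap, uniform_map
from foundercnv.sharing import (
    Region,
    _walk,
    build_flank_window,
    consensus_haplotype,
    exclude_relatives,
    extend_shared,
    measure_sharing,
    shared_segment,
)


def walk_oracle(hap, cons, rescue_k):
    """Independent statement of the extension rule, written declaratively.

    The walk stops at the first mismatch position i whose following
    ``rescue_k`` positions (all remaining, if fewer) do not all match; the
    terminus is the last matching position before the stop, the rescued
    count is the number of mismatches passed, and the walk is censored when
    no such stopping mismatch exists.
    """
    n = len(hap)
    mismatches = [i for i in range(n) if hap[i] != cons[i]]
    stop = None
    for i in mismatches:
        if rescue_k == 0:
            stop = i
            break
        lookahead_end = n if math.isinf(rescue_k) else i + 1 + rescue_k
        mismatches_in = [j for j in mismatches if i < j < lookahead_end]
        if mismatches_in:
            stop = i
            break
    if stop is None:
        last = max((i for i in range(n) if hap[i] == cons[i]), default=-1)
        return last, len(mismatches), True
    matched_before = [i for i in range(stop) if hap[i] == cons[i]]
    rescued = sum(1 for i in mismatches if i < stop)
    return (matched_before[-1] if matched_before else -1), rescued, False


class TestWalk:
    def test_all_match_censored(self):
        hap = np.zeros(60, dtype=np.int8)
        res = _walk(hap, hap, rescue_k=5)
        assert res.last_match == 59 and res.censored and res.n_rescued == 0

    def test_isolated_mismatch_rescued(self):
        hap = np.zeros(60, dtype=np.int8)
        cons = hap.copy()
        hap[10] = 1  # SNPs 11-15 match -> rescued
        res = _walk(hap, cons, rescue_k=5)
        assert res.censored and res.n_rescued == 1 and res.last_match == 59

    def test_two_close_mismatches_stop(self):
        hap = np.zeros(60, dtype=np.int8)
        cons = hap.copy()
        hap[10] = hap[12] = 1
        res = _walk(hap, cons, rescue_k=5)
        assert res.last_match == 9 and res.n_rescued == 0 and not res.censored

    def test_rescue_zero_stops_at_first_mismatch(self):
        hap = np.zeros(20, dtype=np.int8)
        cons = hap.copy()
        hap[3] = 1
        res = _walk(hap, cons, rescue_k=0)
        assert res.last_match == 2 and not res.censored

    @pytest.mark.parametrize("rescue_k", [0, 5, math.inf])
    def test_exhaustive_12_snp_oracle(self, rescue_k):
        """The walk agrees with an independent declarative statement of the
        rule on every allele pattern of a 12-SNP window."""
        cons = np.zeros(12, dtype=np.int8)
        for bits in itertools.product([0, 1], repeat=12):
            hap = np.array(bits, dtype=np.int8)
            res = _walk(hap, cons, rescue_k)
            assert (res.last_match, res.n_rescued, res.censored) == walk_oracle(
                hap, cons, rescue_k
            ), bits

    def test_rescued_mismatches_isolated(self):
        """No two rescued positions can lie within rescue_k of each other."""
        rng = np.random.default_rng(7)
        cons = np.zeros(40, dtype=np.int8)
        k = 5
        for _ in range(300):
            hap = (rng.random(40) < 0.15).astype(np.int8)
            res = _walk(hap, cons, k)
            end = 40 if res.censored else res.last_match + 1
            rescued_pos = [i for i in range(end) if hap[i] != cons[i]]
            assert len(rescued_pos) == res.n_rescued
            for a, b in zip(rescued_pos, rescued_pos[1:]):
                assert b - a > k


class TestWindowAndConsensus:
    def test_window_selection(self, toy_panel, small_region):
        w = build_flank_window(toy_panel, small_region, n_snps=10)
        assert len(w.left_positions) == 10 and len(w.right_positions) == 10
        assert w.left_positions.max() < small_region.start_bp
        assert w.right_positions.min() > small_region.end_bp
        assert not w.short_left and not w.short_right

    def test_short_side_flagged(self, toy_panel, small_region):
        w = build_flank_window(toy_panel, small_region, n_snps=60)
        assert w.short_left and w.short_right
        assert len(w.left_positions) == 10

    def test_snps_inside_region_excluded(self, toy_panel):
        # widen the region to swallow 1 left SNP (4,999,000) and 2 right SNPs
        region = Region("chr1", 4_998_500, 5_102_500)
        w = build_flank_window(toy_panel, region, n_snps=60)
        assert len(w.left_positions) == 9 and len(w.right_positions) == 8

    def test_no_flank_is_error(self, toy_panel):
        with pytest.raises(ValueError):
            build_flank_window(toy_panel, Region("chr1", 1, 6_000_000))

    def test_consensus_majority_and_tie(self, toy_panel, small_region):
        w = build_flank_window(toy_panel, small_region, n_snps=10)
        left, right = consensus_haplotype(w, ["A_h1", "B_h1", "C_h1"])
        # A and B are ancestral; C deviates at one SNP per side -> majority wins
        np.testing.assert_array_equal(left, toy_panel.alleles[0][:10])
        np.testing.assert_array_equal(right, toy_panel.alleles[0][10:])
        # 2v2 tie: allele of the lexicographically first carrier (A)
        left4, _ = consensus_haplotype(w, ["A_h1", "B_h1", "C_h1", "D_h1"])
        np.testing.assert_array_equal(left4, toy_panel.alleles[0][:10])

    def test_empty_carrier_set_error(self, toy_panel, small_region):
        w = build_flank_window(toy_panel, small_region, n_snps=10)
        with pytest.raises(ValueError):
            consensus_haplotype(w, [])


class TestSharedSegment:
    def test_uniform_rate_closed_form(self, toy_panel, small_region, flat_map):
        """Full sharing out to the outermost toy SNPs (10 kb from each CNV
        boundary) at 1 cM/Mb is 2 * 1e-4 Morgans."""
        w = build_flank_window(toy_panel, small_region, n_snps=10)
        cons = consensus_haplotype(w, ["A_h1", "B_h1"])
        seg = shared_segment(w, "A_h1", cons, flat_map)
        assert seg.censored_left and seg.censored_right
        assert seg.genetic_length_morgans == pytest.approx(2 * 10_000 * 1e-8)
        assert seg.length_bp == (small_region.start_bp - 4_990_000) + (
            5_110_000 - small_region.end_bp
        )

    def test_zero_sharing(self, toy_panel, small_region, flat_map):
        w = build_flank_window(toy_panel, small_region, n_snps=10)
        cons = consensus_haplotype(w, ["A_h1", "B_h1"])
        seg = shared_segment(w, "D_h1", cons, flat_map, rescue_k=0)
        assert seg.genetic_length_morgans == 0.0
        assert seg.left_terminus_bp == small_region.start_bp
        assert seg.right_terminus_bp == small_region.end_bp

    def test_two_rate_map_hand_sum(self):
        """2 Mb of left sharing at 0.5 cM/Mb plus 1 Mb of right sharing at
        1 cM/Mb totals 2 cM = 0.02 Morgans."""
        region = Region("chr2", 10_000_000, 11_000_000)
        gmap = GeneticMap()
        gmap.add_chromosome(
            "chr2",
            [6_000_000, 10_000_000, 11_000_000, 14_000_000],
            [0.5, 0.5, 1.0, 1.0],
            [0.0, 2.0, 2.5, 5.5],
        )
        positions = np.array([8_000_000, 9_999_000, 12_000_000, 12_001_000])
        # X shares both left SNPs and only the first right SNP
        alleles = np.array([[0, 0, 0, 1]], dtype=np.int8)
        from foundercnv.formats import HaplotypePanel

        panel = HaplotypePanel("chr2", positions, alleles, ["X_h1"])
        w = build_flank_window(panel, region, n_snps=2)
        cons = (np.zeros(2, dtype=np.int8), np.zeros(2, dtype=np.int8))
        seg = shared_segment(w, "X_h1", cons, gmap, rescue_k=0)
        # left terminus 8 Mb (2 Mb at 0.5), right terminus 12 Mb (1 Mb at 1.0)
        assert seg.left_terminus_bp == 8_000_000
        assert seg.right_terminus_bp == 12_000_000
        assert seg.censored_left and not seg.censored_right
        assert seg.genetic_length_morgans == pytest.approx(0.02)

    def test_genetic_length_monotone_in_extent(self, flat_map):
        """A haplotype sharing strictly further has genetic length at least
        as large (cm_at is monotone)."""
        region = Region("chr1", 5_000_000, 5_100_000)
        rng = np.random.default_rng(3)
        positions = np.concatenate([
            np.sort(rng.choice(np.arange(4_000_000, 5_000_000), 30, replace=False)),
            np.sort(rng.choice(np.arange(5_100_001, 6_100_000), 30, replace=False)),
        ])
        from foundercnv.formats import HaplotypePanel

        cons_row = np.zeros(60, dtype=np.int8)
        rows, ids = [cons_row], ["CONS_h1"]
        for i in range(10):
            h = cons_row.copy()
            stop = rng.integers(0, 30)
            h[:stop] = 1  # kill left flank beyond stop
            rows.append(h)
            ids.append(f"H{i}_h1")
        panel = HaplotypePanel("chr1", positions, np.stack(rows), ids)
        w = build_flank_window(panel, region, n_snps=30)
        cons = (cons_row[:30], cons_row[30:])
        segs = [shared_segment(w, h, cons, flat_map, rescue_k=0) for h in ids[1:]]
        segs.sort(key=lambda s: s.length_bp)
        lengths = [s.genetic_length_morgans for s in segs]
        assert all(b >= a - 1e-12 for a, b in zip(lengths, lengths[1:]))


class TestExcludeRelatives:
    def test_no_pairs_all_retained(self):
        ids = ["A_h1", "A_h2", "B_h1"]
        assert exclude_relatives(ids, []) == ids

    def test_single_pair_drops_lexicographic_first(self):
        ids = ["A_h1", "A_h2", "B_h1", "B_h2"]
        assert exclude_relatives(ids, [("A", "B")]) == ["B_h1", "B_h2"]

    def test_star_drops_hub(self):
        """A related to both B and C: dropping A alone clears all pairs,
        matching the minimum vertex cover on this graph."""
        ids = [f"{s}_h1" for s in "ABC"]
        assert exclude_relatives(ids, [("A", "B"), ("A", "C")]) == ["B_h1", "C_h1"]

    def test_pairs_involving_absent_samples_ignored(self):
        ids = ["A_h1"]
        assert exclude_relatives(ids, [("B", "C")]) == ["A_h1"]


class TestMeasureSharing:
    def test_consensus_vs_pairwise_modes(self, toy_panel, small_region, flat_map):
        carriers = ["A_h1", "B_h1", "C_h1"]
        cons_segs = measure_sharing(toy_panel, small_region, flat_map, carriers,
                                    n_snps=10, rescue_k=0)
        pair_segs = measure_sharing(toy_panel, small_region, flat_map, carriers,
                                    n_snps=10, rescue_k=0, mode="pairwise")
        # A matches B fully in both modes
        assert cons_segs[0].censored and pair_segs[0].censored
        # C stops at its private mismatch against the consensus, but pairwise
        # can never do better than its best partner either
        assert cons_segs[2].length_bp == pair_segs[2].length_bp
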