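import numpy as np
import pytest

from metmap import (
    CGSite,
    call_gg_islands,
    compute_span,
    enumerate_fragments,
    neighbor_exclusion_fraction,
    scan_cg_sites,
    sites_in_scope,
)
from metmap.genome import _maximal_scoring_segments, merge_intervals


def _random_sequence(rng, n, p_gc=0.5):
    return "".join(rng.choice(list("ACGT"), size=n, p=[(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]))


def _hpaii(chrom, cuts):
    return [CGSite(chrom, c, True) for c in cuts]


class TestScanCGSites:
    def test_ccgg_is_flagged_and_cut_at_the_cg(self):
        sites = scan_cg_sites("ACCGGT")
        assert len(sites) == 1
        s = sites[0]
        assert (s.pos, s.is_hpaii, s.cut_pos) == (2, True, 2)

    def test_sequence_without_cg_yields_nothing(self):
        assert scan_cg_sites("ATATAT") == []
        assert scan_cg_sites("") == []

    def test_matches_naive_string_scan_on_random_sequence(self, rng):
        seq = _random_sequence(rng, 10_000)
        sites = scan_cg_sites(seq)
        naive = [i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"]
        assert [s.pos for s in sites] == naive
        for s in sites:
            assert seq[s.pos : s.pos + 2] == "CG"
            assert s.is_hpaii == (seq[s.pos - 1 : s.pos + 3] == "CCGG")

    def test_n_containing_matches_are_skipped(self):
        # the CG inside CNGG is broken; only the intact CG is found
        sites = scan_cg_sites("CNGGACGT")
        assert [s.pos for s in sites] == [5]


class TestEnumerateFragments:
    def test_single_passing_pair(self):
        frags = enumerate_fragments(_hpaii("c", [10, 60, 400]), 50, 300)
        assert [(f.start, f.end, f.length) for f in frags] == [(10, 60, 50)]
        assert frags[0].interior_sites == ()

    def test_non_adjacent_pairs_and_interiors(self):
        frags = enumerate_fragments(_hpaii("c", [0, 100, 200]), 50, 300)
        ends = sorted((f.start, f.end) for f in frags)
        assert ends == [(0, 100), (0, 200), (100, 200)]
        wide = next(f for f in frags if (f.start, f.end) == (0, 200))
        assert [s.cut_pos for s in wide.interior_sites] == [100]

    def test_matches_all_pairs_brute_force(self, rng):
        cuts = sorted(rng.choice(5000, size=50, replace=False).tolist())
        frags = enumerate_fragments(_hpaii("c", cuts), 50, 300)
        expected = {
            (a, b)
            for i, a in enumerate(cuts)
            for b in cuts[i + 1 :]
            if 50 <= b - a <= 300
        }
        assert {(f.start, f.end) for f in frags} == expected

    def test_widening_the_window_never_removes_fragments(self, rng):
        cuts = sorted(rng.choice(3000, size=30, replace=False).tolist())
        narrow = {(f.start, f.end) for f in enumerate_fragments(_hpaii("c", cuts), 80, 200)}
        wide = {(f.start, f.end) for f in enumerate_fragments(_hpaii("c", cuts), 50, 300)}
        assert narrow <= wide

    def test_fragments_spanning_assembly_gaps_are_dropped(self):
        seq = "A" * 10 + "N" * 20 + "A" * 100
        frags = enumerate_fragments(_hpaii("c", [5, 80]), 50, 300, sequence=seq)
        assert frags == []

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            enumerate_fragments(_hpaii("c", [0, 100]), 0, 0)


class TestScope:
    def test_isolated_site_is_out_of_scope(self):
        sites = _hpaii("c", [10, 60, 400])
        frags = enumerate_fragments(sites, 50, 300)
        assert {s.cut_pos for s in sites_in_scope(sites, frags)} == {10, 60}

    def test_matches_brute_force_membership(self, rng):
        cuts = sorted(rng.choice(4000, size=40, replace=False).tolist())
        sites = _hpaii("c", cuts)
        frags = enumerate_fragments(sites, 50, 300)
        got = {s.cut_pos for s in sites_in_scope(sites, frags)}
        expected = set()
        for i, a in enumerate(cuts):
            for j in range(i + 1, len(cuts)):
                if 50 <= cuts[j] - a <= 300:
                    expected.update(cuts[i : j + 1])
        assert got == expected

    def test_scope_is_monotone_in_the_window(self, rng):
        cuts = sorted(rng.choice(4000, size=40, replace=False).tolist())
        sites = _hpaii("c", cuts)
        narrow = sites_in_scope(sites, enumerate_fragments(sites, 80, 200))
        wide = sites_in_scope(sites, enumerate_fragments(sites, 50, 300))
        assert {s.cut_pos for s in narrow} <= {s.cut_pos for s in wide}


class TestSpan:
    def test_hand_run_of_the_bounded_region_rule(self):
        rep = compute_span(_hpaii("c", [0, 100, 200, 600]), 50, 300, "methylseq")
        assert rep.genome_bp_spanned == 200
        assert rep.n_informative_ccgg == 3

    def test_no_informative_sites_means_zero_span(self):
        # all pairwise gaps below l_min
        rep = compute_span(_hpaii("c", [0, 10, 20]), 50, 300, "methylseq")
        assert rep.genome_bp_spanned == 0

    def test_rrbs_uses_adjacent_fragments_only(self):
        # gaps: 100 (in window), 500 (out); site 600 only reachable by a
        # non-adjacent pair, which complete MspI digestion cannot produce
        rep = compute_span(_hpaii("c", [0, 100, 600]), 40, 220, "rrbs")
        assert rep.n_informative_ccgg == 2
        assert rep.genome_bp_spanned == 100

    def test_island_span_extends_to_edges(self):
        sites = _hpaii("c", [100, 200, 300])
        islands = {"c": [(50, 350)]}
        rep = compute_span(sites, 50, 300, "methylseq", genome_length=1000, islands=islands)
        # interior span 100-300 plus both edge extensions
        assert rep.island_bp_spanned == 300
        assert rep.fraction_of_islands == 1.0

    def test_span_never_exceeds_genome_and_fraction_bounded(self, rng):
        cuts = sorted(rng.choice(4000, size=30, replace=False).tolist())
        rep = compute_span(_hpaii("c", cuts), 50, 300, "methylseq", genome_length=4000)
        assert 0 <= rep.genome_bp_spanned <= 4000
        assert 0.0 <= rep.fraction_of_genome <= 1.0


class TestNeighborExclusion:
    def test_hand_computation(self):
        assert neighbor_exclusion_fraction(_hpaii("c", [0, 30, 50, 300])) == 0.25

    def test_no_site_excluded_when_gaps_are_wide(self):
        assert neighbor_exclusion_fraction(_hpaii("c", [0, 40, 80, 120])) == 0.0

    def test_terminal_sites_never_counted(self):
        # both interior gaps small: only the two middle sites qualify
        assert neighbor_exclusion_fraction(_hpaii("c", [0, 10, 20, 30])) == 0.5

    def test_fewer_than_three_sites(self):
        assert neighbor_exclusion_fraction(_hpaii("c", [0, 10])) == 0.0


def _oracle_max_segments(scores):
    """Independent quadratic oracle: extract the maximum-sum segment
    (shortest, then leftmost, on ties — the minimal representative the
    linear-time algorithm reports), then recurse on both flanks."""

    def best(lo, hi):
        top = None
        for i in range(lo, hi):
            acc = 0.0
            for j in range(i, hi):
                acc += scores[j]
                if acc <= 0:
                    continue
                key = (-acc, j + 1 - i, i)
                if top is None or key < top[0]:
                    top = (key, i, j + 1)
        return top

    def recurse(lo, hi):
        seg = best(lo, hi)
        if seg is None:
            return []
        _, i, j = seg
        return recurse(lo, i) + [(i, j)] + recurse(j, hi)

    return recurse(0, len(scores))


class TestGGIslands:
    def test_at_only_sequence_has_no_islands(self):
        assert call_gg_islands("AT" * 200) == []

    def test_pure_cg_sequence_is_one_island(self):
        islands = call_gg_islands("CG" * 150)
        assert len(islands) == 1
        isl = islands[0]
        assert (isl.start, isl.end) == (0, 300)
        assert isl.gc_fraction == 1.0
        assert isl.obs_exp_cg > 0.6

    def test_maximal_segments_match_recursive_oracle(self, rng):
        # continuous scores: no element is exactly zero, as with the
        # +17/-1 dinucleotide scoring, so segment sums tie only by chance
        for _ in range(25):
            scores = rng.normal(size=60).tolist()
            assert _maximal_scoring_segments(scores) == _oracle_max_segments(scores)
        # integer scores shaped like the dinucleotide scheme
        for _ in range(25):
            scores = [17 if x < 0.12 else -1 for x in rng.random(80)]
            assert _maximal_scoring_segments(scores) == _oracle_max_segments(scores)

    def test_island_calls_are_reverse_complement_invariant(self, rng):
        comp = str.maketrans("ACGT", "TGCA")
        core = "".join(rng.choice(list("CG"), size=260))
        seq = _random_sequence(rng, 300, p_gc=0.3) + core + _random_sequence(rng, 300, p_gc=0.3)
        fwd = call_gg_islands(seq)
        rev = call_gg_islands(seq.translate(comp)[::-1])
        n = len(seq)
        mirrored = sorted((n - isl.end, n - isl.start) for isl in rev)
        assert sorted((isl.start, isl.end) for isl in fwd) == mirrored

    def test_filters_reject_short_or_at_rich_segments(self):
        # a CG-rich patch of 150 bp scores well but fails the length filter
        seq = "AT" * 100 + "CG" * 75 + "AT" * 100
        assert call_gg_islands(seq) == []


def test_merge_intervals_produces_disjoint_sorted_output(rng):
    ivs = [(int(a), int(a + b)) for a, b in zip(rng.integers(0, 500, 40), rng.integers(1, 60, 40))]
    merged = merge_intervals(ivs)
    assert merged == sorted(merged)
    assert all(e1 <= s2 for (_, e1), (s2, _) in zip(merged, merged[1:]))
    # same base coverage
    cover = np.zeros(600, dtype=bool)
    for s, e in ivs:
        cover[s:e] = True
    assert sum(e - s for s, e in merged) == int(cover.sum())
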