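import pytest
from hypothesis import given, settings, strategies as st

from phagemosaic.breakpoints import (
    LandmarkError,
    call_crossover_intervals,
    detect_flipflops,
    estimate_modules,
    genome_length_delta,
    segment_origins,
)
from phagemosaic.homology import find_homology_regions
from phagemosaic.io_formats import GenomeRecord
from phagemosaic.origin_typing import InformativeSite, OriginCall
from phagemosaic.pipeline import analyze_recombinant
from phagemosaic.simulate import compact_config, simulate_trio

from _oracles import rle


def mk_calls(pattern, region_id="R1", start_rec=1000, spacing=10, start_a=2000):
    """Fabricate an origin-call vector from a string: A/B calls, '.'=missing,
    'n'=novel. Sites are evenly spaced on recombinant and parent A."""
    calls = []
    alleles = {"A": ("C", "G"), "B": ("C", "G")}
    for i, ch in enumerate(pattern):
        site = InformativeSite(region_id, i, start_a + i * spacing, 500 + i * spacing, "C", "G")
        pos_rec = start_rec + i * spacing
        if ch == "A":
            calls.append(OriginCall(site, pos_rec, "C", "A"))
        elif ch == "B":
            calls.append(OriginCall(site, pos_rec, "G", "B"))
        elif ch == "n":
            calls.append(OriginCall(site, pos_rec, "T", "novel"))
        else:
            calls.append(OriginCall(site, None, None, "missing"))
    return calls


class TestSegmentOrigins:
    @pytest.mark.parametrize(
        "pattern,expected",
        [
            ("AAAA", [("A", 4)]),
            ("AABBB", [("A", 2), ("B", 3)]),
            ("ABABB", [("A", 1), ("B", 1), ("A", 1), ("B", 2)]),
            ("A.nA", [("A", 2)]),  # novel/missing neither break nor extend runs
            ("nn..", []),
            ("", []),
        ],
    )
    def test_run_length_structure(self, pattern, expected):
        blocks = segment_origins(mk_calls(pattern))
        assert [(b.origin, b.n_sites) for b in blocks] == expected

    @settings(max_examples=200, deadline=None)
    @given(st.text(alphabet="ABn.", max_size=40))
    def test_matches_rle_oracle(self, pattern):
        blocks = segment_origins(mk_calls(pattern))
        origins = ["A" if c == "A" else "B" if c == "B" else c for c in pattern]
        assert [(b.origin, b.n_sites) for b in blocks] == rle(origins)

    def test_block_spans_cover_first_and_last_site(self):
        blocks = segment_origins(mk_calls("AABB"))
        assert blocks[0].rec_span.start == 1000
        assert blocks[0].rec_span.end == 1010
        assert blocks[1].rec_span.start == 1020
        assert blocks[1].rec_span.end == 1030


class TestCrossoverIntervals:
    def test_definition(self):
        calls = mk_calls("AABBB", spacing=50)
        # last A at rec 1050, first B at rec 1100
        blocks = segment_origins(calls)
        (xo,) = call_crossover_intervals(blocks)
        assert xo.left_pos_rec == 1050
        assert xo.right_pos_rec == 1100
        assert xo.width == 49
        assert xo.rec_interval.start == 1051 and xo.rec_interval.end == 1099

    def test_explicit_bounds(self):
        calls = mk_calls("AB", start_rec=1000, spacing=150)
        (xo,) = call_crossover_intervals(segment_origins(calls))
        assert (xo.left_pos_rec, xo.right_pos_rec, xo.width) == (1000, 1150, 149)

    def test_single_block_no_interval(self):
        assert call_crossover_intervals(segment_origins(mk_calls("AAAA"))) == []

    def test_adjacent_sites_zero_width(self):
        calls = mk_calls("AB", spacing=1)
        (xo,) = call_crossover_intervals(segment_origins(calls))
        assert xo.width == 0
        assert xo.rec_interval is None


class TestFlipflops:
    def test_single_site_tract(self):
        blocks = segment_origins(mk_calls("AAAAABAAAAAA"))
        (t,) = detect_flipflops(blocks)
        assert t.block.origin == "B" and t.block.n_sites == 1

    def test_threshold_excludes_long_tracts(self):
        blocks = segment_origins(mk_calls("AAAAABBBBAAAAAA"))
        assert detect_flipflops(blocks, max_tract_sites=3) == []
        assert len(detect_flipflops(blocks, max_tract_sites=4)) == 1

    def test_edge_blocks_are_not_tracts(self):
        blocks = segment_origins(mk_calls("BAAAAA"))
        assert detect_flipflops(blocks) == []


class TestEstimateModules:
    def test_landmark_arithmetic(self):
        r1 = mk_calls("AABBB", region_id="R1", start_rec=1000, spacing=1, start_a=5000)
        # first B in region 1: rec 1002, pos_a 5002
        r2 = mk_calls("BBAA", region_id="R2", start_rec=9797, spacing=1, start_a=16561)
        # first A after B in region 2: rec 9799, pos_a 16563
        est = estimate_modules(r1, r2)
        assert est.donor_len == 9799 - 1002 == 8797
        assert est.replaced_len == 16563 - 5002
        assert est.delta == est.replaced_len - est.donor_len

    def test_parent_a_like_vector_raises(self):
        with pytest.raises(LandmarkError, match="not a two-crossover"):
            estimate_modules(mk_calls("AAAA"), mk_calls("BBAA", region_id="R2"))

    def test_region2_without_return_raises(self):
        with pytest.raises(LandmarkError, match="region 2"):
            estimate_modules(mk_calls("AABB"), mk_calls("BBBB", region_id="R2"))

    def test_leading_a_in_region2_is_not_a_landmark(self):
        r2 = mk_calls("ABBA", region_id="R2", start_rec=9000, spacing=1)
        est = estimate_modules(mk_calls("AB"), r2)
        assert est.donor_end_rec == 9003  # the A *after* donor calls, not pos 9000


class TestArchitectureAndDelta:
    def test_double_crossover_is_aba(self, full_analysis):
        _, analysis, _ = full_analysis
        assert analysis.report.architecture == "A-B-A"

    def test_parent_copy_is_a(self, compact_trio):
        parent_a, parent_b, _, _ = compact_trio
        regions = find_homology_regions(parent_a, parent_b)
        copy = GenomeRecord("copy", parent_a.seq, source="synthetic")
        report = analyze_recombinant(parent_a, parent_b, regions, copy).report
        assert report.architecture == "A"
        assert report.modules is None
        assert "not a two-crossover" in report.error

    def test_single_crossover_is_ab(self, compact_trio):
        parent_a, parent_b, _, truth = compact_trio
        r1 = truth.regions[0]
        xo = 600
        seq = parent_a.seq[: r1.a_start - 1 + xo] + parent_b.seq[r1.b_start - 1 + xo :]
        single = GenomeRecord("single", seq, source="synthetic")
        regions = find_homology_regions(parent_a, parent_b)
        report = analyze_recombinant(parent_a, parent_b, regions, single).report
        assert report.architecture == "A-B"
        assert report.modules is None

    def test_genome_length_delta(self, compact_trio):
        parent_a, parent_b, rec, _ = compact_trio
        assert genome_length_delta(parent_a, parent_a) == 0
        assert genome_length_delta(parent_a, rec) == parent_a.length - rec.length

    @pytest.mark.parametrize("seed", range(10))
    def test_module_delta_equals_genome_delta(self, seed):
        """Conservation identity: replaced - donor == len(A) - len(rec)."""
        parent_a, parent_b, rec, _ = simulate_trio(compact_config(seed=seed))
        regions = find_homology_regions(parent_a, parent_b)
        report = analyze_recombinant(parent_a, parent_b, regions, rec).report
        assert report.modules is not None
        assert report.modules.delta == genome_length_delta(parent_a, rec)

    def test_determinism(self, compact_trio):
        parent_a, parent_b, rec, _ = compact_trio
        regions = find_homology_regions(parent_a, parent_b)
        rep1 = analyze_recombinant(parent_a, parent_b, regions, rec).report
        rep2 = analyze_recombinant(parent_a, parent_b, regions, rec).report
        assert rep1.to_dict() == rep2.to_dict()


def test_crossover_coverage_and_monotone_width(full_analysis, full_trio):
    """True junctions lie inside their called intervals; the denser region
    (lower identity, more sites) gives the narrower interval."""
    regions, analysis, truth = full_analysis
    rep = analysis.report
    xo1, xo2 = truth.crossover_rec_left
    (i1,) = rep.crossovers["R1"]
    (i2,) = rep.crossovers["R2"]
    assert i1.contains(xo1)
    assert i2.contains(xo2)
    # region 1 is at 84% identity (dense sites), region 2 at 98% (sparse)
    assert i1.width <= i2.width
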