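"""Coverage tracks, fold enrichment, region calling and density maps."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gagabind import chipprofile as cp
from gagabind.errors import ContractError, FormatError


def track(values, chrom="chr1", start=0):
    return cp.CoverageTrack(chrom=chrom, start=start, values=np.asarray(values, float))


class TestBedgraphIO:
    def test_basic_parse(self, tmp_path):
        p = tmp_path / "a.bg"
        p.write_text("chr1\t0\t4\t2.0\n")
        t = cp.read_bedgraph(p)
        assert t.chrom == "chr1" and list(t.values) == [2.0] * 4

    def test_gap_reads_back_as_zero(self, tmp_path):
        p = tmp_path / "a.bg"
        p.write_text("chr1\t0\t2\t1.0\nchr1\t4\t6\t3.0\n")
        t = cp.read_bedgraph(p)
        assert list(t.values) == [1, 1, 0, 0, 3, 3]

    def test_overlap_and_multichrom_errors_cite_line(self, tmp_path):
        p = tmp_path / "bad.bg"
        p.write_text("chr1\t0\t4\t2.0\nchr1\t2\t6\t1.0\n")
        with pytest.raises(FormatError, match=":2"):
            cp.read_bedgraph(p)
        p.write_text("chr1\t0\t4\t2.0\nchr2\t0\t4\t1.0\n")
        with pytest.raises(FormatError, match="chromosomes"):
            cp.read_bedgraph(p)

    @given(
        vals=st.lists(
            st.floats(min_value=0, max_value=100, allow_nan=False), min_size=1, max_size=50
        ),
        start=st.integers(0, 1000),
    )
    def test_roundtrip_identity(self, vals, start, tmp_path_factory):
        t = track(vals, start=start)
        p = tmp_path_factory.mktemp("bg") / "t.bg"
        cp.write_bedgraph(t, p)
        back = cp.read_bedgraph(p)
        # trailing zeros are legitimately absorbed into the uncovered tail
        assert back.start == t.start
        n = len(back.values)
        assert np.array_equal(back.values, t.values[:n])
        assert np.all(t.values[n:] == 0)


class TestFoldTracks:
    def test_pointwise_ratio_with_pseudocount(self):
        t = cp.fold_enrichment_track(track([10, 0, 5]), track([2, 0, 5]), pseudocount=1)
        assert list(t.values) == [11 / 3, 1.0, 1.0]

    def test_identical_tracks_give_unity(self):
        a = track([3, 4, 5])
        assert np.allclose(cp.fold_enrichment_track(a, a).values, 1.0)

    def test_chrom_mismatch_rejected(self):
        with pytest.raises(ContractError):
            cp.fold_enrichment_track(track([1]), track([1], chrom="chr2"))

    def test_median_of_four_combinations(self):
        # treat {4,4}, control {1,2}: folds (with pc -> 0) are {4,2,4,2}, median 3
        pc = 1e-9
        med = cp.median_fold_track(
            [track([4.0]), track([4.0])], [track([1.0]), track([2.0])], pseudocount=pc
        )
        assert med.values[0] == pytest.approx(3.0, rel=1e-6)

    def test_median_replicate_layout_enforced(self):
        with pytest.raises(ContractError):
            cp.median_fold_track([track([1])], [track([1]), track([1])])
        out = cp.median_fold_track(
            [track([2.0])], [track([1.0]), track([1.0])], allow_general=True
        )
        assert out.values[0] == pytest.approx(1.5)

    def test_median_invariant_under_replicate_swaps(self):
        rng = np.random.default_rng(0)
        t1, t2 = track(rng.poisson(5, 30)), track(rng.poisson(5, 30))
        c1, c2 = track(rng.poisson(3, 30)), track(rng.poisson(3, 30))
        a = cp.median_fold_track([t1, t2], [c1, c2]).values
        b = cp.median_fold_track([t2, t1], [c2, c1]).values
        assert np.array_equal(a, b)

    def test_zero_control_finite_with_pseudocount(self):
        out = cp.median_fold_track(
            [track([5, 5]), track([5, 5])], [track([0, 0]), track([0, 0])], pseudocount=1
        )
        assert np.all(np.isfinite(out.values))


class TestRegionsAndPeaks:
    def test_strictly_above_threshold(self):
        regions = cp.call_enriched_regions(track([1, 6, 7, 1]), threshold=5)
        assert [(r.start, r.end) for r in regions] == [(1, 3)]
        assert regions[0].min_fold == 6
        assert cp.call_enriched_regions(track([5, 5, 5]), threshold=5) == []

    def test_min_length_filter(self):
        regions = cp.call_enriched_regions(track([6, 6, 1, 6]), threshold=5, min_length=2)
        assert [(r.start, r.end) for r in regions] == [(0, 2)]

    def test_regions_are_maximal(self):
        regions = cp.call_enriched_regions(track([9, 9, 1, 9]), threshold=5)
        assert [(r.start, r.end) for r in regions] == [(0, 2), (3, 4)]

    def test_peak_center_simple_and_plateau(self):
        assert cp.locate_peak_center(track([0, 1, 5, 1, 0])).position == 2
        peak = cp.locate_peak_center(track([0, 5, 5, 0]))
        assert peak.position == 1 and not peak.degenerate  # floor of run midpoint
        flat = cp.locate_peak_center(track([0, 0, 0]))
        assert flat.degenerate

    def test_peak_center_respects_region_and_offset(self):
        t = track([9, 0, 0, 7, 0], start=100)
        assert cp.locate_peak_center(t, region=(102, 105)).position == 103
        with pytest.raises(ContractError):
            cp.locate_peak_center(t, region=(103, 103))


class TestDensityMap:
    def test_motif_at_center(self):
        seqs = {"c": "T" * 10 + "GAGA" + "T" * 10}
        prof = cp.motif_density_map(seqs, {"g1": ("c", 10)}, halfwidth=10)
        at_zero = prof.occupancy["GAGA"][0, list(prof.offsets).index(0)]
        assert at_zero == 1
        assert prof.aggregate["GAGA"][list(prof.offsets).index(0)] == 1.0
        assert prof.aggregate["TCTC"].sum() == 0

    def test_no_motifs_gives_zero_profile(self):
        prof = cp.motif_density_map({"c": "T" * 30}, {"g": ("c", 15)}, halfwidth=10)
        assert prof.aggregate["GAGA"].sum() == 0

    def test_aggregate_is_mean_over_genes(self):
        seqs = {"a": "T" * 10 + "GAGA" + "T" * 10, "b": "T" * 24}
        prof = cp.motif_density_map(
            seqs, {"g1": ("a", 10), "g2": ("b", 10)}, halfwidth=10
        )
        assert prof.aggregate["GAGA"][list(prof.offsets).index(0)] == 0.5

    def test_overlapping_occurrences_all_marked(self):
        seqs = {"c": "T" * 8 + "GAGAGA" + "T" * 8}
        prof = cp.motif_density_map(seqs, {"g": ("c", 8)}, halfwidth=8)
        idx = list(prof.offsets)
        row = prof.occupancy["GAGA"][0]
        assert row[idx.index(0)] == 1 and row[idx.index(2)] == 1

    def test_clipping_and_skipping(self):
        seqs = {"c": "T" * 12}
        with pytest.warns(UserWarning, match="outside"):
            prof = cp.motif_density_map(
                seqs, {"edge": ("c", 2), "lost": ("c", 99)}, halfwidth=5
            )
        assert prof.clipped == ["edge"] and prof.skipped == ["lost"]
        assert prof.genes == ["edge"]
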