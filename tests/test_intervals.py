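"""Interval model, BED I/O, tag counting, peak calling and set operations."""

import numpy as np
import pytest

from enhrev import (
    GenomicInterval,
    RegionSet,
    TagTrack,
    call_peaks,
    concordant_regions,
    count_tags_in_regions,
    overlap_classes,
    read_bed,
    simulate_tag_cluster,
    write_bed,
)
from enhrev.intervals import BedParseError, read_tag_bed, write_tag_bed


def brute_force_counts(track, regions):
    """O(N*M) oracle: count tags per region by direct membership."""
    out = []
    for r in regions:
        n = 0
        for chrom, positions in track.tags.items():
            if chrom != r.chrom:
                continue
            n += sum(1 for p in positions if r.start <= p < r.end)
        out.append(n)
    return np.array(out)


def random_instance(rng, n_tags=200, n_regions=30, span=5000):
    chroms = ["chr1", "chr2"]
    track = TagTrack.from_positions(
        "t",
        [
            (chroms[rng.integers(2)], int(rng.integers(span)))
            for _ in range(n_tags)
        ],
    )
    regions = []
    for i in range(n_regions):
        s = int(rng.integers(span - 1))
        e = s + 1 + int(rng.integers(200))
        regions.append(GenomicInterval(chroms[rng.integers(2)], s, e, ".", f"r{i}"))
    return track, RegionSet(regions)


class TestGenomicInterval:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -5, 10)

    def test_duplicate_ids_rejected(self):
        r = GenomicInterval("chr1", 0, 10, ".", "x")
        with pytest.raises(ValueError, match="duplicate"):
            RegionSet([r, r])


class TestBedIO:
    def test_bed6_line_maps_to_interval(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\tE1\t0\t+\n")
        rs = read_bed(str(p))
        (r,) = rs
        assert (r.chrom, r.start, r.end, r.strand, r.id) == ("chr1", 100, 200, "+", "E1")

    def test_empty_file_gives_empty_set(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("")
        assert len(read_bed(str(p))) == 0

    def test_reversed_coordinates_raise_with_line_number(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t200\t100\n")
        with pytest.raises(BedParseError, match="line 1"):
            read_bed(str(p))

    def test_missing_name_and_strand_defaults(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\n")
        (r,) = read_bed(str(p))
        assert r.id == "chr1:100-200" and r.strand == "."

    def test_round_trip_preserves_coordinates_and_ids(self, tmp_path, rng):
        _, regions = random_instance(rng)
        path = tmp_path / "rt.bed"
        write_bed(regions, str(path))
        back = read_bed(str(path))
        assert [(r.chrom, r.start, r.end, r.id) for r in back] == [
            (r.chrom, r.start, r.end, r.id) for r in regions
        ]

    def test_tag_track_round_trip(self, tmp_path, rng):
        track, _ = random_instance(rng)
        path = tmp_path / "tags.bed"
        write_tag_bed(track, str(path))
        back = read_tag_bed(str(path))
        for chrom in track.tags:
            assert np.array_equal(track.tags[chrom], back.tags[chrom])


class TestCountTags:
    def test_no_tags_gives_zeros(self):
        rs = RegionSet([GenomicInterval("chr1", 0, 100, ".", "a")])
        assert count_tags_in_regions(TagTrack("t", {}), rs).tolist() == [0]

    def test_tag_in_two_regions_counts_in_both(self):
        rs = RegionSet(
            [
                GenomicInterval("chr1", 100, 200, ".", "a"),
                GenomicInterval("chr1", 150, 300, ".", "b"),
            ]
        )
        track = TagTrack.from_positions(
            "t", [("chr1", 120), ("chr1", 160), ("chr1", 250), ("chr2", 50)]
        )
        assert count_tags_in_regions(track, rs).tolist() == [2, 2]

    def test_end_coordinate_is_exclusive(self):
        rs = RegionSet([GenomicInterval("chr1", 100, 200, ".", "a")])
        track = TagTrack.from_positions("t", [("chr1", 200)])
        assert count_tags_in_regions(track, rs).tolist() == [0]

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            track, regions = random_instance(rng)
            fast = count_tags_in_regions(track, regions)
            assert np.array_equal(fast, brute_force_counts(track, regions))


class TestCallPeaks:
    def test_uniform_tags_give_no_peaks(self):
        track = simulate_tag_cluster(
            GenomicInterval("chr1", 0, 200), 0, 1000 / 1e7, seed=3
        )
        assert len(call_peaks(track)) == 0

    def test_planted_cluster_recovered_as_single_peak(self):
        region = GenomicInterval("chr1", 5_000_000, 5_000_200)
        track = simulate_tag_cluster(region, 100, 1000 / 1e7, seed=5)
        peaks = call_peaks(track)
        assert len(peaks) == 1
        assert peaks[0].start <= region.start and peaks[0].end >= region.end

    def test_parameter_validation(self):
        track = TagTrack.from_positions("t", [("chr1", 5)])
        with pytest.raises(ValueError):
            call_peaks(track, min_density=0)
        with pytest.raises(ValueError):
            call_peaks(TagTrack("empty", {}))


class TestSetOperations:
    def test_concordant_self_preserves_span(self, rng):
        _, regions = random_instance(rng)
        out = concordant_regions(regions, regions)
        assert out.total_span() == regions.total_span()

    def test_concordant_disjoint_is_empty(self):
        a = RegionSet([GenomicInterval("chr1", 0, 10, ".", "a")])
        b = RegionSet([GenomicInterval("chr1", 20, 30, ".", "b")])
        assert len(concordant_regions(a, b)) == 0

    def test_concordant_takes_union_span(self):
        a = RegionSet([GenomicInterval("chr1", 100, 200, ".", "a")])
        b = RegionSet([GenomicInterval("chr1", 150, 250, ".", "b")])
        (r,) = concordant_regions(a, b)
        assert (r.start, r.end, r.id) == (100, 250, "a")

    def test_overlap_identical_sets_all_shared(self):
        _, regions = random_instance(np.random.default_rng(1))
        oc = overlap_classes(regions, regions)
        assert oc.a_only == [] and oc.b_only == []

    def test_overlap_disjoint_sets_no_shared(self):
        a = RegionSet([GenomicInterval("chr1", 0, 10, ".", "a")])
        b = RegionSet([GenomicInterval("chr2", 0, 10, ".", "b")])
        oc = overlap_classes(a, b)
        assert oc.shared == [] and oc.a_only == ["a"] and oc.b_only == ["b"]

    def test_region_overlapping_two_partners_counted_once(self):
        a = RegionSet(
            [
                GenomicInterval("chr1", 0, 100, ".", "a1"),
                GenomicInterval("chr1", 500, 600, ".", "a2"),
                GenomicInterval("chr1", 900, 950, ".", "a3"),
            ]
        )
        b = RegionSet(
            [
                GenomicInterval("chr1", 10, 30, ".", "b1"),
                GenomicInterval("chr1", 50, 80, ".", "b2"),
            ]
        )
        oc = overlap_classes(a, b)
        assert len(oc.a_shared) == 1
        assert len(oc.shared) == 2
        assert oc.counts()["a_only"] + oc.counts()["a_shared"] == len(a)

    def test_partition_counts_add_up_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            _, a = random_instance(rng, n_regions=15)
            _, b = random_instance(rng, n_regions=15)
            oc = overlap_classes(a, b)
            assert len(oc.a_only) + len(oc.a_shared) == len(a)
            assert len(oc.b_only) + len(oc.b_shared) == len(b)
            # oracle: pairwise overlap check
            expected_pairs = {
                (ra.id, rb.id)
                for ra in a
                for rb in b
                if ra.overlaps(rb)
            }
            assert set(oc.shared) == expected_pairs
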