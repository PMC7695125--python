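"""BigWig/BigBed parsing: headers, trees, blocks, queries, oracles."""
import struct

import numpy as np
import pytest

from trackquery.bbi import (
    BBIFile,
    decode_bed_block,
    decode_wig_section,
    decode_zoom_block,
    find_blocks,
    parse_header,
    read_chrom_tree,
)
from trackquery.core import GenomicRange
from trackquery.errors import (
    CorruptBlock,
    CorruptIndex,
    UnknownChromosome,
    UnrecognizedFormat,
)
from trackquery.fixtures import corrupt_fixture
from trackquery.range_io import BlockCache, open_resource

from conftest import brute_force_overlap


class TestHeader:
    def test_bigwig_header_fields(self, signal_track):
        handle = open_resource(signal_track.path)
        header, zooms = parse_header(handle)
        assert header.kind == "bigwig"
        assert header.zoom_levels == len(signal_track.spec.zoom_reductions)
        assert [z.reduction_level for z in zooms] == \
            list(signal_track.spec.zoom_reductions)
        assert header.uncompress_buf_size > 0  # compressed fixture

    def test_bigbed_header_kind(self, region_track):
        handle = open_resource(region_track.path)
        header, zooms = parse_header(handle)
        assert header.kind == "bigbed"
        assert zooms == []

    def test_zero_bytes_unrecognized(self, tmp_path):
        path = tmp_path / "zeros.bin"
        path.write_bytes(b"\0" * 64)
        with pytest.raises(UnrecognizedFormat):
            parse_header(open_resource(str(path)))

    def test_header_reads_are_pinned(self, signal_track):
        cache = BlockCache()
        parse_header(open_resource(signal_track.path), cache)
        assert len(cache.pinned) >= 2  # header + zoom headers


class TestChromTree:
    def test_lists_exactly_the_fixture_chromosomes(self, signal_track):
        handle = open_resource(signal_track.path)
        header, _ = parse_header(handle)
        entries = read_chrom_tree(handle, header)
        assert {(e.name, e.length) for e in entries} == \
            {("chr1", 100_000), ("chr2", 50_000)}
        assert len({e.id for e in entries}) == 2

    def test_absent_name_not_present(self, signal_track):
        handle = open_resource(signal_track.path)
        header, _ = parse_header(handle)
        names = {e.name for e in read_chrom_tree(handle, header)}
        assert "chrX" not in names

    def test_corrupt_tree_magic(self, signal_track, tmp_path):
        layout = signal_track.layout
        mutated = corrupt_fixture(
            signal_track.path, ("flip", layout.chrom_tree[0]),
            str(tmp_path / "bad.bw"))
        handle = open_resource(mutated)
        header, _ = parse_header(handle)
        with pytest.raises(CorruptIndex):
            read_chrom_tree(handle, header)


class TestFindBlocks:
    def test_single_block_query(self, signal_track):
        handle = open_resource(signal_track.path)
        header, _ = parse_header(handle)
        layout = signal_track.layout
        first = layout.data_blocks[0]
        blocks = find_blocks(handle, header.full_index_offset,
                             first.chrom_id, first.start,
                             first.start + 1)
        assert len(blocks) == 1
        assert (blocks[0].offset, blocks[0].size) == (first.offset,
                                                      first.size)

    def test_absent_chrom_id_empty(self, signal_track):
        handle = open_resource(signal_track.path)
        header, _ = parse_header(handle)
        assert find_blocks(handle, header.full_index_offset, 99,
                           0, 1000) == []

    def test_block_boundary_returns_both(self, signal_track):
        handle = open_resource(signal_track.path)
        header, _ = parse_header(handle)
        layout = signal_track.layout
        b0, b1 = layout.data_blocks[0], layout.data_blocks[1]
        assert b0.chrom_id == b1.chrom_id
        blocks = find_blocks(handle, header.full_index_offset,
                             b0.chrom_id, b0.end - 1, b1.start + 1)
        offsets = {b.offset for b in blocks}
        assert {b0.offset, b1.offset} <= offsets


class TestSectionDecoding:
    def test_fixed_step_expansion(self):
        raw = struct.pack("<IIIIIBBH", 0, 0, 200, 100, 100, 3, 0, 2)
        raw += struct.pack("<ff", 1.5, 2.5)
        frame = decode_wig_section(raw, {0: "chr1"})
        assert frame["start"].tolist() == [0, 100]
        assert frame["end"].tolist() == [100, 200]
        assert frame["value"].tolist() == [1.5, 2.5]

    def test_variable_step_uses_span(self):
        raw = struct.pack("<IIIIIBBH", 0, 10, 40, 0, 5, 2, 0, 2)
        raw += struct.pack("<IfIf", 10, 3.0, 30, 4.0)
        frame = decode_wig_section(raw, {0: "chr1"})
        assert frame["start"].tolist() == [10, 30]
        assert frame["end"].tolist() == [15, 35]

    def test_bedgraph_round_trip(self):
        raw = struct.pack("<IIIIIBBH", 0, 10, 20, 0, 0, 1, 0, 1)
        raw += struct.pack("<IIf", 10, 20, 3.0)
        frame = decode_wig_section(raw, {0: "chr1"})
        assert frame.iloc[0].tolist() == ["chr1", 10, 20, 3.0]

    def test_unknown_section_type(self):
        raw = struct.pack("<IIIIIBBH", 0, 0, 100, 0, 0, 0, 0, 1)
        raw += struct.pack("<IIf", 0, 100, 1.0)
        with pytest.raises(CorruptBlock):
            decode_wig_section(raw, {0: "chr1"})

    def test_item_count_mismatch(self):
        raw = struct.pack("<IIIIIBBH", 0, 0, 100, 0, 0, 1, 0, 5)
        raw += struct.pack("<IIf", 0, 100, 1.0)  # only one item
        with pytest.raises(CorruptBlock):
            decode_wig_section(raw, {0: "chr1"})


class TestBedBlockDecoding:
    def test_two_items_with_named_columns(self):
        raw = (struct.pack("<III", 0, 0, 100) + b"peak1\t960\0"
               + struct.pack("<III", 0, 200, 300) + b"peak2\t400\0")
        frame = decode_bed_block(raw, {0: "chr1"}, ("name", "score"))
        assert frame["name"].tolist() == ["peak1", "peak2"]
        assert frame["score"].tolist() == [960, 400]

    def test_empty_rest_has_no_extra_columns(self):
        raw = struct.pack("<III", 0, 5, 10) + b"\0"
        frame = decode_bed_block(raw, {0: "chr1"})
        assert list(frame.columns) == ["chrom", "start", "end"]
        assert frame.iloc[0].tolist() == ["chr1", 5, 10]

    def test_missing_terminator_raises(self):
        raw = struct.pack("<III", 0, 5, 10) + b"name-without-nul"
        with pytest.raises(CorruptBlock):
            decode_bed_block(raw, {0: "chr1"})


class TestZoomDecoding:
    def test_mean_from_sum_and_count(self):
        raw = struct.pack("<IIIIffff", 0, 0, 160, 10, 1.0, 4.0, 25.0,
                          70.0)
        (rec,) = decode_zoom_block(raw)
        assert rec[3] == 10 and rec[6] / rec[3] == 2.5

    def test_empty_block(self):
        assert decode_zoom_block(b"") == []

    def test_bad_length(self):
        with pytest.raises(CorruptBlock):
            decode_zoom_block(b"\0" * 33)


class TestQueries:
    def test_whole_chromosome_round_trip(self, signal_track):
        f = BBIFile(signal_track.path, cache=BlockCache())
        for chrom in ("chr1", "chr2"):
            got = f.query(chrom, 0, signal_track.spec.chrom_sizes[chrom])
            truth = signal_track.intervals[
                signal_track.intervals["chrom"] == chrom
            ].reset_index(drop=True)
            assert got["start"].tolist() == truth["start"].tolist()
            assert got["end"].tolist() == truth["end"].tolist()
            assert np.array_equal(got["value"].to_numpy(np.float32),
                                  truth["value"].to_numpy(np.float32))

    def test_overlap_semantics_unclipped(self, tiled_track):
        # query inside one 100 bp tile returns that tile unclipped
        f = BBIFile(tiled_track.path, cache=BlockCache())
        got = f.query("chr1", 512, 515)
        assert len(got) == 1
        assert got.iloc[0]["start"] == 500 and got.iloc[0]["end"] == 600

    def test_random_regions_match_brute_force(self, signal_track):
        f = BBIFile(signal_track.path, cache=BlockCache())
        rng = np.random.default_rng(1)
        for _ in range(200):
            s = int(rng.integers(0, 99_000))
            e = s + int(rng.integers(1, 5_000))
            got = f.query("chr1", s, e)
            want = brute_force_overlap(signal_track.intervals,
                                       GenomicRange("chr1", s, e))
            assert got["start"].tolist() == want["start"].tolist()
            assert got["end"].tolist() == want["end"].tolist()
            assert np.array_equal(got["value"].to_numpy(np.float32),
                                  want["value"].to_numpy(np.float32))

    def test_empty_region(self, signal_track):
        f = BBIFile(signal_track.path, cache=BlockCache())
        # beyond the last record on chr2
        last_end = int(signal_track.intervals.query(
            "chrom == 'chr2'")["end"].max())
        got = f.query("chr2", last_end + 10, last_end + 100)
        assert len(got) == 0

    def test_unknown_chromosome(self, signal_track):
        f = BBIFile(signal_track.path, cache=BlockCache())
        with pytest.raises(UnknownChromosome):
            f.query("chrX", 0, 100)

    def test_bigbed_query_matches_truth(self, region_track):
        f = BBIFile(region_track.path, cache=BlockCache(),
                    column_names=("name", "score"))
        got = f.query("chr1", 0, 100_000)
        truth = region_track.intervals
        assert got["start"].tolist() == truth["start"].tolist()
        assert got["name"].tolist() == truth["name"].tolist()
        assert got["score"].tolist() == truth["score"].tolist()

    def test_zoom_records_match_generator(self, tiled_track):
        # zoom record means must equal per-base means of the raw signal
        f = BBIFile(tiled_track.path, cache=BlockCache())
        truth = tiled_track.intervals
        starts = truth["start"].to_numpy()
        values = truth["value"].to_numpy(np.float64)
        per_base = np.repeat(values, truth["end"].to_numpy() - starts)
        for zi, reduction in enumerate(tiled_track.spec.zoom_reductions):
            zoomed = f.query("chr1", 0, 100_000, zoom_index=zi)
            for _, row in zoomed.head(50).iterrows():
                window = per_base[row["start"]: row["end"]]
                assert row["valid_count"] == len(window)
                assert row["value"] == pytest.approx(window.mean(),
                                                     abs=1e-4)

    def test_truncated_file_raises_not_hangs(self, signal_track,
                                             tmp_path):
        layout = signal_track.layout
        cut = layout.data_blocks[0].offset + 2
        mutated = corrupt_fixture(signal_track.path, ("truncate", cut),
                                  str(tmp_path / "trunc.bw"))
        f = BBIFile(mutated, cache=BlockCache())
        from trackquery.errors import TrackQueryError
        with pytest.raises(TrackQueryError):
            f.query("chr1", 0, 100_000)


class TestAccessMinimality:
    def test_single_block_query_reads_only_needed_ranges(
            self, many_block_track):
        layout = many_block_track.layout
        assert len(layout.data_blocks) >= 100
        target = layout.data_blocks[5]
        f = BBIFile(many_block_track.path, cache=BlockCache())
        f.query("chr1", target.start + 1, target.start + 2)
        allowed = (layout.metadata_regions()
                   + [layout.rtree_header] + layout.rtree_nodes
                   + [(target.offset, target.size)])
        data_reads = []
        for off, ln in f.handle.fetch_log:
            assert any(off >= a and off + ln <= a + s
                       for a, s in allowed), (off, ln)
            if any(off == b.offset and ln == b.size
                   for b in layout.data_blocks):
                data_reads.append((off, ln))
        assert data_reads == [(target.offset, target.size)]
        assert f.handle.bytes_fetched < 0.05 * layout.file_size

    def test_repeat_query_zero_new_reads(self, many_block_track):
        f = BBIFile(many_block_track.path, cache=BlockCache())
        first = f.query("chr1", 1000, 2000)
        count = f.handle.fetch_count
        second = f.query("chr1", 1000, 2000)
        assert f.handle.fetch_count == count
        assert first.equals(second)


class TestPyBigWigCrossCheck:
    """Independent oracle: the same files read by libBigWig."""

    def test_intervals_agree(self, signal_track):
        pyBigWig = pytest.importorskip("pyBigWig")
        bw = pyBigWig.open(signal_track.path)
        mine = BBIFile(signal_track.path,
                       cache=BlockCache()).query("chr1", 0, 100_000)
        theirs = bw.intervals("chr1")
        assert len(theirs) == len(mine)
        for (s, e, v), (_, row) in zip(theirs, mine.iterrows()):
            assert s == row["start"] and e == row["end"]
            assert v == pytest.approx(row["value"], abs=1e-6)
        bw.close()

    def test_bigbed_entries_agree(self, region_track):
        pyBigWig = pytest.importorskip("pyBigWig")
        bb = pyBigWig.open(region_track.path)
        mine = BBIFile(region_track.path, cache=BlockCache(),
                       column_names=("name", "score")
                       ).query("chr1", 0, 100_000)
        theirs = bb.entries("chr1", 0, 100_000)
        assert len(theirs) == len(mine)
        for (s, e, rest), (_, row) in zip(theirs, mine.iterrows()):
            assert s == row["start"] and e == row["end"]
            assert rest.split("\t")[0] == row["name"]
        bb.close()
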