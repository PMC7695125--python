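"""Zoom selection, bin summarization and query orchestration."""
from concurrent.futures import ThreadPoolExecutor

import numpy as np
import pandas as pd
import pytest

from trackquery.bbi import ZoomHeader
from trackquery.core import GenomicRange, interval_frame
from trackquery.measurements import (
    Catalog,
    FileMeasurement,
    add_computed_measurement,
)
from trackquery.query_engine import (
    BinSpec,
    QueryEngine,
    bin_edges,
    bin_intervals,
    select_zoom_level,
)
from trackquery.transform import ComputeSpec

from conftest import brute_force_overlap


def zooms(*reductions):
    return [ZoomHeader(r, 0, 0) for r in reductions]


class TestZoomSelection:
    def test_browser_example_wants_12bp_per_bin(self):
        # a 10,000 bp window on an 800-pixel canvas: 12 bp per bin,
        # so pick the largest reduction not exceeding 12
        chosen = select_zoom_level(zooms(10, 40, 160), 10_000, 800)
        assert chosen == 0  # reduction 10

    def test_bins_finer_than_data_returns_none(self):
        assert select_zoom_level(zooms(10, 40), 500, 500) is None
        assert select_zoom_level(zooms(10, 40), 500, 600) is None

    def test_all_reductions_too_coarse(self):
        assert select_zoom_level(zooms(100, 400), 10_000, 800) is None

    def test_no_zoom_levels(self):
        assert select_zoom_level([], 10_000, 10) is None

    def test_picks_largest_not_exceeding(self):
        # desired 100 bp/bin: reduction 40 fits, 160 does not
        assert select_zoom_level(zooms(10, 40, 160), 100_000, 1000) == 1
        # desired 200 bp/bin: reduction 160 now fits
        assert select_zoom_level(zooms(10, 40, 160), 200_000, 1000) == 2


class TestBinning:
    def test_bins_coinciding_with_records(self):
        frame = interval_frame(chrom=["chr1"] * 2, start=[0, 10],
                               end=[10, 20], value=[1.0, 3.0])
        out = bin_intervals(frame, GenomicRange("chr1", 0, 20),
                            BinSpec(2))
        assert out["value"].tolist() == [1.0, 3.0]
        assert out["start"].tolist() == [0, 10]

    def test_weighted_mean_across_partial_overlap(self):
        frame = interval_frame(chrom=["chr1"] * 2, start=[0, 15],
                               end=[15, 20], value=[2.0, 4.0])
        out = bin_intervals(frame, GenomicRange("chr1", 0, 20),
                            BinSpec(2))
        assert out["value"].tolist() == [2.0, (2 * 5 + 4 * 5) / 10]

    def test_empty_frame_gives_all_missing(self):
        frame = interval_frame(value=())
        out = bin_intervals(frame, GenomicRange("chr1", 0, 100),
                            BinSpec(4))
        assert len(out) == 4
        assert out["value"].isna().all()

    def test_remainder_goes_to_first_bins(self):
        edges = bin_edges(GenomicRange("chr1", 0, 10), 3)
        assert np.diff(edges).tolist() == [4, 3, 3]
        assert edges[0] == 0 and edges[-1] == 10

    def test_weighted_mean_equals_per_base_oracle(self, signal_track):
        rng = np.random.default_rng(17)
        truth = signal_track.intervals
        for _ in range(50):
            s = int(rng.integers(0, 90_000))
            width = int(rng.integers(500, 9_000))
            n_bins = int(rng.integers(2, 60))
            grange = GenomicRange("chr1", s, s + width)
            sub = brute_force_overlap(truth, grange)
            out = bin_intervals(sub, grange, BinSpec(n_bins))
            assert len(out) == n_bins
            # per-base oracle
            base_vals = np.full(width, np.nan)
            for _, row in sub.iterrows():
                lo = max(int(row["start"]), s) - s
                hi = min(int(row["end"]), s + width) - s
                base_vals[lo:hi] = row["value"]
            edges = bin_edges(grange, n_bins) - s
            for b in range(n_bins):
                window = base_vals[edges[b]:edges[b + 1]]
                covered = window[~np.isnan(window)]
                got = out["value"].iloc[b]
                if len(covered) == 0:
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(covered.mean(),
                                                rel=1e-12)


class TestGetData:
    def _catalog(self, signal_track, tiled_track):
        catalog = Catalog()
        catalog.add(FileMeasurement("sig", "Signal", signal_track.path,
                                    "bigwig"))
        catalog.add(FileMeasurement("tile", "Tiled", tiled_track.path,
                                    "bigwig"))
        return catalog

    def test_raw_query_returns_unclipped_records(self, signal_track,
                                                 tiled_track):
        engine = QueryEngine(self._catalog(signal_track, tiled_track))
        grange = GenomicRange("chr1", 10_000, 30_000)
        result = engine.get_data("sig", grange)
        want = brute_force_overlap(signal_track.intervals, grange)
        assert result.frame["start"].tolist() == want["start"].tolist()
        assert result.resolution == "raw"

    def test_bins_request_returns_exact_row_count(self, signal_track,
                                                  tiled_track):
        engine = QueryEngine(self._catalog(signal_track, tiled_track))
        result = engine.get_data(
            "sig", GenomicRange("chr1", 0, 100_000), bins=1000)
        assert len(result.frame) == 1000
        assert result.frame["start"].iloc[0] == 0
        assert result.frame["end"].iloc[-1] == 100_000

    def test_zoom_used_when_it_fits(self, tiled_track):
        catalog = Catalog()
        catalog.add(FileMeasurement("t", "T", tiled_track.path,
                                    "bigwig"))
        engine = QueryEngine(catalog)
        result = engine.get_data(
            "t", GenomicRange("chr1", 0, 100_000), bins=500)
        # width/bins = 200 bp per bin; reductions (16, 64, 256): pick 64
        assert result.resolution.startswith("zoom:64")

    def test_zoom_and_raw_binning_agree_on_aligned_bins(self,
                                                        tiled_track):
        # full coverage + bin width a multiple of the reduction level
        # makes the zoom path's weighted record means equal raw means
        catalog = Catalog()
        catalog.add(FileMeasurement("t", "T", tiled_track.path,
                                    "bigwig"))
        engine = QueryEngine(catalog)
        # 96,000 bp / 125 bins = 768 bp bins = 3 whole 256 bp zoom spans
        grange = GenomicRange("chr1", 0, 96_000)
        binned = engine.get_data("t", grange, bins=125)
        assert binned.resolution.startswith("zoom:256")
        raw = engine.get_data("t", grange)
        raw_binned = bin_intervals(raw.frame, grange, BinSpec(125))
        assert np.allclose(binned.frame["value"],
                           raw_binned["value"], rtol=1e-6)

    def test_computed_binned_equals_eager_binned(self, signal_track,
                                                 tiled_track):
        catalog = self._catalog(signal_track, tiled_track)
        add_computed_measurement(
            catalog,
            ComputeSpec("mean", "Mean", ["sig", "tile"], np.mean))
        engine = QueryEngine(catalog)
        grange = GenomicRange("chr1", 20_000, 40_000)
        binned = engine.get_data("mean", grange, bins=100)
        eager = engine.get_data("mean", grange)
        eager_binned = bin_intervals(eager.frame, grange, BinSpec(100))
        assert np.allclose(binned.frame["mean"], eager_binned["mean"],
                           equal_nan=True)

    def test_concurrent_queries_equal_serial(self, signal_track,
                                             tiled_track):
        catalog = self._catalog(signal_track, tiled_track)
        add_computed_measurement(
            catalog, ComputeSpec("d", "D", ["sig", "tile"], np.diff))
        engine = QueryEngine(catalog)
        rng = np.random.default_rng(23)
        jobs = []
        for _ in range(20):
            s = int(rng.integers(0, 90_000))
            mid = ["sig", "tile", "d"][int(rng.integers(0, 3))]
            bins = int(rng.integers(10, 200)) if rng.random() < 0.5 \
                else None
            jobs.append((mid, GenomicRange("chr1", s, s + 5000), bins))
        serial = [engine.get_data(*j).frame for j in jobs]
        with ThreadPoolExecutor(max_workers=8) as pool:
            concurrent = [f.result() for f in
                          [pool.submit(engine.get_data, *j)
                           for j in jobs]]
        for a, b in zip(serial, concurrent):
            pd.testing.assert_frame_equal(a, b.frame)

    def test_cache_on_off_results_identical(self, signal_track,
                                            tiled_track):
        cat = self._catalog(signal_track, tiled_track)
        cached = QueryEngine(cat, use_cache=True)
        plain = QueryEngine(cat, use_cache=False)
        rng = np.random.default_rng(31)
        for _ in range(30):
            s = int(rng.integers(0, 90_000))
            grange = GenomicRange("chr1", s, s + 3000)
            pd.testing.assert_frame_equal(
                cached.get_data("sig", grange).frame,
                plain.get_data("sig", grange).frame)
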