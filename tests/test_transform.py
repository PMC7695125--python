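"""Interval alignment (disjoin) and computed-measurement evaluation."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from trackquery.core import GenomicRange, interval_frame
from trackquery.errors import (
    ComputeError,
    OverlapWithinSource,
    ShapeError,
    UnknownMeasurement,
)
from trackquery.transform import (
    AXIS_ACROSS,
    AXIS_ALONG,
    MISSING_DROP_ROW,
    MISSING_FILL_ZERO,
    ComputeSpec,
    apply_compute,
    disjoin,
    evaluate_computed,
)


def frame_of(intervals, chrom="chr1"):
    """[(start, end, value), ...] -> interval frame."""
    return interval_frame(
        chrom=[chrom] * len(intervals),
        start=[i[0] for i in intervals],
        end=[i[1] for i in intervals],
        value=[i[2] for i in intervals])


def per_base_expand(frame, query):
    """Oracle: per-base value vector over the query (NaN = uncovered)."""
    out = np.full(query.width, np.nan)
    for _, row in frame.iterrows():
        if row["chrom"] != query.chrom:
            continue
        s = max(int(row["start"]), query.start) - query.start
        e = min(int(row["end"]), query.end) - query.start
        if s < e:
            out[s:e] = row["value"]
    return out


class TestDisjoin:
    def test_two_overlapping_sources(self):
        a = frame_of([(0, 10, 2.0)])
        b = frame_of([(5, 15, 4.0)])
        aligned = disjoin([a, b], GenomicRange("chr1", 0, 15),
                          ["A", "B"])
        assert aligned["start"].tolist() == [0, 5, 10]
        assert aligned["end"].tolist() == [5, 10, 15]
        assert aligned["A"].tolist()[:2] == [2.0, 2.0]
        assert np.isnan(aligned["A"].iloc[2])
        assert np.isnan(aligned["B"].iloc[0])
        assert aligned["B"].tolist()[1:] == [4.0, 4.0]

    def test_single_source_identity(self):
        a = frame_of([(2, 6, 1.5), (8, 12, 2.5)])
        aligned = disjoin([a], GenomicRange("chr1", 0, 20), ["A"])
        assert aligned["start"].tolist() == [2, 8]
        assert aligned["end"].tolist() == [6, 12]
        assert aligned["A"].tolist() == [1.5, 2.5]

    def test_uncovered_gap_absent(self):
        a = frame_of([(0, 5, 1.0)])
        b = frame_of([(10, 15, 9.0)])
        aligned = disjoin([a, b], GenomicRange("chr1", 0, 15),
                          ["A", "B"])
        assert aligned["start"].tolist() == [0, 10]
        assert aligned["end"].tolist() == [5, 15]

    def test_within_source_overlap_rejected(self):
        a = frame_of([(0, 10, 1.0), (5, 15, 2.0)])
        with pytest.raises(OverlapWithinSource):
            disjoin([a], GenomicRange("chr1", 0, 20), ["A"])

    def test_per_base_oracle_on_random_tracks(self):
        rng = np.random.default_rng(11)
        query = GenomicRange("chr1", 0, 2000)
        for _ in range(20):
            frames = []
            for _ in range(3):
                pos, ivs = 0, []
                while pos < 1900:
                    ln = int(rng.integers(10, 120))
                    if rng.random() < 0.7:
                        ivs.append((pos, min(pos + ln, 2000),
                                    float(rng.integers(1, 10))))
                    pos += ln + int(rng.integers(0, 60))
                frames.append(frame_of(ivs))
            aligned = disjoin(frames, query,
                              ["s0", "s1", "s2"])
            for j, frame in enumerate(frames):
                expanded = per_base_expand(frame, query)
                rebuilt = per_base_expand(
                    aligned.rename(columns={f"s{j}": "value"})
                    [["chrom", "start", "end", "value"]], query)
                covered = ~np.isnan(expanded)
                assert np.array_equal(expanded[covered],
                                      rebuilt[covered])
            # rows must be disjoint and sorted
            assert (aligned["start"].to_numpy()[1:]
                    >= aligned["end"].to_numpy()[:-1]).all()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.integers(0, 90), st.integers(1, 30),
                  st.floats(0, 100, allow_nan=False, width=32)),
        min_size=0, max_size=8))
    def test_partition_covers_exactly_the_source_union(self, raw):
        # build one non-overlapping source from possibly messy intervals
        ivs, cursor = [], 0
        for s, ln, v in sorted(raw):
            start = max(s, cursor)
            ivs.append((start, start + ln, float(np.float32(v))))
            cursor = start + ln
        frame = frame_of(ivs)
        query = GenomicRange("chr1", 0, 150)
        aligned = disjoin([frame], query, ["A"])
        expanded = per_base_expand(frame, query)
        rebuilt = per_base_expand(
            aligned.rename(columns={"A": "value"}), query)
        assert np.array_equal(np.isnan(expanded), np.isnan(rebuilt))
        mask = ~np.isnan(expanded)
        assert np.array_equal(expanded[mask], rebuilt[mask])


class TestApplyCompute:
    def _aligned(self):
        a = frame_of([(0, 10, 2.0)])
        b = frame_of([(5, 15, 4.0)])
        return disjoin([a, b], GenomicRange("chr1", 0, 15), ["A", "B"])

    def test_row_wise_difference_propagates_missing(self):
        spec = ComputeSpec("diff", "Diff", ["A", "B"], np.diff)
        out = apply_compute(self._aligned(), spec)
        vals = out["diff"].tolist()
        assert np.isnan(vals[0]) and vals[1] == 2.0 and np.isnan(vals[2])

    def test_drop_row_policy(self):
        spec = ComputeSpec("diff", "Diff", ["A", "B"], np.diff,
                           missing_policy=MISSING_DROP_ROW)
        out = apply_compute(self._aligned(), spec)
        assert out["start"].tolist() == [5]
        assert out["diff"].tolist() == [2.0]

    def test_fill_zero_policy(self):
        spec = ComputeSpec("diff", "Diff", ["A", "B"], np.diff,
                           missing_policy=MISSING_FILL_ZERO)
        out = apply_compute(self._aligned(), spec)
        assert out["diff"].tolist() == [-2.0, 2.0, 4.0]

    def test_mean_centering_along_rows(self):
        aligned = interval_frame(
            chrom=["chr1"] * 3, start=[0, 10, 20], end=[10, 20, 30],
            A=[1.0, 2.0, 3.0])
        spec = ComputeSpec("norm", "Norm", ["A"],
                           lambda col: col - np.mean(col),
                           axis=AXIS_ALONG)
        out = apply_compute(aligned, spec)
        assert out["A"].tolist() == [-1.0, 0.0, 1.0]

    def test_raising_func_names_the_spec(self):
        def bad(_):
            raise RuntimeError("boom")
        spec = ComputeSpec("myspec", "Bad", ["A", "B"], bad)
        with pytest.raises(ComputeError, match="myspec"):
            apply_compute(self._aligned(), spec)

    def test_arity_violation_raises_shape_error(self):
        calls = {"n": 0}

        def flaky(vec):
            calls["n"] += 1
            return np.zeros(1 if calls["n"] == 1 else 3)
        spec = ComputeSpec("flaky", "Flaky", ["A", "B"], flaky,
                           missing_policy=MISSING_FILL_ZERO)
        with pytest.raises(ShapeError):
            apply_compute(self._aligned(), spec)

    def test_along_rows_wrong_length_raises(self):
        aligned = interval_frame(chrom=["chr1"] * 2, start=[0, 10],
                                 end=[10, 20], A=[1.0, 2.0])
        spec = ComputeSpec("s", "S", ["A"], lambda col: col[:1],
                           axis=AXIS_ALONG)
        with pytest.raises(ShapeError):
            apply_compute(aligned, spec)


class TestEvaluateComputed:
    def _catalog_fetch(self, frames):
        def fetch(source_id, query):
            return frames[source_id]
        return fetch

    def test_lazy_equals_eager(self):
        rng = np.random.default_rng(5)
        frames = {}
        for sid in ("x", "y", "z"):
            ivs, pos = [], 0
            while pos < 900:
                ln = int(rng.integers(20, 100))
                ivs.append((pos, pos + ln, float(rng.integers(1, 20))))
                pos += ln + int(rng.integers(0, 50))
            frames[sid] = frame_of(ivs)
        spec = ComputeSpec("m", "Mean", ["x", "y", "z"], np.mean)
        query = GenomicRange("chr1", 0, 1000)
        lazy = evaluate_computed(spec, self._catalog_fetch(frames),
                                 query)
        eager_aligned = disjoin([frames["x"], frames["y"], frames["z"]],
                                query, ["x", "y", "z"])
        eager = apply_compute(eager_aligned, spec)
        pd.testing.assert_frame_equal(lazy, eager)

    def test_identity_over_one_source(self):
        frames = {"only": frame_of([(0, 10, 3.0), (20, 30, 4.0)])}
        spec = ComputeSpec("id", "Identity", ["only"],
                           lambda v: v)
        out = evaluate_computed(spec, self._catalog_fetch(frames),
                                GenomicRange("chr1", 0, 40))
        assert out["start"].tolist() == [0, 20]
        assert out["id"].tolist() == [3.0, 4.0]

    def test_completion_order_never_changes_result(self):
        import time
        frames = {"a": frame_of([(0, 10, 1.0)]),
                  "b": frame_of([(0, 10, 2.0)]),
                  "c": frame_of([(0, 10, 3.0)])}
        delays = {"a": 0.03, "b": 0.0, "c": 0.015}

        def slow_fetch(sid, query):
            time.sleep(delays[sid])
            return frames[sid]
        spec = ComputeSpec("d", "D", ["a", "b", "c"], np.diff)
        fast = evaluate_computed(spec, self._catalog_fetch(frames),
                                 GenomicRange("chr1", 0, 10))
        slow = evaluate_computed(spec, slow_fetch,
                                 GenomicRange("chr1", 0, 10))
        pd.testing.assert_frame_equal(fast, slow)

    def test_source_error_is_annotated(self):
        def fetch(sid, query):
            raise UnknownMeasurement(f"no such source")
        spec = ComputeSpec("d", "D", ["p", "q"], np.diff)
        with pytest.raises(UnknownMeasurement, match="'p'"):
            evaluate_computed(spec, fetch, GenomicRange("chr1", 0, 10))
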