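"""Interval alignment and lazily computed measurements.

Applying a function *across* tracks that carry different intervals first
requires a common partition: ``disjoin`` cuts the query range at every
record boundary of every source, producing disjoint rows within which
each source's value is constant. A :class:`ComputeSpec` then names a
transformation over the aligned columns; it is never precomputed — each
query aligns the freshly fetched source frames and applies the function
to exactly the region asked for.
"""
from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import GenomicRange, interval_frame
from .errors import (
    ComputeError,
    OverlapWithinSource,
    ShapeError,
    UnknownMeasurement,
)

AXIS_ACROSS = "across_measurements"   # row-wise over the k source values
AXIS_ALONG = "along_rows"             # column-wise over the whole column

MISSING_PROPAGATE = "propagate"
MISSING_DROP_ROW = "drop_row"
MISSING_FILL_ZERO = "fill_zero"


@dataclass
class ComputeSpec:
    """A named, lazy transformation over ordered source measurements.

    ``func`` follows a NumPy-style contract: for ``across_measurements``
    it maps the length-k vector of source values in one aligned row to a
    scalar (or fixed-m vector, e.g. ``numpy.diff``); for ``along_rows``
    it maps a whole column of length n to a length-n column (e.g. mean
    centering).
    """

    id: str
    name: str
    source_ids: Sequence[str]
    func: Callable
    axis: str = AXIS_ACROSS
    missing_policy: str = MISSING_PROPAGATE
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.source_ids:
            raise ValueError(f"computed measurement {self.id!r} needs at "
                             "least one source")
        if self.axis not in (AXIS_ACROSS, AXIS_ALONG):
            raise ValueError(f"unknown axis {self.axis!r}")
        if self.missing_policy not in (MISSING_PROPAGATE, MISSING_DROP_ROW,
                                       MISSING_FILL_ZERO):
            raise ValueError(
                f"unknown missing policy {self.missing_policy!r}")


def _clip_and_check(frame: pd.DataFrame, query: GenomicRange,
                    source_id: str) -> tuple[np.ndarray, np.ndarray,
                                             np.ndarray]:
    """Clip one source's records into the query; reject internal overlaps."""
    mask = ((frame["chrom"] == query.chrom)
            & (frame["start"] < query.end) & (frame["end"] > query.start))
    sub = frame.loc[mask]
    starts = np.maximum(sub["start"].to_numpy(np.int64), query.start)
    ends = np.minimum(sub["end"].to_numpy(np.int64), query.end)
    if "value" in sub.columns:
        values = sub["value"].to_numpy(np.float64)
    else:
        # first numeric value column, else all-ones occupancy
        numeric = [c for c in sub.columns
                   if c not in ("chrom", "start", "end")
                   and pd.api.types.is_numeric_dtype(sub[c])]
        values = (sub[numeric[0]].to_numpy(np.float64) if numeric
                  else np.ones(len(sub)))
    order = np.argsort(starts, kind="stable")
    starts, ends, values = starts[order], ends[order], values[order]
    if len(starts) > 1 and np.any(starts[1:] < ends[:-1]):
        raise OverlapWithinSource(
            f"source {source_id!r} has internally overlapping records in "
            f"{query}")
    return starts, ends, values


def disjoin(frames: Sequence[pd.DataFrame], query: GenomicRange,
            source_ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Align source frames onto the common disjoint partition of ``query``.

    Output rows are the maximal sub-intervals between consecutive record
    boundaries (clipped into the query) covered by at least one source;
    cell ``(row, source)`` holds the covering record's value, else NaN.
    """
    if source_ids is None:
        source_ids = [f"source{i}" for i in range(len(frames))]
    clipped = [_clip_and_check(f, query, sid)
               for f, sid in zip(frames, source_ids)]
    cuts = [np.array([query.start, query.end], dtype=np.int64)]
    for starts, ends, _ in clipped:
        cuts.append(starts)
        cuts.append(ends)
    edges = np.unique(np.concatenate(cuts))
    seg_start = edges[:-1]
    seg_end = edges[1:]
    n_seg = len(seg_start)
    columns = np.full((n_seg, len(frames)), np.nan)
    covered = np.zeros(n_seg, dtype=bool)
    for j, (starts, ends, values) in enumerate(clipped):
        if len(starts) == 0:
            continue
        # every segment lies fully inside or outside each record, because
        # edges include all record boundaries
        idx = np.searchsorted(starts, seg_start, side="right") - 1
        valid = (idx >= 0) & (seg_end <= ends[np.clip(idx, 0, None)])
        columns[valid, j] = values[idx[valid]]
        covered |= valid
    keep = covered
    out = interval_frame(
        chrom=[query.chrom] * int(keep.sum()),
        start=seg_start[keep], end=seg_end[keep])
    for j, sid in enumerate(source_ids):
        out[sid] = columns[keep, j]
    return out


def _apply_missing_policy(matrix: np.ndarray, policy: str
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Returns (matrix, row_keep_mask)."""
    keep = np.ones(matrix.shape[0], dtype=bool)
    if policy == MISSING_FILL_ZERO:
        matrix = np.nan_to_num(matrix, nan=0.0)
    elif policy == MISSING_DROP_ROW:
        keep = ~np.isnan(matrix).any(axis=1)
        matrix = matrix[keep]
    return matrix, keep


def apply_compute(aligned: pd.DataFrame, spec: ComputeSpec) -> pd.DataFrame:
    """Apply a compute spec to an aligned frame.

    ``across_measurements``: ``func`` is applied per row to the length-k
    vector of source values; the declared output arity is fixed by the
    first row and enforced on the rest. ``along_rows``: ``func`` maps
    each source column (length n) to a length-n column.
    """
    source_cols = [c for c in aligned.columns
                   if c not in ("chrom", "start", "end")]
    if list(source_cols) != list(spec.source_ids):
        # allow positional match when disjoin used default names
        if len(source_cols) != len(spec.source_ids):
            raise ShapeError(
                f"aligned frame has {len(source_cols)} source columns, "
                f"spec {spec.id!r} expects {len(spec.source_ids)}")
    matrix = aligned[source_cols].to_numpy(np.float64)
    matrix, keep = _apply_missing_policy(matrix, spec.missing_policy)
    coords = aligned.loc[keep, ["chrom", "start", "end"]]
    n = matrix.shape[0]

    def call(vec: np.ndarray):
        try:
            return spec.func(vec)
        except Exception as exc:
            raise ComputeError(
                f"computed measurement {spec.id!r} raised: {exc}") from exc

    if spec.axis == AXIS_ACROSS:
        outputs = []
        arity = None
        for i in range(n):
            res = np.atleast_1d(np.asarray(call(matrix[i]),
                                           dtype=np.float64))
            if arity is None:
                arity = res.shape[0]
            elif res.shape[0] != arity:
                raise ShapeError(
                    f"computed measurement {spec.id!r}: row {i} produced "
                    f"{res.shape[0]} values, expected {arity}")
            outputs.append(res)
        arity = arity if arity is not None else 1
        stacked = (np.vstack(outputs) if outputs
                   else np.empty((0, arity)))
        out = coords.reset_index(drop=True)
        if arity == 1:
            out[spec.id] = stacked[:, 0] if n else np.array([])
        else:
            for m in range(arity):
                out[f"{spec.id}_{m}"] = stacked[:, m]
        return out
    # along_rows: per-column whole-vector transform
    out = coords.reset_index(drop=True)
    for j, col in enumerate(source_cols):
        res = np.asarray(call(matrix[:, j]), dtype=np.float64).ravel()
        if res.shape[0] != n:
            raise ShapeError(
                f"computed measurement {spec.id!r}: column {col!r} "
                f"transform returned {res.shape[0]} values for {n} rows")
        out[col] = res
    return out


def evaluate_computed(spec: ComputeSpec, fetch: Callable,
                      query: GenomicRange,
                      max_workers: int = 4) -> pd.DataFrame:
    """Fetch sources (concurrently), align, and apply the transformation.

    ``fetch(source_id, query)`` must return the source's raw interval
    frame; results are assembled by source position, so completion order
    can never change the answer.
    """
    source_ids = list(spec.source_ids)
    if len(source_ids) == 1:
        frames = [fetch(source_ids[0], query)]
    else:
        with ThreadPoolExecutor(max_workers=max_workers) as pool:
            futures = [pool.submit(fetch, sid, query)
                       for sid in source_ids]
            frames = []
            for sid, fut in zip(source_ids, futures):
                try:
                    frames.append(fut.result())
                except (ComputeError, ShapeError, OverlapWithinSource):
                    raise
                except Exception as exc:
                    try:
                        annotated = type(exc)(f"source {sid!r}: {exc}")
                    except Exception:
                        annotated = exc
                    raise annotated from exc
    aligned = disjoin(frames, query, source_ids)
    return apply_compute(aligned, spec)
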