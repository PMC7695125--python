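"""Resolution-aware query orchestration.

``get_data(measurement, range, bins)`` routes a request through zoom
selection, raw or zoom-level file queries, computed-measurement
evaluation and bin summarization. Binning targets genome-browser
rendering: a track drawn into *b* screen bins only needs *b* values, so
when a BigWig carries zoom levels the engine picks the one whose
reduction (bp per zoom bin) is the largest not exceeding
``range_width // bins``, then summarizes to exactly ``bins``
coverage-weighted means.
"""
from __future__ import annotations

import threading
import time
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .bbi import BBIFile, ZoomHeader
from .core import GenomicRange, interval_frame, value_columns
from .errors import UnknownMeasurement
from .measurements import (
    Catalog,
    FileMeasurement,
    GeneIndex,
    GenomeAnnotation,
)
from .range_io import DEFAULT_CACHE_BYTES, BlockCache
from .tabix import TabixFile
from .transform import ComputeSpec, evaluate_computed


@dataclass
class BinSpec:
    n_bins: int
    aggregator: str = "mean"

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError(f"n_bins must be >= 1, got {self.n_bins}")
        if self.aggregator != "mean":
            raise ValueError(f"unsupported aggregator {self.aggregator!r}")


@dataclass
class QueryResult:
    measurement_id: str
    range: GenomicRange
    frame: pd.DataFrame
    resolution: str          # "raw" | "zoom:<reduction>" (+ ":binned:<n>")
    timing_ms: float = 0.0


def select_zoom_level(zoom_headers: list[ZoomHeader], range_width: int,
                      n_bins: int) -> Optional[int]:
    """Index of the zoom level to read for a binned query, or ``None``.

    The desired resolution is ``floor(range_width / n_bins)`` bp per bin
    (a 10,000 bp window on 800 pixels wants ~12 bp per bin); we take the
    level with the largest reduction not exceeding it, falling back to
    raw data when even the finest level is too coarse.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    desired = range_width // n_bins
    best: Optional[int] = None
    for i, zh in enumerate(zoom_headers):
        if zh.reduction_level <= desired:
            if best is None or (zh.reduction_level
                                > zoom_headers[best].reduction_level):
                best = i
    return best


def bin_edges(rng: GenomicRange, n_bins: int) -> np.ndarray:
    """Split ``rng`` into ``n_bins`` near-equal half-open bins; the first
    ``width % n_bins`` bins get one extra base."""
    width = rng.width
    base = width // n_bins
    rem = width % n_bins
    sizes = np.full(n_bins, base, dtype=np.int64)
    sizes[:rem] += 1
    return rng.start + np.concatenate(([0], np.cumsum(sizes)))


def bin_intervals(frame: pd.DataFrame, rng: GenomicRange,
                  spec: Union[BinSpec, int]) -> pd.DataFrame:
    """Summarize records into coverage-weighted per-bin means.

    Each bin's value is the mean over covered bases (weight = overlap
    bp), which equals the per-base mean; bins with zero coverage carry
    NaN. Output has exactly ``n_bins`` rows partitioning the range.
    """
    if isinstance(spec, int):
        spec = BinSpec(spec)
    n = spec.n_bins
    edges = bin_edges(rng, n)
    # valid_count is zoom-record plumbing, not a signal column
    cols = [c for c in value_columns(frame)
            if pd.api.types.is_numeric_dtype(frame[c])
            and c != "valid_count"]
    out = interval_frame(chrom=[rng.chrom] * n, start=edges[:-1],
                         end=edges[1:])
    sub = frame.loc[(frame["chrom"] == rng.chrom)
                    & (frame["start"] < rng.end)
                    & (frame["end"] > rng.start)]
    starts = np.maximum(sub["start"].to_numpy(np.int64), rng.start)
    ends = np.minimum(sub["end"].to_numpy(np.int64), rng.end)
    for col in cols:
        values = sub[col].to_numpy(np.float64)
        sums = np.zeros(n)
        weights = np.zeros(n)
        for s, e, v in zip(starts, ends, values):
            if not np.isfinite(v):
                continue  # e.g. zoom record with zero valid bases
            b0 = np.searchsorted(edges, s, side="right") - 1
            b1 = np.searchsorted(edges, e, side="left") - 1
            b0 = max(b0, 0)
            b1 = min(b1, n - 1)
            if b0 == b1:
                w = e - s
                sums[b0] += v * w
                weights[b0] += w
            else:
                span = np.arange(b0, b1 + 1)
                lo = np.maximum(edges[span], s)
                hi = np.minimum(edges[span + 1], e)
                w = (hi - lo).astype(np.float64)
                np.add.at(sums, span, v * w)
                np.add.at(weights, span, w)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(weights > 0, sums / weights, np.nan)
        out[col] = mean
    return out


class QueryEngine:
    """Runtime state over a catalog: block cache plus lazily opened files."""

    def __init__(self, catalog: Catalog,
                 cache_bytes: int = DEFAULT_CACHE_BYTES,
                 max_workers: int = 4,
                 use_cache: bool = True) -> None:
        self.catalog = catalog
        self.cache = BlockCache(cache_bytes) if use_cache else None
        self.max_workers = max_workers
        self._files: dict[str, Union[BBIFile, TabixFile]] = {}
        self._gene_indexes: dict[str, GeneIndex] = {}
        self._lock = threading.RLock()  # gene_lookup re-enters via _file

    # -- file management ---------------------------------------------------
    def open_count(self) -> int:
        return len(self._files)

    def _file(self, entry) -> Union[BBIFile, TabixFile]:
        with self._lock:
            existing = self._files.get(entry.id)
            if existing is not None:
                return existing
            schema = getattr(entry, "column_schema", None)
            if getattr(entry, "format", None) in ("bigwig", "bigbed"):
                obj: Union[BBIFile, TabixFile] = BBIFile(
                    entry.uri, cache=self.cache, column_names=schema)
            else:
                obj = TabixFile(entry.uri, cache=self.cache,
                                column_names=schema)
            self._files[entry.id] = obj
            return obj

    def handles(self):
        """Open resource handles (for fetch accounting in tests)."""
        out = []
        for obj in self._files.values():
            h = getattr(obj, "_handle", None) or getattr(
                obj, "_data_handle", None)
            if h is not None:
                out.append(h)
        return out

    # -- queries -----------------------------------------------------------
    def get_data(self, measurement_id: str, rng: GenomicRange,
                 bins: Optional[int] = None) -> QueryResult:
        """Query a measurement, optionally summarized to ``bins`` rows.

        File measurements use a zoom level when one fits the requested
        resolution; computed measurements are evaluated on raw-resolution
        aligned rows and binned afterwards. Without ``bins`` the raw
        overlapping records are returned unclipped.
        """
        t0 = time.perf_counter()
        entry = self.catalog[measurement_id]
        if isinstance(entry, ComputeSpec):
            frame = evaluate_computed(
                entry, lambda sid, q: self.get_data(sid, q).frame, rng,
                self.max_workers)
            resolution = "raw"
        elif isinstance(entry, (FileMeasurement, GenomeAnnotation)):
            obj = self._file(entry)
            if (isinstance(obj, BBIFile) and bins is not None
                    and bins < rng.width):
                obj._ensure_meta()
                zoom = select_zoom_level(obj.zoom_headers, rng.width,
                                         bins)
            else:
                zoom = None
            if isinstance(obj, BBIFile):
                frame = obj.query(rng.chrom, rng.start, rng.end,
                                  zoom_index=zoom)
            else:
                frame = obj.query(rng.chrom, rng.start, rng.end)
            resolution = ("raw" if zoom is None else
                          f"zoom:{obj.zoom_headers[zoom].reduction_level}")
        else:  # pragma: no cover - catalog enforces entry types
            raise UnknownMeasurement(
                f"{measurement_id!r} has unsupported type "
                f"{type(entry).__name__}")
        if bins is not None:
            frame = bin_intervals(frame, rng, BinSpec(bins))
            resolution += f":binned:{bins}"
        return QueryResult(
            measurement_id=measurement_id, range=rng, frame=frame,
            resolution=resolution,
            timing_ms=(time.perf_counter() - t0) * 1e3)

    def gene_lookup(self, genome_id: str, gene_name: str) -> GenomicRange:
        entry = self.catalog[genome_id]
        if not isinstance(entry, GenomeAnnotation):
            raise UnknownMeasurement(
                f"{genome_id!r} is not a genome annotation")
        with self._lock:
            gi = self._gene_indexes.get(genome_id)
            if gi is None:
                gi = GeneIndex(entry, self._file(entry))
                self._gene_indexes[genome_id] = gi
        return gi.lookup(gene_name)

    def close(self) -> None:
        for obj in self._files.values():
            obj.close()
        self._files.clear()


def get_data(catalog: Catalog, measurement_id: str, rng: GenomicRange,
             bins: Optional[int] = None,
             engine: Optional[QueryEngine] = None) -> QueryResult:
    """One-shot convenience wrapper (creates a transient engine)."""
    own = engine is None
    engine = engine or QueryEngine(catalog)
    try:
        return engine.get_data(measurement_id, rng, bins)
    finally:
        if own:
            engine.close()
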