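"""Seeded synthetic track generators with fully recorded ground truth.

Every generator is deterministic in its seed and returns a
:class:`GroundTruth` holding the exact interval list it wrote, so round
trips through the parsers can be checked bit-for-bit. Signal shapes
emulate genome-browser data: uniform tiles (methylation-like), sparse
random intervals (bedGraph coverage), and Poisson-placed peaks with
triangular summits (ChIP-seq-like). Values are quantized to quarters so
they are exact in 32-bit floats and zoom sums stay exact.

BigWig/BigBed writing uses this package's own layout-recording writer;
Tabix indexing of tabular tracks delegates to pysam (htslib), keeping
the index creation independent of the query code under test.
"""
from __future__ import annotations

import os
import shutil
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import pysam

from ..core import interval_frame, sort_frame
from ..errors import GenerationError
from .bbi_writer import FileLayout, write_bigbed, write_bigwig

MODELS = ("tiled_fixed_step", "random_intervals", "peaks")


@dataclass
class SyntheticTrackSpec:
    seed: int
    chrom_sizes: dict[str, int]
    model: str = "random_intervals"
    # interval-length / placement parameters
    step: int = 100                  # tiled_fixed_step tile width
    n_intervals: int = 200           # random_intervals count per chrom
    min_len: int = 20
    max_len: int = 200
    min_gap: int = 0
    max_gap: int = 100
    n_peaks: int = 50                # peaks per chrom
    peak_halfwidth: int = 500
    # value distribution: quantized to quarters for float32 exactness
    value_low: float = 0.0
    value_high: float = 16.0
    zoom: bool = False
    zoom_reductions: tuple = (16, 64, 256)
    compress: bool = True
    items_per_slot: int = 64
    rtree_block_size: int = 8
    section_type: Optional[int] = None  # default chosen per model

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise GenerationError(f"unknown model {self.model!r}")
        if not self.chrom_sizes:
            raise GenerationError("chrom_sizes is empty")


@dataclass
class GroundTruth:
    """What a generated file truly contains."""

    intervals: pd.DataFrame          # interval frame over all chroms
    path: str
    layout: Optional[FileLayout] = None
    spec: Optional[SyntheticTrackSpec] = None
    extra: dict = field(default_factory=dict)


def _quantize(values: np.ndarray) -> np.ndarray:
    return (np.round(values * 4.0) / 4.0).astype(np.float32)


def _gen_intervals(spec: SyntheticTrackSpec,
                   rng: np.random.Generator,
                   chrom: str, length: int) -> np.ndarray:
    """Non-overlapping sorted (start, end, value) records for one chrom."""
    dtype = np.dtype([("start", np.int64), ("end", np.int64),
                      ("value", np.float32)])
    if spec.model == "tiled_fixed_step":
        starts = np.arange(0, length - spec.step + 1, spec.step,
                           dtype=np.int64)
        ends = starts + spec.step
        values = _quantize(rng.uniform(spec.value_low, spec.value_high,
                                       len(starts)))
    elif spec.model == "random_intervals":
        starts, ends = [], []
        pos = int(rng.integers(0, spec.max_gap + 1))
        for _ in range(spec.n_intervals):
            ln = int(rng.integers(spec.min_len, spec.max_len + 1))
            if pos + ln > length:
                break
            starts.append(pos)
            ends.append(pos + ln)
            pos += ln + int(rng.integers(spec.min_gap, spec.max_gap + 1))
        starts = np.array(starts, dtype=np.int64)
        ends = np.array(ends, dtype=np.int64)
        values = _quantize(rng.uniform(spec.value_low, spec.value_high,
                                       len(starts)))
    else:  # peaks: triangular summits, run-length encoded per base
        signal = np.zeros(length, dtype=np.float64)
        n = rng.poisson(spec.n_peaks)
        centers = np.sort(rng.integers(spec.peak_halfwidth,
                                       max(length - spec.peak_halfwidth,
                                           spec.peak_halfwidth + 1),
                                       max(n, 1)))
        heights = rng.uniform(spec.value_high / 2, spec.value_high,
                              len(centers))
        for c, h in zip(centers, heights):
            w = spec.peak_halfwidth
            lo, hi = max(0, c - w), min(length, c + w)
            x = np.arange(lo, hi)
            signal[lo:hi] = np.maximum(
                signal[lo:hi], h * (1 - np.abs(x - c) / w))
        quant = np.round(signal * 4.0) / 4.0
        # run-length encode nonzero stretches
        change = np.flatnonzero(np.diff(quant) != 0) + 1
        bounds = np.concatenate(([0], change, [length]))
        starts_l, ends_l, vals_l = [], [], []
        for s, e in zip(bounds[:-1], bounds[1:]):
            if quant[s] != 0:
                starts_l.append(s)
                ends_l.append(e)
                vals_l.append(quant[s])
        starts = np.array(starts_l, dtype=np.int64)
        ends = np.array(ends_l, dtype=np.int64)
        values = np.array(vals_l, dtype=np.float32)
    out = np.empty(len(starts), dtype=dtype)
    out["start"], out["end"], out["value"] = starts, ends, values
    return out


def _truth_frame(per_chrom: dict[str, np.ndarray]) -> pd.DataFrame:
    frames = []
    for chrom in sorted(per_chrom):
        arr = per_chrom[chrom]
        frames.append(interval_frame(
            chrom=[chrom] * len(arr), start=arr["start"],
            end=arr["end"], value=arr["value"].astype(np.float32)))
    if not frames:
        return interval_frame(value=())
    return sort_frame(pd.concat(frames, ignore_index=True))


def make_signal_track(spec: SyntheticTrackSpec, path: str) -> GroundTruth:
    """Write a BigWig for ``spec``; deterministic in ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    per_chrom = {
        chrom: _gen_intervals(spec, rng, chrom, length)
        for chrom, length in sorted(spec.chrom_sizes.items())
    }
    section_type = spec.section_type or (
        3 if spec.model == "tiled_fixed_step" else 1)
    layout = write_bigwig(
        path, spec.chrom_sizes, per_chrom,
        section_type=section_type, items_per_slot=spec.items_per_slot,
        compress=spec.compress,
        zoom_reductions=spec.zoom_reductions if spec.zoom else (),
        rtree_block_size=spec.rtree_block_size)
    return GroundTruth(intervals=_truth_frame(per_chrom), path=path,
                       layout=layout, spec=spec,
                       extra={"per_chrom": per_chrom})


def make_region_track(spec: SyntheticTrackSpec, path: str) -> GroundTruth:
    """Write a BigBed of named, scored regions (peaks-style)."""
    rng = np.random.default_rng(spec.seed)
    records_by_chrom: dict[str, list] = {}
    frames = []
    counter = 0
    for chrom, length in sorted(spec.chrom_sizes.items()):
        arr = _gen_intervals(spec, rng, chrom, length)
        recs = []
        names, scores = [], []
        for s, e, v in zip(arr["start"], arr["end"], arr["value"]):
            name = f"peak{counter}"
            score = int(min(1000, round(float(v) * 60)))
            recs.append((int(s), int(e), f"{name}\t{score}"))
            names.append(name)
            scores.append(score)
            counter += 1
        records_by_chrom[chrom] = recs
        frames.append(interval_frame(
            chrom=[chrom] * len(arr), start=arr["start"],
            end=arr["end"], name=names,
            score=np.array(scores, dtype=np.int64)))
    layout = write_bigbed(path, spec.chrom_sizes, records_by_chrom,
                          field_count=5,
                          items_per_slot=spec.items_per_slot,
                          compress=spec.compress,
                          rtree_block_size=spec.rtree_block_size)
    truth = sort_frame(pd.concat(frames, ignore_index=True)) if frames \
        else interval_frame(name=(), score=())
    return GroundTruth(intervals=truth, path=path, layout=layout,
                       spec=spec,
                       extra={"records_by_chrom": records_by_chrom})


def make_tabular_track(spec: SyntheticTrackSpec, path: str,
                       zero_based: bool = True) -> GroundTruth:
    """Write a BGZF+Tabix tab-delimited table (bedGraph-like).

    ``zero_based=False`` writes 1-based inclusive coordinates and indexes
    them with the matching preset; ground truth is always normalized to
    0-based half-open.
    """
    rng = np.random.default_rng(spec.seed)
    per_chrom = {
        chrom: _gen_intervals(spec, rng, chrom, length)
        for chrom, length in sorted(spec.chrom_sizes.items())
    }
    plain = path + ".tsv"
    with open(plain, "w", encoding="utf-8") as fh:
        for chrom in sorted(per_chrom):
            for s, e, v in per_chrom[chrom]:
                if zero_based:
                    fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{float(v)}\n")
                else:
                    fh.write(f"{chrom}\t{int(s) + 1}\t{int(e)}\t"
                             f"{float(v)}\n")
    pysam.tabix_compress(plain, path, force=True)
    os.unlink(plain)
    pysam.tabix_index(path, force=True, seq_col=0, start_col=1,
                      end_col=2, zerobased=zero_based)
    return GroundTruth(intervals=_truth_frame(per_chrom), path=path,
                       spec=spec, extra={"index": path + ".tbi",
                                         "zero_based": zero_based})


def make_gene_annotation(path: str, genes: list[tuple],
                         zero_based: bool = True) -> GroundTruth:
    """Write a Tabix-indexed gene table from (chrom, start, end, name,
    strand) tuples (0-based half-open input)."""
    genes = sorted(genes, key=lambda g: (g[0], g[1], g[2]))
    plain = path + ".tsv"
    with open(plain, "w", encoding="utf-8") as fh:
        for chrom, s, e, name, strand in genes:
            start_out = s if zero_based else s + 1
            fh.write(f"{chrom}\t{start_out}\t{e}\t{name}\t{strand}\n")
    pysam.tabix_compress(plain, path, force=True)
    os.unlink(plain)
    pysam.tabix_index(path, force=True, seq_col=0, start_col=1,
                      end_col=2, zerobased=zero_based)
    truth = interval_frame(
        chrom=[g[0] for g in genes], start=[g[1] for g in genes],
        end=[g[2] for g in genes], gene=[g[3] for g in genes],
        strand=[g[4] for g in genes])
    return GroundTruth(intervals=truth, path=path,
                       extra={"index": path + ".tbi"})


def corrupt_fixture(path: str, mutation: tuple, out_path: str) -> str:
    """Mutated copy of a fixture: ``("flip", offset)`` XORs one byte,
    ``("truncate", n)`` keeps only the first n bytes."""
    kind = mutation[0]
    with open(path, "rb") as fh:
        data = bytearray(fh.read())
    if kind == "flip":
        offset = mutation[1]
        data[offset] ^= 0xFF
    elif kind == "truncate":
        data = data[: mutation[1]]
    else:
        raise GenerationError(f"unknown mutation {kind!r}")
    with open(out_path, "wb") as fh:
        fh.write(bytes(data))
    return out_path


def precomputed_mean_track(truths: list[GroundTruth], chrom_sizes,
                           path: str, compress: bool = True
                           ) -> GroundTruth:
    """Eagerly build the mean-signal track over several ground truths.

    Mirrors an analyst precomputing a summary with external tooling: the
    per-base mean over sources covering each base, run-length encoded and
    written as a BigWig. Serves as the oracle for lazy computed
    measurements.
    """
    per_chrom: dict[str, np.ndarray] = {}
    dtype = np.dtype([("start", np.int64), ("end", np.int64),
                      ("value", np.float32)])
    for chrom, length in sorted(chrom_sizes.items()):
        acc = np.zeros(length, dtype=np.float64)
        cov = np.zeros(length, dtype=np.int32)
        for truth in truths:
            sub = truth.intervals[truth.intervals["chrom"] == chrom]
            for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
                acc[s:e] += float(v)
                cov[s:e] += 1
        covered = cov > 0
        mean = np.zeros(length)
        mean[covered] = acc[covered] / cov[covered]
        mean32 = mean.astype(np.float32)
        boundary = np.flatnonzero(
            (np.diff(mean32) != 0) | (np.diff(covered.astype(np.int8))
                                      != 0)) + 1
        bounds = np.concatenate(([0], boundary, [length]))
        starts, ends, vals = [], [], []
        for s, e in zip(bounds[:-1], bounds[1:]):
            if covered[s]:
                starts.append(s)
                ends.append(e)
                vals.append(mean32[s])
        arr = np.empty(len(starts), dtype=dtype)
        arr["start"], arr["end"], arr["value"] = starts, ends, vals
        per_chrom[chrom] = arr
    layout = write_bigwig(path, dict(chrom_sizes), per_chrom,
                          section_type=1, compress=compress)
    return GroundTruth(intervals=_truth_frame(per_chrom), path=path,
                       layout=layout, extra={"per_chrom": per_chrom})
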