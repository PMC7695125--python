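"""Shared coordinate types and the interval-frame convention.

All coordinates in this library are 0-based half-open ``[start, end)``.
Query results are plain :class:`pandas.DataFrame` objects ("interval
frames") with leading columns ``chrom`` (str), ``start`` and ``end``
(int64), followed by one column per value vector. Rows are sorted by
``(chrom, start, end)``; the missing marker is ``NaN``.
"""
from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Missing-value marker used in interval frames and aligned frames.
MISSING = float("nan")

_RANGE_RE = re.compile(r"^([^:]+):([0-9,]+)-([0-9,]+)$")


@dataclass(frozen=True)
class GenomicRange:
    """A chromosome plus a 0-based half-open coordinate pair."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty range: start={self.start} end={self.end}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @classmethod
    def parse(cls, text: str) -> "GenomicRange":
        """Parse ``chrom:start-end`` (commas in numbers allowed)."""
        m = _RANGE_RE.match(text.strip())
        if m is None:
            raise ValueError(
                f"malformed range {text!r}; expected chrom:start-end"
            )
        return cls(m.group(1),
                   int(m.group(2).replace(",", "")),
                   int(m.group(3).replace(",", "")))

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def interval_frame(chrom=(), start=(), end=(), **columns) -> pd.DataFrame:
    """Build an interval frame from aligned vectors."""
    data = {
        "chrom": np.asarray(chrom, dtype=object),
        "start": np.asarray(start, dtype=np.int64),
        "end": np.asarray(end, dtype=np.int64),
    }
    for name, values in columns.items():
        data[name] = np.asarray(values)
    return pd.DataFrame(data)


def empty_frame(*value_columns: str) -> pd.DataFrame:
    """An interval frame with zero rows and the given value columns."""
    return interval_frame(**{c: () for c in value_columns})


def sort_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Sort an interval frame by (chrom, start, end), resetting the index."""
    return frame.sort_values(
        ["chrom", "start", "end"], kind="stable"
    ).reset_index(drop=True)


def value_columns(frame: pd.DataFrame) -> list[str]:
    """Names of the non-coordinate columns of an interval frame."""
    return [c for c in frame.columns if c not in ("chrom", "start", "end")]


def overlap_filter(frame: pd.DataFrame, rng: GenomicRange) -> pd.DataFrame:
    """Rows overlapping ``rng`` (original coordinates kept, not clipped)."""
    mask = (
        (frame["chrom"] == rng.chrom)
        & (frame["start"] < rng.end)
        & (frame["end"] > rng.start)
    )
    return frame.loc[mask].reset_index(drop=True)
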