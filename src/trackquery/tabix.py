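"""Range queries over BGZF-compressed, Tabix-indexed tabular files.

A ``.tbi`` index maps each reference sequence to (a) a hierarchical
binning of positions into 37,449 bins across 6 levels (smallest bin
16 kb, coordinates < 2^29) with the file chunks holding each bin's
records, and (b) a linear index giving, per 16 kb window, the lowest
virtual offset of any record ending in or after the window. A query
collects the chunks of every bin overlapping the region, prunes them by
the linear lower bound, merges them, inflates only the touched BGZF
blocks, and overlap-filters the lines.

All output coordinates are normalized to 0-based half-open, regardless
of the index's declared convention.
"""
from __future__ import annotations

import struct
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from . import bgzf
from .core import interval_frame, empty_frame
from .errors import CorruptIndex, UnknownChromosome, UnrecognizedFormat
from .range_io import BlockCache, ResourceHandle, read_range

TBI_MAGIC = b"TBI\x01"

#: format_flags bit: coordinates are 0-based half-open (BED convention).
FLAG_ZERO_BASED = 0x10000

_BIN_LEVEL_OFFSETS = (0, 1, 9, 73, 585, 4681)
_BIN_LEVEL_SHIFTS = (29, 26, 23, 20, 17, 14)
N_BINS_TOTAL = 37449
MAX_COORD = 1 << 29


@dataclass
class SequenceIndex:
    bins: dict[int, list[tuple[int, int]]]  # bin id -> [(vstart, vend)]
    linear: list[int]                       # 16 kb window -> min voffset


@dataclass
class TabixIndex:
    n_sequences: int
    format_flags: int
    col_seq: int
    col_beg: int
    col_end: int
    meta_char: str
    skip_lines: int
    names: list[str]
    sequences: list[SequenceIndex] = field(default_factory=list)

    @property
    def zero_based(self) -> bool:
        return bool(self.format_flags & FLAG_ZERO_BASED)


def parse_tbi(handle: ResourceHandle,
              cache: Optional[BlockCache] = None) -> TabixIndex:
    """Decode a ``.tbi`` index (itself BGZF-compressed); reads are pinned."""
    raw = bgzf.read_virtual(handle, bgzf.VirtualOffset(0, 0), None, cache,
                            pin=True)
    if raw[:4] != TBI_MAGIC:
        raise UnrecognizedFormat(
            f"{handle.uri}: magic {raw[:4]!r} is not TBI\\x01")
    try:
        (n_ref, fmt, col_seq, col_beg, col_end, meta, skip,
         l_nm) = struct.unpack_from("<8i", raw, 4)
        pos = 36
        names_blob = raw[pos: pos + l_nm]
        names = [n.decode("ascii") for n in names_blob.split(b"\0") if n]
        if len(names) != n_ref:
            raise CorruptIndex(
                f"{handle.uri}: {len(names)} names for {n_ref} sequences")
        pos += l_nm
        sequences: list[SequenceIndex] = []
        for _ in range(n_ref):
            (n_bin,) = struct.unpack_from("<i", raw, pos)
            pos += 4
            bins: dict[int, list[tuple[int, int]]] = {}
            for _ in range(n_bin):
                bin_id, n_chunk = struct.unpack_from("<Ii", raw, pos)
                pos += 8
                chunks = []
                for _ in range(n_chunk):
                    vs, ve = struct.unpack_from("<QQ", raw, pos)
                    pos += 16
                    if vs >= ve and bin_id < N_BINS_TOTAL:
                        raise CorruptIndex(
                            f"{handle.uri}: chunk with start >= end in "
                            f"bin {bin_id}")
                    chunks.append((vs, ve))
                # bins past the binning range (e.g. 37450) are htslib
                # metadata pseudo-bins, not positional bins
                if bin_id < N_BINS_TOTAL:
                    bins[bin_id] = chunks
            (n_intv,) = struct.unpack_from("<i", raw, pos)
            pos += 4
            linear = list(struct.unpack_from(f"<{n_intv}Q", raw, pos))
            pos += 8 * n_intv
            sequences.append(SequenceIndex(bins, linear))
    except struct.error as exc:
        raise CorruptIndex(
            f"{handle.uri}: truncated tabix index") from exc
    return TabixIndex(
        n_sequences=n_ref, format_flags=fmt, col_seq=col_seq,
        col_beg=col_beg, col_end=col_end,
        meta_char=chr(meta) if meta else "#", skip_lines=skip,
        names=names, sequences=sequences)


def region_to_bins(start: int, end: int) -> set[int]:
    """All bins at the 6 levels overlapping ``[start, end)``."""
    if not (0 <= start < end <= MAX_COORD):
        raise ValueError(f"region [{start}, {end}) outside [0, 2^29]")
    bins = set()
    last = end - 1
    for offset, shift in zip(_BIN_LEVEL_OFFSETS, _BIN_LEVEL_SHIFTS):
        bins.update(range(offset + (start >> shift),
                          offset + (last >> shift) + 1))
    return bins


def bin_to_region(bin_id: int) -> tuple[int, int]:
    """The half-open base range a bin covers (oracle helper)."""
    if not (0 <= bin_id < N_BINS_TOTAL):
        raise ValueError(f"bin id {bin_id} out of range")
    for offset, shift in zip(_BIN_LEVEL_OFFSETS, _BIN_LEVEL_SHIFTS):
        next_offset = offset + (1 << (29 - shift))
        if bin_id < next_offset:
            i = bin_id - offset
            return i << shift, (i + 1) << shift
    raise AssertionError("unreachable")


def _merge_chunks(chunks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and coalesce overlapping/adjacent virtual-offset chunks so no
    line is scanned twice (bins interleave in file order)."""
    if not chunks:
        return []
    chunks = sorted(chunks)
    merged = [chunks[0]]
    for vs, ve in chunks[1:]:
        ls, le = merged[-1]
        if vs <= le:
            merged[-1] = (ls, max(le, ve))
        else:
            merged.append((vs, ve))
    return merged


def _parse_lines(text: str, index: TabixIndex, chrom: str, start: int,
                 end: int, skip_head: int) -> list[tuple[int, int, list]]:
    rows = []
    for lineno, line in enumerate(text.split("\n")):
        if not line:
            continue
        if lineno < skip_head:
            continue
        if line.startswith(index.meta_char):
            continue
        fields = line.split("\t")
        if fields[index.col_seq - 1] != chrom:
            continue
        beg = int(fields[index.col_beg - 1])
        if index.col_end > 0 and index.col_end != index.col_beg:
            stop = int(fields[index.col_end - 1])
        else:
            stop = beg + (0 if index.zero_based else 1)
        if not index.zero_based:
            beg -= 1  # 1-based inclusive -> 0-based half-open
        if stop <= beg:
            stop = beg + 1
        if beg < end and stop > start:
            skip_cols = {index.col_seq - 1, index.col_beg - 1}
            if index.col_end > 0:
                skip_cols.add(index.col_end - 1)
            rest = [f for i, f in enumerate(fields) if i not in skip_cols]
            rows.append((beg, stop, rest))
    return rows


def query_tabix(data_handle: ResourceHandle, index: TabixIndex,
                chrom: str, start: int, end: int,
                cache: Optional[BlockCache] = None,
                column_names: Optional[Sequence[str]] = None
                ) -> pd.DataFrame:
    """Every data line overlapping ``[start, end)`` as an interval frame.

    Candidate chunks come from the bins overlapping the region, are
    pruned by the linear index's lower bound for the query start, merged,
    and scanned once.
    """
    try:
        rid = index.names.index(chrom)
    except ValueError:
        raise UnknownChromosome(
            f"{data_handle.uri}: {chrom!r} not in index "
            f"(has {index.names})") from None
    seq = index.sequences[rid]
    window = min(start >> 14, max(len(seq.linear) - 1, 0))
    min_voff = seq.linear[window] if seq.linear else 0
    chunks = []
    for bin_id in region_to_bins(start, min(end, MAX_COORD)):
        for vs, ve in seq.bins.get(bin_id, ()):
            if ve > min_voff:
                chunks.append((max(vs, min_voff), ve))
    rows: list[tuple[int, int, list]] = []
    for vs, ve in _merge_chunks(chunks):
        text = bgzf.read_virtual(
            data_handle, bgzf.unpack_voffset(vs), bgzf.unpack_voffset(ve),
            cache).decode("utf-8")
        skip_head = index.skip_lines if vs == 0 else 0
        rows.extend(_parse_lines(text, index, chrom, start, end,
                                 skip_head))
    if not rows:
        return empty_frame()
    rows.sort(key=lambda r: (r[0], r[1]))
    width = max(len(r[2]) for r in rows)
    if column_names is not None and len(column_names) >= width:
        names = list(column_names[:width])
    else:
        names = [f"col{i + 4}" for i in range(width)]
    frame = interval_frame(chrom=[chrom] * len(rows),
                           start=[r[0] for r in rows],
                           end=[r[1] for r in rows])
    for j, name in enumerate(names):
        col = pd.Series(
            [r[2][j] if j < len(r[2]) else None for r in rows],
            dtype=object)
        numeric = pd.to_numeric(col, errors="coerce")
        if col.notna().all() and numeric.notna().all():
            col = numeric
        frame[name] = col
    return frame


class TabixFile:
    """Paired data + index handle with lazy index parsing."""

    def __init__(self, data_uri: str, index_uri: Optional[str] = None,
                 cache: Optional[BlockCache] = None,
                 column_names: Optional[Sequence[str]] = None) -> None:
        from .range_io import open_resource
        self.data_uri = data_uri
        self.index_uri = index_uri or data_uri + ".tbi"
        self.cache = cache
        self.column_names = column_names
        self._data_handle = None
        self._index: Optional[TabixIndex] = None

    @property
    def handle(self):
        from .range_io import open_resource
        if self._data_handle is None:
            self._data_handle = open_resource(self.data_uri)
        return self._data_handle

    @property
    def index(self) -> TabixIndex:
        from .range_io import open_resource
        if self._index is None:
            idx_handle = open_resource(self.index_uri)
            try:
                self._index = parse_tbi(idx_handle, self.cache)
            finally:
                idx_handle.close()
        return self._index

    def chroms(self) -> list[str]:
        return list(self.index.names)

    def query(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        return query_tabix(self.handle, self.index, chrom, start, end,
                           self.cache, self.column_names)

    def read_all_text(self) -> str:
        """The whole decompressed table (used for gene-name scans)."""
        return bgzf.read_all(self.handle, self.cache).decode("utf-8")

    def close(self) -> None:
        if self._data_handle is not None:
            self._data_handle.close()
            self._data_handle = None
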