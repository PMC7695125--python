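"""Parser for the BBI container formats (BigWig and BigBed).

BBI files share one layout: a 64-byte header, a list of 24-byte zoom
headers, a chromosome B+ tree, a data section of (optionally deflate
compressed) blocks, an R-tree spatial index over those blocks, and per
zoom level a reduced data section with its own R-tree. A range query
walks header -> chromosome tree -> R-tree path -> overlapping data
blocks, reading nothing else; every read goes through
:mod:`trackquery.range_io` so the access pattern is accounted and cached.

Magic numbers (either byte order): BigWig ``0x888FFC26``, BigBed
``0x8789F2EB``, chromosome B+ tree ``0x78CA8C91``, R-tree ``0x2468ACE0``.
Overlapping records are returned with their original, unclipped
coordinates; clipping and weighting belong to the summarizer.
"""
from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import interval_frame, empty_frame
from .errors import (
    CorruptBlock,
    CorruptHeader,
    CorruptIndex,
    SerializationError,
    UnknownChromosome,
    UnrecognizedFormat,
)
from .range_io import (
    BlockCache,
    ResourceHandle,
    deserialize_state,
    open_resource,
    read_range,
    serialize_state,
)

BIGWIG_MAGIC = 0x888FFC26
BIGBED_MAGIC = 0x8789F2EB
CHROM_TREE_MAGIC = 0x78CA8C91
RTREE_MAGIC = 0x2468ACE0

HEADER_SIZE = 64
ZOOM_HEADER_SIZE = 24
ZOOM_RECORD_SIZE = 32


@dataclass
class BBIHeader:
    kind: str                      # "bigwig" | "bigbed"
    byte_order: str                # "little" | "big"
    version: int
    zoom_levels: int
    chrom_tree_offset: int
    full_data_offset: int
    full_index_offset: int
    field_count: int
    defined_field_count: int
    auto_sql_offset: int
    total_summary_offset: int
    uncompress_buf_size: int

    @property
    def endian(self) -> str:
        return "<" if self.byte_order == "little" else ">"


@dataclass
class ZoomHeader:
    reduction_level: int
    data_offset: int
    index_offset: int


@dataclass
class ChromEntry:
    name: str
    id: int
    length: int


@dataclass
class BlockRef:
    chrom_id_start: int
    base_start: int
    chrom_id_end: int
    base_end: int
    offset: int
    size: int


def parse_header(handle: ResourceHandle,
                 cache: Optional[BlockCache] = None
                 ) -> tuple[BBIHeader, list[ZoomHeader]]:
    """Parse the 64-byte main header and the zoom-header list.

    Both reads are pinned in the cache: every subsequent query needs them.
    """
    raw = read_range(handle, 0, HEADER_SIZE, cache, pin=True)
    magic_le = struct.unpack_from("<I", raw)[0]
    magic_be = struct.unpack_from(">I", raw)[0]
    if magic_le in (BIGWIG_MAGIC, BIGBED_MAGIC):
        endian, magic = "<", magic_le
    elif magic_be in (BIGWIG_MAGIC, BIGBED_MAGIC):
        endian, magic = ">", magic_be
    else:
        raise UnrecognizedFormat(
            f"{handle.uri}: magic 0x{magic_le:08X} is neither BigWig nor "
            "BigBed")
    kind = "bigwig" if magic == BIGWIG_MAGIC else "bigbed"
    (version, zoom_levels, chrom_tree_offset, full_data_offset,
     full_index_offset, field_count, defined_field_count, auto_sql_offset,
     total_summary_offset, uncompress_buf_size,
     _reserved) = struct.unpack_from(endian + "HHQQQHHQQIQ", raw, 4)
    header = BBIHeader(
        kind=kind,
        byte_order="little" if endian == "<" else "big",
        version=version,
        zoom_levels=zoom_levels,
        chrom_tree_offset=chrom_tree_offset,
        full_data_offset=full_data_offset,
        full_index_offset=full_index_offset,
        field_count=field_count,
        defined_field_count=defined_field_count,
        auto_sql_offset=auto_sql_offset,
        total_summary_offset=total_summary_offset,
        uncompress_buf_size=uncompress_buf_size,
    )
    if handle.total_size is not None:
        for off in (chrom_tree_offset, full_data_offset, full_index_offset):
            if off > handle.total_size:
                raise CorruptHeader(
                    f"{handle.uri}: header offset {off} beyond file end")
    zooms: list[ZoomHeader] = []
    if zoom_levels:
        zraw = read_range(handle, HEADER_SIZE,
                          zoom_levels * ZOOM_HEADER_SIZE, cache, pin=True)
        for i in range(zoom_levels):
            reduction, _res, doff, ioff = struct.unpack_from(
                endian + "IIQQ", zraw, i * ZOOM_HEADER_SIZE)
            zooms.append(ZoomHeader(reduction, doff, ioff))
        levels = [z.reduction_level for z in zooms]
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise CorruptHeader(
                f"{handle.uri}: zoom reduction levels not increasing: "
                f"{levels}")
    return header, zooms


def read_chrom_tree(handle: ResourceHandle, header: BBIHeader,
                    cache: Optional[BlockCache] = None) -> list[ChromEntry]:
    """Read the chromosome B+ tree; result and reads are pinned."""
    e = header.endian
    hdr = read_range(handle, header.chrom_tree_offset, 32, cache, pin=True)
    magic, block_size, key_size, val_size, item_count, _res = (
        struct.unpack(e + "IIIIQQ", hdr))
    if magic != CHROM_TREE_MAGIC:
        raise CorruptIndex(
            f"{handle.uri}: bad chromosome-tree magic 0x{magic:08X}")
    if val_size != 8:
        raise CorruptIndex(
            f"{handle.uri}: chromosome-tree value size {val_size} != 8")
    entries: list[ChromEntry] = []

    def walk(offset: int) -> None:
        node_hdr = read_range(handle, offset, 4, cache, pin=True)
        is_leaf, _res, count = struct.unpack(e + "BBH", node_hdr)
        item_size = key_size + 8
        body = read_range(handle, offset + 4, count * item_size, cache,
                          pin=True)
        for i in range(count):
            base = i * item_size
            if is_leaf:
                key = body[base: base + key_size].split(b"\0", 1)[0]
                chrom_id, chrom_len = struct.unpack_from(
                    e + "II", body, base + key_size)
                entries.append(ChromEntry(key.decode("ascii"), chrom_id,
                                          chrom_len))
            else:
                (child,) = struct.unpack_from(e + "Q", body,
                                              base + key_size)
                walk(child)

    walk(header.chrom_tree_offset + 32)
    if len(entries) != item_count:
        raise CorruptIndex(
            f"{handle.uri}: chromosome tree lists {len(entries)} entries, "
            f"header says {item_count}")
    return entries


def _region_overlaps(qchrom: int, qstart: int, qend: int,
                     cs: int, ss: int, ce: int, se: int) -> bool:
    """Does the (chrom, base) rectangle [cs:ss, ce:se] overlap the query?"""
    if cs > qchrom or (cs == qchrom and ss >= qend):
        return False
    if ce < qchrom or (ce == qchrom and se <= qstart):
        return False
    return True


def find_blocks(handle: ResourceHandle, index_offset: int, chrom_id: int,
                start: int, end: int,
                cache: Optional[BlockCache] = None,
                endian: str = "<") -> list[BlockRef]:
    """R-tree search: leaf items whose region overlaps [start, end).

    Only index nodes on overlapping root-to-leaf paths are read; results
    come back in file order. ``index_offset`` may point at the main index
    or at any zoom level's index.
    """
    e = endian
    hdr = read_range(handle, index_offset, 48, cache)
    (magic, _block_size, _item_count, _scix, _sb, _ecix, _eb,
     _end_file_offset, _items_per_slot, _res) = struct.unpack(
        e + "IIQIIIIQII", hdr)
    if magic != RTREE_MAGIC:
        raise CorruptIndex(
            f"{handle.uri}: bad R-tree magic 0x{magic:08X} at "
            f"{index_offset}")
    out: list[BlockRef] = []

    def walk(offset: int) -> None:
        node_hdr = read_range(handle, offset, 4, cache)
        is_leaf, _res2, count = struct.unpack(e + "BBH", node_hdr)
        item_size = 32 if is_leaf else 24
        body = read_range(handle, offset + 4, count * item_size, cache)
        for i in range(count):
            if is_leaf:
                cs, ss, ce, se, boff, bsize = struct.unpack_from(
                    e + "IIIIQQ", body, i * item_size)
                if _region_overlaps(chrom_id, start, end, cs, ss, ce, se):
                    out.append(BlockRef(cs, ss, ce, se, boff, bsize))
            else:
                cs, ss, ce, se, child = struct.unpack_from(
                    e + "IIIIQ", body, i * item_size)
                if _region_overlaps(chrom_id, start, end, cs, ss, ce, se):
                    walk(child)

    walk(index_offset + 48)
    return out


# --- block decoding ----------------------------------------------------------

_WIG_SECTION_HEADER = struct.Struct("<IIIIIBBH")


def decode_wig_section(raw: bytes, chrom_names: dict[int, str],
                       endian: str = "<") -> pd.DataFrame:
    """Decode one decompressed BigWig data section into an interval frame.

    Section types: 1 = bedGraph-style (start, end, value), 2 = variable
    step (start, value; end = start + span), 3 = fixed step (value;
    coordinates derived from section start/step/span).
    """
    if len(raw) < 24:
        raise CorruptBlock("wig section shorter than its 24-byte header")
    (chrom_id, chrom_start, chrom_end, item_step, item_span, sec_type,
     _res, item_count) = struct.unpack_from(endian + "IIIIIBBH", raw, 0)
    chrom = chrom_names.get(chrom_id)
    if chrom is None:
        raise CorruptBlock(f"wig section references unknown chrom id "
                           f"{chrom_id}")
    body = raw[24:]
    if sec_type == 1:
        item = 12
        if len(body) != item_count * item:
            raise CorruptBlock(
                f"bedGraph section: {len(body)} bytes for {item_count} "
                "items")
        arr = np.frombuffer(body, dtype=np.dtype(
            [("start", endian + "u4"), ("end", endian + "u4"),
             ("value", endian + "f4")]))
        starts = arr["start"].astype(np.int64)
        ends = arr["end"].astype(np.int64)
        values = arr["value"].astype(np.float32)
    elif sec_type == 2:
        item = 8
        if len(body) != item_count * item:
            raise CorruptBlock(
                f"variable-step section: {len(body)} bytes for "
                f"{item_count} items")
        arr = np.frombuffer(body, dtype=np.dtype(
            [("start", endian + "u4"), ("value", endian + "f4")]))
        starts = arr["start"].astype(np.int64)
        ends = starts + item_span
        values = arr["value"].astype(np.float32)
    elif sec_type == 3:
        item = 4
        if len(body) != item_count * item:
            raise CorruptBlock(
                f"fixed-step section: {len(body)} bytes for {item_count} "
                "items")
        values = np.frombuffer(body, dtype=endian + "f4").astype(np.float32)
        starts = chrom_start + item_step * np.arange(item_count,
                                                     dtype=np.int64)
        ends = starts + item_span
    else:
        raise CorruptBlock(f"unknown wig section type {sec_type}")
    return interval_frame(chrom=[chrom] * item_count, start=starts,
                          end=ends, value=values)


def decode_bed_block(raw: bytes, chrom_names: dict[int, str],
                     column_names: Optional[Sequence[str]] = None,
                     endian: str = "<") -> pd.DataFrame:
    """Decode one decompressed BigBed block.

    Items are (chromId u32, start u32, end u32, NUL-terminated rest); the
    rest-of-line is split on tabs into named columns (``column_names`` or
    ``col4``, ``col5``, ...).
    """
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    rests: list[list[str]] = []
    pos = 0
    n = len(raw)
    while pos < n:
        if n - pos < 12:
            raise CorruptBlock("bed item truncated before coordinates")
        chrom_id, s, e = struct.unpack_from(endian + "III", raw, pos)
        pos += 12
        nul = raw.find(b"\0", pos)
        if nul < 0:
            raise CorruptBlock("bed item missing NUL terminator")
        rest = raw[pos:nul].decode("utf-8")
        pos = nul + 1
        chrom = chrom_names.get(chrom_id)
        if chrom is None:
            raise CorruptBlock(f"bed item references unknown chrom id "
                               f"{chrom_id}")
        chroms.append(chrom)
        starts.append(s)
        ends.append(e)
        rests.append(rest.split("\t") if rest else [])
    width = max((len(r) for r in rests), default=0)
    if column_names is not None and len(column_names) >= width:
        names = list(column_names[:width])
    else:
        names = [f"col{i + 4}" for i in range(width)]
    columns: dict[str, list] = {name: [] for name in names}
    for r in rests:
        for j, name in enumerate(names):
            columns[name].append(r[j] if j < len(r) else None)
    frame = interval_frame(chrom=chroms, start=starts, end=ends)
    for name, vals in columns.items():
        series = pd.Series(vals, dtype=object)
        numeric = pd.to_numeric(series, errors="coerce")
        # keep text columns as text; promote fully numeric columns
        if series.notna().all() and numeric.notna().all():
            series = numeric
        frame[name] = series
    return frame


def decode_zoom_block(raw: bytes, endian: str = "<") -> list[tuple]:
    """Decode 32-byte zoom records: (chrom_id, start, end, valid_count,
    min, max, sum, sum_sq)."""
    if len(raw) % ZOOM_RECORD_SIZE != 0:
        raise CorruptBlock(
            f"zoom block of {len(raw)} bytes is not a multiple of "
            f"{ZOOM_RECORD_SIZE}")
    out = []
    for off in range(0, len(raw), ZOOM_RECORD_SIZE):
        out.append(struct.unpack_from(endian + "IIIIffff", raw, off))
    return out


def _inflate(header: BBIHeader, raw: bytes) -> bytes:
    if header.uncompress_buf_size == 0:
        return raw
    try:
        return zlib.decompress(raw)
    except zlib.error as exc:
        raise CorruptBlock(f"block failed to inflate: {exc}") from exc


class BBIFile:
    """High-level handle over a BigWig/BigBed resource.

    Metadata (header, zoom headers, chromosome tree) is parsed lazily on
    first use and pinned in the cache; queries then read only R-tree path
    nodes and overlapping data blocks.
    """

    def __init__(self, uri: str, cache: Optional[BlockCache] = None,
                 column_names: Optional[Sequence[str]] = None) -> None:
        self.uri = uri
        self.cache = cache
        self.column_names = column_names
        self._handle: Optional[ResourceHandle] = None
        self.header: Optional[BBIHeader] = None
        self.zoom_headers: list[ZoomHeader] = []
        self.chrom_entries: list[ChromEntry] = []

    # -- lazy plumbing -----------------------------------------------------
    @property
    def handle(self) -> ResourceHandle:
        if self._handle is None:
            self._handle = open_resource(self.uri)
        return self._handle

    def _ensure_meta(self) -> None:
        if self.header is None:
            self.header, self.zoom_headers = parse_header(self.handle,
                                                          self.cache)
            self.chrom_entries = read_chrom_tree(self.handle, self.header,
                                                 self.cache)

    @property
    def kind(self) -> str:
        self._ensure_meta()
        return self.header.kind

    def chroms(self) -> dict[str, int]:
        self._ensure_meta()
        return {c.name: c.length for c in self.chrom_entries}

    def _chrom_id(self, chrom: str) -> int:
        for entry in self.chrom_entries:
            if entry.name == chrom:
                return entry.id
        raise UnknownChromosome(
            f"{self.uri}: chromosome {chrom!r} not in file "
            f"(has {[c.name for c in self.chrom_entries]})")

    # -- queries -----------------------------------------------------------
    def query(self, chrom: str, start: int, end: int,
              zoom_index: Optional[int] = None) -> pd.DataFrame:
        """All records overlapping ``[start, end)``, unclipped, in order.

        With ``zoom_index`` the records come from that zoom level
        (``value`` = per-record mean, plus ``valid_count``).
        """
        self._ensure_meta()
        if start < 0 or start >= end:
            raise ValueError(f"bad query range [{start}, {end})")
        chrom_id = self._chrom_id(chrom)
        header = self.header
        names = {c.id: c.name for c in self.chrom_entries}
        if zoom_index is None:
            index_offset = header.full_index_offset
        else:
            zh = self.zoom_headers[zoom_index]
            index_offset = zh.index_offset
        blocks = find_blocks(self.handle, index_offset, chrom_id, start,
                             end, self.cache, header.endian)
        frames: list[pd.DataFrame] = []
        for blk in blocks:
            raw = _inflate(header, read_range(self.handle, blk.offset,
                                              blk.size, self.cache))
            if zoom_index is not None:
                recs = decode_zoom_block(raw, header.endian)
                rows = [r for r in recs
                        if r[0] == chrom_id and r[1] < end and r[2] > start]
                if rows:
                    arr = np.array([(r[1], r[2], r[3], r[4], r[5], r[6],
                                     r[7]) for r in rows], dtype=np.float64)
                    valid = arr[:, 2]
                    with np.errstate(invalid="ignore", divide="ignore"):
                        mean = np.where(valid > 0, arr[:, 5] / valid,
                                        np.nan)
                    frames.append(interval_frame(
                        chrom=[chrom] * len(rows),
                        start=arr[:, 0].astype(np.int64),
                        end=arr[:, 1].astype(np.int64),
                        value=mean,
                        valid_count=valid.astype(np.int64)))
            elif header.kind == "bigwig":
                frame = decode_wig_section(raw, names, header.endian)
                mask = ((frame["chrom"] == chrom)
                        & (frame["start"] < end) & (frame["end"] > start))
                frames.append(frame.loc[mask])
            else:
                frame = decode_bed_block(raw, names, self.column_names,
                                         header.endian)
                mask = ((frame["chrom"] == chrom)
                        & (frame["start"] < end) & (frame["end"] > start))
                frames.append(frame.loc[mask])
        frames = [f for f in frames if len(f)]
        if not frames:
            if zoom_index is not None:
                return empty_frame("value", "valid_count")
            return empty_frame("value") if header.kind == "bigwig" \
                else empty_frame()
        out = pd.concat(frames, ignore_index=True)
        return out.sort_values(["start", "end"],
                               kind="stable").reset_index(drop=True)

    # -- persistence -------------------------------------------------------
    def save(self, path: str) -> None:
        """Serialize parsed metadata plus this file's pinned cache blocks."""
        self._ensure_meta()
        pinned = (self.cache.pinned_entries_for(self.uri)
                  if self.cache is not None else {})
        serialize_state({
            "container": "bbi",
            "uri": self.uri,
            "header": self.header,
            "zoom_headers": self.zoom_headers,
            "chrom_entries": self.chrom_entries,
            "column_names": (list(self.column_names)
                             if self.column_names else None),
            "pinned_blocks": {tuple(k): v for k, v in pinned.items()},
        }, path)

    @classmethod
    def load(cls, path: str,
             cache: Optional[BlockCache] = None) -> "BBIFile":
        """Restore a serialized handle; queries after restore read only
        data blocks (metadata comes back from the state file)."""
        state = deserialize_state(path)
        if state.get("container") != "bbi":
            raise SerializationError(f"{path!r}: not a BBI state file")
        try:
            obj = cls(state["uri"], cache=cache,
                      column_names=state["column_names"])
            obj.header = state["header"]
            obj.zoom_headers = state["zoom_headers"]
            obj.chrom_entries = state["chrom_entries"]
            pinned = state["pinned_blocks"]
        except KeyError as exc:
            raise SerializationError(
                f"{path!r}: missing field {exc}") from exc
        if cache is not None:
            cache.preload(pinned, pin=True)
        return obj

    def close(self) -> None:
        if self._handle is not None:
            self._handle.close()
            self._handle = None


def query_bbi(uri_or_file, chrom: str, start: int, end: int,
              zoom_index: Optional[int] = None,
              cache: Optional[BlockCache] = None) -> pd.DataFrame:
    """Convenience one-shot query over a path/URL or an open BBIFile."""
    if isinstance(uri_or_file, BBIFile):
        return uri_or_file.query(chrom, start, end, zoom_index)
    bbifile = BBIFile(uri_or_file, cache=cache)
    try:
        return bbifile.query(chrom, start, end, zoom_index)
    finally:
        bbifile.close()
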