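"""BGZF block reading over byte-range IO.

BGZF is the blocked gzip dialect used by htslib: a concatenation of gzip
members, each at most 64 KiB uncompressed, carrying its own compressed
size in a "BC" extra-field subfield so a reader can hop from block to
block without inflating anything in between. Random access uses *virtual
offsets*: ``compressed_block_offset << 16 | within_block_offset``.
"""
from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass
from typing import Optional

from .errors import CorruptBlock, InvalidOffset
from .range_io import BlockCache, ResourceHandle, read_range

#: The fixed 28-byte empty block that terminates every BGZF file.
BGZF_EOF = bytes.fromhex(
    "1f8b08040000000000ff0600424302001b0003000000000000000000")


@dataclass(frozen=True)
class VirtualOffset:
    compressed_offset: int
    uncompressed_offset: int

    def __post_init__(self) -> None:
        if not (0 <= self.uncompressed_offset < 65536):
            raise InvalidOffset(
                f"uncompressed offset {self.uncompressed_offset} out of "
                "[0, 65536)")
        if self.compressed_offset < 0:
            raise InvalidOffset("negative compressed offset")

    def packed(self) -> int:
        return pack_voffset(self.compressed_offset,
                            self.uncompressed_offset)


def pack_voffset(compressed_offset: int, uncompressed_offset: int) -> int:
    """Pack a (block offset, within-block offset) pair: ``c * 65536 + u``."""
    if not (0 <= uncompressed_offset < 65536):
        raise InvalidOffset(
            f"uncompressed offset {uncompressed_offset} out of [0, 65536)")
    if compressed_offset < 0:
        raise InvalidOffset("negative compressed offset")
    return compressed_offset * 65536 + uncompressed_offset


def unpack_voffset(voffset: int) -> VirtualOffset:
    if voffset < 0:
        raise InvalidOffset("negative virtual offset")
    return VirtualOffset(voffset >> 16, voffset & 0xFFFF)


def read_block(handle: ResourceHandle, offset: int,
               cache: Optional[BlockCache] = None,
               pin: bool = False) -> tuple[bytes, int]:
    """Inflate the single BGZF block at ``offset``.

    Returns ``(decompressed bytes, offset of the next block)``. Raises
    :class:`CorruptBlock` on anything that is not a gzip member with the
    mandatory BC extra subfield.
    """
    size = handle.total_size
    if size is not None and offset + 18 > size:
        raise CorruptBlock(
            f"{handle.uri}: truncated BGZF block at {offset}")
    head = read_range(handle, offset, 18, cache, pin=pin)
    if head[0] != 0x1F or head[1] != 0x8B or head[2] != 0x08:
        raise CorruptBlock(
            f"{handle.uri}: not a gzip member at offset {offset}")
    flags = head[3]
    if not flags & 0x04:  # FEXTRA
        raise CorruptBlock(
            f"{handle.uri}: gzip member at {offset} lacks the BGZF extra "
            "field")
    (xlen,) = struct.unpack_from("<H", head, 10)
    extra = read_range(handle, offset + 12, xlen, cache, pin=pin)
    bsize = None
    pos = 0
    while pos + 4 <= len(extra):
        si1, si2, slen = extra[pos], extra[pos + 1], struct.unpack_from(
            "<H", extra, pos + 2)[0]
        if si1 == 0x42 and si2 == 0x43 and slen == 2:  # "BC"
            (bsize,) = struct.unpack_from("<H", extra, pos + 4)
            bsize += 1
        pos += 4 + slen
    if bsize is None:
        raise CorruptBlock(
            f"{handle.uri}: gzip member at {offset} has no BC subfield")
    if size is not None and offset + bsize > size:
        raise CorruptBlock(
            f"{handle.uri}: BGZF block at {offset} extends past file end")
    member = read_range(handle, offset, bsize, cache, pin=pin)
    try:
        data = zlib.decompress(member, wbits=31)
    except zlib.error as exc:
        raise CorruptBlock(
            f"{handle.uri}: BGZF block at {offset} failed to inflate: "
            f"{exc}") from exc
    return data, offset + bsize


def read_virtual(handle: ResourceHandle, start: VirtualOffset,
                 end: Optional[VirtualOffset] = None,
                 cache: Optional[BlockCache] = None,
                 pin: bool = False) -> bytes:
    """Decompressed bytes of the half-open virtual range ``[start, end)``.

    Only the BGZF blocks the range touches are inflated. ``end=None``
    reads to end of file (the 28-byte EOF block contributes nothing).
    """
    if end is not None and start.packed() >= end.packed():
        raise InvalidOffset(
            f"virtual range start {start} not before end {end}")
    chunks: list[bytes] = []
    coffset = start.compressed_offset
    first = True
    total = handle.total_size
    while True:
        if total is not None and coffset >= total:
            break
        if end is not None and coffset > end.compressed_offset:
            break
        data, next_offset = read_block(handle, coffset, cache, pin=pin)
        lo = start.uncompressed_offset if first else 0
        hi = len(data)
        if end is not None and coffset == end.compressed_offset:
            hi = min(hi, end.uncompressed_offset)
        chunks.append(data[lo:hi])
        first = False
        if end is not None and coffset == end.compressed_offset:
            break
        if len(data) == 0 and end is None:
            break  # EOF block
        coffset = next_offset
    return b"".join(chunks)


def read_all(handle: ResourceHandle,
             cache: Optional[BlockCache] = None) -> bytes:
    """Inflate an entire BGZF file."""
    return read_virtual(handle, VirtualOffset(0, 0), None, cache)
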