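"""Packet wire format: field layouts, serialization, checksums, header chunk.

One packet is one encoded symbol.  On the wire it is the concatenation

    [#chunks] [seed | degree + chunk ids] [payload] [checksum]

where every integer is big-endian in its configured byte width and the
checksum is computed over all bytes preceding it, so corruption of the
seed or chunk-count fields — which is fatal to decoding — is caught too.
Field widths are configurable and static fields may be omitted entirely
(width 0) and carried out-of-band instead, trading per-packet overhead
against self-description.

Two layout modes exist:

* ``seed_based`` — the packet carries only a seed; the decoder re-runs the
  seeded degree/index selection to learn which chunks were combined.
* ``explicit_list`` — the packet enumerates its chunk indices, required
  for unequal error protection where the selection is not seed-derivable.

Checksum options: ``nocode`` (identity, no protection), ``crc8``
(poly 0x07, init 0, non-reflected), ``crc32`` (IEEE 802.3 reflected, via
zlib), and ``reed_solomon`` with a configurable parity size that repairs
up to floor(rs_symbols/2) byte errors before accepting a packet.
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass, field

from ._reedsolomon import rs_decode, rs_encode
from .errors import (
    FormatError,
    IntegrityError,
    OverflowFieldError,
    ParameterError,
)

__all__ = [
    "PacketLayout",
    "Packet",
    "compute_checksum",
    "serialize_packet",
    "deserialize_packet",
    "build_header_chunk",
    "parse_header_chunk",
]

CHECKSUM_KINDS = ("nocode", "crc8", "crc32", "reed_solomon")


def _crc8(data: bytes) -> int:
    # CRC-8 with polynomial 0x07, init 0x00, MSB first, no reflection
    crc = 0
    for byte in data:
        crc ^= byte
        for _ in range(8):
            crc = ((crc << 1) ^ 0x07) & 0xFF if crc & 0x80 else (crc << 1) & 0xFF
    return crc


def compute_checksum(data: bytes, kind: str, rs_symbols: int = 0) -> bytes:
    """Checksum bytes for ``data``: empty for nocode, 1 for crc8, 4 for
    crc32, ``rs_symbols`` parity bytes for reed_solomon."""
    if kind == "nocode":
        return b""
    if kind == "crc8":
        return bytes([_crc8(data)])
    if kind == "crc32":
        return struct.pack(">I", zlib.crc32(data) & 0xFFFFFFFF)
    if kind == "reed_solomon":
        return rs_encode(data, rs_symbols)
    raise ParameterError(f"unknown checksum kind: {kind!r}")


@dataclass(frozen=True)
class PacketLayout:
    """Byte widths and options defining the packet wire format."""

    mode: str = "seed_based"
    num_chunks_width: int = 4
    seed_width: int = 4
    degree_width: int = 0
    chunk_id_width: int = 2
    checksum_kind: str = "crc32"
    rs_symbols: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("seed_based", "explicit_list"):
            raise ParameterError(f"unknown layout mode: {self.mode!r}")
        for name in ("num_chunks_width", "seed_width", "degree_width",
                     "chunk_id_width", "rs_symbols"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.mode == "seed_based" and self.seed_width < 1:
            raise ParameterError("seed_based layout requires seed_width >= 1")
        if self.mode == "explicit_list":
            if self.chunk_id_width < 1:
                raise ParameterError(
                    "explicit_list layout requires chunk_id_width >= 1")
            if self.degree_width < 1:
                raise ParameterError(
                    "explicit_list layout requires degree_width >= 1 "
                    "(the id list is length-prefixed by the degree field)")
        if self.checksum_kind not in CHECKSUM_KINDS:
            raise ParameterError(f"unknown checksum kind: {self.checksum_kind!r}")
        if self.checksum_kind == "reed_solomon" and self.rs_symbols < 1:
            raise ParameterError("reed_solomon checksum requires rs_symbols >= 1")

    @property
    def checksum_len(self) -> int:
        return {"nocode": 0, "crc8": 1, "crc32": 4,
                "reed_solomon": self.rs_symbols}[self.checksum_kind]

    @property
    def seed_space(self) -> int:
        """Number of distinct seed values the seed field can carry."""
        return 256 ** self.seed_width

    def packet_length(self, chunk_size: int, degree: int | None = None) -> int:
        """Total serialized length.  In explicit_list mode the length
        depends on the degree (one id per combined chunk)."""
        n = self.num_chunks_width + chunk_size + self.checksum_len
        if self.mode == "seed_based":
            return n + self.seed_width + self.degree_width
        if degree is None:
            raise ParameterError("explicit_list packet length needs the degree")
        return n + self.degree_width + degree * self.chunk_id_width


@dataclass
class Packet:
    """One encoded symbol: XOR payload plus reconstruction metadata.

    Exactly one of ``seed`` / ``chunk_ids`` is set, matching the layout
    mode.  ``checksum`` holds the wire checksum after (de)serialization
    and does not participate in equality — it is a pure function of the
    other fields and the layout.
    """

    payload: bytes
    seed: int | None = None
    chunk_ids: tuple[int, ...] | None = None
    total_chunks: int | None = None
    degree: int | None = None
    checksum: bytes = field(default=b"", compare=False)

    def __post_init__(self) -> None:
        if (self.seed is None) == (self.chunk_ids is None):
            raise ParameterError("exactly one of seed / chunk_ids must be set")
        if self.chunk_ids is not None:
            self.chunk_ids = tuple(self.chunk_ids)
            if len(set(self.chunk_ids)) != len(self.chunk_ids):
                raise ParameterError("chunk_ids must be distinct")


def _pack_int(value: int | None, width: int, name: str) -> bytes:
    if value is None:
        raise ParameterError(f"layout transmits {name} but packet lacks it")
    if value < 0 or value >= 256 ** width:
        raise OverflowFieldError(
            f"{name}={value} does not fit in {width} byte(s)")
    return value.to_bytes(width, "big")


def serialize_packet(packet: Packet, layout: PacketLayout) -> bytes:
    """Wire bytes for ``packet`` under ``layout`` (checksum appended)."""
    out = bytearray()
    if layout.num_chunks_width:
        out += _pack_int(packet.total_chunks, layout.num_chunks_width,
                         "total_chunks")
    if layout.mode == "seed_based":
        if packet.seed is None:
            raise ParameterError("seed_based layout requires a seeded packet")
        out += _pack_int(packet.seed, layout.seed_width, "seed")
        if layout.degree_width:
            out += _pack_int(packet.degree, layout.degree_width, "degree")
    else:
        if packet.chunk_ids is None:
            raise ParameterError("explicit_list layout requires chunk_ids")
        out += _pack_int(len(packet.chunk_ids), layout.degree_width, "degree")
        for cid in packet.chunk_ids:
            out += _pack_int(cid, layout.chunk_id_width, "chunk id")
    out += packet.payload
    checksum = compute_checksum(bytes(out), layout.checksum_kind,
                                layout.rs_symbols)
    packet.checksum = checksum
    return bytes(out) + checksum


def deserialize_packet(raw: bytes, layout: PacketLayout,
                       chunk_size: int) -> Packet:
    """Parse and verify wire bytes back into a :class:`Packet`.

    Raises :class:`IntegrityError` on checksum mismatch or uncorrectable
    Reed-Solomon damage (the packet then counts as erased) and
    :class:`FormatError` on structural problems.
    """
    kind = layout.checksum_kind
    clen = layout.checksum_len
    if len(raw) < clen + chunk_size:
        raise FormatError("packet shorter than payload + checksum")
    if kind == "nocode":
        body = raw
    elif kind == "reed_solomon":
        body = rs_decode(raw, layout.rs_symbols)
    else:
        body, tail = raw[:-clen], raw[-clen:]
        if compute_checksum(body, kind) != tail:
            raise IntegrityError(f"{kind} checksum mismatch")

    pos = 0

    def take(width: int, what: str) -> int:
        nonlocal pos
        if pos + width > len(body):
            raise FormatError(f"packet truncated inside {what}")
        val = int.from_bytes(body[pos:pos + width], "big")
        pos += width
        return val

    total_chunks = take(layout.num_chunks_width, "#chunks") \
        if layout.num_chunks_width else None
    seed = chunk_ids = degree = None
    if layout.mode == "seed_based":
        seed = take(layout.seed_width, "seed")
        if layout.degree_width:
            degree = take(layout.degree_width, "degree")
    else:
        degree = take(layout.degree_width, "degree")
        ids = [take(layout.chunk_id_width, "chunk id") for _ in range(degree)]
        if len(set(ids)) != len(ids):
            raise FormatError("explicit chunk ids are not distinct")
        chunk_ids = tuple(ids)
    payload = body[pos:]
    if len(payload) != chunk_size:
        raise FormatError(
            f"payload length {len(payload)} != chunk size {chunk_size}")
    return Packet(payload=payload, seed=seed, chunk_ids=chunk_ids,
                  total_chunks=total_chunks, degree=degree,
                  checksum=raw[len(raw) - clen:] if clen else b"")


def build_header_chunk(filename: str, last_chunk_padding: int,
                       chunk_size: int) -> bytes:
    """Artificial chunk 0 carrying file metadata.

    Layout: 2-byte big-endian count of zero-padding bytes appended to the
    last data chunk, then the UTF-8 filename, zero-padded to chunk_size.
    """
    encoded = filename.encode("utf-8")
    if 2 + len(encoded) > chunk_size:
        raise ParameterError(
            f"filename needs {2 + len(encoded)} bytes but chunk size is "
            f"{chunk_size}")
    if not (0 <= last_chunk_padding < 65536):
        raise ParameterError("padding count must fit in 2 bytes")
    return struct.pack(">H", last_chunk_padding) + encoded + \
        b"\x00" * (chunk_size - 2 - len(encoded))


def parse_header_chunk(chunk: bytes) -> tuple[str, int]:
    """Inverse of :func:`build_header_chunk`: (filename, padding)."""
    if len(chunk) < 2:
        raise FormatError("header chunk shorter than 2 bytes")
    padding = struct.unpack(">H", chunk[:2])[0]
    filename = chunk[2:].rstrip(b"\x00").decode("utf-8")
    return filename, padding
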