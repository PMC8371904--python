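"""LT (Luby transform) codec: chunking, seeded chunk selection, XOR
combination, and decode-matrix construction.

The file is divided into n equal-length chunks (the last one zero-padded).
Each packet draws a degree d from the degree distribution and XORs d
distinct, uniformly chosen chunks.  The packet's seed initializes the
deterministic generator; the first draw yields the degree and subsequent
draws the chunk indices, so the decoder re-derives the exact selection
from the seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass

from .decoding import GF2System
from .distributions import DegreeDistribution, DeterministicRng, sample_degree
from .errors import ParameterError
from .packet_model import Packet, PacketLayout, build_header_chunk

__all__ = [
    "SourceBlock",
    "split_into_chunks",
    "choose_chunk_indices",
    "lt_encode",
    "lt_encode_priority",
    "lt_rows",
    "derive_selection",
    "xor_chunks",
    "assemble_data",
    "LTCodec",
]


def xor_chunks(chunks: list[bytes], indices) -> bytes:
    """XOR the selected equal-length chunks."""
    it = iter(indices)
    first = next(it)
    acc = int.from_bytes(chunks[first], "big")
    size = len(chunks[first])
    for i in it:
        acc ^= int.from_bytes(chunks[i], "big")
    return acc.to_bytes(size, "big")


@dataclass(frozen=True)
class SourceBlock:
    """The file split into n equal-length chunks plus padding metadata."""

    chunks: tuple[bytes, ...]
    chunk_size: int
    padding: int
    header_present: bool = False

    def __post_init__(self) -> None:
        if not self.chunks:
            raise ParameterError("a source block needs at least one chunk")
        if any(len(c) != self.chunk_size for c in self.chunks):
            raise ParameterError("all chunks must have length chunk_size")
        if not (0 <= self.padding < self.chunk_size):
            raise ParameterError("padding must satisfy 0 <= padding < chunk_size")

    @property
    def n(self) -> int:
        return len(self.chunks)


def split_into_chunks(data: bytes, chunk_size: int | None = None,
                      num_chunks: int | None = None,
                      header_filename: str | None = None) -> SourceBlock:
    """Split ``data`` into equal chunks, zero-padding the last one.

    Exactly one of ``chunk_size`` / ``num_chunks`` must be given.  When
    ``header_filename`` is not None an artificial header chunk carrying the
    filename and the padding count is prepended as chunk 0, so the decoder
    can strip the padding without out-of-band knowledge.
    """
    if not data:
        raise ParameterError("cannot encode an empty payload")
    if (chunk_size is None) == (num_chunks is None):
        raise ParameterError("give exactly one of chunk_size / num_chunks")
    if num_chunks is not None:
        if num_chunks < 1:
            raise ParameterError("num_chunks must be >= 1")
        chunk_size = -(-len(data) // num_chunks)
    if chunk_size < 1:
        raise ParameterError("chunk_size must be >= 1")
    n_data = -(-len(data) // chunk_size)
    padding = n_data * chunk_size - len(data)
    padded = data + b"\x00" * padding
    chunks = [padded[i * chunk_size:(i + 1) * chunk_size] for i in range(n_data)]
    header_present = header_filename is not None
    if header_present:
        chunks.insert(0, build_header_chunk(header_filename, padding, chunk_size))
    return SourceBlock(tuple(chunks), chunk_size, padding, header_present)


def choose_chunk_indices(rng: DeterministicRng, degree: int, n: int) -> list[int]:
    """``degree`` distinct uniform indices in [0, n), in draw order.

    Duplicates are rejected and redrawn, which keeps the selection uniform
    over subsets and reproducible from the generator state.
    """
    if not (1 <= degree <= n):
        raise ParameterError("degree must satisfy 1 <= degree <= n")
    seen: set[int] = set()
    out: list[int] = []
    while len(out) < degree:
        i = rng.below(n)
        if i not in seen:
            seen.add(i)
            out.append(i)
    return out


def derive_selection(seed: int, dist: DegreeDistribution, n: int) -> list[int]:
    """The chunk selection a seed deterministically expands to.

    Shared by encoder and decoder: seed -> rng -> degree (capped at n) ->
    distinct indices.
    """
    rng = DeterministicRng(seed)
    degree = min(sample_degree(dist, rng), n)
    return choose_chunk_indices(rng, degree, n)


def lt_encode(block: SourceBlock, seed: int, dist: DegreeDistribution,
              layout: PacketLayout) -> Packet:
    """Encode one LT packet for ``seed``."""
    if seed >= layout.seed_space and layout.mode == "seed_based":
        raise ParameterError("seed does not fit the layout's seed field")
    indices = derive_selection(seed, dist, block.n)
    payload = xor_chunks(list(block.chunks), indices)
    total = block.n if layout.num_chunks_width else None
    if layout.mode == "seed_based":
        return Packet(payload=payload, seed=seed, total_chunks=total,
                      degree=len(indices) if layout.degree_width else None)
    return Packet(payload=payload, chunk_ids=tuple(indices),
                  total_chunks=total, degree=len(indices))


def _weighted_distinct(rng: DeterministicRng, degree: int, n: int,
                       weights: list[int]) -> list[int]:
    """``degree`` distinct indices drawn proportionally to integer weights."""
    total = sum(weights)
    seen: set[int] = set()
    out: list[int] = []
    while len(out) < degree:
        r = rng.below(total)
        for i, w in enumerate(weights):
            r -= w
            if r < 0:
                break
        if i not in seen:
            seen.add(i)
            out.append(i)
    return out


# priority chunks' degree cutoff and weight boost for unequal error
# protection: below this degree, priority chunks are twice as likely picked
PRIORITY_MAX_DEGREE = 4
PRIORITY_WEIGHT = 2


def lt_encode_priority(block: SourceBlock, dist: DegreeDistribution,
                       layout: PacketLayout, priority_chunks,
                       count: int, rng: DeterministicRng) -> list[Packet]:
    """Unequal error protection: packets favouring the priority chunks.

    One degree-1 packet is forced for every priority chunk, guaranteeing it
    is decodable on its own; the remaining packets double the priority
    chunks' selection weight whenever the sampled degree is small
    (<= 4).  The selection is no longer reconstructible from a seed, so an
    explicit_list layout is required.
    """
    if layout.mode != "explicit_list":
        raise ParameterError(
            "priority encoding requires an explicit_list layout")
    priority = sorted(set(priority_chunks))
    if any(not 0 <= c < block.n for c in priority):
        raise ParameterError("priority chunk index out of range")
    if count < len(priority):
        raise ParameterError("count smaller than the priority chunk list")
    chunks = list(block.chunks)
    total = block.n if layout.num_chunks_width else None
    packets = [Packet(payload=chunks[c], chunk_ids=(c,), total_chunks=total,
                      degree=1) for c in priority]
    weights = [PRIORITY_WEIGHT if i in set(priority) else 1
               for i in range(block.n)]
    while len(packets) < count:
        degree = min(sample_degree(dist, rng), block.n)
        if degree <= PRIORITY_MAX_DEGREE:
            indices = _weighted_distinct(rng, degree, block.n, weights)
        else:
            indices = choose_chunk_indices(rng, degree, block.n)
        packets.append(Packet(payload=xor_chunks(chunks, indices),
                              chunk_ids=tuple(indices), total_chunks=total,
                              degree=degree))
    return packets


def lt_rows(packets, n: int, dist: DegreeDistribution | None,
            payload_size: int | None = None) -> GF2System:
    """Decode matrix: one row per verified packet.

    Seed-based packets re-derive their selection by re-running the seeded
    draw, which requires the degree distribution; explicit-list packets use
    their stored ids, so ``dist`` may then be None.
    """
    packets = list(packets)
    if payload_size is None:
        if not packets:
            raise ParameterError("cannot infer payload size from zero packets")
        payload_size = len(packets[0].payload)
    system = GF2System(n_unknowns=n, payload_size=payload_size)
    for p in packets:
        if p.chunk_ids is not None:
            indices = p.chunk_ids
        else:
            if dist is None:
                raise ParameterError(
                    "seed-based packets need the degree distribution to "
                    "re-derive their chunk selection")
            indices = derive_selection(p.seed, dist, n)
        system.add_row(indices, p.payload)
    return system


def assemble_data(chunks: list[bytes], header_present: bool,
                  padding: int | None = None) -> tuple[str | None, bytes]:
    """Join decoded chunks back into the original byte stream.

    With a header chunk, the filename and padding come from chunk 0;
    otherwise ``padding`` must be supplied out-of-band (None keeps the
    zero-padded tail).
    """
    from .packet_model import parse_header_chunk

    if header_present:
        filename, padding = parse_header_chunk(chunks[0])
        body = b"".join(chunks[1:])
    else:
        filename = None
        body = b"".join(chunks)
    if padding:
        body = body[:-padding]
    return filename, body


class LTCodec:
    """Bundles a source block (encoder side) or its parameters (decoder
    side) with the degree distribution and packet layout."""

    name = "lt"

    def __init__(self, *, block: SourceBlock | None = None, n: int | None = None,
                 chunk_size: int | None = None, dist: DegreeDistribution,
                 layout: PacketLayout, header_present: bool | None = None):
        self.block = block
        if block is not None:
            n, chunk_size = block.n, block.chunk_size
            header_present = block.header_present
        if n is None or chunk_size is None:
            raise ParameterError("need a block or (n, chunk_size)")
        self.n = n
        self.chunk_size = chunk_size
        self.dist = dist
        self.layout = layout
        self.header_present = bool(header_present)

    # unknowns of the linear system; for plain LT these are the chunks
    @property
    def symbol_count(self) -> int:
        return self.n

    @property
    def chunk_count(self) -> int:
        return self.n

    def encode(self, seed: int) -> Packet:
        if self.block is None:
            raise ParameterError("decoder-side codec cannot encode")
        return lt_encode(self.block, seed, self.dist, self.layout)

    def indices_for(self, packet: Packet) -> list[int]:
        if packet.chunk_ids is not None:
            return list(packet.chunk_ids)
        return derive_selection(packet.seed, self.dist, self.symbol_count)

    def system(self, packets) -> GF2System:
        return lt_rows(packets, self.n, self.dist, self.chunk_size)

    def chunk_expansion(self) -> list[int]:
        """Per-symbol bit mask of the chunks whose bytes feed that symbol;
        for plain LT every symbol is a chunk."""
        return [1 << i for i in range(self.n)]
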