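"""Raptor codec: fixed-rate precode plus an inner LT code with the fixed
degree table.

The precode expands the k chunks into L = k + S + H intermediate symbols:

* S parity blocks from a circulant (LDPC-style) construction in which each
  chunk is XORed into exactly 3 of the S blocks, and
* H parity blocks from a Gray-ordered half-weight construction over the
  first k + S symbols: symbol j belongs to parity i iff bit i of the j-th
  H-bit codeword of weight ceil(H/2) is set (codewords in increasing
  numeric order, reused cyclically when exhausted).

The block counts come from the smallest-integer conditions

    f(k): smallest x with x(x-1) >= 2k          (auxiliary value)
    S   : smallest prime >= ceil(0.01 k + f(k))
    H   : smallest x with C(x, ceil(x/2)) >= f(k) + S

The inner code then encodes the L intermediates ratelessly: a packet's
seed expands to a (d, a, b) tuple — degree d from the fixed table, step a
in [1, L') and start b in [0, L') with L' the smallest prime >= L — and
the packet XORs the first d in-range positions of the modular walk
b -> (b + a) mod L'.  Operation is non-systematic: chunks never appear
verbatim as packets.

At decode time the S + H parity definitions contribute zero-right-hand-side
rows; the first k solved unknowns are the chunks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .decoding import GF2System
from .distributions import DeterministicRng, raptor_degree_lookup
from .errors import ParameterError
from .lt_codec import SourceBlock, xor_chunks
from .packet_model import Packet, PacketLayout

__all__ = [
    "RaptorParams",
    "precode_counts",
    "ldpc_memberships",
    "half_memberships",
    "build_intermediates",
    "raptor_tuple",
    "raptor_encode",
    "raptor_system",
    "RaptorCodec",
]


def _is_prime(n: int) -> bool:
    if n < 2:
        return False
    if n < 4:
        return True
    if n % 2 == 0:
        return False
    i = 3
    while i * i <= n:
        if n % i == 0:
            return False
        i += 2
    return True


def _next_prime(n: int) -> int:
    while not _is_prime(n):
        n += 1
    return n


@dataclass(frozen=True)
class RaptorParams:
    """Precode sizing for k chunks."""

    k: int
    f_k: int
    S: int
    H: int

    @property
    def L(self) -> int:
        return self.k + self.S + self.H

    @property
    def L_prime(self) -> int:
        return _next_prime(self.L)


def precode_counts(k: int) -> RaptorParams:
    """Smallest-satisfying precode block counts for k chunks."""
    if k < 1:
        raise ParameterError("precode_counts requires k >= 1")
    f = 1
    while f * (f - 1) < 2 * k:
        f += 1
    S = _next_prime(f + -(-k // 100))  # ceil(0.01 k) + f, exact in integers
    H = 1
    while math.comb(H, -(-H // 2)) < f + S:
        H += 1
    return RaptorParams(k=k, f_k=f, S=S, H=H)


def ldpc_memberships(k: int, S: int) -> list[list[int]]:
    """Circulant parity memberships: for each of the S parity blocks, the
    chunk indices it accumulates.  Each chunk lands in exactly 3 distinct
    blocks: starting at b = i mod S it advances twice by the chunk's step
    a = 1 + (i div S) mod (S - 1)."""
    if S < 3:
        raise ParameterError("circulant construction needs S >= 3")
    members: list[list[int]] = [[] for _ in range(S)]
    for i in range(k):
        a = 1 + (i // S) % (S - 1)
        b = i % S
        for _ in range(3):
            members[b].append(i)
            b = (b + a) % S
    return members


def _half_weight_codewords(H: int) -> list[int]:
    """H-bit integers with popcount ceil(H/2), in increasing order."""
    weight = -(-H // 2)
    return [v for v in range(1 << H) if v.bit_count() == weight]


def half_memberships(k: int, S: int, H: int) -> list[list[int]]:
    """Half-weight parity memberships over the first k + S symbols: symbol
    j belongs to parity i iff bit i of codeword[j mod count] is set."""
    words = _half_weight_codewords(H)
    members: list[list[int]] = [[] for _ in range(H)]
    for j in range(k + S):
        w = words[j % len(words)]
        for i in range(H):
            if w >> i & 1:
                members[i].append(j)
    return members


def build_intermediates(block: SourceBlock,
                        params: RaptorParams) -> list[bytes]:
    """Precode: chunks, then S circulant parities over the chunks, then H
    half-weight parities over chunks + circulant parities."""
    if block.n != params.k:
        raise ParameterError("params.k must equal the block's chunk count")
    size = block.chunk_size
    symbols = [int.from_bytes(c, "big") for c in block.chunks]
    for member in ldpc_memberships(params.k, params.S):
        acc = 0
        for i in member:
            acc ^= symbols[i]
        symbols.append(acc)
    for member in half_memberships(params.k, params.S, params.H):
        acc = 0
        for j in member:
            acc ^= symbols[j]
        symbols.append(acc)
    return [v.to_bytes(size, "big") for v in symbols]


@dataclass(frozen=True)
class RaptorTuple:
    """Per-packet (degree, step, start) triple and the index walk it emits."""

    d: int
    a: int
    b: int
    indices: tuple[int, ...]


def raptor_tuple(seed: int, params: RaptorParams) -> RaptorTuple:
    """Expand a seed into its (d, a, b) tuple and intermediate indices.

    d comes from the fixed degree table (capped at L), a is uniform in
    [1, L') and b in [0, L'); the walk emits the first d values of the
    orbit b -> (b + a) mod L' that fall below L.  Because L' is prime the
    orbit visits every residue once, so the emitted indices are distinct.
    """
    L, Lp = params.L, params.L_prime
    rng = DeterministicRng(seed)
    d = min(raptor_degree_lookup(rng.below(1 << 20)), L)
    a = 1 + rng.below(Lp - 1)
    b = rng.below(Lp)
    b0 = b
    indices = []
    while len(indices) < d:
        while b >= L:
            b = (b + a) % Lp
        indices.append(b)
        b = (b + a) % Lp
    return RaptorTuple(d=d, a=a, b=b0, indices=tuple(indices))


def raptor_encode(intermediates: list[bytes], seed: int,
                  layout: PacketLayout, params: RaptorParams) -> Packet:
    """Inner LT step: XOR the intermediates at the tuple's indices."""
    tup = raptor_tuple(seed, params)
    payload = xor_chunks(intermediates, tup.indices)
    total = params.k if layout.num_chunks_width else None
    if layout.mode == "seed_based":
        return Packet(payload=payload, seed=seed, total_chunks=total,
                      degree=tup.d if layout.degree_width else None)
    return Packet(payload=payload, chunk_ids=tup.indices,
                  total_chunks=total, degree=tup.d)


def raptor_system(packets, params: RaptorParams,
                  payload_size: int) -> GF2System:
    """Decode system over the L intermediates.

    One row per packet (indicator at its tuple indices) plus S + H parity
    rows with zero right-hand side.  The first k solved unknowns are the
    original chunks.
    """
    k, S, H = params.k, params.S, params.H
    system = GF2System(n_unknowns=params.L, payload_size=payload_size)
    for j, member in enumerate(ldpc_memberships(k, S)):
        system.add_row(member + [k + j], 0)
    for i, member in enumerate(half_memberships(k, S, H)):
        system.add_row(member + [k + S + i], 0)
    for p in packets:
        if p.chunk_ids is not None:
            indices = list(p.chunk_ids)
        else:
            indices = list(raptor_tuple(p.seed, params).indices)
        system.add_row(indices, p.payload)
    return system


class RaptorCodec:
    """Encoder/decoder bundle for the Raptor code (fixed degree table)."""

    name = "raptor"

    def __init__(self, *, block: SourceBlock | None = None,
                 k: int | None = None, chunk_size: int | None = None,
                 layout: PacketLayout, header_present: bool | None = None):
        self.block = block
        if block is not None:
            k, chunk_size = block.n, block.chunk_size
            header_present = block.header_present
        if k is None or chunk_size is None:
            raise ParameterError("need a block or (k, chunk_size)")
        self.n = k
        self.chunk_size = chunk_size
        self.params = precode_counts(k)
        self.layout = layout
        self.header_present = bool(header_present)
        self.intermediates: list[bytes] | None = None
        if block is not None:
            self.intermediates = build_intermediates(block, self.params)

    @property
    def symbol_count(self) -> int:
        return self.params.L

    @property
    def chunk_count(self) -> int:
        return self.n

    def encode(self, seed: int) -> Packet:
        if self.intermediates is None:
            raise ParameterError("decoder-side codec cannot encode")
        return raptor_encode(self.intermediates, seed, self.layout, self.params)

    def indices_for(self, packet: Packet) -> list[int]:
        if packet.chunk_ids is not None:
            return list(packet.chunk_ids)
        return list(raptor_tuple(packet.seed, self.params).indices)

    def system(self, packets) -> GF2System:
        return raptor_system(packets, self.params, self.chunk_size)

    def chunk_expansion(self) -> list[int]:
        """Per-symbol chunk masks: intermediate parity symbols expand
        (XOR-transitively) to the chunks that feed them."""
        k, S, H = self.params.k, self.params.S, self.params.H
        masks = [1 << i for i in range(k)]
        for member in ldpc_memberships(k, S):
            acc = 0
            for i in member:
                acc ^= masks[i]
            masks.append(acc)
        for member in half_memberships(k, S, H):
            acc = 0
            for j in member:
                acc ^= masks[j]
            masks.append(acc)
        return masks
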