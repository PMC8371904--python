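"""Online codec: auxiliary-block outer code plus an inner LT code.

The Online code fights the coupon-collector weakness of plain LT by a
two-stage construction.  The outer stage builds M = ceil(0.55 * q * eps * F)
auxiliary blocks and XORs every one of the F chunks into q distinct aux
blocks.  The inner stage is an ordinary LT code over the union of chunks
and aux blocks (F + M symbols, chunks first).  At decode time the aux
definitions become M extra constraint rows with zero right-hand side
(aux_j XOR its members = 0), and the chunk unknowns are read off the
solved system.

The chunk->aux assignment is derived from a dedicated ``aux_seed`` known
to both ends (a layout-level constant, default 1), which makes the outer
code reconstructible without transmitting the membership map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .decoding import GF2System
from .distributions import DegreeDistribution, DeterministicRng, sample_degree
from .errors import ParameterError
from .lt_codec import SourceBlock, choose_chunk_indices, xor_chunks
from .packet_model import Packet, PacketLayout

__all__ = [
    "OnlineParams",
    "DEFAULT_AUX_SEED",
    "aux_memberships",
    "build_aux_blocks",
    "online_encode",
    "online_system",
    "OnlineCodec",
]

DEFAULT_AUX_SEED = 1


@dataclass(frozen=True)
class OnlineParams:
    """Outer-code parameters: quality q, overhead factor eps, chunk count F."""

    q: int
    epsilon: float
    F: int

    def __post_init__(self) -> None:
        if self.q < 1 or self.F < 1 or self.epsilon <= 0:
            raise ParameterError("OnlineParams require q >= 1, F >= 1, eps > 0")

    @property
    def M(self) -> int:
        """Auxiliary block count, ceil(0.55 * q * eps * F)."""
        return math.ceil(0.55 * self.q * self.epsilon * self.F)


def aux_memberships(params: OnlineParams,
                    aux_seed: int = DEFAULT_AUX_SEED) -> list[list[int]]:
    """Per-chunk list of the q distinct aux blocks each chunk joins.

    Reproducible from (params, aux_seed) alone — the decoder calls this to
    rebuild the outer-code constraints without seeing any data.
    """
    M = params.M
    if M < params.q:
        raise ParameterError(
            f"only {M} aux blocks but q={params.q}; increase epsilon or F")
    rng = DeterministicRng(aux_seed)
    return [choose_chunk_indices(rng, params.q, M) for _ in range(params.F)]


def build_aux_blocks(block: SourceBlock, params: OnlineParams,
                     aux_seed: int = DEFAULT_AUX_SEED
                     ) -> tuple[list[bytes], list[list[int]]]:
    """Outer encoding: XOR every chunk into its q assigned aux blocks."""
    if block.n != params.F:
        raise ParameterError("params.F must equal the block's chunk count")
    members = aux_memberships(params, aux_seed)
    aux_ints = [0] * params.M
    for i, chunk in enumerate(block.chunks):
        v = int.from_bytes(chunk, "big")
        for j in members[i]:
            aux_ints[j] ^= v
    aux = [a.to_bytes(block.chunk_size, "big") for a in aux_ints]
    return aux, members


def _derive_selection(seed: int, dist: DegreeDistribution, total: int) -> list[int]:
    rng = DeterministicRng(seed)
    degree = min(sample_degree(dist, rng), total)
    return choose_chunk_indices(rng, degree, total)


def online_encode(block: SourceBlock, aux: list[bytes], seed: int,
                  dist: DegreeDistribution, layout: PacketLayout) -> Packet:
    """Inner LT encoding over the F + M symbols (chunks then aux blocks)."""
    symbols = list(block.chunks) + list(aux)
    indices = _derive_selection(seed, dist, len(symbols))
    payload = xor_chunks(symbols, indices)
    total = block.n if layout.num_chunks_width else None
    if layout.mode == "seed_based":
        return Packet(payload=payload, seed=seed, total_chunks=total,
                      degree=len(indices) if layout.degree_width else None)
    return Packet(payload=payload, chunk_ids=tuple(indices),
                  total_chunks=total, degree=len(indices))


def online_system(packets, params: OnlineParams, dist: DegreeDistribution,
                  payload_size: int,
                  aux_seed: int = DEFAULT_AUX_SEED) -> GF2System:
    """Decode system over F + M unknowns.

    One row per received packet plus M outer-code constraint rows
    (aux_j XOR its member chunks = 0, zero right-hand side).  Decoding
    succeeds when the chunk unknowns (the first F) are resolved; solving
    the full system resolves the aux symbols along the way, realizing the
    reverse-order unwinding of the two encoding stages.
    """
    F, M = params.F, params.M
    system = GF2System(n_unknowns=F + M, payload_size=payload_size)
    members = aux_memberships(params, aux_seed)
    per_aux: list[list[int]] = [[] for _ in range(M)]
    for chunk_idx, targets in enumerate(members):
        for j in targets:
            per_aux[j].append(chunk_idx)
    for j in range(M):
        system.add_row(per_aux[j] + [F + j], 0)
    for p in packets:
        if p.chunk_ids is not None:
            indices = list(p.chunk_ids)
        else:
            indices = _derive_selection(p.seed, dist, F + M)
        system.add_row(indices, p.payload)
    return system


class OnlineCodec:
    """Encoder/decoder bundle for the Online code."""

    name = "online"

    def __init__(self, *, block: SourceBlock | None = None,
                 n: int | None = None, chunk_size: int | None = None,
                 q: int = 2, epsilon: float = 0.1,
                 dist: DegreeDistribution, layout: PacketLayout,
                 aux_seed: int = DEFAULT_AUX_SEED,
                 header_present: bool | None = None):
        self.block = block
        if block is not None:
            n, chunk_size = block.n, block.chunk_size
            header_present = block.header_present
        if n is None or chunk_size is None:
            raise ParameterError("need a block or (n, chunk_size)")
        self.n = n
        self.chunk_size = chunk_size
        self.params = OnlineParams(q=q, epsilon=epsilon, F=n)
        self.dist = dist
        self.layout = layout
        self.aux_seed = aux_seed
        self.header_present = bool(header_present)
        self.aux: list[bytes] | None = None
        if block is not None:
            self.aux, self.membership = build_aux_blocks(
                block, self.params, aux_seed)
        else:
            self.membership = aux_memberships(self.params, aux_seed)

    @property
    def symbol_count(self) -> int:
        return self.params.F + self.params.M

    @property
    def chunk_count(self) -> int:
        return self.n

    def encode(self, seed: int) -> Packet:
        if self.block is None:
            raise ParameterError("decoder-side codec cannot encode")
        return online_encode(self.block, self.aux, seed, self.dist, self.layout)

    def indices_for(self, packet: Packet) -> list[int]:
        if packet.chunk_ids is not None:
            return list(packet.chunk_ids)
        return _derive_selection(packet.seed, self.dist, self.symbol_count)

    def system(self, packets) -> GF2System:
        return online_system(packets, self.params, self.dist,
                             self.chunk_size, self.aux_seed)

    def chunk_expansion(self) -> list[int]:
        """Per-symbol chunk masks: a chunk symbol is itself; an aux symbol
        expands to the chunks XORed into it."""
        masks = [1 << i for i in range(self.n)]
        aux_masks = [0] * self.params.M
        for chunk_idx, targets in enumerate(self.membership):
            for j in targets:
                aux_masks[j] ^= 1 << chunk_idx
        return masks + aux_masks
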