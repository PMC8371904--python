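"""Workflow orchestration: encode/decode pipelines, seed-space sweeps,
bounded packet generation, channel simulation, and coverage analytics.

The end-to-end store/retrieve path is: split the file into chunks, encode
packets with a fountain codec, serialize each packet, map it to DNA, write
FASTA (synthesis stands in for the write side); later read FASTA, map DNA
back to bytes, verify/deserialize (integrity failures become erasures),
build the GF(2) system and solve it to recover the file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .decoding import IncrementalGauss, gauss_solve, mask_from_indices
from .distributions import (
    DegreeDistribution,
    DeterministicRng,
    ideal_soliton,
    robust_soliton,
)
from .dna_layer import (
    DEFAULT_MAPPING,
    BaseMapping,
    DnaSequence,
    bytes_to_dna,
    dna_to_bytes,
    read_fasta,
)
from .errors import (
    DecodeError,
    FormatError,
    IllegalSymbolError,
    IntegrityError,
    ParameterError,
    ProgressTimeoutError,
)
from .lt_codec import LTCodec, SourceBlock, assemble_data, split_into_chunks
from .online_codec import DEFAULT_AUX_SEED, OnlineCodec
from .packet_model import Packet, PacketLayout, deserialize_packet, serialize_packet
from .raptor_codec import RaptorCodec
from .rule_engine import RuleConfig, RuleReport, drop_decision, total_error

__all__ = [
    "SweepEntry",
    "default_distribution",
    "make_codec",
    "sweep_seed_space",
    "encode_with_bound",
    "encode_until_decodable",
    "simulate_channel",
    "chunk_coverage",
    "packet_to_sequence",
    "sequences_to_packets",
    "decode_packets",
    "encode",
    "decode",
    "EncodeResult",
    "DecodeResult",
]

# enumerating more than a 3-byte seed space (16.7M packets) is refused
# unless explicitly overridden
SWEEP_SEED_WIDTH_GUARD = 3


def default_distribution(n: int) -> DegreeDistribution:
    """Robust Soliton with spike at K = round(sqrt(n)) and delta = 0.05;
    degenerates to the ideal distribution when n < 2.

    Both encoder and decoder derive this from n alone, so seed-based
    packets are re-derivable without transmitting the distribution.
    """
    if n < 2:
        return ideal_soliton(max(n, 1))
    K = max(1, min(n - 1, round(math.sqrt(n))))
    return robust_soliton(n, K, 0.05)


def make_codec(name: str, *, block: SourceBlock | None = None,
               n: int | None = None, chunk_size: int | None = None,
               layout: PacketLayout | None = None,
               dist: DegreeDistribution | None = None,
               q: int = 2, epsilon: float = 0.1,
               aux_seed: int = DEFAULT_AUX_SEED,
               header_present: bool | None = None):
    """Construct an LT / Online / Raptor codec for encoding (with a source
    block) or decoding (with n and chunk_size)."""
    layout = layout or PacketLayout()
    count = block.n if block is not None else n
    if name == "lt":
        dist = dist or default_distribution(count)
        return LTCodec(block=block, n=n, chunk_size=chunk_size, dist=dist,
                       layout=layout, header_present=header_present)
    if name == "online":
        if dist is None:
            params_m = math.ceil(0.55 * q * epsilon * count)
            dist = default_distribution(count + params_m)
        return OnlineCodec(block=block, n=n, chunk_size=chunk_size, q=q,
                           epsilon=epsilon, dist=dist, layout=layout,
                           aux_seed=aux_seed, header_present=header_present)
    if name == "raptor":
        return RaptorCodec(block=block, k=n, chunk_size=chunk_size,
                           layout=layout, header_present=header_present)
    raise ParameterError(f"unknown codec {name!r}; choose lt, online, raptor")


def packet_to_sequence(packet: Packet, layout: PacketLayout,
                       mapping: BaseMapping = DEFAULT_MAPPING,
                       index: int | None = None,
                       score: float | None = None) -> DnaSequence:
    """Serialize a packet and map it to DNA, with a descriptive header."""
    raw = serialize_packet(packet, layout)
    parts = [f"pkt_{index}" if index is not None else "pkt"]
    if packet.seed is not None:
        parts.append(f"seed={packet.seed}")
    if score is not None:
        parts.append(f"err={score:.4f}")
    return bytes_to_dna(raw, mapping, id=" ".join(parts))


@dataclass(frozen=True)
class SweepEntry:
    seed: int
    sequence: DnaSequence
    report: RuleReport


def sweep_seed_space(codec, rules: RuleConfig,
                     mapping: BaseMapping = DEFAULT_MAPPING,
                     allow_large: bool = False) -> list[SweepEntry]:
    """Generate one packet per seed in the layout's full seed range, score
    each candidate DNA sequence, and sort by error ascending (ties by
    seed).  Synthesis is expensive; enumerating every seed guarantees the
    best possible sequences are the ones stored.
    """
    layout = codec.layout
    if layout.mode != "seed_based":
        raise ParameterError("seed sweeps require a seed_based layout")
    if layout.seed_width > SWEEP_SEED_WIDTH_GUARD and not allow_large:
        raise ParameterError(
            f"seed space of {layout.seed_width} bytes is too large to "
            "enumerate; pass allow_large=True to override")
    entries = []
    for seed in range(layout.seed_space):
        packet = codec.encode(seed)
        raw = serialize_packet(packet, layout)
        seq = bytes_to_dna(raw, mapping, id=f"pkt_{seed} seed={seed}")
        report = total_error(seq, rules)
        entries.append(SweepEntry(seed=seed, sequence=seq, report=report))
    entries.sort(key=lambda e: (e.report.total, e.seed))
    return entries


def encode_with_bound(codec, rules: RuleConfig, mode: str, bound: float,
                      count: int, rng: DeterministicRng,
                      mapping: BaseMapping = DEFAULT_MAPPING,
                      seed_budget: int | None = None) -> list[Packet]:
    """Generate packets subject to a strict or weak error bound.

    strict: a packet is accepted only if its DNA error score is <= bound.
    weak: accept iff a uniform draw in [0, 1) is >= the score — useful
    when the rules are so strict that no packet clears a hard bound.
    Seeds advance sequentially until ``count`` packets are accepted;
    exhausting the budget (default: the layout's full seed space) raises
    :class:`ProgressTimeoutError` so an unreachable bound cannot spin
    forever.
    """
    if mode not in ("strict", "weak"):
        raise ParameterError("mode must be 'strict' or 'weak'")
    if bound < 0:
        raise ParameterError("bound must be non-negative")
    layout = codec.layout
    budget = layout.seed_space if seed_budget is None else seed_budget
    accepted: list[Packet] = []
    for seed in range(budget):
        packet = codec.encode(seed)
        raw = serialize_packet(packet, layout)
        score = total_error(bytes_to_dna(raw, mapping), rules).total
        if mode == "strict":
            ok = score <= bound
        else:
            ok = rng.random() >= score
        if ok:
            accepted.append(packet)
            if len(accepted) >= count:
                return accepted
    raise ProgressTimeoutError(
        f"only {len(accepted)}/{count} packets accepted within a "
        f"{budget}-seed budget")


def encode_until_decodable(codec, overhead_extra: int = 0,
                           rng: DeterministicRng | None = None) -> list[Packet]:
    """Generate packets until the structure-only pseudo-decoder reports the
    set decodable, then ``overhead_extra`` more (static overhead to ride
    out channel losses).  Seeds are drawn from ``rng`` without repetition;
    by construction the returned set is Gaussian-decodable.
    """
    rng = rng or DeterministicRng(1)
    inc = IncrementalGauss(codec.symbol_count)
    for mask in codec.system([]).rows:  # outer-code/parity constraints
        inc.add(mask)
    packets: list[Packet] = []
    used: set[int] = set()
    space = codec.layout.seed_space
    while not inc.determined(codec.chunk_count):
        if len(used) >= space:
            raise ProgressTimeoutError(
                "seed space exhausted before the packet set became decodable")
        seed = rng.below(space)
        if seed in used:
            continue
        used.add(seed)
        packet = codec.encode(seed)
        packets.append(packet)
        inc.add(mask_from_indices(codec.indices_for(packet)))
    for _ in range(overhead_extra):
        if len(used) >= space:
            break
        seed = rng.below(space)
        if seed in used:
            continue
        used.add(seed)
        packets.append(codec.encode(seed))
    return packets


def simulate_channel(seqs, rules: RuleConfig, generations: int,
                     rng: DeterministicRng) -> list[DnaSequence]:
    """Erasure-channel simulation: each sequence is independently dropped
    with probability min(score * generations, 1); survivors keep order."""
    survivors = []
    for seq in seqs:
        score = total_error(seq, rules).total
        if not drop_decision(score, generations, rng):
            survivors.append(seq)
    return survivors


def chunk_coverage(codec, packets) -> np.ndarray:
    """How many packets each original chunk is present in.

    A chunk is present in a packet when its bytes feed the packet's XOR an
    odd number of times — directly or through auxiliary/intermediate parity
    symbols.  Rarely covered chunks are the coupon-collector failure mode:
    losing the few packets containing them makes the file unrecoverable;
    precoded codecs spread chunks over many more packets than plain LT.
    """
    expansion = codec.chunk_expansion()
    counts = np.zeros(codec.chunk_count, dtype=np.int64)
    for p in packets:
        mask = 0
        for i in codec.indices_for(p):
            mask ^= expansion[i]
        j = 0
        while mask:
            if mask & 1:
                counts[j] += 1
            mask >>= 1
            j += 1
    return counts


def sequences_to_packets(seqs, layout: PacketLayout, chunk_size: int,
                         mapping: BaseMapping = DEFAULT_MAPPING
                         ) -> tuple[list[Packet], int]:
    """Translate DNA sequences back into verified packets.

    Sequences failing translation, structural parsing, or the integrity
    check are counted as erased, not fatal — the erasure channel at work.
    """
    packets: list[Packet] = []
    erased = 0
    for seq in seqs:
        try:
            raw = dna_to_bytes(seq, mapping)
            packets.append(deserialize_packet(raw, layout, chunk_size))
        except (IllegalSymbolError, FormatError, IntegrityError):
            erased += 1
    return packets, erased


def decode_packets(codec, packets, padding: int | None = None
                   ) -> tuple[str | None, bytes]:
    """Solve the decode system and reassemble the byte stream.

    Returns (filename, data); the filename is None unless a header chunk
    was encoded.  Raises :class:`DecodeError` while unknowns remain
    unresolved.
    """
    if not packets:
        raise DecodeError("no packets survived the channel")
    system = codec.system(packets)
    result = gauss_solve(system, required=range(codec.chunk_count))
    if not result.ok:
        raise DecodeError(
            f"undecodable: rank {result.rank}/{system.n_unknowns}, "
            f"{len(result.missing)} chunk unknowns unresolved")
    chunks = result.solved[:codec.chunk_count]
    return assemble_data(chunks, codec.header_present, padding)


@dataclass
class EncodeResult:
    codec: object
    packets: list[Packet]
    sequences: list[DnaSequence]


@dataclass
class DecodeResult:
    filename: str | None
    data: bytes
    packets_used: int
    erased: int


def encode(data: bytes, *, filename: str | None = None, codec: str = "lt",
           chunk_size: int | None = None, num_chunks: int | None = None,
           layout: PacketLayout | None = None,
           dist: DegreeDistribution | None = None,
           q: int = 2, epsilon: float = 0.1,
           aux_seed: int = DEFAULT_AUX_SEED,
           mode: str = "until-decodable", bound: float = 0.2,
           count: int | None = None, overhead_extra: int | None = None,
           rules: RuleConfig | None = None, rng_seed: int = 1,
           mapping: BaseMapping = DEFAULT_MAPPING) -> EncodeResult:
    """Full encode pipeline: bytes -> packets -> DNA sequences.

    ``mode`` selects the generation strategy: ``until-decodable`` (default;
    pseudo-decoder driven, plus a static overhead of ``overhead_extra``
    packets, default 5% of the chunk count but at least 2), ``strict`` /
    ``weak`` (error-bounded generation of ``count`` packets), or ``sweep``
    (full seed enumeration, keep the ``count`` best-scoring packets).
    """
    if chunk_size is None and num_chunks is None:
        chunk_size = 32
    block = split_into_chunks(data, chunk_size=chunk_size,
                              num_chunks=num_chunks,
                              header_filename=filename)
    layout = layout or PacketLayout()
    cdc = make_codec(codec, block=block, layout=layout, dist=dist, q=q,
                     epsilon=epsilon, aux_seed=aux_seed)
    rng = DeterministicRng(rng_seed)
    if mode == "until-decodable":
        if overhead_extra is None:
            overhead_extra = max(2, math.ceil(0.05 * cdc.chunk_count))
        packets = encode_until_decodable(cdc, overhead_extra, rng)
    elif mode in ("strict", "weak"):
        if rules is None or count is None:
            raise ParameterError(f"{mode} mode requires rules and count")
        packets = encode_with_bound(cdc, rules, mode, bound, count, rng,
                                    mapping)
    elif mode == "sweep":
        if rules is None or count is None:
            raise ParameterError("sweep mode requires rules and count")
        entries = sweep_seed_space(cdc, rules, mapping)
        packets = [cdc.encode(e.seed) for e in entries[:count]]
    else:
        raise ParameterError(f"unknown encode mode {mode!r}")
    sequences = [packet_to_sequence(p, layout, mapping, index=i)
                 for i, p in enumerate(packets)]
    return EncodeResult(codec=cdc, packets=packets, sequences=sequences)


def decode(source, *, codec: str = "lt", chunk_size: int | None = None,
           n: int | None = None, layout: PacketLayout | None = None,
           dist: DegreeDistribution | None = None,
           q: int = 2, epsilon: float = 0.1,
           aux_seed: int = DEFAULT_AUX_SEED, header_present: bool = True,
           padding: int | None = None,
           mapping: BaseMapping = DEFAULT_MAPPING) -> DecodeResult:
    """Full decode pipeline: FASTA path or DnaSequence list -> bytes.

    ``chunk_size`` is inferred from the sequence length for seed-based
    layouts; ``n`` is taken from the packets' chunk-count field when the
    layout transmits it.
    """
    seqs = read_fasta(source) if not isinstance(source, list) else source
    if not seqs:
        raise DecodeError("no sequences to decode")
    layout = layout or PacketLayout()
    if chunk_size is None:
        if layout.mode != "seed_based":
            raise ParameterError(
                "chunk_size cannot be inferred for explicit_list layouts")
        raw_len = len(seqs[0].bases) // 4
        chunk_size = raw_len - layout.packet_length(0)
        if chunk_size < 1:
            raise FormatError("sequences shorter than the packet overhead")
    packets, erased = sequences_to_packets(seqs, layout, chunk_size, mapping)
    if not packets:
        raise DecodeError("every sequence was erased")
    if n is None:
        n = packets[0].total_chunks
        if n is None:
            raise ParameterError(
                "chunk count is neither in the packets nor supplied")
    cdc = make_codec(codec, n=n, chunk_size=chunk_size, layout=layout,
                     dist=dist, q=q, epsilon=epsilon, aux_seed=aux_seed,
                     header_present=header_present)
    filename, data = decode_packets(cdc, packets, padding)
    return DecodeResult(filename=filename, data=data,
                        packets_used=len(packets), erased=erased)
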