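"""LT codec: chunking, seeded selection, XOR combination, decode rows."""

import math

import pytest

from ratelessdna import (
    DeterministicRng,
    PacketLayout,
    ParameterError,
    choose_chunk_indices,
    decode_packets,
    default_distribution,
    gauss_solve,
    ideal_soliton,
    lt_encode,
    lt_encode_priority,
    lt_rows,
    make_codec,
    split_into_chunks,
)
from ratelessdna.lt_codec import derive_selection, xor_chunks

from conftest import random_payload


class TestSplitting:
    def test_ten_bytes_into_chunks_of_four(self):
        block = split_into_chunks(b"0123456789", chunk_size=4)
        assert block.n == 3 and block.padding == 2
        assert block.chunks[2] == b"89\x00\x00"

    def test_exact_division_has_no_padding(self):
        block = split_into_chunks(b"0123456789ab", chunk_size=4)
        assert block.n == 3 and block.padding == 0

    def test_header_chunk_is_prepended_as_chunk_zero(self):
        block = split_into_chunks(b"0123456789", chunk_size=8,
                                  header_filename="f")
        assert block.n == 3 and block.header_present
        from ratelessdna import parse_header_chunk

        assert parse_header_chunk(block.chunks[0]) == ("f", 6)

    def test_num_chunks_mode(self):
        block = split_into_chunks(b"x" * 100, num_chunks=7)
        assert block.n == 7
        assert all(len(c) == block.chunk_size for c in block.chunks)

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            split_into_chunks(b"", chunk_size=4)

    def test_exactly_one_splitting_parameter(self):
        with pytest.raises(ParameterError):
            split_into_chunks(b"xy", chunk_size=1, num_chunks=2)


class TestIndexSelection:
    def test_full_degree_selects_every_index(self):
        rng = DeterministicRng(3)
        assert sorted(choose_chunk_indices(rng, 10, 10)) == list(range(10))

    def test_indices_are_distinct(self):
        rng = DeterministicRng(9)
        for _ in range(200):
            picked = choose_chunk_indices(rng, 5, 12)
            assert len(set(picked)) == 5

    def test_degree_beyond_n_rejected(self):
        with pytest.raises(ParameterError):
            choose_chunk_indices(DeterministicRng(1), 5, 4)

    def test_uniformity_of_single_draws(self):
        # 1e5 degree-1 selections over 10 chunks: each frequency within
        # 4 standard errors of 0.1
        rng = DeterministicRng(77)
        n = 100_000
        counts = [0] * 10
        for _ in range(n):
            counts[choose_chunk_indices(rng, 1, 10)[0]] += 1
        se = math.sqrt(0.1 * 0.9 / n)
        for c in counts:
            assert abs(c / n - 0.1) < 4 * se


class TestEncoding:
    def test_xor_of_selected_chunks(self):
        # indicator (0,1,0,0,1,1) over six chunks
        chunks = [bytes([17 * i, 3 * i]) for i in range(6)]
        payload = xor_chunks(chunks, [1, 4, 5])
        expected = bytes(a ^ b ^ c for a, b, c in
                         zip(chunks[1], chunks[4], chunks[5]))
        assert payload == expected

    def test_degree_one_packet_equals_its_chunk(self, rnd):
        block = split_into_chunks(random_payload(rnd, 64), chunk_size=8)
        dist = default_distribution(block.n)
        layout = PacketLayout(seed_width=2)
        for seed in range(300):
            sel = derive_selection(seed, dist, block.n)
            if len(sel) == 1:
                packet = lt_encode(block, seed, dist, layout)
                assert packet.payload == block.chunks[sel[0]]
                break
        else:
            pytest.fail("no degree-1 seed found in 300 seeds")

    def test_encoding_is_deterministic(self, rnd, seed2_layout):
        block = split_into_chunks(random_payload(rnd, 50), chunk_size=5)
        dist = default_distribution(block.n)
        a = lt_encode(block, 123, dist, seed2_layout)
        b = lt_encode(block, 123, dist, seed2_layout)
        assert a == b and a.payload == b.payload

    def test_single_chunk_block_always_degree_one(self, rnd):
        block = split_into_chunks(b"tiny", chunk_size=4)
        dist = default_distribution(block.n)
        layout = PacketLayout(seed_width=2)
        for seed in (0, 5, 999):
            assert lt_encode(block, seed, dist, layout).payload == \
                block.chunks[0]

    def test_seed_must_fit_layout(self, rnd):
        block = split_into_chunks(b"abcdefgh", chunk_size=4)
        with pytest.raises(ParameterError):
            lt_encode(block, 70000, default_distribution(2),
                      PacketLayout(seed_width=2))


class TestDecodeRows:
    def test_row_matches_encoder_selection(self, rnd, seed2_layout):
        block = split_into_chunks(random_payload(rnd, 96), chunk_size=8)
        dist = default_distribution(block.n)
        packets = [lt_encode(block, s, dist, seed2_layout)
                   for s in range(30)]
        system = lt_rows(packets, block.n, dist)
        for packet, row_set in zip(packets, system.index_sets()):
            assert sorted(derive_selection(packet.seed, dist, block.n)) == \
                row_set

    def test_three_packet_cascade_recovers_chunks(self):
        # {C1, C1^C2, C2^C3} as explicit-list packets
        from ratelessdna import Packet

        chunks = [b"\xaa\x01", b"\xbb\x02", b"\xcc\x03"]
        x = xor_chunks
        packets = [
            Packet(payload=chunks[0], chunk_ids=(0,)),
            Packet(payload=x(chunks, [0, 1]), chunk_ids=(0, 1)),
            Packet(payload=x(chunks, [1, 2]), chunk_ids=(1, 2)),
        ]
        system = lt_rows(packets, 3, None)
        assert gauss_solve(system).solved == chunks

    def test_duplicate_packet_does_not_change_rank(self, rnd, seed2_layout):
        block = split_into_chunks(random_payload(rnd, 40), chunk_size=8)
        dist = default_distribution(block.n)
        packets = [lt_encode(block, s, dist, seed2_layout) for s in range(8)]
        base = gauss_solve(lt_rows(packets, block.n, dist)).rank
        doubled = gauss_solve(
            lt_rows(packets + [packets[0]], block.n, dist)).rank
        assert base == doubled

    def test_seed_based_rows_require_distribution(self, rnd, seed2_layout):
        block = split_into_chunks(random_payload(rnd, 40), chunk_size=8)
        dist = default_distribution(block.n)
        packets = [lt_encode(block, 1, dist, seed2_layout)]
        with pytest.raises(ParameterError):
            lt_rows(packets, block.n, None)


class TestRoundTrip:
    @pytest.mark.parametrize("size", [1, 37, 2048])
    def test_payload_recovered_bit_exact(self, rnd, size, seed2_layout):
        data = random_payload(rnd, size)
        block = split_into_chunks(data, chunk_size=16,
                                  header_filename="p.bin")
        codec = make_codec("lt", block=block, layout=seed2_layout)
        from ratelessdna import encode_until_decodable

        packets = encode_until_decodable(codec, overhead_extra=2,
                                         rng=DeterministicRng(5))
        filename, out = decode_packets(codec, packets)
        assert out == data and filename == "p.bin"


class TestPriorityEncoding:
    def test_every_priority_chunk_gets_a_degree_one_packet(self, rnd):
        block = split_into_chunks(random_payload(rnd, 160), chunk_size=8)
        layout = PacketLayout(mode="explicit_list", degree_width=1)
        priority = [2, 7, 11]
        packets = lt_encode_priority(
            block, ideal_soliton(block.n), layout, priority, 60,
            DeterministicRng(4))
        for chunk in priority:
            assert any(p.chunk_ids == (chunk,) for p in packets)
        # forced packets carry the chunk verbatim
        for p in packets:
            if len(p.chunk_ids) == 1 and p.chunk_ids[0] in priority:
                assert p.payload == block.chunks[p.chunk_ids[0]]

    def test_priority_chunks_overrepresented_in_small_degrees(self, rnd):
        block = split_into_chunks(random_payload(rnd, 160), chunk_size=8)
        layout = PacketLayout(mode="explicit_list", degree_width=1)
        priority = list(range(5))
        packets = lt_encode_priority(
            block, ideal_soliton(block.n), layout, priority, 2000,
            DeterministicRng(8))
        small = [p for p in packets
                 if len(p.chunk_ids) > 1 and len(p.chunk_ids) <= 4]
        pri_hits = sum(1 for p in small for c in p.chunk_ids
                       if c in set(priority))
        other_hits = sum(1 for p in small for c in p.chunk_ids
                         if c not in set(priority))
        # 5 priority chunks at double weight vs 15 others: expect the
        # per-chunk rate of priority chunks to clearly exceed the others'
        assert pri_hits / 5 > 1.3 * (other_hits / 15)

    def test_requires_explicit_layout(self, rnd):
        block = split_into_chunks(random_payload(rnd, 64), chunk_size=8)
        with pytest.raises(ParameterError):
            lt_encode_priority(block, ideal_soliton(block.n),
                               PacketLayout(), [0], 10, DeterministicRng(1))


def test_coupon_collector_overhead_exists(rnd):
    # LT needs strictly more than n packets on average (k + O(sqrt(k) ln^2)
    # symbols); 20 seeded trials at n = 100
    from ratelessdna import encode_until_decodable

    block = split_into_chunks(random_payload(rnd, 800), chunk_size=8)
    assert block.n == 100
    codec = make_codec("lt", block=block, layout=PacketLayout(seed_width=4))
    totals = []
    for trial in range(20):
        packets = encode_until_decodable(
            codec, overhead_extra=0, rng=DeterministicRng(1000 + trial))
        totals.append(len(packets))
    assert sum(totals) / len(totals) > 100
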