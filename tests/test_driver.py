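"""Workflow orchestration: sweeps, bounded generation, channel, pipelines."""

import random

import pytest

from ratelessdna import (
    DeterministicRng,
    PacketLayout,
    ParameterError,
    ProgressTimeoutError,
    RuleConfig,
    chunk_coverage,
    decode,
    encode,
    encode_until_decodable,
    encode_with_bound,
    gauss_solve,
    make_codec,
    simulate_channel,
    split_into_chunks,
    sweep_seed_space,
)
from ratelessdna.dna_layer import DnaSequence
from ratelessdna.rule_engine import default_rules

from conftest import random_payload

NO_RULES = RuleConfig(rules=())
ALWAYS_FAIL = RuleConfig(rules=("length",), length_limits=(1, 2))


def small_codec(rnd, seed_width=1, codec="lt"):
    block = split_into_chunks(random_payload(rnd, 64), chunk_size=8)
    return make_codec(codec, block=block,
                      layout=PacketLayout(seed_width=seed_width))


class TestSweep:
    def test_one_entry_per_seed_sorted_by_error(self, rnd):
        codec = small_codec(rnd, seed_width=1)
        entries = sweep_seed_space(codec, default_rules())
        assert len(entries) == 256
        totals = [e.report.total for e in entries]
        assert totals == sorted(totals)
        assert len({e.seed for e in entries}) == 256

    def test_ties_broken_by_ascending_seed(self, rnd):
        codec = small_codec(rnd, seed_width=1)
        entries = sweep_seed_space(codec, NO_RULES)  # all scores zero
        assert [e.seed for e in entries] == list(range(256))

    def test_deterministic_across_runs(self, rnd):
        codec = small_codec(rnd, seed_width=1)
        a = sweep_seed_space(codec, default_rules())
        b = sweep_seed_space(codec, default_rules())
        assert [(x.seed, x.sequence.bases, x.report.total) for x in a] == \
            [(x.seed, x.sequence.bases, x.report.total) for x in b]

    def test_large_seed_space_refused_without_override(self, rnd):
        codec = small_codec(rnd, seed_width=4)
        with pytest.raises(ParameterError):
            sweep_seed_space(codec, NO_RULES)


class TestBoundedGeneration:
    def test_strict_bound_zero_accepts_only_clean_packets(self, rnd):
        codec = small_codec(rnd)
        packets = encode_with_bound(codec, NO_RULES, "strict", 0.0, 10,
                                    DeterministicRng(1))
        assert len(packets) == 10  # every score is 0 with no rules

    def test_strict_unreachable_bound_times_out(self, rnd):
        codec = small_codec(rnd)
        with pytest.raises(ProgressTimeoutError):
            encode_with_bound(codec, ALWAYS_FAIL, "strict", 0.5, 5,
                              DeterministicRng(1), seed_budget=50)

    def test_weak_mode_accepts_all_when_scores_are_zero(self, rnd):
        codec = small_codec(rnd)
        packets = encode_with_bound(codec, NO_RULES, "weak", 0.0, 20,
                                    DeterministicRng(1))
        assert [p.seed for p in packets] == list(range(20))

    def test_weak_mode_never_accepts_saturated_scores(self, rnd):
        # a draw in [0, 1) is never >= 1.0
        codec = small_codec(rnd)
        with pytest.raises(ProgressTimeoutError):
            encode_with_bound(codec, ALWAYS_FAIL, "weak", 0.0, 1,
                              DeterministicRng(1), seed_budget=100)


class TestUntilDecodable:
    def test_single_chunk_stops_after_one_packet(self):
        block = split_into_chunks(b"tiny", chunk_size=4)
        codec = make_codec("lt", block=block,
                           layout=PacketLayout(seed_width=2))
        packets = encode_until_decodable(codec, overhead_extra=3,
                                         rng=DeterministicRng(1))
        assert len(packets) == 1 + 3

    @pytest.mark.parametrize("name", ["lt", "online", "raptor"])
    def test_returned_set_is_always_gaussian_decodable(self, rnd, name):
        block = split_into_chunks(random_payload(rnd, 120), chunk_size=8)
        codec = make_codec(name, block=block,
                           layout=PacketLayout(seed_width=2))
        packets = encode_until_decodable(codec, rng=DeterministicRng(3))
        result = gauss_solve(codec.system(packets),
                             required=range(codec.chunk_count))
        assert result.ok


class TestChannel:
    def test_zero_scores_all_survive(self):
        seqs = [DnaSequence("ACGTACGT", id=f"s{i}") for i in range(10)]
        out = simulate_channel(seqs, NO_RULES, 1, DeterministicRng(1))
        assert out == seqs

    def test_survivors_preserve_order(self, rnd):
        seqs = [DnaSequence("".join(rnd.choice("ACGT") for _ in range(60)),
                            id=f"s{i}") for i in range(60)]
        out = simulate_channel(seqs, default_rules(), 1, DeterministicRng(5))
        ids = [s.id for s in out]
        assert ids == sorted(ids, key=lambda x: int(x[1:]))

    def test_more_generations_erase_more(self, rnd):
        seqs = [DnaSequence("".join(rnd.choice("ACGT") for _ in range(60)),
                            id=f"s{i}") for i in range(200)]
        one = len(simulate_channel(seqs, default_rules(), 1,
                                   DeterministicRng(5)))
        five = len(simulate_channel(seqs, default_rules(), 5,
                                    DeterministicRng(5)))
        assert five <= one


class TestCoverage:
    def test_single_full_degree_packet_covers_everything(self, rnd):
        from ratelessdna import Packet

        block = split_into_chunks(random_payload(rnd, 32), chunk_size=8)
        codec = make_codec("lt", block=block,
                           layout=PacketLayout(mode="explicit_list",
                                               degree_width=1))
        from ratelessdna.lt_codec import xor_chunks

        pkt = Packet(payload=xor_chunks(list(block.chunks), range(block.n)),
                     chunk_ids=tuple(range(block.n)), total_chunks=block.n,
                     degree=block.n)
        assert chunk_coverage(codec, [pkt]).tolist() == [1] * block.n

    def test_empty_packet_list_gives_zeros(self, rnd):
        codec = small_codec(rnd)
        assert chunk_coverage(codec, []).tolist() == [0] * codec.chunk_count

    def test_lt_counts_sum_to_total_degree(self, rnd):
        codec = small_codec(rnd, seed_width=2)
        packets = [codec.encode(s) for s in range(50)]
        total_degree = sum(len(codec.indices_for(p)) for p in packets)
        assert chunk_coverage(codec, packets).sum() == total_degree

    def test_precoding_lifts_minimum_coverage_over_lt(self, rnd):
        # at n = 196 and 500 packets per trial, the Raptor precode spreads
        # every chunk into far more packets than plain LT manages
        data = random_payload(rnd, 196 * 4)
        block = split_into_chunks(data, chunk_size=4)
        layout = PacketLayout(seed_width=4)
        lt = make_codec("lt", block=block, layout=layout)
        rp = make_codec("raptor", block=block, layout=layout)
        rnd2 = random.Random(11)
        wins = 0
        for _ in range(50):
            lt_pk = [lt.encode(rnd2.randrange(2**31)) for _ in range(500)]
            rp_pk = [rp.encode(rnd2.randrange(2**31)) for _ in range(500)]
            wins += chunk_coverage(lt, lt_pk).min() <= \
                chunk_coverage(rp, rp_pk).min()
        assert wins >= 40  # >= 80% of trials


class TestFullPipeline:
    @pytest.mark.parametrize("codec_name", ["lt", "online", "raptor"])
    @pytest.mark.parametrize("size", [1, 100, 2000])
    @pytest.mark.parametrize("seed_width", [2, 4])
    def test_file_to_dna_to_file(self, rnd, codec_name, size, seed_width):
        data = random_payload(rnd, size)
        layout = PacketLayout(seed_width=seed_width)
        # q=1 keeps the Online outer code valid down to single-chunk files
        kw = dict(q=1, epsilon=0.5) if codec_name == "online" else {}
        result = encode(data, filename="f.bin", codec=codec_name,
                        chunk_size=16, layout=layout, rng_seed=7, **kw)
        back = decode(result.sequences, codec=codec_name, layout=layout,
                      **kw)
        assert back.data == data
        assert back.filename == "f.bin"

    def test_erased_sequences_are_survivable(self, rnd, seed2_layout):
        data = random_payload(rnd, 400)
        result = encode(data, filename="e.bin", chunk_size=16,
                        layout=seed2_layout, overhead_extra=15, rng_seed=3)
        # corrupt a few sequences: mutated bases must fail the checksum and
        # be treated as erasures, not poison the decode
        seqs = list(result.sequences)
        for i in (0, 3):
            bases = list(seqs[i].bases)
            bases[10] = "A" if bases[10] != "A" else "C"
            seqs[i] = DnaSequence("".join(bases), id=seqs[i].id)
        bases = list(seqs[5].bases)
        bases[4] = "N"  # illegal symbol: erased at translation
        seqs[5] = DnaSequence("".join(bases), id=seqs[5].id)
        back = decode(seqs, codec="lt", layout=seed2_layout)
        assert back.data == data
        assert back.erased >= 1  # the illegal-symbol sequence at least

    def test_no_header_round_trip_with_out_of_band_padding(self, rnd,
                                                           seed2_layout):
        data = random_payload(rnd, 100)
        result = encode(data, filename=None, chunk_size=16,
                        layout=seed2_layout, rng_seed=5)
        back = decode(result.sequences, codec="lt", layout=seed2_layout,
                      header_present=False, padding=12)  # 7*16 - 100
        assert back.data == data and back.filename is None
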