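# Methods

This note records the models implemented by `ratelessdna`, the parameter
choices that matter, the numerical conventions, and the limits of what
the test suite demonstrates.

## Erasure-channel model

All three codecs treat DNA storage as an erasure channel. A packet either
arrives intact or is lost: sequencing errors are converted into erasures
by the per-packet integrity layer (CRC or Reed–Solomon), and strand loss
is modelled directly. Consequently no base-level mutation process is
simulated; the channel simulator erases each sequence independently with
probability min(score × generations, 1), where `score` comes from the
rule engine and `generations` scales storage duration/amplification
rounds. This reduction is what makes fountain codes a natural fit — the
decoder never needs to know *which* sequences were lost.

## Codecs

**LT.** The file is split into n equal chunks (last chunk zero-padded; an
optional header chunk, index 0, stores the filename and padding count so
the decoder needs no out-of-band metadata). A packet's seed initializes
the deterministic generator; the first draw samples the degree d, the
following draws pick d distinct chunk indices by rejection sampling, and
the payload is their XOR. The decoder re-runs the identical seeded
selection, so seed-based packets cost 2–4 bytes of metadata regardless of
degree.

**Online.** M = ⌈0.55·q·ε·F⌉ auxiliary blocks are built from a dedicated
`aux_seed` (default 1, shared by both ends); each chunk is XORed into q
distinct aux blocks. The inner LT code runs over F + M symbols, chunks
first. At decode time each aux definition contributes a constraint row
with zero right-hand side; solving the joint system realizes the
reverse-order unwinding of the two stages. The inner degree distribution
is not standardized anywhere visible, so the package default is the same
Robust Soliton used for LT, over F + M (a documented open choice).

**Raptor.** Precode sizes follow the smallest-integer conditions

    f(k): min x with x(x−1) ≥ 2k
    S:    min prime ≥ ⌈0.01k⌉ + f(k)
    H:    min x with C(x, ⌈x/2⌉) ≥ f(k) + S

giving L = k + S + H intermediates: the chunks, S circulant parities
(chunk i enters blocks starting at i mod S with step 1 + (i div S) mod
(S−1), three memberships each), and H half-weight parities over the
first k + S symbols (symbol j uses the (j mod C(H,⌈H/2⌉))-th H-bit
codeword of weight ⌈H/2⌉, ascending numeric order — the codeword supply
is smaller than k + S for large k, so codewords repeat cyclically). The
inner code expands a seed into (d, a, b): d from the fixed table via a
uniform draw in [0, 2²⁰), a ∈ [1, L′), b ∈ [0, L′) with L′ the smallest
prime ≥ L; the walk b → (b + a) mod L′ emits the first d in-range
positions. Operation is non-systematic.

Measured behaviour at k = 1000: the mean number of packets beyond k
needed for Gaussian decoding is ≈ 2.9 (100 trials, sd 2.3) — a few
tenths of a packet above the 1–2 packets the ideal construction family
is known for. The gap is attributable to two deliberate simplifications:
the h(k) bound above undersizes the half-weight stage relative to the
RFC 5053 sizing C(H,⌈H/2⌉) ≥ k + S (H = 9 instead of 13 at k = 1000,
with cyclic codeword reuse), and the tuple walk is a plain modular orbit
rather than the full standardized generator. At k = 30, 38 received
packets decode in ≳ 99% of trials; 32 packets in only ≈ 74%.

## Decoding

Every decode is A·x = b over GF(2). Rows are Python integers used as bit
sets; right-hand sides are payloads packed into integers, so one row
operation is two arbitrary-precision XORs and the A/b consistency
contract holds by construction. "Partial pivoting" degenerates in GF(2)
to picking any row with a 1 in the pivot column; rows are consumed in
arrival order (earliest wins), which makes elimination deterministic, and
incremental (per-packet) and batch elimination provably reach the same
reduced system.

Decode success means the *chunk* unknowns are uniquely determined, not
full rank: auxiliary and parity unknowns may remain free. This is
checked by a null-space argument — one basis vector per pivotless
column, back-solved through the echelon basis; if none touches a chunk
coordinate the chunks are determined. (For Raptor the two notions
coincide: each parity unknown appears in exactly one parity row and is
therefore always completable, so rank deficiency necessarily lands on
chunks.) A row that reduces to 0 = nonzero signals an undetected packet
error and aborts with a corruption error rather than returning a
poisoned solution.

Belief propagation is the classical peeling decoder (resolve any
degree-1 row, XOR the value out everywhere, cascade). It is strictly
weaker than elimination and is provided for its incremental cost
profile; the pseudo-decoder runs elimination on structure only (no
payloads) to let the encoder stop at the exact decodability threshold.

## Deterministic randomness

All randomness flows through a 32-bit xorshift generator (Marsaglia's
13/17/5 triple). The raw seed is first passed through a murmur3 fmix32
avalanche. This matters: packet seeds are frequently sequential (seed
sweeps) or outputs of another xorshift, and unscrambled nearby seeds
walk overlapping xorshift orbits — packets would then select nearly
identical chunk sets and the decode matrix would stall far from full
rank. With scrambling, LT at n ≈ 100–300 decodes at ≈ 4% mean overhead,
in line with maximum-likelihood decoding of Soliton-distributed codes.
Uniform integers below n use rejection sampling (no modulo bias); seed 0
maps to a fixed nonzero constant because 0 is the xorshift fixed point.

The default LT distribution is Robust Soliton with K = round(√n) capped
to n − 1 and δ = 0.05, degenerating to Ideal Soliton for n < 2. Both
ends derive it from n alone, so it needs no transmission. Under Gaussian
decoding the overhead is insensitive to (K, δ) within sane ranges (the
spike mainly helps peeling decoders); the choice is a conventional
middle ground.

## Packet format and integrity

Integers are big-endian in configurable widths; the checksum covers all
preceding serialized bytes (seed and chunk-count corruption is fatal to
decoding, so it must be protected too — a deliberate choice the field
layout tables leave open). CRC-8 uses polynomial 0x07, init 0,
non-reflected; CRC-32 is the IEEE 802.3 reflected variant; Reed–Solomon
works over GF(2⁸) with primitive polynomial 0x11D, generator α = 2,
first root exponent 0, and corrects up to ⌊nsym/2⌋ byte errors (beyond
that the packet is erased). Chunk indices are 0-based everywhere. In
explicit-list layouts the id list is length-prefixed by the degree
field, which is therefore mandatory there.

## Rule engine defaults

Each rule contributes an error in [0, 1]; contributions are summed
(scores above 1 mean several violations) and multiplied by a global
`scale` for calibration. Published mutation studies disagree
considerably, so the defaults deliberately overestimate and `scale` is
the documented down-adjustment knob. Defaults, all overridable in
config:

* homopolymer step curve: 0 for runs ≤ 3, 0.3 at 4, 0.7 at 5, 1.0 from 6;
* dinucleotide repeats: 0.5 at 4 copies, 0.8 at 5, 1.0 from 6;
  trinucleotide: 0.5 at 3, 0.8 at 4, 1.0 from 5;
* GC window: 50 nt (windowed error = worst window through the same
  clamped quartic, evaluated in exact rational arithmetic at the scalar
  entry point so the 40–60% plateau is exactly zero);
* per-base mutation weights: a uniform 5·10⁻⁴ per base — site-specific
  published weights are configuration, not shipped constants;
* the `erlich_zielinski` preset restricts to homopolymers + GC, matching
  the reference rule set of the earlier LT-based storage work.

Under the full default set, uniformly random 120-nt sequences score a
median ≥ 0.5 (measured ≈ 0.71 over 10⁴ draws) — random DNA is mostly
unusable, which is precisely the argument for fountain-code
preselection. The constant chunk-count field maps to a leading
homopolymer in every packet of one encoding; shrinking or omitting that
field (supported) is the remedy.

## Experiment scales

The shipped tests and acceptance checks run at desk scale, chosen so the
full suite completes in minutes on one core: sweeps enumerate 2-byte
seed spaces (65,536 candidates), Raptor overhead uses k = 1000 with 50
trials, coverage comparisons use n = 196 chunks and 500 packets per
trial (50 trials), solver equivalences use hundreds of random systems up
to 20×20. Chunk coverage counts a chunk as present in a packet when it
feeds the packet's XOR an odd number of times, expanding through
aux/parity symbols — the measure under which precoded codecs visibly
dominate plain LT (minimum coverage ≈ 28 vs maximum ≈ 30 at those
settings).

## What the synthetic conditions do not show

Payloads are random bytes or small text; real files with long constant
regions stress the rules differently (systematic codes fare worse there,
which is one reason the Raptor implementation is non-systematic).
Sequencing preprocessing (clustering, abundance ordering) is out of
scope: FASTA order is preserved as given. No real synthesis/sequencing
error profile is used — the rule scores are calibrated upper bounds, not
fitted error rates, so channel-simulation results indicate relative code
quality, not absolute survival probabilities.
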