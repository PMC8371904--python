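# ratelessdna

Fountain codes for DNA data storage: encode arbitrary binary files into
synthesizable DNA sequences with near-optimal rateless erasure codes, and
recover the original file from any sufficiently large subset of the
sequences that survive synthesis, storage, and sequencing.

DNA is a dense, durable storage medium, but the channel is hostile: long
homopolymer runs, unbalanced GC content, and micro-satellite repeats make
individual strands error-prone, and whole strands are routinely lost. A
rateless (fountain) code turns this into an erasure problem it can win:
from a file split into *n* chunks it can mint an unbounded stream of
encoded packets, any ≈ (1+ε)·n of which reconstruct the file — so the
encoder is free to discard every candidate sequence that violates the
biochemical constraints and keep only clean ones.

The package is aimed at researchers comparing coding schemes for DNA
storage and at anyone who needs a transparent, pure-Python reference
implementation of LT, Online, and Raptor codes over GF(2).

## What is implemented

**Codecs.** Three fountain codes sharing one packet model and decoder:

* **LT** — degree *d* drawn from a Soliton distribution, *d* distinct
  chunks XORed per packet. Ideal Soliton: ρ(1) = 1/N, ρ(k) = 1/(k(k−1));
  Robust Soliton: μ(i) ∝ ρ(i) + τ(i) with a spike at degree K controlled
  by the failure probability δ.
* **Online** — an outer code first XORs every chunk into *q* of
  M = ⌈0.55·q·ε·F⌉ auxiliary blocks; an inner LT code then runs over the
  F + M symbols. The aux constraints join the decode system as
  zero-right-hand-side rows.
* **Raptor** — a fixed-rate precode expands k chunks into
  L = k + S + H intermediates (S circulant LDPC-style parities, each
  chunk in exactly 3 of them, plus H half-weight parities), then an inner
  LT code with the fixed degree table over {1, 2, 3, 4, 10, 11, 40} and a
  (d, a, b) modular index walk encodes the intermediates ratelessly.

**Decoders.** Every decode is a GF(2) linear system A·x = b: Gaussian
elimination (rows as integer bit sets, payloads XORed alongside), a
belief-propagation peeling decoder, and a structure-only pseudo-decoder
used to stop packet generation the moment the set becomes decodable.

**Packet model.** Configurable wire format `#chunks | seed (or explicit
chunk list) | payload | checksum` with big-endian fields of configurable
widths; checksums: none, CRC-8, CRC-32, or Reed–Solomon over GF(2⁸) with
a configurable parity size that *repairs* up to ⌊nsym/2⌋ byte errors
before a packet is accepted. An optional header chunk carries the
filename and padding length.

**DNA layer and rules.** Two bits per base (00→A, 01→C, 10→G, 11→T, or
any bijection), FASTA I/O, and a rule engine scoring sequences for
homopolymers, overall and windowed GC content
(err_gc = clamp((−x⁴/7200 + x³/36 − 121x²/72 + 175x/6 + 100)/100)),
di-/trinucleotide repeats, illegal symbols/motifs, length bounds, and
per-base mutation weights. Scores drive packet preselection (seed-space
sweeps, strict/weak error bounds) and the erasure-channel simulator
(drop probability min(score × generations, 1)).

## Worked example

```sh
$ ratelessdna encode tale.txt --codec raptor --chunk-size 16 \
      --seed-width 2 --out tale.fasta
encoded 96 bytes into 11 sequences of 104 nt (7 chunks, codec=raptor)

$ head -2 tale.fasta
>pkt_0 seed=53755
AAAAAAAAAAAAAACTTCACTTGTAATACCCACAGGAGCAACGGCAGCAAAAAACCAATT

$ ratelessdna decode tale.fasta --codec raptor --seed-width 2 \
      --out tale_out.txt
decoded 96 bytes (tale.txt) from 11 packets (0 erased)
```

The 96-byte file became 7 chunks of 16 bytes (one is the header chunk
carrying the filename and padding); 11 packets of 26 bytes each — chunk
count, seed, payload, CRC-32 — map to 104-nt sequences, and any
decodable subset of them reconstructs the file bit-exactly.

The same sequences can be scored against the stability rules:

```python
>>> from ratelessdna import read_fasta, total_error, preset
>>> report = total_error(read_fasta("tale.fasta")[0], preset("default"))
>>> round(report.total, 3)
3.322
>>> report.per_rule["homopolymer"]
1.0
```

A score above 1 means several rules fired at saturation — here the
leading `AAAA…` run produced by the constant chunk-count field. Packet
preselection exists for exactly this reason: sweep the whole seed space
(`ratelessdna sweep`), sort by score, and synthesize only the best
candidates, or shrink/omit the chunk-count field.

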