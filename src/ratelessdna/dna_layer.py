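"""Binary <-> DNA conversion, FASTA I/O, and composition analytics.

Packets are mapped to DNA two bits per base (the maximal information
density for a four-letter alphabet): each byte becomes four bases, most
significant bit pair first.  The default assignment is 00->A, 01->C,
10->G, 11->T; any bijection of the four bit pairs onto the four bases is
accepted.  One-bit-per-base schemes trade density for robustness and are
deliberately not implemented — constraint violations are avoided by
packet preselection instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, IllegalSymbolError, ParameterError

__all__ = [
    "DnaSequence",
    "BaseMapping",
    "DEFAULT_MAPPING",
    "bytes_to_dna",
    "dna_to_bytes",
    "read_fasta",
    "write_fasta",
    "sliding_window_composition",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class DnaSequence:
    """A DNA string over {A, C, G, T} with a record identifier."""

    bases: str
    id: str = ""

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class BaseMapping:
    """Bijection from the four 2-bit values onto the four bases."""

    pair_to_base: tuple[str, str, str, str]
    _byte_table: tuple[str, ...] = field(init=False, repr=False, compare=False)
    _base_to_pair: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if sorted(self.pair_to_base) != sorted(_BASES):
            raise ParameterError(
                "mapping must be a bijection onto {A, C, G, T}")
        table = tuple(
            "".join(self.pair_to_base[(byte >> shift) & 0b11]
                    for shift in (6, 4, 2, 0))
            for byte in range(256))
        object.__setattr__(self, "_byte_table", table)
        object.__setattr__(
            self, "_base_to_pair",
            {b: i for i, b in enumerate(self.pair_to_base)})


DEFAULT_MAPPING = BaseMapping(("A", "C", "G", "T"))


def bytes_to_dna(data: bytes, mapping: BaseMapping = DEFAULT_MAPPING,
                 id: str = "") -> DnaSequence:
    """Four bases per byte, most significant bit pair first."""
    table = mapping._byte_table
    return DnaSequence("".join(table[b] for b in data), id=id)


def dna_to_bytes(seq: DnaSequence | str,
                 mapping: BaseMapping = DEFAULT_MAPPING) -> bytes:
    """Inverse of :func:`bytes_to_dna`.

    Raises :class:`IllegalSymbolError` for non-ACGT symbols (the sequence
    is then treated as erased) and :class:`FormatError` when the length is
    not a multiple of four.
    """
    bases = seq.bases if isinstance(seq, DnaSequence) else seq
    if len(bases) % 4:
        raise FormatError("DNA length must be a multiple of 4 bases")
    lookup = mapping._base_to_pair
    out = bytearray(len(bases) // 4)
    try:
        for i in range(0, len(bases), 4):
            out[i // 4] = (lookup[bases[i]] << 6 | lookup[bases[i + 1]] << 4
                           | lookup[bases[i + 2]] << 2 | lookup[bases[i + 3]])
    except KeyError as exc:
        raise IllegalSymbolError(f"illegal DNA symbol {exc.args[0]!r}") from exc
    return bytes(out)


def read_fasta(path) -> list[DnaSequence]:
    """Parse a FASTA file, preserving record order exactly.

    Sequences are normalized to uppercase; multi-line records are
    concatenated.  Abundance ordering (most-sequenced cluster first) is
    the caller's concern — whatever order the file has is kept.
    """
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(
                        f"{path}: line {lineno}: expected '>' header, "
                        f"got {line.strip()[:20]!r}")
                break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description or rec.id
        records.append(DnaSequence(str(rec.seq).upper(), id=header))
    return records


def write_fasta(seqs, path) -> None:
    """Write sequences in order; ids become FASTA headers verbatim."""
    records = []
    for i, s in enumerate(seqs):
        rid = s.id or f"seq_{i}"
        first, _, rest = rid.partition(" ")
        records.append(SeqRecord(Seq(s.bases), id=first, description=rest))
    SeqIO.write(records, str(path), "fasta")


def sliding_window_composition(seq: DnaSequence | str,
                               window: int) -> np.ndarray:
    """Per-window relative base frequencies.

    Returns an array of shape (len - window + 1, 4) with columns ordered
    A, C, G, T; every row sums to 1.  Window starts advance one base at a
    time.
    """
    bases = seq.bases if isinstance(seq, DnaSequence) else seq
    if window < 1 or window > len(bases):
        raise ParameterError("window must satisfy 1 <= window <= length")
    arr = np.frombuffer(bases.encode("ascii"), dtype=np.uint8)
    out = np.empty((len(bases) - window + 1, 4))
    for col, base in enumerate(_BASES):
        hits = (arr == ord(base)).astype(np.int32)
        csum = np.concatenate(([0], np.cumsum(hits)))
        out[:, col] = (csum[window:] - csum[:-window]) / window
    return out
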