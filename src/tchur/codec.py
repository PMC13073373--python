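"""Payload <-> nucleotide codecs and FASTA plumbing.

Digital payloads are stored at the theoretical density of 2 bits per
nucleotide: each byte becomes four quaternary digits (MSB-first bit pairs)
and each digit maps to one base.  The default mapping is

    digit  0  1  2  3
    base   A  T  C  G
    bits   00 01 10 11

so that ``0x41`` (ASCII ``A``, bits ``01 00 00 01``) encodes to the digit
vector ``[1, 0, 0, 1]`` = ``TAAT``.  Both mappings are configurable but must
stay bijections.

The optimizer works on quaternary digit vectors; :class:`NucleotideSequence`
keeps the digit view and the base-string view consistent at all times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "EncodingMap",
    "NucleotideSequence",
    "DEFAULT_MAP",
    "text_to_dna",
    "dna_to_text",
    "digits_to_bases",
    "bases_to_digits",
    "reverse_complement_digits",
    "read_fasta",
    "write_fasta",
    "make_benchmark_text",
    "benchmark_sequence",
]


@dataclass(frozen=True)
class EncodingMap:
    """Bijective digit->base mapping; bit-pair value *is* the digit."""

    digit_to_base: tuple[str, str, str, str] = ("A", "T", "C", "G")

    def __post_init__(self) -> None:
        if sorted(self.digit_to_base) != ["A", "C", "G", "T"]:
            raise ValueError(
                f"digit_to_base must be a permutation of A/C/G/T, got {self.digit_to_base}"
            )

    @property
    def base_to_digit(self) -> dict[str, int]:
        return {b: d for d, b in enumerate(self.digit_to_base)}


DEFAULT_MAP = EncodingMap()

# complement partners under the DEFAULT digit order (A<->T, C<->G) are the
# xor-1 pairs 0<->1, 2<->3; for arbitrary maps we derive the permutation.
_COMPLEMENT_BASE = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _complement_digit_table(mapping: EncodingMap) -> np.ndarray:
    b2d = mapping.base_to_digit
    return np.array(
        [b2d[_COMPLEMENT_BASE[mapping.digit_to_base[d]]] for d in range(4)],
        dtype=np.int8,
    )


@dataclass(frozen=True)
class NucleotideSequence:
    """A DNA sequence with paired base-string and digit-vector views.

    Invariant: ``len(bases) == len(digits)`` and the two views round-trip
    under ``mapping``.  Construct through :meth:`from_bases` /
    :meth:`from_digits` rather than directly.
    """

    bases: str
    digits: np.ndarray = field(compare=False)
    mapping: EncodingMap = DEFAULT_MAP

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise ValueError("sequence must contain at least one base")
        if len(self.bases) != len(self.digits):
            raise ValueError("bases and digits views differ in length")

    @classmethod
    def from_bases(cls, bases: str, mapping: EncodingMap = DEFAULT_MAP) -> "NucleotideSequence":
        bases = bases.upper()
        bad = set(bases) - set("ACGT")
        if bad:
            raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")
        return cls(bases=bases, digits=bases_to_digits(bases, mapping), mapping=mapping)

    @classmethod
    def from_digits(cls, digits, mapping: EncodingMap = DEFAULT_MAP) -> "NucleotideSequence":
        digits = np.asarray(digits, dtype=np.int8)
        return cls(bases=digits_to_bases(digits, mapping), digits=digits, mapping=mapping)

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self) -> "NucleotideSequence":
        rc = reverse_complement_digits(self.digits, self.mapping)
        return NucleotideSequence.from_digits(rc, self.mapping)


def digits_to_bases(digits, mapping: EncodingMap = DEFAULT_MAP) -> str:
    digits = np.asarray(digits)
    if digits.size == 0:
        raise ValueError("empty digit vector")
    if digits.min() < 0 or digits.max() > 3:
        raise ValueError("digits must lie in {0,1,2,3}")
    lut = np.array(mapping.digit_to_base)
    return "".join(lut[digits.astype(np.int64)])


def bases_to_digits(bases: str, mapping: EncodingMap = DEFAULT_MAP) -> np.ndarray:
    if not bases:
        raise ValueError("empty base string")
    b2d = mapping.base_to_digit
    try:
        return np.array([b2d[b] for b in bases.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-ACGT base {exc.args[0]!r}") from None


def reverse_complement_digits(digits: np.ndarray, mapping: EncodingMap = DEFAULT_MAP) -> np.ndarray:
    comp = _complement_digit_table(mapping)
    return comp[np.asarray(digits, dtype=np.int8)][::-1]


def text_to_dna(payload: bytes | str, mapping: EncodingMap = DEFAULT_MAP) -> NucleotideSequence:
    """Encode a payload at 2 bits/nt; L = 4 x byte count.

    Bit pairs are read MSB-first within each byte, so byte ``0x41`` yields
    digits ``[1, 0, 0, 1]``.
    """
    if isinstance(payload, str):
        payload = payload.encode("utf-8")
    if len(payload) == 0:
        raise ValueError("nothing to encode: payload is empty")
    data = np.frombuffer(payload, dtype=np.uint8)
    digits = np.empty(4 * len(data), dtype=np.int8)
    digits[0::4] = (data >> 6) & 3
    digits[1::4] = (data >> 4) & 3
    digits[2::4] = (data >> 2) & 3
    digits[3::4] = data & 3
    return NucleotideSequence.from_digits(digits, mapping)


def dna_to_text(seq: NucleotideSequence, mapping: EncodingMap | None = None) -> bytes:
    """Invert :func:`text_to_dna`; requires a multiple-of-4 length."""
    mapping = mapping or seq.mapping
    d = seq.digits.astype(np.uint8)
    if len(d) % 4 != 0:
        raise ValueError("sequence length is not a multiple of 4 nt (one byte = 4 nt)")
    quads = d.reshape(-1, 4)
    out = (quads[:, 0] << 6) | (quads[:, 1] << 4) | (quads[:, 2] << 2) | quads[:, 3]
    return out.astype(np.uint8).tobytes()


def write_fasta(records: list[tuple[str, NucleotideSequence]], path) -> None:
    """Write 60-column-wrapped FASTA; record ids must be unique and non-empty."""
    ids = [rid for rid, _ in records]
    if any(not rid for rid in ids):
        raise ValueError("empty FASTA record id")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate FASTA record ids")
    bio = [SeqRecord(Seq(seq.bases), id=rid, description="") for rid, seq in records]
    SeqIO.write(bio, str(path), "fasta")


def read_fasta(path, mapping: EncodingMap = DEFAULT_MAP) -> list[tuple[str, NucleotideSequence]]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.id, NucleotideSequence.from_bases(str(rec.seq), mapping)))
    return out


def make_benchmark_text(target_nt: int, seed: int) -> bytes:
    """Deterministic synthetic payload encoding to exactly ``target_nt`` nt.

    Stands in for an undisclosed benchmark text.  Returns
    ``ceil(target_nt / 4)`` bytes; when ``target_nt`` is not a multiple of 4
    the unused low bits of the final byte are zero padding
    (``pad_nt = 4 * ceil(target_nt / 4) - target_nt`` trailing nucleotides
    are dropped by :func:`benchmark_sequence`).
    """
    if target_nt < 4:
        raise ValueError("target_nt must be at least 4 (one byte)")
    n_bytes = math.ceil(target_nt / 4)
    pad_bits = 2 * (4 * n_bytes - target_nt)
    rng = np.random.default_rng(seed)
    data = rng.integers(0, 256, size=n_bytes, dtype=np.uint8)
    if pad_bits:
        data[-1] &= np.uint8((0xFF << pad_bits) & 0xFF)
    return data.tobytes()


def benchmark_sequence(
    target_nt: int, seed: int, mapping: EncodingMap = DEFAULT_MAP
) -> NucleotideSequence:
    """Encode the synthetic benchmark payload and trim the zero-bit padding."""
    full = text_to_dna(make_benchmark_text(target_nt, seed), mapping)
    if len(full) == target_nt:
        return full
    return NucleotideSequence.from_digits(full.digits[:target_nt], mapping)
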