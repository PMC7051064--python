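"""Reference sequence containers for a circular mitochondrial genome and a
NUMT-bearing nuclear background.

Coordinates follow two conventions throughout the package: internal arithmetic
is 0-based half-open, while every emitted coordinate (SAM, VCF, variant
tables) is 1-based per those standards.  Position arithmetic on the circle is
always modulo the genome length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"

# 256-entry lookup: ASCII byte -> base code 0..3 (255 = invalid)
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i

_DECODE_LUT = np.frombuffer(BASES.encode(), dtype=np.uint8)


def encode(sequence: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 array of base codes 0..3."""
    arr = _CODE_LUT[np.frombuffer(sequence.encode(), dtype=np.uint8)]
    if arr.size and arr.max() == 255:
        raise ValueError("sequence contains characters outside ACGT")
    return arr


def decode(codes: np.ndarray) -> str:
    return _DECODE_LUT[codes].tobytes().decode()


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement on base codes (A<->T, C<->G)."""
    return (3 - codes)[::-1]


def revcomp(sequence: str) -> str:
    return decode(revcomp_codes(encode(sequence)))


@dataclass(frozen=True)
class CircularGenome:
    """A circular reference sequence with a declared linearization origin.

    ``sequence`` is the linear representation starting at the origin; base 1
    (1-based) of the circle is ``sequence[0]``.
    """

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 200:
            raise ValueError(f"circular genome must be >= 200 bp, got {len(self.sequence)}")
        encode(self.sequence)  # validates alphabet

    @property
    def length(self) -> int:
        return len(self.sequence)

    def codes(self) -> np.ndarray:
        return encode(self.sequence)

    def base(self, position: int) -> str:
        """Base at a 1-based circular position (wraps modulo length)."""
        return self.sequence[(position - 1) % self.length]


@dataclass(frozen=True)
class NumtInsertion:
    """A nuclear insertion of mtDNA-derived sequence (NUMT).

    ``nuclear_start`` / ``mt_source_start`` are 0-based offsets; ``divergence``
    is the requested substitution rate per site applied when the mt segment
    was copied into the nuclear background.
    """

    nuclear_start: int
    mt_source_start: int
    source_length: int
    divergence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence <= 0.3):
            raise ValueError("NUMT divergence must be in [0, 0.3]")
        if self.source_length <= 0:
            raise ValueError("NUMT source_length must be positive")


@dataclass(frozen=True)
class NuclearBackground:
    """Nuclear reference with embedded NUMT copies of the mt genome."""

    name: str
    sequence: str
    numts: tuple[NumtInsertion, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for numt in self.numts:
            if numt.nuclear_start < 0 or numt.nuclear_start + numt.source_length > len(self.sequence):
                raise ValueError("NUMT interval outside nuclear sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def codes(self) -> np.ndarray:
        return encode(self.sequence)


def write_fasta(path: str | Path, entries: list[tuple[str, str]]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in entries]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
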