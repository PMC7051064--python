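"""Read mapping against the linearized circular reference (plus optional
nuclear decoy sequences), reference rotation, and the coordinate remapping
that supports patching calls across the linearization origin.

The mapper is k-mer seeded, ungapped, and substitution-only: a read maps
only if its best placement (across all reference sequences and both
orientations) has a mismatch fraction at or below the threshold and is
unique — a read with two co-optimal placements is discarded rather than
randomly assigned.  Reads spanning the linear end of the circular reference
cannot be placed and come back unmapped: this loss is exactly what the
rotate-and-patch step repairs.  Externally produced SAM is accepted as a
drop-in substitute.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .genome import CircularGenome, NuclearBackground, _CODE_LUT, encode

_RC_TABLE = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

logger = logging.getLogger(__name__)

DEFAULT_ROTATION = 8000
DEFAULT_PATCH_WINDOWS = ((1, 500), (15800, 16299))

#: placement policies: ``best_unique`` (default) keeps a read only if its
#: minimum-mismatch placement is unique; ``best_random`` random-assigns among
#: co-optimal placements; ``any_random`` random-assigns among *all* placements
#: within the mismatch budget (a naive-aligner negative control).
POLICIES = ("best_unique", "best_random", "any_random")


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    ref_name: str
    start: int               # 0-based offset on the linearized reference
    strand: str              # '+' or '-'
    aligned_sequence: str    # reference-oriented
    mismatch_count: int
    mapped: bool

    def __post_init__(self) -> None:
        if self.mapped and self.start < 0:
            raise ValueError("mapped record with negative start")

    @property
    def length(self) -> int:
        return len(self.aligned_sequence)

    @property
    def end(self) -> int:
        """0-based exclusive end."""
        return self.start + self.length


@dataclass(frozen=True)
class RotationConfig:
    """Rotation amount and the 1-based closed patch windows near the origin."""

    rotation: int = DEFAULT_ROTATION
    patch_windows: tuple[tuple[int, int], ...] = DEFAULT_PATCH_WINDOWS
    genome_length: int = 16299

    def __post_init__(self) -> None:
        if not (0 < self.rotation < self.genome_length):
            raise ValueError("rotation must be in (0, genome_length)")
        for lo, hi in self.patch_windows:
            if not (1 <= lo <= hi <= self.genome_length):
                raise ValueError(f"patch window [{lo},{hi}] outside [1,{self.genome_length}]")

    def in_patch_window(self, position: int) -> bool:
        return any(lo <= position <= hi for lo, hi in self.patch_windows)


def rotate_reference(genome: CircularGenome, rotation: int) -> CircularGenome:
    """Cut the first ``rotation`` bp and append them to the end.

    Base ``rotation + 1`` of the original becomes base 1 of the rotated
    reference.
    """
    if not (0 < rotation < genome.length):
        raise ValueError("rotation must be in (0, genome length)")
    seq = genome.sequence[rotation:] + genome.sequence[:rotation]
    return CircularGenome(f"{genome.name}|rot{rotation}", seq)


def remap_position(pos_rotated: int, cfg: RotationConfig) -> int:
    """Map a 1-based position on the rotated reference back to the original.

    Bijective over [1, L]: ``((pos - 1 + rotation) mod L) + 1``.
    """
    L = cfg.genome_length
    if not (1 <= pos_rotated <= L):
        raise ValueError(f"position {pos_rotated} outside [1, {L}]")
    return (pos_rotated - 1 + cfg.rotation) % L + 1


class ReadMapper:
    """k-mer seeded, ungapped, substitution-only mapper over one or more
    reference sequences.

    Seeds are taken at every k-th offset of the read in both orientations;
    each seed hit proposes a full-length placement, which is scored by
    Hamming distance against the reference.  The default k of 31 is
    effectively unique in a 16 kb genome.
    """

    def __init__(self, references: list[CircularGenome | NuclearBackground | tuple[str, str]],
                 k: int = 31, max_mismatch_frac: float = 0.02,
                 policy: str = "best_unique"):
        if policy not in POLICIES:
            raise ValueError(f"unknown policy {policy!r}")
        self.k = int(k)
        self.max_mismatch_frac = float(max_mismatch_frac)
        self.policy = policy
        self.ref_names: list[str] = []
        self.ref_codes: list[np.ndarray] = []
        for ref in references:
            if isinstance(ref, tuple):
                name, seq = ref
            else:
                name, seq = ref.name, ref.sequence
            self.ref_names.append(name)
            self.ref_codes.append(encode(seq))
        self.ref_bufs = [codes.tobytes() for codes in self.ref_codes]
        self._index: dict[bytes, list[tuple[int, int]]] = {}
        for ri, buf in enumerate(self.ref_bufs):
            for pos in range(0, len(buf) - self.k + 1):
                self._index.setdefault(buf[pos:pos + self.k], []).append((ri, pos))

    def _placements(self, read_codes: np.ndarray, buf: bytes, max_mm: int):
        """Placements of one read orientation with mismatches <= max_mm.

        Seeds are taken at the start, middle and end of the read, so a
        placement is found unless every one of those three k-mers carries a
        mismatch against it.
        """
        n = read_codes.size
        seen = set()
        out = []
        index_get = self._index.get
        for off in {0, (n - self.k) // 2, n - self.k}:
            for ri, pos in index_get(buf[off:off + self.k], ()):
                start = pos - off
                key = (ri << 34) | (start + 1)
                if start < 0 or start + n > self.ref_codes[ri].size or key in seen:
                    continue
                seen.add(key)
                if self.ref_bufs[ri][start:start + n] == buf:
                    out.append((ri, start, 0))
                else:
                    mm = int(np.count_nonzero(self.ref_codes[ri][start:start + n] != read_codes))
                    if mm <= max_mm:
                        out.append((ri, start, mm))
        return out

    def map_read(self, read_id: str, sequence: str,
                 rng: np.random.Generator | None = None) -> AlignmentRecord:
        fwd = _CODE_LUT[np.frombuffer(sequence.encode(), dtype=np.uint8)]
        rev = (3 - fwd)[::-1]
        max_mm = int(self.max_mismatch_frac * fwd.size)
        cands = [(ri, s, mm, "+", fwd) for ri, s, mm in self._placements(fwd, fwd.tobytes(), max_mm)]
        cands += [(ri, s, mm, "-", rev) for ri, s, mm in self._placements(rev, rev.tobytes(), max_mm)]
        if not cands:
            return AlignmentRecord(read_id, "*", -1, "+", sequence, 0, False)

        if self.policy == "any_random":
            if len(cands) > 1:
                if rng is None:
                    raise ValueError("any_random policy requires an rng")
                pick = cands[int(rng.integers(0, len(cands)))]
            else:
                pick = cands[0]
        else:
            best = min(c[2] for c in cands)
            top = [c for c in cands if c[2] == best]
            if len(top) == 1:
                pick = top[0]
            elif self.policy == "best_random":
                if rng is None:
                    raise ValueError("best_random policy requires an rng")
                pick = top[int(rng.integers(0, len(top)))]
            else:  # best_unique: ambiguous read discarded
                return AlignmentRecord(read_id, "*", -1, "+", sequence, 0, False)
        ri, start, mm, strand, _oriented = pick
        oriented_str = sequence if strand == "+" else sequence.translate(_RC_TABLE)[::-1]
        return AlignmentRecord(read_id, self.ref_names[ri], start, strand,
                               oriented_str, mm, True)

    def map_reads(self, reads: list[tuple[str, str]],
                  rng: np.random.Generator | None = None) -> list[AlignmentRecord]:
        if not reads:
            warnings.warn("empty read set passed to map_reads")
            logger.warning("map_reads called with an empty read set")
            return []
        return [self.map_read(rid, seq, rng=rng) for rid, seq in reads]


def map_reads(reads: list[tuple[str, str]], reference, k: int = 31,
              max_mismatch_frac: float = 0.02, policy: str = "best_unique",
              decoys: list | None = None,
              rng: np.random.Generator | None = None) -> list[AlignmentRecord]:
    """One-shot convenience wrapper around :class:`ReadMapper`."""
    refs = [reference] + list(decoys or [])
    return ReadMapper(refs, k=k, max_mismatch_frac=max_mismatch_frac,
                      policy=policy).map_reads(reads, rng=rng)


def coverage_profile(alignments: list[AlignmentRecord], L: int,
                     ref_name: str | None = None) -> tuple[np.ndarray, int]:
    """Per-position depth vector and total aligned bases for one reference.

    The depth vector sums to the total aligned bases by construction.
    """
    diff = np.zeros(L + 1, dtype=np.int64)
    total = 0
    for rec in alignments:
        if not rec.mapped:
            continue
        if ref_name is not None and rec.ref_name != ref_name:
            continue
        if rec.end > L:
            raise ValueError(f"alignment end {rec.end} beyond reference length {L}")
        diff[rec.start] += 1
        diff[rec.end] -= 1
        total += rec.length
    depth = np.cumsum(diff[:-1])
    return depth, total


# ---------------------------------------------------------------------------
# SAM text I/O (minimal, standards-compliant; BAM is out of scope)

def write_sam(alignments: list[AlignmentRecord], references: list[tuple[str, int]],
              path: str | Path) -> None:
    """Write a minimal valid SAM file: @SQ lines plus one record per read."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in references:
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for rec in alignments:
            if rec.mapped:
                flag = 16 if rec.strand == "-" else 0
                fh.write(f"{rec.read_id}\t{flag}\t{rec.ref_name}\t{rec.start + 1}\t60\t"
                         f"{rec.length}M\t*\t0\t0\t{rec.aligned_sequence}\t*\tNM:i:{rec.mismatch_count}\n")
            else:
                fh.write(f"{rec.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{rec.aligned_sequence}\t*\n")


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Parse a SAM file (ours or an external aligner's) into alignment
    records.  Only fully-aligned substitution-only records (single ``NM``
    count, cigar ``<n>M``) are representable; others raise."""
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                out.append(AlignmentRecord(aln.query_name, "*", -1, "+",
                                           aln.query_sequence or "", 0, False))
                continue
            if len(aln.cigartuples) != 1 or aln.cigartuples[0][0] != 0:
                raise ValueError(f"record {aln.query_name}: only ungapped <n>M alignments supported")
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            out.append(AlignmentRecord(aln.query_name, aln.reference_name,
                                       aln.reference_start, "-" if aln.is_reverse else "+",
                                       aln.query_sequence, int(nm), True))
    return out
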