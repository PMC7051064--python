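"""Low-frequency point-mutation calling from pileups, and the patch rule
merging calls from the primary and rotated alignments.

The caller is an explicit threshold caller operating tumor-only on a haploid
reference: every alternate allele at a column is considered independently
(no cap on events per region), reads are downsampled to at most
``max_reads_per_start`` per (start, strand) before piling up, and a call
requires minimum alternate-read count, allele fraction, column depth, and —
when both strands carry coverage — alternate support on both strands.

Columns within one read length of the ends of the linearized reference are
excluded from calling (``edge_exclusion``): coverage there tapers because
fragments spanning the origin cannot be placed, and such edge artifacts are
precisely what the rotated alignment, via the patch windows, supplies
reliable calls for.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .genome import BASES, CircularGenome, encode
from .mapping import AlignmentRecord, RotationConfig, remap_position


@dataclass(frozen=True)
class CallerConfig:
    min_alt_reads: int = 3
    min_allele_fraction: float = 0.005
    min_depth: int = 20
    #: at most this many reads contribute per (start, strand); excess dropped
    #: deterministically in read-id order.  None disables the cap.
    max_reads_per_start: int | None = 5
    #: minimum alt reads per strand, enforced only when the column has
    #: coverage on both strands.
    min_strand_support: int = 1
    #: columns within this many bp of either end of the linear reference are
    #: not callable; None = auto (longest contributing read minus one).
    edge_exclusion: int | None = None

    def __post_init__(self) -> None:
        if self.min_alt_reads < 0 or self.min_depth < 0 or self.min_strand_support < 0:
            raise ValueError("thresholds must be >= 0")
        if not (0.0 <= self.min_allele_fraction < 1.0):
            raise ValueError("min_allele_fraction must be in [0, 1)")


@dataclass(frozen=True)
class PileupColumn:
    """One reference column: per-base counts split by strand."""

    position: int            # 1-based
    ref_base: str
    counts_fwd: tuple[int, int, int, int]   # A, C, G, T
    counts_rev: tuple[int, int, int, int]

    @property
    def effective_depth(self) -> int:
        return sum(self.counts_fwd) + sum(self.counts_rev)


@dataclass
class Pileup:
    """Dense pileup over a linear reference: counts[strand, base, position]."""

    ref_name: str
    ref_codes: np.ndarray
    counts: np.ndarray        # shape (2, 4, L) int64
    max_read_len: int = 0
    n_reads_capped: int = 0

    @property
    def length(self) -> int:
        return self.ref_codes.size

    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=(0, 1))

    def total_bases(self) -> int:
        return int(self.counts.sum())

    def column(self, position: int) -> PileupColumn:
        i = position - 1
        return PileupColumn(position, BASES[self.ref_codes[i]],
                            tuple(int(c) for c in self.counts[0, :, i]),
                            tuple(int(c) for c in self.counts[1, :, i]))

    def columns(self):
        for pos in np.nonzero(self.depth())[0]:
            yield self.column(int(pos) + 1)


@dataclass(frozen=True)
class VariantCall:
    position: int            # 1-based
    ref: str
    alt: str
    alt_count: int
    depth: int
    sample_id: str = ""
    tissue: str = ""
    classification: str = "unclassified"

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise ValueError("alt allele equals ref")
        if not (0 < self.alt_count <= self.depth):
            raise ValueError("alt_count must be in (0, depth]")
        if self.position < 1:
            raise ValueError("position is 1-based")

    @property
    def allele_fraction(self) -> float:
        return self.alt_count / self.depth

    def key(self) -> tuple[int, str]:
        """Mutation identity used by the cross-tissue sharing rule."""
        return (self.position, self.alt)


def build_pileup(alignments: list[AlignmentRecord], genome: CircularGenome,
                 cfg: CallerConfig = CallerConfig()) -> Pileup:
    """Pile mapped reads onto the reference, capping contributions per
    (start, strand) at ``max_reads_per_start`` (excess dropped in read-id
    order, for reproducibility without seed plumbing)."""
    L = genome.length
    mapped = [r for r in alignments if r.mapped and r.ref_name == genome.name]
    mapped.sort(key=lambda r: (r.start, r.strand, r.read_id))
    cap = cfg.max_reads_per_start
    kept: list[AlignmentRecord] = []
    n_capped = 0
    if cap is None:
        kept = mapped
    else:
        count: dict[tuple[int, str], int] = {}
        for rec in mapped:
            k = (rec.start, rec.strand)
            c = count.get(k, 0)
            if c < cap:
                count[k] = c + 1
                kept.append(rec)
            else:
                n_capped += 1

    counts = np.zeros((2, 4, L), dtype=np.int64)
    max_len = 0
    by_len: dict[int, list[AlignmentRecord]] = {}
    for rec in kept:
        if rec.end > L:
            raise ValueError("alignment extends beyond reference")
        by_len.setdefault(rec.length, []).append(rec)
    for n, recs in by_len.items():
        max_len = max(max_len, n)
        m = len(recs)
        starts = np.fromiter((r.start for r in recs), dtype=np.int64, count=m)
        strands = np.fromiter((0 if r.strand == "+" else 1 for r in recs), dtype=np.int64, count=m)
        codes = encode("".join(r.aligned_sequence for r in recs)).reshape(m, n).astype(np.int64)
        pos = starts[:, None] + np.arange(n)[None, :]
        flat = (strands[:, None] * 4 + codes) * L + pos
        counts += np.bincount(flat.ravel(), minlength=8 * L).reshape(2, 4, L)
    return Pileup(genome.name, genome.codes(), counts, max_len, n_capped)


def call_variants(pileup: Pileup, cfg: CallerConfig = CallerConfig(),
                  sample_id: str = "", tissue: str = "") -> list[VariantCall]:
    """Emit one call per (position, alt allele) passing all thresholds,
    sorted by position then alt."""
    L = pileup.length
    depth = pileup.depth()
    fwd_depth = pileup.counts[0].sum(axis=0)
    rev_depth = pileup.counts[1].sum(axis=0)

    edge = cfg.edge_exclusion
    if edge is None:
        edge = max(pileup.max_read_len - 1, 0)
    callable_mask = np.ones(L, dtype=bool)
    if edge > 0:
        callable_mask[:min(edge, L)] = False
        callable_mask[max(L - edge, 0):] = False

    calls: list[VariantCall] = []
    for b in range(4):
        alt_fwd = pileup.counts[0, b]
        alt_rev = pileup.counts[1, b]
        alt = alt_fwd + alt_rev
        ok = (pileup.ref_codes != b) & callable_mask
        ok &= alt >= cfg.min_alt_reads
        ok &= depth >= cfg.min_depth
        with np.errstate(invalid="ignore", divide="ignore"):
            af = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
        ok &= af >= cfg.min_allele_fraction
        both = (fwd_depth > 0) & (rev_depth > 0)
        ok &= ~both | ((alt_fwd >= cfg.min_strand_support) & (alt_rev >= cfg.min_strand_support))
        for i in np.nonzero(ok)[0]:
            calls.append(VariantCall(int(i) + 1, BASES[pileup.ref_codes[i]], BASES[b],
                                     int(alt[i]), int(depth[i]), sample_id, tissue))
    calls.sort(key=lambda c: (c.position, c.alt))
    return calls


def remap_calls(rotated_calls: list[VariantCall], cfg: RotationConfig) -> list[VariantCall]:
    """Translate calls made on the rotated reference back to original
    coordinates."""
    return [replace(c, position=remap_position(c.position, cfg)) for c in rotated_calls]


def patch_calls(primary_calls: list[VariantCall], rotated_calls: list[VariantCall],
                cfg: RotationConfig) -> list[VariantCall]:
    """Merge the two call sets: outside every patch window the primary
    alignment's calls are authoritative; inside a window only calls from the
    rotated alignment (already remapped to original coordinates) are kept."""
    merged = [c for c in primary_calls if not cfg.in_patch_window(c.position)]
    merged += [c for c in rotated_calls if cfg.in_patch_window(c.position)]
    keys = [(c.position, c.alt, c.sample_id, c.tissue) for c in merged]
    assert len(keys) == len(set(keys)), "duplicate (position, alt) after patching"
    merged.sort(key=lambda c: (c.position, c.alt))
    return merged


# ---------------------------------------------------------------------------
# Minimal VCF 4.2 I/O

_VCF_HEADER = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth at the site">',
    '##INFO=<ID=AC,Number=1,Type=Integer,Description="Alternate-supporting read count">',
    '##INFO=<ID=AF,Number=1,Type=Float,Description="Alternate allele fraction">',
    '##INFO=<ID=CLS,Number=1,Type=String,Description="Classification: unclassified/germline/somatic">',
]


def write_vcf(calls: list[VariantCall], genome_name: str, genome_length: int,
              path: str | Path, sample_id: str = "") -> None:
    with open(path, "w") as fh:
        for line in _VCF_HEADER:
            fh.write(line + "\n")
        fh.write(f"##contig=<ID={genome_name},length={genome_length}>\n")
        if sample_id:
            fh.write(f"##sample=<ID={sample_id}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: (c.position, c.alt)):
            info = f"DP={c.depth};AC={c.alt_count};AF={c.allele_fraction:.6g};CLS={c.classification}"
            fh.write(f"{genome_name}\t{c.position}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t{info}\n")


def read_vcf(path: str | Path, sample_id: str = "", tissue: str = "") -> list[VariantCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _id, ref, alt, _q, _f, info = line.rstrip("\n").split("\t")
            fields = dict(kv.split("=", 1) for kv in info.split(";"))
            calls.append(VariantCall(int(pos), ref, alt, int(fields["AC"]), int(fields["DP"]),
                                     sample_id, tissue, fields.get("CLS", "unclassified")))
    return calls
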