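"""Ground-truth simulator for circular-genome heteroplasmy studies.

Generates every input the analysis chain consumes — a circular mtDNA
reference, a NUMT-bearing nuclear background, paired-end reads with planted
germline/somatic variants at known allele fractions, and qPCR Cq tables from
known per-cycle amplification factors — together with the truth records
needed for parameter-recovery tests.

The read model is deliberately minimal: fragment start positions are uniform
on the circle (so fragments wrap across the linearization origin and carry
the wrapped sequence), allele fractions are fixed per variant (an optional
Beta mode adds molecule-to-molecule dispersion), substitution errors are
injected explicitly at a flat per-base rate, and base qualities are a single
high value.  Fragment counts are Poisson-distributed around
``depth * length / fragment_length`` so coverage carries realistic sampling
noise.  No indels, GC bias, or duplicate structure are modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import CircularGenome, NuclearBackground, NumtInsertion, decode, encode, revcomp_codes

#: Default circular genome length: the mouse mitochondrial genome.
DEFAULT_GENOME_LENGTH = 16299
#: Default per-base substitution error after base-quality filtering
#: (roughly Q37, typical of quality-trimmed short-read data).
DEFAULT_ERROR_RATE = 2e-4
#: Default fold coverage of the mt genome.
DEFAULT_DEPTH = 500.0
#: Paired-end read length.
DEFAULT_READ_LEN = 250

_SALT_REFERENCE = 101
_SALT_BACKGROUND = 211
_SALT_VARIANTS = 307
_SALT_MT_READS = 401
_SALT_NUC_READS = 503
_SALT_QPCR = 601


@dataclass(frozen=True)
class Variant:
    """A planted point variant: 1-based position, ref/alt bases, allele fraction."""

    position: int
    ref: str
    alt: str
    allele_fraction: float

    def key(self) -> tuple[int, str]:
        return (self.position, self.alt)


@dataclass
class SimTruth:
    """Planted truth for one simulated animal.

    ``germline_variants`` are shared by every tissue; ``somatic_variants``
    maps tissue -> its private variants.  All planted positions are distinct
    genome-wide, so classification by cross-tissue sharing is exact on the
    truth.
    """

    germline_variants: list[Variant]
    somatic_variants: dict[str, list[Variant]]
    copy_ratio: float
    error_rate: float
    seed: int

    def variants_for(self, tissue: str) -> list[Variant]:
        return list(self.germline_variants) + list(self.somatic_variants[tissue])

    def to_frame(self, animal: str = "sim") -> pd.DataFrame:
        rows = []
        for tissue in sorted(self.somatic_variants):
            for v in self.germline_variants:
                rows.append((animal, tissue, v.position, v.ref, v.alt, v.allele_fraction, "germline"))
            for v in self.somatic_variants[tissue]:
                rows.append((animal, tissue, v.position, v.ref, v.alt, v.allele_fraction, "somatic"))
        return pd.DataFrame(rows, columns=["animal", "tissue", "pos", "ref", "alt", "af", "class"])


@dataclass(frozen=True)
class QpcrTruth:
    """Generating parameters for a simulated qPCR run.

    Amplification factors are per-cycle template multipliers in (1, 2]
    (2 = perfectly efficient doubling).  ``input_ratio`` is the true
    mitochondrial : nuclear template ratio of the undiluted sample.
    """

    amp_factor_nuclear: float = 2.0
    amp_factor_mito: float = 2.0
    cq_noise_sd: float = 0.0
    input_ratio: float = 1000.0
    #: fluorescence threshold in template-equivalents; sets the Cq scale only
    threshold: float = 1e10
    #: undiluted nuclear template amount at dilution 0.  The default puts the
    #: single-copy nuclear assay near Cq 17: because the copy-number formula
    #: exponentiates the fitted amplification factor by the absolute Cq,
    #: standard-curve slope error is leveraged by the Cq magnitude, and this
    #: scale keeps that leverage within a realistic error budget.
    base_template: float = 1e5

    def __post_init__(self) -> None:
        for f in (self.amp_factor_nuclear, self.amp_factor_mito):
            if not (1.0 < f <= 2.0):
                raise ValueError("amplification factor must be in (1, 2]")
        if self.cq_noise_sd < 0:
            raise ValueError("cq_noise_sd must be >= 0")
        if self.input_ratio <= 0:
            raise ValueError("input_ratio must be positive")


@dataclass(frozen=True)
class ReadPair:
    name: str
    seq1: str
    seq2: str


@dataclass
class ReadSet:
    """Paired reads plus bookkeeping on their true origin (read-name prefixes
    ``mt|`` and ``nuc|`` record whether a fragment came from the circle or the
    nuclear background)."""

    pairs: list[ReadPair]
    read_len: int

    def reads(self) -> list[tuple[str, str]]:
        """Flatten to (read_id, sequence) with /1 and /2 mate suffixes."""
        out = []
        for p in self.pairs:
            out.append((p.name + "/1", p.seq1))
            out.append((p.name + "/2", p.seq2))
        return out

    def n_mt_pairs(self) -> int:
        return sum(1 for p in self.pairs if p.name.startswith("mt|"))

    def write_fastq(self, prefix: str | Path) -> tuple[Path, Path]:
        prefix = Path(prefix)
        p1 = prefix.with_name(prefix.name + "_1.fastq")
        p2 = prefix.with_name(prefix.name + "_2.fastq")
        qual = "I" * self.read_len
        with open(p1, "w") as f1, open(p2, "w") as f2:
            for p in self.pairs:
                f1.write(f"@{p.name}/1\n{p.seq1}\n+\n{qual}\n")
                f2.write(f"@{p.name}/2\n{p.seq2}\n+\n{qual}\n")
        return p1, p2


def _rng(seed: int, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), salt]))


def generate_reference(length: int = DEFAULT_GENOME_LENGTH, gc: float = 0.38,
                       seed: int = 0, name: str = "chrM") -> CircularGenome:
    """Random circular reference with the requested GC content."""
    if length < 200:
        raise ValueError("reference length must be >= 200 bp")
    if not (0.0 < gc < 1.0):
        raise ValueError("gc must be in (0, 1)")
    rng = _rng(seed, _SALT_REFERENCE)
    at = (1.0 - gc) / 2.0
    codes = rng.choice(4, size=length, p=[at, gc / 2.0, gc / 2.0, at]).astype(np.uint8)
    return CircularGenome(name, decode(codes))


def generate_background(genome: CircularGenome, length: int = 50_000,
                        n_numts: int = 4, numt_length: int = 800,
                        divergence: float = 0.05, gc: float = 0.42,
                        seed: int = 0, name: str = "chrN") -> NuclearBackground:
    """Random nuclear background with embedded, diverged NUMT copies.

    Each NUMT copies ``numt_length`` bp from a random arc of the circle and
    substitutes bases at the requested per-site divergence before embedding
    at a non-overlapping nuclear offset.
    """
    if n_numts * numt_length > length // 2:
        raise ValueError("NUMTs would occupy more than half the background")
    rng = _rng(seed, _SALT_BACKGROUND)
    at = (1.0 - gc) / 2.0
    codes = rng.choice(4, size=length, p=[at, gc / 2.0, gc / 2.0, at]).astype(np.uint8)
    mt_codes = genome.codes()
    doubled = np.concatenate([mt_codes, mt_codes])

    # evenly spaced slots keep placement trivially non-overlapping
    slot = length // max(n_numts, 1)
    numts = []
    for i in range(n_numts):
        src = int(rng.integers(0, genome.length))
        seg = doubled[src:src + numt_length].copy()
        mask = rng.random(numt_length) < divergence
        shift = rng.integers(1, 4, size=int(mask.sum()))
        seg[mask] = (seg[mask] + shift) % 4
        lo = i * slot
        hi = lo + slot - numt_length
        nstart = int(rng.integers(lo, max(hi, lo + 1)))
        codes[nstart:nstart + numt_length] = seg
        numts.append(NumtInsertion(nstart, src, numt_length, divergence))
    return NuclearBackground(name, decode(codes), tuple(numts))


def plant_variants(genome: CircularGenome, n_germline: int, n_somatic_per_tissue: int,
                   af_germline: float = 0.5, af_somatic: float = 0.05,
                   tissues: tuple[str, ...] = ("brain", "liver"), seed: int = 0,
                   copy_ratio: float = 1000.0, error_rate: float = DEFAULT_ERROR_RATE,
                   af_mode: str = "fixed", beta_concentration: float = 50.0) -> SimTruth:
    """Plant germline (shared across tissues) and tissue-private somatic
    variants at distinct positions genome-wide.

    With ``af_mode='beta'`` each variant's fraction is drawn from a Beta
    distribution with the requested mean and concentration instead of being
    fixed.
    """
    total = n_germline + n_somatic_per_tissue * len(tissues)
    if total > genome.length:
        raise ValueError("more variants requested than genome positions")
    for af in (af_germline, af_somatic):
        if not (0.0 < af <= 1.0):
            raise ValueError("allele fractions must be in (0, 1]")
    if af_mode not in ("fixed", "beta"):
        raise ValueError("af_mode must be 'fixed' or 'beta'")

    rng = _rng(seed, _SALT_VARIANTS)
    positions = rng.choice(genome.length, size=total, replace=False) + 1  # 1-based

    def _af(mean: float) -> float:
        if af_mode == "fixed":
            return mean
        a = mean * beta_concentration
        b = (1.0 - mean) * beta_concentration
        return float(np.clip(rng.beta(a, b), 1e-6, 1.0))

    def _make(pos: int, mean_af: float) -> Variant:
        ref = genome.base(pos)
        alts = [b for b in "ACGT" if b != ref]
        alt = alts[int(rng.integers(0, 3))]
        return Variant(int(pos), ref, alt, _af(mean_af))

    germline = [_make(p, af_germline) for p in positions[:n_germline]]
    germline.sort(key=lambda v: v.position)
    somatic: dict[str, list[Variant]] = {}
    off = n_germline
    for tissue in tissues:
        block = positions[off:off + n_somatic_per_tissue]
        off += n_somatic_per_tissue
        somatic[tissue] = sorted((_make(p, af_somatic) for p in block), key=lambda v: v.position)
    return SimTruth(germline, somatic, copy_ratio, error_rate, int(seed))


def _inject_and_split(frags: np.ndarray, starts: np.ndarray, L: int,
                      variants: list[Variant], error_rate: float,
                      rng: np.random.Generator, read_len: int) -> tuple[np.ndarray, np.ndarray]:
    """Inject variant alleles (per-fragment Bernoulli at each truth fraction),
    then flat substitution errors; return the two mate matrices."""
    for v in variants:
        offset = (v.position - 1 - starts) % L
        cover = np.nonzero(offset < frags.shape[1])[0]
        if cover.size == 0:
            continue
        carry = cover[rng.random(cover.size) < v.allele_fraction]
        frags[carry, offset[carry]] = encode(v.alt)[0]
    if error_rate > 0:
        mask = rng.random(frags.shape) < error_rate
        n_err = int(mask.sum())
        if n_err:
            shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
            frags[mask] = (frags[mask] + shift) % 4
    mate1 = frags[:, :read_len]
    mate2 = (3 - frags[:, -read_len:])[:, ::-1]  # reverse complement
    return mate1, mate2


def simulate_reads(genome: CircularGenome, background: NuclearBackground | None,
                   truth: SimTruth, tissue: str, depth_mt: float = DEFAULT_DEPTH,
                   depth_nuc: float = 30.0, read_len: int = DEFAULT_READ_LEN,
                   error_rate: float | None = None, purified: bool = True,
                   seed: int = 0, fragment_length: int | None = None) -> ReadSet:
    """Simulate paired-end reads for one sample (animal x tissue x prep).

    Mt fragment starts are uniform on the circle and wrap across the origin.
    ``purified=True`` suppresses nuclear/NUMT fragments entirely; the mt read
    stream is seeded independently of the nuclear stream, so a purified and
    an unpurified run with the same seed share identical mt reads and differ
    only by the nuclear additions.
    """
    if read_len >= genome.length:
        raise ValueError("read length must be shorter than the genome")
    if depth_mt <= 0:
        raise ValueError("depth_mt must be positive")
    frag_len = fragment_length if fragment_length is not None else 2 * read_len
    if frag_len < read_len:
        raise ValueError("fragment length must be >= read length")
    err = truth.error_rate if error_rate is None else error_rate
    L = genome.length

    rng_mt = _rng(seed, _SALT_MT_READS)
    n_mt = int(rng_mt.poisson(depth_mt * L / frag_len))
    mt_codes = genome.codes()
    doubled = np.concatenate([mt_codes, mt_codes])
    starts = rng_mt.integers(0, L, size=n_mt)
    frags = doubled[starts[:, None] + np.arange(frag_len)[None, :]]
    variants = truth.variants_for(tissue)
    m1, m2 = _inject_and_split(frags, starts, L, variants, err, rng_mt, read_len)

    pairs = [ReadPair(f"mt|{tissue}|{i}", decode(m1[i]), decode(m2[i])) for i in range(n_mt)]

    if not purified:
        if background is None:
            raise ValueError("unpurified simulation requires a nuclear background")
        if depth_nuc < 0:
            raise ValueError("depth_nuc must be >= 0")
        rng_nuc = _rng(seed, _SALT_NUC_READS)
        n_nuc = int(rng_nuc.poisson(depth_nuc * background.length / frag_len))
        if n_nuc:
            bg = background.codes()
            nstarts = rng_nuc.integers(0, background.length - frag_len + 1, size=n_nuc)
            nfrags = bg[nstarts[:, None] + np.arange(frag_len)[None, :]].copy()
            n1, n2 = _inject_and_split(nfrags, nstarts, background.length, [], err, rng_nuc, read_len)
            pairs.extend(ReadPair(f"nuc|{tissue}|{i}", decode(n1[i]), decode(n2[i]))
                         for i in range(n_nuc))
    return ReadSet(pairs, read_len)


def simulate_qpcr(qtruth: QpcrTruth, dilutions: int = 4, replicates: int = 5,
                  seed: int = 0) -> pd.DataFrame:
    """Simulate a ten-fold dilution series for the nuclear and mitochondrial
    assays.

    For template amount ``N`` and per-cycle amplification factor ``f`` the
    quantification cycle is ``Cq = log_f(threshold / N)`` plus Gaussian noise.
    Dilution ``d`` holds ``N * 10^-d`` template; dilution 0 is the undiluted
    sample whose replicate-averaged Cq feeds the copy-number formula.
    Columns: assay, dilution, replicate, Cq.
    """
    if dilutions < 3:
        raise ValueError("need at least 3 dilution levels")
    if replicates < 1:
        raise ValueError("need at least 1 replicate")
    rng = _rng(seed, _SALT_QPCR)
    rows = []
    assays = [
        ("mB2M", qtruth.amp_factor_nuclear, qtruth.base_template),
        ("mMito", qtruth.amp_factor_mito, qtruth.base_template * qtruth.input_ratio),
    ]
    for assay, amp, n0 in assays:
        for d in range(dilutions):
            n_template = n0 * 10.0 ** (-d)
            cq0 = math.log(qtruth.threshold / n_template) / math.log(amp)
            noise = rng.normal(0.0, qtruth.cq_noise_sd, size=replicates) if qtruth.cq_noise_sd > 0 \
                else np.zeros(replicates)
            for r in range(replicates):
                rows.append((assay, d, r, cq0 + float(noise[r])))
    return pd.DataFrame(rows, columns=["assay", "dilution", "replicate", "Cq"])


def simulate_sample_cq(qtruth: QpcrTruth, replicates: int = 3, seed: int = 0) -> pd.DataFrame:
    """Replicate Cq measurements of one undiluted sample (both assays), in
    the same table layout as the dilution series (all rows dilution 0)."""
    if replicates < 1:
        raise ValueError("need at least 1 replicate")
    rng = _rng(seed, _SALT_QPCR + 1)
    rows = []
    for assay, amp, n0 in (("mB2M", qtruth.amp_factor_nuclear, qtruth.base_template),
                           ("mMito", qtruth.amp_factor_mito, qtruth.base_template * qtruth.input_ratio)):
        cq0 = math.log(qtruth.threshold / n0) / math.log(amp)
        noise = rng.normal(0.0, qtruth.cq_noise_sd, size=replicates) if qtruth.cq_noise_sd > 0 \
            else np.zeros(replicates)
        for r in range(replicates):
            rows.append((assay, 0, r, cq0 + float(noise[r])))
    return pd.DataFrame(rows, columns=["assay", "dilution", "replicate", "Cq"])


def write_truth(truth: SimTruth, path: str | Path, animal: str = "sim") -> None:
    truth.to_frame(animal).to_csv(path, sep="\t", index=False)


def write_manifest(path: str | Path, params: dict) -> None:
    """Echo resolved run parameters as a flat key-value file."""
    with open(path, "w") as fh:
        for k in sorted(params):
            fh.write(f"{k}\t{params[k]}\n")
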