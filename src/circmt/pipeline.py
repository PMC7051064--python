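"""End-to-end rotate-and-patch processing of one sample's reads.

Reads are mapped twice — against the linear reference and against a copy
rotated by ``RotationConfig.rotation`` bp — variants are called on each
pileup, rotated calls are remapped to original coordinates, and the two
call sets are merged by the patch rule: positions inside the patch windows
near the origin are taken exclusively from the rotated alignment,
everything else from the primary one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calling import CallerConfig, VariantCall, build_pileup, call_variants, patch_calls, remap_calls
from .genome import CircularGenome, NuclearBackground
from .mapping import AlignmentRecord, ReadMapper, RotationConfig, coverage_profile, rotate_reference


@dataclass
class MapperBundle:
    """Primary and rotated mappers sharing decoys; build once, reuse across
    samples (the k-mer index is the expensive part)."""

    mt_genome: CircularGenome
    rotation_cfg: RotationConfig
    primary: ReadMapper
    rotated: ReadMapper
    rotated_genome: CircularGenome
    decoy_names: tuple[str, ...] = ()
    decoy_lengths: dict[str, int] = field(default_factory=dict)


def build_mappers(mt_genome: CircularGenome, decoys: list[NuclearBackground] | None = None,
                  rotation_cfg: RotationConfig | None = None, k: int = 31,
                  max_mismatch_frac: float = 0.02, policy: str = "best_unique") -> MapperBundle:
    if rotation_cfg is None:
        rotation_cfg = RotationConfig(genome_length=mt_genome.length)
    if rotation_cfg.genome_length != mt_genome.length:
        raise ValueError("rotation config genome_length disagrees with the genome")
    decoys = decoys or []
    rot = rotate_reference(mt_genome, rotation_cfg.rotation)
    primary = ReadMapper([mt_genome, *decoys], k=k, max_mismatch_frac=max_mismatch_frac, policy=policy)
    rotated = ReadMapper([rot, *decoys], k=k, max_mismatch_frac=max_mismatch_frac, policy=policy)
    return MapperBundle(mt_genome, rotation_cfg, primary, rotated, rot,
                        tuple(d.name for d in decoys), {d.name: d.length for d in decoys})


@dataclass
class SampleResult:
    sample_id: str
    tissue: str
    calls: list[VariantCall]              # patched, original coordinates
    primary_calls: list[VariantCall]      # unpatched, for diagnostics
    mt_coverage: np.ndarray               # per-position depth, primary alignment
    mt_total_bases: int
    decoy_mean_depth: dict[str, float]
    n_reads: int
    n_mt_mapped: int

    @property
    def mt_mean_depth(self) -> float:
        return float(self.mt_coverage.mean())

    @property
    def mt_mapped_fraction(self) -> float:
        return self.n_mt_mapped / self.n_reads if self.n_reads else 0.0


def call_sample(reads: list[tuple[str, str]], bundle: MapperBundle,
                caller_cfg: CallerConfig = CallerConfig(), sample_id: str = "",
                tissue: str = "", rng: np.random.Generator | None = None,
                with_rotated: bool = True) -> SampleResult:
    """Run map -> pileup -> call -> patch for one read set.

    ``with_rotated=False`` skips the rotated pass (coverage-only uses, e.g.
    copy number); the patched call list then equals the primary calls.
    """
    mt = bundle.mt_genome
    primary_aln = bundle.primary.map_reads(reads, rng=rng)
    pri_pile = build_pileup(primary_aln, mt, caller_cfg)
    primary_calls = call_variants(pri_pile, caller_cfg, sample_id=sample_id, tissue=tissue)

    if with_rotated:
        rotated_aln = bundle.rotated.map_reads(reads, rng=rng)
        rot_pile = build_pileup(rotated_aln, bundle.rotated_genome, caller_cfg)
        rot_calls = call_variants(rot_pile, caller_cfg, sample_id=sample_id, tissue=tissue)
        rot_calls = remap_calls(rot_calls, bundle.rotation_cfg)
        calls = patch_calls(primary_calls, rot_calls, bundle.rotation_cfg)
    else:
        calls = list(primary_calls)

    mt_depth, mt_total = coverage_profile(primary_aln, mt.length, ref_name=mt.name)
    decoy_mean = {}
    for name in bundle.decoy_names:
        d, _t = coverage_profile(primary_aln, bundle.decoy_lengths[name], ref_name=name)
        decoy_mean[name] = float(d.mean())
    n_mt_mapped = sum(1 for r in primary_aln if r.mapped and r.ref_name == mt.name)
    return SampleResult(sample_id, tissue, calls, primary_calls, mt_depth, mt_total,
                        decoy_mean, len(reads), n_mt_mapped)
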