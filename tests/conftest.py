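import numpy as np
import pytest

from circmt import (CallerConfig, RotationConfig, build_mappers, call_sample,
                    classify_germline, generate_reference, plant_variants,
                    simulate_reads)
from circmt.simulate import SimTruth, Variant


@pytest.fixture(scope="session")
def mt_genome():
    """The default-scale circular reference (16,299 bp, 38% GC)."""
    return generate_reference(16299, 0.38, seed=7)


@pytest.fixture(scope="session")
def toy_genome():
    """A small circle that keeps mapper tests fast."""
    return generate_reference(2000, 0.45, seed=13)


@pytest.fixture(scope="session")
def mt_bundle(mt_genome):
    return build_mappers(mt_genome)


def make_truth(genome, variants_by_tissue, germline=(), error_rate=2e-4, seed=0):
    """Assemble a SimTruth from explicit variant lists."""
    return SimTruth(list(germline), {t: list(v) for t, v in variants_by_tissue.items()},
                    copy_ratio=1000.0, error_rate=error_rate, seed=seed)


def variant_at(genome, position, af, alt=None):
    ref = genome.base(position)
    if alt is None:
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
    return Variant(position, ref, alt, af)


@pytest.fixture(scope="session")
def default_animal_run(mt_genome, mt_bundle):
    """One simulated animal at study-default conditions: 50 germline (AF 0.5)
    plus 100 private somatic variants per tissue (AF 0.05), 500x depth,
    fully processed and classified.  Shared by several recovery tests."""
    truth = plant_variants(mt_genome, 50, 100, 0.5, 0.05,
                           tissues=("brain", "liver"), seed=21)
    results = {}
    for tissue in ("brain", "liver"):
        reads = simulate_reads(mt_genome, None, truth, tissue, depth_mt=500.0,
                               purified=True, seed=33)
        results[tissue] = call_sample(reads.reads(), mt_bundle,
                                      sample_id="animal0", tissue=tissue)
    classified = classify_germline({t: r.calls for t, r in results.items()})
    return {"truth": truth, "results": results, "classified": classified,
            "genome": mt_genome}
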