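"""Mutation rate and mutation load, and germline/somatic partitioning by
cross-tissue sharing.

*Mutation rate* is the fraction of genome positions with at least one called
mutation (distinct positions / L).  *Mutation load* is mutation observations
normalized by total sequenced bases; the default numerator is read-weighted
(sum of alternate-supporting reads), reflecting how widely each mutation has
spread through the mtDNA population — a record-weighted numerator (one per
called variant) is available as ``numerator='events'``.

A variant is *germline* when the same (position, alt allele) is called in
every tissue of an animal; otherwise it is *somatic*.  With exactly two
tissues this is the shared-between-tissues rule; the germline key set, and
hence the germline rate, is identical across the animal's tissues by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .calling import VariantCall

SCOPES = ("total", "germline", "somatic")


@dataclass(frozen=True)
class MutationMetrics:
    sample_id: str
    tissue: str
    class_scope: str          # total / germline / somatic
    mutated_positions: int
    mutation_events: int      # number of called (position, alt) records
    alt_base_count: int       # read-level mutation observations
    total_bases: int
    genome_length: int

    @property
    def rate(self) -> float:
        return self.mutated_positions / self.genome_length

    @property
    def load(self) -> float:
        return self.alt_base_count / self.total_bases


def classify_germline(calls_by_tissue: dict[str, list[VariantCall]]) -> dict[str, list[VariantCall]]:
    """Set the classification of every call of one animal.

    A call is germline iff its (position, alt) key is called in *every*
    supplied tissue; all other calls are somatic.  Requires at least two
    tissues (the rule is undefined for one).
    """
    if len(calls_by_tissue) < 2:
        raise ValueError("germline classification needs calls from >= 2 tissues")
    key_sets = [{c.key() for c in calls} for calls in calls_by_tissue.values()]
    shared = set.intersection(*key_sets)
    return {
        tissue: [replace(c, classification="germline" if c.key() in shared else "somatic")
                 for c in calls]
        for tissue, calls in calls_by_tissue.items()
    }


def compute_rate(calls: list[VariantCall], genome_length: int) -> float:
    """Distinct mutated positions over genome length (multi-allelic sites
    count once)."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    for c in calls:
        if c.position > genome_length:
            raise ValueError(f"call at {c.position} beyond genome length {genome_length}")
    return len({c.position for c in calls}) / genome_length


def compute_load(calls: list[VariantCall], total_bases: int,
                 numerator: str = "reads") -> float:
    """Mutation observations over total sequenced bases.

    ``numerator='reads'`` (default) sums alternate-supporting reads;
    ``'events'`` counts called records.
    """
    if total_bases <= 0:
        raise ValueError("total_bases must be positive")
    if numerator == "reads":
        num = sum(c.alt_count for c in calls)
    elif numerator == "events":
        num = len(calls)
    else:
        raise ValueError("numerator must be 'reads' or 'events'")
    return num / total_bases


def sample_metrics(sample_id: str, tissue: str, calls: list[VariantCall],
                   total_bases: int, genome_length: int) -> list[MutationMetrics]:
    """Per-scope metrics rows for one classified call set."""
    out = []
    for scope in SCOPES:
        sub = calls if scope == "total" else [c for c in calls if c.classification == scope]
        out.append(MutationMetrics(
            sample_id, tissue, scope,
            mutated_positions=len({c.position for c in sub}),
            mutation_events=len(sub),
            alt_base_count=sum(c.alt_count for c in sub),
            total_bases=total_bases,
            genome_length=genome_length,
        ))
    return out


def metrics_table(metrics: list[MutationMetrics]) -> pd.DataFrame:
    """One row per (sample, tissue, scope) with numerators, denominators,
    rate and load."""
    rows = [{
        "sample_id": m.sample_id, "tissue": m.tissue, "scope": m.class_scope,
        "mutated_positions": m.mutated_positions, "mutation_events": m.mutation_events,
        "alt_base_count": m.alt_base_count, "total_bases": m.total_bases,
        "rate": m.rate, "load": m.load,
    } for m in metrics]
    return pd.DataFrame(rows).sort_values(["sample_id", "tissue", "scope"]).reset_index(drop=True)
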