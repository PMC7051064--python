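"""The two headline in-silico experiments and small summary statistics.

*Purification experiment*: simulated animals are sequenced twice from
identical mt truth — once as purified mtDNA (no nuclear material) and once
as total genomic extract (nuclear background with NUMT copies added).  Both
read sets run through the full rotate-and-patch pipeline and the per-animal
mutation rate and load are compared across conditions.  With the default
best-unique placement policy the two preparations agree: NUMT-origin reads
either exceed the mismatch budget on the mt reference or place strictly
better on their true nuclear locus.  A negative control (naive random
placement among acceptable hits, low NUMT divergence) shows the agreement
is a property of the mapping policy, not of an absence of contamination.

*Concordance experiment*: a panel of samples with known mt:nuclear copy
ratios is measured by both estimators — qPCR (simulated dilution series and
sample Cq) and sequencing coverage — and their Pearson correlation and
per-sample recovery errors are reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .calling import CallerConfig
from .copynum import (copy_number_from_sequencing, copy_number_qpcr, fit_dilution_series,
                      mean_sample_cq)
from .genome import CircularGenome, NuclearBackground
from .mapping import ReadMapper, RotationConfig
from .metrics import compute_load, compute_rate
from .pipeline import build_mappers, call_sample
from .simulate import (DEFAULT_ERROR_RATE, QpcrTruth, SimTruth, generate_background,
                       generate_reference, plant_variants, simulate_qpcr,
                       simulate_reads, simulate_sample_cq)


@dataclass(frozen=True)
class ExperimentConfig:
    """Simulation and analysis settings shared by the experiments.

    Defaults mirror the study conditions: a 16,299 bp circle sequenced at
    500x with 250 bp paired reads, NUMTs at 5% divergence, four
    quintuplicate ten-fold qPCR dilutions.
    """

    seed: int = 0
    genome_length: int = 16299
    gc: float = 0.38
    read_len: int = 250
    depth_mt: float = 500.0
    error_rate: float = DEFAULT_ERROR_RATE
    # nuclear background / NUMTs
    nuclear_length: int = 50_000
    nuclear_depth: float = 30.0
    n_numts: int = 4
    numt_length: int = 800
    numt_divergence: float = 0.05
    # mapper / caller
    k: int = 31
    max_mismatch_frac: float = 0.02
    policy: str = "best_unique"
    caller: CallerConfig = field(default_factory=CallerConfig)
    # purification experiment
    n_animals: int = 6
    n_germline: int = 50
    af_germline: float = 0.5
    af_somatic: float = 0.05
    somatic_counts: tuple[int, ...] | None = None   # default: spread across animals
    # concordance experiment
    n_samples: int = 12
    ratio_range: tuple[float, float] = (100.0, 3000.0)
    concordance_depth_mt: float = 50.0
    concordance_nuclear_length: int = 1_000_000
    #: well-to-well noise of sample Cq measurements (cycles)
    cq_noise_sd: float = 0.15
    #: well-to-well noise of the standard-curve wells (cycles)
    calibration_noise_sd: float = 0.1
    amp_factor_nuclear: float = 2.0
    amp_factor_mito: float = 1.95
    dilutions: int = 4
    replicates: int = 5
    #: qPCR reactions per sample measurement (triplicate)
    sample_replicates: int = 3

    def animal_somatic_counts(self) -> tuple[int, ...]:
        if self.somatic_counts is not None:
            if len(self.somatic_counts) != self.n_animals:
                raise ValueError("somatic_counts length must equal n_animals")
            return self.somatic_counts
        # burden varies animal to animal so cross-condition correlation is informative
        return tuple(60 + 40 * i for i in range(self.n_animals))


@dataclass(frozen=True)
class ComparisonResult:
    metric: str
    group_stats: dict[str, tuple[float, float, int]]   # group -> (mean, sem, n)
    paired_t: tuple[float, float] | None = None        # (statistic, two-sided p)
    pearson_r: tuple[float, float] | None = None       # (r, two-sided p)


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with the two-sided p-value from
    ``t = r * sqrt((n - 2) / (1 - r^2))``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of at least 3 values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    xd = x - x.mean()
    yd = y - y.mean()
    r = float(np.dot(xd, yd) / math.sqrt(np.dot(xd, xd) * np.dot(yd, yd)))
    r = max(-1.0, min(1.0, r))
    n = x.size
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return r, p


def summarize_groups(table: pd.DataFrame, value: str, group: str,
                     paired_on: str | None = None) -> ComparisonResult:
    """Per-group mean, SEM (sd/sqrt(n)) and n for one metric column.

    With ``paired_on`` and exactly two groups, a paired two-sided t statistic
    on within-subject differences is included.
    """
    group_stats: dict[str, tuple[float, float, int]] = {}
    for g, sub in table.groupby(group, observed=False):
        vals = sub[value].to_numpy(dtype=float)
        if vals.size == 0:
            warnings.warn(f"group {g!r} is empty; omitted")
            continue
        sem = float(np.std(vals, ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else 0.0
        group_stats[str(g)] = (float(vals.mean()), sem, int(vals.size))
    paired = None
    if paired_on is not None and len(group_stats) == 2:
        ga, gb = sorted(group_stats)
        wide = table.pivot_table(index=paired_on, columns=group, values=value)
        wide = wide.dropna()
        t, p = stats.ttest_rel(wide[ga], wide[gb])
        paired = (float(t), float(p))
    return ComparisonResult(value, group_stats, paired_t=paired)


def _sub_seed(seed: int, i: int) -> int:
    return (int(seed) * 7919 + i * 104729 + 17) % (2 ** 31)


@dataclass
class PurificationResult:
    samples: pd.DataFrame                 # animal, condition, rate, load, mt_fraction
    rate_r: tuple[float, float]
    load_r: tuple[float, float]
    rate_t: tuple[float, float]
    load_t: tuple[float, float]
    mt_fraction_t: tuple[float, float]
    comparisons: list[ComparisonResult]


def run_purification_experiment(cfg: ExperimentConfig) -> PurificationResult:
    """Purified vs unpurified rate/load over ``cfg.n_animals`` simulated
    animals sharing one reference and nuclear background."""
    if cfg.n_animals < 3:
        raise ValueError("need at least 3 animals for a correlation")
    genome = generate_reference(cfg.genome_length, cfg.gc, seed=_sub_seed(cfg.seed, 0))
    background = generate_background(genome, cfg.nuclear_length, cfg.n_numts,
                                     cfg.numt_length, cfg.numt_divergence,
                                     seed=_sub_seed(cfg.seed, 1))
    rotation = RotationConfig(genome_length=cfg.genome_length) if cfg.genome_length == 16299 \
        else RotationConfig(rotation=cfg.genome_length // 2,
                            patch_windows=((1, cfg.read_len * 2),
                                           (cfg.genome_length - 2 * cfg.read_len + 1, cfg.genome_length)),
                            genome_length=cfg.genome_length)
    bundle = build_mappers(genome, [background], rotation, k=cfg.k,
                           max_mismatch_frac=cfg.max_mismatch_frac, policy=cfg.policy)
    rows = []
    for i, n_som in enumerate(cfg.animal_somatic_counts()):
        aseed = _sub_seed(cfg.seed, 10 + i)
        truth = plant_variants(genome, cfg.n_germline, n_som, cfg.af_germline,
                               cfg.af_somatic, tissues=("brain",), seed=aseed,
                               error_rate=cfg.error_rate)
        for condition, purified in (("purified", True), ("unpurified", False)):
            reads = simulate_reads(genome, background, truth, "brain",
                                   depth_mt=cfg.depth_mt, depth_nuc=cfg.nuclear_depth,
                                   read_len=cfg.read_len, purified=purified, seed=aseed)
            rng = np.random.default_rng(np.random.SeedSequence([aseed, 7]))
            res = call_sample(reads.reads(), bundle, cfg.caller,
                              sample_id=f"animal{i}", tissue="brain", rng=rng)
            rows.append({
                "animal": f"animal{i}", "condition": condition,
                "rate": compute_rate(res.calls, genome.length),
                "load": compute_load(res.calls, res.mt_total_bases),
                "mt_fraction": res.mt_mapped_fraction,
                "n_calls": len(res.calls), "n_true_somatic": n_som,
            })
    samples = pd.DataFrame(rows)
    wide = {m: samples.pivot(index="animal", columns="condition", values=m)
            for m in ("rate", "load", "mt_fraction")}
    def _paired_t(a, b) -> tuple[float, float]:
        # identical paired values -> no evidence of a difference, not NaN
        if np.allclose(np.asarray(a, dtype=float), np.asarray(b, dtype=float)):
            return (0.0, 1.0)
        t, p = stats.ttest_rel(a, b)
        return (float(t), float(p))

    rate_r = pearson(wide["rate"]["purified"], wide["rate"]["unpurified"])
    load_r = pearson(wide["load"]["purified"], wide["load"]["unpurified"])
    rate_t = _paired_t(wide["rate"]["purified"], wide["rate"]["unpurified"])
    load_t = _paired_t(wide["load"]["purified"], wide["load"]["unpurified"])
    mt_t = _paired_t(wide["mt_fraction"]["purified"], wide["mt_fraction"]["unpurified"])
    comparisons = [summarize_groups(samples, m, "condition", paired_on="animal")
                   for m in ("rate", "load", "mt_fraction")]
    return PurificationResult(samples, rate_r, load_r, rate_t, load_t, mt_t, comparisons)


@dataclass
class ConcordanceResult:
    samples: pd.DataFrame          # replicate, sample, true_ratio, qpcr, sequencing
    r_per_replicate: list[float]
    median_error_qpcr: float
    median_error_seq: float

    @property
    def r(self) -> float:
        return self.r_per_replicate[0]


def run_concordance_experiment(cfg: ExperimentConfig, n_replicates: int = 1) -> ConcordanceResult:
    """qPCR vs sequencing copy-number concordance over a simulated panel.

    True copy ratios are log-uniform over ``cfg.ratio_range``; the nuclear
    sequencing depth is ``depth_mt / ratio`` so the coverage ratio carries
    realistic Poisson counting noise.  The reference, background and k-mer
    index are shared across replicates.
    """
    if cfg.n_samples < 3:
        raise ValueError("need at least 3 samples")
    lo, hi = cfg.ratio_range
    if not (0 < lo < hi):
        raise ValueError("degenerate copy-ratio range")
    genome = generate_reference(cfg.genome_length, cfg.gc, seed=_sub_seed(cfg.seed, 0))
    background = generate_background(genome, cfg.concordance_nuclear_length, 2,
                                     cfg.numt_length, cfg.numt_divergence,
                                     seed=_sub_seed(cfg.seed, 2))
    mapper = ReadMapper([genome, background], k=cfg.k,
                        max_mismatch_frac=cfg.max_mismatch_frac, policy=cfg.policy)
    empty_truth = SimTruth([], {"panel": []}, 0.0, cfg.error_rate, cfg.seed)

    rows = []
    r_values = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence([_sub_seed(cfg.seed, 100 + rep), 3]))
        ratios = np.exp(rng.uniform(math.log(lo), math.log(hi), size=cfg.n_samples))
        # one standard curve per primer pair per run, as in a real plate layout
        cal_truth = QpcrTruth(cfg.amp_factor_nuclear, cfg.amp_factor_mito,
                              cfg.calibration_noise_sd, 1000.0)
        cal = simulate_qpcr(cal_truth, cfg.dilutions, cfg.replicates,
                            seed=_sub_seed(cfg.seed, 90 + rep))
        nuc = fit_dilution_series(cal, "mB2M")
        mito = fit_dilution_series(cal, "mMito")
        for j, ratio in enumerate(ratios):
            sseed = _sub_seed(cfg.seed, 100 + rep * cfg.n_samples * 4 + j)
            # qPCR arm: triplicate sample wells against the shared curve
            qtruth = QpcrTruth(cfg.amp_factor_nuclear, cfg.amp_factor_mito,
                               cfg.cq_noise_sd, float(ratio))
            cq = simulate_sample_cq(qtruth, cfg.sample_replicates, seed=sseed)
            qpcr_est = copy_number_qpcr(nuc, mito, mean_sample_cq(cq, "mB2M"),
                                        mean_sample_cq(cq, "mMito")).value
            # sequencing arm
            truth = replace(empty_truth, copy_ratio=float(ratio))
            reads = simulate_reads(genome, background, truth, "panel",
                                   depth_mt=cfg.concordance_depth_mt,
                                   depth_nuc=cfg.concordance_depth_mt / float(ratio),
                                   read_len=cfg.read_len, purified=False, seed=sseed)
            aln = mapper.map_reads(reads.reads())
            from .mapping import coverage_profile
            mt_depth, _ = coverage_profile(aln, genome.length, ref_name=genome.name)
            nuc_depth, _ = coverage_profile(aln, background.length, ref_name=background.name)
            seq_est = copy_number_from_sequencing(mt_depth, float(nuc_depth.mean())).value
            rows.append({"replicate": rep, "sample": f"s{j}", "true_ratio": float(ratio),
                         "qpcr": qpcr_est, "sequencing": seq_est})
        sub = pd.DataFrame(rows[-cfg.n_samples:])
        r, _p = pearson(sub["qpcr"], sub["sequencing"])
        r_values.append(r)
    samples = pd.DataFrame(rows)
    err_q = np.abs(samples["qpcr"] - samples["true_ratio"]) / samples["true_ratio"]
    err_s = np.abs(samples["sequencing"] - samples["true_ratio"]) / samples["true_ratio"]
    return ConcordanceResult(samples, r_values, float(err_q.median()), float(err_s.median()))
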