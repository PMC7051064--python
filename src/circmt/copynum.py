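"""mtDNA copy number per nuclear genome equivalent, by qPCR and by
sequencing coverage, plus the concordance between the two estimators.

qPCR route: primer efficiency comes from the slope of the Cq vs
log10(concentration) line over a ten-fold dilution series
(``efficiency = -1 + 10^(-1/slope)``).  Copy number is the
efficiency-corrected Cq ratio

    copy number = f_nuclear ** Cq_nuclear / f_mito ** Cq_mito

where ``f = 10^(-1/slope) = efficiency + 1`` is the per-cycle amplification
factor.  Note the amplification factor, not the efficiency itself, is
exponentiated: a perfect assay has efficiency 1 and raising 1 to any Cq
would collapse the formula, so the factor form — the standard
efficiency-corrected delta-Cq method — is the computable reading.

Sequencing route: mean per-base mt coverage divided by mean per-base
nuclear coverage, from the same alignment run, optionally scaled by a
nuclear ploidy factor (default 1, i.e. per haploid genome equivalent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class QpcrAssay:
    """A fitted dilution-series standard curve for one primer pair."""

    name: str
    slope: float          # Cq per log10(template)
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("a valid standard curve has negative slope")

    @property
    def amp_factor(self) -> float:
        """Per-cycle template multiplication, 10^(-1/slope)."""
        return 10.0 ** (-1.0 / self.slope)

    @property
    def efficiency(self) -> float:
        """-1 + 10^(-1/slope); 1.0 for perfect doubling."""
        return self.amp_factor - 1.0


@dataclass(frozen=True)
class CopyNumberResult:
    sample_id: str
    tissue: str
    method: str           # 'qpcr' or 'sequencing'
    value: float

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("copy number must be positive")
        if self.method not in ("qpcr", "sequencing"):
            raise ValueError("method must be 'qpcr' or 'sequencing'")


def fit_dilution_series(cq_table: pd.DataFrame, assay: str) -> QpcrAssay:
    """Ordinary least squares of Cq on log10(relative concentration) over a
    ten-fold dilution series (dilution d holds 10^-d of the undiluted
    template)."""
    sub = cq_table[cq_table["assay"] == assay]
    if sub["dilution"].nunique() < 3:
        raise ValueError("need at least 3 distinct dilution levels")
    log_conc = -sub["dilution"].to_numpy(dtype=float)
    fit = stats.linregress(log_conc, sub["Cq"].to_numpy(dtype=float))
    return QpcrAssay(assay, float(fit.slope), float(fit.intercept), float(fit.rvalue) ** 2)


def copy_number_qpcr(nuclear: QpcrAssay, mito: QpcrAssay,
                     cq_nuclear: float, cq_mito: float,
                     sample_id: str = "", tissue: str = "") -> CopyNumberResult:
    """Efficiency-corrected Cq ratio (amplification factors exponentiated)."""
    if cq_nuclear <= 0 or cq_mito <= 0:
        raise ValueError("Cq values must be positive")
    for assay in (nuclear, mito):
        if assay.amp_factor <= 1.0:
            raise ValueError(f"assay {assay.name} has amplification factor <= 1")
    value = nuclear.amp_factor ** cq_nuclear / mito.amp_factor ** cq_mito
    return CopyNumberResult(sample_id, tissue, "qpcr", value)


def copy_number_from_sequencing(mt_coverage: np.ndarray | float, nuclear_coverage: float,
                                ploidy_factor: float = 1.0,
                                sample_id: str = "", tissue: str = "") -> CopyNumberResult:
    """Mean mt depth over mean nuclear depth (x ploidy factor)."""
    mt_mean = float(np.mean(mt_coverage))
    if nuclear_coverage <= 0:
        raise ValueError("nuclear coverage must be positive")
    return CopyNumberResult(sample_id, tissue, "sequencing",
                            ploidy_factor * mt_mean / float(nuclear_coverage))


def mean_sample_cq(cq_table: pd.DataFrame, assay: str, dilution: int = 0) -> float:
    """Replicate-averaged Cq of the (undiluted, by default) sample."""
    sub = cq_table[(cq_table["assay"] == assay) & (cq_table["dilution"] == dilution)]
    if sub.empty:
        raise ValueError(f"no Cq rows for assay {assay} at dilution {dilution}")
    return float(sub["Cq"].mean())


def concordance(pairs: pd.DataFrame, col_a: str = "qpcr", col_b: str = "sequencing"
                ) -> tuple[float, float, pd.DataFrame]:
    """Pearson correlation between two copy-number estimators over a sample
    panel; returns (r, two-sided p, the pairs table)."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 paired samples")
    x = pairs[col_a].to_numpy(dtype=float)
    y = pairs[col_b].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one estimator")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), pairs
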