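"""Poisson colony-size model and chromosome-distribution test.

Dyads are modelled as a homogeneous Poisson process on the genome. The
expected number of dyads in a fixed window of ``window_bp`` bases is

    lambda = window_bp * dyad_count / genome_size_bp

with defaults window_bp = 26,000 and genome_size_bp = 3e9; ``dyad_count``
is the number of colony-member dyads genome-wide. The significance score
of a size-k colony is the Poisson density P(K = k) = exp(-lambda)
lambda^k / k!, evaluated in log space (log p = -lambda + k ln lambda -
ln Gamma(k+1)) so that deep-tail values (k ~ 100 -> ~1e-220) are exact;
below the double-precision floor the linear value is reported as 0 while
the log10 value stays finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .colony import Colony

_LN10 = math.log(10.0)
# exp() underflows to 0 below roughly -745 in natural log
_MIN_EXP_ARG = math.log(5e-324)


@dataclass(frozen=True)
class PoissonModel:
    """Parameters of the colony-size null; lambda is always derived, never set."""

    window_bp: int = 26_000
    dyad_count: int = 0
    genome_size_bp: float = 3e9

    def __post_init__(self) -> None:
        if self.window_bp <= 0 or self.dyad_count <= 0 or self.genome_size_bp <= 0:
            raise ValueError("window_bp, dyad_count and genome_size_bp must be > 0")

    @property
    def lam(self) -> float:
        return self.window_bp * self.dyad_count / self.genome_size_bp


def fit_lambda(
    dyad_count: int, genome_size_bp: float = 3e9, window_bp: int = 26_000
) -> PoissonModel:
    """Build the Poisson model from its three parameters."""
    return PoissonModel(
        window_bp=window_bp, dyad_count=dyad_count, genome_size_bp=genome_size_bp
    )


def poisson_log10_pmf(k: int, model: PoissonModel) -> float:
    if k < 0:
        raise ValueError("k must be >= 0")
    lam = model.lam
    return (-lam + k * math.log(lam) - math.lgamma(k + 1)) / _LN10


def poisson_pmf(k: int, model: PoissonModel) -> Tuple[float, float]:
    """(probability, log10 probability) of exactly k dyads in one window.

    The linear value is 0.0 when the true probability is below the smallest
    positive double; the log10 value is always finite.
    """
    log10p = poisson_log10_pmf(k, model)
    ln_p = log10p * _LN10
    probability = math.exp(ln_p) if ln_p > _MIN_EXP_ARG else 0.0
    return probability, log10p


def score_colonies(colonies: Sequence[Colony], model: PoissonModel) -> List[Colony]:
    """Return copies of the colonies with probability fields filled in."""
    out: List[Colony] = []
    for c in colonies:
        p, log10p = poisson_pmf(c.size, model)
        out.append(replace(c, probability=p, log10_probability=log10p))
    return out


def colony_size_table(colonies: Sequence[Colony], model: PoissonModel) -> pd.DataFrame:
    """Size-spectrum summary: one row per colony size with count and probability."""
    from .colony import colony_size_spectrum

    spectrum = colony_size_spectrum(colonies)
    rows = []
    for size, count in spectrum.items():
        p, log10p = poisson_pmf(size, model)
        rows.append(
            {
                "colony_size": size,
                "count": count,
                "probability": p,
                "log10_probability": log10p,
            }
        )
    return pd.DataFrame(
        rows, columns=["colony_size", "count", "probability", "log10_probability"]
    )


@dataclass
class ChromosomeStats:
    """Chi-square goodness of fit of per-chromosome counts to length proportionality."""

    per_chromosome: pd.DataFrame  # name, length_bp, observed, expected, std_residual
    statistic: float
    df: int
    pvalue: float


def chromosome_proportionality_test(
    names: Sequence[str],
    lengths_bp: Sequence[float],
    counts: Sequence[int],
) -> ChromosomeStats:
    """Test whether counts are proportional to chromosome lengths.

    Expected counts are total * length_i / sum(lengths); the statistic is
    Pearson's chi-square with df = #chromosomes - 1, and per-chromosome
    standardized residuals (obs - exp) / sqrt(exp) localize the deviation.
    """
    names = list(names)
    lengths = np.asarray(lengths_bp, dtype=float)
    observed = np.asarray(counts, dtype=float)
    if len(names) < 2:
        raise ValueError("need at least 2 chromosomes")
    if np.any(lengths <= 0):
        raise ValueError("every chromosome length must be positive")
    total = observed.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    expected = total * lengths / lengths.sum()
    statistic, pvalue = sps.chisquare(observed, expected)
    residuals = (observed - expected) / np.sqrt(expected)
    table = pd.DataFrame(
        {
            "chromosome": names,
            "length_bp": lengths,
            "observed": observed.astype(int),
            "expected": expected,
            "std_residual": residuals,
        }
    )
    return ChromosomeStats(
        per_chromosome=table,
        statistic=float(statistic),
        df=len(names) - 1,
        pvalue=float(pvalue),
    )


def window_occupancy_spectrum(
    positions: Sequence[int], genome_length: int, window_bp: int = 26_000
) -> Dict[int, int]:
    """Count dyads per disjoint window; mapping occupancy k -> number of windows.

    This is the empirical counterpart of the Poisson model: under uniform
    placement the fraction of windows holding exactly k dyads estimates
    poisson_pmf(k). Only complete windows are counted.
    """
    n_windows = genome_length // window_bp
    if n_windows == 0:
        raise ValueError("genome shorter than one window")
    pos = np.asarray(positions, dtype=np.int64)
    pos = pos[pos < n_windows * window_bp]
    per_window = np.bincount(pos // window_bp, minlength=n_windows)
    occupancy, counts = np.unique(per_window, return_counts=True)
    return {int(k): int(c) for k, c in zip(occupancy, counts)}
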