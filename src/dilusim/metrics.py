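"""Community diversity statistics and run summaries.

Diversity is quantified by the Shannon entropy of start-of-batch relative
abundances, ``S = -sum_sigma P_sigma ln P_sigma`` (nats), and the effective
number of species ``m_e = exp(S)`` — an evenness-weighted species count
that equals the raw count for a perfectly even community.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class DiversitySummary:
    shannon: float
    effective_species: float
    extant_count: int
    fractions: np.ndarray


@dataclass(frozen=True)
class RankAbundanceCurve:
    ranks: np.ndarray
    abundances: np.ndarray  # non-increasing


def _validated(fractions) -> np.ndarray:
    f = np.asarray(fractions, dtype=float)
    if np.any(f < 0):
        raise ValueError("fractions must be non-negative")
    if abs(f.sum() - 1.0) > _NORM_TOL:
        raise ValueError(f"fractions sum to {f.sum()!r}, not 1")
    return f


def shannon_diversity(fractions) -> float:
    """Shannon entropy in nats; zero-abundance entries contribute zero."""
    f = _validated(fractions)
    nz = f[f > 0]
    return float(-(nz * np.log(nz)).sum())


def effective_species(fractions) -> float:
    """Effective number of species m_e = exp(S)."""
    return float(np.exp(shannon_diversity(fractions)))


def rank_abundance(fractions) -> RankAbundanceCurve:
    """Abundances sorted descending, ranked from 1."""
    f = _validated(fractions)
    order = np.sort(f)[::-1]
    return RankAbundanceCurve(np.arange(1, f.size + 1), order)


def gini(fractions) -> float:
    """Gini coefficient of the abundance distribution (0 = perfectly flat).

    Used as the flatness score for rank-abundance comparisons: flatter
    curves have smaller Gini.
    """
    f = np.sort(_validated(fractions))
    n = f.size
    return float((2.0 * np.arange(1, n + 1) - n - 1.0) @ f / n)


def diversity_summary(fractions) -> DiversitySummary:
    f = _validated(fractions)
    s = shannon_diversity(f)
    return DiversitySummary(
        shannon=s,
        effective_species=float(np.exp(s)),
        extant_count=int(np.count_nonzero(f)),
        fractions=f,
    )


def median_extant_over_batches(counts: np.ndarray | pd.DataFrame, burn_in: int) -> float:
    """Median number of extant strategies over post-burn-in batches.

    ``counts`` holds start-of-batch counts, one row per batch; a strategy is
    extant in a batch if its count is nonzero.  ``burn_in`` initial batches
    are discarded.
    """
    arr = np.asarray(counts)
    if burn_in >= arr.shape[0]:
        raise ValueError("burn-in leaves no batches to summarize")
    extant = np.count_nonzero(arr[burn_in:], axis=1)
    return float(np.median(extant))
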