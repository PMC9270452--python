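"""Incidence-based similarity metrics and beta-diversity partitioning.

All metrics work from the pair counts ``(a, b, c)`` of a site pair: ``a``
species shared, ``b`` unique to the first site, ``c`` unique to the second.
Joint absences are never counted.  Similarities (Jaccard, corrected Forbes,
Sorensen) run from 0 (disjoint) to 1 (identical); the Baselga partition
splits total Sorensen dissimilarity into a turnover (Simpson) and a
nestedness-resultant component, ``beta_sor = beta_sim + beta_sne``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .occurrences import IncidenceMatrix


class PairCounts(NamedTuple):
    """Shared/unique species counts for one site pair (a = shared)."""

    a: int
    b: int
    c: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c


def pair_counts(site1, site2) -> PairCounts:
    """Count shared and unique species of two non-empty species sets."""
    s1, s2 = frozenset(site1), frozenset(site2)
    if not s1 or not s2:
        raise ValueError("pair_counts requires two non-empty species sets")
    a = len(s1 & s2)
    return PairCounts(a=a, b=len(s1) - a, c=len(s2) - a)


# ---------------------------------------------------------------------------
# scalar metrics (array-safe: every function accepts numpy arrays for a, b, c)


def _jaccard(a, b, c):
    return a / (a + b + c)


def _sorensen(a, b, c):
    return 2 * a / (2 * a + b + c)


def _forbes_corrected(a, b, c):
    # Alroy's corrected Forbes index: a(n + sqrt(n)) / [a(n + sqrt(n)) + 1.5 bc].
    n = a + b + c
    num = a * (n + np.sqrt(n))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(a == 0, 0.0, num / (num + 1.5 * b * c))


def _simpson_turnover(a, b, c):
    m = np.minimum(b, c)
    denom = a + m
    return np.where(denom == 0, 0.0, m / np.where(denom == 0, 1, denom))


def _nestedness(a, b, c):
    return (b + c) / (2 * a + b + c) - _simpson_turnover(a, b, c)


#: Registry of pairwise metrics keyed by the names the CLI exposes.
METRICS = {
    "jaccard": _jaccard,
    "forbes_corrected": _forbes_corrected,
    "sorensen": _sorensen,
    "simpson_turnover": _simpson_turnover,
    "nestedness": _nestedness,
}


def jaccard(pc: PairCounts) -> float:
    """Jaccard similarity J/(A + B - J) = a/(a+b+c)."""
    return float(_jaccard(pc.a, pc.b, pc.c))


def sorensen(pc: PairCounts) -> float:
    """Sorensen similarity 2a/(2a+b+c)."""
    return float(_sorensen(pc.a, pc.b, pc.c))


def corrected_forbes(pc: PairCounts) -> float:
    """Corrected Forbes similarity; 1 iff b=c=0 and 0 iff a=0, like Jaccard."""
    if pc.a == 0:
        return 0.0
    n = pc.n
    num = pc.a * (n + math.sqrt(n))
    return num / (num + 1.5 * pc.b * pc.c)


@dataclass(frozen=True)
class BetaPartition:
    """Sorensen dissimilarity split into turnover (Simpson) and nestedness parts."""

    total: float
    turnover: float
    nestedness: float

    def __post_init__(self):
        for v in (self.total, self.turnover, self.nestedness):
            if not (-1e-12 <= v <= 1 + 1e-12):
                raise ValueError("partition components must lie in [0, 1]")


def sorensen_simpson_partition(pc: PairCounts) -> BetaPartition:
    """Pairwise Baselga partition: beta_sor = beta_sim + beta_sne.

    ``beta_sim = min(b,c)/(a+min(b,c))`` (0 when the denominator vanishes,
    i.e. the nested limit), ``beta_sor = (b+c)/(2a+b+c)``.
    """
    total = float((pc.b + pc.c) / (2 * pc.a + pc.b + pc.c))
    m = min(pc.b, pc.c)
    turnover = float(m / (pc.a + m)) if (pc.a + m) > 0 else 0.0
    return BetaPartition(total=total, turnover=turnover, nestedness=total - turnover)


def multisite_partition(m: IncidenceMatrix) -> BetaPartition:
    """Baselga multiple-site partition of Sorensen dissimilarity.

    Uses the closed forms over all ordered site pairs: with ``b_ij`` the number
    of species in site i absent from site j,

        beta_SIM = S_min / (S_min + S_shared)
        beta_SOR = (S_min + S_max) / (2 S_shared + S_min + S_max)

    where ``S_min/S_max`` sum min/max(b_ij, b_ji) over pairs and
    ``S_shared = sum_i S_i - S_T``.  Reduces to the pairwise forms at 2 sites.
    """
    X = m.values.astype(np.int64)
    if X.shape[0] < 2:
        raise ValueError("multisite partition needs at least 2 sites")
    shared = X @ X.T
    rich = X.sum(axis=1)
    bij = rich[:, None] - shared  # species in i absent from j
    iu = np.triu_indices(X.shape[0], k=1)
    s_min = np.minimum(bij[iu], bij.T[iu]).sum()
    s_max = np.maximum(bij[iu], bij.T[iu]).sum()
    s_shared = rich.sum() - int((X.sum(axis=0) > 0).sum())
    if s_min + s_shared == 0:
        turnover = 0.0
    else:
        turnover = float(s_min / (s_min + s_shared))
    denom = 2 * s_shared + s_min + s_max
    total = float((s_min + s_max) / denom) if denom else 0.0
    return BetaPartition(total=total, turnover=turnover, nestedness=total - turnover)


# ---------------------------------------------------------------------------
# matrix-level helpers


def pairwise_counts(m: IncidenceMatrix):
    """Arrays (a, b, c) for all unordered site pairs i<j, in triu order."""
    X = m.values.astype(np.int64)
    shared = X @ X.T
    rich = X.sum(axis=1)
    iu = np.triu_indices(X.shape[0], k=1)
    a = shared[iu]
    b = rich[iu[0]] - a
    c = rich[iu[1]] - a
    return a, b, c


def pairwise_matrix(m: IncidenceMatrix, metric: str = "jaccard") -> np.ndarray:
    """Full symmetric site-by-site matrix of a registered pairwise metric."""
    fn = METRICS[metric]
    X = m.values.astype(np.int64)
    shared = X @ X.T
    rich = X.sum(axis=1)
    a = shared
    b = rich[:, None] - shared
    c = rich[None, :] - shared
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.asarray(fn(a, b, c), dtype=float)
    np.fill_diagonal(vals, fn(np.array(1), np.array(0), np.array(0)))
    return vals


@dataclass(frozen=True)
class SimilaritySummary:
    """Mean +/- SEM of a pairwise metric over all unordered site pairs."""

    bin_label: str
    metric: str
    mean: float
    sem: float
    n_pairs: int


def mean_pairwise_similarity(m: IncidenceMatrix, metric: str = "jaccard", bin_label: str = "") -> SimilaritySummary:
    """Average a registered pairwise metric over the s(s-1)/2 site pairs."""
    if m.n_sites < 2:
        raise ValueError("mean pairwise similarity needs at least 2 sites")
    a, b, c = pairwise_counts(m)
    vals = np.asarray(METRICS[metric](a, b, c), dtype=float)
    n = vals.size
    sem = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return SimilaritySummary(bin_label=bin_label, metric=metric, mean=float(vals.mean()), sem=sem, n_pairs=n)
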