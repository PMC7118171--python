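"""Population-level inference across LFP-EMG pairs.

Covers pooled significance with an exact-binomial limit, the Z-transformed
coherence-difference permutation test, circular statistics on phase
distributions (Rayleigh, Mardia-Watson-Wheeler), Welch comparison of onset
latencies, and intermuscle connection counting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
import pingouin as pg


# ------------------------------------------------------- pooled significance
@dataclass
class PooledSignificance:
    """Per-frequency proportion of significant pairs with a binomial limit."""

    freqs: np.ndarray
    proportion: np.ndarray
    n_pairs: int
    limit: float
    base_rate: float = 0.005
    level: float = 0.05

    @property
    def significant(self) -> np.ndarray:
        return self.proportion >= self.limit


def binomial_limit(n: int, base_rate: float = 0.005, level: float = 0.05) -> float:
    """Smallest proportion k/n whose exact binomial tail is below ``level``.

    The tail P(Bin(n, base_rate) >= k) is computed exactly; a normal
    approximation fails this far out (base rate 0.005).
    """
    for k in range(n + 1):
        if stats.binom.sf(k - 1, n, base_rate) < level:
            return k / n
    return 1.0


def pooled_significance(
    masks: np.ndarray,
    freqs: np.ndarray,
    base_rate: float = 0.005,
    level: float = 0.05,
) -> PooledSignificance:
    """Proportion of pairs significant at each frequency, with its limit.

    ``masks`` is boolean (n_pairs, n_freqs); all pairs must share the grid.
    """
    masks = np.asarray(masks, dtype=bool)
    freqs = np.asarray(freqs, dtype=float)
    if masks.ndim != 2 or masks.shape[1] != len(freqs):
        raise ValueError("masks must be (n_pairs, n_freqs) on a common grid")
    n = masks.shape[0]
    if n < 2:
        raise ValueError("need at least two pairs")
    return PooledSignificance(
        freqs=freqs,
        proportion=masks.mean(axis=0),
        n_pairs=n,
        limit=binomial_limit(n, base_rate, level),
        base_rate=base_rate,
        level=level,
    )


# ------------------------------------------------- Z-difference permutation
@dataclass
class ZDifferenceResult:
    freqs: np.ndarray
    z: np.ndarray
    lower: np.ndarray  # 2.5th permutation percentile
    upper: np.ndarray  # 97.5th permutation percentile
    df1: int
    df2: int
    iterations: int

    @property
    def group1_greater(self) -> np.ndarray:
        return self.z > self.upper

    @property
    def group2_greater(self) -> np.ndarray:
        return self.z < self.lower


def _z_of(c1: np.ndarray, c2: np.ndarray, df1: int, df2: int) -> np.ndarray:
    b1, b2 = 1.0 / (df1 - 2), 1.0 / (df2 - 2)
    return ((np.arctanh(np.abs(c1)) - b1) - (np.arctanh(np.abs(c2)) - b2)) / np.sqrt(b1 + b2)


def z_difference_test(
    coh1: np.ndarray,
    coh2: np.ndarray,
    iterations: int = 10000,
    seed: int | np.random.Generator = 0,
) -> ZDifferenceResult:
    """Z-transformed difference of group-mean coherence with a permutation
    envelope.

    ``coh1``/``coh2`` are (n_pairs, n_freqs) coherence spectra.  The
    observed Z(f) compares bias-corrected atanh-transformed group means
    (degrees of freedom 2 x pairs x frequency bins per group).  Whole pairs
    (entire spectra) are permuted between groups; the 2.5th/97.5th
    percentiles of the permuted Z at each frequency form the envelope.
    """
    coh1 = np.atleast_2d(np.asarray(coh1, dtype=float))
    coh2 = np.atleast_2d(np.asarray(coh2, dtype=float))
    if coh1.shape[1] != coh2.shape[1]:
        raise ValueError("groups must share the frequency grid")
    if min(coh1.shape[0], coh2.shape[0]) < 2:
        raise ValueError("both groups need at least two pairs")
    if iterations < 1000:
        warnings.warn("fewer than 1000 permutations: unstable percentiles",
                      stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1, nf = coh1.shape
    n2 = coh2.shape[0]
    df1 = 2 * n1 * nf
    df2 = 2 * n2 * nf
    z_obs = _z_of(coh1.mean(axis=0), coh2.mean(axis=0), df1, df2)
    pool = np.concatenate([coh1, coh2], axis=0)
    z_perm = np.empty((iterations, nf))
    for it in range(iterations):
        perm = rng.permutation(n1 + n2)
        g1 = pool[perm[:n1]].mean(axis=0)
        g2 = pool[perm[n1:]].mean(axis=0)
        z_perm[it] = _z_of(g1, g2, df1, df2)
    lower, upper = np.percentile(z_perm, [2.5, 97.5], axis=0)
    return ZDifferenceResult(
        freqs=np.arange(nf, dtype=float), z=z_obs, lower=lower, upper=upper,
        df1=df1, df2=df2, iterations=iterations,
    )


# -------------------------------------------------------- circular statistics
def rayleigh_test(angles: np.ndarray) -> tuple[float, float]:
    """Rayleigh test of circular non-uniformity; returns (z, p)."""
    angles = np.asarray(angles, dtype=float)
    if len(angles) < 3:
        raise ValueError("need at least three angles")
    z, p = pg.circ_rayleigh(angles)
    return float(z), float(p)


def mww_test(angles1: np.ndarray, angles2: np.ndarray) -> tuple[float, float]:
    """Mardia-Watson-Wheeler uniform-scores two-sample test on the circle.

    Combined angles are replaced by uniform scores beta = 2 pi rank / N;
    the statistic ``W = 2 sum_i R_i^2 / n_i`` is chi-square with 2 df for
    two groups.  Returns (W, p).  The chi-square approximation is poor for
    group sizes below ~5 (a warning is raised).
    """
    a1 = np.asarray(angles1, dtype=float)
    a2 = np.asarray(angles2, dtype=float)
    n1, n2 = len(a1), len(a2)
    if min(n1, n2) < 5:
        warnings.warn("group size below 5: chi-square approximation is poor",
                      stacklevel=2)
    combined = np.concatenate([a1, a2])
    ranks = stats.rankdata(np.mod(combined, 2 * np.pi))
    beta = 2.0 * np.pi * ranks / (n1 + n2)
    w = 0.0
    for sl, n in (((slice(0, n1)), n1), (slice(n1, n1 + n2), n2)):
        c = np.cos(beta[sl]).sum()
        s = np.sin(beta[sl]).sum()
        w += (c * c + s * s) / n
    w *= 2.0
    return float(w), float(stats.chi2.sf(w, df=2))


def circular_mean(angles: np.ndarray) -> tuple[float, float]:
    """Circular mean and circular SD (rad) of a sample of angles."""
    angles = np.asarray(angles, dtype=float)
    mean = float(stats.circmean(angles, high=np.pi, low=-np.pi))
    sd = float(stats.circstd(angles, high=np.pi, low=-np.pi))
    return mean, sd


# ------------------------------------------------------- latency comparison
@dataclass
class LatencyComparison:
    statistic: float
    p_value: float
    median1: float
    median2: float
    n1: int
    n2: int


def latency_comparison(lat1: np.ndarray, lat2: np.ndarray) -> LatencyComparison:
    """Welch t test (unequal variances) between two latency distributions."""
    lat1 = np.asarray(lat1, dtype=float)
    lat2 = np.asarray(lat2, dtype=float)
    if min(len(lat1), len(lat2)) < 2:
        raise ValueError("both groups need at least two latencies")
    if np.var(lat1) == 0 and np.var(lat2) == 0:
        # degenerate: identical constants are indistinguishable
        stat = 0.0 if np.mean(lat1) == np.mean(lat2) else np.inf
        p = 1.0 if stat == 0.0 else 0.0
    else:
        res = stats.ttest_ind(lat1, lat2, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
    return LatencyComparison(
        statistic=stat, p_value=p,
        median1=float(np.median(lat1)), median2=float(np.median(lat2)),
        n1=len(lat1), n2=len(lat2),
    )


# --------------------------------------------------------- connection graph
@dataclass
class ConnectionGraph:
    """Counts of muscle pairs co-significant at shared recording sites."""

    edges: pd.DataFrame  # muscle_a, muscle_b, count
    site_muscles: dict[str, list[str]]

    @property
    def total_edges(self) -> int:
        return int(self.edges["count"].sum()) if len(self.edges) else 0


def connection_graph(site_muscles: dict[str, list[str]]) -> ConnectionGraph:
    """Count unordered muscle combinations per site ("interacting muscles").

    For each site, every unordered pair of muscles with significant
    coherence at that site increments its edge; totals are summed over
    sites.
    """
    counts: dict[tuple[str, str], int] = {}
    for muscles in site_muscles.values():
        for a, b in combinations(sorted(set(muscles)), 2):
            counts[(a, b)] = counts.get((a, b), 0) + 1
    rows = [
        {"muscle_a": a, "muscle_b": b, "count": c}
        for (a, b), c in sorted(counts.items())
    ]
    return ConnectionGraph(
        edges=pd.DataFrame(rows, columns=["muscle_a", "muscle_b", "count"]),
        site_muscles={k: sorted(set(v)) for k, v in site_muscles.items()},
    )
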