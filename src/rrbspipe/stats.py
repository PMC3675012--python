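"""Statistical primitives used across the pipeline.

The inference stages rely on a small set of tests: the two-sided
Wilcoxon (Mann-Whitney) rank-sum test for group shifts in methylation
or expression, the exact two-sided binomial test for pooled-count
differential expression, Benjamini-Hochberg step-up adjustment, an
upper-tail binomial overlap statistic for cross-study gene sharing,
a permutation gene-set enrichment test, and a Gaussian kernel density
used for the difference-distribution summaries.

The rank-sum exact null distribution and the BH step-up are implemented
here directly (the exact null table is cached per group-size pair, which
is what makes testing tens of thousands of CpGs cheap); scipy supplies
pmf/sf building blocks and ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps


class StatsError(ValueError):
    """Raised on invalid arguments to a statistical primitive."""


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str

    def __post_init__(self):
        if not np.isfinite(self.statistic):
            raise StatsError("test statistic must be finite")
        if not (0.0 <= self.p_value <= 1.0):
            raise StatsError("p-value outside [0, 1]")


@dataclass(frozen=True)
class AdjustedPValues:
    raw: np.ndarray
    adjusted: np.ndarray


@dataclass(frozen=True)
class EnrichmentConfig:
    """Settings for the permutation gene-set enrichment test.

    The defaults mirror the study design this pipeline models: 1000
    permutations against a background universe of 15,203 genes.
    """

    n_permutations: int = 1000
    universe_size: int = 15203
    seed: int = 0

    def __post_init__(self):
        if self.n_permutations < 1:
            raise StatsError("n_permutations must be >= 1")
        if self.universe_size < 1:
            raise StatsError("universe_size must be >= 1")


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

@lru_cache(maxsize=256)
def _mw_null_cdf(n1: int, n2: int) -> np.ndarray:
    """CDF of the Mann-Whitney U statistic under the tie-free null.

    dp[j, s] counts subsets of ranks 1..t of size j with rank sum s;
    built by a standard subset-sum recursion over the combined ranks.
    """
    n = n1 + n2
    max_s = n1 * n + 1  # rank sums are at most n1*n
    dp = np.zeros((n1 + 1, max_s), dtype=np.float64)
    dp[0, 0] = 1.0
    for t in range(1, n + 1):
        for j in range(min(t, n1), 0, -1):
            dp[j, t:] += dp[j - 1, :-t]
    sums = dp[n1]
    # U = R1 - n1(n1+1)/2
    off = n1 * (n1 + 1) // 2
    u_counts = sums[off : off + n1 * n2 + 1]
    cdf = np.cumsum(u_counts)
    return cdf / cdf[-1]


def wilcoxon_rank_sum(
    group_a: Sequence[float],
    group_b: Sequence[float],
    exact_cutoff: int = 20,
) -> TestResult:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum test.

    Uses the exact tie-free null distribution when the combined sample
    size is at most ``exact_cutoff`` and the data carry no ties;
    otherwise mid-ranks with the tie-corrected normal approximation and
    a continuity correction.  All-tied data carry no evidence (p = 1).
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise StatsError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = bool((tie_counts > 1).any())
    if tie_counts.size == 1:  # every value identical
        return TestResult(u, 1.0, "rank-sum/degenerate")
    if not has_ties and (n1 + n2) <= exact_cutoff:
        cdf = _mw_null_cdf(n1, n2)
        ui = int(round(u))
        p_le = cdf[ui]
        p_ge = 1.0 - (cdf[ui - 1] if ui > 0 else 0.0)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult(u, p, "rank-sum/exact")
    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return TestResult(u, 1.0, "rank-sum/degenerate")
    diff = u - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var) if diff != 0 else 0.0
    p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
    return TestResult(u, p, "rank-sum/normal")


# ---------------------------------------------------------------------------
# Binomial tests
# ---------------------------------------------------------------------------

def exact_binomial_test(x: int, n: int, p0: float) -> TestResult:
    """Two-sided exact binomial test (minimum-likelihood tail convention).

    The p-value sums the probabilities of all outcomes no more probable
    than the observed one.
    """
    if not (0 <= x <= n):
        raise StatsError("require 0 <= x <= n")
    if not (0.0 <= p0 <= 1.0):
        raise StatsError("p0 must be in [0, 1]")
    k = np.arange(n + 1)
    pmf = sps.binom.pmf(k, n, p0)
    px = pmf[x]
    p = float(pmf[pmf <= px * (1.0 + 1e-7)].sum())
    return TestResult(float(x), min(1.0, p), "binomial/two-sided")


def binomial_overlap_test(
    k_shared: int, n_tested: int, rate_a: float, rate_b: float
) -> TestResult:
    """Upper-tail binomial test for the number of genes shared between
    two independent differential-methylation screens.

    Under independence a gene is differentially methylated in both
    studies with probability ``rate_a * rate_b``; the statistic is
    P(X >= k_shared) for X ~ Binomial(n_tested, rate_a * rate_b).
    """
    if not (0 <= k_shared <= n_tested):
        raise StatsError("require 0 <= k_shared <= n_tested")
    for r in (rate_a, rate_b):
        if not (0.0 <= r <= 1.0):
            raise StatsError("rates must be in [0, 1]")
    p0 = rate_a * rate_b
    p = float(sps.binom.sf(k_shared - 1, n_tested, p0)) if k_shared > 0 else 1.0
    return TestResult(float(k_shared), min(1.0, p), "binomial/upper-tail")


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: Sequence[float]) -> AdjustedPValues:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return AdjustedPValues(p.copy(), p.copy())
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise StatsError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return AdjustedPValues(p.copy(), out)


# ---------------------------------------------------------------------------
# Permutation gene-set enrichment
# ---------------------------------------------------------------------------

def permutation_geneset_test(
    query: Iterable,
    target: Iterable,
    universe: Iterable,
    cfg: EnrichmentConfig | None = None,
) -> TestResult:
    """Permutation test for query/target gene-set overlap.

    Each permutation redraws ``|query|`` genes uniformly without
    replacement from the universe; the p-value uses the add-one
    estimator ``(1 + #{overlap >= observed}) / (1 + B)`` so it is never
    exactly zero.  Fully seeded and reproducible.
    """
    cfg = cfg or EnrichmentConfig()
    query = set(query)
    target = set(target)
    uni = sorted(set(universe), key=str)
    uni_set = set(uni)
    if not query <= uni_set:
        raise StatsError("query must be a subset of the universe")
    if not target <= uni_set:
        raise StatsError("target must be a subset of the universe")
    observed = len(query & target)
    rng = np.random.default_rng(cfg.seed)
    target_mask = np.fromiter((g in target for g in uni), dtype=bool, count=len(uni))
    q = len(query)
    hits = 0
    for _ in range(cfg.n_permutations):
        idx = rng.choice(len(uni), size=q, replace=False)
        if int(target_mask[idx].sum()) >= observed:
            hits += 1
    p = (1 + hits) / (1 + cfg.n_permutations)
    return TestResult(float(observed), p, "permutation/overlap")


# ---------------------------------------------------------------------------
# Kernel density
# ---------------------------------------------------------------------------

def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 * min(sd, IQR/1.34) * n^(-1/5)."""
    v = np.asarray(values, dtype=np.float64)
    n = v.size
    sd = float(v.std(ddof=1))
    q75, q25 = np.percentile(v, [75, 25])
    iqr = float(q75 - q25)
    spread_candidates = [s for s in (sd, iqr / 1.34) if s > 0]
    if not spread_candidates:
        # degenerate (all values equal): fall back to a narrow kernel
        scale = max(abs(float(v[0])), 1.0)
        return 1e-3 * scale
    return 0.9 * min(spread_candidates) * n ** (-0.2)


def kde_density(
    values: Sequence[float],
    grid: Sequence[float],
    bandwidth: float | str = "auto",
) -> np.ndarray:
    """Gaussian kernel density of ``values`` evaluated on ``grid``."""
    v = np.asarray(values, dtype=np.float64)
    g = np.asarray(grid, dtype=np.float64)
    if v.size == 0:
        raise StatsError("kde_density requires at least one value")
    if bandwidth == "auto":
        if v.size < 2:
            raise StatsError("auto bandwidth requires at least 2 values")
        h = silverman_bandwidth(v)
    else:
        h = float(bandwidth)
        if h <= 0:
            raise StatsError("bandwidth must be positive")
    z = (g[:, None] - v[None, :]) / h
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (v.size * h * np.sqrt(2 * np.pi))
    return dens


def load_gene_set(path) -> set[str]:
    """Read a gene set from a one-id-per-line text file ('#' comments)."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.add(line)
    return out
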