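"""Two-sample Wilcoxon rank-sum testing, scalar and vectorized over voxel maps.

The voxel-wise atlas comparison needs p-values far into the tail (Bonferroni
thresholds of order alpha / n_voxels), where the normal approximation to the
rank-sum null is unreliable.  Whenever a voxel's combined sample has no ties,
the exact null distribution of the Mann-Whitney U statistic is used (computed
once per group-size pair by the standard counting recursion); voxels with
ties fall back to the normal approximation with tie and continuity
corrections.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import stats as sps


@lru_cache(maxsize=32)
def exact_u_pmf(n_a: int, n_b: int) -> np.ndarray:
    """Exact null pmf of the Mann-Whitney U statistic for group sizes (n_a, n_b).

    Counting recursion over the combined ranking: processing items in rank
    order, an A-item placed as the i-th item with m-th A-membership adds
    (i - m) to U (the number of B-items ranked below it).
    """
    max_u = n_a * n_b
    f = np.zeros((n_a + 1, max_u + 1), dtype=float)
    f[0, 0] = 1.0
    for i in range(1, n_a + n_b + 1):
        new = f.copy()
        for m in range(min(i, n_a), 0, -1):
            shift = i - m
            if shift <= max_u:
                new[m, shift:] += f[m - 1, : max_u + 1 - shift]
        f = new
    pmf = f[n_a]
    pmf /= pmf.sum()
    return pmf


@lru_cache(maxsize=32)
def _exact_two_sided_table(n_a: int, n_b: int) -> np.ndarray:
    """Two-sided exact p for every U value: min(1, 2 * min(P(U<=u), P(U>=u)))."""
    pmf = exact_u_pmf(n_a, n_b)
    cdf = np.cumsum(pmf)
    sf = np.cumsum(pmf[::-1])[::-1]
    return np.minimum(1.0, 2.0 * np.minimum(cdf, sf))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Mann-Whitney U for group A, vectorized over trailing axes; midranks for ties."""
    comb = np.concatenate([a, b], axis=0)
    ranks = sps.rankdata(comb, axis=0)
    n_a = a.shape[0]
    r_a = ranks[:n_a].sum(axis=0)
    return r_a - n_a * (n_a + 1) / 2.0


def _tie_term(comb_sorted: np.ndarray) -> np.ndarray:
    """Sum of t^3 - t over tie groups, vectorized along trailing axes."""
    n = comb_sorted.shape[0]
    same = comb_sorted[1:] == comb_sorted[:-1]  # (n-1, ...)
    out = np.zeros(comb_sorted.shape[1:], dtype=float)
    run = np.ones(comb_sorted.shape[1:], dtype=float)
    for i in range(1, n + 1):
        cont = same[i - 1] if i < n else np.zeros(comb_sorted.shape[1:], dtype=bool)
        out += np.where(cont, 0.0, run**3 - run)  # a run of length `run` just ended
        run = np.where(cont, run + 1, 1.0)
    return out


def rank_sum_p_map(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum p-values, vectorized over all trailing axes.

    Exact null distribution where the combined sample is tie-free; otherwise
    normal approximation with tie and continuity corrections.  Returned
    p-values lie in (0, 1].
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = a.shape[0], b.shape[0]
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 samples")
    u = _u_statistic(a, b)
    comb = np.sort(np.concatenate([a, b], axis=0), axis=0)
    has_tie = (comb[1:] == comb[:-1]).any(axis=0)

    n = n_a + n_b
    mu = n_a * n_b / 2.0
    tie = _tie_term(comb)
    var = n_a * n_b / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    var = np.maximum(var, 1e-12)
    z = np.maximum((np.abs(u - mu) - 0.5) / np.sqrt(var), 0.0)
    p_norm = np.minimum(1.0, 2.0 * sps.norm.sf(z))

    table = _exact_two_sided_table(n_a, n_b)
    u_idx = np.clip(np.rint(u).astype(int), 0, n_a * n_b)
    p = np.where(has_tie, p_norm, table[u_idx])
    return np.maximum(p, np.finfo(float).tiny)


def rank_sum_test(a, b) -> float:
    """Scalar two-sided Wilcoxon rank-sum p-value (exact where tie-free)."""
    return float(rank_sum_p_map(np.asarray(a, float)[:, None], np.asarray(b, float)[:, None])[0])
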