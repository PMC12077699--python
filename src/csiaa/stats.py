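"""Group-comparison statistics: ANOSIM, rank tests, Spearman correlation.

ANOSIM is implemented in-house because its permutation scheme, mid-rank tie
handling and seeded reproducibility are part of this package's contract:

    R = (mean between-group rank − mean within-group rank) / (n(n−1)/4),

with the n(n−1)/2 pairwise Euclidean distances ranked with mid-ranks, and a
Monte-Carlo p-value p = (1 + #{R* ≥ R}) / (1 + B) so p = 0 is impossible.
Negative R values are reported as-is.

The classical univariate tests (Mann-Whitney, Wilcoxon signed-rank,
Spearman) delegate to scipy behind a thin policy layer: exact null
distributions at small sample sizes without ties, tie-corrected normal
approximations otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.spatial.distance import pdist
from scipy.stats import rankdata

from .exceptions import DomainError, UndefinedResultError


def subseed(seed: int, counter: int) -> np.random.Generator:
    """Derive an independent generator from a top-level seed and a counter.

    Adding a new seeded test to a battery never perturbs the streams of the
    existing ones.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(counter,)))


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnosimResult:
    r_statistic: float
    p_value: float
    n_permutations: int
    group_sizes: tuple[int, ...]


def _anosim_r_batch(rank_matrix_pairs: np.ndarray, same_group: np.ndarray,
                    denom: float) -> np.ndarray:
    """R for a batch of labelings.

    ``same_group`` is (B × M) boolean: pair (i, j) has equal labels.
    """
    ranks = rank_matrix_pairs  # (M,)
    n_within = same_group.sum(axis=1)
    n_between = same_group.shape[1] - n_within
    sum_within = same_group @ ranks
    sum_between = ranks.sum() - sum_within
    mean_within = sum_within / n_within
    mean_between = sum_between / n_between
    return (mean_between - mean_within) / denom


def anosim(points, labels, n_permutations: int = 9999,
           seed: int | None = None) -> AnosimResult:
    """Analysis of similarities on Euclidean distances.

    Parameters
    ----------
    points
        (n × d) coordinate matrix.
    labels
        Group label per row; every group needs ≥ 2 members and n ≥ 4.
    n_permutations
        Random label permutations for the Monte-Carlo p-value.
    seed
        Seed for the permutation stream (reproducible when given).
    """
    x = np.atleast_2d(np.asarray(points, float))
    labels = np.asarray(labels)
    n = x.shape[0]
    if labels.shape[0] != n:
        raise DomainError("labels length must match the number of points")
    if n < 4:
        raise DomainError("ANOSIM needs at least 4 points")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise DomainError("ANOSIM needs at least 2 groups")
    if np.any(counts < 2):
        raise DomainError("every group needs at least 2 members")

    ranks = rankdata(pdist(x, metric="euclidean"), method="average")
    denom = n * (n - 1) / 4.0  # normalizes R into [-1, 1]
    iu, ju = np.triu_indices(n, k=1)

    codes = np.searchsorted(uniq, labels)
    observed = float(_anosim_r_batch(ranks, (codes[iu] == codes[ju])[None, :], denom)[0])

    rng = np.random.default_rng(seed)
    if n_permutations > 0:
        perms = rng.permuted(np.tile(codes, (n_permutations, 1)), axis=1)
        r_perm = _anosim_r_batch(ranks, perms[:, iu] == perms[:, ju], denom)
        exceed = int(np.sum(r_perm >= observed))
    else:
        exceed = 0
    p = (1.0 + exceed) / (1.0 + n_permutations)
    return AnosimResult(
        r_statistic=observed, p_value=float(p),
        n_permutations=n_permutations, group_sizes=tuple(int(c) for c in counts),
    )


def anosim_r(points, labels) -> float:
    """The ANOSIM R statistic alone (no permutation test)."""
    return anosim(points, labels, n_permutations=0, seed=0).r_statistic


# ---------------------------------------------------------------------------
# univariate rank tests
# ---------------------------------------------------------------------------

def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when the combined sample is ≤ 20 without ties,
    tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise DomainError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    method = "exact" if (combined.size <= 20 and not _has_ties(combined)) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(paired_diffs) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped.  Exact null for n ≤ 15 without tied
    magnitudes, tie-corrected normal approximation otherwise.
    """
    d = np.asarray(paired_diffs, float)
    d = d[d != 0]
    if d.size == 0:
        raise UndefinedResultError("all paired differences are zero")
    method = "exact" if (d.size <= 15 and not _has_ties(np.abs(d))) else "approx"
    res = sps.wilcoxon(d, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (Pearson on mid-ranks, t-approximation p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise DomainError("spearman needs equal-length samples of size ≥ 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedResultError("spearman undefined for a constant input vector")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
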