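"""Shared statistical kernels.

This module collects the statistics every other stage leans on:

* the weighted Kolmogorov--Smirnov running-sum enrichment score (the GSEA
  statistic) together with its gene-set permutation null,
* the Benjamini--Hochberg step-up FDR adjustment, and
* the hypergeometric PMF / upper tail used for over-representation of
  immune-cell marker genes.

Everything here is pure: no files, no hidden state.  All stochastic entry
points take an explicit seed.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "NoOverlapError",
    "enrichment_score",
    "running_sum",
    "null_enrichment_scores",
    "permutation_p",
    "bh_adjust",
    "hypergeom_pmf",
    "hypergeom_tail",
]


class NoOverlapError(ValueError):
    """Raised when a gene set shares no member with the ranked list."""


# ---------------------------------------------------------------------------
# Running-sum enrichment score
# ---------------------------------------------------------------------------

def _hit_positions(ranked_ids: Sequence[str], gene_set: Iterable[str]) -> np.ndarray:
    members = set(gene_set)
    pos = np.fromiter(
        (i for i, g in enumerate(ranked_ids) if g in members), dtype=np.int64
    )
    n = len(ranked_ids)
    if pos.size == 0:
        raise NoOverlapError("gene set has no member in the ranked list")
    if pos.size == n:
        raise ValueError(
            "every ranked item is a set member; the miss decrement is undefined"
        )
    return pos


def _es_from_positions(
    pos: np.ndarray, weights: np.ndarray, exponent: float
) -> np.ndarray:
    """Signed maximal running-sum deviation for one or many hit-position rows.

    ``pos`` has shape (m,) or (n_draws, m) and must be sorted along the last
    axis.  The walk only changes direction at hits, so the extrema are attained
    either immediately after a hit or immediately before one; evaluating the
    running sum at those 2m candidate points reproduces the full N-step walk.
    """
    pos = np.atleast_2d(pos)
    n = weights.shape[0]
    m = pos.shape[1]
    hw = np.abs(weights[pos]) ** exponent
    denom = hw.sum(axis=1, keepdims=True)
    # A set whose weights are all zero (possible at exponent>0 when every
    # member sits at score 0) degenerates to the unweighted statistic.
    flat = denom[:, 0] == 0
    if np.any(flat):
        hw[flat] = 1.0
        denom[flat] = float(m)
    cum_hit = np.cumsum(hw, axis=1) / denom
    ranks = np.arange(1, m + 1)
    miss_after = (pos + 1 - ranks) / (n - m)   # misses up to and incl. each hit
    miss_before = (pos - (ranks - 1)) / (n - m)
    s_after = cum_hit - miss_after             # value just after each hit
    s_before = (cum_hit - hw / denom) - miss_before  # value just before each hit
    top = s_after.max(axis=1)
    bottom = np.minimum(s_before.min(axis=1), 0.0)
    es = np.where(top >= -bottom, top, bottom)
    return es


def _hit_curve(
    pos: np.ndarray, weights: np.ndarray, exponent: float
) -> tuple[np.ndarray, np.ndarray]:
    """Running-sum values just after and just before each hit (one row)."""
    n = weights.shape[0]
    m = pos.shape[0]
    hw = np.abs(weights[pos]) ** exponent
    denom = hw.sum()
    if denom == 0:
        hw = np.ones(m)
        denom = float(m)
    cum_hit = np.cumsum(hw) / denom
    ranks = np.arange(1, m + 1)
    s_after = cum_hit - (pos + 1 - ranks) / (n - m)
    s_before = (cum_hit - hw / denom) - (pos - (ranks - 1)) / (n - m)
    return s_after, s_before


def enrichment_score(
    ranked_ids: Sequence[str],
    weights: Sequence[float],
    gene_set: Iterable[str],
    weight_exponent: float = 1.0,
) -> float:
    """Classic running-sum enrichment score of ``gene_set`` in a ranked list.

    Walking the list in order, hits increment the sum by
    ``|w|**weight_exponent`` normalised by the sum over hits (uniform ``1/m``
    at exponent 0) and misses decrement by ``1/(N - m)``.  The score is the
    signed maximum deviation from zero, in ``[-1, 1]``.

    Parameters
    ----------
    ranked_ids
        Item identifiers in analysis order (the caller decides ascending or
        descending; this function is direction-agnostic).
    weights
        Ranking statistic aligned with ``ranked_ids``.
    gene_set
        Members to test; items absent from the list are ignored.
    weight_exponent
        Exponent applied to ``|weight|`` at hit positions; must be >= 0.

    Raises
    ------
    NoOverlapError
        If no member of ``gene_set`` occurs in the ranked list (distinct from
        a legitimate score of 0).
    ValueError
        If every ranked item belongs to the set.
    """
    if weight_exponent < 0:
        raise ValueError("weight_exponent must be >= 0")
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != len(ranked_ids):
        raise ValueError("weights and ranked_ids must have equal length")
    pos = _hit_positions(ranked_ids, gene_set)
    return float(_es_from_positions(pos, w, weight_exponent)[0])


def running_sum(
    ranked_ids: Sequence[str],
    weights: Sequence[float],
    gene_set: Iterable[str],
    weight_exponent: float = 1.0,
) -> np.ndarray:
    """Full N-step running sum (position i -> value after item i).

    Provided for inspection and plotting; ``enrichment_score`` is its signed
    maximal deviation.
    """
    w = np.asarray(weights, dtype=float)
    members = set(gene_set)
    hit = np.fromiter((g in members for g in ranked_ids), dtype=bool)
    m = int(hit.sum())
    n = hit.size
    if m == 0:
        raise NoOverlapError("gene set has no member in the ranked list")
    if m == n:
        raise ValueError("every ranked item is a set member")
    hw = np.abs(w) ** weight_exponent * hit
    if hw.sum() == 0:
        hw = hit.astype(float)
    steps = np.where(hit, hw / hw.sum(), -1.0 / (n - m))
    return np.cumsum(steps)


def null_enrichment_scores(
    n_items: int,
    set_size: int,
    weights: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    weight_exponent: float = 1.0,
) -> np.ndarray:
    """ES of ``n_perm`` uniformly drawn size-``set_size`` sets.

    The null preserves the observed weight profile of the ranked list and
    randomises only which positions are hits, which is the gene-set
    permutation null of the running-sum statistic.
    """
    if not (0 < set_size < n_items):
        raise ValueError("set_size must be in (0, n_items)")
    draws = np.argpartition(
        rng.random((n_perm, n_items)), set_size - 1, axis=1
    )[:, :set_size]
    draws.sort(axis=1)
    return _es_from_positions(draws, np.asarray(weights, dtype=float), weight_exponent)


def permutation_p(
    ranked_ids: Sequence[str],
    weights: Sequence[float],
    gene_set: Iterable[str],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    weight_exponent: float = 1.0,
) -> float:
    """Two-sided gene-set permutation p-value for the enrichment score.

    Uses the add-one estimator ``(1 + #{|ES_null| >= |ES_obs|}) / (n_perm + 1)``
    so that p can never be exactly zero.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    w = np.asarray(weights, dtype=float)
    pos = _hit_positions(ranked_ids, gene_set)
    obs = _es_from_positions(pos, w, weight_exponent)[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null = null_enrichment_scores(len(ranked_ids), pos.size, w, n_perm, rng, weight_exponent)
    return float((1 + np.sum(np.abs(null) >= abs(obs))) / (n_perm + 1))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini--Hochberg step-up adjusted p-values (q-values).

    The output is monotone consistent with the input ordering of p-values,
    satisfies ``q >= p`` elementwise and is capped at 1.  Thresholding
    ``q <= alpha`` reproduces the BH rejection set.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Hypergeometric
# ---------------------------------------------------------------------------

def _log_comb(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _check_hypergeom(N: int, M: int, n: int) -> None:
    if N < 0 or not (0 <= M <= N) or not (0 <= n <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N}, M={M}, n={n}")


def hypergeom_pmf(N: int, M: int, n: int, k: int) -> float:
    """P(X = k) when drawing ``n`` items from ``N`` of which ``M`` are marked.

    ``C(M, k) * C(N-M, n-k) / C(N, n)``, evaluated in log space.  Out-of-support
    ``k`` returns 0 rather than raising.
    """
    _check_hypergeom(N, M, n)
    if k < max(0, n + M - N) or k > min(n, M):
        return 0.0
    log_p = _log_comb(M, k) + _log_comb(N - M, n - k) - _log_comb(N, n)
    return float(np.exp(log_p))


def hypergeom_tail(N: int, M: int, n: int, k: int) -> float:
    """Upper tail P(X >= k) of the hypergeometric distribution.

    The enrichment significance of observing at least ``k`` marked items in a
    size-``n`` draw, i.e. the usual over-representation p-value.
    """
    _check_hypergeom(N, M, n)
    hi = min(n, M)
    if k > hi:
        return 0.0
    lo = max(k, max(0, n + M - N))
    js = np.arange(lo, hi + 1)
    log_terms = _log_comb(M, js) + _log_comb(N - M, n - js) - _log_comb(N, n)
    # log-sum-exp for a numerically stable tail sum
    top = log_terms.max()
    return float(min(1.0, np.exp(top) * np.exp(log_terms - top).sum()))
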