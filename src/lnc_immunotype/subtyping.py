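"""Consensus clustering of tumor samples on the dysregulated-lncRNA panel.

Subsample the samples many times, cluster each subsample, and record for
every sample pair how often it lands in the same cluster among the runs where
both were drawn.  The consensus matrix's CDF and its area as a function of k
(the Monti criterion) pick the cluster number; the final subtype labels come
from hierarchically clustering the consensus-derived distances.  Clusters are
named ``C1, C2, ...`` in decreasing order of mean panel expression so C1 is
always the immune-high subtype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io_formats import ExpressionMatrix, PipelineConfig

__all__ = ["ConsensusResult", "consensus_cluster", "choose_k", "assign_subtype_names"]


@dataclass
class ConsensusResult:
    k_range: list[int]
    consensus: dict[int, pd.DataFrame]     # k -> samples x samples in [0, 1]
    cdf_area: dict[int, float]             # k -> area under consensus CDF
    delta_area: dict[int, float]           # k -> relative area increase
    pac: dict[int, float]                  # k -> proportion ambiguous pairs
    chosen_k: int
    labels: pd.Series                      # sample -> C1/C2/...
    metadata: dict = field(default_factory=dict)


def _cluster_subsample(x: np.ndarray, k: int, method: str,
                       rng: np.random.Generator) -> np.ndarray:
    """Cluster columns of ``x`` (features x samples) into k groups."""
    if method == "hierarchical":
        d = _correlation_distance(x)
        z = linkage(squareform(d, checks=False), method="average")
        return fcluster(z, t=k, criterion="maxclust")
    if method == "kmeans":
        from sklearn.cluster import KMeans
        km = KMeans(n_clusters=k, n_init=5,
                    random_state=int(rng.integers(2**31 - 1)))
        return km.fit_predict(x.T) + 1
    raise ValueError(f"unknown consensus_method {method!r}")


def _correlation_distance(x: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between columns (samples) of ``x``."""
    xc = x - x.mean(axis=0, keepdims=True)
    sd = xc.std(axis=0)
    sd[sd == 0] = 1.0
    z = xc / sd
    r = z.T @ z / x.shape[0]
    np.clip(r, -1.0, 1.0, out=r)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return d


def _cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of the upper-triangular consensus values."""
    vals = np.sort(consensus[np.triu_indices_from(consensus, k=1)])
    if vals.size == 0:
        return 0.0
    # A = sum over consecutive sorted values of (x_{i+1} - x_i) * CDF(x_i)
    cdf = np.arange(1, vals.size + 1) / vals.size
    return float(np.sum(np.diff(vals) * cdf[:-1]) + (1.0 - vals[-1]))


def _pac(consensus: np.ndarray, lo: float = 0.1, hi: float = 0.9) -> float:
    """Proportion of ambiguous clustering: pairs with consensus in (lo, hi)."""
    vals = consensus[np.triu_indices_from(consensus, k=1)]
    if vals.size == 0:
        return 0.0
    return float(((vals > lo) & (vals < hi)).mean())


def consensus_cluster(
    expr: ExpressionMatrix, config: PipelineConfig, seed: int | None = None
) -> ConsensusResult:
    """Consensus clustering over ``config.k_range``.

    ``expr`` must be the log-transformed expression of the dysregulated
    lncRNA panel (>= 2 rows) over >= 10 tumor samples.  For each k,
    ``config.n_resamples`` subsamples of ``ceil(resample_fraction * n)``
    samples (drawn without replacement) are clustered -- hierarchical
    average-linkage on 1 - Pearson sample correlation by default -- and the
    consensus matrix accumulates co-clustering frequencies over the runs
    where both samples were drawn.  Pairs never co-sampled get consensus 0.
    Fully deterministic for a fixed seed.
    """
    if not expr.log_transformed:
        raise ValueError("consensus clustering expects log-transformed input")
    x = expr.values.to_numpy(dtype=float)
    samples = expr.sample_ids
    n = len(samples)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 panel lncRNAs")
    if n < 10:
        raise ValueError("need at least 10 samples")
    if config.k_max >= n:
        raise ValueError("k_range maximum must be below the sample count")
    if seed is None:
        seed = config.rng_seed
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    m = int(np.ceil(config.resample_fraction * n))

    consensus: dict[int, pd.DataFrame] = {}
    cdf_area: dict[int, float] = {}
    pac: dict[int, float] = {}
    for k in config.k_range:
        together = np.zeros((n, n))
        sampled = np.zeros((n, n))
        for _ in range(config.n_resamples):
            idx = rng.choice(n, size=m, replace=False)
            idx.sort()
            labels = _cluster_subsample(x[:, idx], k, config.consensus_method, rng)
            co = (labels[:, None] == labels[None, :]).astype(float)
            together[np.ix_(idx, idx)] += co
            sampled[np.ix_(idx, idx)] += 1.0
        with np.errstate(invalid="ignore"):
            cons = np.where(sampled > 0, together / np.maximum(sampled, 1), 0.0)
        np.fill_diagonal(cons, 1.0)
        consensus[k] = pd.DataFrame(cons, index=samples, columns=samples)
        cdf_area[k] = _cdf_area(cons)
        pac[k] = _pac(cons)

    ks = list(config.k_range)
    delta_area: dict[int, float] = {}
    for i, k in enumerate(ks):
        if i == 0:
            delta_area[k] = cdf_area[k]
        else:
            prev = cdf_area[ks[i - 1]]
            delta_area[k] = (cdf_area[k] - prev) / prev if prev > 0 else 0.0

    result = ConsensusResult(
        k_range=ks, consensus=consensus, cdf_area=cdf_area,
        delta_area=delta_area, pac=pac, chosen_k=ks[0],
        labels=pd.Series(dtype=object),
        metadata={
            "n_resamples": config.n_resamples,
            "resample_fraction": config.resample_fraction,
            "method": config.consensus_method,
            "k_selection": "min PAC (config override available)",
            "seed": seed,
        },
    )
    result.chosen_k = choose_k(result, config)
    final = consensus[result.chosen_k].to_numpy()
    d = 1.0 - final
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    z = linkage(squareform(d, checks=False), method="average")
    raw = fcluster(z, t=result.chosen_k, criterion="maxclust")
    raw_labels = pd.Series(raw, index=samples)
    result.labels = assign_subtype_names(raw_labels, expr)
    return result


def choose_k(result: ConsensusResult, config: PipelineConfig | None = None) -> int:
    """Cluster number minimizing the proportion of ambiguous clustering (PAC).

    PAC(k) is the fraction of sample pairs whose consensus lies strictly
    between 0.1 and 0.9 -- pairs the resampling could not firmly place
    together or apart.  The smallest k wins ties.  The consensus CDF areas
    and delta-areas are retained on the result for inspection, and
    ``config.consensus_k`` overrides the automatic choice.
    """
    if config is not None and config.consensus_k is not None:
        if config.consensus_k not in result.k_range:
            raise ValueError("consensus_k override outside k_range")
        return config.consensus_k
    if len(result.k_range) < 2:
        return result.k_range[0]
    return min(result.pac, key=lambda k: (result.pac[k], k))


def assign_subtype_names(labels: pd.Series, expr: ExpressionMatrix) -> pd.Series:
    """Rename clusters ``C1, C2, ...`` by decreasing mean panel expression.

    C1 is therefore always the immune-high subtype, whatever arbitrary ids
    the clustering produced.  Ties in mean expression break by decreasing
    cluster size, then by the lexicographically smallest member sample id.
    """
    if set(labels.index) != set(expr.sample_ids):
        raise ValueError("labels must cover exactly the expression samples")
    means = expr.values.mean(axis=0)
    order = []
    for cl in labels.unique():
        members = labels.index[labels == cl]
        order.append((
            -round(float(means[members].mean()), 12),
            -len(members),
            min(members),
            cl,
        ))
    order.sort()
    mapping = {cl: f"C{i + 1}" for i, (_, _, _, cl) in enumerate(order)}
    return labels.map(mapping).rename("subtype")
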