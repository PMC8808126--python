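"""Subtype characterization: differential expression, over-representation,
subtype-level GSEA, marker and single-sample immune scores, and concordance
with external subtype labels.

Differential expression uses an empirical-Bayes moderated t: per-gene pooled
variances are shrunk toward a common prior whose degrees of freedom and scale
are fitted by the method of moments on log variances, stabilising the
denominator for small groups.  The remaining operations reuse the shared
enrichment kernels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .enrichment import (
    _es_from_positions,
    _hit_curve,
    bh_adjust,
    hypergeom_tail,
)
from .io_formats import ExpressionMatrix, GeneSetCollection, PipelineConfig

logger = logging.getLogger(__name__)

__all__ = [
    "differential_expression",
    "moderate_variances",
    "count_significant_features",
    "ora",
    "subtype_gsea",
    "marker_score",
    "ssgsea_scores",
    "ConcordanceTable",
    "concordance",
]


# ---------------------------------------------------------------------------
# Moderated-t differential expression
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the log scale)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def moderate_variances(
    s2: np.ndarray, df: float, prior_df: float | None = None
) -> tuple[float, float, np.ndarray]:
    """Empirical-Bayes shrinkage of per-gene variances.

    Fits an inverse-chi-square prior (``prior_df`` d0, scale s0^2) to the
    observed variances by matching the first two moments of ``log(s^2)``,
    then returns the posterior variances
    ``(d0 * s0^2 + df * s^2) / (d0 + df)``.

    ``prior_df`` overrides the fit: 0 recovers the ordinary per-gene
    variances, ``inf`` collapses every gene onto the common scale.
    Returns ``(d0, s0_squared, moderated_variances)``.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2 > 0
    if not positive.any():
        raise ValueError("all gene variances are zero")
    z = np.log(s2[positive])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    if prior_df is None:
        e_var = float(np.var(e, ddof=1)) if e.size > 1 else 0.0
        target = e_var - polygamma(1, df / 2.0)
        d0 = 2.0 * _trigamma_inverse(target) if target > 0 else np.inf
    else:
        d0 = float(prior_df)
    if np.isinf(d0):
        s0_sq = float(np.exp(e_mean))
    elif d0 == 0:
        s0_sq = float(np.exp(e_mean))  # unused: no shrinkage
    else:
        s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    if np.isinf(d0):
        post = np.full_like(s2, s0_sq)
    elif d0 == 0:
        post = s2.copy()
    else:
        post = (d0 * s0_sq + df * s2) / (d0 + df)
    return d0, s0_sq, post


def _two_group_masks(labels: pd.Series, sample_ids: list[str]) -> tuple:
    aligned = labels.loc[sample_ids]
    groups = sorted(aligned.unique())
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    m1 = (aligned == groups[0]).to_numpy()
    m2 = (aligned == groups[1]).to_numpy()
    return groups, m1, m2


def _moderated_t(
    x: np.ndarray, m1: np.ndarray, m2: np.ndarray, prior_df: float | None
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, np.ndarray]:
    """Moderated t of group2 - group1 for each row of ``x``.

    Returns (t, p, total_df, mean1, mean2).
    """
    n1, n2 = int(m1.sum()), int(m2.sum())
    x1, x2 = x[:, m1], x[:, m2]
    mean1, mean2 = x1.mean(axis=1), x2.mean(axis=1)
    df = n1 + n2 - 2
    ss = ((x1 - mean1[:, None]) ** 2).sum(axis=1) + ((x2 - mean2[:, None]) ** 2).sum(axis=1)
    s2 = ss / df
    d0, _, s2_post = moderate_variances(s2, df, prior_df)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    diff = mean2 - mean1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
    total_df = df + (0.0 if np.isinf(d0) else d0)
    if np.isinf(d0) or np.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=total_df)
    # degenerate rows: no variance anywhere and no mean difference
    degenerate = (se == 0) & (diff == 0)
    p = np.where(degenerate, 1.0, p)
    return t, p, total_df, mean1, mean2


def differential_expression(
    expr: ExpressionMatrix,
    labels: pd.Series,
    config: PipelineConfig,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Two-group moderated-t differential expression on log2 expression.

    ``labels`` maps sample id to exactly two groups (at least 3 samples
    each); fold change is oriented C2 minus C1 (second group minus first in
    sorted order).  A gene is significant when ``FDR < deg_fdr_max`` and its
    linear fold change ``2**|log2FC|`` strictly exceeds ``fc_min``.

    Returns one row per gene with means, log2FC, FC, moderated t, p, FDR and
    a status in ``{up_in_C2, down_in_C2, not_significant}``.
    """
    if not expr.log_transformed:
        raise ValueError("differential expression expects log2 input")
    groups, m1, m2 = _two_group_masks(labels, expr.sample_ids)
    if m1.sum() < 3 or m2.sum() < 3:
        raise ValueError("each group needs at least 3 samples")
    x = expr.values.to_numpy(dtype=float)
    t, p, total_df, mean1, mean2 = _moderated_t(x, m1, m2, prior_df)
    log2fc = mean2 - mean1
    fc = np.exp2(np.abs(log2fc))
    fdr = bh_adjust(p)
    significant = (fdr < config.deg_fdr_max) & (fc > config.fc_min)
    status = np.where(
        significant, np.where(log2fc > 0, "up_in_C2", "down_in_C2"),
        "not_significant",
    )
    return pd.DataFrame({
        "gene": expr.gene_ids,
        f"mean_{groups[0]}": mean1,
        f"mean_{groups[1]}": mean2,
        "log2fc": log2fc,
        "fc": fc,
        "t": t,
        "p": p,
        "fdr": fdr,
        "status": status,
    })


def count_significant_features(
    p_values, alpha: float = 0.05
) -> tuple[int, int, float]:
    """(count, total, percentage) of features with ``p < alpha`` (strict).

    The percentage is rounded to 2 decimals, e.g. 11 of 17 -> 64.71.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one feature")
    count = int((p < alpha).sum())
    return count, p.size, round(100.0 * count / p.size, 2)


# ---------------------------------------------------------------------------
# Over-representation analysis
# ---------------------------------------------------------------------------

def ora(
    query,
    universe,
    gene_sets: GeneSetCollection,
    fdr_max: float = 0.05,
    keep_all: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in a query list.

    All sets are intersected with the universe before testing; BH adjusts
    across sets.  By default only sets with ``FDR < fdr_max`` are returned;
    ``keep_all`` returns the full table with an ``enriched`` flag.
    """
    query = set(query)
    universe = set(universe)
    if not query:
        logger.warning("empty ORA query")
        return pd.DataFrame(columns=["set", "N", "M", "n", "k", "p", "fdr", "enriched"])
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for gs in gene_sets:
        in_universe = gs.genes & universe
        if not in_universe:
            continue
        k = len(query & in_universe)
        rows.append({
            "set": gs.name, "N": N, "M": len(in_universe), "n": n, "k": k,
            "p": hypergeom_tail(N, len(in_universe), n, k),
        })
    table = pd.DataFrame(rows)
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    table["enriched"] = table["fdr"] < fdr_max
    table = table.sort_values("p", kind="mergesort").reset_index(drop=True)
    return table if keep_all else table[table["enriched"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Subtype GSEA
# ---------------------------------------------------------------------------

def _ranked_positions(stat: np.ndarray, gene_ids: np.ndarray,
                      members: set) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Descending ordering by ``stat`` (ties by gene id) and member positions."""
    order = np.lexsort((gene_ids, -stat))
    ranked = gene_ids[order]
    weights = stat[order]
    hit = np.fromiter((g in members for g in ranked), dtype=bool)
    return weights, hit.nonzero()[0], ranked


def subtype_gsea(
    expr: ExpressionMatrix,
    labels: pd.Series,
    pathways: GeneSetCollection,
    config: PipelineConfig,
    seed: int | None = None,
    n_perm: int | None = None,
    keep_all: bool = False,
) -> pd.DataFrame:
    """Gene-set enrichment between two subtypes with a phenotype-label null.

    Genes are ranked descending by the moderated t oriented so that genes
    higher in C1 (the immune-high subtype, first group in sorted label
    order) get positive statistics; a positive ES therefore means enrichment
    toward C1.  Significance comes from label permutations (the t statistics
    and ranking are recomputed for every permutation) with the add-one
    estimator, BH-adjusted across pathways.  Pathways pass the screen when
    ``|ES| > gsea_es_min``, ``p < gsea_p_max`` and ``FDR < gsea_fdr_max``
    (all strict).
    """
    if not expr.log_transformed:
        raise ValueError("subtype GSEA expects log2 input")
    groups, m1, m2 = _two_group_masks(labels, expr.sample_ids)
    x = expr.values.to_numpy(dtype=float)
    gene_ids = np.asarray(expr.gene_ids)
    if seed is None:
        seed = config.rng_seed * 10 + 3
    if n_perm is None:
        n_perm = config.n_permutations
    exponent = config.weight_exponent

    def _stat(mask1: np.ndarray, mask2: np.ndarray) -> np.ndarray:
        t, _, _, _, _ = _moderated_t(x, mask1, mask2, prior_df=None)
        return -t  # orient positive toward the first (immune-high) group

    obs_stat = _stat(m1, m2)
    member_sets = {gs.name: set(gs.genes) & set(gene_ids) for gs in pathways}
    member_sets = {k: v for k, v in member_sets.items() if v}

    obs: dict[str, tuple[float, int]] = {}
    leading: dict[str, list[str]] = {}
    for name, members in member_sets.items():
        weights, pos, ranked = _ranked_positions(obs_stat, gene_ids, members)
        if pos.size == gene_ids.size:
            continue
        es = float(_es_from_positions(pos, weights, exponent)[0])
        obs[name] = (es, pos.size)
        s_after, s_before = _hit_curve(pos, weights, exponent)
        if es >= 0:
            # leading edge: members at or before the running-sum maximum
            peak = pos[int(np.argmax(s_after))]
            leading[name] = [g for g in ranked[: peak + 1] if g in members]
        else:
            trough = int(np.argmin(s_before))
            leading[name] = [g for g in ranked[pos[trough]:] if g in members]

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    exceed = {name: 0 for name in obs}
    n_samples = x.shape[1]
    both = m1 | m2
    idx_all = np.flatnonzero(both)
    n1 = int(m1.sum())
    for _ in range(n_perm):
        perm = rng.permutation(idx_all)
        pm1 = np.zeros(n_samples, dtype=bool)
        pm1[perm[:n1]] = True
        pm2 = both & ~pm1
        stat = _stat(pm1, pm2)
        for name, members in member_sets.items():
            if name not in obs:
                continue
            weights, pos, _ = _ranked_positions(stat, gene_ids, members)
            es = _es_from_positions(pos, weights, exponent)[0]
            if abs(es) >= abs(obs[name][0]):
                exceed[name] += 1

    rows = [
        {
            "pathway": name,
            "es": obs[name][0],
            "n_hits": obs[name][1],
            "p": (1 + exceed[name]) / (n_perm + 1),
            "leading_edge": ",".join(leading[name]),
        }
        for name in obs
    ]
    table = pd.DataFrame(rows)
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    table["passed"] = (
        (table["es"].abs() > config.gsea_es_min)
        & (table["p"] < config.gsea_p_max)
        & (table["fdr"] < config.gsea_fdr_max)
    )
    table = table.sort_values("p", kind="mergesort").reset_index(drop=True)
    return table if keep_all else table[table["passed"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Immune scoring
# ---------------------------------------------------------------------------

def marker_score(expr: ExpressionMatrix, markers: GeneSetCollection) -> pd.DataFrame:
    """Mean log2 expression of each marker set per sample.

    Sets with no gene in the matrix are omitted with a warning.  Rows are
    samples, columns cell types.
    """
    if not expr.log_transformed:
        raise ValueError("marker scores expect log2 input")
    cols = {}
    for gs in markers:
        present = sorted(gs.genes & set(expr.gene_ids))
        if not present:
            logger.warning("marker set %s has no gene in the matrix", gs.name)
            continue
        cols[gs.name] = expr.values.loc[present].mean(axis=0)
    return pd.DataFrame(cols, index=expr.sample_ids)


def ssgsea_scores(
    expr: ExpressionMatrix,
    signatures: GeneSetCollection,
    weight_exponent: float = 0.25,
) -> pd.DataFrame:
    """Single-sample running-sum enrichment scores per signature.

    Within each sample genes are ranked descending by expression (ties broken
    by gene id) and weighted by their rank; the signature score is the signed
    maximal running-sum deviation.  When the collection contains an immune
    and a stromal signature (matched case-insensitively on the set name), an
    ``ESTIMATEScore`` column is added as their sum, mirroring the combined
    tumor-microenvironment score.
    """
    gene_ids = np.asarray(expr.gene_ids)
    n = gene_ids.size
    x = expr.values.to_numpy(dtype=float)
    rank_weights = np.arange(n, 0, -1, dtype=float)  # weight of rank position i
    scores: dict[str, list[float]] = {gs.name: [] for gs in signatures}
    member_sets = {gs.name: set(gs.genes) & set(gene_ids) for gs in signatures}
    for name, members in member_sets.items():
        if not members:
            raise ValueError(f"signature {name!r} has no gene in the matrix")
        if len(members) == n:
            raise ValueError(f"signature {name!r} covers the whole matrix")
    for j in range(x.shape[1]):
        order = np.lexsort((gene_ids, -x[:, j]))
        ranked = gene_ids[order]
        pos_of = {g: i for i, g in enumerate(ranked)}
        for name, members in member_sets.items():
            pos = np.array(sorted(pos_of[g] for g in members))
            es = _es_from_positions(pos, rank_weights, weight_exponent)[0]
            scores[name].append(float(es))
    out = pd.DataFrame(scores, index=expr.sample_ids)
    immune = [c for c in out.columns if "immune" in c.lower()]
    stromal = [c for c in out.columns if "stromal" in c.lower()]
    if len(immune) == 1 and len(stromal) == 1:
        out["ESTIMATEScore"] = out[immune[0]] + out[stromal[0]]
    return out


# ---------------------------------------------------------------------------
# Concordance with external subtype labels
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceTable:
    counts: pd.DataFrame        # internal subtype x external label counts
    row_pct: pd.DataFrame       # row-normalised percentages (2 decimals)
    combined_pct: dict | None   # internal subtype -> % in the requested pair


def concordance(
    internal: pd.Series,
    external: pd.Series,
    combine: tuple[str, str] | None = None,
) -> ConcordanceTable:
    """Cross-tabulate internal subtypes against external labels.

    Works on the overlapping samples (error when none).  External label
    categories absent from the overlap keep zero columns for auditability.
    ``combine`` asks, per internal subtype, for the combined percentage of
    two external labels (e.g. ``("Atypical", "Basal")``).
    """
    common = internal.index.intersection(external.index)
    if len(common) == 0:
        raise ValueError("no overlapping samples between label sets")
    internal = internal.loc[common]
    external_all_labels = sorted(external.unique())
    external = external.loc[common]
    counts = pd.crosstab(internal, external)
    counts = counts.reindex(columns=external_all_labels, fill_value=0)
    counts.index.name = "internal"
    counts.columns.name = "external"
    row_pct = (100.0 * counts.div(counts.sum(axis=1), axis=0)).round(2)
    combined = None
    if combine is not None:
        a, b = combine
        for lab in (a, b):
            if lab not in counts.columns:
                raise ValueError(f"external label {lab!r} unknown")
        combined = {
            st: round(
                100.0 * (counts.loc[st, a] + counts.loc[st, b])
                / counts.loc[st].sum(), 2,
            )
            for st in counts.index
        }
    return ConcordanceTable(counts=counts, row_pct=row_pct, combined_pct=combined)
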