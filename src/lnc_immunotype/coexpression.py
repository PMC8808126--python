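"""lncRNA--mRNA co-expression: log2 transform, Pearson correlation with
two-sided significance, the significance filter, and the correlation Score.

The Score combines a correlation's strength of evidence and its direction,
``Score = -log10(P) * sign(R)``; ranked ascending it drives the running-sum
enrichment of immune pathways in each lncRNA's mRNA neighbourhood.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "log2_transform",
    "pearson_correlate",
    "filter_significant",
    "correlation_score",
]

P_FLOOR = 1e-300


def log2_transform(m: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Return ``log2(TPM + offset)``; refuses to transform twice."""
    if m.log_transformed:
        raise ValueError("matrix is already log-transformed")
    if offset <= 0:
        raise ValueError("offset must be positive")
    return ExpressionMatrix(np.log2(m.values + offset), log_transformed=True)


def pearson_correlate(lnc: ExpressionMatrix, mrna: ExpressionMatrix) -> pd.DataFrame:
    """All-pairs Pearson correlation between lncRNA and mRNA profiles.

    Both matrices must be log-transformed and share an identical, identically
    ordered sample set with at least 3 samples.  The two-sided p-value comes
    from the exact t transform ``t = R * sqrt((n-2) / (1 - R^2))`` with
    ``n - 2`` degrees of freedom.  Zero-variance genes on either side are
    skipped and logged.

    Returns a long DataFrame with columns ``lnc_id, mrna_id, R, P, score``.
    """
    if not (lnc.log_transformed and mrna.log_transformed):
        raise ValueError("correlate expects log-transformed matrices")
    if lnc.sample_ids != mrna.sample_ids:
        raise ValueError("lncRNA and mRNA matrices must share sample order")
    n = len(lnc.sample_ids)
    if n < 3:
        raise ValueError("need at least 3 samples")

    def _standardise(m: ExpressionMatrix) -> tuple[np.ndarray, list[str]]:
        x = m.values.to_numpy(dtype=float)
        x = x - x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1)
        keep = sd > 0
        if not keep.all():
            skipped = [g for g, k in zip(m.gene_ids, keep) if not k]
            logger.info("skipping %d zero-variance genes", len(skipped))
        x = x[keep] / sd[keep, None]
        ids = [g for g, k in zip(m.gene_ids, keep) if k]
        return x, ids

    zl, lnc_ids = _standardise(lnc)
    zm, mrna_ids = _standardise(mrna)
    r = zl @ zm.T / n
    np.clip(r, -1.0, 1.0, out=r)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.clip(p, P_FLOOR, 1.0)
    out = pd.DataFrame(
        {
            "lnc_id": np.repeat(lnc_ids, len(mrna_ids)),
            "mrna_id": np.tile(mrna_ids, len(lnc_ids)),
            "R": r.ravel(),
            "P": p.ravel(),
        }
    )
    out["score"] = correlation_score(out["R"].to_numpy(), out["P"].to_numpy())
    return out


def filter_significant(
    records: pd.DataFrame, r_min: float = 0.5, p_max: float = 0.05
) -> pd.DataFrame:
    """Keep pairs with ``|R| > r_min`` and ``P < p_max`` (both strict)."""
    keep = (records["R"].abs() > r_min) & (records["P"] < p_max)
    return records[keep].reset_index(drop=True)


def correlation_score(R, P):
    """``-log10(P) * sign(R)``; scalar in, scalar out.

    P is floored at 1e-300 before the log so perfect correlations (numerical
    p of 0) still yield a finite score; ``sign(0) = 0``.
    """
    R_arr = np.asarray(R, dtype=float)
    P_arr = np.asarray(P, dtype=float)
    if np.any(P_arr > 1) or np.any(P_arr <= 0):
        raise ValueError("p-values must lie in (0, 1]")
    score = -np.log10(np.maximum(P_arr, P_FLOOR)) * np.sign(R_arr)
    if np.isscalar(R) and np.isscalar(P):
        return float(score)
    return score
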