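"""Kaplan--Meier estimation, log-rank comparison and the rank-sum test.

Thin, validated wrappers around lifelines / scipy that expose exactly the
quantities the subtype characterization needs: the product-limit curve with
at-risk and event counts, the median survival time, the multi-group log-rank
chi-square, and the two-sided Wilcoxon rank-sum p-value (exact for small
tie-free samples, normal approximation with tie correction otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .io_formats import ENDPOINTS, SurvivalTable

__all__ = ["KMCurve", "LogRankResult", "km_estimate", "logrank_test",
           "wilcoxon_rank_sum"]


@dataclass
class KMCurve:
    """Product-limit estimate at each distinct event time."""

    times: np.ndarray          # ascending distinct event times
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray        # subjects at risk entering each time
    events: np.ndarray         # deaths at each time
    median: float | None       # first time S <= 0.5, None if never reached

    def __post_init__(self) -> None:
        s = np.asarray(self.survival)
        if s.size and (np.any(np.diff(s) > 1e-12) or s.min() < -1e-12 or s.max() > 1 + 1e-12):
            raise ValueError("survival estimates must be non-increasing in [0, 1]")


def _endpoint_frame(surv: SurvivalTable, endpoint: str) -> pd.DataFrame:
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    return surv.endpoint(endpoint)


def km_estimate(
    surv: SurvivalTable, endpoint: str, group: "list[str] | None" = None
) -> KMCurve:
    """Kaplan--Meier curve for one endpoint, optionally restricted to a group.

    Ties are handled the standard way: deaths precede censorings at equal
    times.  The median is the first time the curve drops to 0.5 or below;
    ``None`` when the curve never reaches it (e.g. everything censored).
    """
    df = _endpoint_frame(surv, endpoint)
    if group is not None:
        df = df[df["sample_id"].isin(set(group))]
    if df.empty:
        raise ValueError("no subjects for the requested endpoint/group")
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], df["event"])
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    times = event_rows.index.to_numpy(dtype=float)
    survival = kmf.survival_function_.loc[times, "KM_estimate"].to_numpy()
    median = kmf.median_survival_time_
    return KMCurve(
        times=times,
        survival=survival,
        at_risk=event_rows["at_risk"].to_numpy(dtype=int),
        events=event_rows["observed"].to_numpy(dtype=int),
        median=None if np.isinf(median) else float(median),
    )


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p: float

    def __post_init__(self) -> None:
        if self.chi_square < -1e-9:
            raise ValueError("chi-square must be non-negative")
        expected = float(stats.chi2.sf(self.chi_square, self.df))
        if not np.isclose(expected, self.p, atol=1e-8):
            raise ValueError("p inconsistent with chi-square CDF")


def logrank_test(
    surv: SurvivalTable, endpoint: str, labels: pd.Series
) -> LogRankResult:
    """Multi-group log-rank test of survival differences between subtypes.

    ``labels`` maps sample id to group; every group must contribute at least
    one subject with survival data for the endpoint.
    """
    df = _endpoint_frame(surv, endpoint)
    df = df[df["sample_id"].isin(labels.index)]
    groups = labels.loc[df["sample_id"]].to_numpy()
    present = pd.unique(groups)
    missing = set(labels.unique()) - set(present)
    if missing or len(present) < 2:
        raise ValueError(
            f"each group needs >= 1 subject with data; missing: {sorted(missing)}"
        )
    res = multivariate_logrank_test(df["time"], groups, df["event"])
    return LogRankResult(
        chi_square=float(res.test_statistic),
        df=len(present) - 1,
        p=float(stats.chi2.sf(res.test_statistic, len(present) - 1)),
    )


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann--Whitney) p-value.

    Exact null distribution when the combined sample has at most 20
    observations and no ties; otherwise the normal approximation with tie
    correction (and continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= 20 and no_ties) else "asymptotic"
    with np.errstate(invalid="ignore"):
        p = stats.mannwhitneyu(
            x, y, alternative="two-sided", method=method, use_continuity=False
        ).pvalue
    # degenerate case: every observation tied -> zero variance -> no evidence
    return 1.0 if np.isnan(p) else float(p)
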