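"""Immune-lncRNA prioritization: lncRES tables, tumor-specific filtering,
overlap summaries, immune-cell enrichment and the dysregulated-set selection.

For every lncRNA the correlation Score orders all mRNAs ascending; the
running-sum enrichment of each immune pathway in that ordering is the lncRES
(signed, in [-1, 1]).  Pairs passing ``FDR < 0.05`` and ``|lncRES| > 0.995``
per cohort define immune-related lncRNAs; lncRNAs significant in tumor but
never in normal are tumor-specific.  Those are then tested for
over-representation of immune-cell marker genes among their significantly
correlated mRNAs (hypergeometric, overlaps below ``k=3`` discarded), and
lncRNAs enriched in enough cell types form the dysregulated set that drives
subtyping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coexpression import filter_significant
from .enrichment import (
    _es_from_positions,
    bh_adjust,
    hypergeom_tail,
    null_enrichment_scores,
)
from .io_formats import GeneSetCollection, PipelineConfig

logger = logging.getLogger(__name__)

__all__ = [
    "compute_lncres",
    "significant_pairs",
    "overlap_stats",
    "tumor_specific_lncrnas",
    "cell_enrichment",
    "DysregulatedSet",
    "select_dysregulated",
]

_COHORT_SEED_OFFSET = {"tumor": 1, "normal": 2}


def compute_lncres(
    cor_records: pd.DataFrame,
    pathways: GeneSetCollection,
    config: PipelineConfig,
    cohort: str = "tumor",
    seed: int | None = None,
) -> pd.DataFrame:
    """lncRES table for one cohort.

    ``cor_records`` is the full correlation table of the cohort (one row per
    lncRNA--mRNA pair with ``R``, ``P`` and ``score``).  Only lncRNAs with at
    least ``config.min_correlated_mrnas`` significantly correlated partners
    (``|R| > r_min`` and ``P < p_max``) enter the enrichment stage; the rest
    are skipped with a warning.  Each tested lncRNA ranks *all* its scored
    mRNAs ascending by Score; every pathway overlapping that ranking yields a
    signed enrichment score, a gene-set permutation p-value (add-one
    estimator, null shared across pathways of equal overlap size) and, after
    all tests in the cohort are collected, a Benjamini--Hochberg FDR.

    Returns a DataFrame with columns
    ``lnc_id, pathway, lncres, n_hits, p, fdr, cohort``.
    """
    if cohort not in _COHORT_SEED_OFFSET:
        raise ValueError("cohort must be 'tumor' or 'normal'")
    if seed is None:
        seed = config.rng_seed * 10 + _COHORT_SEED_OFFSET[cohort]

    sig = filter_significant(cor_records, config.r_min, config.p_max)
    n_sig = sig.groupby("lnc_id").size()
    tested = sorted(n_sig.index[n_sig >= config.min_correlated_mrnas])
    skipped = cor_records["lnc_id"].nunique() - len(tested)
    if skipped:
        logger.info(
            "%s cohort: %d lncRNAs below %d significant partners, skipped",
            cohort, skipped, config.min_correlated_mrnas,
        )
    if not tested:
        return pd.DataFrame(
            columns=["lnc_id", "pathway", "lncres", "n_hits", "p", "fdr", "cohort"]
        )

    score = cor_records.pivot(index="lnc_id", columns="mrna_id", values="score")
    exponent = config.weight_exponent
    n_perm = config.n_permutations
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(tested))

    records: list[dict] = []
    for lnc, child in zip(tested, child_seeds):
        row = score.loc[lnc].dropna()
        # ascending by score; ties broken by gene id so the ranking is
        # reproducible across runs
        ordered = row.sort_index().sort_values(kind="mergesort")
        ranked_ids = ordered.index.to_numpy()
        weights = ordered.to_numpy()
        n_items = ranked_ids.size
        id_pos = {g: i for i, g in enumerate(ranked_ids)}
        rng = np.random.default_rng(child)
        null_cache: dict[int, np.ndarray] = {}
        for gs in pathways:
            pos = np.array(sorted(id_pos[g] for g in gs.genes if g in id_pos))
            if pos.size == 0:
                logger.warning(
                    "pathway %s has no member among lncRNA %s's mRNAs", gs.name, lnc
                )
                continue
            if pos.size == n_items:
                logger.warning(
                    "pathway %s covers every scored mRNA of %s; skipped", gs.name, lnc
                )
                continue
            es = _es_from_positions(pos, weights, exponent)[0]
            m = pos.size
            if m not in null_cache:
                null_cache[m] = null_enrichment_scores(
                    n_items, m, weights, n_perm, rng, exponent
                )
            null = null_cache[m]
            p = (1 + np.sum(np.abs(null) >= abs(es))) / (n_perm + 1)
            records.append({
                "lnc_id": lnc, "pathway": gs.name, "lncres": float(es),
                "n_hits": m, "p": float(p),
            })
    if not records:
        return pd.DataFrame(
            columns=["lnc_id", "pathway", "lncres", "n_hits", "p", "fdr", "cohort"]
        )
    table = pd.DataFrame(records)
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    table["cohort"] = cohort
    return table


def significant_pairs(lncres_table: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Pairs with ``FDR < lncres_fdr_max`` and ``|lncRES| > lncres_abs_min``.

    Both inequalities strict: a pair sitting exactly on either threshold is
    dropped.
    """
    if lncres_table.empty:
        return lncres_table.copy()
    keep = (lncres_table["fdr"] < config.lncres_fdr_max) & (
        lncres_table["lncres"].abs() > config.lncres_abs_min
    )
    return lncres_table[keep].reset_index(drop=True)


def _pair_set(pairs: pd.DataFrame | set) -> set[tuple[str, str]]:
    if isinstance(pairs, pd.DataFrame):
        return set(zip(pairs["lnc_id"], pairs["pathway"]))
    return {tuple(p) for p in pairs}


def _pct(num: int, den: int) -> float:
    return round(100.0 * num / den, 2) if den else 0.0


def overlap_stats(tumor_pairs, normal_pairs) -> dict:
    """Counts and percentages describing tumor/normal overlap.

    Accepts significant-pair tables (or bare sets of ``(lnc_id, pathway)``
    tuples) from both cohorts and returns pair- and lncRNA-level totals, the
    shared counts, the tumor-specific lncRNA count, and each shared count as
    a percentage of the normal and tumor totals (rounded to 2 decimals).
    """
    t_pairs = _pair_set(tumor_pairs)
    n_pairs = _pair_set(normal_pairs)
    shared_pairs = t_pairs & n_pairs
    t_lnc = {l for l, _ in t_pairs}
    n_lnc = {l for l, _ in n_pairs}
    shared_lnc = t_lnc & n_lnc
    specific = t_lnc - n_lnc
    return {
        "tumor_pairs": len(t_pairs),
        "normal_pairs": len(n_pairs),
        "shared_pairs": len(shared_pairs),
        "tumor_lncrnas": len(t_lnc),
        "normal_lncrnas": len(n_lnc),
        "shared_lncrnas": len(shared_lnc),
        "tumor_specific_lncrnas": len(specific),
        "shared_pair_pct_of_normal": _pct(len(shared_pairs), len(n_pairs)),
        "shared_pair_pct_of_tumor": _pct(len(shared_pairs), len(t_pairs)),
        "shared_lnc_pct_of_normal": _pct(len(shared_lnc), len(n_lnc)),
        "shared_lnc_pct_of_tumor": _pct(len(shared_lnc), len(t_lnc)),
        "tumor_specific_lnc_pct": _pct(len(specific), len(t_lnc)),
    }


def tumor_specific_lncrnas(tumor_pairs, normal_pairs) -> set[str]:
    """lncRNAs with >= 1 significant tumor pair and none in normal."""
    t_lnc = {l for l, _ in _pair_set(tumor_pairs)}
    n_lnc = {l for l, _ in _pair_set(normal_pairs)}
    return t_lnc - n_lnc


def cell_enrichment(
    lnc_ids,
    sig_cor_records: pd.DataFrame,
    markers: GeneSetCollection,
    universe,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Hypergeometric enrichment of immune-cell marker sets per lncRNA.

    For lncRNA i and cell type j the test draws ``n`` (the lncRNA's
    significantly correlated mRNAs) from a universe of ``N`` mRNAs containing
    ``M`` marker genes and asks whether the observed overlap ``k`` is larger
    than chance (upper tail).  Overlaps below ``config.min_marker_overlap_k``
    are kept in the table but forced to ``p = 1`` and flagged non-significant,
    mirroring the rule that tiny overlaps carry no evidence.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty mRNA universe")
    N = len(universe)
    by_lnc = {
        l: set(g["mrna_id"]) & universe
        for l, g in sig_cor_records.groupby("lnc_id")
    }
    records = []
    for lnc in sorted(lnc_ids):
        correlated = by_lnc.get(lnc, set())
        n = len(correlated)
        for gs in markers:
            in_universe = gs.genes & universe
            M = len(in_universe)
            k = len(correlated & in_universe)
            if k < config.min_marker_overlap_k:
                p, significant = 1.0, False
            else:
                p = hypergeom_tail(N, M, n, k)
                significant = p < config.cell_p_max
            records.append({
                "lnc_id": lnc, "cell_type": gs.name,
                "N": N, "M": M, "n": n, "k": k,
                "p": p, "significant": significant,
            })
    return pd.DataFrame(records)


@dataclass
class DysregulatedSet:
    """The selected dysregulated immune lncRNAs plus audit information."""

    lnc_ids: list[str]
    enriched_cell_counts: dict[str, int] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.lnc_ids)


def select_dysregulated(
    cell_table: pd.DataFrame, config: PipelineConfig
) -> DysregulatedSet:
    """lncRNAs enriched (``p < cell_p_max``, strict) in at least
    ``min_enriched_cells`` cell types (inclusive)."""
    provenance = {
        "cell_p_max": config.cell_p_max,
        "min_enriched_cells": config.min_enriched_cells,
        "min_marker_overlap_k": config.min_marker_overlap_k,
    }
    if cell_table.empty:
        return DysregulatedSet([], {}, provenance)
    hits = cell_table[cell_table["p"] < config.cell_p_max]
    counts = hits.groupby("lnc_id").size().to_dict()
    selected = sorted(l for l, c in counts.items() if c >= config.min_enriched_cells)
    return DysregulatedSet(selected, counts, provenance)
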