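"""End-to-end orchestration of the discovery pipeline on one cohort bundle.

Wires the individual stages together in the order of the analysis: data
preparation, per-cohort co-expression, lncRES enrichment, tumor-specific
filtering, immune-cell enrichment, dysregulated-set selection and consensus
subtyping.  Each stage remains importable on its own; this module only
sequences them and collects the intermediate tables for auditing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .coexpression import filter_significant, log2_transform, pearson_correlate
from .immune_lncrna import (
    DysregulatedSet,
    cell_enrichment,
    compute_lncres,
    overlap_stats,
    select_dysregulated,
    significant_pairs,
    tumor_specific_lncrnas,
)
from .io_formats import (
    ExpressionMatrix,
    GeneSetCollection,
    PipelineConfig,
    drop_all_zero_genes,
    split_by_annotation,
)
from .subtyping import ConsensusResult, consensus_cluster

__all__ = ["DiscoveryResult", "prepare_cohort", "run_discovery"]


@dataclass
class DiscoveryResult:
    """All intermediate and final tables of one discovery run."""

    correlations: dict[str, pd.DataFrame]       # cohort -> full table
    lncres: dict[str, pd.DataFrame]             # cohort -> lncRES table
    significant: dict[str, pd.DataFrame]        # cohort -> significant pairs
    overlap: dict                               # tumor/normal overlap summary
    tumor_specific: set[str]
    cell_table: pd.DataFrame
    dysregulated: DysregulatedSet
    consensus: ConsensusResult | None
    universe: list[str] = field(default_factory=list)

    @property
    def subtype_labels(self) -> pd.Series:
        if self.consensus is None:
            raise ValueError("no consensus result (too few dysregulated lncRNAs)")
        return self.consensus.labels


def prepare_cohort(
    expr: ExpressionMatrix, biotype, config: PipelineConfig
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Zero-gene filtering, lncRNA/mRNA split and log2 transform."""
    filtered = drop_all_zero_genes(expr)
    lnc, mrna = split_by_annotation(filtered, biotype)
    return (
        log2_transform(lnc, config.log2_offset),
        log2_transform(mrna, config.log2_offset),
    )


def run_discovery(
    tumor: ExpressionMatrix,
    normal: ExpressionMatrix,
    biotype,
    pathways: GeneSetCollection,
    markers: GeneSetCollection,
    config: PipelineConfig,
    subtype: bool = True,
) -> DiscoveryResult:
    """Run the full discovery chain on raw TPM tumor/normal matrices."""
    lnc_t, mrna_t = prepare_cohort(tumor, biotype, config)
    lnc_n, mrna_n = prepare_cohort(normal, biotype, config)

    correlations = {
        "tumor": pearson_correlate(lnc_t, mrna_t),
        "normal": pearson_correlate(lnc_n, mrna_n),
    }
    lncres = {
        cohort: compute_lncres(correlations[cohort], pathways, config, cohort=cohort)
        for cohort in ("tumor", "normal")
    }
    significant = {
        cohort: significant_pairs(lncres[cohort], config)
        for cohort in ("tumor", "normal")
    }
    overlap = overlap_stats(significant["tumor"], significant["normal"])
    specific = tumor_specific_lncrnas(significant["tumor"], significant["normal"])

    universe = mrna_t.gene_ids
    sig_cor_t = filter_significant(
        correlations["tumor"], config.r_min, config.p_max
    )
    cell_table = cell_enrichment(specific, sig_cor_t, markers, universe, config)
    dysregulated = select_dysregulated(cell_table, config)

    consensus = None
    if subtype and len(dysregulated) >= 2:
        panel = lnc_t.subset_genes(dysregulated.lnc_ids)
        consensus = consensus_cluster(panel, config)

    return DiscoveryResult(
        correlations=correlations,
        lncres=lncres,
        significant=significant,
        overlap=overlap,
        tumor_specific=specific,
        cell_table=cell_table,
        dysregulated=dysregulated,
        consensus=consensus,
        universe=universe,
    )
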