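"""Molecular characterization of the subtypes.

Differential expression (moderated t) between C1 and C2, over-representation
of the immune pathways among the DEGs, subtype-level GSEA, marker-based and
single-sample immune scores with rank-sum comparisons, the share of panel
lncRNAs that are differentially expressed, and concordance of the discovered
subtypes with the planted ground-truth labels.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from lnc_immunotype.downstream import (
    concordance,
    count_significant_features,
    differential_expression,
    marker_score,
    ora,
    ssgsea_scores,
    subtype_gsea,
)
from lnc_immunotype.io_formats import (
    GeneSet,
    GeneSetCollection,
    PipelineConfig,
    read_biotype,
    read_expression,
    read_gmt,
    read_labels,
)
from lnc_immunotype.pipeline import prepare_cohort
from lnc_immunotype.survival import wilcoxon_rank_sum


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--labels", type=Path,
                    default=Path("results/subtypes/subtype_labels.tsv"))
    ap.add_argument("--panel", type=Path,
                    default=Path("results/immune_lncrna/dysregulated_lncrnas.tsv"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/downstream"))
    ap.add_argument("--config", type=Path, default=None)
    ap.add_argument("--gsea-permutations", type=int, default=200)
    args = ap.parse_args()

    cfg = PipelineConfig.from_yaml(args.config) if args.config else PipelineConfig()
    args.out_dir.mkdir(parents=True, exist_ok=True)
    labels = read_labels(args.labels, label_col="subtype")
    biotype = read_biotype(args.data_dir / "biotype.tsv")
    tumor = read_expression(args.data_dir / "tumor_tpm.tsv")
    lnc_t, mrna_t = prepare_cohort(tumor, biotype, cfg)
    pathways = read_gmt(args.data_dir / "immune_pathways.gmt")
    markers = read_gmt(args.data_dir / "immune_cell_markers.gmt")
    summary: dict = {}

    # --- differential expression (mRNA) ----------------------------------
    deg = differential_expression(mrna_t, labels, cfg)
    deg.to_csv(args.out_dir / "deg_mrna.tsv", sep="\t", index=False,
               float_format="%.6g")
    up = deg[deg["status"] == "up_in_C2"]
    down = deg[deg["status"] == "down_in_C2"]
    summary["deg"] = {"total": int((deg["status"] != "not_significant").sum()),
                      "up_in_C2": len(up), "down_in_C2": len(down)}
    print(f"DEGs (FDR<{cfg.deg_fdr_max}, FC>{cfg.fc_min}): "
          f"{summary['deg']['total']} ({len(up)} up in C2, {len(down)} down in C2)")

    # --- panel lncRNA differential expression ----------------------------
    panel_ids = pd.read_csv(args.panel, sep="\t")["lnc_id"].tolist()
    panel_deg = differential_expression(lnc_t.subset_genes(panel_ids), labels, cfg)
    count, total, pct = count_significant_features(panel_deg["p"], cfg.p_max)
    summary["panel_lncrna_deg"] = {"significant": count, "total": total, "pct": pct}
    print(f"panel lncRNAs differentially expressed: {count}/{total} = {pct}%")

    # --- ORA of down-in-C2 (immune-high C1) genes on immune pathways ------
    down_genes = down["gene"].tolist()
    ora_table = ora(down_genes, mrna_t.gene_ids, pathways,
                    fdr_max=cfg.deg_fdr_max, keep_all=True)
    ora_table.to_csv(args.out_dir / "ora_down_in_C2.tsv", sep="\t", index=False,
                     float_format="%.6g")
    summary["ora_down_in_C2_enriched"] = int(ora_table["enriched"].sum())
    print(f"immune pathways over-represented among down-in-C2 genes: "
          f"{summary['ora_down_in_C2_enriched']}/{len(ora_table)}")

    # --- subtype GSEA -----------------------------------------------------
    gsea = subtype_gsea(mrna_t, labels, pathways, cfg,
                        n_perm=args.gsea_permutations, keep_all=True)
    gsea.drop(columns="leading_edge").to_csv(
        args.out_dir / "subtype_gsea.tsv", sep="\t", index=False,
        float_format="%.6g")
    summary["gsea_passed"] = gsea[gsea["passed"]]["pathway"].tolist()
    print(f"subtype GSEA: {len(summary['gsea_passed'])} pathways pass the screen "
          f"(all ES>0 means enrichment toward C1: "
          f"{bool((gsea['es'] > 0).all())})")

    # --- immune scores ----------------------------------------------------
    mscores = marker_score(mrna_t, markers)
    mscores.to_csv(args.out_dir / "marker_scores.tsv", sep="\t",
                   float_format="%.6g")
    mean_ms = mscores.mean(axis=1)
    p_ms = wilcoxon_rank_sum(mean_ms[labels == "C1"], mean_ms[labels == "C2"])
    summary["marker_score"] = {
        "mean_C1": float(mean_ms[labels == "C1"].mean()),
        "mean_C2": float(mean_ms[labels == "C2"].mean()),
        "wilcoxon_p": p_ms,
    }
    print(f"mean marker score C1 {summary['marker_score']['mean_C1']:.3f} vs "
          f"C2 {summary['marker_score']['mean_C2']:.3f} (rank-sum p={p_ms:.3g})")

    immune_sig = sorted(pathways.genes() & set(mrna_t.gene_ids))
    stromal_sig = [g for g in mrna_t.gene_ids
                   if g not in set(immune_sig) and g not in markers.genes()][:150]
    sigs = GeneSetCollection({
        "ImmuneScore": GeneSet("ImmuneScore", "immune pathway union",
                               frozenset(immune_sig)),
        "StromalScore": GeneSet("StromalScore", "synthetic stromal stand-in",
                                frozenset(stromal_sig)),
    })
    sscores = ssgsea_scores(mrna_t, sigs)
    sscores.to_csv(args.out_dir / "ssgsea_scores.tsv", sep="\t",
                   float_format="%.6g")
    p_ss = wilcoxon_rank_sum(sscores.loc[labels == "C1", "ImmuneScore"],
                             sscores.loc[labels == "C2", "ImmuneScore"])
    summary["ssgsea_immune_wilcoxon_p"] = p_ss
    print(f"ssGSEA ImmuneScore C1 vs C2 rank-sum p = {p_ss:.3g}")

    # --- concordance with the planted subtypes ---------------------------
    with open(args.data_dir / "truth.json") as fh:
        truth_labels = pd.Series(json.load(fh)["subtype_labels"])
    conc = concordance(labels, truth_labels)
    conc.counts.to_csv(args.out_dir / "concordance_counts.tsv", sep="\t")
    conc.row_pct.to_csv(args.out_dir / "concordance_pct.tsv", sep="\t")
    summary["concordance_row_pct"] = conc.row_pct.to_dict()
    print("concordance with planted subtypes (row %):")
    print(conc.row_pct.to_string())

    with open(args.out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=str)


if __name__ == "__main__":
    main()
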