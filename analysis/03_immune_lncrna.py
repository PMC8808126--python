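"""Identify tumor-specific dysregulated immune lncRNAs.

Computes per-cohort lncRES tables (running-sum enrichment of each immune
pathway in every lncRNA's score-ranked mRNA list), screens pairs at
FDR < 0.05 and |lncRES| > 0.995, summarizes the tumor/normal overlap,
keeps lncRNAs significant only in tumor, tests those for immune-cell marker
enrichment and selects the ones enriched in enough cell types.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from lnc_immunotype.coexpression import filter_significant
from lnc_immunotype.immune_lncrna import (
    cell_enrichment,
    compute_lncres,
    overlap_stats,
    select_dysregulated,
    significant_pairs,
    tumor_specific_lncrnas,
)
from lnc_immunotype.io_formats import (
    PipelineConfig,
    read_biotype,
    read_expression,
    read_gmt,
)
from lnc_immunotype.pipeline import prepare_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--cor-dir", type=Path, default=Path("results/coexpression"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/immune_lncrna"))
    ap.add_argument("--config", type=Path, default=None)
    ap.add_argument("--seed", type=int, default=None,
                    help="override config.rng_seed for the permutation nulls")
    args = ap.parse_args()

    cfg = PipelineConfig.from_yaml(args.config) if args.config else PipelineConfig()
    if args.seed is not None:
        cfg = cfg.with_overrides(rng_seed=args.seed)
    pathways = read_gmt(args.data_dir / "immune_pathways.gmt")
    markers = read_gmt(args.data_dir / "immune_cell_markers.gmt")
    args.out_dir.mkdir(parents=True, exist_ok=True)

    sig_pairs = {}
    for cohort in ("tumor", "normal"):
        cor = pd.read_csv(args.cor_dir / f"{cohort}_correlations.tsv", sep="\t")
        lncres = compute_lncres(cor, pathways, cfg, cohort=cohort)
        lncres.to_csv(args.out_dir / f"{cohort}_lncres.tsv", sep="\t",
                      index=False, float_format="%.6g")
        sig = significant_pairs(lncres, cfg)
        sig_pairs[cohort] = sig
        print(f"{cohort}: {len(lncres)} lncRNA-pathway tests, "
              f"{len(sig)} significant pairs "
              f"(FDR<{cfg.lncres_fdr_max}, |lncRES|>{cfg.lncres_abs_min})")

    overlap = overlap_stats(sig_pairs["tumor"], sig_pairs["normal"])
    with open(args.out_dir / "overlap.json", "w") as fh:
        json.dump(overlap, fh, indent=1)
    print("overlap:", overlap)

    specific = tumor_specific_lncrnas(sig_pairs["tumor"], sig_pairs["normal"])
    print(f"tumor-specific immune lncRNAs: {len(specific)}")

    biotype = read_biotype(args.data_dir / "biotype.tsv")
    tumor = read_expression(args.data_dir / "tumor_tpm.tsv")
    _, mrna_t = prepare_cohort(tumor, biotype, cfg)
    cor_t = pd.read_csv(args.cor_dir / "tumor_correlations.tsv", sep="\t")
    sig_cor = filter_significant(cor_t, cfg.r_min, cfg.p_max)
    cells = cell_enrichment(specific, sig_cor, markers, mrna_t.gene_ids, cfg)
    cells.to_csv(args.out_dir / "cell_enrichment.tsv", sep="\t",
                 index=False, float_format="%.6g")

    dysregulated = select_dysregulated(cells, cfg)
    pd.Series(dysregulated.lnc_ids, name="lnc_id").to_csv(
        args.out_dir / "dysregulated_lncrnas.tsv", sep="\t", index=False
    )
    print(f"dysregulated set (enriched in >={cfg.min_enriched_cells} cell types): "
          f"{len(dysregulated)} lncRNAs -> {args.out_dir}/dysregulated_lncrnas.tsv")


if __name__ == "__main__":
    main()
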