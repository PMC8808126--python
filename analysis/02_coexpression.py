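"""Per-cohort lncRNA--mRNA co-expression tables.

Prepares each cohort (drop all-zero genes, split lncRNA/mRNA, log2) and
computes the full Pearson correlation table with significance and the
correlation Score, writing one TSV per cohort plus a summary of how many
pairs pass the |R| > 0.5, p < 0.05 screen.
"""

import argparse
from pathlib import Path

from lnc_immunotype.coexpression import filter_significant, pearson_correlate
from lnc_immunotype.io_formats import PipelineConfig, read_biotype, read_expression
from lnc_immunotype.pipeline import prepare_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/coexpression"))
    ap.add_argument("--config", type=Path, default=None)
    args = ap.parse_args()

    cfg = PipelineConfig.from_yaml(args.config) if args.config else PipelineConfig()
    biotype = read_biotype(args.data_dir / "biotype.tsv")
    args.out_dir.mkdir(parents=True, exist_ok=True)

    for cohort in ("tumor", "normal"):
        expr = read_expression(args.data_dir / f"{cohort}_tpm.tsv")
        lnc, mrna = prepare_cohort(expr, biotype, cfg)
        table = pearson_correlate(lnc, mrna)
        table.to_csv(args.out_dir / f"{cohort}_correlations.tsv",
                     sep="\t", index=False, float_format="%.6g")
        sig = filter_significant(table, cfg.r_min, cfg.p_max)
        per_lnc = sig.groupby("lnc_id").size()
        print(f"{cohort}: {len(table):,} lncRNA-mRNA pairs scored; "
              f"{len(sig):,} significant (|R|>{cfg.r_min}, p<{cfg.p_max}); "
              f"{len(per_lnc)} lncRNAs with >=1 significant partner "
              f"(median {int(per_lnc.median()) if len(per_lnc) else 0} partners)")


if __name__ == "__main__":
    main()
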