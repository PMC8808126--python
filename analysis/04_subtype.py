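"""Consensus-clustering molecular subtypes on the dysregulated-lncRNA panel.

Restricts the log2 tumor expression to the selected dysregulated lncRNAs,
runs resampled consensus clustering over k = 2..6, picks the cluster number
by minimum PAC, names the clusters C1/C2/... by decreasing panel expression,
and writes labels, the consensus matrices and the selection diagnostics.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from lnc_immunotype.io_formats import (
    PipelineConfig,
    read_biotype,
    read_expression,
    write_labels,
)
from lnc_immunotype.pipeline import prepare_cohort
from lnc_immunotype.subtyping import consensus_cluster


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--panel", type=Path,
                    default=Path("results/immune_lncrna/dysregulated_lncrnas.tsv"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/subtypes"))
    ap.add_argument("--config", type=Path, default=None)
    ap.add_argument("--seed", type=int, default=None)
    args = ap.parse_args()

    cfg = PipelineConfig.from_yaml(args.config) if args.config else PipelineConfig()
    if args.seed is not None:
        cfg = cfg.with_overrides(rng_seed=args.seed)
    args.out_dir.mkdir(parents=True, exist_ok=True)

    biotype = read_biotype(args.data_dir / "biotype.tsv")
    tumor = read_expression(args.data_dir / "tumor_tpm.tsv")
    lnc_t, _ = prepare_cohort(tumor, biotype, cfg)
    panel_ids = pd.read_csv(args.panel, sep="\t")["lnc_id"].tolist()
    panel = lnc_t.subset_genes(panel_ids)
    print(f"clustering {panel.shape[1]} tumor samples on {panel.shape[0]} lncRNAs")

    res = consensus_cluster(panel, cfg)
    write_labels(res.labels, args.out_dir / "subtype_labels.tsv",
                 label_col="subtype")
    for k, cons in res.consensus.items():
        cons.round(4).to_csv(args.out_dir / f"consensus_k{k}.tsv", sep="\t")
    summary = {
        "chosen_k": res.chosen_k,
        "cdf_area": res.cdf_area,
        "delta_area": res.delta_area,
        "pac": res.pac,
        "sizes": res.labels.value_counts().to_dict(),
        "metadata": res.metadata,
    }
    with open(args.out_dir / "consensus_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)

    print(f"chosen k = {res.chosen_k} (PAC: "
          + ", ".join(f"k={k}: {v:.3f}" for k, v in res.pac.items()) + ")")
    print("subtype sizes:", summary["sizes"])

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        for k, cons in res.consensus.items():
            import numpy as np
            vals = np.sort(cons.to_numpy()[np.triu_indices(len(cons), 1)])
            ax.plot(vals, np.arange(1, vals.size + 1) / vals.size, label=f"k={k}")
        ax.set_xlabel("consensus index")
        ax.set_ylabel("CDF")
        ax.legend()
        fig.tight_layout()
        fig.savefig(args.out_dir / "consensus_cdf.png", dpi=120)
    except Exception as exc:  # plotting is best-effort
        print(f"skipping CDF plot: {exc}")


if __name__ == "__main__":
    main()
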