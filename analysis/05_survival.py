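"""Survival comparison of the discovered molecular subtypes.

Kaplan--Meier curves and medians per subtype for each endpoint (OS, PFS,
DSS) and the log-rank test between subtypes, written as per-endpoint curve
TSVs and one JSON of test statistics.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from lnc_immunotype.io_formats import ENDPOINTS, read_labels, read_survival
from lnc_immunotype.survival import km_estimate, logrank_test


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--labels", type=Path,
                    default=Path("results/subtypes/subtype_labels.tsv"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/survival"))
    args = ap.parse_args()

    surv = read_survival(args.data_dir / "survival.tsv")
    labels = read_labels(args.labels, label_col="subtype")
    args.out_dir.mkdir(parents=True, exist_ok=True)

    stats: dict = {}
    for endpoint in ENDPOINTS:
        rows = []
        for subtype in sorted(labels.unique()):
            members = labels.index[labels == subtype].tolist()
            curve = km_estimate(surv, endpoint, group=members)
            rows.extend({
                "subtype": subtype, "time": t, "survival": s,
                "at_risk": n, "events": d,
            } for t, s, n, d in zip(curve.times, curve.survival,
                                    curve.at_risk, curve.events))
            stats.setdefault(endpoint, {})[f"median_{subtype}"] = curve.median
        pd.DataFrame(rows).to_csv(args.out_dir / f"km_{endpoint}.tsv",
                                  sep="\t", index=False, float_format="%.6g")
        res = logrank_test(surv, endpoint, labels)
        stats[endpoint].update(
            chi_square=res.chi_square, df=res.df, p=res.p
        )
        medians = {k: v for k, v in stats[endpoint].items() if k.startswith("median")}
        print(f"{endpoint}: log-rank chi2 = {res.chi_square:.3f}, "
              f"p = {res.p:.4g}; medians {medians}")

    with open(args.out_dir / "logrank.json", "w") as fh:
        json.dump(stats, fh, indent=1)

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, len(ENDPOINTS), figsize=(12, 3.5), sharey=True)
        for ax, endpoint in zip(axes, ENDPOINTS):
            for subtype in sorted(labels.unique()):
                members = labels.index[labels == subtype].tolist()
                curve = km_estimate(surv, endpoint, group=members)
                ax.step([0, *curve.times], [1.0, *curve.survival],
                        where="post", label=subtype)
            ax.set_title(f"{endpoint} (p={stats[endpoint]['p']:.3g})")
            ax.set_xlabel("days")
        axes[0].set_ylabel("survival")
        axes[0].legend()
        fig.tight_layout()
        fig.savefig(args.out_dir / "km_curves.png", dpi=120)
    except Exception as exc:
        print(f"skipping KM plot: {exc}")


if __name__ == "__main__":
    main()
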