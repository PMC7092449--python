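#!/usr/bin/env python
"""Metric-vs-sample-size figures from a grid results CSV.

Reads the table written by 01_simulate_grid.py and draws the three
headline panels: mean estimate, SE-calibration ratio, and 95% CI coverage
against sample size, one line per (method, #covariates).  PNG output goes
under results/figures/.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results/grid_continuous.csv"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/figures"))
    args = ap.parse_args()

    df = pd.read_csv(args.results)
    df = df[df["method"].isin(["regression", "iptw"])]
    args.out_dir.mkdir(parents=True, exist_ok=True)

    panels = [
        ("mean_theta", "mean treatment effect estimate", "mean_estimate.png", 5.0),
        ("se_ratio", "mean estimated SE / empirical SE", "se_calibration.png", 1.0),
        ("coverage_pct", "95% CI coverage (%)", "coverage.png", 95.0),
    ]
    for col, label, fname, ref in panels:
        fig, ax = plt.subplots(figsize=(7, 4.5))
        for (method, p), sub in df.groupby(["method", "n_covariates"]):
            sub = sub.sort_values("n")
            ax.plot(sub["n"], sub[col], marker="o", ms=3,
                    ls="-" if method == "regression" else "--",
                    label=f"{method}, {p} cov.")
        ax.axhline(ref, color="grey", lw=0.8)
        if col == "coverage_pct":
            ax.axhspan(94, 96, color="grey", alpha=0.15)
        ax.set_xlabel("sample size n")
        ax.set_ylabel(label)
        ax.legend(fontsize=7, ncol=2)
        fig.tight_layout()
        fig.savefig(args.out_dir / fname, dpi=150)
        plt.close(fig)
        print(f"wrote {args.out_dir / fname}")


if __name__ == "__main__":
    main()
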