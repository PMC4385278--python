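#!/usr/bin/env python
"""Summarise the design-grid run: rank-vs-p curves and AUC(CV_T) histograms.

Reads results/design_grid.csv and results/design_grid_detail.json (written
by 04_run_design_grid.py) and produces, under results/figures/:

  rank_vs_p.png          ranked p values, one curve per activity level
  grouped_by_param.png   p values grouped by kernel, iterations and cutoff
  top_design_auc.png     AUC(CV_T) histograms (healthy vs COPD) of the
                         top-ranked design

Usage: python analysis/05_report_figures.py
"""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def main():
    out = Path("results/figures")
    out.mkdir(parents=True, exist_ok=True)
    df = pd.read_csv("results/design_grid.csv")
    detail = json.loads(Path("results/design_grid_detail.json").read_text())
    ranked = df[df["rank"].notna()].sort_values("rank")

    fig, ax = plt.subplots(figsize=(6, 4))
    for mbq, sub in ranked.groupby("activity_mbq"):
        ax.semilogy(np.arange(1, len(sub) + 1), sub["p_value"].sort_values(), "o-",
                    label=f"{int(mbq)} MBq", ms=3)
    ax.set_xlabel("rank within activity level")
    ax.set_ylabel("Mann-Whitney p value")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "rank_vs_p.png", dpi=120)

    fig, axes = plt.subplots(1, 3, figsize=(11, 3.5), sharey=True)
    for ax, col in zip(axes, ["kernel_cm", "n_updates", "cutoff_cm"]):
        groups = ranked.fillna({"cutoff_cm": -1}).groupby(col)["p_value"]
        keys = list(groups.groups)
        ax.boxplot([np.log10(groups.get_group(k)) for k in keys],
                   tick_labels=["none" if k == -1 else f"{k:g}" for k in keys])
        ax.set_xlabel(col)
    axes[0].set_ylabel("log10 p")
    fig.tight_layout()
    fig.savefig(out / "grouped_by_param.png", dpi=120)

    best_id = ranked.iloc[0]["design_id"]
    d = detail[best_id]
    fig, ax = plt.subplots(figsize=(5.5, 4))
    bins = np.linspace(
        min(min(d["auc_healthy"]), min(d["auc_copd"])) - 1,
        max(max(d["auc_healthy"]), max(d["auc_copd"])) + 1, 15)
    ax.hist(d["auc_healthy"], bins=bins, alpha=0.6, label="healthy")
    ax.hist(d["auc_copd"], bins=bins, alpha=0.6, label="COPD")
    ax.set_xlabel("AUC(CV$_T$) [%]")
    ax.set_ylabel("realisations")
    ax.set_title(f"{best_id}  (CV$_T$ = {d['cv_t_percent']:.1f}%, p = {d['p']:.1e})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "top_design_auc.png", dpi=120)
    print(f"figures written to {out}/")


if __name__ == "__main__":
    main()
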