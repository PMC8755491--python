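"""Optional figures: correlation bar charts and per-tissue profiles.

Requires matplotlib (the ``plot`` extra); nothing else imports this module.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd


def plot_run(run_dir) -> list[Path]:
    """Bar chart of the three E–R correlations, plus a tissue profile if present."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    written = []
    summary = pd.read_csv(run_dir / "summary.tsv", sep="\t")
    corr = summary[summary["section"] == "correlation"]
    if len(corr):
        fig, ax = plt.subplots(figsize=(4, 3))
        labels = ["intracellular", "transmembrane", "extracellular"]
        rhos = corr["statistic"].astype(float).to_numpy()
        pvals = corr["p_value"].astype(float).to_numpy()
        ax.bar(labels, rhos, color=["#4878a8", "#999999", "#c44e52"])
        for x, (rho, p) in enumerate(zip(rhos, pvals)):
            if p == p and p < 0.05:
                ax.annotate("*", (x, rho), ha="center",
                            va="bottom" if rho >= 0 else "top", fontsize=14)
        ax.axhline(0, color="black", linewidth=0.8)
        ax.set_ylabel("Spearman rho (omega vs abundance)")
        fig.tight_layout()
        out = run_dir / "correlations.png"
        fig.savefig(out, dpi=150)
        plt.close(fig)
        written.append(out)

    sweep_path = run_dir / "sweep.tsv"
    if sweep_path.exists():
        sweep = pd.read_csv(sweep_path, sep="\t")
        fig, ax = plt.subplots(figsize=(6, 3))
        x = range(len(sweep))
        for col, label in (("rho_i", "intracellular"), ("rho_t", "transmembrane"),
                           ("rho_e", "extracellular")):
            ax.plot(x, sweep[col], marker="o", markersize=3, label=label)
        ax.axhline(0, color="black", linewidth=0.8)
        ax.set_xticks(list(x))
        ax.set_xticklabels(sweep["tissue"], rotation=90, fontsize=6)
        ax.set_ylabel("Spearman rho")
        ax.legend(fontsize=7)
        fig.tight_layout()
        out = run_dir / "tissue_profile.png"
        fig.savefig(out, dpi=150)
        plt.close(fig)
        written.append(out)
    return written
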