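"""Simple static diagnostics: love plot and means-by-system plot."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .balance import BalanceReport  # noqa: E402


def love_plot(report: BalanceReport, path: str | Path) -> Path:
    """Standardized mean differences before vs after weighting."""
    smd = report.smd
    labels = [f"{v}:{l}" for v, l in zip(smd["variable"], smd["level"])]
    y = range(len(labels))
    fig, ax = plt.subplots(figsize=(6, 0.3 * len(labels) + 1.5))
    ax.scatter(smd["smd_before"].abs(), y, label="before", marker="o")
    ax.scatter(smd["smd_after"].abs(), y, label="after", marker="x")
    ax.axvline(0.1, color="grey", ls="--", lw=0.8)
    ax.set_yticks(list(y), labels, fontsize=7)
    ax.set_xlabel("|standardized mean difference|")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def means_plot(means, path: str | Path) -> Path:
    """Weighted outcome means by school system with 95% intervals."""
    fig, ax = plt.subplots(figsize=(6, 4))
    outcomes = means["outcome"].unique()
    for i, outcome in enumerate(outcomes):
        sub = means[means["outcome"] == outcome]
        for j, (_, row) in enumerate(sub.iterrows()):
            x = i + (j - (len(sub) - 1) / 2) * 0.15
            ax.errorbar(x, row["mean"],
                        yerr=[[row["mean"] - row["lo95"]],
                              [row["hi95"] - row["mean"]]],
                        fmt="o", capsize=3, label=row["system"] if i == 0 else None)
    ax.set_xticks(range(len(outcomes)), outcomes)
    ax.set_ylabel("weighted mean")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
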