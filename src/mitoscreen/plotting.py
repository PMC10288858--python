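"""Diagnostic plots: PCA before/after batch adjustment, sex-ratio strip."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402


def pca_pair_plot(
    before: pd.DataFrame,
    after: pd.DataFrame,
    labels: pd.Series,
    path: str | Path,
    title: str = "Batch adjustment (visualisation only)",
) -> Path:
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharex=False, sharey=False)
    for ax, coords, name in ((axes[0], before, "before"), (axes[1], after, "after")):
        for level in sorted(labels.unique()):
            sel = labels.reindex(coords.index) == level
            ax.scatter(coords.loc[sel, "PC1"], coords.loc[sel, "PC2"], s=12, label=str(level))
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.set_title(name)
    axes[0].legend(fontsize=7)
    fig.suptitle(title)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def sex_ratio_plot(calls: pd.DataFrame, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(6, 3))
    for sex, marker in (("male", "o"), ("female", "s")):
        sel = calls["predicted"] == sex
        ax.scatter(
            calls.loc[sel, "yx_log_ratio"],
            [0] * int(sel.sum()),
            marker=marker,
            alpha=0.6,
            label=sex,
        )
    ax.set_xlabel("log10 chrY/chrX count ratio")
    ax.set_yticks([])
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
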