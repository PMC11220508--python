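"""Diagnostic figures: ROC panels and accuracy-versus-subset-size curves."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_roc_panel", "plot_accuracy_vs_k"]


def plot_roc_panel(curves: Mapping[str, np.ndarray], path: str | Path,
                   title: str = "ROC curves") -> None:
    """One ROC panel; ``curves`` maps model name -> (n, 2) array of (FPR, TPR)."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, pts in curves.items():
        ax.plot(pts[:, 0], pts[:, 1], label=name)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="chance")
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_accuracy_vs_k(traces: Mapping[str, Sequence[tuple[int, float, float]]],
                       path: str | Path) -> None:
    """CV balanced accuracy against subset size, one line per modality;
    diamonds mark the BIC-selected size."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, entries in traces.items():
        ks = [e[0] for e in entries]
        accs = [e[1] for e in entries]
        bics = [e[2] for e in entries]
        line, = ax.plot(ks, accs, label=name)
        k_star = ks[int(np.argmin(bics))]
        ax.plot([k_star], [accs[ks.index(k_star)]], marker="D", color=line.get_color())
    ax.set_xlabel("Number of ranked features")
    ax.set_ylabel("CV balanced accuracy (%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
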