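"""Optional figure output (volcano scatter, VIP bars, PLS-DA scores)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .plsda import PLSDAModel, VIPResult
from .univariate import VolcanoRecord


def volcano_plot(records: list[VolcanoRecord], path: str | Path, p_thresh: float = 0.05,
                 fc_thresh_log2: float = 1.0) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    fc = np.array([r.log2_fc for r in records])
    logp = -np.log10(np.maximum([r.p_value for r in records], 1e-300))
    sig = np.array([r.significant for r in records])
    ax.scatter(fc[~sig], logp[~sig], s=12, c="0.6", label="not significant")
    if sig.any():
        ax.scatter(fc[sig], logp[sig], s=16, c="crimson", label="significant")
    ax.axhline(-np.log10(p_thresh), ls="--", lw=0.8, c="k")
    for x in (-fc_thresh_log2, fc_thresh_log2):
        ax.axvline(x, ls="--", lw=0.8, c="k")
    ax.set_xlabel("log2 fold change (early / late)")
    ax.set_ylabel("-log10 p")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def vip_plot(vip: VIPResult, path: str | Path, top: int = 15) -> None:
    ranked = vip.ranking.head(top)[::-1]
    fig, ax = plt.subplots(figsize=(5, 0.3 * len(ranked) + 1))
    ax.barh(ranked.index.astype(str), ranked.to_numpy(), color="seagreen")
    ax.axvline(1.0, ls="--", lw=0.8, c="k")
    ax.set_xlabel("VIP score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def scores_plot(model: PLSDAModel, y, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    y = np.asarray(y)
    for cls in model.classes:
        mask = y == cls
        ax.scatter(model.scores[mask, 0], model.scores[mask, 1], s=18, label=str(cls))
    ax.set_xlabel("component 1 scores")
    ax.set_ylabel("component 2 scores")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
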