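"""Report figures: train-vs-test distance heatmaps and impostor maps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .authenticate import AuthReport, DistanceMatrix


def plot_distance_heatmap(d: DistanceMatrix, path: Path, template_index: int = 0) -> None:
    """Cold colors = small distances (self-matches sit on the diagonal)."""
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(d.values[:, :, template_index], cmap="jet", aspect="auto")
    ax.set_xlabel("test subject")
    ax.set_ylabel("training subject")
    fig.colorbar(im, ax=ax, label="Manhattan distance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_impostor_map(report: AuthReport, subject_ids: list[str], path: Path) -> None:
    """Binary impostor map: entry (j, i) marks j authenticated as an
    impostor of i; the diagonal is excluded by construction."""
    n = len(subject_ids)
    m = np.zeros((n, n))
    idx = {sid: i for i, sid in enumerate(subject_ids)}
    for sid, hits in report.impostors.items():
        for other in hits:
            m[idx[other], idx[sid]] = 1.0
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.imshow(m, cmap="Blues", aspect="auto")
    ax.set_xlabel("test subject")
    ax.set_ylabel("impostor (training subject)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
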