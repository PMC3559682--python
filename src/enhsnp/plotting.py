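"""Optional figures; nothing downstream depends on these."""

from __future__ import annotations

from pathlib import Path

from .mcc import MccMatrix


def mcc_heatmap(matrix: MccMatrix, path: str | Path, cmap: str = "Greys"):
    """Write a basic sample-by-sample MCC heatmap image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(matrix.sample_ids)
    fig, ax = plt.subplots(figsize=(max(4, n * 0.4), max(4, n * 0.4)))
    im = ax.imshow(matrix.values, cmap=cmap, vmin=-1, vmax=1)
    ax.set_xticks(range(n), matrix.sample_ids, rotation=90, fontsize=7)
    ax.set_yticks(range(n), matrix.sample_ids, fontsize=7)
    fig.colorbar(im, ax=ax, label="MCC")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
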