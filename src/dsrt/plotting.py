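"""Minimal visualization: a compound x cell line response matrix plot."""

from __future__ import annotations


def plot_auc_matrix(auc_table, path, cmap: str = "RdYlGn", vmin: float = 0.0,
                    vmax: float = 4.0):
    """Basic heatmap of the AUC matrix (green = insensitive, red = sensitive)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1 + 0.5 * auc_table.shape[1],
                                    1 + 0.4 * auc_table.shape[0]))
    im = ax.imshow(auc_table.to_numpy(float), cmap=cmap, vmin=vmin, vmax=vmax,
                   aspect="auto")
    ax.set_xticks(range(auc_table.shape[1]), auc_table.columns, rotation=90)
    ax.set_yticks(range(auc_table.shape[0]), auc_table.index)
    fig.colorbar(im, ax=ax, label="viability AUC")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
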