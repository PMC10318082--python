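"""Optional plotting helpers (require matplotlib)."""

from __future__ import annotations

import numpy as np

from .deconvolve import DeconvolutionResult
from .grid import BitGrid


def plot_deconvolution(result: DeconvolutionResult, path: str) -> None:
    """Scatter of raw vs curated per-well ratios colored by cluster, next
    to the called binary image (errors highlighted when truth was given).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
    observed = ~result.missing
    idx = np.arange(96)

    ax = axes[0]
    ax.scatter(idx[observed], result.values[observed], s=14, c="tab:gray")
    if result.outliers is not None:
        out_idx = idx[observed][result.outliers.labels == -1]
        ax.scatter(out_idx, result.values[out_idx], s=22, c="tab:red",
                   label="outlier (-1)")
        ax.legend(loc="center right", fontsize=7)
    ax.set_title("raw excision ratios")
    ax.set_ylim(-0.05, 1.05)

    ax = axes[1]
    if result.model is not None:
        labels = np.full(96, -1)
        labels[observed] = result.model.labels
        for c in range(result.model.k):
            sel = labels == c
            ax.scatter(idx[sel], result.curated[sel], s=14,
                       label=f"M{c}={result.model.means[c]:.2f}")
        ax.legend(loc="center right", fontsize=7)
    ax.set_title(f"curated + clustered ({result.mode.value})")
    ax.set_ylim(-0.05, 1.05)

    ax = axes[2]
    ax.imshow(result.grid.values, cmap="Blues", vmin=0, vmax=1)
    if result.errors is not None and result.errors.any():
        ys, xs = np.nonzero(result.errors)
        ax.scatter(xs, ys, marker="x", c="tab:orange")
    ax.set_title("called image" + (
        f" (accuracy {result.accuracy:.3f})" if result.accuracy is not None else ""
    ))
    ax.set_xticks(range(12), [str(i + 1) for i in range(12)], fontsize=6)
    ax.set_yticks(range(8), list("ABCDEFGH"), fontsize=6)

    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_grid(grid: BitGrid, path: str, title: str = "") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.imshow(grid.values, cmap="Blues", vmin=0, vmax=1)
    ax.set_xticks(range(12), [str(i + 1) for i in range(12)], fontsize=6)
    ax.set_yticks(range(8), list("ABCDEFGH"), fontsize=6)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
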