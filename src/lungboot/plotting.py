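"""Optional figure export (cumulative error distributions, map panels)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .metrics import CDFCurve  # noqa: E402


def plot_error_cdfs(curves: dict[str, CDFCurve], xlabel: str, path=None):
    """Step plot of empirical error CDFs (one line per label)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        ax.step(curve.sorted_values, curve.cum_fraction, where="post", label=label)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("cumulative fraction of lung voxels")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_map(values, title: str = "", path=None):
    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(values, origin="upper")
    ax.set_title(title)
    ax.axis("off")
    fig.colorbar(im, ax=ax, shrink=0.85)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
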