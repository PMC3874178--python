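"""Optional basic plotting: covariation heatmaps and ROC curves.

Imports matplotlib lazily so the core pipeline has no plotting dependency.
"""

from __future__ import annotations

from pathlib import Path


def _plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_map_heatmap(maps, which: str, path: str | Path, cmap: str = "Blues") -> None:
    """Heatmap of one covariation statistic (−log10 p or MI)."""
    plt = _plt()
    m = getattr(maps, which)
    if m is None:
        raise ValueError(f"map {which!r} was not computed")
    fig, ax = plt.subplots(figsize=(6, max(3, 0.12 * m.shape[0])))
    im = ax.imshow(m, aspect="auto", cmap=cmap, interpolation="nearest")
    ax.set_xlabel("DNA position")
    ax.set_ylabel("protein alignment position")
    ax.set_xticks(range(m.shape[1]), [p + 1 for p in maps.dna_positions])
    fig.colorbar(im, ax=ax, label=which)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_roc(curve: dict, path: str | Path, label: str = "") -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(curve["fpr"], curve["tpr"], label=label or None)
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    if label:
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
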