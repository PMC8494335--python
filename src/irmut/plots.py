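"""Static rendering of 119-channel signatures as bar plots."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .spectra import SCHEME

_CLASS_COLORS = {0: "#2d72b3", 1: "#8e5aa8", 2: "#b07aa1", 3: "#d1762b", 4: "#3f8f4d"}


def plot_signature(values: np.ndarray, title: str = "", ax=None):
    """Bar plot of a 119-channel signature, colored by mutation class.

    Returns the matplotlib Axes; pass ``ax`` to draw into an existing figure.
    """
    import matplotlib.pyplot as plt

    values = np.asarray(values, float)
    if values.shape != (119,):
        raise ValueError("signature must have length 119")
    if ax is None:
        _, ax = plt.subplots(figsize=(16, 3.2))
    ci = SCHEME.class_indices()
    ax.bar(np.arange(119), values, color=[_CLASS_COLORS[c] for c in ci], width=0.8)
    ax.set_xticks(np.arange(119))
    ax.set_xticklabels(SCHEME.labels, rotation=90, fontsize=4)
    ax.set_xlim(-1, 119)
    ax.set_ylabel("rate / count")
    if title:
        ax.set_title(title)
    ax.figure.tight_layout()
    return ax


def save_signature_plot(values: np.ndarray, path: str | Path, title: str = "") -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    ax = plot_signature(values, title=title)
    ax.figure.savefig(path, dpi=150)
    import matplotlib.pyplot as plt

    plt.close(ax.figure)
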