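"""Minimal plotting helpers for decomposition and network results."""

from __future__ import annotations

import numpy as np


def plot_variance_fractions(basis, ax=None):
    """Bar chart of per-eigentrait variance fractions."""
    import matplotlib.pyplot as plt

    from .eigentraits import variance_fractions

    if ax is None:
        _, ax = plt.subplots()
    fr = variance_fractions(basis)
    ax.bar(np.arange(1, len(fr) + 1), fr)
    ax.set_xlabel("eigentrait")
    ax.set_ylabel("variance fraction")
    return ax


def plot_adjacency(net, ax=None):
    """Heatmap of the signed adjacency; LD-untested pairs shown hatched gray."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 6))
    W = net.weights.to_numpy()
    lim = max(np.abs(W).max(), 1e-9)
    im = ax.imshow(W, cmap="RdBu_r", vmin=-lim, vmax=lim, aspect="auto")
    mask = net.untested.to_numpy()
    ys, xs = np.nonzero(mask)
    ax.scatter(xs, ys, s=4, c="0.6", marker=".")
    ax.set_xticks(range(len(net.targets)))
    ax.set_xticklabels(net.targets, rotation=90, fontsize=5)
    ax.set_yticks(range(len(net.sources)))
    ax.set_yticklabels(net.sources, fontsize=5)
    ax.set_xlabel("target")
    ax.set_ylabel("source")
    ax.figure.colorbar(im, ax=ax, label="standardized effect")
    return ax
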