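"""Plotting conveniences: parcellation rasters and t-SNE feature embeddings."""

from __future__ import annotations

import numpy as np


def plot_parcellation(raster: np.ndarray, truth: np.ndarray | None = None, ax=None):
    """Show a label raster; if ``truth`` is given, overlay its boundaries."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    masked = np.ma.masked_equal(raster, 0)
    ax.imshow(masked, cmap="tab10", interpolation="nearest")
    if truth is not None:
        edges = np.zeros(truth.shape, dtype=bool)
        edges[:, 1:] |= (truth[:, 1:] != truth[:, :-1]) & (truth[:, 1:] > 0)
        edges[1:, :] |= (truth[1:, :] != truth[:-1, :]) & (truth[1:, :] > 0)
        ys, xs = np.nonzero(edges)
        ax.scatter(xs, ys, s=1, c="black")
    ax.set_axis_off()
    return ax


def plot_feature_embedding(features: np.ndarray, labels: np.ndarray, ax=None,
                           perplexity: float = 30.0, seed: int = 0):
    """2-D t-SNE embedding of reduced features, colored by area label."""
    import matplotlib.pyplot as plt
    from sklearn.manifold import TSNE

    if ax is None:
        _, ax = plt.subplots()
    emb = TSNE(
        n_components=2, perplexity=min(perplexity, max(5, len(labels) // 4)),
        random_state=seed, init="pca",
    ).fit_transform(np.asarray(features))
    for code in np.unique(labels):
        sel = labels == code
        ax.scatter(emb[sel, 0], emb[sel, 1], s=4, label=str(code))
    ax.legend(title="area", markerscale=3, fontsize="small")
    return ax
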