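"""Minimal static plots: PCA scores and the STOCSY pseudo-spectrum."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .pca import PCAResults
from .stocsy import StocsyResult
from .types import AnnotationTable

__all__ = ["plot_scores", "plot_stocsy"]


def plot_scores(results: PCAResults, annotations: AnnotationTable | None = None,
                components: tuple[int, int] = (1, 2), ax=None):
    """Scatter of two score components, colored by class when annotated."""
    a, b = components
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    t = results.scores_
    if annotations is not None:
        labels = np.asarray([annotations.class_of(s)
                             for s in results.sample_ids])
        for cls in sorted(set(labels)):
            m = labels == cls
            ax.scatter(t[m, a - 1], t[m, b - 1], label=cls, s=18)
        ax.legend(frameon=False)
    else:
        ax.scatter(t[:, a - 1], t[:, b - 1], s=18)
    evr = results.explained_variance_ratio
    ax.set_xlabel(f"t{a} ({evr[a - 1]:.1%})")
    ax.set_ylabel(f"t{b} ({evr[b - 1]:.1%})")
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    return ax


def plot_stocsy(result: StocsyResult, ax=None):
    """Covariance trace colored by squared correlation, ppm descending."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    sc = ax.scatter(result.ppm_grid, result.covariance,
                    c=result.correlation ** 2, cmap="viridis", s=4,
                    vmin=0, vmax=1)
    ax.figure.colorbar(sc, ax=ax, label="r²")
    ax.invert_xaxis()
    ax.set_xlabel("ppm")
    ax.set_ylabel("covariance with driver")
    ax.set_title(f"STOCSY driven at {result.driver_ppm:.3f} ppm")
    return ax
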