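"""Consensus (multiblock) PCA over user-defined ppm blocks.

A 1H-NMR spectrum spans several orders of magnitude in intensity, so a
whole-spectrum PCA is dominated by the tallest resonances.  Splitting the
grid into blocks (spectral subsections), scaling each block on its own and
down-weighting large blocks lets low-intensity regions contribute, which is
the point of multiblock modelling of spectra.

The algorithm is the CPCA-W variant of consensus PCA: per component, block
loadings are regressed against the current super score, block scores are
combined through unit-norm super weights into a new super score, and at
convergence every block is deflated by the super score.  With this
normalization the super scores coincide with the scores of an ordinary PCA
run on the column-concatenated weighted blocks — a property the test suite
uses as an independent oracle.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .preprocess import scale as _scale_matrix
from .types import SpectraMatrix

__all__ = ["BlockDefinition", "ConsensusPCA", "ConsensusPCAResults"]

logger = logging.getLogger("nmrprofile.multiblock")


@dataclass
class BlockDefinition:
    """A named ppm window with its own scaling and weight rule."""

    name: str
    ppm_hi: float
    ppm_lo: float
    scaling: Literal["none", "center", "uv", "pareto"] = "center"
    weight_rule: Literal["inverse_sqrt_p", "unit"] = "inverse_sqrt_p"

    def __post_init__(self) -> None:
        if not self.ppm_hi > self.ppm_lo:
            raise ValueError(f"block {self.name!r}: ppm_hi must exceed ppm_lo")


def _block_columns(grid: np.ndarray, block: BlockDefinition) -> np.ndarray:
    return np.nonzero((grid <= block.ppm_hi) & (grid >= block.ppm_lo))[0]


class ConsensusPCA:
    """Multiblock PCA model (CPCA-W) of a :class:`SpectraMatrix`.

    Each block is scaled per its own ``scaling`` (centering is implied for
    every choice except ``none``) and multiplied by ``1/sqrt(p_b)`` under
    the default ``inverse_sqrt_p`` weight rule, p_b being the block's
    variable count.
    """

    def __init__(self, matrix: SpectraMatrix, blocks: list[BlockDefinition],
                 n_components: int, *, tol: float = 1e-10,
                 max_iter: int = 500):
        if not blocks:
            raise ValueError("need at least one block")
        cols = [_block_columns(matrix.ppm_grid, b) for b in blocks]
        for b, c in zip(blocks, cols):
            if len(c) < 2:
                raise ValueError(f"block {b.name!r} covers fewer than 2 "
                                 "grid points")
        flat = np.concatenate(cols)
        if len(np.unique(flat)) != len(flat):
            raise ValueError("blocks overlap on the ppm grid")
        self.matrix = matrix
        self.blocks = list(blocks)
        self.block_columns = cols
        self.n_components = int(n_components)
        self.tol = float(tol)
        self.max_iter = int(max_iter)

    def _prepare_blocks(self) -> list[np.ndarray]:
        prepared = []
        for b, c in zip(self.blocks, self.block_columns):
            sub = SpectraMatrix(list(self.matrix.sample_ids),
                                self.matrix.ppm_grid[c], self.matrix.X[:, c])
            Xb = _scale_matrix(sub, b.scaling).matrix.X if b.scaling != "none" \
                else sub.X.copy()
            if b.weight_rule == "inverse_sqrt_p":
                Xb = Xb / np.sqrt(Xb.shape[1])
            prepared.append(np.array(Xb, dtype=float))
        return prepared

    def fit(self) -> "ConsensusPCAResults":
        Xb = self._prepare_blocks()
        n = self.matrix.n_samples
        B = len(Xb)
        A = self.n_components
        block_ss = [float((x ** 2).sum()) for x in Xb]
        total_ss = sum(block_ss)

        super_scores = np.zeros((n, A))
        super_weights = np.zeros((B, A))
        block_scores = [np.zeros((n, A)) for _ in range(B)]
        block_loadings = [np.zeros((x.shape[1], A)) for x in Xb]
        block_evr = np.zeros((B, A))
        overall_evr = np.zeros(A)

        for a in range(A):
            # start from the single column with the largest SS across blocks
            best = max(((b, j) for b in range(B)
                        for j in range(Xb[b].shape[1])),
                       key=lambda bj: float((Xb[bj[0]][:, bj[1]] ** 2).sum()))
            t_T = Xb[best[0]][:, best[1]].copy()
            if not np.any(t_T):
                t_T = np.ones(n)
            converged = False
            for _ in range(self.max_iter):
                T_blk = np.empty((n, B))
                for b in range(B):
                    p_b = Xb[b].T @ t_T / (t_T @ t_T)
                    nrm = np.linalg.norm(p_b)
                    if nrm > 0:
                        p_b /= nrm
                    T_blk[:, b] = Xb[b] @ p_b
                    block_loadings[b][:, a] = p_b
                w_T = T_blk.T @ t_T / (t_T @ t_T)
                w_T /= np.linalg.norm(w_T)
                t_new = T_blk @ w_T
                if np.linalg.norm(t_new - t_T) <= self.tol * np.linalg.norm(
                        t_new):
                    t_T = t_new
                    super_weights[:, a] = w_T
                    for b in range(B):
                        block_scores[b][:, a] = T_blk[:, b]
                    converged = True
                    break
                t_T = t_new
                super_weights[:, a] = w_T
                for b in range(B):
                    block_scores[b][:, a] = T_blk[:, b]
            if not converged:
                warnings.warn(f"consensus PCA component {a + 1} did not "
                              f"converge in {self.max_iter} iterations",
                              RuntimeWarning, stacklevel=2)
            # sign convention: largest |entry| of the effective concatenated
            # loading (w_b * p_b stacked) positive
            eff = np.concatenate([super_weights[b, a] * block_loadings[b][:, a]
                                  for b in range(B)])
            if eff[int(np.argmax(np.abs(eff)))] < 0:
                t_T = -t_T
                super_weights[:, a] *= -1
                for b in range(B):
                    block_loadings[b][:, a] *= -1
                    block_scores[b][:, a] *= -1
            super_scores[:, a] = t_T
            for b in range(B):
                pb_defl = Xb[b].T @ t_T / (t_T @ t_T)
                explained = float(t_T @ t_T) * float(pb_defl @ pb_defl)
                if block_ss[b] > 0:
                    block_evr[b, a] = explained / block_ss[b]
                overall_evr[a] += explained / total_ss if total_ss > 0 else 0.0
                Xb[b] -= np.outer(t_T, pb_defl)

        return ConsensusPCAResults(
            model=self, super_scores=super_scores,
            super_weights=super_weights, block_scores=block_scores,
            block_loadings=block_loadings,
            block_explained_variance=block_evr,
            explained_variance_ratio=overall_evr)


@dataclass
class ConsensusPCAResults:
    """Super scores/weights plus per-block scores and loadings."""

    model: ConsensusPCA
    super_scores: np.ndarray            # n x A
    super_weights: np.ndarray           # B x A, unit-norm columns
    block_scores: list[np.ndarray]      # per block, n x A
    block_loadings: list[np.ndarray]    # per block, p_b x A
    block_explained_variance: np.ndarray  # B x A fractions of block SS
    explained_variance_ratio: np.ndarray  # overall, length A

    @property
    def block_names(self) -> list[str]:
        return [b.name for b in self.model.blocks]

    def super_scores_frame(self) -> pd.DataFrame:
        cols = [f"t{a + 1}" for a in range(self.super_scores.shape[1])]
        return pd.DataFrame(self.super_scores,
                            index=self.model.matrix.sample_ids, columns=cols)

    def super_weights_frame(self) -> pd.DataFrame:
        cols = [f"t{a + 1}" for a in range(self.super_weights.shape[1])]
        return pd.DataFrame(self.super_weights, index=self.block_names,
                            columns=cols)

    def summary(self) -> str:
        A = self.super_scores.shape[1]
        lines = [
            f"Consensus PCA ({len(self.block_names)} blocks, "
            f"{A} components)",
            "  block weights per component:",
        ]
        for b, name in enumerate(self.block_names):
            ws = "  ".join(f"{self.super_weights[b, a]:+0.3f}"
                           for a in range(A))
            lines.append(f"    {name:<12} {ws}")
        evr = "  ".join(f"{v:0.3f}" for v in self.explained_variance_ratio)
        lines.append(f"  overall R2X per component: {evr}")
        return "\n".join(lines)
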