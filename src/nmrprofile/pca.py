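"""Principal components analysis by NIPALS, with the outlier workflow.

NIPALS (nonlinear iterative partial least squares) extracts components one
at a time by power iteration with deflation.  It is the conventional
chemometrics algorithm and composes naturally with the interactive
exclude-refit-reproject loop: a sample flagged by its Hotelling T² distance
can be dropped, the model refit on the retained samples, and the dropped
sample projected back in to judge the effect of its removal.

Usage follows the Model/Results convention::

    model = PCA(matrix, n_components=3)
    res = model.fit()
    res.scores, res.loadings, res.explained_variance_ratio
    report = res.hotelling_outliers(alpha=0.05)
    new_scores = res.project(other_matrix)
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import SpectraMatrix

__all__ = ["PCA", "PCAResults", "OutlierReport", "refit_excluding"]

logger = logging.getLogger("nmrprofile.pca")


def _fix_sign(p: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Make the largest-|value| loading entry positive (reproducible plots)."""
    k = int(np.argmax(np.abs(p)))
    if p[k] < 0:
        return -p, -t
    return p, t


def nipals(X: np.ndarray, n_components: int, tol: float = 1e-10,
           max_iter: int = 500) -> tuple[np.ndarray, np.ndarray, float]:
    """Run NIPALS on an already centered/scaled matrix.

    Returns ``(T, P, total_ss)`` with scores T (n x A), loadings P (p x A,
    unit-norm columns) and the total sum of squares of the input.
    """
    X = np.array(X, dtype=float)
    n, p = X.shape
    if n_components > min(n, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(n, p)={min(n, p)}")
    total_ss = float((X ** 2).sum())
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    for a in range(n_components):
        start = int(np.argmax((X ** 2).sum(axis=0)))
        t = X[:, start].copy()
        if not np.any(t):
            t = np.ones(n)  # degenerate residual; component will be ~0
        converged = False
        for _ in range(max_iter):
            pa = X.T @ t / (t @ t)
            pa /= np.linalg.norm(pa)
            t_new = X @ pa
            if np.linalg.norm(t_new - t) <= tol * np.linalg.norm(t_new):
                t = t_new
                converged = True
                break
            t = t_new
        if not converged:
            warnings.warn(f"NIPALS component {a + 1} did not converge in "
                          f"{max_iter} iterations; using best iterate",
                          RuntimeWarning, stacklevel=2)
        pa = X.T @ t / (t @ t)
        pa /= np.linalg.norm(pa)
        t = X @ pa
        pa, t = _fix_sign(pa, t)
        T[:, a], P[:, a] = t, pa
        X -= np.outer(t, pa)
    return T, P, total_ss


@dataclass
class OutlierReport:
    t2: pd.Series           # per-sample Hotelling T²
    limit: float            # critical value at the chosen alpha
    flagged: list[str]      # sample ids with t2 > limit
    alpha: float


class PCA:
    """NIPALS PCA model of a :class:`SpectraMatrix` (or plain array).

    Parameters
    ----------
    matrix : SpectraMatrix or ndarray
        Sample-by-variable data.  Centering is applied internally by
        default; pass ``center=False`` for data already centered upstream.
    n_components : int
        Number of components, at most ``min(n - 1, p)`` with centering.
    """

    def __init__(self, matrix: SpectraMatrix | np.ndarray, n_components: int,
                 *, center: bool = True, tol: float = 1e-10,
                 max_iter: int = 500):
        if isinstance(matrix, SpectraMatrix):
            self.sample_ids = list(matrix.sample_ids)
            self.ppm_grid = matrix.ppm_grid.copy()
            X = matrix.X
        else:
            X = np.asarray(matrix, dtype=float)
            self.sample_ids = [f"s{i}" for i in range(X.shape[0])]
            self.ppm_grid = None
        self.X_raw = np.array(X, dtype=float)
        self.n_components = int(n_components)
        self.center = bool(center)
        self.tol = float(tol)
        self.max_iter = int(max_iter)
        n, p = self.X_raw.shape
        limit = min(n - 1, p) if center else min(n, p)
        if self.n_components > limit:
            raise ValueError(f"n_components={n_components} exceeds {limit}")

    def fit(self) -> "PCAResults":
        centers = (self.X_raw.mean(axis=0) if self.center
                   else np.zeros(self.X_raw.shape[1]))
        Xc = self.X_raw - centers
        T, P, total_ss = nipals(Xc, self.n_components, self.tol,
                                self.max_iter)
        evr = (T ** 2).sum(axis=0) / total_ss if total_ss > 0 else \
            np.zeros(self.n_components)
        return PCAResults(model=self, centers=centers, scores_=T, loadings_=P,
                          explained_variance_ratio=evr, total_ss=total_ss)


@dataclass
class PCAResults:
    """Fitted PCA: scores, loadings, explained variance, projections."""

    model: PCA
    centers: np.ndarray
    scores_: np.ndarray                 # n x A
    loadings_: np.ndarray               # p x A, orthonormal columns
    explained_variance_ratio: np.ndarray
    total_ss: float

    @property
    def sample_ids(self) -> list[str]:
        return self.model.sample_ids

    @property
    def n_components(self) -> int:
        return self.model.n_components

    @property
    def scores(self) -> pd.DataFrame:
        cols = [f"t{a + 1}" for a in range(self.n_components)]
        return pd.DataFrame(self.scores_, index=self.sample_ids, columns=cols)

    @property
    def loadings(self) -> pd.DataFrame:
        cols = [f"p{a + 1}" for a in range(self.n_components)]
        idx = (self.model.ppm_grid if self.model.ppm_grid is not None
               else np.arange(self.loadings_.shape[0]))
        return pd.DataFrame(self.loadings_, index=idx, columns=cols)

    def project(self, new: SpectraMatrix | np.ndarray) -> np.ndarray:
        """Project new samples (same ppm grid) into the model: T = X_c P."""
        if isinstance(new, SpectraMatrix):
            if self.model.ppm_grid is not None and (
                    len(new.ppm_grid) != len(self.model.ppm_grid)
                    or not np.allclose(new.ppm_grid, self.model.ppm_grid)):
                mism = _first_mismatch(self.model.ppm_grid, new.ppm_grid)
                raise ValueError(f"ppm grid mismatch at {mism}")
            Xn = new.X
        else:
            Xn = np.asarray(new, dtype=float)
        one_d = Xn.ndim == 1
        Xn = np.atleast_2d(Xn)
        if Xn.shape[1] != len(self.centers):
            raise ValueError(f"expected {len(self.centers)} variables, "
                             f"got {Xn.shape[1]}")
        T = (Xn - self.centers) @ self.loadings_
        return T[0] if one_d else T

    def hotelling_t2(self) -> pd.Series:
        """Hotelling T² per training sample from the score variances."""
        lam = self.scores_.var(axis=0, ddof=1)
        if np.any(lam <= 0):
            raise ValueError("zero-variance score component; reduce "
                             "n_components")
        t2 = ((self.scores_ ** 2) / lam).sum(axis=1)
        return pd.Series(t2, index=self.sample_ids, name="T2")

    def hotelling_limit(self, alpha: float = 0.05) -> float:
        """F-distribution critical value for the T² ellipse at 1 - alpha."""
        n, A = self.scores_.shape
        if n <= A:
            raise ValueError(f"need n > n_components ({n} <= {A})")
        f_crit = stats.f.ppf(1.0 - alpha, A, n - A)
        return A * (n - 1) * (n + 1) / (n * (n - A)) * f_crit

    def hotelling_outliers(self, alpha: float = 0.05) -> OutlierReport:
        t2 = self.hotelling_t2()
        limit = self.hotelling_limit(alpha)
        flagged = list(t2.index[t2 > limit])
        return OutlierReport(t2=t2, limit=float(limit), flagged=flagged,
                             alpha=alpha)

    def summary(self) -> str:
        n, A = self.scores_.shape
        lines = [
            "PCA (NIPALS)",
            f"  samples: {n}   variables: {self.loadings_.shape[0]}   "
            f"components: {A}",
            "  comp   R2X    cumulative",
        ]
        cum = 0.0
        for a, r in enumerate(self.explained_variance_ratio, start=1):
            cum += r
            lines.append(f"  {a:>4}   {r:0.3f}  {cum:0.3f}")
        return "\n".join(lines)


def _first_mismatch(a: np.ndarray, b: np.ndarray) -> str:
    if len(a) != len(b):
        return f"length ({len(a)} vs {len(b)})"
    i = int(np.argmax(~np.isclose(a, b)))
    return f"index {i} ({a[i]} vs {b[i]})"


def refit_excluding(matrix: SpectraMatrix, excluded_ids: list[str],
                    n_components: int, **kwargs
                    ) -> tuple[PCAResults, pd.DataFrame]:
    """Refit on the retained samples and reproject the excluded ones.

    Returns the new results and a DataFrame of projected scores for the
    excluded samples, evaluating the impact of their removal.
    """
    unknown = [s for s in excluded_ids if s not in matrix.sample_ids]
    if unknown:
        raise KeyError(f"excluded ids not in matrix: {unknown}")
    retained = matrix.drop(excluded_ids)
    if retained.n_samples < n_components + 1:
        raise ValueError(
            f"only {retained.n_samples} samples remain; need at least "
            f"{n_components + 1}")
    res = PCA(retained, n_components, **kwargs).fit()
    cols = [f"t{a + 1}" for a in range(n_components)]
    if excluded_ids:
        proj = res.project(matrix.subset(list(excluded_ids)))
        proj_df = pd.DataFrame(proj, index=list(excluded_ids), columns=cols)
    else:
        proj_df = pd.DataFrame(np.empty((0, n_components)), columns=cols)
    return res, proj_df
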