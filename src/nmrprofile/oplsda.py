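"""Orthogonal projections to latent structures discriminant analysis.

OPLS-DA splits the X-variation of a two-class problem into a single
y-predictive component and ``n_orth`` components orthogonal to y.  The
orthogonal filter removes structured variation (instrumental drift, diet,
within-class physiology) that would otherwise rotate the predictive
direction, so the predictive loading reads directly as the between-class
spectral signature.

Algorithm (per orthogonal component, on centered/scaled X and centered y):

1. ``w = X'y / (y'y)``, normalized — the PLS1 weight.
2. ``t = Xw``; ``p = X't / (t't)``.
3. ``w_o = p - (w'p) w``, normalized — the part of p orthogonal to w.
4. ``t_o = X w_o``; ``p_o = X't_o / (t_o't_o)``; deflate
   ``X <- X - t_o p_o'``.

The final predictive component is the PLS1 component of the deflated X;
``y_hat = q * t_pred + y_mean`` with ``q = y't_pred / (t_pred't_pred)``.
Class membership of new samples is the sign of ``y_hat`` under the -1/+1
coding.  With ``n_orth=0`` the model reduces exactly to PLS1's first
component.

Multiclass problems are handled one-vs-rest with argmax-``y_hat``
assignment (:class:`OneVsRestOPLSDA`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import AnnotationTable, SpectraMatrix

__all__ = ["OPLSDA", "OPLSDAResults", "PredictionResult", "OneVsRestOPLSDA",
           "cross_validate"]

logger = logging.getLogger("nmrprofile.oplsda")


def _as_array(matrix: SpectraMatrix | np.ndarray) -> np.ndarray:
    return matrix.X if isinstance(matrix, SpectraMatrix) else \
        np.asarray(matrix, dtype=float)


def _encode_labels(labels: np.ndarray) -> tuple[np.ndarray, tuple[str, str]]:
    """Code the lexicographically first class as -1, the second as +1."""
    uniq = sorted(set(map(str, labels)))
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 classes, got {uniq}")
    y = np.where(np.asarray(list(map(str, labels))) == uniq[0], -1.0, 1.0)
    return y, (uniq[0], uniq[1])


@dataclass
class PredictionResult:
    """Projected scores, predicted responses and class calls for new data."""

    t_pred: np.ndarray
    t_orth: np.ndarray          # n x n_orth
    y_hat: np.ndarray
    predicted_class: list[str]

    def to_frame(self, sample_ids: list[str] | None = None) -> pd.DataFrame:
        n = len(self.y_hat)
        idx = sample_ids if sample_ids is not None else list(range(n))
        df = pd.DataFrame({"t_pred": self.t_pred, "y_hat": self.y_hat,
                           "predicted_class": self.predicted_class},
                          index=idx)
        for j in range(self.t_orth.shape[1]):
            df[f"t_orth{j + 1}"] = self.t_orth[:, j]
        return df


class OPLSDA:
    """Two-class OPLS-DA model.

    Parameters
    ----------
    matrix : SpectraMatrix or ndarray
        Training data; centered internally by default (means stored for
        prediction).  Apply any normalization/scaling upstream.
    y : array of class labels, or ±1 floats
    n_orth : int
        Number of y-orthogonal components (default 1).
    """

    def __init__(self, matrix: SpectraMatrix | np.ndarray, y, *,
                 n_orth: int = 1, center: bool = True):
        X = _as_array(matrix)
        if isinstance(matrix, SpectraMatrix):
            self.sample_ids = list(matrix.sample_ids)
            self.ppm_grid = matrix.ppm_grid.copy()
        else:
            self.sample_ids = [f"s{i}" for i in range(X.shape[0])]
            self.ppm_grid = None
        y = np.asarray(y)
        if y.dtype.kind in "OUS":
            y_num, class_labels = _encode_labels(y)
        else:
            y_num = np.asarray(y, dtype=float)
            vals = sorted(set(y_num))
            if vals == [-1.0, 1.0]:
                class_labels = ("-1", "+1")
            else:
                raise ValueError("numeric y must be coded -1/+1 with both "
                                 "classes present")
        if len(set(y_num)) < 2:
            raise ValueError("y contains a single class")
        if len(y_num) != X.shape[0]:
            raise ValueError("y length does not match number of samples")
        if n_orth < 0:
            raise ValueError("n_orth must be >= 0")
        if n_orth >= min(X.shape):
            raise ValueError(f"n_orth={n_orth} too large for data of shape "
                             f"{X.shape}")
        self.X_raw = np.array(X, dtype=float)
        self.y = y_num
        self.class_labels = class_labels
        self.n_orth = int(n_orth)
        self.center = bool(center)

    def fit(self) -> "OPLSDAResults":
        centers = (self.X_raw.mean(axis=0) if self.center
                   else np.zeros(self.X_raw.shape[1]))
        X = self.X_raw - centers
        y_mean = float(self.y.mean()) if self.center else 0.0
        y = self.y - y_mean
        total_ss_x = float((X ** 2).sum())
        ss_y = float((y ** 2).sum())

        n, p = X.shape
        W_o = np.zeros((p, self.n_orth))
        P_o = np.zeros((p, self.n_orth))
        T_o = np.zeros((n, self.n_orth))
        r2x_orth = 0.0
        for j in range(self.n_orth):
            w = X.T @ y / (y @ y)
            w /= np.linalg.norm(w)
            t = X @ w
            pl = X.T @ t / (t @ t)
            w_o = pl - (w @ pl) * w
            norm_wo = np.linalg.norm(w_o)
            if norm_wo < 1e-12:
                logger.warning("orthogonal component %d is degenerate "
                               "(no y-orthogonal structure left)", j + 1)
                W_o = W_o[:, :j]; P_o = P_o[:, :j]; T_o = T_o[:, :j]
                break
            w_o /= norm_wo
            t_o = X @ w_o
            p_o = X.T @ t_o / (t_o @ t_o)
            X = X - np.outer(t_o, p_o)
            W_o[:, j], P_o[:, j], T_o[:, j] = w_o, p_o, t_o
            r2x_orth += float(t_o @ t_o) * float(p_o @ p_o) / total_ss_x

        w = X.T @ y / (y @ y)
        w /= np.linalg.norm(w)
        t_pred = X @ w
        p_pred = X.T @ t_pred / (t_pred @ t_pred)
        q = float(y @ t_pred / (t_pred @ t_pred))
        r2y = 1.0 - float(((y - q * t_pred) ** 2).sum()) / ss_y
        r2x_pred = float(t_pred @ t_pred) * float(p_pred @ p_pred) / total_ss_x

        return OPLSDAResults(
            model=self, centers=centers, y_mean=y_mean, w=w, t_pred=t_pred,
            p_pred=p_pred, q=q, W_o=W_o, P_o=P_o, T_o=T_o, r2y=r2y,
            r2x_pred=r2x_pred, r2x_orth=r2x_orth)


@dataclass
class OPLSDAResults:
    """Fitted OPLS-DA model parameters and diagnostics."""

    model: OPLSDA
    centers: np.ndarray
    y_mean: float
    w: np.ndarray               # predictive weights, unit norm
    t_pred: np.ndarray
    p_pred: np.ndarray
    q: float                    # scalar y-loading
    W_o: np.ndarray             # p x k orthogonal weights, unit-norm columns
    P_o: np.ndarray
    T_o: np.ndarray
    r2y: float
    r2x_pred: float
    r2x_orth: float
    q2: float | None = field(default=None)

    @property
    def class_labels(self) -> tuple[str, str]:
        return self.model.class_labels

    @property
    def n_orth(self) -> int:
        return self.W_o.shape[1]

    def predict(self, new: SpectraMatrix | np.ndarray) -> PredictionResult:
        """Orthogonal-filter new samples, then score and classify them."""
        if isinstance(new, SpectraMatrix):
            if self.model.ppm_grid is not None and (
                    len(new.ppm_grid) != len(self.model.ppm_grid)
                    or not np.allclose(new.ppm_grid, self.model.ppm_grid)):
                raise ValueError("ppm grid mismatch between model and data")
            Xn = new.X
        else:
            Xn = np.atleast_2d(np.asarray(new, dtype=float))
        X = Xn - self.centers
        t_orth = np.zeros((X.shape[0], self.n_orth))
        for j in range(self.n_orth):
            t_o = X @ self.W_o[:, j]
            X = X - np.outer(t_o, self.P_o[:, j])
            t_orth[:, j] = t_o
        t = X @ self.w
        y_hat = self.q * t + self.y_mean
        neg, pos = self.class_labels
        # exact ties go to the lexicographically first label
        labels = [pos if v > 0 else neg for v in y_hat]
        ties = int(np.sum(y_hat == 0))
        if ties:
            logger.info("%d samples with y_hat exactly 0 assigned to %r",
                        ties, neg)
        return PredictionResult(t_pred=t, t_orth=t_orth, y_hat=y_hat,
                                predicted_class=labels)

    def loading_decomposition(self) -> pd.DataFrame:
        """Per-variable predictive vs orthogonal loadings, ranked by |p_pred|."""
        idx = (self.model.ppm_grid if self.model.ppm_grid is not None
               else np.arange(len(self.p_pred)))
        df = pd.DataFrame({"ppm": idx, "p_pred": self.p_pred})
        for j in range(self.n_orth):
            df[f"p_orth{j + 1}"] = self.P_o[:, j]
        order = np.argsort(-np.abs(self.p_pred), kind="stable")
        ranks = np.empty(len(order), dtype=int)
        ranks[order] = np.arange(1, len(order) + 1)
        df["rank"] = ranks
        return df

    def summary(self) -> str:
        lines = [
            "OPLS-DA (1 predictive + "
            f"{self.n_orth} orthogonal component{'s' if self.n_orth != 1 else ''})",
            f"  classes: {self.class_labels[0]} (-1) vs "
            f"{self.class_labels[1]} (+1)",
            f"  R2Y = {self.r2y:0.4f}   R2X(pred) = {self.r2x_pred:0.4f}   "
            f"R2X(orth) = {self.r2x_orth:0.4f}",
        ]
        if self.q2 is not None:
            lines.append(f"  Q2 (cross-validated) = {self.q2:0.4f}")
        return "\n".join(lines)


def _stratified_folds(y: np.ndarray, folds: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    """Index partition with each class spread as evenly as possible."""
    assignments = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        rng.shuffle(idx)
        for k, i in enumerate(idx):
            assignments[i] = k % folds
    return [np.nonzero(assignments == f)[0] for f in range(folds)]


def cross_validate(matrix: SpectraMatrix | np.ndarray, y, *, n_orth: int = 1,
                   folds: int = 7, seed: int = 0) -> float:
    """Stratified k-fold cross-validated Q² = 1 - PRESS / SS_y.

    PRESS accumulates squared prediction errors of held-out samples; SS_y is
    the total sum of squares of y about its mean.  Deterministic given
    *seed*.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = _as_array(matrix)
    y_arr = np.asarray(y)
    if y_arr.dtype.kind in "OUS":
        y_num, _ = _encode_labels(y_arr)
    else:
        y_num = np.asarray(y_arr, dtype=float)
    counts = [int((y_num == v).sum()) for v in np.unique(y_num)]
    if min(counts) < folds:
        raise ValueError(f"smallest class has {min(counts)} samples; "
                         f"cannot stratify into {folds} folds")
    rng = np.random.default_rng(seed)
    press = 0.0
    for test_idx in _stratified_folds(y_num, folds, rng):
        train_idx = np.setdiff1d(np.arange(len(y_num)), test_idx)
        res = OPLSDA(X[train_idx], y_num[train_idx], n_orth=n_orth).fit()
        pred = res.predict(X[test_idx])
        press += float(((y_num[test_idx] - pred.y_hat) ** 2).sum())
    ss_y = float(((y_num - y_num.mean()) ** 2).sum())
    return 1.0 - press / ss_y


class OneVsRestOPLSDA:
    """Multiclass OPLS-DA: one binary model per class, argmax-y_hat calls."""

    def __init__(self, matrix: SpectraMatrix | np.ndarray, labels, *,
                 n_orth: int = 1):
        self.labels = np.asarray(list(map(str, labels)))
        self.classes = sorted(set(self.labels))
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")
        self.matrix = matrix
        self.n_orth = n_orth

    def fit(self) -> "OneVsRestOPLSDA":
        self.results_: dict[str, OPLSDAResults] = {}
        X = _as_array(self.matrix)
        for cls in self.classes:
            # target class coded +1, rest -1
            y = np.where(self.labels == cls, 1.0, -1.0)
            self.results_[cls] = OPLSDA(X, y, n_orth=self.n_orth).fit()
        return self

    def predict(self, new: SpectraMatrix | np.ndarray) -> list[str]:
        scores = np.column_stack([self.results_[c].predict(new).y_hat
                                  for c in self.classes])
        return [self.classes[i] for i in np.argmax(scores, axis=1)]


def labels_from_annotations(matrix: SpectraMatrix,
                            annotations: AnnotationTable) -> np.ndarray:
    """Class labels aligned to the matrix's sample order."""
    return np.asarray([annotations.class_of(s) for s in matrix.sample_ids])
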