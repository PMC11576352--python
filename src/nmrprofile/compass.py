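"""Reference-pattern matching across a cohort (COMPASS-style).

A user picks a clean, well-resolved multiplet in one high-quality spectrum;
that window becomes a template which is slid over every spectrum within a
small shift tolerance (pH and ionic strength move peaks by a few points).
The match statistic is the Pearson correlation between template and window,
which is invariant to per-sample intensity scale and baseline offset, so a
threshold on it cleanly separates "contains the pattern" from "does not",
independent of abundance.  Samples that contain the pattern are then ranked
by matched-window intensity — a relative-abundance ordering.

Iterating with STOCSY sharpens the template: the matched subset is
correlated at the template apex to reveal the compound's other resonances,
and the template is re-estimated as the lag-aligned mean of the matched
windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stocsy import StocsyResult, stocsy
from .types import SpectraMatrix

__all__ = ["ReferencePattern", "CompassResult", "extract_reference",
           "compass_match", "compass_stocsy_iterate"]

logger = logging.getLogger("nmrprofile.compass")

#: Default match threshold on the best lag-scanned Pearson correlation.
DEFAULT_THRESHOLD = 0.8


@dataclass
class ReferencePattern:
    source_sample: str
    ppm_window: tuple[float, float]     # (hi, lo)
    template: np.ndarray                # mean-subtracted intensities
    window_indices: tuple[int, int]     # [start, stop) on the grid

    def __post_init__(self) -> None:
        self.template = np.asarray(self.template, dtype=float)
        if len(self.template) < 5:
            raise ValueError("reference pattern needs at least 5 points")
        if np.ptp(self.template) == 0:
            raise ValueError("no pattern in window (constant template)")

    @property
    def apex_offset(self) -> int:
        """Index of the template maximum within the window."""
        return int(np.argmax(self.template))


@dataclass
class CompassResult:
    sample_ids: list[str]
    best_correlation: np.ndarray
    best_shift: np.ndarray              # grid points, int
    matched_intensity: np.ndarray       # max raw intensity in matched window
    contains_pattern: np.ndarray        # bool
    threshold: float
    max_shift_points: int

    @property
    def n_containing(self) -> int:
        return int(self.contains_pattern.sum())

    @property
    def ranking(self) -> list[str]:
        """Pattern-containing samples, most intense matched window first."""
        idx = np.nonzero(self.contains_pattern)[0]
        order = idx[np.argsort(-self.matched_intensity[idx], kind="stable")]
        return [self.sample_ids[i] for i in order]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "best_correlation": self.best_correlation,
            "best_shift": self.best_shift,
            "matched_intensity": self.matched_intensity,
            "contains_pattern": self.contains_pattern,
        }, index=self.sample_ids)


def extract_reference(matrix: SpectraMatrix, sample_id: str,
                      ppm_hi: float, ppm_lo: float) -> ReferencePattern:
    """Cut a mean-subtracted template from one sample's [ppm_hi, ppm_lo]."""
    if not ppm_hi > ppm_lo:
        raise ValueError("ppm_hi must exceed ppm_lo")
    cols = np.nonzero((matrix.ppm_grid <= ppm_hi)
                      & (matrix.ppm_grid >= ppm_lo))[0]
    if len(cols) < 5:
        raise ValueError(f"window [{ppm_hi}, {ppm_lo}] covers only "
                         f"{len(cols)} grid points; need at least 5")
    start, stop = int(cols[0]), int(cols[-1]) + 1
    segment = matrix.row(sample_id)[start:stop]
    return ReferencePattern(source_sample=sample_id,
                            ppm_window=(ppm_hi, ppm_lo),
                            template=segment - segment.mean(),
                            window_indices=(start, stop))


def _lag_order(max_shift: int) -> list[int]:
    """0, -1, +1, -2, +2, ... — ties resolve to smallest |lag|, then negative."""
    lags = [0]
    for k in range(1, max_shift + 1):
        lags += [-k, k]
    return lags


def compass_match(matrix: SpectraMatrix, pattern: ReferencePattern,
                  max_shift_points: int = 3,
                  threshold: float = DEFAULT_THRESHOLD) -> CompassResult:
    """Scan the template over every sample within ±max_shift_points.

    best_correlation is the maximum Pearson r over integer lags; windows
    with zero variance correlate at 0.  A sample contains the pattern when
    its best correlation reaches *threshold*.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if max_shift_points < 0:
        raise ValueError("max_shift_points must be >= 0")
    start, stop = pattern.window_indices
    p = matrix.n_variables
    lo_ok = -start
    hi_ok = p - stop
    if -max_shift_points < lo_ok or max_shift_points > hi_ok:
        raise ValueError(
            f"window plus shift leaves the grid; admissible shifts are "
            f"[{lo_ok}, {hi_ok}] grid points")
    tpl = pattern.template - pattern.template.mean()
    tpl_norm = np.linalg.norm(tpl)
    n = matrix.n_samples
    best_r = np.full(n, -np.inf)
    best_lag = np.zeros(n, dtype=int)
    for lag in _lag_order(max_shift_points):
        win = matrix.X[:, start + lag:stop + lag]
        wc = win - win.mean(axis=1, keepdims=True)
        denom = np.linalg.norm(wc, axis=1) * tpl_norm
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, wc @ tpl / denom, 0.0)
        better = r > best_r  # strict: earlier lags win ties
        best_r[better] = r[better]
        best_lag[better] = lag
    best_r = np.clip(best_r, -1.0, 1.0)
    matched = np.array([matrix.X[i, start + best_lag[i]:stop + best_lag[i]]
                        .max() for i in range(n)])
    contains = best_r >= threshold
    return CompassResult(sample_ids=list(matrix.sample_ids),
                         best_correlation=best_r, best_shift=best_lag,
                         matched_intensity=matched,
                         contains_pattern=contains, threshold=threshold,
                         max_shift_points=max_shift_points)


def compass_stocsy_iterate(matrix: SpectraMatrix, pattern: ReferencePattern,
                           max_shift_points: int = 3,
                           threshold: float = DEFAULT_THRESHOLD
                           ) -> tuple[CompassResult, StocsyResult,
                                      ReferencePattern]:
    """One COMPASS -> STOCSY -> template-refinement step.

    The matched subset is STOCSY-driven at the template apex; the refined
    template is the mean of the matched, lag-aligned windows.  Callers loop
    until the containing count stabilizes.
    """
    result = compass_match(matrix, pattern, max_shift_points, threshold)
    if result.n_containing == 0:
        raise ValueError("no samples match the pattern; lower the threshold")
    matched_ids = [s for s, c in zip(result.sample_ids,
                                     result.contains_pattern) if c]
    subset = matrix.subset(matched_ids)
    start, stop = pattern.window_indices
    apex_ppm = float(matrix.ppm_grid[start + pattern.apex_offset])
    sub_stocsy = stocsy(subset, apex_ppm)
    aligned = np.array([
        matrix.X[matrix.index_of(s),
                 start + result.best_shift[i]:stop + result.best_shift[i]]
        for i, s in zip(np.nonzero(result.contains_pattern)[0], matched_ids)
    ])
    mean_window = aligned.mean(axis=0)
    refined = ReferencePattern(
        source_sample=f"refined({pattern.source_sample})",
        ppm_window=pattern.ppm_window,
        template=mean_window - mean_window.mean(),
        window_indices=pattern.window_indices)
    return result, sub_stocsy, refined
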