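"""Statistical Total Correlation Spectroscopy (STOCSY).

Peaks belonging to one molecule vary together across samples (their
intensities are proportional to the same concentration), so correlating one
"driver" variable against every other variable lights up all resonances of
the driver's molecule with correlations near 1, plus weaker correlations to
metabolically related compounds.  Covariance is reported alongside because
it retains intensity units, giving the familiar pseudo-spectrum display.

STOCSY is conventionally run on the normalized-but-unscaled matrix so the
covariance trace resembles a lineshape; it works on scaled data too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .types import SpectraMatrix

__all__ = ["StocsyResult", "stocsy", "rank_variables"]

logger = logging.getLogger("nmrprofile.stocsy")


@dataclass
class StocsyResult:
    driver_ppm: float           # snapped grid position actually used
    driver_index: int
    correlation: np.ndarray     # Pearson r, length p
    covariance: np.ndarray      # n-1 denominator, length p
    ppm_grid: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"ppm": self.ppm_grid,
                             "correlation": self.correlation,
                             "covariance": self.covariance})


def stocsy(matrix: SpectraMatrix, driver_ppm: float) -> StocsyResult:
    """Correlate the variable nearest *driver_ppm* against all variables.

    Zero-variance columns get correlation 0 by convention (logged);
    a constant driver column raises, suggesting the nearest usable one.
    """
    if matrix.n_samples < 3:
        raise ValueError("STOCSY needs at least 3 samples")
    d = matrix.nearest_index(driver_ppm)
    snapped = float(matrix.ppm_grid[d])
    if abs(snapped - driver_ppm) > 0:
        logger.info("driver %.4f ppm snapped to grid point %.4f ppm",
                    driver_ppm, snapped)
    X = matrix.X
    n = matrix.n_samples
    Xc = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if sd[d] == 0:
        usable = np.nonzero(sd > 0)[0]
        if len(usable):
            nearest = usable[np.argmin(np.abs(matrix.ppm_grid[usable]
                                              - snapped))]
            raise ValueError(
                f"driver column at {snapped} ppm is constant; nearest "
                f"non-constant variable is {matrix.ppm_grid[nearest]} ppm")
        raise ValueError("driver column is constant and no non-constant "
                         "variable exists")
    cov = Xc[:, d] @ Xc / (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(sd > 0, cov / (sd[d] * sd), 0.0)
    n_zero = int((sd == 0).sum())
    if n_zero:
        logger.info("%d zero-variance columns assigned correlation 0", n_zero)
    corr = np.clip(corr, -1.0, 1.0)
    return StocsyResult(driver_ppm=snapped, driver_index=d,
                        correlation=corr, covariance=cov,
                        ppm_grid=matrix.ppm_grid.copy())


def rank_variables(matrix: SpectraMatrix,
                   statistic: Literal["median", "mean", "max"] = "median"
                   ) -> pd.DataFrame:
    """Rank ppm variables by a per-column intensity statistic, descending.

    Ties break by descending ppm, so the ordering is deterministic.  Used
    to judge which signals are most abundant across the cohort.
    """
    if matrix.n_variables == 0:
        raise ValueError("empty matrix")
    func = {"median": np.median, "mean": np.mean, "max": np.max}[statistic]
    values = func(matrix.X, axis=0)
    # sort by (-value, -ppm); lexsort uses the last key as primary
    order = np.lexsort((-matrix.ppm_grid, -values))
    return pd.DataFrame({"ppm": matrix.ppm_grid[order],
                         "value": values[order]},
                        index=pd.RangeIndex(1, len(order) + 1, name="rank"))
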