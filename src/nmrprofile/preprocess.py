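"""Region exclusion, normalization and variable scaling.

The pipeline order is fixed: exclusion -> normalization -> scaling, so that
excluded signal (e.g. the residual water resonance) never influences
dilution-factor estimates.  Every applied factor is recorded in the
:class:`PreprocessResult` so the processed matrix can be reproduced from the
raw data.

Normalization methods
---------------------
* ``total_area`` — each spectrum divided by its summed intensity over the
  retained region, rescaled to ``area_target``.
* ``pqn`` — probabilistic quotient normalization: after a total-area
  pre-normalization, each sample is divided by the median of its
  variable-wise quotients against the element-wise median spectrum.  This
  estimates a per-sample dilution factor robustly, the standard approach
  for urine where osmolality varies widely.

Scaling methods (variable-wise, sd with denominator n-1)
--------------------------------------------------------
``center`` (mean subtraction), ``uv`` (unit variance) and ``pareto``
(centered, divided by sqrt(sd) — damps the dominance of intense peaks
without amplifying baseline noise as much as uv does).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .types import SpectraMatrix

__all__ = ["PreprocessConfig", "PreprocessResult", "exclude_regions",
           "normalize_total_area", "normalize_pqn", "scale",
           "run_preprocess", "WATER_REGION"]

logger = logging.getLogger("nmrprofile.preprocess")

#: Default residual-water exclusion window (ppm_hi, ppm_lo); applied only
#: when explicitly requested.
WATER_REGION: tuple[float, float] = (4.90, 4.55)

Normalization = Literal["none", "total_area", "pqn"]
Scaling = Literal["none", "center", "uv", "pareto"]


@dataclass
class PreprocessConfig:
    excluded_regions: list[tuple[float, float]] = field(default_factory=list)
    normalization: Normalization = "none"
    area_target: float = 100.0
    scaling: Scaling = "none"

    def __post_init__(self) -> None:
        for hi, lo in self.excluded_regions:
            if not hi > lo:
                raise ValueError(f"region ({hi}, {lo}): ppm_hi must exceed ppm_lo")
        if self.area_target <= 0:
            raise ValueError("area_target must be positive")


@dataclass
class PreprocessResult:
    """Processed matrix plus the provenance needed to reproduce it."""

    matrix: SpectraMatrix
    dilution_factors: np.ndarray | None = None   # total divisor per sample
    quotient_factors: np.ndarray | None = None   # PQN quotient step only
    centers: np.ndarray | None = None
    scales: np.ndarray | None = None
    dropped_ppm: np.ndarray | None = None        # zero-variance columns


def exclude_regions(matrix: SpectraMatrix,
                    regions: list[tuple[float, float]]) -> SpectraMatrix:
    """Remove grid columns falling inside any closed [ppm_hi, ppm_lo] interval."""
    keep = np.ones(matrix.n_variables, dtype=bool)
    for hi, lo in regions:
        if not hi > lo:
            raise ValueError(f"region ({hi}, {lo}): ppm_hi must exceed ppm_lo")
        keep &= ~((matrix.ppm_grid <= hi) & (matrix.ppm_grid >= lo))
    if not keep.any():
        raise ValueError("all grid points excluded")
    return SpectraMatrix(list(matrix.sample_ids), matrix.ppm_grid[keep],
                         matrix.X[:, keep])


def normalize_total_area(matrix: SpectraMatrix,
                         area_target: float = 100.0) -> PreprocessResult:
    """Divide each row by its intensity sum and rescale to *area_target*."""
    if area_target <= 0:
        raise ValueError("area_target must be positive")
    sums = matrix.X.sum(axis=1)
    bad = np.nonzero(sums <= 0)[0]
    if len(bad):
        names = [matrix.sample_ids[i] for i in bad]
        raise ValueError(f"non-positive total intensity for samples: {names}")
    factors = sums / area_target
    X = matrix.X / factors[:, None]
    return PreprocessResult(
        matrix=SpectraMatrix(list(matrix.sample_ids), matrix.ppm_grid.copy(),
                             X),
        dilution_factors=factors)


def normalize_pqn(matrix: SpectraMatrix, *, area_target: float = 100.0,
                  reference: Literal["median_spectrum"] = "median_spectrum"
                  ) -> PreprocessResult:
    """Probabilistic quotient normalization against the median spectrum.

    A total-area normalization is always applied first so quotients are
    scale-free.  ``dilution_factors`` is the combined divisor applied to the
    input rows; ``quotient_factors`` is the median-quotient step alone.
    """
    if matrix.n_samples < 2:
        raise ValueError("PQN needs at least 2 samples")
    ta = normalize_total_area(matrix, area_target)
    X = ta.matrix.X
    ref = np.median(X, axis=0)
    usable = ref > 0
    if not usable.any():
        raise ValueError("median reference spectrum is all zeros")
    quotients = X[:, usable] / ref[usable]
    q_factors = np.median(quotients, axis=1)
    if np.any(q_factors <= 0):
        bad = [matrix.sample_ids[i] for i in np.nonzero(q_factors <= 0)[0]]
        raise ValueError(f"non-positive quotient factor for samples: {bad}")
    Xn = X / q_factors[:, None]
    return PreprocessResult(
        matrix=SpectraMatrix(list(matrix.sample_ids), matrix.ppm_grid.copy(),
                             Xn),
        dilution_factors=ta.dilution_factors * q_factors,
        quotient_factors=q_factors)


def scale(matrix: SpectraMatrix, method: Scaling) -> PreprocessResult:
    """Variable-wise scaling; zero-variance columns are dropped for uv/pareto."""
    if method == "none":
        return PreprocessResult(matrix=matrix)
    if matrix.n_samples < 2 and method in ("uv", "pareto"):
        raise ValueError(f"{method} scaling needs at least 2 samples")
    centers = matrix.X.mean(axis=0)
    if method == "center":
        return PreprocessResult(
            matrix=SpectraMatrix(list(matrix.sample_ids),
                                 matrix.ppm_grid.copy(),
                                 matrix.X - centers),
            centers=centers)
    sd = matrix.X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = matrix.ppm_grid[~keep]
    if len(dropped):
        logger.warning("dropping %d zero-variance columns under %s scaling: "
                       "%s", len(dropped), method, dropped)
    if not keep.any():
        raise ValueError("all columns have zero variance")
    scales = sd[keep] if method == "uv" else np.sqrt(sd[keep])
    X = (matrix.X[:, keep] - centers[keep]) / scales
    return PreprocessResult(
        matrix=SpectraMatrix(list(matrix.sample_ids), matrix.ppm_grid[keep],
                             X),
        centers=centers[keep], scales=scales,
        dropped_ppm=dropped if len(dropped) else None)


def run_preprocess(matrix: SpectraMatrix,
                   config: PreprocessConfig) -> PreprocessResult:
    """Apply exclusion -> normalization -> scaling and merge provenance."""
    m = exclude_regions(matrix, config.excluded_regions) \
        if config.excluded_regions else matrix
    dilution = quotient = None
    if config.normalization == "total_area":
        r = normalize_total_area(m, config.area_target)
        m, dilution = r.matrix, r.dilution_factors
    elif config.normalization == "pqn":
        r = normalize_pqn(m, area_target=config.area_target)
        m, dilution, quotient = r.matrix, r.dilution_factors, r.quotient_factors
    s = scale(m, config.scaling)
    return PreprocessResult(matrix=s.matrix, dilution_factors=dilution,
                            quotient_factors=quotient, centers=s.centers,
                            scales=s.scales, dropped_ppm=s.dropped_ppm)
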