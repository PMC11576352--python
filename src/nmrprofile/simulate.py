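"""Synthetic multi-class 1H-NMR cohort generator with known ground truth.

Each compound is a list of Lorentzian peaks (center ppm, relative
intensity) sharing one linewidth.  A sample's spectrum is the sum over
compounds of concentration x Lorentzian multiplet, where the Lorentzian

    L(v; mu, w) = (w/2)^2 / ((v - mu)^2 + (w/2)^2)

has unit apex, so an on-grid apex reads concentration x relative intensity
directly.  Per-sample base concentrations are log-uniform (biological
concentrations span decades), designated biomarkers get per-class
multiplicative effects, every sample carries one global chemical-shift
offset (pH/ionic-strength shifts move a spectrum coherently), and white
Gaussian noise is added per grid point.  Everything is driven by a single
seeded generator, so a dataset is bit-reproducible from its config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import AnnotationTable, SpectraMatrix

__all__ = ["CompoundSpec", "SimConfig", "SimDataset", "simulate_dataset",
           "render_spectrum", "builtin_library"]

logger = logging.getLogger("nmrprofile.simulate")


@dataclass
class CompoundSpec:
    """A compound as a peak list: (center_ppm, relative_intensity) pairs."""

    name: str
    peaks: list[tuple[float, float]]
    linewidth_ppm: float = 0.004

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError(f"compound {self.name!r} has no peaks")
        if any(rel <= 0 for _, rel in self.peaks):
            raise ValueError(f"compound {self.name!r}: relative intensities "
                             "must be positive")
        if self.linewidth_ppm <= 0:
            raise ValueError(f"compound {self.name!r}: linewidth must be "
                             "positive")

    @property
    def tallest_peak_ppm(self) -> float:
        return max(self.peaks, key=lambda pk: pk[1])[0]


@dataclass
class SimConfig:
    """Cohort design: classes, biomarkers, concentration ranges, noise."""

    compounds: list[CompoundSpec]
    n_classes: int = 2
    n_per_class: list[int] = field(default_factory=lambda: [20, 20])
    #: compound name -> per-class mean multipliers (length n_classes)
    biomarkers: dict[str, list[float]] = field(default_factory=dict)
    #: compound name -> (low, high) of the log-uniform base concentration
    conc_range: dict[str, tuple[float, float]] = field(default_factory=dict)
    default_conc_range: tuple[float, float] = (0.5, 2.0)
    shift_jitter_sd: float = 0.0
    noise_sd: float = 0.0
    grid: tuple[float, float, int] = (10.0, 0.0, 1000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if len(self.n_per_class) != self.n_classes:
            raise ValueError("n_per_class length must equal n_classes")
        names = {c.name for c in self.compounds}
        for name, mults in self.biomarkers.items():
            if name not in names:
                raise ValueError(f"biomarker {name!r} not among compounds")
            if len(mults) != self.n_classes:
                raise ValueError(f"biomarker {name!r}: need one multiplier "
                                 "per class")
            if any(m <= 0 for m in mults):
                raise ValueError(f"biomarker {name!r}: multipliers must be "
                                 "positive")
        for name, (lo, hi) in self.conc_range.items():
            if not 0 < lo < hi:
                raise ValueError(f"conc_range for {name!r}: need 0 < low < "
                                 "high")
        hi, lo, npts = self.grid
        if not hi > lo:
            raise ValueError("grid ppm_hi must exceed ppm_lo")
        if npts < 100:
            raise ValueError("grid needs at least 100 points")

    def class_names(self) -> list[str]:
        return [f"class{g + 1}" for g in range(self.n_classes)]


@dataclass
class SimDataset:
    """Generated cohort with its ground truth."""

    matrix: SpectraMatrix
    annotations: AnnotationTable
    truth: pd.DataFrame             # sample x compound concentrations
    truth_jitter: pd.Series         # per-sample global ppm offset
    config: SimConfig


def _lorentzian(grid: np.ndarray, center: float, width: float) -> np.ndarray:
    hw = width / 2.0
    return hw ** 2 / ((grid - center) ** 2 + hw ** 2)


def render_spectrum(grid: np.ndarray, compounds: list[CompoundSpec],
                    concentrations: list[float] | np.ndarray,
                    shift: float = 0.0) -> np.ndarray:
    """Noise-free spectrum of a compound mixture on *grid*.

    Additive by construction: the mixture spectrum is the sum of the
    single-compound spectra at the same shift offset.
    """
    spectrum = np.zeros(len(grid))
    for conc, comp in zip(concentrations, compounds, strict=True):
        for mu, rel in comp.peaks:
            spectrum += conc * rel * _lorentzian(grid, mu + shift,
                                                 comp.linewidth_ppm)
    return spectrum


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Generate a cohort; deterministic given ``config.seed``.

    Draw order is fixed (per sample: base concentrations over compounds in
    config order, then the shift offset; finally the noise field), so a
    given seed always yields a bit-identical dataset.
    """
    rng = np.random.default_rng(config.seed)
    hi, lo, npts = config.grid
    grid = np.linspace(hi, lo, npts)
    out_of_grid = [c.name for c in config.compounds
                   if any(not lo <= mu <= hi for mu, _ in c.peaks)]
    if out_of_grid:
        logger.warning("peaks outside the grid (tails truncated) for: %s",
                       out_of_grid)

    n_total = sum(config.n_per_class)
    classes = config.class_names()
    sample_ids, labels = [], []
    for g, cname in enumerate(classes):
        for k in range(config.n_per_class[g]):
            sample_ids.append(f"{cname}_{k + 1:03d}")
            labels.append(cname)

    comp_names = [c.name for c in config.compounds]
    conc = np.zeros((n_total, len(config.compounds)))
    jitter = np.zeros(n_total)
    X = np.zeros((n_total, npts))
    i = 0
    for g in range(config.n_classes):
        for _ in range(config.n_per_class[g]):
            for ci, comp in enumerate(config.compounds):
                lo_c, hi_c = config.conc_range.get(comp.name,
                                                  config.default_conc_range)
                base = np.exp(rng.uniform(np.log(lo_c), np.log(hi_c)))
                mult = config.biomarkers.get(comp.name,
                                             [1.0] * config.n_classes)[g]
                conc[i, ci] = base * mult
            if config.shift_jitter_sd > 0:
                jitter[i] = rng.normal(0.0, config.shift_jitter_sd)
            i += 1
    for i in range(n_total):
        X[i] = render_spectrum(grid, config.compounds, conc[i], jitter[i])
    if config.noise_sd > 0:
        X += rng.normal(0.0, config.noise_sd, size=X.shape)

    matrix = SpectraMatrix(sample_ids, grid, X)
    ann = AnnotationTable.from_mapping(
        dict(zip(sample_ids, labels)),
        covariates={s: {"seed": str(config.seed)} for s in sample_ids})
    truth = pd.DataFrame(conc, index=sample_ids, columns=comp_names)
    truth_jitter = pd.Series(jitter, index=sample_ids, name="shift_offset")
    return SimDataset(matrix=matrix, annotations=ann, truth=truth,
                      truth_jitter=truth_jitter, config=config)


def builtin_library() -> list[CompoundSpec]:
    """Urine-plausible illustrative compound specs.

    Multiplet positions and intensity ratios are chosen to look like common
    urinary metabolites (doublets, singlets, quartets at familiar shifts);
    they are synthetic fixtures for simulation, not literature chemical
    shift assignments.
    """
    return [
        CompoundSpec("lactate", [(1.326, 3.0), (1.340, 3.0),
                                 (4.104, 0.25), (4.111, 0.75),
                                 (4.118, 0.75), (4.125, 0.25)]),
        CompoundSpec("alanine", [(1.466, 3.0), (1.480, 3.0),
                                 (3.770, 0.5), (3.784, 0.5)]),
        CompoundSpec("creatinine", [(3.045, 3.0), (4.060, 2.0)]),
        CompoundSpec("citrate", [(2.540, 1.0), (2.560, 1.0),
                                 (2.660, 1.0), (2.680, 1.0)]),
        CompoundSpec("glucose", [(5.233, 0.4), (5.245, 0.4),
                                 (3.400, 1.0), (3.460, 1.2), (3.530, 1.1),
                                 (3.700, 1.4), (3.820, 0.9)]),
        CompoundSpec("hippurate", [(7.550, 2.0), (7.640, 1.0),
                                   (7.830, 2.0), (3.970, 2.0)]),
        CompoundSpec("taurine", [(3.250, 2.0), (3.265, 2.0),
                                 (3.420, 2.0), (3.435, 2.0)]),
        CompoundSpec("glycine", [(3.560, 2.0)]),
        CompoundSpec("formate", [(8.440, 1.0)]),
        CompoundSpec("trimethylamine-N-oxide", [(3.270, 9.0)]),
    ]
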