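"""Shared fixtures: small synthetic cohorts and random matrices."""

import numpy as np
import pytest

from nmrprofile import (SimConfig, SpectraMatrix, builtin_library,
                        simulate_dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_matrix(rng):
    """15 x 40 random matrix on a descending grid (no spectral structure)."""
    grid = np.linspace(9.0, 0.2, 40)
    X = rng.normal(size=(15, 40))
    return SpectraMatrix([f"s{i:02d}" for i in range(15)], grid, X)


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free two-class cohort, lactate doubled in class2."""
    cfg = SimConfig(compounds=builtin_library(), n_classes=2,
                    n_per_class=[15, 15],
                    biomarkers={"lactate": [1.0, 2.0]},
                    noise_sd=0.0, shift_jitter_sd=0.0,
                    grid=(10.0, 0.0, 1000), seed=404)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def single_compound_cohort():
    """Only lactate present: every spectrum is a scalar multiple of one shape."""
    lib = {c.name: c for c in builtin_library()}
    cfg = SimConfig(compounds=[lib["lactate"]], n_classes=1, n_per_class=[12],
                    noise_sd=0.0, shift_jitter_sd=0.0,
                    grid=(10.0, 0.0, 2000), seed=77)
    return simulate_dataset(cfg)
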