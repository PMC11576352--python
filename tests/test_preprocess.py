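"""Region exclusion, total-area and PQN normalization, variable scaling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmrprofile import (PreprocessConfig, SimConfig, SpectraMatrix,
                        builtin_library, exclude_regions, normalize_pqn,
                        normalize_total_area, run_preprocess, scale,
                        simulate_dataset)


def _matrix(X, grid=None, ids=None):
    X = np.asarray(X, dtype=float)
    grid = np.arange(X.shape[1], 0, -1.0) if grid is None else grid
    ids = [f"s{i}" for i in range(X.shape[0])] if ids is None else ids
    return SpectraMatrix(ids, grid, X)


class TestExcludeRegions:
    def test_closed_interval_counting(self):
        m = _matrix(np.ones((2, 11)), grid=np.arange(10, -1, -1.0))
        out = exclude_regions(m, [(5.0, 4.0)])
        assert out.n_variables == 9
        assert 5.0 not in out.ppm_grid and 4.0 not in out.ppm_grid

    def test_empty_region_list_is_identity(self, small_matrix):
        out = exclude_regions(small_matrix, [])
        assert np.array_equal(out.X, small_matrix.X)
        assert np.array_equal(out.ppm_grid, small_matrix.ppm_grid)

    def test_matches_bruteforce_membership(self, rng, small_matrix):
        for _ in range(50):
            k = rng.integers(1, 4)
            regions = []
            for _ in range(k):
                a, b = np.sort(rng.uniform(0, 10, 2))
                if a == b:
                    continue
                regions.append((b, a))
            if not regions:
                continue
            keep_expected = [
                not any(lo <= p <= hi for hi, lo in regions)
                for p in small_matrix.ppm_grid
            ]
            if not any(keep_expected):
                with pytest.raises(ValueError):
                    exclude_regions(small_matrix, regions)
                continue
            out = exclude_regions(small_matrix, regions)
            assert np.array_equal(out.ppm_grid,
                                  small_matrix.ppm_grid[keep_expected])

    def test_all_excluded_raises(self, small_matrix):
        with pytest.raises(ValueError, match="excluded"):
            exclude_regions(small_matrix, [(100.0, -100.0)])

    def test_order_preserved(self, small_matrix):
        out = exclude_regions(small_matrix, [(5.0, 4.0)])
        assert np.all(np.diff(out.ppm_grid) < 0)


class TestTotalArea:
    def test_simple_row(self):
        out = normalize_total_area(_matrix([[1, 2, 3]]), area_target=1.0)
        assert np.allclose(out.matrix.X[0], [1 / 6, 2 / 6, 3 / 6])
        assert np.isclose(out.dilution_factors[0], 6.0)

    def test_already_at_target_unchanged(self):
        out = normalize_total_area(_matrix([[0.5, 0.5]]), area_target=1.0)
        assert np.allclose(out.matrix.X[0], [0.5, 0.5])
        assert np.isclose(out.dilution_factors[0], 1.0)

    def test_row_sums_conserved_on_simulated_cohort(self):
        ds = simulate_dataset(SimConfig(
            compounds=builtin_library(), n_classes=1, n_per_class=[50],
            grid=(10.0, 0.0, 500), seed=12))
        out = normalize_total_area(ds.matrix, area_target=100.0)
        assert np.allclose(out.matrix.X.sum(axis=1), 100.0, atol=1e-9)

    def test_nonpositive_row_named(self):
        m = _matrix([[1.0, 2.0], [-1.0, 0.5]], ids=["ok", "neg"])
        with pytest.raises(ValueError, match="neg"):
            normalize_total_area(m)

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_idempotent(self, seed):
        r = np.random.default_rng(seed)
        m = _matrix(r.uniform(0.1, 5.0, size=(4, 12)))
        once = normalize_total_area(m, 7.0)
        twice = normalize_total_area(once.matrix, 7.0)
        assert np.allclose(once.matrix.X, twice.matrix.X, atol=1e-12)
        assert np.allclose(twice.dilution_factors, 1.0, atol=1e-12)


class TestPqn:
    def test_identical_rows_unchanged(self):
        row = np.array([1.0, 4.0, 2.0, 3.0])
        m = _matrix([row, row])
        out = normalize_pqn(m, area_target=float(row.sum()))
        assert np.allclose(out.quotient_factors, 1.0)
        assert np.allclose(out.matrix.X, m.X, atol=1e-12)

    def test_recovers_constructed_dilution_factors(self, rng):
        profile = rng.uniform(0.5, 3.0, 80)
        k = np.array([0.5, 1.0, 1.7, 2.4, 4.0])
        m = _matrix(np.outer(k, profile),
                    grid=np.linspace(9, 1, 80))
        out = normalize_pqn(m)
        ratios = out.dilution_factors / out.dilution_factors[1]
        assert np.allclose(ratios, k / k[1], atol=1e-9)

    def test_simulated_dilution_log_correlation(self, rng):
        """Multiplying simulated spectra by random dilutions is undone by PQN.

        Composition is held nearly constant so the recovered factor reflects
        the applied dilution rather than biological variation.
        """
        ds = simulate_dataset(SimConfig(
            compounds=builtin_library(), n_classes=1, n_per_class=[40],
            default_conc_range=(0.95, 1.05),
            grid=(10.0, 0.0, 600), seed=21))
        true = np.exp(rng.uniform(np.log(0.5), np.log(2.0), 40))
        diluted = SpectraMatrix(ds.matrix.sample_ids, ds.matrix.ppm_grid,
                                ds.matrix.X * true[:, None])
        out = normalize_pqn(diluted)
        r = np.corrcoef(np.log(true),
                        np.log(out.dilution_factors))[0, 1]
        assert r > 0.99

    def test_quotient_factors_invariant_to_global_constant(self, rng):
        X = rng.uniform(0.1, 2.0, size=(6, 30))
        a = normalize_pqn(_matrix(X))
        b = normalize_pqn(_matrix(X * 37.5))
        assert np.allclose(a.quotient_factors, b.quotient_factors, atol=1e-12)

    def test_needs_two_samples(self):
        with pytest.raises(ValueError, match="2 samples"):
            normalize_pqn(_matrix([[1.0, 2.0]]))


class TestScale:
    def test_center(self):
        out = scale(_matrix(np.array([[1.0], [2.0], [3.0]])), "center")
        assert np.allclose(out.matrix.X[:, 0], [-1, 0, 1])

    def test_uv_gives_unit_sd(self, small_matrix):
        out = scale(small_matrix, "uv")
        assert np.allclose(out.matrix.X.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_pareto_sd_is_sqrt_of_original(self, small_matrix):
        sd0 = small_matrix.X.std(axis=0, ddof=1)
        out = scale(small_matrix, "pareto")
        assert np.allclose(out.matrix.X.std(axis=0, ddof=1), np.sqrt(sd0),
                           atol=1e-9)

    def test_zero_variance_columns_dropped(self, rng):
        X = rng.normal(size=(5, 4))
        X[:, 2] = 3.14
        out = scale(_matrix(X), "uv")
        assert out.matrix.n_variables == 3
        assert out.dropped_ppm is not None and len(out.dropped_ppm) == 1

    def test_uv_needs_two_samples(self):
        with pytest.raises(ValueError):
            scale(_matrix([[1.0, 2.0]]), "uv")


class TestPipelineProvenance:
    def test_recorded_factors_reproduce_processed_matrix(self, rng):
        X = rng.uniform(0.1, 3.0, size=(10, 60))
        m = _matrix(X, grid=np.linspace(9.5, 0.5, 60))
        cfg = PreprocessConfig(excluded_regions=[(7.0, 6.0)],
                               normalization="pqn", area_target=50.0,
                               scaling="pareto")
        res = run_preprocess(m, cfg)
        # replay: exclusion -> divide by dilution factor -> center/scale
        replay = exclude_regions(m, cfg.excluded_regions).X
        replay = replay / res.dilution_factors[:, None]
        replay = (replay - res.centers) / res.scales
        assert np.max(np.abs(replay - res.matrix.X)) < 1e-12

    def test_exclusion_happens_before_normalization(self):
        # a huge excluded peak must not influence dilution factors
        X = np.array([[1.0, 1.0, 100.0], [2.0, 2.0, 1000.0]])
        m = _matrix(X, grid=np.array([3.0, 2.0, 1.0]))
        cfg = PreprocessConfig(excluded_regions=[(1.5, 0.5)],
                               normalization="total_area", area_target=1.0)
        res = run_preprocess(m, cfg)
        assert np.allclose(res.dilution_factors, [2.0, 4.0])
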