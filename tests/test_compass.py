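"""COMPASS pattern extraction, lag-scanned matching, STOCSY iteration."""

import numpy as np
import pytest

from nmrprofile import (SimConfig, SpectraMatrix, builtin_library,
                        compass_match, compass_stocsy_iterate,
                        extract_reference, simulate_dataset)


def _lib():
    return {c.name: c for c in builtin_library()}


def _cohort_with_marker_in(n_total, marker_ids, seed=55, grid_n=2000):
    """Cohort where 'formate' (isolated singlet at 8.44) is present only in
    the chosen samples; built by adding a marker-only simulation onto a
    marker-free one (spectra are additive)."""
    lib = _lib()
    background = [lib[n] for n in ("lactate", "creatinine", "citrate",
                                   "glycine")]
    base = simulate_dataset(SimConfig(
        compounds=background, n_classes=1, n_per_class=[n_total],
        noise_sd=0.0, grid=(10.0, 0.0, grid_n), seed=seed))
    marker = simulate_dataset(SimConfig(
        compounds=[lib["formate"]], n_classes=1, n_per_class=[n_total],
        noise_sd=0.0, grid=(10.0, 0.0, grid_n), seed=seed + 1))
    X = base.matrix.X.copy()
    for i in marker_ids:
        X[i] += marker.matrix.X[i]
    m = SpectraMatrix(base.matrix.sample_ids, base.matrix.ppm_grid, X)
    return m, marker


class TestExtractReference:
    def test_self_match_is_perfect_at_zero_shift(self, single_compound_cohort):
        m = single_compound_cohort.matrix
        sid = m.sample_ids[0]
        pat = extract_reference(m, sid, 1.36, 1.30)
        res = compass_match(m, pat, max_shift_points=3, threshold=0.8)
        i = m.index_of(sid)
        assert np.isclose(res.best_correlation[i], 1.0, atol=1e-12)
        assert res.best_shift[i] == 0

    def test_tiny_window_rejected(self, single_compound_cohort):
        m = single_compound_cohort.matrix
        with pytest.raises(ValueError, match="5"):
            extract_reference(m, m.sample_ids[0], 1.331, 1.325)

    def test_template_is_mean_subtracted(self, single_compound_cohort):
        m = single_compound_cohort.matrix
        pat = extract_reference(m, m.sample_ids[0], 1.36, 1.30)
        assert abs(pat.template.mean()) < 1e-12

    def test_flat_window_rejected(self, rng):
        X = np.ones((3, 50))
        m = SpectraMatrix(["a", "b", "c"], np.linspace(5, 1, 50), X)
        with pytest.raises(ValueError, match="pattern"):
            extract_reference(m, "a", 4.0, 2.0)


class TestCompassMatch:
    def test_counts_samples_containing_compound(self):
        rng = np.random.default_rng(2)
        marker_ids = sorted(rng.choice(60, size=17, replace=False))
        m, _ = _cohort_with_marker_in(60, marker_ids)
        source = m.sample_ids[marker_ids[0]]
        pat = extract_reference(m, source, 8.47, 8.41)
        res = compass_match(m, pat, max_shift_points=3, threshold=0.8)
        assert res.n_containing == 17
        flagged = [i for i, c in enumerate(res.contains_pattern) if c]
        assert flagged == marker_ids

    def test_scale_invariance_at_threshold_one(self, rng):
        """Exact scalar multiples of the template all reach r = 1."""
        p = 60
        grid = np.linspace(5, 1, p)
        template_shape = np.sin(np.linspace(0, 3 * np.pi, 11)) + 2
        X = rng.normal(0.0, 1.0, size=(8, p))
        for i, a in enumerate([0.5, 2.0, 7.5, 1.0]):  # first 4: multiples
            X[i, 20:31] = a * template_shape
        m = SpectraMatrix([f"s{i}" for i in range(8)], grid, X)
        pat = extract_reference(m, "s3", grid[20], grid[30])
        res = compass_match(m, pat, max_shift_points=0, threshold=1.0 - 1e-12)
        assert list(np.nonzero(res.contains_pattern)[0]) == [0, 1, 2, 3]

    def test_matches_bruteforce_double_loop(self, rng):
        X = rng.normal(size=(10, 50))
        m = SpectraMatrix([f"s{i}" for i in range(10)],
                          np.linspace(9, 1, 50), X)
        pat = extract_reference(m, "s0", m.ppm_grid[20], m.ppm_grid[27])
        max_shift = 4
        res = compass_match(m, pat, max_shift, threshold=0.5)
        start, stop = pat.window_indices
        tpl = pat.template - pat.template.mean()
        for i in range(10):
            best = -np.inf
            for lag in range(-max_shift, max_shift + 1):
                seg = X[i, start + lag:stop + lag]
                r = np.corrcoef(tpl, seg)[0, 1]
                best = max(best, r)
            assert abs(res.best_correlation[i] - best) < 1e-12

    def test_count_monotone_in_threshold(self, rng):
        X = rng.normal(size=(20, 60))
        m = SpectraMatrix([f"s{i}" for i in range(20)],
                          np.linspace(9, 1, 60), X)
        pat = extract_reference(m, "s0", m.ppm_grid[10], m.ppm_grid[20])
        counts = [compass_match(m, pat, 2, th).n_containing
                  for th in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert counts == sorted(counts, reverse=True)

    def test_affine_intensity_transform_invariance(self, rng):
        X = rng.normal(size=(6, 40))
        m = SpectraMatrix([f"s{i}" for i in range(6)],
                          np.linspace(8, 1, 40), X)
        pat = extract_reference(m, "s0", m.ppm_grid[5], m.ppm_grid[14])
        base = compass_match(m, pat, 2, 0.5)
        transformed = SpectraMatrix(m.sample_ids, m.ppm_grid,
                                    3.7 * m.X + 11.0)
        res = compass_match(transformed, pat, 2, 0.5)
        assert np.max(np.abs(res.best_correlation
                             - base.best_correlation)) < 1e-10

    def test_window_plus_shift_must_stay_on_grid(self, rng):
        X = rng.normal(size=(4, 30))
        m = SpectraMatrix([f"s{i}" for i in range(4)],
                          np.linspace(8, 1, 30), X)
        pat = extract_reference(m, "s0", m.ppm_grid[0], m.ppm_grid[6])
        with pytest.raises(ValueError, match="admissible"):
            compass_match(m, pat, max_shift_points=2, threshold=0.8)

    def test_ranking_orders_matches_by_intensity(self):
        marker_ids = [2, 5, 9]
        m, _ = _cohort_with_marker_in(12, marker_ids, seed=91)
        pat = extract_reference(m, m.sample_ids[2], 8.47, 8.41)
        res = compass_match(m, pat, 3, 0.8)
        ranked = res.ranking
        assert set(ranked) == {m.sample_ids[i] for i in marker_ids}
        intensities = [res.matched_intensity[m.index_of(s)] for s in ranked]
        assert intensities == sorted(intensities, reverse=True)


class TestCompassStocsyIteration:
    def test_refined_pattern_close_to_original_on_homogeneous_subset(
            self, single_compound_cohort):
        m = single_compound_cohort.matrix
        pat = extract_reference(m, m.sample_ids[0], 1.36, 1.30)
        _, _, refined = compass_stocsy_iterate(m, pat, 3, 0.8)
        r = np.corrcoef(pat.template, refined.template)[0, 1]
        assert r > 0.999

    def test_subset_stocsy_reveals_other_resonances(self):
        marker_ids = list(range(0, 30))
        m, marker = _cohort_with_marker_in(40, marker_ids, seed=13)
        # use lactate (multiplets at 1.33 and 4.11) as the template compound
        pat = extract_reference(m, m.sample_ids[0], 1.36, 1.30)
        _, sub_stocsy, _ = compass_stocsy_iterate(m, pat, 3, 0.8)
        other_apex = m.nearest_index(4.111)
        assert sub_stocsy.correlation[other_apex] > 0.95

    def test_fixed_point_on_noise_free_data(self):
        marker_ids = [1, 4, 7, 10, 13]
        m, _ = _cohort_with_marker_in(15, marker_ids, seed=29)
        pat = extract_reference(m, m.sample_ids[1], 8.47, 8.41)
        res1, _, refined = compass_stocsy_iterate(m, pat, 3, 0.8)
        res2, _, _ = compass_stocsy_iterate(m, refined, 3, 0.8)
        assert res2.n_containing == res1.n_containing

    def test_no_matches_advises_lower_threshold(self, rng):
        X = rng.normal(size=(6, 60))
        m = SpectraMatrix([f"s{i}" for i in range(6)],
                          np.linspace(9, 1, 60), X)
        pat = extract_reference(m, "s0", m.ppm_grid[20], m.ppm_grid[30])
        strict = SpectraMatrix(m.sample_ids, m.ppm_grid,
                               rng.normal(size=(6, 60)))
        with pytest.raises(ValueError, match="threshold"):
            compass_stocsy_iterate(strict, pat, 0, 1.0)
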