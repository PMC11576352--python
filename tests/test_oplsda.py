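"""OPLS-DA: PLS1 reduction, orthogonality, prediction, Q² cross-validation."""

import numpy as np
import pytest

from nmrprofile import (OneVsRestOPLSDA, OPLSDA, SimConfig, SpectraMatrix,
                        builtin_library, cross_validate,
                        labels_from_annotations, simulate_dataset)


def _xy(rng, n=30, p=40, effect=1.0):
    y = np.repeat([-1.0, 1.0], n // 2)
    X = rng.normal(size=(n, p))
    X[:, 0] += effect * y
    return X, y


class TestFit:
    def test_zero_orth_equals_pls1_first_component(self, rng):
        X, y = _xy(rng)
        res = OPLSDA(X, y, n_orth=0).fit()
        # independent PLS1: w ∝ X'y on centered data, t = Xw
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        w = Xc.T @ yc / (yc @ yc)
        w /= np.linalg.norm(w)
        t = Xc @ w
        assert np.max(np.abs(np.abs(res.w) - np.abs(w))) < 1e-10
        assert np.max(np.abs(np.abs(res.t_pred) - np.abs(t))) < 1e-10

    def test_orthogonal_weight_recovers_confounding_axis(self, rng):
        """A strong y-orthogonal trend is captured by w_o, not w."""
        n, p = 60, 50
        y = np.repeat([-1.0, 1.0], n // 2)
        axis_a = np.zeros(p); axis_a[5] = 1.0      # class axis
        axis_b = np.zeros(p); axis_b[20] = 1.0     # confounder axis
        confounder = rng.normal(size=n) * 5.0
        confounder -= confounder @ y / (y @ y) * y  # make exactly y-orthogonal
        X = (np.outer(y, axis_a) + np.outer(confounder, axis_b)
             + rng.normal(0, 0.01, (n, p)))
        res = OPLSDA(X, y, n_orth=1).fit()
        cos = abs(res.W_o[:, 0] @ axis_b)
        assert cos > 0.99

    def test_orthogonal_scores_uncorrelated_with_y(self, rng):
        X, y = _xy(rng, n=40, p=30)
        res = OPLSDA(X, y, n_orth=2).fit()
        yc = y - y.mean()
        for j in range(res.n_orth):
            t_o = res.T_o[:, j]
            assert abs(np.corrcoef(t_o, yc)[0, 1]) < 1e-8

    def test_predictive_orthogonal_to_orthogonal_scores(self, rng):
        X, y = _xy(rng, n=40, p=30)
        res = OPLSDA(X, y, n_orth=2).fit()
        for j in range(res.n_orth):
            ip = abs(res.t_pred @ res.T_o[:, j])
            assert ip < 1e-8 * np.linalg.norm(res.t_pred) * np.linalg.norm(
                res.T_o[:, j])

    def test_r2x_decomposition_sums_to_one(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            X, y = _xy(r, n=24, p=18)
            res = OPLSDA(X, y, n_orth=2).fit()
            Xc = X - X.mean(axis=0)
            filtered = Xc.copy()
            for j in range(res.n_orth):
                t_o = filtered @ res.W_o[:, j]
                filtered -= np.outer(t_o, res.P_o[:, j])
            resid = filtered - np.outer(res.t_pred, res.p_pred)
            resid_frac = (resid ** 2).sum() / (Xc ** 2).sum()
            assert np.isclose(res.r2x_pred + res.r2x_orth + resid_frac, 1.0,
                              atol=1e-8)

    def test_unit_norm_weights(self, rng):
        X, y = _xy(rng)
        res = OPLSDA(X, y, n_orth=2).fit()
        assert np.isclose(np.linalg.norm(res.w), 1.0, atol=1e-12)
        for j in range(res.n_orth):
            assert np.isclose(np.linalg.norm(res.W_o[:, j]), 1.0, atol=1e-12)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 5))
        with pytest.raises(ValueError, match="class"):
            OPLSDA(X, np.ones(10))

    def test_string_labels_coded_lexicographically(self, rng):
        X, _ = _xy(rng, n=10)
        labels = ["case"] * 5 + ["control"] * 5
        res = OPLSDA(X, np.array(labels), n_orth=0).fit()
        assert res.class_labels == ("case", "control")


class TestPredict:
    def test_training_set_self_consistency(self, rng):
        X, y = _xy(rng, n=40, p=30)
        res = OPLSDA(X, y, n_orth=1).fit()
        pred = res.predict(X)
        assert np.max(np.abs(pred.t_pred - res.t_pred)) < 1e-8

    def test_mean_spectrum_is_tie_broken_to_first_label(self, rng):
        X, _ = _xy(rng, n=20)
        labels = np.array(["a"] * 10 + ["b"] * 10)
        res = OPLSDA(X, labels, n_orth=1).fit()
        pred = res.predict(X.mean(axis=0))
        assert pred.y_hat[0] == 0.0
        assert pred.predicted_class == ["a"]

    def test_separable_cohort_perfect_heldout_accuracy(self):
        # tight biomarker concentration range: the 3x class effect is
        # several within-class standard deviations, i.e. separable
        cfg = SimConfig(compounds=builtin_library(), n_classes=2,
                        n_per_class=[60, 60],
                        biomarkers={"alanine": [1.0, 3.0]},
                        conc_range={"alanine": (0.8, 1.25)},
                        noise_sd=0.0, grid=(10.0, 0.0, 600), seed=15)
        ds = simulate_dataset(cfg)
        labels = labels_from_annotations(ds.matrix, ds.annotations)
        train = np.r_[np.arange(0, 40), np.arange(60, 100)]
        test = np.setdiff1d(np.arange(120), train)
        res = OPLSDA(ds.matrix.X[train], labels[train], n_orth=1).fit()
        pred = res.predict(ds.matrix.X[test])
        assert pred.predicted_class == list(labels[test])


class TestCrossValidation:
    def test_perfectly_predictable_y_gives_high_q2(self, rng):
        # X is rank-1 and driven by y, so one PLS component suffices
        n = 28
        y = np.repeat([-1.0, 1.0], n // 2)
        X = np.outer(y, rng.uniform(0.5, 2.0, 10))
        X += rng.normal(0, 1e-3, X.shape)
        q2 = cross_validate(X, y, n_orth=0, folds=7, seed=5)
        assert q2 > 0.99

    def test_permuted_labels_give_no_predictivity(self, rng):
        n = 28
        X = rng.normal(size=(n, 15))
        q2s = []
        for k in range(20):
            y = np.repeat([-1.0, 1.0], n // 2)
            rng.shuffle(y)
            q2s.append(cross_validate(X, y, n_orth=0, folds=4, seed=k))
        assert np.mean(q2s) < 0.1

    def test_q2_not_above_r2y(self, rng):
        X, y = _xy(rng, n=40, p=30, effect=2.0)
        res = OPLSDA(X, y, n_orth=1).fit()
        q2 = cross_validate(X, y, n_orth=1, folds=5, seed=2)
        assert q2 <= res.r2y + 1e-12

    def test_deterministic_given_seed(self, rng):
        X, y = _xy(rng)
        a = cross_validate(X, y, folds=5, seed=9)
        b = cross_validate(X, y, folds=5, seed=9)
        assert a == b

    def test_too_few_samples_per_class_for_folds(self, rng):
        X, y = _xy(rng, n=10)
        with pytest.raises(ValueError, match="stratify"):
            cross_validate(X, y, folds=7, seed=0)


class TestLoadingDecomposition:
    def test_biomarker_peak_holds_rank_one(self):
        cfg = SimConfig(compounds=builtin_library(), n_classes=2,
                        n_per_class=[30, 30],
                        biomarkers={"creatinine": [1.0, 2.5]},
                        noise_sd=0.0, grid=(10.0, 0.0, 1000), seed=8)
        ds = simulate_dataset(cfg)
        labels = labels_from_annotations(ds.matrix, ds.annotations)
        res = OPLSDA(ds.matrix, labels, n_orth=1).fit()
        table = res.loading_decomposition()
        top_ppm = float(table.loc[table["rank"] == 1, "ppm"].iloc[0])
        lib = {c.name: c for c in builtin_library()}
        apex = lib["creatinine"].tallest_peak_ppm
        step = 10.0 / 999
        assert abs(top_ppm - apex) <= 2 * step

    def test_no_orth_columns_when_zero_orth(self, rng):
        X, y = _xy(rng)
        table = OPLSDA(X, y, n_orth=0).fit().loading_decomposition()
        assert not [c for c in table.columns if c.startswith("p_orth")]

    def test_row_count_equals_p(self, rng):
        X, y = _xy(rng, p=37)
        table = OPLSDA(X, y, n_orth=1).fit().loading_decomposition()
        assert len(table) == 37


class TestMulticlass:
    def test_one_vs_rest_recovers_three_classes(self):
        lib = {c.name: c for c in builtin_library()}
        cfg = SimConfig(
            compounds=[lib["lactate"], lib["creatinine"], lib["glycine"],
                       lib["citrate"]],
            n_classes=3, n_per_class=[20, 20, 20],
            biomarkers={"lactate": [3.0, 1.0, 1.0],
                        "creatinine": [1.0, 3.0, 1.0],
                        "glycine": [1.0, 1.0, 3.0]},
            conc_range={"lactate": (0.8, 1.25),
                        "creatinine": (0.8, 1.25),
                        "glycine": (0.8, 1.25)},
            noise_sd=0.0, grid=(10.0, 0.0, 500), seed=31)
        ds = simulate_dataset(cfg)
        labels = labels_from_annotations(ds.matrix, ds.annotations)
        model = OneVsRestOPLSDA(ds.matrix.X, labels, n_orth=1).fit()
        pred = model.predict(ds.matrix.X)
        accuracy = np.mean(np.asarray(pred) == labels)
        assert accuracy == 1.0
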