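"""Shallow-network modeling: fitting, LOOCV, surface, hot spot, ablation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.neural_network import MLPRegressor

from ppx import neuronet as nn

FAST = nn.NetSpec(n_restarts=2, max_iter=500)


def _hand_net(w1, b1, w2, b2):
    """A TrainedNet with explicitly set weights (identity standardization)."""
    w1 = np.asarray(w1, float)
    model = MLPRegressor(
        hidden_layer_sizes=(w1.shape[1],), activation="tanh", solver="lbfgs",
        max_iter=5, random_state=0,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(np.zeros((12, w1.shape[0])), np.zeros(12))
    model.coefs_ = [w1, np.asarray(w2, float).reshape(-1, 1)]
    model.intercepts_ = [np.asarray(b1, float), np.asarray([b2], float)]
    return nn.TrainedNet(
        spec=FAST, x_mean=np.zeros(w1.shape[0]), x_sd=np.ones(w1.shape[0]),
        y_mean=0.0, y_sd=1.0, model=model, train_loss=0.0, restart_chosen=0,
    )


def _surface_from(predictions, g1=None, g2=None, threshold=0.0):
    n2, n1 = predictions.shape
    return nn.ResponseSurface(
        axis1_name="hormones", axis1_grid=g1 if g1 is not None else np.linspace(-2, 2, n1),
        axis2_name="eicosanoids", axis2_grid=g2 if g2 is not None else np.linspace(-2, 2, n2),
        fixed_name="neuroinflammation", fixed_value=0.0,
        predictions=predictions, threshold=threshold,
        mask=predictions > threshold, boundary=[], threshold_rule="mean_measured",
    )


class TestBaselineRegressions:
    def test_exact_univariate_fit(self, rng):
        X = rng.normal(size=(20, 3))
        res = nn.baseline_regressions(X, 2 * X[:, 0])
        assert res["univariate_hormones"].effect_size == pytest.approx(1.0)

    def test_independent_target_low_r2(self, rng):
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        res = nn.baseline_regressions(X, y)
        assert all(v.effect_size < 0.2 for v in res.values())

    def test_multivariate_dominates_univariates(self, rng):
        X = rng.normal(size=(25, 3))
        y = X @ [1.0, -0.5, 0.2] + rng.normal(size=25)
        res = nn.baseline_regressions(X, y)
        uni = max(
            res[f"univariate_{n}"].effect_size for n in nn.INPUT_NAMES
        )
        assert res["multivariate"].effect_size >= uni - 1e-12


class TestFitNetwork:
    def test_zero_variance_target_rejected(self, rng):
        with pytest.raises(ValueError, match="zero-variance target"):
            nn.fit_network(rng.normal(size=(12, 3)), np.ones(12), FAST)

    def test_nonfinite_rejected(self, rng):
        X = rng.normal(size=(12, 3))
        y = rng.normal(size=12)
        y[0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            nn.fit_network(X, y, FAST)

    def test_linear_function_representable(self, rng):
        X = rng.normal(size=(30, 3))
        y = X[:, 0]
        net = nn.fit_network(X, y, nn.NetSpec(n_restarts=3, weight_decay=1e-4))
        pred = net.predict(X)
        r2 = np.corrcoef(pred, y)[0, 1] ** 2
        assert r2 >= 0.99

    def test_bitwise_determinism(self, rng):
        X = rng.normal(size=(15, 3))
        y = rng.normal(size=15)
        n1 = nn.fit_network(X, y, FAST)
        n2 = nn.fit_network(X, y, FAST)
        assert n1.restart_chosen == n2.restart_chosen
        for a, b in zip(n1.model.coefs_, n2.model.coefs_):
            assert np.array_equal(a, b)


class TestLOOCV:
    def test_recoverable_linear_signal(self, rng):
        X = rng.normal(size=(24, 3))
        res = nn.loocv(X, X[:, 0], nn.NetSpec(n_restarts=2, weight_decay=1e-3))
        assert res.variance_explained >= 0.95

    def test_permuted_target_uninformative(self, rng):
        X = rng.normal(size=(24, 3))
        y = X @ [1.0, 1.0, 1.0]
        y_perm = rng.permutation(y)
        res = nn.loocv(X, y_perm, FAST)
        assert res.variance_explained < 0.2

    def test_exclusion_property_exact(self, rng):
        """The fold-i model never sees (x_i, y_i): changing y_i leaves the
        out-of-fold prediction for i bit-identical."""
        X = rng.normal(size=(12, 3))
        y = X[:, 0] + 0.1 * rng.normal(size=12)
        base = nn.loocv(X, y, FAST)
        y2 = y.copy()
        y2[0] += 100.0
        perturbed = nn.loocv(X, y2, FAST)
        assert perturbed.predictions[0] == base.predictions[0]

    def test_per_cohort_regressions_reported(self, rng):
        X = rng.normal(size=(16, 3))
        y = X[:, 0] + 0.2 * rng.normal(size=16)
        cohorts = np.array(["a"] * 8 + ["b"] * 8)
        res = nn.loocv(X, y, FAST, cohorts)
        assert set(res.per_cohort) == {"a", "b"}
        assert res.per_cohort["a"]["n"] == 8


class TestResponseSurface:
    def test_zero_output_weights_empty_hotspot(self, rng):
        net = _hand_net(np.zeros((3, 2)), np.zeros(2), np.zeros(2), 0.0)
        X = rng.normal(size=(20, 3))
        y = np.tile([1.0, -1.0], 10)  # mean exactly 0 = constant prediction
        surf = nn.response_surface(net, X, y, grid_n=25)
        assert surf.threshold == 0.0
        assert not surf.mask.any()

    def test_monotone_function_gives_suffix_mask(self, rng):
        # small-weight tanh ~ linear, increasing in both plotted axes
        net = _hand_net(0.1 * np.array([[1.0], [1.0], [0.0]]), [0.0], [10.0], 0.0)
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        surf = nn.response_surface(net, X, y, grid_n=25)
        for row in surf.mask:
            assert np.all(np.diff(row.astype(int)) >= 0)  # row suffix
        for col in surf.mask.T:
            assert np.all(np.diff(col.astype(int)) >= 0)

    def test_grid_covers_data_range_with_padding(self, rng):
        net = _hand_net(np.zeros((3, 2)), np.zeros(2), np.zeros(2), 0.0)
        X = rng.normal(size=(30, 3))
        surf = nn.response_surface(net, X, rng.normal(size=30), grid_n=25)
        assert surf.axis1_grid[0] < X[:, 0].min() < X[:, 0].max() < surf.axis1_grid[-1]

    def test_small_grid_rejected(self, rng):
        net = _hand_net(np.zeros((3, 2)), np.zeros(2), np.zeros(2), 0.0)
        with pytest.raises(ValueError, match="grid_n"):
            nn.response_surface(net, rng.normal(size=(20, 3)),
                                rng.normal(size=20), grid_n=10)


class TestHotSpot:
    def _data(self, rng, n=20):
        return pd.DataFrame(
            {
                "participant_id": [f"p{i}" for i in range(n)],
                "cohort": ["a"] * (n // 2) + ["b"] * (n // 2),
                "hormones": rng.normal(size=n),
                "eicosanoids": rng.normal(size=n),
            }
        )

    def test_everyone_inside_zero_margin_error(self, rng):
        net = _hand_net(np.zeros((3, 2)), np.zeros(2), np.zeros(2), 5.0)
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)  # mean(y) << constant prediction 5
        y -= y.mean()
        surf = nn.response_surface(net, X, y, grid_n=25)
        with pytest.raises(ValueError, match="same side"):
            nn.hotspot_membership_test(surf, net, self._data(rng))

    def test_counts_sum_to_participants(self, model_frame, model_xy):
        X, y = model_xy
        net = nn.fit_network(X, y, FAST)
        surf = nn.response_surface(net, X, y, grid_n=25)
        hot = nn.hotspot_membership_test(surf, net, model_frame)
        assert hot.counts.sum() == len(model_frame)
        assert len(hot.membership) == len(model_frame)

    def test_single_cohort_rejected(self, rng):
        net = _hand_net(np.zeros((3, 2)), np.zeros(2), np.zeros(2), 0.0)
        data = self._data(rng)
        data["cohort"] = "a"
        X = rng.normal(size=(20, 3))
        surf = nn.response_surface(net, X, rng.normal(size=20), grid_n=25)
        with pytest.raises(ValueError, match="cohorts"):
            nn.hotspot_membership_test(surf, net, data)


class TestAblation:
    def test_irrelevant_input_harmless(self, rng):
        X = rng.normal(size=(24, 3))
        y = X[:, 0] + 0.05 * rng.normal(size=24)
        res = nn.ablation(X, y, FAST)
        full = res["full"]["variance_explained"]
        assert abs(res["without_eicosanoids"]["delta_r2"]) < 0.05
        assert full > 0.9

    def test_sole_informative_input_essential(self, rng):
        X = rng.normal(size=(24, 3))
        y = X[:, 0] + 0.05 * rng.normal(size=24)
        res = nn.ablation(X, y, FAST)
        assert res["without_hormones"]["variance_explained"] < 0.2


class TestShapeDiagnostics:
    def test_linear_increasing_surface(self):
        g = np.linspace(-2, 2, 30)
        preds = np.add.outer(0 * g, g)  # increases along axis1 only
        out = nn.shape_diagnostics(_surface_from(preds))
        assert out["monotonicity_hormones"] == pytest.approx(1.0)
        assert abs(out["monotonicity_eicosanoids"]) < 1e-9

    def test_flat_surface(self):
        out = nn.shape_diagnostics(_surface_from(np.zeros((30, 30))))
        assert out["monotonicity_hormones"] == 0.0
        assert not out["eicosanoid_profile_unimodal"]

    def test_planted_gaussian_profile_unimodal(self):
        g = np.linspace(-2, 2, 40)
        bump = np.exp(-((g - 0.3) ** 2) / 0.5)
        preds = np.add.outer(bump, 0.5 * g)  # bump along axis2, tilt on axis1
        out = nn.shape_diagnostics(_surface_from(preds))
        assert out["eicosanoid_profile_unimodal"]

    def test_monotone_decreasing_not_unimodal(self):
        g = np.linspace(-2, 2, 40)
        preds = np.add.outer(-g, 0 * g)
        out = nn.shape_diagnostics(_surface_from(preds))
        assert not out["eicosanoid_profile_unimodal"]


def test_generator_truth_end_to_end_recovery(model_xy, model_frame):
    """At N=30 study scale the network recovers most outcome variance and the
    infection cohort concentrates inside the hot spot."""
    X, y = model_xy
    spec = nn.NetSpec(n_restarts=5)
    cv = nn.loocv(X, y, spec, model_frame["cohort"].to_numpy())
    assert cv.variance_explained >= 0.5
    net = nn.fit_network(X, y, spec)
    surf = nn.response_surface(net, X, y, grid_n=41)
    hot = nn.hotspot_membership_test(surf, net, model_frame)
    inf_row = list(hot.cohorts).index("infection")
    inside_inf = hot.counts[inf_row, 0] / hot.counts[inf_row].sum()
    inside_neu = hot.counts[1 - inf_row, 0] / hot.counts[1 - inf_row].sum()
    assert inside_inf > inside_neu
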