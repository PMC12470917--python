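"""Surrogate training, splitting, metrics, residuals and baselines."""

import numpy as np
import pandas as pd
import pytest

from latticeplate.surrogate import (EvalReport, MLPSurrogate, PolySurface,
                                    ResidualModel, Standardizer, TrainingError,
                                    crossvalidate, evaluate,
                                    fit_residual_model, poly_baseline,
                                    split_stratified)


def _grid_df(n=480, seed=0):
    """Synthetic stand-in for the factorial dataset (smooth targets)."""
    rng = np.random.default_rng(seed)
    from itertools import product
    rows = []
    for d, a, tl, tp, P in product((0.4, 0.7, 1.0), (2.0, 3.0, 4.0),
                                   (1.5, 2.5, 3.5, 4.5), (1.0, 1.5),
                                   (300.0, 600.0)):
        sigma = P * (0.1 + 0.05 * tl) / (tp * d)
        rows.append({"d": d, "a": a, "t_lat": tl, "t_plate": tp, "P": P,
                     "sigma_vm_max": sigma, "delta_max": sigma / 500,
                     "sigma_screw_max": sigma / 3})
    return pd.DataFrame(rows)


class TestSplit:
    def test_exact_sizes_on_100_rows(self):
        df = pd.DataFrame({"x": np.arange(100.0)})
        tr, va, te = split_stratified(df, seed=1, strata=())
        assert (len(tr), len(va), len(te)) == (70, 15, 15)

    def test_disjoint_and_exhaustive(self):
        df = _grid_df()
        tr, va, te = split_stratified(df, seed=2)
        idx = np.concatenate([tr.index, va.index, te.index])
        assert len(idx) == len(df)
        assert len(np.unique(idx)) == len(df)

    def test_per_stratum_proportions_within_one_row(self):
        df = _grid_df()
        tr, va, te = split_stratified(df, seed=3)
        strata_cols = ["P", "t_plate", "t_lat"]
        for key, grp in df.groupby(strata_cols):
            n = len(grp)
            for part, frac in ((tr, 0.70), (va, 0.15), (te, 0.15)):
                got = len(part.groupby(strata_cols).groups.get(key, ()))
                assert abs(got - frac * n) <= 1

    def test_reproducible_under_seed(self):
        df = _grid_df()
        a = split_stratified(df, seed=4)[0]
        b = split_stratified(df, seed=4)[0]
        pd.testing.assert_frame_equal(a, b)

    def test_small_strata_pooled_with_warning(self):
        df = pd.DataFrame({"P": [300.0] * 10 + [600.0],
                           "t_plate": 1.0, "t_lat": 1.5,
                           "x": np.arange(11.0)})
        with pytest.warns(UserWarning, match="pooled"):
            split_stratified(df, seed=5)


class TestStandardizer:
    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        X = rng.normal(3.0, 2.5, (50, 4))
        sc = Standardizer().fit(X)
        assert np.allclose(sc.inverse_transform(sc.transform(X)), X,
                           atol=1e-12)

    def test_zero_variance_rejected(self):
        X = np.column_stack([np.arange(10.0), np.full(10, 7.0)])
        with pytest.raises(ValueError, match="zero variance"):
            Standardizer().fit(X)


class TestMLP:
    def test_linear_target_learned_to_high_fidelity(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(-1, 1, (200, 1))
        y = 2.0 * X[:, 0]
        net = MLPSurrogate(hidden_layer_sizes=(16,), dropout=0.0,
                           max_epochs=500, patience=100, random_state=3)
        net.fit(X, y)
        Xt = rng.uniform(-1, 1, (50, 1))
        rep = evaluate(net, Xt, 2.0 * Xt[:, 0], ["y"])
        assert rep.r2[0] >= 0.999

    def test_hand_set_weights_forward_pass(self):
        # one hidden ReLU layer, worked 2-vector input computed by hand:
        # h = relu(W1 x + b1), y = W2 h + b2
        W1 = np.array([[1.0, -1.0], [2.0, 0.5]])  # (2 in, 2 hidden)
        b1 = np.array([0.0, -1.0])
        W2 = np.array([[1.0], [3.0]])  # (2 hidden, 1 out)
        b2 = np.array([0.5])
        net = MLPSurrogate.from_weights([W1, W2], [b1, b2])
        x = np.array([2.0, -1.0])
        # W1^T x + b1 = [2*1 + (-1)*2, 2*(-1) + (-1)*0.5 - 1] = [0, -3.5]
        # relu -> [0, 0]; y = 0.5
        assert net.predict(x) == pytest.approx([0.5])
        x2 = np.array([1.0, 1.0])
        # pre-act = [1+2, -1+0.5-1] = [3, -1.5]; relu [3, 0]; y = 3 + 0.5
        assert net.predict(x2) == pytest.approx([3.5])

    def test_prediction_deterministic_across_calls(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 1, (60, 3))
        y = X @ np.array([1.0, -2.0, 0.5])
        net = MLPSurrogate(hidden_layer_sizes=(8,), max_epochs=120,
                           patience=50, random_state=0).fit(X, y)
        a = net.predict(X)
        assert np.array_equal(a, net.predict(X))

    def test_fixed_seed_identical_weights(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, (80, 2))
        y = np.column_stack([X.sum(axis=1), X.prod(axis=1)])
        kw = dict(hidden_layer_sizes=(8, 4), max_epochs=100, patience=30,
                  random_state=11)
        n1 = MLPSurrogate(**kw).fit(X, y)
        n2 = MLPSurrogate(**kw).fit(X, y)
        for a, b in zip(n1.coefs_, n2.coefs_):
            assert np.array_equal(a, b)

    def test_early_stop_triggers_after_patience_on_plateau(self):
        # zero learning rate: validation MAE is flat from epoch 0
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 1, (40, 2))
        y = X[:, 0]
        net = MLPSurrogate(hidden_layer_sizes=(4,), learning_rate=0.0,
                           dropout=0.0, patience=10, max_epochs=500,
                           random_state=5).fit(X, y)
        assert net.best_epoch_ == 0
        assert net.n_iter_ == 11  # stopped exactly patience epochs later

    def test_wrong_input_width_rejected(self):
        net = MLPSurrogate.from_weights(
            [np.ones((2, 2)), np.ones((2, 1))], [np.zeros(2), np.zeros(1)])
        with pytest.raises(ValueError, match="expected 2 inputs"):
            net.predict(np.ones((3, 3)))

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(6)
        X = rng.uniform(0, 1, (60, 3))
        y = np.column_stack([X.sum(axis=1), X[:, 0]])
        net = MLPSurrogate(hidden_layer_sizes=(8,), max_epochs=80,
                           patience=20, random_state=1).fit(X, y)
        net.save(tmp_path / "net.json")
        back = MLPSurrogate.load(tmp_path / "net.json")
        assert np.allclose(back.predict(X), net.predict(X), atol=1e-12)

    def test_invalid_patience_rejected(self):
        with pytest.raises(ValueError):
            MLPSurrogate(patience=100, max_epochs=50).fit(
                np.ones((10, 1)) * np.arange(10)[:, None], np.arange(10.0))


class _ConstModel:
    def __init__(self, c):
        self.c = np.atleast_1d(c)

    def predict(self, X):
        return np.tile(self.c, (len(X), 1))


class TestEvaluate:
    def test_perfect_predictions(self):
        X = np.arange(10.0)[:, None]
        y = 3 * X[:, 0]

        class Exact:
            def predict(self, X):
                return 3 * X[:, 0]

        rep = evaluate(Exact(), X, y, ["t"])
        assert rep.mae[0] == 0 and rep.r2[0] == 1

    def test_constant_mean_predictor_scores_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        rep = evaluate(_ConstModel(y.mean()), np.zeros((4, 1)), y, ["t"])
        assert rep.r2[0] == pytest.approx(0.0, abs=1e-12)

    def test_five_row_fixture_matches_hand_arithmetic(self):
        y = np.array([10.0, 12.0, 8.0, 11.0, 9.0])
        pred = np.array([11.0, 11.0, 9.0, 10.0, 10.0])

        class Fixed:
            def predict(self, X):
                return pred

        rep = evaluate(Fixed(), np.zeros((5, 1)), y, ["t"])
        # by hand: residuals [-1, 1, -1, 1, -1]
        assert rep.mae[0] == pytest.approx(1.0)
        assert rep.rmse[0] == pytest.approx(1.0)
        assert rep.mae_pct[0] == pytest.approx(100 * 1.0 / 10.0)
        ss_res, ss_tot = 5.0, float(((y - y.mean()) ** 2).sum())
        assert rep.r2[0] == pytest.approx(1 - ss_res / ss_tot)
        assert rep.mae[0] <= rep.rmse[0]

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError):
            evaluate(_ConstModel(0.0), np.zeros((0, 1)), np.zeros(0))


class TestCrossValidate:
    def test_linear_fixture_near_zero_error(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(-1, 1, (60, 1))
        y = 3.0 * X[:, 0] + 1.0
        cv = crossvalidate(X, y, k=3, seed=0, output_names=["y"],
                           hidden_layer_sizes=(16,), dropout=0.0,
                           max_epochs=400, patience=100)
        assert cv["r2_mean"][0] > 0.995

    def test_fold_partition_reproducible(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(0, 1, (40, 2))
        y = X.sum(axis=1)
        kw = dict(k=4, seed=9, output_names=["y"], hidden_layer_sizes=(4,),
                  max_epochs=50, patience=20)
        a = crossvalidate(X, y, **kw)
        b = crossvalidate(X, y, **kw)
        assert np.array_equal(a["r2_mean"], b["r2_mean"])

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            crossvalidate(np.zeros((10, 1)), np.zeros(10), k=1)


class TestResidualModel:
    def test_sigma_matches_known_noise_scale(self):
        rng = np.random.default_rng(10)
        y = rng.normal(0.0, 2.0, (4000, 1))
        model = fit_residual_model(_ConstModel(0.0), np.zeros((4000, 1)), y,
                                   ["t"])
        assert model.sigma[0] == pytest.approx(2.0, rel=0.05)

    def test_sigma_equals_evaluate_rmse_exactly(self):
        rng = np.random.default_rng(11)
        y = rng.normal(5.0, 1.0, (50, 1))
        m = _ConstModel(5.0)
        rep = evaluate(m, np.zeros((50, 1)), y, ["t"])
        model = fit_residual_model(m, np.zeros((50, 1)), y, ["t"])
        assert model.sigma[0] == rep.rmse[0]

    def test_zero_residuals_rejected(self):
        y = np.full((10, 1), 3.0)
        with pytest.raises(ValueError, match="degenerate"):
            fit_residual_model(_ConstModel(3.0), np.zeros((10, 1)), y, ["t"])

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            ResidualModel(sigma=np.array([1.0, 0.0, 2.0]))

    def test_sampling_reproducible(self):
        model = ResidualModel(sigma=np.array([1.0, 2.0]))
        a = model.sample(5, np.random.default_rng(1))
        b = model.sample(5, np.random.default_rng(1))
        assert np.array_equal(a, b)


class TestPolyBaseline:
    def test_exact_quadratic_recovered(self):
        rng = np.random.default_rng(12)
        X = rng.uniform(-1, 1, (50, 2))
        y = 1 + 2 * X[:, 0] - X[:, 1] + 3 * X[:, 0] * X[:, 1] + X[:, 1] ** 2
        model, rep = poly_baseline(X, y[:, None], X, y[:, None], degree=2)
        assert rep.r2[0] == pytest.approx(1.0, abs=1e-10)

    def test_degree_one_on_linear_target(self):
        X = np.arange(10.0)[:, None]
        y = 2 * X[:, 0] + 1
        model, rep = poly_baseline(X, y[:, None], X, y[:, None], degree=1)
        assert rep.r2[0] == pytest.approx(1.0, abs=1e-10)

    def test_underdetermined_fit_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            PolySurface(degree=3).fit(np.zeros((4, 3)), np.zeros(4))


class TestRandomSearch:
    def test_reproducible_and_returns_best_by_val_mae(self):
        from latticeplate.surrogate import random_search
        rng = np.random.default_rng(14)
        X = rng.uniform(-1, 1, (80, 2))
        y = X.sum(axis=1)
        Xv = rng.uniform(-1, 1, (20, 2))
        yv = Xv.sum(axis=1)
        kw = dict(n_trials=3, seed=5, max_epochs=30, patience=10)
        best1, trials1 = random_search(X, y, Xv, yv, **kw)
        best2, trials2 = random_search(X, y, Xv, yv, **kw)
        assert best1 == best2
        assert min(t["val_mae"] for t in trials1) == \
            [t for t in trials1 if t["params"] == best1][0]["val_mae"]


class TestNoLeakage:
    def test_test_set_permutation_never_changes_training(self):
        df = _grid_df()
        tr, va, te = split_stratified(df, seed=13)
        cols = ["d", "a", "t_lat", "t_plate", "P"]
        kw = dict(hidden_layer_sizes=(8,), max_epochs=60, patience=20,
                  random_state=2)
        n1 = MLPSurrogate(**kw).fit(tr[cols].to_numpy(),
                                    tr["sigma_vm_max"].to_numpy(),
                                    X_val=va[cols].to_numpy(),
                                    y_val=va["sigma_vm_max"].to_numpy())
        te_perm = te.sample(frac=1.0, random_state=99)
        n2 = MLPSurrogate(**kw).fit(tr[cols].to_numpy(),
                                    tr["sigma_vm_max"].to_numpy(),
                                    X_val=va[cols].to_numpy(),
                                    y_val=va["sigma_vm_max"].to_numpy())
        for a, b in zip(n1.coefs_, n2.coefs_):
            assert np.array_equal(a, b)
        # residual sigma is a pure function of the (unordered) test split
        r1 = fit_residual_model(n1, te[cols].to_numpy(),
                                te["sigma_vm_max"].to_numpy(), ["s"])
        r2 = fit_residual_model(n2, te_perm[cols].to_numpy(),
                                te_perm["sigma_vm_max"].to_numpy(), ["s"])
        assert r1.sigma[0] == pytest.approx(r2.sigma[0], rel=1e-12)
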