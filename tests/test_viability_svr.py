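import numpy as np
import pytest

from vitaspec import viability_svr
from vitaspec.spectra_io import CalibrationModel
from vitaspec.viability_svr import (
    build_features,
    compute_training_means,
    gkcv_predictions,
    gkcv_rmse,
    is_valid_prediction,
    make_svr,
    predict_samples,
    screen_timepoint_sets,
    targets_and_groups,
    tune_and_train,
)

from conftest import make_sample, make_series, make_spectrum


def linear_problem(n_per_group=4, n_groups=3, n_features=3, seed=0, noise=0.0):
    """Targets exactly linear in the first feature (plus optional noise)."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_per_group * n_groups, n_features))
    y = 50.0 + 10.0 * X[:, 0] + noise * rng.standard_normal(len(X))
    groups = np.repeat([f"E{i}" for i in range(n_groups)], n_per_group)
    return X, y, groups


class TestFeatureConstruction:
    def test_feature_count_is_timepoints_times_wavelengths(self):
        n_wl = 251
        series = [make_series(np.ones((100, n_wl))) for _ in range(3)]
        means1 = compute_training_means(series, [0.0])
        assert build_features(series, [0.0], means1).shape == (3, n_wl)
        means2 = compute_training_means(series, [0.0, 1000.0])
        assert build_features(series, [0.0, 1000.0], means2).shape == (3, 2 * n_wl)

    def test_reordering_timepoints_permutes_feature_blocks(self):
        n_wl = 7
        rng = np.random.default_rng(1)
        series = [make_series(rng.uniform(size=(10, n_wl))) for _ in range(4)]
        means_a = compute_training_means(series, [0.0, 100.0])
        Xa = build_features(series, [0.0, 100.0], means_a)
        means_b = compute_training_means(series, [100.0, 0.0])
        Xb = build_features(series, [100.0, 0.0], means_b)
        np.testing.assert_array_equal(Xa[:, :n_wl], Xb[:, n_wl:])
        np.testing.assert_array_equal(Xa[:, n_wl:], Xb[:, :n_wl])

    def test_unknown_sample_id_is_rejected(self):
        series = [make_series(np.ones((2, 3)), sample_id="ghost")]
        with pytest.raises(KeyError, match="ghost"):
            targets_and_groups(series, [make_sample()])


class TestGroupedCV:
    def test_realisable_linear_target_reaches_epsilon_floor(self):
        # identical design points across groups: the held-out points lie in
        # the training hull, where the affine fit error is bounded by epsilon
        rng = np.random.default_rng(0)
        base = rng.normal(size=(4, 3))
        X = np.vstack([base, base, base])
        y = 50.0 + 10.0 * X[:, 0]
        groups = np.repeat(["E0", "E1", "E2"], 4)
        rmse = gkcv_rmse(X, y, groups, C=100.0, epsilon=0.1)
        assert rmse <= 0.1 + 1e-6

    def test_constant_targets_give_near_zero_rmse(self):
        X, _, groups = linear_problem()
        y = np.full(len(X), 42.0)
        assert gkcv_rmse(X, y, groups, C=1.0, epsilon=0.1) <= 0.1 + 1e-9

    def test_single_group_is_rejected(self):
        X, y, _ = linear_problem()
        with pytest.raises(ValueError, match="2 groups"):
            gkcv_rmse(X, y, np.repeat("E0", len(X)), 1.0, 0.1)

    def test_never_trains_on_held_out_group(self, monkeypatch):
        X, y, groups = linear_problem()
        seen: list[np.ndarray] = []
        real_make_svr = make_svr

        def spy(C, epsilon):
            model = real_make_svr(C, epsilon)
            original_fit = model.fit

            def fit(Xf, yf):
                seen.append(Xf)
                return original_fit(Xf, yf)

            model.fit = fit
            return model

        monkeypatch.setattr(viability_svr, "make_svr", spy)
        gkcv_predictions(X, y, groups, 1.0, 0.1)
        unique = sorted(set(groups))
        assert len(seen) == len(unique)
        for g, Xf in zip(unique, seen):
            held_rows = X[groups == g]
            for row in held_rows:
                assert not any(np.array_equal(row, r) for r in Xf)

    def test_matches_brute_force_qp_oracle(self):
        """Linear epsilon-SVR solved by libsvm agrees with a direct primal
        quadratic program on a tiny 6-point, 2-group instance."""
        from scipy import optimize

        # epsilon = 0 keeps the intercept unique on a tiny instance (see the
        # L1-loss median argument: odd point counts give a strict kink)
        X = np.array([[0.0], [1.0], [2.0], [0.5], [1.5], [2.5]])
        y = np.array([10.0, 30.0, 35.0, 20.0, 25.0, 45.0])
        groups = np.array(["A", "A", "A", "B", "B", "B"])
        C, eps = 2.0, 0.0

        def primal_svr(Xtr, ytr):
            n, d = Xtr.shape

            def objective(z):
                w, b, xi = z[:d], z[d], z[d + 1 :]
                return 0.5 * w @ w + C * xi.sum()

            def constraint(z):
                w, b, xi = z[:d], z[d], z[d + 1 :]
                resid = np.abs(Xtr @ w + b - ytr)
                return (eps + xi) - resid  # >= 0

            z0 = np.zeros(d + 1 + n)
            sol = optimize.minimize(
                objective,
                z0,
                constraints=[{"type": "ineq", "fun": constraint}],
                bounds=[(None, None)] * (d + 1) + [(0, None)] * n,
                method="SLSQP",
                options={"maxiter": 500, "ftol": 1e-12},
            )
            assert sol.success
            return sol.x[:d], sol.x[d]

        pooled_sq = []
        for g in ["A", "B"]:
            held = groups == g
            w, b = primal_svr(X[~held], y[~held])
            pooled_sq.extend((X[held] @ w + b - y[held]) ** 2)
        oracle_rmse = float(np.sqrt(np.mean(pooled_sq)))
        assert gkcv_rmse(X, y, groups, C, eps) == pytest.approx(
            oracle_rmse, abs=1e-3
        )


class TestScreening:
    def test_single_candidate_is_chosen(self):
        X, y, groups = linear_problem()
        table, chosen = screen_timepoint_sets([X], [[0.0]], y, groups)
        assert chosen == 0 and len(table) == 1

    def test_ranking_matches_independent_rmse_calls(self):
        X, y, groups = linear_problem()
        rng = np.random.default_rng(5)
        X_noisy = np.hstack([X, rng.normal(size=X.shape)])
        candidates = [[0.0], [0.0, 1000.0]]
        table, chosen = screen_timepoint_sets(
            [X, X_noisy], candidates, y, groups
        )
        independent = [
            gkcv_rmse(F, y, groups, C=1.0, epsilon=0.1) for F in (X, X_noisy)
        ]
        np.testing.assert_allclose(table["gkcv_rmse"].to_numpy(), independent)
        assert chosen == int(np.argmin(independent))

    def test_uninformative_extra_timepoints_lose_to_first_frame_alone(self):
        """When only the first frame carries signal, appending pure-noise
        blocks cannot beat the single-spectrum candidate."""
        X, y, groups = linear_problem(n_per_group=8, noise=1.0, seed=2)
        rng = np.random.default_rng(3)
        X_extra = np.hstack([X, 5.0 * rng.normal(size=(len(X), 6))])
        table, chosen = screen_timepoint_sets(
            [X, X_extra], [[0.0], [0.0, 1244.0]], y, groups
        )
        assert chosen == 0


class TestTuneAndTrain:
    def make_means(self, n_timepoints, n_wl):
        return [make_spectrum(np.zeros(n_wl)) for _ in range(n_timepoints)]

    def test_single_point_grid_is_returned(self):
        X, y, groups = linear_problem()
        grid = {"C": [0.7], "epsilon": [0.05]}
        model, table = tune_and_train(
            X, y, groups, grid, [0.0], self.make_means(1, X.shape[1])
        )
        assert model.C == 0.7 and model.epsilon == 0.05
        assert len(table) == 1

    def test_choice_equals_exhaustive_recomputation(self):
        X, y, groups = linear_problem(noise=2.0, seed=4)
        grid = {"C": [0.1, 1.0, 10.0], "epsilon": [0.01, 0.1, 1.0]}
        model, table = tune_and_train(
            X, y, groups, grid, [0.0], self.make_means(1, X.shape[1])
        )
        best = None
        for C in grid["C"]:
            for eps in grid["epsilon"]:
                rmse = gkcv_rmse(X, y, groups, C, eps)
                if best is None or rmse < best[2]:
                    best = (C, eps, rmse)
        assert (model.C, model.epsilon) == best[:2]

    def test_primal_weights_reproduce_trainer_predictions(self):
        X, y, groups = linear_problem(noise=1.0, seed=6)
        grid = {"C": [1.0], "epsilon": [0.1]}
        model, _ = tune_and_train(
            X, y, groups, grid, [0.0], self.make_means(1, X.shape[1])
        )
        trainer = make_svr(1.0, 0.1).fit(X, y)
        np.testing.assert_allclose(
            model.predict_features(X), trainer.predict(X), atol=1e-8
        )

    def test_tuned_model_not_worse_than_defaults_in_training(self):
        X, y, groups = linear_problem(noise=3.0, seed=7)
        model, table = tune_and_train(
            X,
            y,
            groups,
            viability_svr.DEFAULT_GRID,
            [0.0],
            self.make_means(1, X.shape[1]),
        )
        default_rmse = gkcv_rmse(X, y, groups, 1.0, 0.1)
        assert table["gkcv_rmse"].min() <= default_rmse + 1e-9


class TestPredictionValidity:
    @pytest.mark.parametrize(
        "value,valid",
        [(-5.0, False), (100.1, False), (100.0, True), (0.0, True), (50.0, True)],
    )
    def test_validity_rule(self, value, valid):
        assert is_valid_prediction(value) is valid

    def test_per_sample_averaging_and_flags(self):
        n_wl = 4
        wl = np.arange(500.0, 500.0 + n_wl)
        # model: prediction = sum of frame-0 intensities (means zero)
        model = CalibrationModel(
            model_kind="svr",
            timepoints=[0.0],
            wavelengths=wl,
            mean_spectra=[np.zeros(n_wl)],
            weights=np.ones(n_wl),
            intercept=0.0,
            C=1.0,
            epsilon=0.1,
            concentration_class=1e8,
        )
        def series(level, mid, sid):
            return make_series(
                np.full((2, n_wl), level), wl, measurement_id=mid, sample_id=sid
            )

        measurements = [
            series(10.0, "a1", "s_ok"),   # prediction 40
            series(15.0, "a2", "s_ok"),   # prediction 60 -> mean 50
            series(-5.0, "b1", "s_neg"),  # mean -20 -> invalid
            series(25.0, "c1", "s_ok100"),  # mean 100 -> valid boundary
        ]
        samples = [
            make_sample("s_ok", mids=("a1", "a2"), f_live_ref=50.0),
            make_sample("s_neg", mids=("b1",), f_live_ref=0.0),
            make_sample("s_ok100", mids=("c1",), f_live_ref=100.0),
        ]
        report = predict_samples(model, measurements, samples)
        by_id = report.set_index("sample_id")
        assert by_id.loc["s_ok", "prediction"] == pytest.approx(50.0)
        assert bool(by_id.loc["s_ok", "valid"])
        assert not bool(by_id.loc["s_neg", "valid"])
        assert bool(by_id.loc["s_ok100", "valid"])

    def test_unknown_measurement_id_is_rejected(self):
        model = CalibrationModel(
            model_kind="svr",
            timepoints=[0.0],
            wavelengths=np.arange(3.0),
            mean_spectra=[np.zeros(3)],
            weights=np.zeros(3),
            intercept=0.0,
            C=1.0,
            epsilon=0.1,
            concentration_class=1e8,
        )
        with pytest.raises(KeyError, match="missing"):
            predict_samples(model, [], [make_sample(mids=("missing",))])
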