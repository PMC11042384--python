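"""Model construction, training contracts and the hyperparameter search."""

import numpy as np
import pandas as pd
import pytest

import guidescreen as gs
from guidescreen.boost import (
    DEFAULT_GRID,
    XgbSearchSpec,
    fit_xgb,
    grid_size,
    predict_xgb,
    sample_configs,
    xgb_search_and_train,
)
from guidescreen.cnn import (
    ABLATIONS,
    CnnModel,
    CnnSpec,
    TrainSpec,
    build_cnn,
    conv_group_output_length,
    flattened_conv_dim,
    predict,
    train_cnn,
)


def random_onehot(n, rng):
    idx = rng.integers(0, 4, size=(n, 20))
    oh = np.zeros((n, 4, 20))
    oh[np.arange(n)[:, None], idx, np.arange(20)[None, :]] = 1.0
    return oh, idx


def valid_conv_dim_oracle(groups, stride2, pool):
    """Independent valid-convolution arithmetic: floor((L-k)/s)+1, then pooling."""
    total = 0
    for k, f in groups:
        if k == 2:
            total += ((20 - k) // stride2 + 1) * f
        else:
            total += (((20 - k) // 1 + 1) // pool) * f
    return total


class TestArchitecture:
    @pytest.mark.parametrize("ablation, expected", [("full", 2240), ("no57", 1400), ("no357", 500)])
    def test_flattened_dim_matches_arithmetic(self, ablation, expected):
        spec = CnnSpec(ablation=ablation)
        assert flattened_conv_dim(spec) == expected
        assert valid_conv_dim_oracle(spec.kernel_groups, 2, 2) == expected
        # and the actual wiring agrees
        model = build_cnn(spec, 3, seed=0)
        assert model.seq_fc.W.shape == (expected, 80)

    def test_group_lengths(self):
        spec = CnnSpec()
        assert [conv_group_output_length(k, spec) for k, _ in spec.kernel_groups] == [10, 9, 8, 7]

    def test_embedding_and_mono_dimensions(self):
        model = build_cnn(CnnSpec(), 5, seed=0)
        assert model.seq_fc.W.shape[1] == 80
        assert model.mono_dim == 20
        assert model.head[0]["fc"].W.shape[0] == 80 + 20 + 5

    def test_sequence_only_model(self):
        model = build_cnn(CnnSpec(), 0, seed=0)
        oh, _ = random_onehot(4, np.random.default_rng(0))
        assert model.forward(oh).shape == (4,)

    def test_annotation_shape_mismatch_rejected(self):
        model = build_cnn(CnnSpec(), 5, seed=0)
        oh, _ = random_onehot(4, np.random.default_rng(0))
        with pytest.raises(ValueError, match="annotation"):
            model.forward(oh, np.zeros((4, 3)))
        with pytest.raises(ValueError, match="annotation"):
            model.forward(oh)

    def test_unknown_ablation_rejected(self):
        with pytest.raises(ValueError, match="ablation"):
            CnnSpec(ablation="no2").kernel_groups


class TestGradients:
    def test_input_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        model = build_cnn(CnnSpec(), 3, seed=1)
        oh, _ = random_onehot(2, rng)
        ann = rng.normal(size=(2, 3))
        g_seq, g_ann = model.input_gradient(oh, ann)
        eps = 1e-6
        for (i, b, p) in [(0, 0, 0), (1, 2, 10), (0, 3, 19)]:
            up, down = oh.copy(), oh.copy()
            up[i, b, p] += eps
            down[i, b, p] -= eps
            fd = (model.forward(up, ann)[i] - model.forward(down, ann)[i]) / (2 * eps)
            assert g_seq[i, b, p] == pytest.approx(fd, abs=1e-4)
        for (i, j) in [(0, 0), (1, 2)]:
            up, down = ann.copy(), ann.copy()
            up[i, j] += eps
            down[i, j] -= eps
            fd = (model.forward(oh, up)[i] - model.forward(oh, down)[i]) / (2 * eps)
            assert g_ann[i, j] == pytest.approx(fd, abs=1e-4)

    def test_parameter_gradients_match_finite_differences(self):
        rng = np.random.default_rng(1)
        model = build_cnn(CnnSpec(ablation="no357"), 2, seed=2)
        oh, _ = random_onehot(8, rng)
        ann = rng.normal(size=(8, 2))
        y = rng.integers(0, 2, 8).astype(float)
        from guidescreen._nn import bce_with_logits

        out = model.forward(oh, ann)
        _, dout = bce_with_logits(out, y)
        model.backward(dout)
        params, grads = model.params(), model.grads()
        eps = 1e-6
        checked = 0
        for p, g in zip(params, grads):
            flat_idx = p.size // 2
            orig = p.flat[flat_idx]
            p.flat[flat_idx] = orig + eps
            up = bce_with_logits(model.forward(oh, ann), y)[0]
            p.flat[flat_idx] = orig - eps
            down = bce_with_logits(model.forward(oh, ann), y)[0]
            p.flat[flat_idx] = orig
            assert g.flat[flat_idx] == pytest.approx((up - down) / (2 * eps), abs=1e-5)
            checked += 1
        assert checked == len(params)


class TestTraining:
    def _toy(self, n=600, seed=0):
        rng = np.random.default_rng(seed)
        oh, idx = random_onehot(n, rng)
        y = (idx[:, 0] == 2).astype(float)  # G at position 1
        return oh, y

    def test_determinism_same_seed_identical_predictions(self):
        oh, y = self._toy()
        spec = TrainSpec(learning_rate=1e-3, batch_size=128, max_epochs=3, seed=7)
        preds = []
        for _ in range(2):
            m = build_cnn(CnnSpec(), 0, seed=7)
            train_cnn(m, (oh[:500], None, y[:500]), (oh[500:], None, y[500:]), spec)
            preds.append(predict(m, oh[500:]))
        np.testing.assert_array_equal(preds[0], preds[1])

    def test_learnable_rule_is_learned(self):
        oh, y = self._toy(n=2000, seed=1)
        m = build_cnn(CnnSpec(), 0, seed=0)
        spec = TrainSpec(learning_rate=1e-3, batch_size=256, max_epochs=25, patience=10, seed=0)
        hist = train_cnn(m, (oh[:1600], None, y[:1600]), (oh[1600:], None, y[1600:]), spec)
        assert gs.auc(predict(m, oh[1600:]), y[1600:]) > 0.9
        # loss drops over early epochs on a learnable task
        assert hist["train_loss"].iloc[-1] < hist["train_loss"].iloc[0]

    def test_single_class_aborts(self):
        oh, _ = self._toy(n=50)
        with pytest.raises(ValueError, match="single class"):
            train_cnn(build_cnn(CnnSpec(), 0, seed=0), (oh, None, np.ones(50)), None,
                      TrainSpec(max_epochs=1))

    def test_empty_training_set_aborts(self):
        with pytest.raises(ValueError, match="empty"):
            train_cnn(build_cnn(CnnSpec(), 0, seed=0), (np.zeros((0, 4, 20)), None, np.zeros(0)),
                      None, TrainSpec(max_epochs=1))

    def test_binary_predictions_in_unit_interval_and_pure(self):
        oh, y = self._toy(n=300)
        m = build_cnn(CnnSpec(), 0, seed=0)
        train_cnn(m, (oh, None, y), None, TrainSpec(max_epochs=2, learning_rate=1e-3))
        p = predict(m, oh[:50])
        assert np.all((p >= 0) & (p <= 1))
        # pure function: same rows give the same scores (up to BLAS summation order)
        np.testing.assert_allclose(p[:10], predict(m, oh[:10]), rtol=0, atol=1e-10)
        assert predict(m, np.zeros((0, 4, 20))).shape == (0,)


class TestXgbSearch:
    def _data(self, n=300, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("abcde"))
        y = (X["a"] + 0.5 * X["b"] > 0).astype(float).to_numpy()
        return X, y

    def test_sample_without_replacement_and_determinism(self):
        spec = XgbSearchSpec(search_seed=11)
        configs = sample_configs(spec)
        assert len(configs) == 57
        assert len({tuple(sorted(c.items())) for c in configs}) == 57
        assert configs == sample_configs(XgbSearchSpec(search_seed=11))
        assert configs != sample_configs(XgbSearchSpec(search_seed=12))
        assert grid_size(DEFAULT_GRID) == 4 * 4 * 6 * 6 * 5 * 4

    def test_grid_smaller_than_n_configs_errors(self):
        small = {"max_depth": (3,), "eta": (0.1, 0.2)}
        with pytest.raises(ValueError, match="exceeds grid size"):
            sample_configs(XgbSearchSpec(grid=small, n_configs=3))

    def test_degenerate_single_config_search(self):
        X, y = self._data()
        grid = {"max_depth": (3,), "min_child_weight": (8,), "subsample": (1.0,),
                "colsample_bytree": (1.0,), "alpha": (10,), "eta": (0.3,)}
        spec = XgbSearchSpec(grid=grid, n_configs=1, n_rounds=20)
        best, booster, board = xgb_search_and_train(X, y, "fitness", spec)
        assert best == {"max_depth": 3, "min_child_weight": 8, "subsample": 1.0,
                        "colsample_bytree": 1.0, "alpha": 10, "eta": 0.3}
        assert len(board) == 1

    def test_flexible_config_wins_on_separable_data(self):
        X, y = self._data(n=500, seed=3)
        grid = {"max_depth": (1, 0), "min_child_weight": (8,), "subsample": (1.0,),
                "colsample_bytree": (1.0,), "alpha": (10,), "eta": (0.3,)}
        spec = XgbSearchSpec(grid=grid, n_configs=2, n_rounds=30, search_seed=0)
        _, _, board = xgb_search_and_train(X, y, "fitness", spec)
        deep = board.loc[board["max_depth"] == 0, "cv_score"].iloc[0]
        stump = board.loc[board["max_depth"] == 1, "cv_score"].iloc[0]
        assert deep >= stump

    def test_predict_feature_mismatch_listed(self):
        X, y = self._data()
        booster = fit_xgb(X, y, "fitness", n_rounds=5)
        bad = X.rename(columns={"a": "z"})
        with pytest.raises(ValueError, match="missing=\\['a'\\]"):
            predict_xgb(booster, bad)

    def test_predict_reorders_columns(self):
        X, y = self._data()
        booster = fit_xgb(X, y, "fitness", n_rounds=5)
        np.testing.assert_allclose(predict_xgb(booster, X[list("edcba")]), predict_xgb(booster, X))


class TestMonotoneAnnotation:
    def test_increasing_planted_positive_annotation_does_not_lower_mean_probability(
        self, screen, fitness_models
    ):
        """Cohort-level monotonicity in the planted-positive H3K27ac analog."""
        te = screen["te"]
        tab = screen["tabular"].iloc[te]
        base = predict_xgb(fitness_models["xgb"], tab).mean()
        bumped = tab.copy()
        bumped["H3K27ac"] = bumped["H3K27ac"] + 1.0
        assert predict_xgb(fitness_models["xgb"], bumped).mean() >= base - 1e-6

        cnn = fitness_models["cnn"]
        oh, ann = screen["one_hot"][te], screen["annotations"].to_numpy()[te]
        col = list(screen["annotations"].columns).index("H3K27ac")
        ann_up = ann.copy()
        ann_up[:, col] += 1.0
        assert predict(cnn, oh, ann_up).mean() >= predict(cnn, oh, ann).mean() - 1e-6
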