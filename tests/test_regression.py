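"""Model/Results surface: preprocessing, fitting, evaluation, persistence."""

import numpy as np
import pandas as pd
import pytest

from irphos.regression import (
    HyperparamSpace,
    PhosphorPropertyModel,
    PhosphorPropertyResults,
    Preprocessor,
    train_ridge,
)


def linear_data(n=300, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.uniform(-1, 1, size=(n, 4)),
        columns=["el_CN_ip", "el_CN_homo", "el_NN_ip", "el_NN_ea"],
    )
    # intercept keeps y strictly positive so the zero floor never bites
    y = 4.0 + 1.5 * X["el_CN_ip"] - 0.7 * X["el_NN_ip"] + noise * rng.standard_normal(n)
    return X, y


class TestPreprocessor:
    def test_standardizes_and_round_trips(self):
        X, _ = linear_data()
        prep = Preprocessor().fit(X)
        Z = prep.transform(X)
        assert Z.mean(axis=0) == pytest.approx(np.zeros(4), abs=1e-12)
        assert Z.std(axis=0) == pytest.approx(np.ones(4))
        assert prep.inverse_transform(Z) == pytest.approx(X.to_numpy())

    def test_invariant_columns_dropped(self):
        X, _ = linear_data(n=50)
        X["constant"] = 3.14
        prep = Preprocessor().fit(X)
        assert prep.dropped_names == ["constant"]
        assert prep.transform(X).shape == (50, 4)

    def test_non_finite_rejected(self):
        X, _ = linear_data(n=10)
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            Preprocessor().fit(X)


class TestRidge:
    def test_noiseless_linear_recovery(self):
        X, y = linear_data(noise=0.0)
        res = train_ridge(X, y, alpha=1e-8)
        assert res.evaluate(X, y)["mae"] < 1e-6

    def test_duplicate_columns_stay_finite(self):
        X, y = linear_data(n=100)
        X["el_CN_ip_copy"] = X["el_CN_ip"]
        res = train_ridge(X, y, alpha=1e-3)
        assert np.all(np.isfinite(res.estimator.coef_))

    def test_predictions_floored_at_zero(self):
        X, y = linear_data(n=100)
        res = train_ridge(X, y - 100.0 + 100.0, alpha=1e-6)  # y as-is
        far = X.copy()
        far.iloc[:, :] = -50.0  # extrapolate to hugely negative response
        assert np.all(res.predict(far) >= 0.0)


class TestRandomForest:
    def test_importances_normalized_and_planted_feature_first(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(
            rng.uniform(size=(300, 5)),
            columns=[f"el_CN_f{i}" for i in range(3)]
            + [f"el_NN_f{i}" for i in range(2)],
        )
        y = 3.0 * X["el_NN_f1"] + 0.01 * rng.standard_normal(300)
        res = PhosphorPropertyModel(X, y, kind="rf").fit(seed=0)
        imp = res.importances()
        assert imp.sum() == pytest.approx(1.0)
        assert imp.index[0] == "el_NN_f1"
        blocks = res.importance_by_block()
        assert blocks["NN"] > blocks["CN"]
        assert sum(blocks.values()) == pytest.approx(1.0)


class TestANN:
    def test_learns_linear_map_and_floors(self):
        X, y = linear_data(n=400, noise=0.0)
        res = PhosphorPropertyModel(X, y, kind="ann").fit(seed=0)
        assert res.evaluate(X, y)["mae"] < 0.2
        assert np.all(res.predict(X) >= 0.0)

    def test_constant_target_learned(self):
        X, _ = linear_data(n=100)
        y = np.full(100, 5.0)
        res = PhosphorPropertyModel(X, y, kind="ann").fit(seed=0)
        assert res.evaluate(X, y)["mae"] < 0.3

    def test_latent_dimension_and_determinism(self):
        X, y = linear_data(n=200)
        res = PhosphorPropertyModel(X, y, kind="ann").fit(seed=0)
        lat = res.latent(X)
        assert lat.shape == (200, res.hyperparams["hidden_layer_sizes"][-1])
        assert res.latent(X) == pytest.approx(lat)
        assert res.training_latents == pytest.approx(lat)

    def test_search_selects_by_validation_mae(self):
        X, y = linear_data(n=250, noise=0.05)
        Xv, yv = linear_data(n=80, seed=5, noise=0.05)
        space = HyperparamSpace(budget=3, width=(16, 64))
        res = PhosphorPropertyModel(
            X, y, kind="ann", X_val=Xv, y_val=yv, space=space
        ).fit(seed=1)
        assert res.val_mae is not None
        assert res.n_train == 330  # refit on train+val

    def test_non_ann_has_no_latent(self):
        X, y = linear_data(n=50)
        res = train_ridge(X, y)
        with pytest.raises(ValueError, match="latent"):
            res.latent(X)


class TestEvaluation:
    def test_mae_of_constant_offset(self):
        X, y = linear_data(n=200, noise=0.0)
        res = train_ridge(X, y, alpha=1e-8)
        metrics = res.evaluate(X, y + 0.5)
        assert metrics["mae"] == pytest.approx(0.5, abs=1e-6)

    def test_scaled_mae_affine_invariant(self):
        X, y = linear_data(n=200, noise=0.05)
        res1 = train_ridge(X, y)
        s1 = res1.evaluate(X, y)["scaled_mae"]
        res2 = train_ridge(X, 10.0 * y + 3.0)
        s2 = res2.evaluate(X, 10.0 * y + 3.0)["scaled_mae"]
        assert s2 == pytest.approx(s1, rel=1e-6)

    def test_empty_test_set_rejected(self):
        X, y = linear_data(n=50)
        res = train_ridge(X, y)
        with pytest.raises(ValueError, match="empty"):
            res.evaluate(X.iloc[:0], y[:0])


class TestPersistence:
    @pytest.mark.parametrize("kind", ["ann", "ridge", "rf"])
    def test_save_load_round_trip(self, kind, tmp_path):
        X, y = linear_data(n=150)
        res = PhosphorPropertyModel(X, y, kind=kind).fit(seed=0)
        res.save(tmp_path / kind)
        back = PhosphorPropertyResults.load(tmp_path / kind)
        assert back.predict(X) == pytest.approx(res.predict(X), abs=1e-8)
        if kind == "ann":
            assert back.training_latents == pytest.approx(res.training_latents)


def test_summary_mentions_key_facts():
    X, y = linear_data(n=80)
    res = PhosphorPropertyModel(X, y, kind="rf", target="lifetime").fit(seed=0)
    text = res.summary()
    assert "lifetime" in text and "rf" in text and "importance" in text
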