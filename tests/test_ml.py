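import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.dummy import DummyClassifier

from plasmafrag.ml import (
    assemble_features,
    benchmark_methods,
    per_modality_consistency,
    train_eval_sgd,
)


def toy_matrix(n=100, seed=0, informative=True, n_noise=5):
    rng = np.random.default_rng(seed)
    labels = pd.Series(
        ["cancer"] * (n // 2) + ["healthy"] * (n - n // 2),
        index=[f"s{i}" for i in range(n)],
    )
    y = (labels == "cancer").to_numpy(float)
    signal = y * 2 + rng.normal(0, 1, n) if informative else rng.normal(0, 1, n)
    blocks = {
        "signal": pd.DataFrame({"x": signal}, index=labels.index),
        "noise": pd.DataFrame(
            rng.normal(size=(n, n_noise)),
            index=labels.index,
            columns=[f"n{i}" for i in range(n_noise)],
        ),
    }
    return blocks, labels


class TestAssembleFeatures:
    def test_blocks_concatenated_with_prefixes(self):
        blocks, labels = toy_matrix(20)
        m = assemble_features(blocks, labels)
        assert m.X.shape == (20, 6)
        assert set(m.blocks) == {"signal", "noise"}
        assert all(c.startswith("signal.") for c in m.blocks["signal"])

    def test_constant_column_dropped(self):
        blocks, labels = toy_matrix(20)
        blocks["signal"]["const"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            m = assemble_features(blocks, labels)
        assert "signal.const" not in m.X.columns

    def test_missing_modality_imputed(self):
        blocks, labels = toy_matrix(20)
        blocks["noise"].iloc[0, 0] = np.nan
        m = assemble_features(blocks, labels)
        assert not m.X.isna().any().any()

    def test_zero_width_block_skipped(self):
        blocks, labels = toy_matrix(10)
        blocks["empty"] = pd.DataFrame(index=labels.index)
        with pytest.warns(UserWarning, match="zero columns"):
            m = assemble_features(blocks, labels)
        assert "empty" not in m.blocks


class TestTrainEvalSGD:
    def test_separable_feature_gives_auc_one(self):
        labels = pd.Series(
            ["cancer"] * 20 + ["healthy"] * 20,
            index=[f"s{i}" for i in range(40)],
        )
        x = np.r_[np.ones(20) + np.arange(20) * 0.01, -np.ones(20)]
        blocks = {"b": pd.DataFrame({"x": x}, index=labels.index)}
        m = assemble_features(blocks, labels)
        rep = train_eval_sgd(m, folds=5, seed=3)
        assert rep.cv_auc == 1.0
        assert rep.test_auc == 1.0
        off_diag = rep.confusion.to_numpy()[0, 1] + rep.confusion.to_numpy()[1, 0]
        assert off_diag == 0

    def test_permuted_labels_auc_near_half(self):
        blocks, labels = toy_matrix(100, seed=5)
        rng = np.random.default_rng(6)
        permuted = pd.Series(
            rng.permutation(labels.to_numpy()), index=labels.index
        )
        m = assemble_features(blocks, permuted)
        rep = train_eval_sgd(m, folds=10, seed=7)
        assert 0.35 <= rep.cv_auc <= 0.65

    def test_fixed_seed_bit_reproducible(self):
        blocks, labels = toy_matrix(60, seed=8)
        m = assemble_features(blocks, labels)
        a = train_eval_sgd(m, folds=5, seed=9)
        b = train_eval_sgd(m, folds=5, seed=9)
        assert a.cv_auc == b.cv_auc
        assert a.test_auc == b.test_auc
        assert (a.probabilities == b.probabilities).all()

    def test_single_class_rejected(self):
        blocks, labels = toy_matrix(20)
        labels[:] = "cancer"
        m = assemble_features(blocks, labels)
        with pytest.raises(ValueError, match="both classes"):
            train_eval_sgd(m)

    def test_folds_reduced_with_warning(self):
        blocks, labels = toy_matrix(8)
        m = assemble_features(blocks, labels)
        with pytest.warns(UserWarning, match="reducing folds"):
            rep = train_eval_sgd(m, folds=10, seed=1)
        assert rep.n_folds == 4

    def test_roc_monotone(self):
        blocks, labels = toy_matrix(80, seed=10)
        m = assemble_features(blocks, labels)
        rep = train_eval_sgd(m, folds=5, seed=11)
        fpr = rep.cv_roc["fpr"].to_numpy()
        tpr = rep.cv_roc["tpr"].to_numpy()
        assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()


class TestPerModalityConsistency:
    def test_identical_blocks_identical_predictions(self):
        blocks, labels = toy_matrix(40, seed=12)
        blocks["signal2"] = blocks["signal"].copy()
        m = assemble_features(
            {"signal": blocks["signal"], "signal2": blocks["signal2"]}, labels
        )
        out = per_modality_consistency(m, folds=4, seed=13)
        assert (out["pred_signal"] == out["pred_signal2"]).all()

    def test_noise_block_near_chance(self):
        blocks, labels = toy_matrix(100, seed=14)
        m = assemble_features(blocks, labels)
        out = per_modality_consistency(m, folds=5, seed=15)
        acc_noise = (out["pred_noise"] == out["label"]).mean()
        assert 0.35 <= acc_noise <= 0.65

    def test_majority_vote_close_to_best_block(self):
        rng = np.random.default_rng(16)
        n = 100
        labels = pd.Series(
            ["cancer"] * 50 + ["healthy"] * 50,
            index=[f"s{i}" for i in range(n)],
        )
        y = (labels == "cancer").to_numpy(float)
        blocks = {
            f"b{i}": pd.DataFrame(
                {"x": y * 1.5 + rng.normal(0, 1, n)}, index=labels.index
            )
            for i in range(3)
        }
        m = assemble_features(blocks, labels)
        out = per_modality_consistency(m, folds=5, seed=17)
        single = max(
            (out[f"pred_b{i}"] == out["label"]).mean() for i in range(3)
        )
        vote = (out["majority_vote"] == out["label"]).mean()
        assert vote >= single - 0.05


class TestBenchmarkMethods:
    def test_duplicate_method_identical_auc(self):
        blocks, labels = toy_matrix(60, seed=18)
        m = assemble_features(blocks, labels)
        res = benchmark_methods(
            m,
            {
                "lr_a": LogisticRegression(max_iter=500),
                "lr_b": LogisticRegression(max_iter=500),
            },
            folds=4,
            seed=19,
        )
        assert res.loc["lr_a", "cv_auc"] == res.loc["lr_b", "cv_auc"]

    def test_dummy_method_near_half_and_run_continues(self):
        blocks, labels = toy_matrix(80, seed=20)
        m = assemble_features(blocks, labels)

        class Broken:
            def get_params(self, deep=True):
                return {}

            def set_params(self, **kw):
                return self

            def fit(self, X, y):
                raise RuntimeError("boom")

        with pytest.warns(UserWarning, match="failed"):
            res = benchmark_methods(
                m,
                {
                    "dummy": DummyClassifier(strategy="prior"),
                    "broken": Broken(),
                    "lr": LogisticRegression(max_iter=500),
                },
                folds=4,
                seed=21,
            )
        assert np.isnan(res.loc["broken", "cv_auc"])
        assert res.loc["lr", "cv_auc"] > 0.8
        assert 0.35 <= res.loc["dummy", "cv_auc"] <= 0.65
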