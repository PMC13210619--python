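"""Classifier baselines: stated hyperparameters, leakage guards, provenance
tags, architecture contracts and end-to-end trainability."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from eegscreen import nn
from eegscreen.evaluation import ProtocolConfig, run_repeated_holdout
from eegscreen.features import spectral_feature_names
from eegscreen.models import (
    LeakageError, ModelConfig, TrainingConfig, build_cnn1d,
    build_eegnet_like, build_shallow_like, channel_zscore_stats,
    fit_extratrees, fit_mlp, inner_subject_split, predict_segment_proba,
    train_raw_model,
)


def _toy_features(n=60, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat(["H", "MDD"], n // 2)
    x = rng.standard_normal((n, 4))
    x[:, 0] += np.where(y == "MDD", 4.0, 0.0)  # separable on feature 0
    return pd.DataFrame(x, columns=list("abcd")), y


class TestExtraTrees:
    def test_importances_sum_to_one(self):
        X, y = _toy_features()
        fitted = fit_extratrees(X, y, seed=0)
        assert fitted.feature_importances.sum() == pytest.approx(1.0, abs=1e-9)

    def test_separable_toy_interpolated(self):
        X, y = _toy_features()
        fitted = fit_extratrees(X, y, seed=0)
        proba = predict_segment_proba(fitted, X)
        assert np.mean((proba >= 0.5) == (y == "MDD")) == 1.0

    def test_stated_hyperparameters(self):
        X, y = _toy_features()
        clf = fit_extratrees(X, y, seed=0).estimator
        assert clf.n_estimators == 300
        assert clf.max_depth is None
        assert clf.criterion == "gini"
        assert clf.class_weight == "balanced"

    def test_single_class_rejected(self):
        X, y = _toy_features()
        with pytest.raises(ValueError):
            fit_extratrees(X, ["H"] * len(X), seed=0)

    def test_same_seed_bit_identical(self):
        X, y = _toy_features()
        a = fit_extratrees(X, y, seed=5)
        b = fit_extratrees(X, y, seed=5)
        assert np.array_equal(a.feature_importances, b.feature_importances)
        assert np.array_equal(predict_segment_proba(a, X),
                              predict_segment_proba(b, X))

    def test_micro_ensemble_vote_consistency(self):
        """Ensemble probability equals the average of the individual trees'
        leaf-class probabilities on a 3-tree toy ensemble."""
        from sklearn.ensemble import ExtraTreesClassifier

        X, y = _toy_features(n=40, seed=3)
        clf = ExtraTreesClassifier(n_estimators=3, random_state=0)
        yi = (y == "MDD").astype(int)
        clf.fit(X.to_numpy(), yi)
        manual = np.mean(
            [t.predict_proba(X.to_numpy())[:, 1] for t in clf.estimators_],
            axis=0,
        )
        assert np.allclose(clf.predict_proba(X.to_numpy())[:, 1], manual)

    def test_planted_effect_tops_importance(self, et_beta_report):
        """On a cohort where only fronto-central beta is elevated, the top
        importance ranks are beta features at the effect channels, with
        relative-beta features among them."""
        from eegscreen.experiments import summarize_importance

        table = summarize_importance(et_beta_report.fitted)
        top8 = list(table.index[:8])
        effect = {f"beta_{kind}_{ch}" for kind in ("rel", "logabs")
                  for ch in ("F3", "F4", "C3", "C4")}
        assert sum(name in effect for name in top8) >= 6
        assert any(name.startswith("beta_rel_") for name in top8)


class TestMlp:
    def test_constant_column_handled(self):
        X, y = _toy_features()
        X["const"] = 1.0
        fitted = fit_mlp(X, y, seed=0)
        proba = predict_segment_proba(fitted, X)
        assert np.all((proba >= 0) & (proba <= 1))

    def test_probabilities_normalised(self):
        X, y = _toy_features(seed=2)
        fitted = fit_mlp(X, y, seed=0)
        full = fitted.estimator.predict_proba(X.to_numpy())
        assert np.allclose(full.sum(axis=1), 1.0)

    def test_stated_hyperparameters(self):
        X, y = _toy_features()
        mlp = fit_mlp(X, y, seed=0).estimator.named_steps["clf"]
        assert mlp.hidden_layer_sizes == (128, 64)
        assert mlp.alpha == 1e-4
        assert mlp.max_iter == 200
        assert mlp.early_stopping and mlp.validation_fraction == 0.15

    def test_null_cohort_chance_level(self, null_run):
        """On the no-effect cohort the MLP's subject-level balanced-accuracy
        CI covers 0.5 across the ten repeats."""
        ds = null_run.dataset.select_features(spectral_feature_names())
        report = run_repeated_holdout(null_run.roster, ds,
                                      ModelConfig(model_id="mlp"),
                                      ProtocolConfig())
        s = report.summary.loc["balanced_accuracy"]
        assert s["ci_low"] <= 0.5 <= s["ci_high"]


class TestArchitectures:
    @pytest.mark.parametrize("builder", [build_cnn1d, build_eegnet_like,
                                         build_shallow_like])
    def test_forward_shape_contract(self, builder):
        model = builder(ModelConfig(model_id="cnn1d", seed=0))
        x = np.random.default_rng(0).standard_normal((2, 8, 1024))
        assert model.forward(x, training=False).shape == (2, 1)

    @pytest.mark.parametrize("builder", [build_cnn1d, build_eegnet_like,
                                         build_shallow_like])
    def test_same_seed_rebuild_identical(self, builder):
        x = np.random.default_rng(0).standard_normal((1, 8, 512))
        a = builder(ModelConfig(model_id="cnn1d", seed=7))
        b = builder(ModelConfig(model_id="cnn1d", seed=7))
        a.forward(x, False)
        b.forward(x, False)
        assert a.n_parameters() == b.n_parameters()
        for pa, pb in zip(a.params(), b.params()):
            assert np.array_equal(pa.value, pb.value)

    def test_eegnet_temporal_kernel_is_half_sampling_rate(self):
        model = build_eegnet_like(ModelConfig(model_id="eegnet_like", seed=0,
                                              sampling_rate=256.0))
        first = model.layers[0]
        assert isinstance(first, nn.Conv1d) and first.k == 128

    def test_shallow_pooling_output_length(self):
        """40 temporal filters of length 25 (no padding) then mean pooling
        (75, stride 15): a 1024-sample epoch yields
        floor((1024-24-75)/15)+1 = 62 pooled frames."""
        model = build_shallow_like(ModelConfig(model_id="shallow_like", seed=0))
        x = np.zeros((1, 8, 1024))
        out_len = (1024 - 24 - 75) // 15 + 1
        model.forward(x, False)
        flat_width = model.layers[-1].inner.w.value.shape[0]
        assert out_len == 62
        assert flat_width == 40 * out_len

    def test_square_then_log_composition(self):
        sq, lg = nn.Square(), nn.LogCompress(eps=1e-6)
        x = np.array([[-2.0, 0.0, 3.0]])[None]
        out = lg.forward(sq.forward(x, True), True)
        assert np.allclose(out, np.log(x**2 + 1e-6))

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError):
            build_cnn1d(ModelConfig(model_id="cnn1d", n_channels=19))

    def test_untrained_model_near_chance(self):
        rng = np.random.default_rng(0)
        model = build_cnn1d(ModelConfig(model_id="cnn1d", seed=0))
        x = rng.standard_normal((40, 8, 512))
        proba = nn.sigmoid(model.forward(x, False).ravel())
        y = np.repeat([0, 1], 20)
        acc = np.mean((proba >= 0.5) == y)
        assert 0.2 <= acc <= 0.8


def _raw_toy(n_subj=12, per=8, L=256, effect=2.5, seed=1):
    rng = np.random.default_rng(seed)
    X, keys, ys = [], [], []
    for s in range(n_subj):
        y = s % 2
        for _ in range(per):
            sig = rng.standard_normal((8, L))
            if y:
                sig[2:4] *= effect
            X.append(sig)
            keys.append(f"{'MDD' if y else 'H'}_S{s}")
            ys.append(y)
    return np.stack(X), np.array(keys), np.array(ys)


class TestRawTraining:
    def test_inner_split_subject_wise_and_stratified(self):
        _, keys, ys = _raw_toy()
        train, val = inner_subject_split(keys, ys, 0.2, seed=0)
        assert not (train & val)
        assert train | val == set(keys)
        val_labels = {k.split("_")[0] for k in val}
        assert val_labels == {"H", "MDD"}

    def test_zscore_stats_from_inner_train_only(self):
        """The stored normalisation statistics equal the statistics of the
        inner-training segments alone — validation subjects contribute
        nothing."""
        X, keys, ys = _raw_toy()
        cfg = ModelConfig(model_id="cnn1d", seed=0,
                          training=TrainingConfig(max_epochs=1))
        fitted = train_raw_model(cfg, X, keys, ys)
        train, _ = inner_subject_split(keys, ys, 0.2, seed=0)
        mask = np.isin(keys, sorted(train))
        expected = channel_zscore_stats(X[mask])
        assert np.allclose(fitted.norm_stats["mean"], expected["mean"])
        assert np.allclose(fitted.norm_stats["sd"], expected["sd"])

    def test_early_stopping_restores_best_epoch(self):
        X, keys, ys = _raw_toy()
        cfg = ModelConfig(model_id="cnn1d", seed=0,
                          training=TrainingConfig(max_epochs=12, patience=3,
                                                  batch_size=32))
        fitted = train_raw_model(cfg, X, keys, ys)
        h = fitted.history
        assert h.attrs["best_epoch"] == int(h["val_loss"].idxmin())
        assert len(h) <= 12

    def test_cnn_learns_planted_variance_effect(self):
        X, keys, ys = _raw_toy(per=10)
        cfg = ModelConfig(model_id="cnn1d", seed=0,
                          training=TrainingConfig(batch_size=32))
        fitted = train_raw_model(cfg, X, keys, ys)
        proba = predict_segment_proba(fitted, X)
        assert np.mean((proba >= 0.5) == ys) > 0.9

    def test_cnn_recovers_planted_cohort_effect(self, tmp_path):
        """End-to-end raw-signal recovery: on a small strong-effect cohort
        the 1D CNN reaches subject-level AUROC > 0.8 under a subject-wise
        split (reduced epochs)."""
        from eegscreen.evaluation import evaluate_split, \
            stratified_subject_split
        from eegscreen.experiments import ExperimentConfig, prepare_dataset
        from eegscreen.synthgen import CohortSpec, write_cohort

        spec = CohortSpec(n_patients=10, n_controls=10,
                          duration_range=(40.0, 56.0), effect_beta_gain=2.0,
                          seed=21)
        root = write_cohort(spec, tmp_path / "raw")
        roster, ds = prepare_dataset(
            ExperimentConfig(dataset_root=root, keep_raw=True))
        plan = stratified_subject_split(roster, 0.25, 42, 0)
        cfg = ModelConfig(model_id="cnn1d", seed=42,
                          training=TrainingConfig(max_epochs=10, patience=4))
        metrics, _, _ = evaluate_split(ds, plan, cfg)
        assert metrics["auroc"] > 0.8

    def test_duplicate_rows_identical_probability(self):
        X, y = _toy_features()
        fitted = fit_extratrees(X, y, seed=0)
        doubled = pd.concat([X.iloc[:1], X.iloc[:1]])
        p = predict_segment_proba(fitted, doubled)
        assert p[0] == p[1]

    def test_leakage_assertion_fires(self):
        X, y = _toy_features()
        fitted = fit_extratrees(X, y, seed=0,
                                train_subjects=["H_S1", "MDD_S2"])
        with pytest.raises(LeakageError):
            predict_segment_proba(fitted, X, subject_keys=["MDD_S2"])

    def test_inner_split_single_class_rejected(self):
        X, keys, ys = _raw_toy(n_subj=4)
        with pytest.raises(ValueError):
            train_raw_model(
                ModelConfig(model_id="cnn1d", seed=0),
                X, keys, np.zeros_like(ys),
            )
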