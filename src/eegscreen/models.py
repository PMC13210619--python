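"""Five compact classifier baselines with fit-on-train / predict-on-anything
contracts.

Feature-based models (Extra Trees, MLP) run on the engineered feature
tables; the three conv nets (compact 1D CNN, EEGNet-style, shallow-ConvNet-
style) run on raw eight-channel segments. Every fitted statistic — tree
splits, network weights, imputation medians, standardisation, per-channel
z-scores — derives from training subjects only, and each fitted model
carries a provenance tag naming that training subject set so the contract
is assertable at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.impute import SimpleImputer
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from . import nn
from .containers import CLASS_LABELS, Segment

MODEL_IDS = ("et", "mlp", "cnn1d", "eegnet_like", "shallow_like")
FEATURE_MODELS = ("et", "mlp")
RAW_MODELS = ("cnn1d", "eegnet_like", "shallow_like")

#: Class order everywhere: H = 0, MDD = 1 (MDD is the positive class).
POSITIVE_CLASS = "MDD"


class LeakageError(RuntimeError):
    """A fitted statistic was about to touch an evaluation subject."""


def label_to_int(labels) -> np.ndarray:
    return np.asarray([CLASS_LABELS.index(c) for c in labels], dtype=int)


@dataclass
class TrainingConfig:
    """Optimisation settings for the raw-signal networks."""

    lr: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 25
    patience: int = 5
    val_fraction: float = 0.2    # of training SUBJECTS, held out subject-wise


@dataclass
class FittedModel:
    model_id: str
    estimator: object                       # sklearn pipeline or nn.Sequential
    train_subjects: frozenset[str]          # provenance tag
    feature_names: list[str] | None = None
    norm_stats: dict | None = None          # per-channel z-score (raw models)
    history: pd.DataFrame | None = None     # training curves (raw models)

    def assert_no_overlap(self, subject_keys) -> None:
        overlap = self.train_subjects & set(subject_keys)
        if overlap:
            raise LeakageError(
                f"evaluation subjects overlap training provenance: "
                f"{sorted(overlap)[:5]}..."
            )

    @property
    def feature_importances(self) -> pd.Series:
        if self.model_id != "et":
            raise AttributeError("Gini importances only exist for Extra Trees")
        est = self.estimator
        clf = est.named_steps["clf"] if isinstance(est, Pipeline) else est
        return pd.Series(clf.feature_importances_, index=self.feature_names)


# ---------------------------------------------------------------------------
# feature-based baselines


def fit_extratrees(features: pd.DataFrame, labels, seed: int,
                   train_subjects=()) -> FittedModel:
    """Extra Trees: 300 trees, unlimited depth, Gini criterion, balanced
    class weighting. Exposes per-feature Gini importance (sums to one)."""
    y = label_to_int(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    clf = ExtraTreesClassifier(
        n_estimators=300, max_depth=None, criterion="gini",
        class_weight="balanced", random_state=seed,
    )
    clf.fit(features.to_numpy(), y)
    return FittedModel(
        model_id="et", estimator=clf,
        train_subjects=frozenset(train_subjects),
        feature_names=list(features.columns),
    )


def fit_mlp(features: pd.DataFrame, labels, seed: int,
            train_subjects=()) -> FittedModel:
    """MLP with hidden layers (128, 64), ReLU, L2 1e-4, Adam, max 200
    iterations, early stopping on an internal 15% validation fraction.
    Median imputation and standardisation are fitted inside the pipeline on
    training rows only."""
    y = label_to_int(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    pipe = Pipeline([
        ("impute", SimpleImputer(strategy="median")),
        ("scale", StandardScaler()),
        ("clf", MLPClassifier(
            hidden_layer_sizes=(128, 64), activation="relu", alpha=1e-4,
            solver="adam", max_iter=200, early_stopping=True,
            validation_fraction=0.15, random_state=seed,
        )),
    ])
    pipe.fit(features.to_numpy(), y)
    return FittedModel(
        model_id="mlp", estimator=pipe,
        train_subjects=frozenset(train_subjects),
        feature_names=list(features.columns),
    )


# ---------------------------------------------------------------------------
# raw-signal architectures


@dataclass
class ModelConfig:
    model_id: str
    seed: int = 0
    n_channels: int = 8
    sampling_rate: float = 256.0
    dropout: float = 0.5
    training: TrainingConfig = field(default_factory=TrainingConfig)

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}")


def build_cnn1d(config: ModelConfig) -> nn.Sequential:
    """Compact 1D CNN: three temporal conv blocks (8->32 k7, 32->64 k5,
    64->128 k5), each with batch norm and ReLU; max pooling after the first
    two, adaptive average pooling after the third; dropout head with 64
    hidden units and a single logit. Pool widths (4) and head dropout are
    unstated upstream choices."""
    if config.n_channels != 8:
        raise ValueError("cnn1d expects 8 input channels")
    rng = np.random.default_rng(config.seed)
    return nn.Sequential([
        nn.Conv1d(8, 32, 7, rng, padding=3),
        nn.BatchNorm1d(32), nn.ReLU(), nn.MaxPool1d(4),
        nn.Conv1d(32, 64, 5, rng, padding=2),
        nn.BatchNorm1d(64), nn.ReLU(), nn.MaxPool1d(4),
        nn.Conv1d(64, 128, 5, rng, padding=2),
        nn.BatchNorm1d(128), nn.ReLU(), nn.AdaptiveAvgPool1d(),
        nn.Flatten(), nn.Dropout(config.dropout, rng),
        nn.Linear(128, 64, rng), nn.ReLU(), nn.Linear(64, 1, rng),
    ])


def build_eegnet_like(config: ModelConfig) -> nn.Sequential:
    """EEGNet-style block structure in 1-D form: per-channel temporal
    filtering (8 temporal filters, kernel = half the sampling rate),
    depthwise spatial combination across the 8 electrodes with depth
    multiplier 2 (16 maps), then a separable temporal convolution with 16
    pointwise filters; ELU, average pooling and dropout 0.5 as in the cited
    design. Pooling widths (4, 8) follow the reference architecture."""
    if config.n_channels != 8:
        raise ValueError("eegnet_like expects 8 input channels")
    rng = np.random.default_rng(config.seed)
    f1, depth_mult, f2 = 8, 2, 16
    k_temp = int(config.sampling_rate // 2)
    pad = k_temp // 2
    # grouped conv emits channel-major order [ch0_f0..ch0_f7, ch1_f0, ...];
    # regroup to filter-major so the depthwise step sees one temporal filter
    # across all 8 electrodes per group
    order = np.arange(8 * f1).reshape(8, f1).T.ravel()
    return nn.Sequential([
        nn.Conv1d(8, 8 * f1, k_temp, rng, padding=pad, groups=8, bias=False),
        nn.Permute(order),
        nn.Conv1d(8 * f1, f1 * depth_mult, 1, rng, groups=f1, bias=False),
        nn.BatchNorm1d(f1 * depth_mult), nn.ELU(), nn.AvgPool1d(4),
        nn.Dropout(config.dropout, rng),
        nn.Conv1d(f1 * depth_mult, f1 * depth_mult, 16, rng, padding=8,
                  groups=f1 * depth_mult, bias=False),
        nn.Conv1d(f1 * depth_mult, f2, 1, rng, bias=False),
        nn.BatchNorm1d(f2), nn.ELU(), nn.AvgPool1d(8),
        nn.Dropout(config.dropout, rng),
        nn.Flatten(), _LazyLinear(1, rng),
    ])


def build_shallow_like(config: ModelConfig) -> nn.Sequential:
    """Shallow-ConvNet-style: 40 temporal filters of length 25 (no padding),
    40 spatial filters across the eight channels, batch norm, square
    activation, mean pooling (window 75, stride 15), log compression,
    dropout 0.5 and a single-logit head."""
    if config.n_channels != 8:
        raise ValueError("shallow_like expects 8 input channels")
    rng = np.random.default_rng(config.seed)
    return nn.Sequential([
        nn.Conv1d(8, 40, 25, rng),
        nn.Conv1d(40, 40, 1, rng, bias=False),
        nn.BatchNorm1d(40), nn.Square(),
        nn.AvgPool1d(75, stride=15), nn.LogCompress(),
        nn.Dropout(config.dropout, rng),
        nn.Flatten(), _LazyLinear(1, rng),
    ])


class _LazyLinear(nn.Layer):
    """Linear layer whose input width is bound at first forward pass (the
    flattened width depends on the segment length)."""

    def __init__(self, n_out: int, rng):
        self.n_out = n_out
        self.rng = rng
        self.inner: nn.Linear | None = None

    def params(self):
        return self.inner.params() if self.inner is not None else []

    def forward(self, x, training):
        if self.inner is None:
            self.inner = nn.Linear(x.shape[1], self.n_out, self.rng)
        return self.inner.forward(x, training)

    def backward(self, gout):
        return self.inner.backward(gout)


_BUILDERS = {
    "cnn1d": build_cnn1d,
    "eegnet_like": build_eegnet_like,
    "shallow_like": build_shallow_like,
}


def build_raw_model(config: ModelConfig) -> nn.Sequential:
    return _BUILDERS[config.model_id](config)


# ---------------------------------------------------------------------------
# raw-signal training


def _materialize(model: nn.Sequential, example: np.ndarray) -> None:
    model.forward(example[:1], training=False)  # bind lazy layers


def inner_subject_split(subject_keys: np.ndarray, labels: np.ndarray,
                        val_fraction: float, seed: int
                        ) -> tuple[set[str], set[str]]:
    """Subject-wise inner split for early-stopping validation, stratified by
    class."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"key": subject_keys, "y": labels}).drop_duplicates("key")
    val: set[str] = set()
    for y in sorted(df["y"].unique()):
        keys = sorted(df.loc[df["y"] == y, "key"])
        n_val = max(1, int(round(len(keys) * val_fraction)))
        if n_val >= len(keys):
            raise ValueError("inner split would leave a class empty")
        perm = rng.permutation(len(keys))
        val.update(keys[i] for i in perm[:n_val])
    train = set(df["key"]) - val
    return train, val


def channel_zscore_stats(x: np.ndarray) -> dict:
    """Per-channel mean/SD over segments and time."""
    mean = x.mean(axis=(0, 2))
    sd = x.std(axis=(0, 2))
    sd[sd == 0] = 1.0
    return {"mean": mean, "sd": sd}


def apply_zscore(x: np.ndarray, stats: dict) -> np.ndarray:
    return (x - stats["mean"][None, :, None]) / stats["sd"][None, :, None]


def train_raw_model(config: ModelConfig, segments_x: np.ndarray,
                    subject_keys: np.ndarray, labels: np.ndarray,
                    ) -> FittedModel:
    """Train one conv net with subject-wise early stopping.

    Per-channel z-score statistics are computed on the inner-training
    segments only (after subject-wise removal of the validation
    participants) and reused unchanged for validation and test data. Weights
    from the best-validation-loss epoch are restored.
    """
    tc = config.training
    y = np.asarray(labels, dtype=int)
    inner_train, inner_val = inner_subject_split(
        subject_keys, y, tc.val_fraction, config.seed
    )
    tr_mask = np.isin(subject_keys, sorted(inner_train))
    va_mask = np.isin(subject_keys, sorted(inner_val))
    if len(np.unique(y[tr_mask])) < 2 or len(np.unique(y[va_mask])) < 2:
        raise ValueError("inner split leaves a class empty")

    stats = channel_zscore_stats(segments_x[tr_mask])
    xtr = apply_zscore(segments_x[tr_mask], stats)
    ytr = y[tr_mask]
    xva = apply_zscore(segments_x[va_mask], stats)
    yva = y[va_mask]

    model = build_raw_model(config)
    _materialize(model, xtr)
    opt = nn.Adam(model.params(), lr=tc.lr)
    rng = np.random.default_rng(config.seed + 1)

    best_loss, best_state, best_epoch, stale = np.inf, model.state(), -1, 0
    rows = []
    for epoch in range(tc.max_epochs):
        perm = rng.permutation(len(xtr))
        epoch_loss = 0.0
        for start in range(0, len(xtr), tc.batch_size):
            idx = perm[start:start + tc.batch_size]
            model.zero_grad()
            logits = model.forward(xtr[idx], training=True)
            loss, grad = nn.bce_with_logits(logits, ytr[idx])
            model.backward(grad)
            opt.step()
            epoch_loss += loss * len(idx)
        val_logits = model.forward(xva, training=False)
        val_loss, _ = nn.bce_with_logits(val_logits, yva)
        rows.append({"epoch": epoch, "train_loss": epoch_loss / len(xtr),
                     "val_loss": val_loss})
        if val_loss < best_loss - 1e-6:
            best_loss, best_state, best_epoch, stale = (
                val_loss, model.state(), epoch, 0
            )
        else:
            stale += 1
            if stale >= tc.patience:
                break
    model.load_state(best_state)
    history = pd.DataFrame(rows)
    history.attrs["best_epoch"] = best_epoch
    return FittedModel(
        model_id=config.model_id, estimator=model,
        train_subjects=frozenset(np.unique(subject_keys)),
        norm_stats=stats, history=history,
    )


# ---------------------------------------------------------------------------
# prediction


def predict_segment_proba(fitted: FittedModel, inputs,
                          subject_keys=None) -> np.ndarray:
    """Per-segment probability of the positive (MDD) class.

    When ``subject_keys`` is supplied (the evaluation path), asserts that
    none of them appear in the model's training provenance.
    """
    if subject_keys is not None:
        fitted.assert_no_overlap(subject_keys)
    if fitted.model_id in FEATURE_MODELS:
        x = inputs.to_numpy() if isinstance(inputs, pd.DataFrame) else np.asarray(inputs)
        proba = fitted.estimator.predict_proba(x)
        classes = list(fitted.estimator.classes_)
        return proba[:, classes.index(1)]
    x = apply_zscore(np.asarray(inputs, dtype=float), fitted.norm_stats)
    logits = fitted.estimator.forward(x, training=False)
    return nn.sigmoid(logits.ravel())


def segments_to_array(segments: list[Segment]) -> np.ndarray:
    return np.stack([s.samples for s in segments]).astype(float)
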