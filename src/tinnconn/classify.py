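"""Four-classifier evaluation protocol: SVM (Loo-CV / 10-CV), MLP, CNN-LSTM.

Reports repeat-averaged accuracy (percent) and wall time per feature set.
Feature standardization is fit on training folds only (leakage guard).
The CNN-LSTM is optional: its architecture contract is validated without a
deep-learning backend, and training requires ``torch``.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import (
    LeaveOneOut,
    StratifiedKFold,
    cross_val_score,
    train_test_split,
)
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .types import ConfigurationError, FeatureVector, InputError

__all__ = [
    "CLASSIFIER_KINDS",
    "TRAIN_FRACTION",
    "MLPParams",
    "CNNLSTMParams",
    "ClassifierConfig",
    "EvaluationResult",
    "stack_features",
    "train_validation_split",
    "evaluate_svm",
    "evaluate_mlp",
    "cnn_lstm_layer_plan",
    "evaluate_cnn_lstm",
    "repeated_evaluation",
]

CLASSIFIER_KINDS = ("svm_loocv", "svm_10cv", "mlp", "cnn_lstm")

#: fixed-split ratio used for MLP / CNN-LSTM repeats (1,622 of 2,312)
TRAIN_FRACTION = 1622 / 2312


@dataclass
class MLPParams:
    hidden_layer_sizes: tuple = (200, 200)
    solver: str = "adam"
    alpha: float = 1e-7
    max_iter: int = 380
    learning_rate_init: float = 0.001


@dataclass
class CNNLSTMParams:
    input_length: int = 66
    conv_filters: tuple = (16, 32)
    kernel_size: int = 3
    stride: int = 1
    lstm_units: tuple = (32, 32)
    dense_units: tuple = (16, 8)
    dropout: float = 0.2
    epochs: int = 60
    batch_size: int = 32
    learning_rate: float = 1e-3


@dataclass
class ClassifierConfig:
    kind: str
    mlp: MLPParams = field(default_factory=MLPParams)
    cnn_lstm: CNNLSTMParams = field(default_factory=CNNLSTMParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ConfigurationError(
                f"unknown classifier kind {self.kind!r}; "
                f"choose from {CLASSIFIER_KINDS}"
            )


@dataclass
class EvaluationResult:
    """Per-repeat accuracies (percent) and timings for one feature × classifier."""

    feature_name: str
    classifier: str
    accuracies: list
    times: list
    n_train: int
    n_validation: int
    flags: list = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def std_accuracy(self) -> float:
        if len(self.accuracies) == 1:
            return 0.0  # single repeat: std reported as 0 (flagged)
        return float(np.std(self.accuracies))

    @property
    def mean_time(self) -> float:
        return float(np.mean(self.times))

    def __post_init__(self) -> None:
        if len(self.accuracies) < 1:
            raise InputError("at least one repeat required")
        accs = np.asarray(self.accuracies, dtype=float)
        if accs.min() < 0 or accs.max() > 100:
            raise InputError("accuracies must be percentages in [0, 100]")
        if len(self.accuracies) == 1 and "single_repeat" not in self.flags:
            self.flags.append("single_repeat")


def stack_features(feature_vectors: Sequence[FeatureVector]):
    """Stack per-epoch FeatureVectors into (X, y); layouts must agree."""
    if not feature_vectors:
        raise InputError("no feature vectors given")
    layouts = {fv.layout for fv in feature_vectors}
    if len(layouts) != 1:
        raise InputError(f"mixed feature layouts: {sorted(layouts)}")
    X = np.vstack([fv.values for fv in feature_vectors])
    y = np.array([fv.label for fv in feature_vectors], dtype=object)
    if any(v is None for v in y):
        raise InputError("all feature vectors need a class label")
    return X, y.astype(str)


def train_validation_split(X: np.ndarray, y: np.ndarray, n_train: int, seed):
    """Disjoint, exhaustive, stratified random split with n_train training rows."""
    X = np.asarray(X)
    y = np.asarray(y)
    if n_train >= len(y):
        raise InputError(f"n_train {n_train} must be < dataset size {len(y)}")
    if n_train < 1:
        raise InputError("n_train must be >= 1")
    x_tr, x_va, y_tr, y_va = train_test_split(
        X, y, train_size=n_train,
        random_state=int(np.random.SeedSequence(seed).generate_state(1)[0]),
        stratify=y, shuffle=True,
    )
    return (x_tr, y_tr), (x_va, y_va)


def _check_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise InputError("need at least 2 classes")


def evaluate_svm(
    X: np.ndarray,
    y: np.ndarray,
    cv: str = "kfold10",
    seed: int = 0,
    feature_name: str = "features",
) -> EvaluationResult:
    """Linear-kernel SVM under leave-one-out ('loocv') or 10-fold ('kfold10') CV."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_classes(y)
    model = make_pipeline(StandardScaler(), SVC(kernel="linear"))
    if cv == "loocv":
        splitter = LeaveOneOut()
        n_train, n_val = len(y) - 1, 1
    elif cv == "kfold10":
        splitter = StratifiedKFold(n_splits=10, shuffle=True,
                                   random_state=seed % (2 ** 32))
        n_train = len(y) - len(y) // 10
        n_val = len(y) // 10
    else:
        raise InputError(f"unknown cv mode {cv!r}; use 'loocv' or 'kfold10'")
    t0 = time.perf_counter()
    scores = cross_val_score(model, X, y, cv=splitter, scoring="accuracy")
    elapsed = time.perf_counter() - t0
    kind = "svm_loocv" if cv == "loocv" else "svm_10cv"
    return EvaluationResult(
        feature_name=feature_name,
        classifier=kind,
        accuracies=[float(scores.mean() * 100)],
        times=[elapsed],
        n_train=n_train,
        n_validation=n_val,
    )


def evaluate_mlp(
    X: np.ndarray,
    y: np.ndarray,
    config: Optional[ClassifierConfig] = None,
    seed: int = 0,
    feature_name: str = "features",
    train_fraction: float = TRAIN_FRACTION,
) -> EvaluationResult:
    """MLP on one stratified fixed-fraction split; non-convergence is flagged."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_classes(y)
    params = (config or ClassifierConfig("mlp")).mlp
    n_train = max(len(np.unique(y)), int(round(train_fraction * len(y))))
    (x_tr, y_tr), (x_va, y_va) = train_validation_split(X, y, n_train, seed)
    model = make_pipeline(
        StandardScaler(),
        MLPClassifier(
            hidden_layer_sizes=tuple(params.hidden_layer_sizes),
            solver=params.solver,
            alpha=params.alpha,
            max_iter=params.max_iter,
            learning_rate_init=params.learning_rate_init,
            random_state=seed % (2 ** 32),
        ),
    )
    flags = []
    t0 = time.perf_counter()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        model.fit(x_tr, y_tr)
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        flags.append("non_converged")
    acc = float(model.score(x_va, y_va) * 100)
    elapsed = time.perf_counter() - t0
    return EvaluationResult(
        feature_name=feature_name,
        classifier="mlp",
        accuracies=[acc],
        times=[elapsed],
        n_train=len(y_tr),
        n_validation=len(y_va),
        flags=flags,
    )


def cnn_lstm_layer_plan(input_length: int, n_classes: int,
                        params: Optional[CNNLSTMParams] = None) -> list:
    """Layer stack with output shapes; validates the declared input length.

    Conv layers use 'same' padding (sequence length preserved); the second
    recurrent layer returns its final hidden state, so the flatten width
    equals the recurrent unit count.
    """
    params = params or CNNLSTMParams()
    if input_length != params.input_length:
        raise ConfigurationError(
            f"input length mismatch: expected {params.input_length}, "
            f"got {input_length}"
        )
    c1, c2 = params.conv_filters
    u1, u2 = params.lstm_units
    d1, d2 = params.dense_units
    length = input_length  # 'same' padding, stride 1
    return [
        ("input", (1, input_length)),
        ("conv1d_1", (c1, length)),
        ("conv1d_2", (c2, length)),
        ("lstm_1", (u1, length)),
        ("lstm_2", (u2,)),
        ("batch_norm", (u2,)),
        ("flatten", (u2,)),
        ("dense_1", (d1,)),
        ("dropout_1", (d1,)),
        ("dense_2", (d2,)),
        ("dropout_2", (d2,)),
        ("output", (n_classes,)),
    ]


def evaluate_cnn_lstm(
    X: np.ndarray,
    y: np.ndarray,
    config: Optional[ClassifierConfig] = None,
    seed: int = 0,
    feature_name: str = "features",
    train_fraction: float = TRAIN_FRACTION,
) -> EvaluationResult:
    """Train/evaluate the CNN-LSTM stack (requires the optional torch backend)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_classes(y)
    config = config or ClassifierConfig("cnn_lstm")
    classes = np.unique(y)
    plan = cnn_lstm_layer_plan(X.shape[1], len(classes), config.cnn_lstm)
    try:
        import torch
        from torch import nn
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise RuntimeError(
            "the CNN-LSTM classifier requires the optional 'torch' dependency "
            "(pip install tinnconn[cnn])"
        ) from exc

    params = config.cnn_lstm
    torch.manual_seed(seed % (2 ** 32))
    n_train = max(len(classes), int(round(train_fraction * len(y))))
    (x_tr, y_tr), (x_va, y_va) = train_validation_split(X, y, n_train, seed)
    scaler = StandardScaler().fit(x_tr)
    x_tr = scaler.transform(x_tr)
    x_va = scaler.transform(x_va)
    cls_index = {c: i for i, c in enumerate(classes)}

    class _Net(nn.Module):  # pragma: no cover - optional dependency
        def __init__(self):
            super().__init__()
            c1, c2 = params.conv_filters
            u1, u2 = params.lstm_units
            d1, d2 = params.dense_units
            pad = params.kernel_size // 2
            self.conv = nn.Sequential(
                nn.Conv1d(1, c1, params.kernel_size, params.stride, padding=pad),
                nn.ReLU(),
                nn.Conv1d(c1, c2, params.kernel_size, params.stride, padding=pad),
                nn.ReLU(),
            )
            self.lstm1 = nn.LSTM(c2, u1, batch_first=True)
            self.lstm2 = nn.LSTM(u1, u2, batch_first=True)
            self.head = nn.Sequential(
                nn.BatchNorm1d(u2), nn.Flatten(),
                nn.Linear(u2, d1), nn.ReLU(), nn.Dropout(params.dropout),
                nn.Linear(d1, d2), nn.ReLU(), nn.Dropout(params.dropout),
                nn.Linear(d2, len(classes)),
            )

        def forward(self, x):
            h = self.conv(x.unsqueeze(1))          # (B, C, L)
            h, _ = self.lstm1(h.transpose(1, 2))   # (B, L, U1)
            h, _ = self.lstm2(h)
            return self.head(h[:, -1, :])          # final hidden state

    net = _Net()
    opt = torch.optim.Adam(net.parameters(), lr=params.learning_rate)
    loss_fn = nn.CrossEntropyLoss()
    xt = torch.as_tensor(x_tr, dtype=torch.float32)
    yt = torch.as_tensor([cls_index[c] for c in y_tr])
    t0 = time.perf_counter()
    net.train()
    for _ in range(params.epochs):  # pragma: no cover - optional dependency
        perm = torch.randperm(len(yt))
        for start in range(0, len(yt), params.batch_size):
            idx = perm[start:start + params.batch_size]
            opt.zero_grad()
            loss = loss_fn(net(xt[idx]), yt[idx])
            loss.backward()
            opt.step()
    net.eval()
    with torch.no_grad():  # pragma: no cover
        pred = net(torch.as_tensor(x_va, dtype=torch.float32)).argmax(dim=1).numpy()
    acc = float(np.mean(pred == np.array([cls_index[c] for c in y_va])) * 100)
    elapsed = time.perf_counter() - t0
    return EvaluationResult(
        feature_name=feature_name,
        classifier="cnn_lstm",
        accuracies=[acc],
        times=[elapsed],
        n_train=len(y_tr),
        n_validation=len(y_va),
        flags=[f"layers:{len(plan)}"],
    )


def repeated_evaluation(
    X: np.ndarray,
    y: np.ndarray,
    feature_name: str,
    configs: Sequence[ClassifierConfig],
    n_repeats: int = 10,
    seed: int = 0,
) -> list:
    """Run each classifier ``n_repeats`` times with fresh seed-derived splits.

    Returns one :class:`EvaluationResult` per config with the full per-repeat
    accuracy/time tables (consumed by the group-analysis ANOVA).
    """
    if n_repeats < 1:
        raise InputError("n_repeats must be >= 1")
    results = []
    for ci, config in enumerate(configs):
        seeds = np.random.SeedSequence([seed, ci]).generate_state(n_repeats)
        accs, times, flags = [], [], []
        n_train = n_val = 0
        for rep_seed in seeds:
            rep_seed = int(rep_seed)
            if config.kind == "svm_loocv":
                r = evaluate_svm(X, y, cv="loocv", seed=rep_seed,
                                 feature_name=feature_name)
            elif config.kind == "svm_10cv":
                r = evaluate_svm(X, y, cv="kfold10", seed=rep_seed,
                                 feature_name=feature_name)
            elif config.kind == "mlp":
                r = evaluate_mlp(X, y, config, seed=rep_seed,
                                 feature_name=feature_name)
            else:
                r = evaluate_cnn_lstm(X, y, config, seed=rep_seed,
                                      feature_name=feature_name)
            accs.extend(r.accuracies)
            times.extend(r.times)
            flags.extend(f for f in r.flags if f != "single_repeat")
            n_train, n_val = r.n_train, r.n_validation
        results.append(
            EvaluationResult(
                feature_name=feature_name,
                classifier=config.kind,
                accuracies=accs,
                times=times,
                n_train=n_train,
                n_validation=n_val,
                flags=sorted(set(flags)),
            )
        )
    return results
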