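"""Seven window classifiers over HJD features.

Two classical baselines (kNN, linear discriminant analysis) run on 1D
feature vectors through scikit-learn.  Five neural families are trained
with the in-package NumPy engine:

* ``fcnet``   — four fully connected layers (240, 60, 15, 5 classes) with
  dropout after each hidden layer, softmax cross-entropy;
* ``conv1d``  — two 1D convolutions (16 then 32 filters, kernel 3) each
  followed by max pooling (kernel 3, stride 3), then dropout, a dense
  reduction and softmax;
* ``conv2d``  — two 2D convolutions (4 then 8 filters, kernel 3, stride 1)
  each followed by max pooling (kernel 3, stride 2), dropout, dense,
  softmax; requires the parts × bins 2D feature matrix;
* ``caps1d``/``caps2d`` — the same convolutional front-end settings (kernel
  3; 32 filters in 1D, 16 in 2D) but with pooling removed: the feature map
  is grouped into 8-dimensional primary capsules, routed by agreement to
  five 16-dimensional class capsules over 3 routing iterations, and
  trained with the capsule margin loss.  A class capsule's vector norm is
  its score.

All defaults are exposed in :class:`ClassifierConfig`; training is
deterministic given the config seed.  Ties in predicted scores break
toward the lowest class index.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import KNeighborsClassifier

from . import _nn
from ._nn import dynamic_routing, margin_loss, squash  # re-exported surface
from .hjd import FeatureDataset

__all__ = [
    "FAMILIES",
    "TABLE_GRIDS",
    "ClassifierConfig",
    "CapsuleLayerSpec",
    "TrainedModel",
    "default_config",
    "required_feature_kind",
    "fit",
    "predict",
    "squash",
    "dynamic_routing",
    "margin_loss",
    "hyperparameter_search",
    "expand_grid",
]

FAMILIES = ("knn", "lda", "fcnet", "conv1d", "conv2d", "caps1d", "caps2d")

#: Hyperparameter search domains per family (two axes each).
TABLE_GRIDS: dict[str, dict[str, list]] = {
    "knn": {"k": [1, 3, 5, 7]},
    "fcnet": {"first_layer": [240, 150, 100], "dropout": [0.5, 0.7, 0.9]},
    "conv1d": {"filters1": [8, 16, 32], "filters2": [8, 16, 32]},
    "conv2d": {"filters1": [4, 8, 32], "filters2": [4, 8, 32]},
    "caps1d": {"kernel": [3, 4, 5], "filters": [16, 32]},
    "caps2d": {"kernel": [3, 4, 5], "filters": [8, 16]},
}


@dataclass(frozen=True)
class CapsuleLayerSpec:
    """Geometry of the capsule stage."""

    dim_primary: int = 8
    n_class_capsules: int = 5
    dim_class: int = 16
    routing_iterations: int = 3
    primary_stride: int = 2  # spatial subsampling when forming primary capsules

    def __post_init__(self) -> None:
        if min(self.dim_primary, self.dim_class, self.primary_stride) < 1:
            raise ValueError("capsule dimensions and stride must be >= 1")
        if self.routing_iterations < 1:
            raise ValueError("routing_iterations must be >= 1")


@dataclass(frozen=True)
class ClassifierConfig:
    """Family choice plus family-specific and training hyperparameters."""

    family: str
    # knn
    k: int = 5
    metric: str = "euclidean"
    # fcnet
    layers: tuple[int, ...] = (240, 60, 15)
    dropout: float = 0.5
    # conv families: (first, second) filter counts; kernel size
    filters: tuple[int, int] = (16, 32)
    kernel: int = 3
    dense_units: int = 64
    # capsules
    caps_filters: int = 32
    capsules: CapsuleLayerSpec = field(default_factory=CapsuleLayerSpec)
    # training
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    n_classes: int = 5

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if min(self.k, self.kernel, self.epochs, self.batch_size, *self.layers,
               *self.filters, self.caps_filters, self.dense_units) < 1:
            raise ValueError("all counts must be positive")


def default_config(family: str, **overrides) -> ClassifierConfig:
    """Per-family defaults; any field can be overridden by keyword."""
    base = {
        "knn": dict(k=5),
        "lda": dict(),
        "fcnet": dict(layers=(240, 60, 15), dropout=0.5),
        "conv1d": dict(filters=(16, 32), kernel=3),
        "conv2d": dict(filters=(4, 8), kernel=3),
        "caps1d": dict(caps_filters=32, kernel=3),
        "caps2d": dict(caps_filters=16, kernel=3),
    }[family]
    base.update(overrides)
    return ClassifierConfig(family=family, **base)


def required_feature_kind(family: str) -> str:
    """2D families consume the parts × bins matrix; the rest consume vectors."""
    return "fused2d" if family in ("conv2d", "caps2d") else "fused1d"


@dataclass
class TrainedModel:
    family: str
    config: ClassifierConfig
    feature_shape: tuple[int, ...]
    classes: np.ndarray
    training_log: list[float]
    _impl: object  # sklearn estimator or (_nn.Sequential, mean, sd, loss kind)

    @property
    def n_parameters(self) -> int:
        if isinstance(self._impl, tuple):
            return self._impl[0].n_parameters
        return 0  # non-parametric / closed-form baselines

    def scores(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        if features.shape[1:] != self.feature_shape:
            raise ValueError(
                f"feature shape {features.shape[1:]} != model contract {self.feature_shape}"
            )
        if not isinstance(self._impl, tuple):
            proba = self._impl.predict_proba(features)
            out = np.zeros((len(features), self.config.n_classes))
            out[:, self._impl.classes_.astype(int)] = proba
            return out
        net, mean, sd, loss_kind = self._impl
        x = _net_input((features - mean) / sd, self.family)
        out = net.forward(x, train=False)
        if loss_kind == "margin":
            return np.linalg.norm(out, axis=-1)  # class-capsule norms in [0, 1)
        return _nn.softmax(out)

    def predict(self, features: np.ndarray) -> np.ndarray:
        return np.argmax(self.scores(features), axis=1)  # first max → lowest label


def predict(model: TrainedModel, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels (0–4) and per-class scores."""
    scores = model.scores(features)
    return np.argmax(scores, axis=1), scores


def _net_input(x: np.ndarray, family: str) -> np.ndarray:
    if family in ("conv1d", "caps1d"):
        return x[:, None, :]  # single channel
    if family in ("conv2d", "caps2d"):
        return x[:, None, :, :]
    return x


def _build_net(config: ClassifierConfig, feature_shape: tuple[int, ...],
               rng: np.random.Generator) -> tuple[_nn.Sequential, str]:
    n_cls = config.n_classes
    fam = config.family
    if fam == "fcnet":
        d = feature_shape[0]
        layers: list[_nn.Layer] = []
        for width in config.layers:
            layers += [_nn.Dense(d, width, rng), _nn.ReLU(), _nn.Dropout(config.dropout, rng)]
            d = width
        layers.append(_nn.Dense(d, n_cls, rng))
        return _nn.Sequential(layers), "ce"
    if fam == "conv1d":
        (L,) = feature_shape
        f1, f2 = config.filters
        net = [
            _nn.Conv1d(1, f1, config.kernel, rng), _nn.ReLU(), _nn.MaxPool1d(3, 3),
            _nn.Conv1d(f1, f2, config.kernel, rng), _nn.ReLU(), _nn.MaxPool1d(3, 3),
            _nn.Dropout(config.dropout, rng), _nn.Flatten(),
        ]
        flat = f2 * _pooled_len(_pooled_len(L, 3, 3), 3, 3)
        net += [_nn.Dense(flat, config.dense_units, rng), _nn.ReLU(),
                _nn.Dense(config.dense_units, n_cls, rng)]
        return _nn.Sequential(net), "ce"
    if fam == "conv2d":
        H, W = feature_shape
        f1, f2 = config.filters
        net = [
            _nn.Conv2d(1, f1, config.kernel, rng), _nn.ReLU(), _nn.MaxPool2d(3, 2),
            _nn.Conv2d(f1, f2, config.kernel, rng), _nn.ReLU(), _nn.MaxPool2d(3, 2),
            _nn.Dropout(config.dropout, rng), _nn.Flatten(),
        ]
        H1, W1 = _pooled_len(H, 3, 2), _pooled_len(W, 3, 2)
        H2, W2 = _pooled_len(H1, 3, 2), _pooled_len(W1, 3, 2)
        net += [_nn.Dense(f2 * H2 * W2, config.dense_units, rng), _nn.ReLU(),
                _nn.Dense(config.dense_units, n_cls, rng)]
        return _nn.Sequential(net), "ce"
    if fam == "caps1d":
        (L,) = feature_shape
        spec = config.capsules
        f = config.caps_filters
        if f % spec.dim_primary:
            raise ValueError("caps_filters must be divisible by the primary capsule dim")
        n_caps = (f // spec.dim_primary) * _strided_len(L, spec.primary_stride)
        net = [
            _nn.Conv1d(1, f, config.kernel, rng), _nn.ReLU(),
            _nn.PrimaryCaps1d(spec.dim_primary, spec.primary_stride),
            _nn.CapsuleRouting(n_caps, spec.dim_primary, n_cls, spec.dim_class,
                               spec.routing_iterations, rng),
        ]
        return _nn.Sequential(net), "margin"
    if fam == "caps2d":
        H, W = feature_shape
        spec = config.capsules
        f = config.caps_filters
        if f % spec.dim_primary:
            raise ValueError("caps_filters must be divisible by the primary capsule dim")
        n_caps = (f // spec.dim_primary) * H * _strided_len(W, spec.primary_stride)
        net = [
            _nn.Conv2d(1, f, config.kernel, rng), _nn.ReLU(),
            _nn.PrimaryCaps2d(spec.dim_primary, spec.primary_stride),
            _nn.CapsuleRouting(n_caps, spec.dim_primary, n_cls, spec.dim_class,
                               spec.routing_iterations, rng),
        ]
        return _nn.Sequential(net), "margin"
    raise ValueError(f"no network for family {config.family!r}")


def _pooled_len(L: int, kernel: int, stride: int) -> int:
    k = min(kernel, L)
    return (L - k) // stride + 1


def _strided_len(L: int, stride: int) -> int:
    return (L + stride - 1) // stride


def fit(config: ClassifierConfig, dataset: FeatureDataset) -> TrainedModel:
    """Train one classifier on a (training-subjects-only) feature dataset."""
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    x = np.asarray(dataset.features, dtype=float)
    y = dataset.labels
    kind_needed = required_feature_kind(config.family)
    is_2d = kind_needed == "fused2d"
    if is_2d and x.ndim != 3:
        raise ValueError(f"family {config.family} requires fused2d features")
    if not is_2d and x.ndim != 2:
        raise ValueError(f"family {config.family} requires 1D feature vectors")
    present = np.unique(y)
    if len(present) < config.n_classes:
        import warnings

        warnings.warn(f"training data covers only classes {present.tolist()}")

    if config.family == "knn":
        est = KNeighborsClassifier(n_neighbors=config.k, metric=config.metric)
        est.fit(x, y)
        return TrainedModel(config.family, config, x.shape[1:], present, [], est)
    if config.family == "lda":
        est = LinearDiscriminantAnalysis()
        est.fit(x, y)
        return TrainedModel(config.family, config, x.shape[1:], present, [], est)

    rng = np.random.default_rng(config.seed)
    net, loss_kind = _build_net(config, x.shape[1:], rng)
    # standardise per feature element with training statistics
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    xs = (x - mean) / sd
    opt = _nn.Adam(net.layers, lr=config.learning_rate)
    n = len(xs)
    log: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            out = net.forward(_net_input(xs[idx], config.family), train=True)
            if loss_kind == "margin":
                loss, grad = margin_loss(out, y[idx])
            else:
                loss, grad = _nn.cross_entropy(out, y[idx])
            net.backward(grad)
            opt.step()
            epoch_loss += loss * len(idx)
        log.append(epoch_loss / n)
    return TrainedModel(config.family, config, x.shape[1:], present, log,
                        (net, mean, sd, loss_kind))


def expand_grid(family: str, grid: dict[str, list] | None = None) -> list[ClassifierConfig]:
    """All configs in the cartesian product of a (named-axis) grid."""
    grid = TABLE_GRIDS[family] if grid is None else grid
    keys = list(grid)
    configs = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        kw = dict(zip(keys, combo))
        if "first_layer" in kw:
            first = kw.pop("first_layer")
            kw["layers"] = (first, 60, 15)
        if "filters1" in kw:
            kw["filters"] = (kw.pop("filters1"), kw.pop("filters2"))
        if "filters" in kw and family.startswith("caps") and isinstance(kw["filters"], int):
            kw["caps_filters"] = kw.pop("filters")
        configs.append(default_config(family, **kw))
    return configs


def hyperparameter_search(
    family: str,
    grid: list[ClassifierConfig],
    dataset: FeatureDataset,
    inner_folds: int | None = None,
    fit_overrides: dict | None = None,
) -> ClassifierConfig:
    """Exhaustive grid search by inner cross-validation grouped by subject.

    Folds hold out whole subjects of the *training* dataset, so no window
    of a held-out evaluation subject can influence the choice.  Ties break
    toward the smaller model (fewer trainable parameters), then grid order.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    subjects = dataset.subjects
    if len(subjects) < 2:
        raise ValueError("inner cross-validation needs >= 2 training subjects")
    folds = subjects if inner_folds is None else subjects[: max(2, inner_folds)]
    best = None
    for config in grid:
        if fit_overrides:
            config_run = replace(config, **fit_overrides)
        else:
            config_run = config
        accs, n_params = [], 0
        for held in folds:
            train, test = dataset.split_subject(held)
            if len(train) == 0 or len(test) == 0:
                continue
            model = fit(config_run, train)
            n_params = model.n_parameters
            accs.append(float(np.mean(model.predict(test.features) == test.labels)))
        score = float(np.mean(accs)) if accs else -1.0
        key = (score, -n_params)
        if best is None or key > best[0]:
            best = (key, config)
    return best[1]
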