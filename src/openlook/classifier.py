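"""Per-participant gaze-AOI classifier.

A deliberately small artificial neural network maps each frame's OpenFace
features to one of three screen areas of interest (left, center, right).
The architecture is four fully connected layers (three hidden): each hidden
block is linear -> 1-D batch normalization -> ReLU -> dropout (p = 0.2),
followed by a final linear layer and softmax over the classes.  One model is
trained per participant on a random 50% of that participant's labeled frames
(labels from a live coder, or from attention-getter calibration windows for
remote sessions); the remaining frames measure agreement.

The network, its training loop (cross-entropy loss, Adam) and prediction are
implemented directly in NumPy so that every source of randomness — weight
initialization, the validation slice, minibatch order, dropout masks — flows
from a single seed and runs are exactly reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .features import FeatureMatrix, Standardizer, apply_standardizer, fit_standardizer
from .openface_io import SessionTable
from .protocol import AOI, AOILabelSeries
from .quality import QualityConfig, frame_quality_flags

__all__ = [
    "ClassifierSpec",
    "TrainConfig",
    "TrainTestSplit",
    "TrainedClassifier",
    "MLPNetwork",
    "split_frames",
    "build_network",
    "train_classifier",
    "predict_frames",
    "save_classifier",
    "load_classifier",
]

DEFAULT_LABEL_MAP = {0: AOI.LEFT, 1: AOI.CENTER, 2: AOI.RIGHT}
# argmax ties resolve in this preference order
_TIE_ORDER = (AOI.CENTER, AOI.LEFT, AOI.RIGHT)

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass(frozen=True)
class ClassifierSpec:
    """Network topology: 3 hidden layers, batch norm, dropout 0.2, ReLU."""

    input_dim: int
    hidden_widths: tuple[int, int, int] = (64, 64, 64)
    n_classes: int = 3
    dropout_p: float = 0.2
    batchnorm: bool = True

    def __post_init__(self) -> None:
        if self.input_dim <= 0 or self.n_classes <= 1:
            raise ConfigError("input_dim and n_classes must be positive")
        if any(w <= 0 for w in self.hidden_widths):
            raise ConfigError("hidden widths must be positive")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ConfigError("dropout_p must lie in [0, 1)")

    @property
    def n_hidden_layers(self) -> int:
        return len(self.hidden_widths)

    @property
    def n_linear_layers(self) -> int:
        return len(self.hidden_widths) + 1


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters (not constrained by the architecture)."""

    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 64
    patience: int = 20
    val_fraction: float = 0.1
    weight_decay: float = 1e-4
    n_ensemble: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.epochs, self.batch_size, self.patience) <= 0:
            raise ConfigError("training hyperparameters must be positive")
        if self.weight_decay < 0:
            raise ConfigError("weight_decay must be nonnegative")
        if self.n_ensemble < 1:
            raise ConfigError("n_ensemble must be at least 1")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ConfigError("val_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class TrainTestSplit:
    train_rows: np.ndarray
    test_rows: np.ndarray
    fraction: float
    seed: int


def split_frames(labeled_rows, fraction: float = 0.5, seed: int = 0) -> TrainTestSplit:
    """Uniform random train/test split of labeled frame rows.

    No stratification; ``round(fraction * n)`` rows go to training.
    Deterministic given the seed.
    """
    rows = np.asarray(labeled_rows, dtype=int)
    if rows.size < 2:
        raise ConfigError("need at least 2 labeled rows to split")
    if not 0.0 < fraction < 1.0:
        raise ConfigError("split fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(rows.size)
    n_train = int(round(fraction * rows.size))
    n_train = min(max(n_train, 1), rows.size - 1)
    train = np.sort(rows[perm[:n_train]])
    test = np.sort(rows[perm[n_train:]])
    return TrainTestSplit(train_rows=train, test_rows=test, fraction=fraction, seed=seed)


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------


class MLPNetwork:
    """Plain-NumPy multilayer perceptron with batch norm and dropout."""

    def __init__(self, spec: ClassifierSpec, seed: int = 0):
        self.spec = spec
        self.params: dict[str, np.ndarray] = {}
        self.running: dict[str, np.ndarray] = {}
        self._init_params(np.random.default_rng(seed))

    def _init_params(self, rng: np.random.Generator) -> None:
        dims = [self.spec.input_dim, *self.spec.hidden_widths, self.spec.n_classes]
        for i, (fan_in, fan_out) in enumerate(zip(dims, dims[1:])):
            std = np.sqrt(2.0 / fan_in)  # He init for ReLU stacks
            self.params[f"W{i}"] = rng.normal(0.0, std, size=(fan_in, fan_out))
            self.params[f"b{i}"] = np.zeros(fan_out)
            if i < self.spec.n_hidden_layers and self.spec.batchnorm:
                self.params[f"gamma{i}"] = np.ones(fan_out)
                self.params[f"beta{i}"] = np.zeros(fan_out)
                self.running[f"mean{i}"] = np.zeros(fan_out)
                self.running[f"var{i}"] = np.ones(fan_out)

    # -- forward -----------------------------------------------------------

    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ):
        """Return (log_probs, cache).  Dropout and batch statistics only in
        training mode; ``rng`` is required when training with dropout."""
        spec = self.spec
        if x.ndim != 2 or x.shape[1] != spec.input_dim:
            raise ConfigError(
                f"input has {x.shape[-1] if x.ndim else 0} features, "
                f"network expects {spec.input_dim}"
            )
        cache = {"x": x, "training": training}
        h = x
        for i in range(spec.n_hidden_layers):
            z = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
            cache[f"h_in{i}"] = h
            if spec.batchnorm:
                if training:
                    mu = z.mean(axis=0)
                    var = z.var(axis=0)
                    self.running[f"mean{i}"] = (
                        (1 - _BN_MOMENTUM) * self.running[f"mean{i}"] + _BN_MOMENTUM * mu
                    )
                    self.running[f"var{i}"] = (
                        (1 - _BN_MOMENTUM) * self.running[f"var{i}"] + _BN_MOMENTUM * var
                    )
                else:
                    mu = self.running[f"mean{i}"]
                    var = self.running[f"var{i}"]
                inv_std = 1.0 / np.sqrt(var + _BN_EPS)
                zhat = (z - mu) * inv_std
                a = self.params[f"gamma{i}"] * zhat + self.params[f"beta{i}"]
                cache[f"zhat{i}"] = zhat
                cache[f"inv_std{i}"] = inv_std
            else:
                a = z
            relu_mask = a > 0
            h = a * relu_mask
            cache[f"relu_mask{i}"] = relu_mask
            if training and spec.dropout_p > 0:
                if rng is None:
                    raise ConfigError("training-mode forward needs an rng for dropout")
                keep = rng.random(h.shape) >= spec.dropout_p
                h = h * keep / (1.0 - spec.dropout_p)
                cache[f"drop_mask{i}"] = keep
            cache[f"h_out{i}"] = h
        k = spec.n_hidden_layers
        logits = h @ self.params[f"W{k}"] + self.params[f"b{k}"]
        logits = logits - logits.max(axis=1, keepdims=True)
        log_probs = logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))
        cache["final_in"] = h
        cache["log_probs"] = log_probs
        return log_probs, cache

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        log_probs, _ = self.forward(x, training=False)
        return np.exp(log_probs)

    # -- backward ----------------------------------------------------------

    def backward(self, cache, y: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of mean cross-entropy w.r.t. every parameter."""
        spec = self.spec
        n = y.shape[0]
        probs = np.exp(cache["log_probs"])
        delta = probs
        delta[np.arange(n), y] -= 1.0
        delta /= n

        grads: dict[str, np.ndarray] = {}
        k = spec.n_hidden_layers
        grads[f"W{k}"] = cache["final_in"].T @ delta
        grads[f"b{k}"] = delta.sum(axis=0)
        dh = delta @ self.params[f"W{k}"].T
        for i in range(k - 1, -1, -1):
            if cache["training"] and spec.dropout_p > 0:
                dh = dh * cache[f"drop_mask{i}"] / (1.0 - spec.dropout_p)
            da = dh * cache[f"relu_mask{i}"]
            if spec.batchnorm:
                zhat = cache[f"zhat{i}"]
                inv_std = cache[f"inv_std{i}"]
                grads[f"gamma{i}"] = (da * zhat).sum(axis=0)
                grads[f"beta{i}"] = da.sum(axis=0)
                dzhat = da * self.params[f"gamma{i}"]
                m = zhat.shape[0]
                dz = (
                    inv_std
                    / m
                    * (m * dzhat - dzhat.sum(axis=0) - zhat * (dzhat * zhat).sum(axis=0))
                )
            else:
                dz = da
            grads[f"W{i}"] = cache[f"h_in{i}"].T @ dz
            grads[f"b{i}"] = dz.sum(axis=0)
            if i > 0:
                dh = dz @ self.params[f"W{i}"].T
        return grads

    def copy_state(self) -> tuple[dict, dict]:
        return (
            {k: v.copy() for k, v in self.params.items()},
            {k: v.copy() for k, v in self.running.items()},
        )

    def load_state(self, state: tuple[dict, dict]) -> None:
        params, running = state
        self.params = {k: v.copy() for k, v in params.items()}
        self.running = {k: v.copy() for k, v in running.items()}


def build_network(spec: ClassifierSpec, seed: int = 0) -> MLPNetwork:
    """Instantiate the network with seeded random initialization."""
    return MLPNetwork(spec, seed=seed)


@dataclass
class TrainedClassifier:
    """Network(s) plus the feature standardizer and class-to-AOI mapping.

    ``networks`` usually holds a small ensemble of independently initialized
    copies of the same architecture; predicted probabilities are their mean.
    ``standardizer=None`` means features are consumed raw (used e.g. for the
    untrained chance-level baseline).
    """

    spec: ClassifierSpec
    networks: list[MLPNetwork]
    standardizer: Standardizer | None = None
    label_map: dict[int, AOI] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))
    train_log: list[dict] = field(default_factory=list)
    seed: int | None = None

    @property
    def network(self) -> MLPNetwork:
        return self.networks[0]

    def predict_proba(self, values: np.ndarray) -> np.ndarray:
        if self.standardizer is not None:
            values = self.standardizer.transform(values)
        probs = self.networks[0].predict_proba(values)
        for net in self.networks[1:]:
            probs = probs + net.predict_proba(values)
        return probs / len(self.networks)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _cross_entropy(net: MLPNetwork, x: np.ndarray, y: np.ndarray) -> float:
    log_probs, _ = net.forward(x, training=False)
    return float(-log_probs[np.arange(len(y)), y].mean())


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def train_classifier(
    model: MLPNetwork | ClassifierSpec,
    features: FeatureMatrix,
    labels: AOILabelSeries,
    split: TrainTestSplit,
    cfg: TrainConfig | None = None,
) -> TrainedClassifier:
    """Train one participant's network on the training half of labeled frames.

    Only rows in ``split.train_rows`` whose label is an on-screen AOI are
    used; OFF/UNLABELED rows are dropped.  A 10% slice of the training rows
    (by default) is held out as a validation set for early stopping on
    cross-entropy.  Feature standardization is fitted on the training rows
    only.  Weights are (re)initialized from ``cfg.seed`` so a run is fully
    reproducible and never depends on the test rows.
    """
    cfg = cfg or TrainConfig()
    spec = model if isinstance(model, ClassifierSpec) else model.spec

    codes = labels.codes
    rows = np.asarray(split.train_rows, dtype=int)
    rows = rows[codes[rows] <= AOI.RIGHT]
    if rows.size == 0:
        raise ConfigError("no on-screen labeled rows to train on")

    label_map = dict(DEFAULT_LABEL_MAP)
    class_of = {aoi: idx for idx, aoi in label_map.items()}
    present = set(int(c) for c in np.unique(codes[rows]))
    for idx, aoi in label_map.items():
        if idx < spec.n_classes and int(aoi) not in present:
            warnings.warn(
                f"class {aoi.name} absent from training rows; it cannot be learned",
                stacklevel=2,
            )

    standardizer = fit_standardizer(features, rows)
    x_all = standardizer.transform(features.values[rows])
    y_all = np.array([class_of[AOI(int(c))] for c in codes[rows]], dtype=int)

    rng = np.random.default_rng(cfg.seed)
    networks: list[MLPNetwork] = []
    log: list[dict] = []
    for member in range(cfg.n_ensemble):
        net, member_log = _train_single(spec, x_all, y_all, cfg, rng)
        for entry in member_log:
            entry["member"] = member
        networks.append(net)
        log.extend(member_log)
    return TrainedClassifier(
        spec=spec,
        networks=networks,
        standardizer=standardizer,
        label_map=label_map,
        train_log=log,
        seed=cfg.seed,
    )


def _train_single(
    spec: ClassifierSpec,
    x_all: np.ndarray,
    y_all: np.ndarray,
    cfg: TrainConfig,
    rng: np.random.Generator,
) -> tuple[MLPNetwork, list[dict]]:
    net = MLPNetwork(spec, seed=int(rng.integers(0, 2**31 - 1)))

    # validation slice carved out of the training rows
    n = x_all.shape[0]
    n_val = int(round(cfg.val_fraction * n))
    order = rng.permutation(n)
    val_idx, fit_idx = order[:n_val], order[n_val:]
    if fit_idx.size == 0:
        fit_idx, val_idx = order, order[:0]
    x_fit, y_fit = x_all[fit_idx], y_all[fit_idx]
    x_val, y_val = x_all[val_idx], y_all[val_idx]

    optim = _Adam(net.params, cfg.learning_rate)
    best_val = np.inf
    best_state = net.copy_state()
    stale = 0
    log: list[dict] = []
    for epoch in range(cfg.epochs):
        perm = rng.permutation(fit_idx.size)
        epoch_loss = 0.0
        n_seen = 0
        for start in range(0, fit_idx.size, cfg.batch_size):
            batch = perm[start : start + cfg.batch_size]
            if batch.size < 2 and fit_idx.size > 1:
                continue  # batch norm is degenerate on singleton batches
            log_probs, cache = net.forward(x_fit[batch], training=True, rng=rng)
            loss = float(-log_probs[np.arange(batch.size), y_fit[batch]].mean())
            grads = net.backward(cache, y_fit[batch])
            if cfg.weight_decay > 0:
                for k in grads:  # L2 on weight matrices only
                    if k.startswith("W"):
                        grads[k] = grads[k] + cfg.weight_decay * net.params[k]
            optim.step(net.params, grads)
            epoch_loss += loss * batch.size
            n_seen += batch.size
        entry = {"epoch": epoch, "train_loss": epoch_loss / max(n_seen, 1)}
        if val_idx.size:
            val_loss = _cross_entropy(net, x_val, y_val)
            entry["val_loss"] = val_loss
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_state = net.copy_state()
                stale = 0
            else:
                stale += 1
            log.append(entry)
            if stale >= cfg.patience:
                break
        else:
            best_state = net.copy_state()
            log.append(entry)
    net.load_state(best_state)
    return net, log


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def predict_frames(
    model: TrainedClassifier,
    table: SessionTable,
    features: FeatureMatrix,
    cfg: QualityConfig | None = None,
) -> AOILabelSeries:
    """Per-frame AOI predictions (source ``model``).

    Usable frames (tracked, confident) get the argmax class, with exact
    probability ties broken CENTER > LEFT > RIGHT; unusable frames get OFF.
    """
    if features.n_frames != table.n_frames:
        raise ConfigError("feature matrix and table disagree on frame count")
    probs = model.predict_proba(features.values)
    inv = {aoi: idx for idx, aoi in model.label_map.items()}
    pref = [inv[a] for a in _TIE_ORDER if a in inv]
    pref += [i for i in range(probs.shape[1]) if i not in pref]
    winners = np.argmax(probs[:, pref], axis=1)  # first max wins -> preference order
    codes = np.empty(table.n_frames, dtype=np.int8)
    for j, cls in enumerate(pref):
        codes[winners == j] = int(model.label_map[cls])
    usable = frame_quality_flags(table, cfg)
    codes[~usable] = AOI.OFF
    return AOILabelSeries(codes, source="model")


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_classifier(model: TrainedClassifier, path) -> str:
    """Persist a model as a single JSON document (spec, weights, scaler)."""
    doc = {
        "spec": {
            "input_dim": model.spec.input_dim,
            "hidden_widths": list(model.spec.hidden_widths),
            "n_classes": model.spec.n_classes,
            "dropout_p": model.spec.dropout_p,
            "batchnorm": model.spec.batchnorm,
        },
        "label_map": {str(k): v.name for k, v in model.label_map.items()},
        "seed": model.seed,
        "members": [
            {
                "params": {k: v.tolist() for k, v in net.params.items()},
                "running": {k: v.tolist() for k, v in net.running.items()},
            }
            for net in model.networks
        ],
        "standardizer": None
        if model.standardizer is None
        else {
            "center": model.standardizer.center.tolist(),
            "scale": model.standardizer.scale.tolist(),
        },
        "train_log": model.train_log,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
    return str(path)


def load_classifier(path) -> TrainedClassifier:
    with open(path) as fh:
        doc = json.load(fh)
    spec = ClassifierSpec(
        input_dim=doc["spec"]["input_dim"],
        hidden_widths=tuple(doc["spec"]["hidden_widths"]),
        n_classes=doc["spec"]["n_classes"],
        dropout_p=doc["spec"]["dropout_p"],
        batchnorm=doc["spec"]["batchnorm"],
    )
    networks = []
    for member in doc["members"]:
        net = MLPNetwork(spec, seed=0)
        net.params = {k: np.asarray(v, dtype=float) for k, v in member["params"].items()}
        net.running = {k: np.asarray(v, dtype=float) for k, v in member["running"].items()}
        networks.append(net)
    std = doc["standardizer"]
    standardizer = (
        None
        if std is None
        else Standardizer(
            center=np.asarray(std["center"], dtype=float),
            scale=np.asarray(std["scale"], dtype=float),
        )
    )
    return TrainedClassifier(
        spec=spec,
        networks=networks,
        standardizer=standardizer,
        label_map={int(k): AOI[v] for k, v in doc["label_map"].items()},
        train_log=doc.get("train_log", []),
        seed=doc.get("seed"),
    )
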