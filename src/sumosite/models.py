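"""Classifier families: random forest, LightGBM, plain CNNs, residual CNN.

All four families consume the encoded peptide tensors from
:mod:`sumosite.encoders` — networks as ``(n, positions, channels)`` tensors,
tree ensembles as the row-major flattened vectors — and emit a SUMOylation
probability per window.

Architecture defaults follow the reference protocol: 128 convolution kernels
of size 3, max-pooling (pool 2 / stride 1 / "same"), dropout 0.5 after each
convolution block, a 128- then 64-unit dense head with L2 penalty 0.01, a
single sigmoid output; the residual network stacks one plain convolution
block and two residual module blocks (five convolution sublayers in total).
Training uses Adam on binary cross-entropy, batch size 512, at most 500
epochs, early stopping once validation accuracy has not improved for 50
epochs, retaining the best-validation-accuracy state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from . import nn

ALGORITHMS = ("rf", "lgbm", "cnn", "rscnn")

#: LightGBM hyperparameter grid searched with 3-fold CV when requested.
LGBM_GRID = {
    "num_leaves": [15, 31, 63],
    "learning_rate": [0.05, 0.1],
    "n_estimators": [100, 200, 400],
}


@dataclass
class ModelConfig:
    """Hyperparameters for one classifier.

    ``n_conv_layers`` only applies to ``cnn`` (the depth-sweep variants
    CNN-1..CNN-8); ``n_residual_blocks`` only to ``rscnn``.
    """

    algorithm: str = "rscnn"
    n_conv_layers: int = 2
    kernels: int = 128
    kernel_size: int = 3
    pool_size: int = 2
    fc_sizes: tuple[int, ...] = (128, 64)
    dropout: float = 0.5
    l2: float = 0.01
    n_residual_blocks: int = 2
    rf_trees: int = 140
    lgbm_grid_search: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.kernels <= 0:
            raise ValueError("kernels must be positive")
        if not self.fc_sizes:
            raise ValueError("fc_sizes must be non-empty")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0,1)")


@dataclass
class TrainedModel:
    """A fitted classifier plus its config and (for networks) training log."""

    config: ModelConfig
    kind: str  # "network" | "tree"
    estimator: object
    input_shape: tuple[int, int]
    fitted: bool = False
    training_log: list[dict] = field(default_factory=list)

    def training_log_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("epoch,train_loss,train_acc,val_loss,val_acc\n")
            for row in self.training_log:
                fh.write(
                    f"{row['epoch']},{row['train_loss']:.6f},{row['train_acc']:.6f},"
                    f"{row['val_loss']:.6f},{row['val_acc']:.6f}\n"
                )


def _conv_block(layers, c_in, cfg, rng):
    layers.append(nn.Conv1D(c_in, cfg.kernels, cfg.kernel_size, rng))
    layers.append(nn.BatchNorm(cfg.kernels))
    layers.append(nn.ReLU())
    layers.append(nn.MaxPool1D(cfg.pool_size))
    layers.append(nn.Dropout(cfg.dropout))


def _dense_head(layers, n_in, cfg, rng):
    for size in cfg.fc_sizes:
        layers.append(nn.Dense(n_in, size, rng, relu=True, l2=cfg.l2))
        n_in = size
    layers.append(nn.Dense(n_in, 1, rng))


def build_cnn(config: ModelConfig, input_shape: tuple[int, int]) -> TrainedModel:
    """Plain CNN with ``config.n_conv_layers`` convolution blocks.

    Each block is conv(kernels, size 3, same) -> batch-norm -> ReLU ->
    max-pool(2, stride 1, same) -> dropout. Same-padding and stride-1
    pooling preserve the position count at every depth, so the flattened
    size entering the dense head is ``L * kernels`` regardless of depth.
    """
    if config.algorithm != "cnn":
        raise ValueError("build_cnn requires algorithm='cnn'")
    if config.n_conv_layers < 1:
        raise ValueError("n_conv_layers must be >= 1")
    L, c_in = input_shape
    rng = np.random.default_rng(config.seed)
    layers: list[nn.Layer] = []
    for i in range(config.n_conv_layers):
        _conv_block(layers, c_in if i == 0 else config.kernels, config, rng)
    layers.append(nn.Flatten())
    _dense_head(layers, L * config.kernels, config, rng)
    return TrainedModel(config, "network", nn.Network(layers, rng), input_shape)


def build_rscnn(config: ModelConfig, input_shape: tuple[int, int]) -> TrainedModel:
    """Residual CNN: one convolution block, then ``n_residual_blocks``
    residual modules (two conv + two batch-norm sublayers each, identity
    skip), then the shared dense head — five convolution sublayers at the
    default two residual blocks."""
    if config.algorithm != "rscnn":
        raise ValueError("build_rscnn requires algorithm='rscnn'")
    L, c_in = input_shape
    rng = np.random.default_rng(config.seed)
    layers: list[nn.Layer] = []
    _conv_block(layers, c_in, config, rng)
    for _ in range(config.n_residual_blocks):
        layers.append(nn.ResidualBlock(config.kernels, config.kernel_size, rng))
    layers.append(nn.Flatten())
    _dense_head(layers, L * config.kernels, config, rng)
    return TrainedModel(config, "network", nn.Network(layers, rng), input_shape)


def build_tree_baseline(
    config: ModelConfig, input_shape: tuple[int, int]
) -> TrainedModel:
    """Random forest (140 trees) or LightGBM baseline on flattened encodings.

    With ``config.lgbm_grid_search=True`` the LightGBM hyperparameters are
    chosen by 3-fold grid search over :data:`LGBM_GRID` (AUC-scored) at fit
    time; otherwise the mid-grid defaults (31 leaves, lr 0.1, 200 trees)
    are used directly.
    """
    if config.algorithm == "rf":
        est = RandomForestClassifier(
            n_estimators=config.rf_trees, random_state=config.seed, n_jobs=1
        )
    elif config.algorithm == "lgbm":
        import lightgbm

        base = lightgbm.LGBMClassifier(
            random_state=config.seed, verbose=-1, n_jobs=1,
            num_leaves=31, learning_rate=0.1, n_estimators=200,
        )
        if config.lgbm_grid_search:
            est = GridSearchCV(
                base, LGBM_GRID, scoring="roc_auc",
                cv=StratifiedKFold(3, shuffle=True, random_state=config.seed),
                n_jobs=1,
            )
        else:
            est = base
    else:
        raise ValueError("build_tree_baseline requires algorithm in {rf, lgbm}")
    return TrainedModel(config, "tree", est, input_shape)


def build_model(config: ModelConfig, input_shape: tuple[int, int]) -> TrainedModel:
    if config.algorithm == "cnn":
        return build_cnn(config, input_shape)
    if config.algorithm == "rscnn":
        return build_rscnn(config, input_shape)
    return build_tree_baseline(config, input_shape)


def _flatten(X: np.ndarray) -> np.ndarray:
    return X.reshape(X.shape[0], -1)


class EarlyStopping:
    """Patience-based early stopping on validation accuracy.

    Training stops once ``patience`` epochs elapse with no strict improvement
    over the best accuracy seen; the epoch of the best accuracy is kept so
    its parameter state can be restored.
    """

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best_acc = -np.inf
        self.best_epoch = 0

    def update(self, epoch: int, val_acc: float) -> bool:
        """Record an epoch; return True when training should stop."""
        if val_acc > self.best_acc:
            self.best_acc, self.best_epoch = val_acc, epoch
            return False
        return epoch - self.best_epoch >= self.patience


def fit_tree(model: TrainedModel, X: np.ndarray, y: np.ndarray) -> TrainedModel:
    if model.kind != "tree":
        raise ValueError("fit_tree expects a tree model")
    model.estimator.fit(_flatten(np.asarray(X)), np.asarray(y))
    model.fitted = True
    return model


def train_network(
    model: TrainedModel,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    batch_size: int = 512,
    max_epochs: int = 500,
    patience: int = 50,
    lr: float = 1e-3,
) -> TrainedModel:
    """Adam / binary cross-entropy training with accuracy-based early stopping.

    Stops after ``max_epochs`` or once validation accuracy (at threshold 0.5)
    has not improved for ``patience`` consecutive epochs; the parameter state
    with the best validation accuracy is restored before returning. Every
    epoch is appended to ``model.training_log``.
    """
    if model.kind != "network":
        raise ValueError("train_network expects a network model")
    X_train = np.asarray(X_train, dtype=np.float32)
    X_val = np.asarray(X_val, dtype=np.float32)
    if X_train.shape[0] == 0 or X_val.shape[0] == 0:
        raise ValueError("training and validation sets must be non-empty")
    if X_train.shape[1:] != X_val.shape[1:]:
        raise ValueError(
            f"encoding shape mismatch: train {X_train.shape[1:]} "
            f"vs validation {X_val.shape[1:]}"
        )
    y_train = np.asarray(y_train, dtype=np.float64)
    y_val = np.asarray(y_val, dtype=np.float64)
    net: nn.Network = model.estimator
    opt = nn.Adam(net.params, lr=lr)
    shuffle_rng = np.random.default_rng(model.config.seed + 1)

    stopper = EarlyStopping(patience)
    best_state = None
    model.training_log = []
    for epoch in range(1, max_epochs + 1):
        order = shuffle_rng.permutation(len(X_train))
        losses = []
        for i in range(0, len(order), batch_size):
            idx = order[i : i + batch_size]
            losses.append(net.train_batch(X_train[idx], y_train[idx]))
            opt.step(net.grads)
        train_p = net.predict_proba(X_train)
        val_p = net.predict_proba(X_val)
        val_logits_loss = float(
            np.mean(nn.bce_with_logits(_safe_logit(val_p), y_val))
        )
        row = {
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "train_acc": float(np.mean((train_p > 0.5) == y_train)),
            "val_loss": val_logits_loss,
            "val_acc": float(np.mean((val_p > 0.5) == y_val)),
        }
        model.training_log.append(row)
        stop = stopper.update(epoch, row["val_acc"])
        if stopper.best_epoch == epoch:
            best_state = net.get_state()
        if stop:
            break
    if best_state is not None:
        net.set_state(best_state)
    model.fitted = True
    return model


def _safe_logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return np.log(p / (1 - p))


def predict_scores(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Per-window SUMOylation probability in [0,1].

    Networks apply the logistic sigmoid to the final unit; tree ensembles
    return the class-1 probability.
    """
    if not model.fitted:
        raise RuntimeError("model is not fitted; train it first")
    X = np.asarray(X)
    if model.kind == "network":
        return model.estimator.predict_proba(X.astype(np.float32))
    return model.estimator.predict_proba(_flatten(X))[:, 1]


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: TrainedModel, path, channel_order: str = "") -> None:
    """Write a network checkpoint: ``<path>.npz`` weights plus a JSON sidecar
    with the configuration and channel order (tree models are not
    checkpointed here; persist them with joblib)."""
    if model.kind != "network":
        raise ValueError("save_checkpoint supports network models")
    state = model.estimator.get_state()
    np.savez(str(path) + ".npz", *state)
    sidecar = {
        "config": asdict(model.config),
        "input_shape": list(model.input_shape),
        "n_arrays": len(state),
        "channel_order": channel_order,
        "fitted": model.fitted,
    }
    with open(str(path) + ".json", "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=1)


def load_checkpoint(path) -> TrainedModel:
    with open(str(path) + ".json", encoding="utf-8") as fh:
        sidecar = json.load(fh)
    cfg_d = sidecar["config"]
    cfg_d["fc_sizes"] = tuple(cfg_d["fc_sizes"])
    config = ModelConfig(**cfg_d)
    model = build_model(config, tuple(sidecar["input_shape"]))
    with np.load(str(path) + ".npz") as data:
        state = [data[f"arr_{i}"] for i in range(sidecar["n_arrays"])]
    model.estimator.set_state(state)
    model.fitted = sidecar["fitted"]
    return model
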