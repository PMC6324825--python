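"""Feed-forward networks scoring residue pairs per distance bin.

Seven networks share one architecture: an input layer, eight hidden
rectifier layers of sizes 120, 50 and six of 30, and a single logistic
output unit scoring how likely the pair falls inside the network's
trained distance interval. Contacts are scored by an ensemble of four
such networks trained on nested upper cutoffs (7.9, 8.0, 8.1, 8.2 Å),
the final contact score being the arithmetic mean of the four outputs;
each non-contact distance bin uses a single network.

Training minimises binary cross-entropy with the Adam optimiser and
stops early on a held-out validation split, returning the weights of the
best validation epoch. All randomness (initialisation, splits, batch
order) is seeded, so training is reproducible bit-for-bit on one
platform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

#: hidden-layer widths shared by all seven networks
HIDDEN_SIZES = (120, 50, 30, 30, 30, 30, 30, 30)


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 10
    validation_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class NetworkModel:
    """One feed-forward scoring network (weights + metadata)."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    seed: int
    trained_interval: tuple[float, float] | None = None
    schema_id: str | None = None

    @property
    def layer_sizes(self) -> list[int]:
        return [self.weights[0].shape[0]] + [w.shape[1] for w in self.weights]

    @property
    def n_parameters(self) -> int:
        return int(sum(w.size for w in self.weights) + sum(b.size for b in self.biases))

    def logits(self, X: np.ndarray) -> np.ndarray:
        a = np.atleast_2d(X)
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.maximum(a @ W + b, 0.0)
        return (a @ self.weights[-1] + self.biases[-1]).ravel()

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Logistic output scores in (0, 1)."""
        return _sigmoid(self.logits(X))

    # ---- persistence -------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {}
        for k, (W, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"W{k}"] = W
            arrays[f"b{k}"] = b
        meta = {
            "seed": self.seed,
            "trained_interval": self.trained_interval,
            "schema_id": self.schema_id,
            "n_layers": len(self.weights),
        }
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "NetworkModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        n = meta["n_layers"]
        interval = meta["trained_interval"]
        return cls(
            weights=[data[f"W{k}"] for k in range(n)],
            biases=[data[f"b{k}"] for k in range(n)],
            seed=meta["seed"],
            trained_interval=tuple(interval) if interval else None,
            schema_id=meta["schema_id"],
        )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce_from_logits(z: np.ndarray, y: np.ndarray) -> float:
    # mean softplus(z) - y z, numerically stable
    return float(np.mean(np.maximum(z, 0) - y * z + np.log1p(np.exp(-np.abs(z)))))


def init_network(
    input_dim: int,
    seed: int,
    trained_interval: tuple[float, float] | None = None,
    schema_id: str | None = None,
) -> NetworkModel:
    """He-initialised network with layer sizes [input, 120, 50, 30 x 6, 1]."""
    if input_dim < 1:
        raise ValueError("input_dim must be >= 1")
    sizes = [input_dim, *HIDDEN_SIZES, 1]
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return NetworkModel(
        weights=weights, biases=biases, seed=seed,
        trained_interval=trained_interval, schema_id=schema_id,
    )


def expected_parameter_count(input_dim: int) -> int:
    """Closed-form parameter count of the fixed architecture."""
    sizes = [input_dim, *HIDDEN_SIZES, 1]
    return sum(a * b + b for a, b in zip(sizes[:-1], sizes[1:]))


@dataclass
class TrainingLog:
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = np.inf
    stopped_early: bool = False

    def record(self, epoch: int, train_loss: float, val_loss: float) -> None:
        self.epochs.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss}
        )


def train_network(
    model: NetworkModel,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
) -> tuple[NetworkModel, TrainingLog]:
    """Train by Adam on binary cross-entropy with early stopping.

    A seeded validation split is held out; after each epoch the
    validation loss is evaluated and training stops once it has failed
    to improve for ``cfg.patience`` consecutive epochs. The returned
    model carries the weights of the best validation epoch.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("feature/label row mismatch")
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])):
        raise ValueError("labels must be binary 0/1")
    if classes.size < 2:
        raise ValueError("training data contains a single class; cannot train")

    rng = np.random.default_rng(cfg.seed)
    n = X.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.validation_fraction * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    # both splits must contain both classes for the losses to be meaningful
    if np.unique(y[train_idx]).size < 2:
        raise ValueError("training split lost one class; provide more data")
    Xtr, ytr = X[train_idx], y[train_idx]
    Xval, yval = X[val_idx], y[val_idx]

    W = [w.copy() for w in model.weights]
    b = [v.copy() for v in model.biases]
    mW = [np.zeros_like(w) for w in W]
    vW = [np.zeros_like(w) for w in W]
    mb = [np.zeros_like(v) for v in b]
    vb = [np.zeros_like(v) for v in b]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = cfg.learning_rate
    t = 0

    def forward_logits(Wl, bl, A):
        acts = [A]
        for Wk, bk in zip(Wl[:-1], bl[:-1]):
            A = np.maximum(A @ Wk + bk, 0.0)
            acts.append(A)
        z = (A @ Wl[-1] + bl[-1]).ravel()
        return z, acts

    log = TrainingLog()
    best_W = [w.copy() for w in W]
    best_b = [v.copy() for v in b]
    no_improve = 0
    n_tr = Xtr.shape[0]

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n_tr)
        for start in range(0, n_tr, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            A0 = Xtr[idx]
            yb = ytr[idx]
            z, acts = forward_logits(W, b, A0)
            delta = (_sigmoid(z) - yb)[:, None] / idx.size
            grads_W = [None] * len(W)
            grads_b = [None] * len(b)
            d = delta
            for k in range(len(W) - 1, -1, -1):
                grads_W[k] = acts[k].T @ d
                grads_b[k] = d.sum(axis=0)
                if k > 0:
                    d = (d @ W[k].T) * (acts[k] > 0)
            t += 1
            corr1 = 1.0 - beta1 ** t
            corr2 = 1.0 - beta2 ** t
            for k in range(len(W)):
                mW[k] = beta1 * mW[k] + (1 - beta1) * grads_W[k]
                vW[k] = beta2 * vW[k] + (1 - beta2) * grads_W[k] ** 2
                W[k] -= lr * (mW[k] / corr1) / (np.sqrt(vW[k] / corr2) + eps)
                mb[k] = beta1 * mb[k] + (1 - beta1) * grads_b[k]
                vb[k] = beta2 * vb[k] + (1 - beta2) * grads_b[k] ** 2
                b[k] -= lr * (mb[k] / corr1) / (np.sqrt(vb[k] / corr2) + eps)

        ztr, _ = forward_logits(W, b, Xtr)
        zval, _ = forward_logits(W, b, Xval)
        train_loss = _bce_from_logits(ztr, ytr)
        val_loss = _bce_from_logits(zval, yval)
        log.record(epoch, train_loss, val_loss)
        if val_loss < log.best_val_loss - 1e-9:
            log.best_val_loss = val_loss
            log.best_epoch = epoch
            best_W = [w.copy() for w in W]
            best_b = [v.copy() for v in b]
            no_improve = 0
        else:
            no_improve += 1
            if no_improve >= cfg.patience:
                log.stopped_early = True
                break

    trained = NetworkModel(
        weights=best_W, biases=best_b, seed=model.seed,
        trained_interval=model.trained_interval, schema_id=model.schema_id,
    )
    return trained, log


@dataclass
class ContactEnsemble:
    """Four contact networks trained on nested distance cutoffs."""

    members: list[NetworkModel]

    def __post_init__(self) -> None:
        if len(self.members) != 4:
            raise ValueError("contact ensemble requires exactly 4 members")
        schema_ids = {m.schema_id for m in self.members}
        if len(schema_ids) > 1:
            raise ValueError("ensemble members disagree on feature schema")

    @property
    def schema_id(self) -> str | None:
        return self.members[0].schema_id

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Mean of the four member scores."""
        return np.mean([m.predict(X) for m in self.members], axis=0)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for k, m in enumerate(self.members):
            m.save(directory / f"contact_member{k}.npz")

    @classmethod
    def load(cls, directory: str | Path) -> "ContactEnsemble":
        directory = Path(directory)
        return cls(
            members=[
                NetworkModel.load(directory / f"contact_member{k}.npz")
                for k in range(4)
            ]
        )


def _check_schema(model_schema: str | None, features_schema: str | None) -> None:
    if model_schema and features_schema and model_schema != features_schema:
        raise ValueError(
            f"feature schema {features_schema} does not match the schema the "
            f"network was trained on ({model_schema})"
        )


def predict_bin(model: NetworkModel, X: np.ndarray, schema_id: str | None = None) -> np.ndarray:
    """Score pairs with one distance-bin network."""
    _check_schema(model.schema_id, schema_id)
    return model.predict(X)


def predict_contact(ensemble: ContactEnsemble, X: np.ndarray, schema_id: str | None = None) -> np.ndarray:
    """Score pairs with the four-network contact ensemble (member mean)."""
    _check_schema(ensemble.schema_id, schema_id)
    return ensemble.predict(X)


def balance_classes(
    y: np.ndarray, ratio: float, seed: int
) -> np.ndarray:
    """Indices keeping all positives and at most ratio x as many negatives.

    Non-contacting pairs outnumber contacts roughly 12:1 in globular
    proteins; training on a capped negative:positive ratio (default 5:1
    at the call sites) keeps gradients informative.
    """
    y = np.asarray(y).ravel()
    rng = np.random.default_rng(seed)
    pos = np.where(y == 1)[0]
    neg = np.where(y == 0)[0]
    n_neg = min(neg.size, int(round(ratio * pos.size)))
    keep_neg = rng.choice(neg, size=n_neg, replace=False)
    idx = np.sort(np.concatenate([pos, keep_neg]))
    return idx
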