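"""Convolutional species classifier for short barcode reads.

The network treats an encoded read as a ``(width, 4)`` single-channel
image.  The first convolutional layer uses a ``7 x 4`` kernel with no
padding, so it spans the full base axis and collapses it, leaving a
1-D feature map over read positions; deeper convolutional layers (up to
three in total, 4-16 filters each, optionally depth-wise separable) slide
a 7-position kernel over that map.  The flattened features feed one to
three dense layers and a softmax output over the ``C`` species of the
reference database.  Leaky-ReLU activations and dropout are applied to
all hidden layers.

The implementation is a compact, dependency-free numpy network (forward
and backward passes, Adam optimiser) sized for the tiny models this
problem needs: a typical configuration has ~10^5 parameters and trains in
seconds to minutes on one CPU.  Training minimises categorical
cross-entropy over freshly augmented batches drawn each epoch; a single
seed controls balancing, augmentation, initialisation, dropout and
shuffling, so runs are reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .augment import AugmentConfig, balance_oversample, make_epoch_batch
from .refdb import ReferenceDB, load_label_index, save_label_index
from .seqcodec import encode_batch

__all__ = [
    "ConvSpec",
    "ModelConfig",
    "TrainedClassifier",
    "build",
    "train",
    "predict_proba",
    "grid_search",
]


@dataclass(frozen=True)
class ConvSpec:
    """One convolutional layer: filter count, kernel extent, separability."""

    n_filters: int
    kernel: tuple[int, int] = (7, 4)
    depthwise_separable: bool = False


@dataclass
class ModelConfig:
    """Architecture of the classifier.

    ``conv_layers`` holds 1-3 :class:`ConvSpec` entries with 4-16 filters
    each; ``dense_layers`` holds 1-3 hidden widths.  ``input_width`` is the
    fixed read width (150 positions for 150-bp sequencers).
    """

    n_classes: int
    conv_layers: list[ConvSpec] = field(default_factory=lambda: [ConvSpec(4)])
    dense_layers: list[int] = field(default_factory=lambda: [128, 128, 128])
    dropout_rate: float = 0.2
    leaky_slope: float = 0.01
    input_width: int = 150

    def __post_init__(self) -> None:
        self.conv_layers = [
            c if isinstance(c, ConvSpec) else ConvSpec(**c) for c in self.conv_layers
        ]
        if not 1 <= len(self.conv_layers) <= 3:
            raise ValueError("conv_layers must have 1-3 entries")
        for c in self.conv_layers:
            if not 4 <= c.n_filters <= 16:
                raise ValueError(f"filters per conv layer must be 4-16, got {c.n_filters}")
        if not 1 <= len(self.dense_layers) <= 3:
            raise ValueError("dense_layers must have 1-3 entries")
        if any(w < 1 for w in self.dense_layers):
            raise ValueError("dense layer widths must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.leaky_slope <= 0:
            raise ValueError("leaky_slope must be > 0")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        width = self.input_width
        k0 = self.conv_layers[0].kernel
        if k0[1] != 4:
            raise ValueError("first conv kernel must span the 4 bases")
        for c in self.conv_layers:
            width -= c.kernel[0] - 1
        if width < 1:
            raise ValueError("conv stack consumes the whole input width")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conv_layers"] = [
            {"n_filters": c.n_filters, "kernel": list(c.kernel),
             "depthwise_separable": c.depthwise_separable}
            for c in self.conv_layers
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["conv_layers"] = [
            ConvSpec(c["n_filters"], tuple(c["kernel"]), c["depthwise_separable"])
            for c in d["conv_layers"]
        ]
        return cls(**d)


# ---------------------------------------------------------------------------
# numpy layers
# ---------------------------------------------------------------------------

class _ConvFirst:
    """2-D valid convolution over (positions, bases), single input channel."""

    def __init__(self, spec: ConvSpec, rng: np.random.Generator):
        kh, kw = spec.kernel
        self.kh, self.kw, self.nf = kh, kw, spec.n_filters
        scale = np.sqrt(2.0 / (kh * kw))
        self.params = [rng.normal(0.0, scale, (kh * kw, self.nf)), np.zeros(self.nf)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, train, rng):
        n = x.shape[0]
        win = sliding_window_view(x, (self.kh, self.kw), axis=(1, 2))
        self._cols = win.reshape(n, -1, self.kh * self.kw)
        return self._cols @ self.params[0] + self.params[1]

    def backward(self, dy):
        self.grads[0][...] = np.einsum("nwk,nwf->kf", self._cols, dy)
        self.grads[1][...] = dy.sum((0, 1))
        return None  # input gradient never needed for the first layer


class _Conv1D:
    """Valid 1-D convolution over positions with full channel depth."""

    def __init__(self, c_in, spec: ConvSpec, rng: np.random.Generator):
        self.k, self.c_in, self.nf = spec.kernel[0], c_in, spec.n_filters
        scale = np.sqrt(2.0 / (self.k * c_in))
        self.params = [
            rng.normal(0.0, scale, (self.k * c_in, self.nf)),
            np.zeros(self.nf),
        ]
        self.grads = [np.zeros_like(p) for p in self.params]

    def _windows(self, x):
        win = sliding_window_view(x, self.k, axis=1)  # (n, w', c, k)
        return np.ascontiguousarray(win.transpose(0, 1, 3, 2))  # (n, w', k, c)

    def forward(self, x, train, rng):
        self._shape = x.shape
        win = self._windows(x)
        self._cols = win.reshape(x.shape[0], -1, self.k * self.c_in)
        return self._cols @ self.params[0] + self.params[1]

    def backward(self, dy):
        self.grads[0][...] = np.einsum("nwk,nwf->kf", self._cols, dy)
        self.grads[1][...] = dy.sum((0, 1))
        dcols = (dy @ self.params[0].T).reshape(
            dy.shape[0], dy.shape[1], self.k, self.c_in
        )
        dx = np.zeros(self._shape)
        wp = dy.shape[1]
        for i in range(self.k):
            dx[:, i : i + wp, :] += dcols[:, :, i, :]
        return dx


class _SepConv1D:
    """Depth-wise separable 1-D convolution (depthwise 7-tap + pointwise mix)."""

    def __init__(self, c_in, spec: ConvSpec, rng: np.random.Generator):
        self.k, self.c_in, self.nf = spec.kernel[0], c_in, spec.n_filters
        self.params = [
            rng.normal(0.0, np.sqrt(2.0 / self.k), (self.k, c_in)),
            rng.normal(0.0, np.sqrt(2.0 / c_in), (c_in, self.nf)),
            np.zeros(self.nf),
        ]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, train, rng):
        self._shape = x.shape
        win = sliding_window_view(x, self.k, axis=1).transpose(0, 1, 3, 2)
        self._win = win  # (n, w', k, c)
        self._mid = np.einsum("nwkc,kc->nwc", win, self.params[0])
        return self._mid @ self.params[1] + self.params[2]

    def backward(self, dy):
        self.grads[2][...] = dy.sum((0, 1))
        self.grads[1][...] = np.einsum("nwc,nwf->cf", self._mid, dy)
        dmid = dy @ self.params[1].T
        self.grads[0][...] = np.einsum("nwkc,nwc->kc", self._win, dmid)
        dwin = dmid[:, :, None, :] * self.params[0][None, None, :, :]
        dx = np.zeros(self._shape)
        wp = dy.shape[1]
        for i in range(self.k):
            dx[:, i : i + wp, :] += dwin[:, :, i, :]
        return dx


class _LeakyReLU:
    def __init__(self, slope):
        self.slope = slope
        self.params, self.grads = [], []

    def forward(self, x, train, rng):
        self._neg = x < 0
        return np.where(self._neg, self.slope * x, x)

    def backward(self, dy):
        return np.where(self._neg, self.slope * dy, dy)


class _Dropout:
    """Inverted dropout, active only in training mode."""

    def __init__(self, rate):
        self.rate = rate
        self.params, self.grads = [], []

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class _Flatten:
    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class _Dense:
    def __init__(self, n_in, n_out, rng):
        self.params = [
            rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)),
            np.zeros(n_out),
        ]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, dy):
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(0)
        return dy @ self.params[0].T


class _Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Network:
    """Layer stack built from a :class:`ModelConfig`."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        layers: list = []
        width = config.input_width
        c_in = 1
        for i, spec in enumerate(config.conv_layers):
            if i == 0:
                layers.append(_ConvFirst(spec, rng))
            elif spec.depthwise_separable:
                layers.append(_SepConv1D(c_in, spec, rng))
            else:
                layers.append(_Conv1D(c_in, spec, rng))
            width -= spec.kernel[0] - 1
            c_in = spec.n_filters
            layers.append(_LeakyReLU(config.leaky_slope))
        layers.append(_Flatten())
        n_in = width * c_in
        for w in config.dense_layers:
            layers.append(_Dense(n_in, w, rng))
            layers.append(_LeakyReLU(config.leaky_slope))
            layers.append(_Dropout(config.dropout_rate))
            n_in = w
        layers.append(_Dense(n_in, config.n_classes, rng))
        self.layers = layers

    def forward(self, X, train=False, rng=None):
        out = X
        for layer in self.layers:
            out = layer.forward(out, train, rng)
        return out

    def backward(self, dlogits):
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
            if grad is None:
                break

    def parameters(self):
        return [p for layer in self.layers for p in layer.params]

    def gradients(self):
        return [g for layer in self.layers for g in layer.grads]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError("weight list does not match the architecture")
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape {w.shape} != expected {p.shape}")
            p[...] = w


# ---------------------------------------------------------------------------
# public classifier API
# ---------------------------------------------------------------------------

_CHECKPOINT_VERSION = 1


class TrainedClassifier:
    """Architecture + fitted weights + species index.

    Maps read strings to a probability distribution over species.  Created
    untrained by :func:`build` and fitted in place by :func:`train`.
    """

    def __init__(
        self,
        config: ModelConfig,
        label_index: dict[str, int] | None = None,
        seed: int = 0,
    ):
        self.config = config
        if label_index is not None and len(label_index) != config.n_classes:
            raise ValueError(
                f"label index has {len(label_index)} species but the model "
                f"has {config.n_classes} output classes"
            )
        self.label_index = label_index
        self.net = _Network(config, np.random.default_rng(seed))
        self.training_meta: dict = {"init_seed": seed, "trained": False}

    @property
    def species(self) -> list[str]:
        """Species labels in class-integer order (class indices if unnamed)."""
        if self.label_index is None:
            return [str(i) for i in range(self.config.n_classes)]
        return sorted(self.label_index, key=self.label_index.get)

    def predict_proba(
        self, seqs: Sequence[str], batch_size: int = 2048
    ) -> np.ndarray:
        """Class probabilities for each read, shape ``(N, C)``.

        Reads are encoded and shaped to the model width internally.  Reads
        containing non-IUPAC characters are skipped: their rows are NaN
        (callers count them as unclassifiable).  Rows of valid reads sum
        to 1.
        """
        n = len(seqs)
        out = np.zeros((n, self.config.n_classes))
        for start in range(0, n, batch_size):
            chunk = list(seqs[start : start + batch_size])
            X, bad = encode_batch(chunk, self.config.input_width, on_error="skip")
            if bad.size:
                good = np.setdiff1d(np.arange(len(chunk)), bad)
                probs = np.full((len(chunk), self.config.n_classes), np.nan)
                if good.size:
                    probs[good] = _softmax(self.net.forward(X[good]))
            else:
                probs = _softmax(self.net.forward(X))
            out[start : start + len(chunk)] = probs
        return out

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write a self-describing checkpoint directory.

        Contains ``config.json``, ``label_index.json``, ``weights.npz``
        (exact float64 arrays) and ``meta.json``; reloading reproduces
        ``predict_proba`` bit-identically.
        """
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        with open(path / "config.json", "w") as fh:
            json.dump(
                {"version": _CHECKPOINT_VERSION, "model": self.config.to_dict()},
                fh,
                indent=1,
            )
        save_label_index(
            self.label_index
            if self.label_index is not None
            else {str(i): i for i in range(self.config.n_classes)},
            path / "label_index.json",
        )
        np.savez(
            path / "weights.npz",
            **{f"w{i}": w for i, w in enumerate(self.net.get_weights())},
        )
        with open(path / "meta.json", "w") as fh:
            json.dump(self.training_meta, fh, indent=1, default=str)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedClassifier":
        path = Path(path)
        with open(path / "config.json") as fh:
            payload = json.load(fh)
        if payload.get("version") != _CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {payload.get('version')}")
        config = ModelConfig.from_dict(payload["model"])
        label_index = load_label_index(path / "label_index.json")
        clf = cls(config, label_index, seed=0)
        with np.load(path / "weights.npz") as npz:
            clf.net.set_weights([npz[f"w{i}"] for i in range(len(npz.files))])
        with open(path / "meta.json") as fh:
            clf.training_meta = json.load(fh)
        return clf


def build(
    config: ModelConfig,
    label_index: dict[str, int] | None = None,
    seed: int = 0,
) -> TrainedClassifier:
    """Instantiate an untrained classifier with seeded weight initialisation."""
    return TrainedClassifier(config, label_index, seed=seed)


def train(
    classifier: TrainedClassifier,
    train_db: ReferenceDB,
    aug: AugmentConfig,
    *,
    epochs: int = 50,
    learning_rate: float = 1e-3,
    batch_size: int = 64,
    seed: int = 0,
    balance: bool = True,
    verbose: bool = False,
) -> TrainedClassifier:
    """Fit the classifier on freshly augmented batches, one per epoch.

    Minimises categorical cross-entropy with Adam.  The species of
    ``train_db`` must match the classifier's label index (which is taken
    from the DB if the classifier has none).  ``seed`` drives class
    balancing, per-epoch augmentation, shuffling and dropout, so the run
    is reproducible.  ``epochs=0`` returns the classifier unchanged.

    Raises
    ------
    ValueError
        On an empty database or a label mismatch.
    FloatingPointError
        If the loss becomes non-finite (reported with epoch diagnostics).
    """
    if len(train_db) == 0:
        raise ValueError("cannot train on an empty reference database")
    if classifier.label_index is None:
        if train_db.n_classes != classifier.config.n_classes:
            raise ValueError(
                f"database has {train_db.n_classes} species but the model "
                f"has {classifier.config.n_classes} output classes"
            )
        classifier.label_index = dict(train_db.label_index)
    elif not set(train_db.label_index) <= set(classifier.label_index):
        extra = sorted(set(train_db.label_index) - set(classifier.label_index))
        raise ValueError(f"database species missing from the label index: {extra[:3]}")

    rng = np.random.default_rng(seed)
    db = balance_oversample(train_db, rng) if balance else train_db
    net = classifier.net
    opt = _Adam(net.parameters(), lr=learning_rate)
    history: list[float] = []
    for epoch in range(epochs):
        X, y = make_epoch_batch(db, aug, rng, label_index=classifier.label_index)
        order = rng.permutation(len(y))
        epoch_loss = 0.0
        for start in range(0, len(order), batch_size):
            sel = order[start : start + batch_size]
            logits = net.forward(X[sel], train=True, rng=rng)
            probs = _softmax(logits)
            loss = -np.mean(
                np.log(np.clip(probs[np.arange(len(sel)), y[sel]], 1e-300, None))
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch offset {start} "
                    f"(lr={learning_rate}); try a smaller learning rate"
                )
            epoch_loss += loss * len(sel)
            dlogits = probs
            dlogits[np.arange(len(sel)), y[sel]] -= 1.0
            dlogits /= len(sel)
            net.backward(dlogits)
            opt.step(net.parameters(), net.gradients())
        history.append(epoch_loss / len(order))
        if verbose:
            print(f"epoch {epoch + 1}/{epochs}  loss {history[-1]:.4f}")
    classifier.training_meta.update(
        trained=classifier.training_meta.get("trained", False) or epochs > 0,
        epochs=epochs,
        learning_rate=learning_rate,
        batch_size=batch_size,
        seed=seed,
        augment=aug.to_dict(),
        final_loss=history[-1] if history else None,
    )
    return classifier


def predict_proba(
    classifier: TrainedClassifier, seqs: Sequence[str], batch_size: int = 2048
) -> np.ndarray:
    """Functional alias for :meth:`TrainedClassifier.predict_proba`."""
    return classifier.predict_proba(seqs, batch_size=batch_size)


def grid_search(
    configs: Sequence[ModelConfig],
    train_db: ReferenceDB,
    holdout_db: ReferenceDB,
    aug: AugmentConfig,
    *,
    seed: int = 0,
    epochs: int = 50,
    learning_rate: float = 1e-3,
    batch_size: int = 64,
):
    """Train every candidate architecture identically and rank by hold-out
    accuracy (argmax, no rejection); ties go to the smaller model.

    Returns ``(best_config, report)`` where ``report`` is a
    :class:`pandas.DataFrame` with one row per configuration.
    """
    import pandas as pd

    if not configs:
        raise ValueError("grid_search needs at least one configuration")
    seqs = [r.sequence for r in holdout_db.records]
    truth = np.array(
        [train_db.label_index[r.species] for r in holdout_db.records]
    )
    rows = []
    for i, cfg in enumerate(configs):
        clf = build(cfg, label_index=dict(train_db.label_index), seed=seed)
        train(
            clf,
            train_db,
            aug,
            epochs=epochs,
            learning_rate=learning_rate,
            batch_size=batch_size,
            seed=seed,
        )
        probs = clf.predict_proba(seqs)
        acc = float(np.mean(np.argmax(probs, axis=1) == truth))
        rows.append(
            {
                "config": i,
                "n_conv": len(cfg.conv_layers),
                "filters": "x".join(str(c.n_filters) for c in cfg.conv_layers),
                "dense": "x".join(str(w) for w in cfg.dense_layers),
                "n_parameters": clf.net.n_parameters(),
                "holdout_accuracy": acc,
            }
        )
    report = pd.DataFrame(rows)
    best = report.sort_values(
        ["holdout_accuracy", "n_parameters"], ascending=[False, True]
    ).iloc[0]
    return configs[int(best["config"])], report
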