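"""Shared DeconvNet backbone: density regression and patch classification.

The backbone stacks three convolution + max-pooling blocks, three
upsampling + convolution ("deconvolution") blocks and a final convolution
producing a single-channel density map at input resolution (3x3 kernels,
ReLU activations).  Fully convolutional: any input whose spatial dims are
divisible by ``2**n_down_blocks`` is accepted.  An optional classifier head
(global average pool -> fully connected -> logistic squashing) turns the
last convolutional features into a patch cancer confidence C(x) in [0, 1].

Training uses MSE loss and Adam with the learning rate decayed from an
initial to a final value in equal steps per epoch; estimator classes
(:class:`DensityRegressor`, :class:`PatchClassifier`) wrap the training
loop in the scikit-learn fit/predict idiom.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin

from . import nn
from .pyramid import Patch


@dataclass
class BackboneConfig:
    """Architecture of the DeconvNet backbone.

    Filter widths double per down block (base_filters, 2x, 4x, ...); kernel
    size must be odd (default 3).  ``upsample`` selects nearest-neighbour
    replication (default) or zero-stuffing, the latter making each
    up block a stride-2 transposed convolution.
    """

    in_channels: int = 3
    base_filters: int = 16
    kernel_size: int = 3
    n_down_blocks: int = 3
    n_up_blocks: int = 3
    head: str = "density"
    upsample: str = "nearest"

    def __post_init__(self):
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        if self.n_down_blocks != self.n_up_blocks:
            raise ValueError("n_down_blocks must equal n_up_blocks")
        if self.head not in ("density", "classifier"):
            raise ValueError("head must be 'density' or 'classifier'")


@dataclass
class TrainConfig:
    """Optimization settings: Adam, lr decayed 1e-3 -> 1e-5 in equal steps."""

    optimizer: str = "adam"
    lr_initial: float = 1e-3
    lr_final: float = 1e-5
    epochs: int = 50
    batch_size: int = 16
    split_fraction: float = 0.70
    seed: int = 0

    def __post_init__(self):
        if self.lr_final > self.lr_initial:
            raise ValueError("lr_final must not exceed lr_initial")
        if not (0 < self.split_fraction < 1):
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is supported")


class DeconvNet:
    """The backbone network with density and (optional) classifier heads."""

    def __init__(self, config, seed=0):
        self.config = config
        rng = np.random.default_rng(seed)
        f = config.base_filters
        k = config.kernel_size
        layers = []
        cin = config.in_channels
        for b in range(config.n_down_blocks):
            cout = f * (2 ** b)
            layers += [nn.Conv2D(cin, cout, k, rng), nn.ReLU(), nn.MaxPool2()]
            cin = cout
        for b in range(config.n_up_blocks):
            cout = f * (2 ** max(config.n_down_blocks - 2 - b, 0))
            layers += [nn.Upsample2(config.upsample), nn.Conv2D(cin, cout, k, rng),
                       nn.ReLU()]
            cin = cout
        self.trunk = nn.Sequential(layers)
        self.density_conv = nn.Conv2D(cin, 1, k, rng)
        self.trunk_channels = cin
        self.classifier_head = None
        if config.head == "classifier":
            self.attach_classifier_head(seed=seed + 1)

    # -- heads -------------------------------------------------------------
    def attach_classifier_head(self, seed=1):
        """Global pooling + fully connected + logistic confidence head."""
        rng = np.random.default_rng(seed)
        self.classifier_head = nn.Sequential([
            nn.GlobalAvgPool(), nn.Dense(self.trunk_channels, 1, rng), nn.Sigmoid()])
        return self

    # -- plumbing ----------------------------------------------------------
    def check_input(self, x):
        div = 2 ** self.config.n_down_blocks
        h, w = x.shape[2], x.shape[3]
        if h % div or w % div:
            raise ValueError(
                f"input spatial dims {h}x{w} must be divisible by "
                f"2**n_down_blocks = {div}")

    def parameters(self, head="density"):
        params = list(self.trunk.params())
        if head == "density":
            params += self.density_conv.params()
        elif head == "classifier":
            if self.classifier_head is None:
                raise ValueError("no classifier head attached")
            params += self.classifier_head.params()
        else:
            raise ValueError(head)
        return params

    def forward_density(self, x, train=False):
        self.check_input(x)
        return self.density_conv.forward(self.trunk.forward(x, train), train)

    def backward_density(self, dy):
        self.trunk.backward(self.density_conv.backward(dy))

    def forward_confidence(self, x, train=False):
        if self.classifier_head is None:
            raise ValueError("no classifier head attached")
        self.check_input(x)
        feats = self.trunk.forward(x, train)
        return self.classifier_head.forward(feats, train)[:, 0]

    def backward_confidence(self, dy):
        self.trunk.backward(self.classifier_head.backward(dy[:, None]))

    # -- checkpoints -------------------------------------------------------
    def save(self, path):
        arrays = {f"p{i}": p for i, (p, _) in enumerate(self._all_params())}
        np.savez(path, __config__=json.dumps(asdict(self.config)), **arrays)

    def _all_params(self):
        params = list(self.trunk.params()) + list(self.density_conv.params())
        if self.classifier_head is not None:
            params += self.classifier_head.params()
        return params

    @classmethod
    def load(cls, path):
        data = np.load(path, allow_pickle=False)
        config = BackboneConfig(**json.loads(str(data["__config__"])))
        model = cls(config, seed=0)
        if config.head != "classifier" and f"p{len(model.parameters('density'))}" in data:
            model.attach_classifier_head()
        for i, (p, _) in enumerate(model._all_params()):
            p[...] = data[f"p{i}"]
        return model


def build_deconvnet(config=None, seed=0):
    """Build a DeconvNet from a :class:`BackboneConfig` (spec entry point)."""
    return DeconvNet(config or BackboneConfig(), seed=seed)


def attach_classifier_head(model, seed=1):
    return model.attach_classifier_head(seed=seed)


def _as_input(X):
    """(n, h, w, 3) uint8/float images -> float32 (n, 3, h, w) in [0, 1]."""
    X = np.asarray(X)
    if X.ndim == 3:
        X = X[None]
    if X.ndim != 4 or X.shape[3] != 3:
        raise ValueError("expected images of shape (n, h, w, 3)")
    X = X.astype(np.float32)
    if X.max() > 1.5:
        X = X / 255.0
    return np.ascontiguousarray(X.transpose(0, 3, 1, 2))


def _train_loop(model, X, targets, cfg, mode):
    """Shared minibatch MSE/Adam loop; returns per-epoch loss history."""
    n = len(X)
    if n == 0:
        raise ValueError("empty dataset")
    params = model.parameters("classifier" if mode == "classifier" else "density")
    opt = nn.Adam(params, lr=cfg.lr_initial)
    rng = np.random.default_rng(cfg.seed)
    history = []
    for epoch in range(cfg.epochs):
        lr = nn.lr_schedule(epoch, cfg.epochs, cfg.lr_initial, cfg.lr_final)
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = X[idx]
            tb = targets[idx]
            opt.zero_grad()
            if mode == "classifier":
                out = model.forward_confidence(xb, train=True)
                err = out - tb
                loss = float(np.mean(err ** 2))
                model.backward_confidence((2.0 / len(idx)) * err.astype(nn.DTYPE))
            else:
                out = model.forward_density(xb, train=True)[:, 0]
                err = out - tb
                loss = float(np.mean(err ** 2))
                model.backward_density(
                    ((2.0 / err.size) * err)[:, None].astype(nn.DTYPE))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"NaN/Inf loss at epoch {epoch} (lr={lr:.2e}); aborting")
            opt.step(lr=lr)
            total += loss * len(idx)
        history.append(total / n)
    return history


def train(model, dataset, cfg=None):
    """Train a DeconvNet on (patch, target) pairs (spec entry point).

    Targets that are 2-D arrays select the density head; scalar {0, 1}
    targets select the classifier head.  Returns ``(model, loss_history)``.
    """
    cfg = cfg or TrainConfig()
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    imgs = [p.image if isinstance(p, Patch) else p for p, _ in dataset]
    X = _as_input(np.stack(imgs))
    first_target = np.asarray(dataset[0][1])
    if first_target.ndim == 2:
        targets = np.stack([np.asarray(t) for _, t in dataset]).astype(np.float32)
        mode = "density"
    else:
        targets = np.asarray([float(t) for _, t in dataset], dtype=np.float32)
        mode = "classifier"
        if model.classifier_head is None:
            model.attach_classifier_head()
    history = _train_loop(model, X, targets, cfg, mode)
    return model, history


def predict_density(model, patch):
    """Predict a nonnegative density map for one patch (negatives clamped)."""
    img = patch.image if isinstance(patch, Patch) else patch
    x = _as_input(img)
    out = model.forward_density(x, train=False)[:, 0]
    return np.maximum(out[0], 0.0)


class DensityRegressor(RegressorMixin, BaseEstimator):
    """Density-map regressor on image patches (DeconvNet density head).

    Parameters follow the backbone defaults; ``fit(X, Y)`` takes images of
    shape (n, h, w, 3) and density targets (n, h, w); ``predict`` returns
    nonnegative maps of the same spatial shape.  Targets are internally
    multiplied by ``target_scale`` during optimization (unit-mass Gaussian
    kernels peak near 0.02, far below a useful MSE working range) and
    predictions divided back, so the interface stays in true density units.
    """

    def __init__(self, base_filters=8, n_blocks=3, kernel_size=3, epochs=50,
                 batch_size=16, lr_initial=1e-3, lr_final=1e-5,
                 target_scale=100.0, upsample="nearest", random_state=0):
        self.base_filters = base_filters
        self.n_blocks = n_blocks
        self.kernel_size = kernel_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr_initial = lr_initial
        self.lr_final = lr_final
        self.target_scale = target_scale
        self.upsample = upsample
        self.random_state = random_state

    def _config(self):
        return BackboneConfig(base_filters=self.base_filters,
                              kernel_size=self.kernel_size,
                              n_down_blocks=self.n_blocks,
                              n_up_blocks=self.n_blocks,
                              upsample=self.upsample)

    def fit(self, X, Y):
        Xc = _as_input(X)
        Y = np.asarray(Y, dtype=np.float32)
        if Y.shape != (Xc.shape[0], Xc.shape[2], Xc.shape[3]):
            raise ValueError("Y must be (n, h, w) density maps matching X")
        self.model_ = DeconvNet(self._config(), seed=self.random_state)
        cfg = TrainConfig(lr_initial=self.lr_initial, lr_final=self.lr_final,
                          epochs=self.epochs, batch_size=self.batch_size,
                          seed=self.random_state)
        self.loss_history_ = _train_loop(self.model_, Xc,
                                         Y * np.float32(self.target_scale),
                                         cfg, "density")
        return self

    def predict(self, X):
        Xc = _as_input(X)
        out = self.model_.forward_density(Xc, train=False)[:, 0]
        return np.maximum(out / np.float32(self.target_scale), 0.0)


class PatchClassifier(ClassifierMixin, BaseEstimator):
    """Tumor/normal patch classifier (DeconvNet + confidence head).

    Trained with MSE on {0, 1} targets by default (the backbone's blanket
    loss choice); ``loss='cross_entropy'`` switches to log loss.
    """

    def __init__(self, base_filters=8, n_blocks=3, kernel_size=3, epochs=50,
                 batch_size=16, lr_initial=1e-3, lr_final=1e-5, loss="mse",
                 upsample="nearest", random_state=0):
        self.base_filters = base_filters
        self.n_blocks = n_blocks
        self.kernel_size = kernel_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr_initial = lr_initial
        self.lr_final = lr_final
        self.loss = loss
        self.upsample = upsample
        self.random_state = random_state

    def fit(self, X, y):
        Xc = _as_input(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if not set(self.classes_.tolist()) <= {0, 1}:
            raise ValueError("labels must be binary {0, 1}")
        yf = y.astype(np.float32)
        if self.loss not in ("mse", "cross_entropy"):
            raise ValueError("loss must be 'mse' or 'cross_entropy'")
        config = BackboneConfig(base_filters=self.base_filters,
                                kernel_size=self.kernel_size,
                                n_down_blocks=self.n_blocks,
                                n_up_blocks=self.n_blocks,
                                head="classifier", upsample=self.upsample)
        self.model_ = DeconvNet(config, seed=self.random_state)
        cfg = TrainConfig(lr_initial=self.lr_initial, lr_final=self.lr_final,
                          epochs=self.epochs, batch_size=self.batch_size,
                          seed=self.random_state)
        if self.loss == "mse":
            self.loss_history_ = _train_loop(self.model_, Xc, yf, cfg, "classifier")
        else:
            self.loss_history_ = self._fit_xent(Xc, yf, cfg)
        return self

    def _fit_xent(self, X, y, cfg):
        opt = nn.Adam(self.model_.parameters("classifier"), lr=cfg.lr_initial)
        rng = np.random.default_rng(cfg.seed)
        history = []
        eps = 1e-7
        for epoch in range(cfg.epochs):
            lr = nn.lr_schedule(epoch, cfg.epochs, cfg.lr_initial, cfg.lr_final)
            order = rng.permutation(len(X))
            total = 0.0
            for start in range(0, len(X), cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                opt.zero_grad()
                p = np.clip(self.model_.forward_confidence(X[idx], train=True),
                            eps, 1 - eps)
                t = y[idx]
                loss = float(np.mean(-(t * np.log(p) + (1 - t) * np.log(1 - p))))
                if not np.isfinite(loss):
                    raise FloatingPointError(f"NaN loss at epoch {epoch}")
                grad = ((p - t) / (p * (1 - p))) / len(idx)
                self.model_.backward_confidence(grad.astype(nn.DTYPE))
                opt.step(lr=lr)
                total += loss * len(idx)
            history.append(total / len(X))
        return history

    def predict_proba(self, X):
        Xc = _as_input(X)
        p = self.model_.forward_confidence(Xc, train=False)
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(np.int64)

    def confidence(self, patch):
        """Cancer confidence C(x) of a single Patch or image."""
        img = patch.image if isinstance(patch, Patch) else patch
        return float(self.predict_proba(img[None] if img.ndim == 3 else img)[0, 1])


def train_test_split_indices(n, split_fraction=0.70, seed=0):
    """Deterministic 70/30-style index split."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(split_fraction * n))
    return order[:n_train], order[n_train:]
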