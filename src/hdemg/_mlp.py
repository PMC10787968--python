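"""Fully-connected classifier trained with label smoothing and one-cycle Adam.

Architecture: input -> [Linear 1000 -> BatchNorm -> ReLU -> Dropout 0.2]
-> [Linear 500 -> BatchNorm -> ReLU -> Dropout 0.2] -> Linear n_classes
-> softmax. Implemented directly on NumPy arrays with hand-written
backpropagation; training is full mini-batch Adam under a one-cycle
learning-rate schedule with early stopping on a held-out validation split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class MLPSpec:
    hidden: tuple[int, int] = (1000, 500)
    dropout: float = 0.2
    label_smoothing_p: float = 0.9  # target-class probability
    epochs: int = 400
    batch_size: int = 64
    max_lr: float = 1e-3
    pct_start: float = 0.25  # warm-up fraction of the one-cycle schedule
    val_fraction: float = 0.1
    patience: int = 20
    bn_momentum: float = 0.9
    bn_eps: float = 1e-5


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def one_cycle_lr(step: int, total_steps: int, max_lr: float, pct_start: float) -> float:
    """Cosine warm-up from max_lr/25 to max_lr, then anneal to max_lr/1e4."""
    warm = max(1, int(total_steps * pct_start))
    if step < warm:
        t = step / warm
        lo = max_lr / 25.0
        return lo + (max_lr - lo) * 0.5 * (1 - np.cos(np.pi * t))
    t = (step - warm) / max(1, total_steps - warm)
    lo = max_lr / 1e4
    return lo + (max_lr - lo) * 0.5 * (1 + np.cos(np.pi * t))


class _Linear:
    def __init__(self, rng, n_in, n_out):
        # He initialization suits the ReLU nonlinearity
        self.W = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.b = np.zeros(n_out)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.gW = self._x.T @ g
        self.gb = g.sum(axis=0)
        return g @ self.W.T

    params = property(lambda self: [self.W, self.b])
    grads = property(lambda self: [self.gW, self.gb])


class _BatchNorm:
    def __init__(self, n, momentum, eps):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.run_mean = np.zeros(n)
        self.run_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training):
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mu
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mu, var = self.run_mean, self.run_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        return self.gamma * self._xhat + self.beta

    def backward(self, g):
        n = g.shape[0]
        xhat = self._xhat
        self.ggamma = (g * xhat).sum(axis=0)
        self.gbeta = g.sum(axis=0)
        gx = g * self.gamma
        return (gx - gx.mean(axis=0) - xhat * (gx * xhat).mean(axis=0)) / self._std

    params = property(lambda self: [self.gamma, self.beta])
    grads = property(lambda self: [self.ggamma, self.gbeta])


class MLPNet:
    """The network itself: parameters, forward pass, backward pass."""

    def __init__(self, n_in: int, n_classes: int, spec: MLPSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.n_in, self.n_classes = n_in, n_classes
        h1, h2 = spec.hidden
        self.lin1 = _Linear(rng, n_in, h1)
        self.bn1 = _BatchNorm(h1, spec.bn_momentum, spec.bn_eps)
        self.lin2 = _Linear(rng, h1, h2)
        self.bn2 = _BatchNorm(h2, spec.bn_momentum, spec.bn_eps)
        self.lin3 = _Linear(rng, h2, n_classes)
        self._layers = [self.lin1, self.bn1, self.lin2, self.bn2, self.lin3]

    @property
    def n_parameters(self) -> int:
        return sum(p.size for layer in self._layers for p in layer.params)

    def forward(self, x, training=False, rng=None):
        p = self.spec.dropout
        h = self.bn1.forward(self.lin1.forward(x), training)
        self._m1 = h > 0
        h = h * self._m1
        if training and p > 0:
            self._d1 = (rng.random(h.shape) >= p) / (1 - p)
            h = h * self._d1
        h = self.bn2.forward(self.lin2.forward(h), training)
        self._m2 = h > 0
        h = h * self._m2
        if training and p > 0:
            self._d2 = (rng.random(h.shape) >= p) / (1 - p)
            h = h * self._d2
        return self.lin3.forward(h)

    def backward(self, g, training_dropout=True):
        g = self.lin3.backward(g)
        if training_dropout and self.spec.dropout > 0:
            g = g * self._d2
        g = self.bn2.backward(g * self._m2)
        g = self.lin2.backward(g)
        if training_dropout and self.spec.dropout > 0:
            g = g * self._d1
        g = self.bn1.backward(g * self._m1)
        self.lin1.backward(g)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(np.asarray(x, dtype=np.float64), training=False))

    # --- serialization -------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self._layers):
            for j, p in enumerate(layer.params):
                out[f"layer{i}_p{j}"] = p
        out["bn1_run_mean"] = self.bn1.run_mean
        out["bn1_run_var"] = self.bn1.run_var
        out["bn2_run_mean"] = self.bn2.run_mean
        out["bn2_run_var"] = self.bn2.run_var
        return out

    def load_state_arrays(self, arrays) -> None:
        for i, layer in enumerate(self._layers):
            for j, p in enumerate(layer.params):
                p[...] = arrays[f"layer{i}_p{j}"]
        self.bn1.run_mean = np.asarray(arrays["bn1_run_mean"], dtype=float)
        self.bn1.run_var = np.asarray(arrays["bn1_run_var"], dtype=float)
        self.bn2.run_mean = np.asarray(arrays["bn2_run_mean"], dtype=float)
        self.bn2.run_var = np.asarray(arrays["bn2_run_var"], dtype=float)


def smoothed_targets(y: np.ndarray, n_classes: int, p: float) -> np.ndarray:
    """Target distribution: p on the true class, (1-p)/(K-1) elsewhere."""
    t = np.full((y.size, n_classes), (1.0 - p) / (n_classes - 1))
    t[np.arange(y.size), y] = p
    return t


def cross_entropy(probs: np.ndarray, targets: np.ndarray) -> float:
    return float(-(targets * np.log(probs + 1e-12)).sum(axis=1).mean())


@dataclass
class TrainLog:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    lr: list = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1


def train_mlp(
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    spec: MLPSpec | None = None,
    seed: int = 0,
) -> tuple[MLPNet, TrainLog]:
    """Train under the full recipe; returns the best-validation-loss network."""
    spec = spec or MLPSpec()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    rng = np.random.default_rng(seed)
    net = MLPNet(X.shape[1], n_classes, spec, seed=seed)

    n = X.shape[0]
    n_val = max(1, int(round(n * spec.val_fraction)))
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, ytr, Xval, yval = X[tr_idx], y[tr_idx], X[val_idx], y[val_idx]
    Ttr = smoothed_targets(ytr, n_classes, spec.label_smoothing_p)
    Tval = smoothed_targets(yval, n_classes, spec.label_smoothing_p)

    params = [p for layer in net._layers for p in layer.params]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    n_batches = max(1, int(np.ceil(len(tr_idx) / spec.batch_size)))
    total_steps = spec.epochs * n_batches
    log = TrainLog()
    best_val, best_state, bad = np.inf, None, 0
    step = 0
    for epoch in range(spec.epochs):
        order = rng.permutation(len(tr_idx))
        ep_loss = 0.0
        for bi in range(n_batches):
            idx = order[bi * spec.batch_size : (bi + 1) * spec.batch_size]
            xb, tb = Xtr[idx], Ttr[idx]
            logits = net.forward(xb, training=True, rng=rng)
            probs = softmax(logits)
            loss = cross_entropy(probs, tb)
            ep_loss += loss * len(idx)
            net.backward((probs - tb) / len(idx))
            lr = one_cycle_lr(step, total_steps, spec.max_lr, spec.pct_start)
            step += 1
            grads = [g for layer in net._layers for g in layer.grads]
            t = step
            for k, (p, g) in enumerate(zip(params, grads)):
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                p -= lr * (m[k] / (1 - beta1**t)) / (np.sqrt(v[k] / (1 - beta2**t)) + eps)
        log.train_loss.append(ep_loss / len(tr_idx))
        log.lr.append(lr)

        val_probs = net.predict_proba(Xval)
        vloss = cross_entropy(val_probs, Tval)
        log.val_loss.append(vloss)
        if vloss < best_val - 1e-6:
            best_val, bad = vloss, 0
            best_state = {k: a.copy() for k, a in net.state_arrays().items()}
            log.best_epoch = epoch
        else:
            bad += 1
            if bad > spec.patience:
                log.stopped_epoch = epoch
                break
    if best_state is not None:
        net.load_state_arrays(best_state)
    return net, log
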