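"""Reference classifiers for the method-comparison harness.

The neural baselines are minimal conventional architectures (documented
repository choices): the 1-D CNN is two width-5 convolutions of 32 and 64
filters with ReLU, a stride-2 max pool between them, global average pooling
and a dense softmax layer; the LSTM-RNN is a single 64-unit recurrent layer
whose final hidden state feeds a dense softmax layer. Both train with the
same Adam settings and schedule as the transformer. SVM (C=1.0), random
forest and decision tree (max depth 10) come from scikit-learn and see the
flattened 125-band spectrum.
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .autodiff import Tensor, concat, conv1d, cross_entropy, max_pool1d, relu, sigmoid
from .training import Adam, TrainConfig

__all__ = ["CNN1DClassifier", "LSTMClassifier", "make_sklearn_baseline"]


def _he(rng, fan_in, shape):
    limit = np.sqrt(6.0 / fan_in)
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def _zeros(shape):
    return Tensor(np.zeros(shape), requires_grad=True)


class _NeuralBaseline:
    """Shared fit/predict loop for the autodiff-based baselines."""

    def fit(self, x: np.ndarray, labels: np.ndarray, cfg: TrainConfig | None = None):
        cfg = cfg or TrainConfig()
        y0 = np.asarray(labels) - 1
        rng = np.random.default_rng(cfg.seed)
        opt = Adam(self.parameters(), cfg.learning_rate, cfg.beta1, cfg.beta2,
                   cfg.epsilon)
        for _ in range(cfg.epochs):
            order = rng.permutation(len(y0))
            for start in range(0, len(y0), cfg.batch_size):
                sel = order[start : start + cfg.batch_size]
                loss = cross_entropy(self.forward(x[sel]), y0[sel])
                if not np.isfinite(loss.numpy()):
                    raise RuntimeError("non-finite baseline training loss")
                opt.zero_grad()
                loss.backward()
                opt.step()
        return self

    def predict(self, x: np.ndarray, batch_size: int = 500) -> np.ndarray:
        out = []
        for start in range(0, len(x), batch_size):
            logits = self.forward(x[start : start + batch_size]).numpy()
            out.append(np.argmax(logits, axis=-1) + 1)
        return np.concatenate(out)


class CNN1DClassifier(_NeuralBaseline):
    def __init__(self, num_classes: int = 7, num_vars: int = 1, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.w1 = _he(rng, 5 * num_vars, (5, num_vars, 32))
        self.b1 = _zeros(32)
        self.w2 = _he(rng, 5 * 32, (5, 32, 64))
        self.b2 = _zeros(64)
        self.w_out = _he(rng, 64, (64, num_classes))
        self.b_out = _zeros(num_classes)

    def forward(self, x) -> Tensor:
        h = relu(conv1d(Tensor(np.asarray(x)), self.w1, self.b1))
        h = max_pool1d(h, 2)
        h = relu(conv1d(h, self.w2, self.b2))
        pooled = h.mean(axis=1)  # global average pool over sequence steps
        return pooled @ self.w_out + self.b_out

    def parameters(self):
        return [self.w1, self.b1, self.w2, self.b2, self.w_out, self.b_out]


class LSTMClassifier(_NeuralBaseline):
    def __init__(self, num_classes: int = 7, num_vars: int = 1, units: int = 64,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.units = units
        self.w_x = _he(rng, num_vars, (num_vars, 4 * units))
        self.w_h = _he(rng, units, (units, 4 * units))
        self.b = _zeros(4 * units)
        self.w_out = _he(rng, units, (units, num_classes))
        self.b_out = _zeros(num_classes)

    def forward(self, x) -> Tensor:
        x = np.asarray(x)
        b, s, _ = x.shape
        u = self.units
        h = Tensor(np.zeros((b, u)))
        c = Tensor(np.zeros((b, u)))
        for t in range(s):
            z = Tensor(x[:, t, :]) @ self.w_x + h @ self.w_h + self.b
            i, f, g, o = (z[:, :u], z[:, u : 2 * u], z[:, 2 * u : 3 * u], z[:, 3 * u :])
            c = sigmoid(f) * c + sigmoid(i) * g.tanh()
            h = sigmoid(o) * c.tanh()
        return h @ self.w_out + self.b_out

    def parameters(self):
        return [self.w_x, self.w_h, self.b, self.w_out, self.b_out]


def make_sklearn_baseline(name: str, seed: int = 0):
    """SVM (C=1.0), RF or DT (max depth 10) on flattened spectra."""
    if name == "SVM":
        return SVC(C=1.0)
    if name == "RF":
        return RandomForestClassifier(max_depth=10, random_state=seed)
    if name == "DT":
        return DecisionTreeClassifier(max_depth=10, random_state=seed)
    raise ValueError(f"unknown sklearn baseline {name!r}")
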