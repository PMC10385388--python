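"""Training protocol: stratified repeated splitting, Adam optimization,
early stopping, and best-checkpoint selection.

Splits come from scikit-learn's StratifiedShuffleSplit, so every train/test
partition preserves the class proportions (within one sample per class).
Each repetition trains an independently initialized model; the checkpoint
kept is the epoch with the highest validation accuracy, ties broken by the
smaller validation loss. Validation here is the held-out test split of the
repetition (no third partition is drawn).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedShuffleSplit

from .autodiff import cross_entropy
from .dataset import SpectralDataset
from .model import MHCgT, ModelConfig, build_model

__all__ = [
    "TrainConfig",
    "SplitPlan",
    "TrainHistory",
    "stratified_shuffle_split",
    "train_model",
    "run_repeated",
    "select_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    """Adam optimizer and schedule settings (lr 1e-3, betas 0.9/0.98,
    epsilon 1e-9, batch 125, 20 epochs, early-stopping patience 10)."""

    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.98
    epsilon: float = 1e-9
    batch_size: int = 125
    epochs: int = 20
    early_stop_patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.epsilon <= 0:
            raise ValueError("learning_rate and epsilon must be positive")
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ValueError("betas must lie in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")


@dataclass
class SplitPlan:
    """Per-iteration stratified train/test index sets."""

    train_fraction: float
    n_iterations: int
    seed: int
    splits: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.splits)

    def __len__(self):
        return len(self.splits)


def stratified_shuffle_split(
    labels: np.ndarray,
    train_fraction: float,
    n_iterations: int = 10,
    seed: int = 0,
) -> SplitPlan:
    """Repeated stratified randomized train/test partitions.

    Each iteration holds ``round(train_fraction * N)`` training samples with
    per-class counts proportional to the global class frequencies (within
    one sample); deterministic given ``seed``.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be non-empty")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples to stratify")
    if int(np.floor(train_fraction * labels.size)) < counts.size:
        raise ValueError(
            f"train_fraction={train_fraction} leaves some class empty in train"
        )
    splitter = StratifiedShuffleSplit(
        n_splits=n_iterations, train_size=train_fraction, random_state=seed
    )
    splits = [
        (np.sort(tr), np.sort(te))
        for tr, te in splitter.split(np.zeros(labels.size), labels)
    ]
    return SplitPlan(train_fraction, n_iterations, seed, splits)


@dataclass
class TrainHistory:
    """Per-epoch metrics and the selected checkpoint epoch (0-based)."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


def select_checkpoint(val_acc: list[float], val_loss: list[float]) -> int:
    """Index of the epoch with maximal validation accuracy; among ties the
    one with the smallest validation loss (earliest on a further tie)."""
    best = 0
    for e in range(1, len(val_acc)):
        if val_acc[e] > val_acc[best] or (
            val_acc[e] == val_acc[best] and val_loss[e] < val_loss[best]
        ):
            best = e
    return best


class Adam:
    """Adam with bias correction (Table-2 settings by default)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.98, eps=1e-9):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def _evaluate(model: MHCgT, x: np.ndarray, y0: np.ndarray,
              batch_size: int = 500) -> tuple[float, float]:
    """Mean cross-entropy loss and accuracy (dropout inactive)."""
    losses, correct = [], 0
    for start in range(0, len(y0), batch_size):
        xb, yb = x[start : start + batch_size], y0[start : start + batch_size]
        logits = model.forward(xb, training=False)
        losses.append(cross_entropy(logits, yb).numpy() * len(yb))
        correct += int((np.argmax(logits.numpy(), axis=-1) == yb).sum())
    return float(np.sum(losses) / len(y0)), correct / len(y0)


def train_model(
    model: MHCgT,
    ds: SpectralDataset,
    split: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig | None = None,
    verbose: bool = False,
) -> tuple[MHCgT, TrainHistory]:
    """Optimize categorical cross-entropy with Adam; early-stop when
    validation accuracy fails to improve for ``early_stop_patience`` epochs;
    return the model restored to its best checkpoint."""
    cfg = cfg or TrainConfig()
    train_idx, val_idx = np.asarray(split[0]), np.asarray(split[1])
    if train_idx.size == 0:
        raise ValueError("empty training set")
    x_train, y_train = ds.data[train_idx], ds.labels[train_idx] - 1
    x_val, y_val = ds.data[val_idx], ds.labels[val_idx] - 1

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), cfg.learning_rate, cfg.beta1, cfg.beta2, cfg.epsilon)
    history = TrainHistory()
    best_state: dict | None = None
    best_acc, best_loss = -np.inf, np.inf
    since_improvement = 0

    for epoch in range(cfg.epochs):
        order = rng.permutation(train_idx.size)
        ep_loss, ep_correct = 0.0, 0
        for start in range(0, train_idx.size, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            xb, yb = x_train[sel], y_train[sel]
            logits = model.forward(xb, training=True, rng=rng)
            loss = cross_entropy(logits, yb)
            value = loss.numpy()
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch offset {start}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += float(value) * len(yb)
            ep_correct += int((np.argmax(logits.numpy(), axis=-1) == yb).sum())
        val_loss, val_acc = _evaluate(model, x_val, y_val) if val_idx.size else (
            ep_loss / train_idx.size, ep_correct / train_idx.size)

        history.train_loss.append(ep_loss / train_idx.size)
        history.train_acc.append(ep_correct / train_idx.size)
        history.val_loss.append(val_loss)
        history.val_acc.append(val_acc)
        if verbose:
            print(
                f"epoch {epoch + 1:3d}  loss {history.train_loss[-1]:.4f}  "
                f"acc {history.train_acc[-1]:.4f}  val_loss {val_loss:.4f}  "
                f"val_acc {val_acc:.4f}"
            )

        if val_acc > best_acc:
            since_improvement = 0
        else:
            since_improvement += 1
        if val_acc > best_acc or (val_acc == best_acc and val_loss < best_loss):
            best_acc, best_loss = val_acc, val_loss
            best_state = model.state_dict()
            history.best_epoch = epoch
        if since_improvement >= cfg.early_stop_patience:
            break

    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


def run_repeated(
    ds: SpectralDataset,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    split_plan: SplitPlan,
    verbose: bool = False,
):
    """One independently seeded model per split iteration.

    Returns (results, summary): results is a list of dicts with the fitted
    model, history and test metrics per iteration; summary holds the mean
    and SD of test accuracy and loss.
    """
    results = []
    for i, (train_idx, test_idx) in enumerate(split_plan):
        seed_i = train_cfg.seed + i
        model = build_model(model_cfg, seed=seed_i)
        cfg_i = replace(train_cfg, seed=seed_i)
        try:
            model, history = train_model(model, ds, (train_idx, test_idx), cfg_i,
                                         verbose=verbose)
        except Exception as err:
            raise RuntimeError(f"training failed at iteration {i}: {err}") from err
        test_loss, test_acc = _evaluate(model, ds.data[test_idx], ds.labels[test_idx] - 1)
        results.append(
            {
                "iteration": i,
                "model": model,
                "history": history,
                "test_loss": test_loss,
                "test_accuracy": test_acc,
            }
        )
    accs = np.array([r["test_accuracy"] for r in results])
    losses = np.array([r["test_loss"] for r in results])
    summary = {
        "mean_accuracy": float(accs.mean()),
        "sd_accuracy": float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
        "mean_loss": float(losses.mean()),
        "sd_loss": float(losses.std(ddof=1)) if len(losses) > 1 else 0.0,
    }
    return results, summary
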