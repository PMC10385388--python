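"""Accuracy, confusion matrices, per-phase reports, the training-fraction
ablation, and the method-comparison harness.

Accuracy is the proportion of exactly matched labels (micro-averaged over
the seven classes, i.e. trace(confusion)/N); per-class TP/TN/FP/FN are
exposed one-vs-rest from the confusion matrix. Tables report fractions in
[0, 1]; ``format_percent`` renders them as percentages with two decimals
for printed output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baselines import CNN1DClassifier, LSTMClassifier, make_sklearn_baseline
from .dataset import PHASES, SpectralDataset, phase_key
from .model import MHCgT, ModelConfig, build_model
from .training import (
    SplitPlan,
    TrainConfig,
    _evaluate,
    run_repeated,
    stratified_shuffle_split,
    train_model,
)

__all__ = [
    "accuracy",
    "ConfusionCounts",
    "confusion_matrix",
    "phase_accuracy_table",
    "per_phase_report",
    "EvaluationReport",
    "evaluate_model",
    "ablation_study",
    "compare_methods",
    "format_percent",
    "COMPARISON_METHODS",
]

COMPARISON_METHODS = ("MHCgT", "CNN-1D", "LSTM-RNN", "SVM", "RF", "DT")


def accuracy(y_true, y_pred) -> float:
    """Proportion of exact label matches, in [0, 1]."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("accuracy of an empty prediction set is undefined")
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: y_true has {y_true.shape}, y_pred has {y_pred.shape}"
        )
    return float(np.mean(y_true == y_pred))


@dataclass
class ConfusionCounts:
    """K×K confusion matrix; rows are actual classes, columns predictions.

    Classes are labelled 1..K. One-vs-rest TP/FP/FN/TN are derived views.
    """

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.matrix < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_classes(self) -> int:
        return self.matrix.shape[0]

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    @property
    def tp(self) -> np.ndarray:
        return np.diag(self.matrix)

    @property
    def fn(self) -> np.ndarray:
        return self.matrix.sum(axis=1) - self.tp

    @property
    def fp(self) -> np.ndarray:
        return self.matrix.sum(axis=0) - self.tp

    @property
    def tn(self) -> np.ndarray:
        return self.total - self.tp - self.fp - self.fn

    def accuracy(self) -> float:
        return float(self.tp.sum() / self.total)

    def to_frame(self, class_names=None) -> pd.DataFrame:
        names = list(class_names) if class_names else list(range(1, self.n_classes + 1))
        return pd.DataFrame(self.matrix, index=names, columns=names)


def confusion_matrix(y_true, y_pred, n_classes: int = 7) -> ConfusionCounts:
    """Count (actual r, predicted c) pairs; labels must lie in 1..n_classes."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 1 or y.max() > n_classes):
            raise ValueError(f"{name} contains labels outside 1..{n_classes}")
    m = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(m, (y_true - 1, y_pred - 1), 1)
    return ConfusionCounts(m)


def _predict_batched(model: MHCgT, x: np.ndarray, batch_size: int = 500) -> np.ndarray:
    out = []
    for start in range(0, len(x), batch_size):
        out.append(model.predict(x[start : start + batch_size]))
    return np.concatenate(out) if out else np.empty(0, dtype=np.int64)


def phase_accuracy_table(
    y_true, y_pred, years, months, class_names
) -> pd.DataFrame:
    """Per-(species, phase) accuracy table from explicit predictions.

    Rows: species (plus a final per-phase mean row); columns: the four
    phases plus an 'Average Accuracy' row-mean column. Cells with no
    evaluated samples are NaN (undefined), never zero.
    """
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    years, months = np.asarray(years), np.asarray(months)
    phase_cols = [phase_key(p) for p in PHASES]
    table = pd.DataFrame(index=list(class_names), columns=phase_cols, dtype=float)
    for s, name in enumerate(class_names, start=1):
        for (year, month), col in zip(PHASES, phase_cols):
            sel = (y_true == s) & (years == year) & (months == month)
            table.loc[name, col] = (
                accuracy(y_true[sel], y_pred[sel]) if sel.any() else np.nan
            )
    table["Average Accuracy"] = table[phase_cols].mean(axis=1)
    phase_means = table[phase_cols].mean(axis=0)
    table.loc["Phase mean"] = list(phase_means) + [np.nan]
    return table


def per_phase_report(
    model: MHCgT, ds: SpectralDataset, split: tuple[np.ndarray, np.ndarray]
) -> pd.DataFrame:
    """Per-class per-phase accuracy of ``model`` on the test indices."""
    test_idx = np.asarray(split[1])
    y_pred = _predict_batched(model, ds.data[test_idx])
    return phase_accuracy_table(
        ds.labels[test_idx], y_pred, ds.years[test_idx], ds.months[test_idx],
        ds.class_names,
    )


@dataclass
class EvaluationReport:
    """Bundle of everything the evaluation stage computes."""

    overall_accuracy: float
    confusion: ConfusionCounts
    per_phase_accuracy: pd.DataFrame
    phase_confusions: dict[str, ConfusionCounts] = field(default_factory=dict)
    ablation: pd.DataFrame | None = None
    comparison: pd.DataFrame | None = None


def evaluate_model(
    model: MHCgT, ds: SpectralDataset, split: tuple[np.ndarray, np.ndarray]
) -> EvaluationReport:
    """Overall accuracy, overall and per-phase confusion matrices, and the
    per-class per-phase accuracy table on the test split."""
    test_idx = np.asarray(split[1])
    y_true = ds.labels[test_idx]
    y_pred = _predict_batched(model, ds.data[test_idx])
    k = len(ds.class_names)
    phase_confusions = {}
    years, months = ds.years[test_idx], ds.months[test_idx]
    for year, month in PHASES:
        sel = (years == year) & (months == month)
        if sel.any():
            phase_confusions[phase_key((year, month))] = confusion_matrix(
                y_true[sel], y_pred[sel], k
            )
    return EvaluationReport(
        overall_accuracy=accuracy(y_true, y_pred),
        confusion=confusion_matrix(y_true, y_pred, k),
        per_phase_accuracy=phase_accuracy_table(
            y_true, y_pred, years, months, ds.class_names
        ),
        phase_confusions=phase_confusions,
    )


def ablation_study(
    ds: SpectralDataset,
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    fractions=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    reps: int = 5,
) -> pd.DataFrame:
    """Mean test loss/accuracy over ``reps`` runs per training fraction."""
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    rows = []
    for fraction in fractions:
        if not 0.0 < fraction < 1.0:
            raise ValueError(f"training fraction must lie in (0, 1), got {fraction}")
        plan = stratified_shuffle_split(ds.labels, fraction, reps, seed=train_cfg.seed)
        try:
            _, summary = run_repeated(ds, model_cfg, train_cfg, plan)
        except Exception as err:
            raise RuntimeError(
                f"ablation failed at training fraction {fraction}: {err}"
            ) from err
        tr, te = plan.splits[0]
        rows.append(
            {
                "fraction": fraction,
                "n_train": len(tr),
                "n_test": len(te),
                "mean_loss": summary["mean_loss"],
                "mean_accuracy": summary["mean_accuracy"],
                "sd_accuracy": summary["sd_accuracy"],
            }
        )
    return pd.DataFrame(rows)


def _run_method(
    name: str,
    ds: SpectralDataset,
    split: tuple[np.ndarray, np.ndarray],
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
) -> float:
    train_idx, test_idx = split
    x_flat = ds.data[:, :, 0]
    y = ds.labels
    if name == "MHCgT":
        model = build_model(model_cfg, seed=train_cfg.seed)
        model, _ = train_model(model, ds, split, train_cfg)
        y_pred = _predict_batched(model, ds.data[test_idx])
    elif name == "CNN-1D":
        clf = CNN1DClassifier(model_cfg.num_classes, model_cfg.num_vars,
                              seed=train_cfg.seed)
        clf.fit(ds.data[train_idx], y[train_idx], train_cfg)
        y_pred = clf.predict(ds.data[test_idx])
    elif name == "LSTM-RNN":
        clf = LSTMClassifier(model_cfg.num_classes, model_cfg.num_vars,
                             seed=train_cfg.seed)
        clf.fit(ds.data[train_idx], y[train_idx], train_cfg)
        y_pred = clf.predict(ds.data[test_idx])
    else:
        clf = make_sklearn_baseline(name, seed=train_cfg.seed)
        clf.fit(x_flat[train_idx], y[train_idx])
        y_pred = clf.predict(x_flat[test_idx])
    return accuracy(y[test_idx], y_pred)


def compare_methods(
    ds: SpectralDataset,
    split_plan: SplitPlan,
    methods=COMPARISON_METHODS,
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
) -> pd.DataFrame:
    """Mean accuracy per method over the split plan's iterations.

    Neural methods train with the shared schedule (20 epochs, batch 125);
    SVM uses C=1.0 and RF/DT max depth 10. Each iteration re-seeds every
    method with seed + iteration.
    """
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    unknown = [m for m in methods if m not in COMPARISON_METHODS]
    if unknown:
        raise ValueError(
            f"unknown method(s) {unknown}; valid names: {list(COMPARISON_METHODS)}"
        )
    rows = []
    from dataclasses import replace

    for name in methods:
        accs = []
        for i, split in enumerate(split_plan):
            # neural methods get an independent init per iteration; the
            # sklearn baselines are deterministic given the split, so they
            # keep the base seed (their spread comes from the splits alone)
            cfg_i = (
                replace(train_cfg, seed=train_cfg.seed + i)
                if name in ("MHCgT", "CNN-1D", "LSTM-RNN")
                else train_cfg
            )
            accs.append(_run_method(name, ds, split, model_cfg, cfg_i))
        accs = np.array(accs)
        rows.append(
            {
                "method": name,
                "mean_accuracy": float(accs.mean()),
                "sd_accuracy": float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
                "n_runs": len(accs),
            }
        )
    return pd.DataFrame(rows).set_index("method")


def format_percent(frame: pd.DataFrame) -> pd.DataFrame:
    """Render fractional accuracy columns as percentages with 2 decimals."""
    out = frame.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = (out[col] * 100).round(2)
    return out
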