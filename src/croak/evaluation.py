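"""Scoring, cross-validation, and the PCA-vs-no-PCA benchmark grid.

A single experiment cell is: split the swept feature dataset 70/30, z-score
features on training statistics, optionally reduce to K = 200 principal
components (fitted on the training partition only), train one named
classifier, and score the held-out rows.  The benchmark grid runs every
combination of feature method {LPC, MFCC} x model {dnn12..24, lstm200..700}
x PCA {off, on} — 32 cells forming 16 paired comparisons — and reports per
pair the accuracy difference ratio

    100 * (treated - baseline) / baseline   [percent, one decimal]

with PCA-off as baseline, plus the (informational, hardware-dependent)
training-period ratios.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import pca_reduce
from .classifiers import build_model
from .dataset import FeatureDataset, split
from .training import Stopwatch, TrainConfig, predict, train


def accuracy(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Fraction of exact matches."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.size == 0 or predictions.shape != labels.shape:
        raise ValueError("predictions and labels must be equal-length and non-empty")
    return float(np.mean(predictions == labels))


def confusion_matrix(
    predictions: np.ndarray, labels: np.ndarray, n_classes: int
) -> np.ndarray:
    """S x S count matrix, entry (i, j) = true class i+1 predicted j+1."""
    predictions = np.asarray(predictions, dtype=np.int64)
    labels = np.asarray(labels, dtype=np.int64)
    for name, a in (("predictions", predictions), ("labels", labels)):
        if np.any(a < 1) or np.any(a > n_classes):
            raise ValueError(f"{name} must lie in 1..{n_classes}")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (labels - 1, predictions - 1), 1)
    return cm


def difference_ratio(baseline: float, treated: float) -> float:
    """Percentage change 100*(treated-baseline)/baseline, one decimal."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return round(100.0 * (treated - baseline) / baseline, 1)


def epochs_to_reach(history: list[float], target: float) -> float:
    """First 1-based epoch whose loss is <= target; inf if never reached."""
    for k, loss in enumerate(history, start=1):
        if loss <= target:
            return float(k)
    return float("inf")


@dataclass
class EvalReport:
    """Outcome of one trained configuration."""

    accuracy: float
    confusion: np.ndarray
    training_period_s: float
    loss_history: list[float] = field(repr=False)
    config: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        cm = self.confusion
        if np.any(cm < 0):
            raise ValueError("confusion entries must be non-negative")
        total = cm.sum()
        if total and abs(self.accuracy - np.trace(cm) / total) > 1e-9:
            raise ValueError("accuracy inconsistent with confusion matrix")


@dataclass
class GridResult:
    """All cells of the benchmark grid plus the paired difference ratios."""

    cells: dict[tuple[str, str, str], EvalReport]  # (feature, model, pca on/off)
    accuracy_ratios: dict[tuple[str, str], float] = field(default_factory=dict)
    time_ratios: dict[tuple[str, str], float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (feat, model, pca), rep in self.cells.items():
            rows.append(
                {
                    "feature": feat,
                    "model": model,
                    "pca": pca,
                    "accuracy": rep.accuracy,
                    "training_period_s": rep.training_period_s,
                    "accuracy_difference_ratio": self.accuracy_ratios.get((feat, model)),
                    "training_period_difference_ratio": self.time_ratios.get((feat, model)),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# The single-cell experiment pipeline


class _Standardizer:
    """Per-feature z-scoring with statistics frozen on the training matrix."""

    def __init__(self, X: np.ndarray):
        self.mean = X.mean(axis=0)
        std = X.std(axis=0)
        self.std = np.where(std > 0, std, 1.0)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.std


def prepare_features(
    train_set: FeatureDataset,
    test_set: FeatureDataset,
    use_pca: bool,
    n_components: int = pca_reduce.DEFAULT_N_COMPONENTS,
    fit_on_all: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Z-score (train stats), optionally PCA-reduce, z-score the scores.

    PCA is fitted on the training partition only unless ``fit_on_all``
    deliberately replicates the permissive fit-before-split reading.
    """
    scaler = _Standardizer(train_set.matrix)
    x_train = scaler(train_set.matrix)
    x_test = scaler(test_set.matrix)
    if use_pca:
        fit_matrix = np.vstack([x_train, x_test]) if fit_on_all else x_train
        proj = pca_reduce.fit_pca(fit_matrix, n_components)
        x_train = pca_reduce.transform(proj, x_train)
        x_test = pca_reduce.transform(proj, x_test)
        # one global scale: per-component scaling would equalize the
        # eigen-spectrum and amplify the low-variance noise directions
        score_scale = x_train.std()
        if score_scale > 0:
            x_train = x_train / score_scale
            x_test = x_test / score_scale
    return x_train, x_test


def run_experiment(
    dataset: FeatureDataset,
    model_name: str,
    use_pca: bool,
    train_config: TrainConfig,
    n_components: int = pca_reduce.DEFAULT_N_COMPONENTS,
    test_fraction: float = 0.3,
    split_mode: str = "row_random",
    split_seed: int = 0,
    seq_len: int | None = None,
) -> EvalReport:
    """Split -> scale -> (PCA) -> train -> score one configuration."""
    train_set, test_set = split(dataset, test_fraction, seed=split_seed, mode=split_mode)
    x_train, x_test = prepare_features(train_set, test_set, use_pca, n_components)
    n_classes = dataset.n_species
    model = build_model(
        model_name, x_train.shape[1], output_dim=n_classes,
        seed=train_config.seed, seq_len=seq_len,
    )
    with Stopwatch() as sw:
        history = train(model, x_train, train_set.species_labels, train_config)
    preds = predict(model, x_test)
    cm = confusion_matrix(preds, test_set.species_labels, n_classes)
    return EvalReport(
        accuracy=accuracy(preds, test_set.species_labels),
        confusion=cm,
        training_period_s=sw.elapsed,
        loss_history=history,
        config={
            "model": model_name,
            "pca": use_pca,
            "n_components": n_components if use_pca else None,
            "feature": dataset.method,
            "epochs": train_config.epochs,
            "learning_rate": train_config.learning_rate,
            "batch_size": train_config.batch_size,
            "seed": train_config.seed,
            "split_mode": split_mode,
            "split_seed": split_seed,
        },
    )


def kfold_cv(
    dataset: FeatureDataset,
    model_name: str,
    use_pca: bool,
    train_config: TrainConfig,
    k: int = 5,
    n_components: int = pca_reduce.DEFAULT_N_COMPONENTS,
    seed: int = 0,
    seq_len: int | None = None,
) -> tuple[float, list[float]]:
    """Stratified k-fold cross-validation; returns (mean, per-fold scores).

    Per fold the scaler and (optional) PCA are re-fitted on the k-1 training
    folds, so no test information leaks through the transform.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(dataset.species_labels)
    lacking = np.flatnonzero((counts > 0) & (counts < k))
    if lacking.size:
        raise ValueError(f"classes with fewer than k={k} rows: {lacking.tolist()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores: list[float] = []
    n_classes = dataset.n_species
    for train_idx, test_idx in skf.split(dataset.matrix, dataset.species_labels):
        tr, te = dataset.subset(train_idx), dataset.subset(test_idx)
        x_train, x_test = prepare_features(tr, te, use_pca, n_components)
        model = build_model(
            model_name, x_train.shape[1], output_dim=n_classes,
            seed=train_config.seed, seq_len=seq_len,
        )
        train(model, x_train, tr.species_labels, train_config)
        scores.append(accuracy(predict(model, x_test), te.species_labels))
    return float(np.mean(scores)), scores


# ---------------------------------------------------------------------------
# Benchmark grid


@dataclass
class GridConfig:
    """What to run: features x models x PCA, under one TrainConfig."""

    feature_methods: tuple[str, ...] = ("LPC", "MFCC")
    model_names: tuple[str, ...] = (
        "dnn12", "dnn16", "dnn20", "dnn24", "lstm200", "lstm300", "lstm500", "lstm700",
    )
    train_config: TrainConfig = field(default_factory=TrainConfig)
    n_components: int = pca_reduce.DEFAULT_N_COMPONENTS
    test_fraction: float = 0.3
    split_mode: str = "row_random"
    split_seed: int = 0


def run_benchmark_grid(
    datasets: dict[str, FeatureDataset],
    grid_config: GridConfig,
    out_dir: str | Path | None = None,
) -> GridResult:
    """Evaluate every (feature, model, pca) cell; failures recorded, not fatal.

    ``datasets`` maps feature-method name to its built FeatureDataset.  When
    ``out_dir`` is given, each completed cell is check-pointed as JSON so an
    interrupted grid resumes without recomputing, and a table-shaped CSV is
    written at the end.
    """
    cells: dict[tuple[str, str, str], EvalReport] = {}
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for feat in grid_config.feature_methods:
        if feat not in datasets:
            raise ValueError(f"no dataset provided for feature method {feat!r}")
        for model_name in grid_config.model_names:
            for pca_flag in ("off", "on"):
                key = (feat, model_name, pca_flag)
                cache_file = (
                    out_dir / f"cell_{feat}_{model_name}_pca-{pca_flag}.json"
                    if out_dir is not None
                    else None
                )
                if cache_file is not None and cache_file.exists():
                    cells[key] = _cell_from_json(cache_file)
                    continue
                try:
                    rep = run_experiment(
                        datasets[feat],
                        model_name,
                        use_pca=(pca_flag == "on"),
                        train_config=grid_config.train_config,
                        n_components=grid_config.n_components,
                        test_fraction=grid_config.test_fraction,
                        split_mode=grid_config.split_mode,
                        split_seed=grid_config.split_seed,
                    )
                except Exception as exc:  # noqa: BLE001 - per-cell capture
                    rep = EvalReport(
                        accuracy=0.0,
                        confusion=np.zeros((0, 0), dtype=np.int64),
                        training_period_s=float("nan"),
                        loss_history=[],
                        config={"error": f"{type(exc).__name__}: {exc}"},
                    )
                cells[key] = rep
                if cache_file is not None and "error" not in rep.config:
                    _cell_to_json(rep, cache_file)
    result = GridResult(cells=cells)
    for feat in grid_config.feature_methods:
        for model_name in grid_config.model_names:
            base = cells[(feat, model_name, "off")]
            treat = cells[(feat, model_name, "on")]
            if base.accuracy > 0:
                result.accuracy_ratios[(feat, model_name)] = difference_ratio(
                    base.accuracy, treat.accuracy
                )
            if np.isfinite(base.training_period_s) and base.training_period_s > 0:
                result.time_ratios[(feat, model_name)] = difference_ratio(
                    base.training_period_s, treat.training_period_s
                )
    if out_dir is not None:
        result.to_frame().to_csv(out_dir / "grid_results.csv", index=False)
    return result


def _cell_to_json(rep: EvalReport, path: Path) -> None:
    path.write_text(
        json.dumps(
            {
                "accuracy": rep.accuracy,
                "confusion": rep.confusion.tolist(),
                "training_period_s": rep.training_period_s,
                "loss_history": rep.loss_history,
                "config": rep.config,
            }
        )
    )


def _cell_from_json(path: Path) -> EvalReport:
    d = json.loads(path.read_text())
    return EvalReport(
        accuracy=d["accuracy"],
        confusion=np.asarray(d["confusion"], dtype=np.int64),
        training_period_s=d["training_period_s"],
        loss_history=d["loss_history"],
        config=d["config"],
    )


def save_confusion_csv(cm: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(
        cm,
        index=[f"true_{i + 1}" for i in range(cm.shape[0])],
        columns=[f"pred_{j + 1}" for j in range(cm.shape[1])],
    ).to_csv(path)


__all__ = [
    "accuracy",
    "confusion_matrix",
    "difference_ratio",
    "epochs_to_reach",
    "EvalReport",
    "GridResult",
    "GridConfig",
    "prepare_features",
    "run_experiment",
    "kfold_cv",
    "run_benchmark_grid",
    "save_confusion_csv",
]
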