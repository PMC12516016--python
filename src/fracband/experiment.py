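"""End-to-end experiment driver: resize -> decompose -> train -> evaluate.

Each run writes a self-describing directory: the config copy, trained
head weights with their YAML sidecar, per-epoch history, metrics JSON,
ROC / PR curve points as CSV, curve plots as PNG and a log file.
Re-running a completed run with ``resume=True`` is a no-op.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path

import numpy as np

from fracband.evaluation import (
    aggregate_folds,
    compute_metrics,
    kfold_indices,
    roc_pr_curves,
    stratified_split,
)
from fracband.io import LabelledImageSet, RunConfig, load_dataset
from fracband.model import FractureClassifier

__all__ = ["crossval", "evaluate_run", "run_experiment"]

logger = logging.getLogger("fracband")


def _setup_logging(run_dir: Path, level: str) -> None:
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(run_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, level.upper(), logging.INFO))


def _write_curves(run_dir: Path, y_true: np.ndarray, y_prob: np.ndarray) -> None:
    fpr, tpr, auroc, precision, recall, auprc = roc_pr_curves(y_true, y_prob)
    with (run_dir / "roc_curve.csv").open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["fpr", "tpr"])
        writer.writerows(zip(fpr, tpr))
    with (run_dir / "pr_curve.csv").open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["recall", "precision"])
        writer.writerows(zip(recall, precision))
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
        ax1.plot(fpr, tpr)
        ax1.plot([0, 1], [0, 1], ls="--", c="grey")
        ax1.set(xlabel="FPR", ylabel="TPR", title=f"ROC (AUROC={auroc:.3f})")
        ax2.plot(recall, precision)
        ax2.set(xlabel="Recall", ylabel="Precision", title=f"PR (AUPRC={auprc:.3f})")
        fig.tight_layout()
        fig.savefig(run_dir / "curves.png", dpi=100)
        plt.close(fig)
    except Exception as exc:  # plotting is best-effort
        logger.warning("curve plotting failed: %s", exc)


def _train_and_score(config: RunConfig, images: np.ndarray, labels: np.ndarray,
                     idx_train: np.ndarray, idx_val: np.ndarray, idx_test: np.ndarray):
    model = FractureClassifier.create(
        branch_config=config.branch,
        train_config=config.train,
        decomposition=config.decomposition,
        seed=config.train.seed,
    )
    history = model.fit(images[idx_train], labels[idx_train],
                        images[idx_val], labels[idx_val])
    probs = model.predict_proba(images[idx_test])
    metrics = compute_metrics(labels[idx_test], probs)
    return model, history, probs, metrics


def run_experiment(config: RunConfig, dataset: LabelledImageSet | None = None,
                   resume: bool = False) -> Path:
    """Execute one full run; returns the run directory."""
    run_dir = Path(config.output_dir)
    if resume and (run_dir / "metrics.json").exists():
        logger.info("run %s already complete; resume is a no-op", run_dir)
        return run_dir
    _setup_logging(run_dir, config.log_level)
    config.save(run_dir / "config.yaml")

    try:
        if dataset is None:
            logger.info("loading dataset from %s", config.data_root)
            dataset = load_dataset(config.data_root)
        images, labels = dataset.images, dataset.labels

        logger.info("splitting %d images (seed %d)", len(labels), config.split.seed)
        idx_train, idx_val, idx_test = stratified_split(labels, config.split)

        logger.info("training (%s/%s, subbands %s, backbone %s)",
                    config.decomposition.method, config.decomposition.wavelet,
                    ",".join(config.train.subbands), config.branch.backbone_id)
        model, history, probs, metrics = _train_and_score(
            config, images, labels, idx_train, idx_val, idx_test)
    except Exception as exc:
        logger.error("run failed: %s", exc)
        raise RuntimeError(f"experiment stage failed in {run_dir}: {exc}") from exc

    model.save(run_dir)
    (run_dir / "history.json").write_text(json.dumps(history, indent=2))
    payload = {
        "seed": config.train.seed,
        "n_train": int(idx_train.size),
        "n_validation": int(idx_val.size),
        "n_test": int(idx_test.size),
        "test_metrics": metrics.as_dict(percent=True),
    }
    (run_dir / "metrics.json").write_text(json.dumps(payload, indent=2))
    _write_curves(run_dir, labels[idx_test], probs)
    logger.info("test accuracy %.4f", metrics.accuracy)
    return run_dir


def evaluate_run(run_dir: str | Path, split: str = "test",
                 dataset: LabelledImageSet | None = None) -> dict:
    """Re-evaluate a completed run on one partition of its dataset."""
    run_dir = Path(run_dir)
    config = RunConfig.load(run_dir / "config.yaml")
    model = FractureClassifier.load(run_dir)
    if dataset is None:
        dataset = load_dataset(config.data_root)
    idx_train, idx_val, idx_test = stratified_split(dataset.labels, config.split)
    idx = {"train": idx_train, "validation": idx_val, "test": idx_test}[split]
    probs = model.predict_proba(dataset.images[idx])
    metrics = compute_metrics(dataset.labels[idx], probs)
    return metrics.as_dict(percent=True)


def crossval(config: RunConfig, k: int = 5, dataset: LabelledImageSet | None = None,
             val_fraction: float = 0.1) -> dict:
    """Stratified k-fold cross-validation; each fold trains a fresh model
    on the remaining folds (with a small validation carve-out for early
    stopping) and is scored on the held-out fold.  Returns per-fold
    metrics and their mean / population standard deviation."""
    if dataset is None:
        dataset = load_dataset(config.data_root)
    images, labels = dataset.images, dataset.labels
    folds = kfold_indices(labels, k=k, seed=config.split.seed)
    per_fold = []
    for i, test_idx in enumerate(folds):
        rest = np.setdiff1d(np.arange(len(labels)), test_idx)
        rng = np.random.default_rng([config.split.seed, i])
        rest = rng.permutation(rest)
        n_val = max(1, int(round(val_fraction * rest.size)))
        idx_val, idx_train = rest[:n_val], rest[n_val:]
        _, _, _, metrics = _train_and_score(config, images, labels,
                                            idx_train, idx_val, test_idx)
        scores = metrics.as_dict(percent=True)
        per_fold.append({name: scores[name]
                         for name in ("accuracy", "precision", "recall", "f1", "kappa")})
        logger.info("fold %d/%d accuracy %.2f%%", i + 1, k, scores["accuracy"])
    summary = aggregate_folds(per_fold)
    return {"per_fold": summary.per_fold, "mean": summary.mean, "std": summary.std}
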