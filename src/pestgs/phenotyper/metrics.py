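"""Evaluation metrics and per-image scoring tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score

from pestgs.nn import Sequential


def classification_metrics(y_true, y_prob, threshold: float = 0.5) -> dict:
    """Accuracy, F1 and the confusion matrix at the given probability cut."""
    y_true = np.asarray(y_true).ravel().astype(int)
    y_prob = np.asarray(y_prob).ravel()
    if len(y_true) == 0:
        raise ValueError("empty evaluation set")
    y_pred = (y_prob >= threshold).astype(int)
    cm = confusion_matrix(y_true, y_pred, labels=[0, 1])
    return {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "f1": float(f1_score(y_true, y_pred, zero_division=0)),
        "confusion": cm,
    }


def regression_metrics(y_true, y_pred) -> dict:
    """MSE, MAE, Pearson r, and R^2 (the squared correlation of the pairing)."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if len(y_true) < 3:
        raise ValueError("need at least 3 labelled points")
    if np.std(y_pred) == 0 or np.std(y_true) == 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    r = float(stats.pearsonr(y_pred, y_true).statistic)
    return {
        "mse": float(np.mean((y_pred - y_true) ** 2)),
        "mae": float(np.mean(np.abs(y_pred - y_true))),
        "pearson_r": r,
        "r2": r * r,
    }


def evaluate_classifier(net: Sequential, X: np.ndarray, y: np.ndarray) -> dict:
    return classification_metrics(y, net.predict(np.asarray(X, dtype=np.float32)))


def evaluate_regressor(net: Sequential, X: np.ndarray, y: np.ndarray) -> dict:
    return regression_metrics(y, net.predict(np.asarray(X, dtype=np.float32)))


def score_images(
    net: Sequential,
    images: np.ndarray,
    image_ids,
    accession_ids,
    task: str = "pds",
) -> pd.DataFrame:
    """Score a stack of preprocessed images into a per-image table."""
    if task not in ("pds", "binary"):
        raise ValueError("task must be 'pds' or 'binary'")
    scores = net.predict(np.asarray(images, dtype=np.float32)).ravel()
    col = "pds_score" if task == "pds" else "prob_severe"
    return pd.DataFrame(
        {"image_id": list(image_ids), "accession_id": list(accession_ids), col: scores}
    )
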