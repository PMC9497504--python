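"""Confusion-count evaluation metrics for imbalanced binary tasks.

Plain accuracy rewards a classifier that always predicts the majority class
(a ``rho : 1 - rho`` test set gives it accuracy ``rho``).  Unweighted
accuracy (UWA, the mean of per-class recalls, also known as balanced
accuracy) scores that same predictor 0.5 regardless of imbalance, which is
why both are reported side by side throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "accuracy",
    "unweighted_accuracy",
    "results_row",
    "RESULTS_COLUMNS",
]

#: flat schema for result tables written by sweeps and the CLI
RESULTS_COLUMNS = [
    "scenario",
    "loss",
    "eta",
    "gamma",
    "run",
    "accuracy",
    "uwa",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN tallies for a binary test set (class 1 = positive)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
            object.__setattr__(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(predictions, truths) -> ConfusionCounts:
    """Tally TP/TN/FP/FN from two equal-length binary vectors."""
    pred = np.asarray(predictions)
    true = np.asarray(truths)
    if pred.shape != true.shape or pred.ndim != 1:
        raise ValueError("predictions and truths must be equal-length 1-d vectors")
    if not (np.isin(pred, (0, 1)).all() and np.isin(true, (0, 1)).all()):
        raise ValueError("entries must be binary (0/1)")
    pred = pred.astype(int)
    true = true.astype(int)
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (true == 1))),
        tn=int(np.sum((pred == 0) & (true == 0))),
        fp=int(np.sum((pred == 1) & (true == 0))),
        fn=int(np.sum((pred == 0) & (true == 1))),
    )


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if c.total == 0:
        raise ValueError("accuracy is undefined on an empty test set")
    return (c.tp + c.tn) / c.total


def unweighted_accuracy(c: ConfusionCounts) -> float:
    """Mean of the two per-class recalls: (TP/(TP+FN) + TN/(TN+FP)) / 2.

    Raises
    ------
    ValueError
        If either class is absent from the ground truth; the mean of
        per-class recalls is undefined then, and dropping the missing term
        silently would mask evaluation bugs.
    """
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ValueError(
            "unweighted accuracy is undefined when a class is absent from "
            f"the ground truth (positives={c.tp + c.fn}, negatives={c.tn + c.fp})"
        )
    return 0.5 * (c.tp / (c.tp + c.fn) + c.tn / (c.tn + c.fp))


def results_row(
    scenario: str, loss: str, eta: float, gamma: float, run: int, c: ConfusionCounts
) -> pd.Series:
    """One row of the flat results schema (metrics as fractions)."""
    return pd.Series(
        {
            "scenario": scenario,
            "loss": loss,
            "eta": eta,
            "gamma": gamma,
            "run": run,
            "accuracy": accuracy(c),
            "uwa": unweighted_accuracy(c),
        }
    )
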