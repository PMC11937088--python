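"""Regression evaluation statistics for the three trait tasks.

RMSE is the root of the mean squared residual.  NRMSE normalizes RMSE by
the mean of the actual values of the split it is computed on; by
convention the same statistic is called NRMSE on the training split and
NRMSEP (NRMSE of prediction) on the test split.  R-squared is
1 - RSS/TSS about the mean of the actuals.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

TRAIT_NAMES = ("weight", "uniformity", "count")


def _check(y, y_hat):
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.size == 0:
        raise ValueError("empty input")
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    return y, y_hat


def rmse(y, y_hat) -> float:
    y, y_hat = _check(y, y_hat)
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def nrmse(y, y_hat) -> float:
    """RMSE divided by the mean of the actual values of this split."""
    y, y_hat = _check(y, y_hat)
    mean = y.mean()
    if mean == 0:
        raise ValueError("NRMSE undefined: actual values have zero mean")
    return rmse(y, y_hat) / mean


def r_squared(y, y_hat) -> float:
    y, y_hat = _check(y, y_hat)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValueError("R^2 undefined: actual values are constant")
    rss = float(np.sum((y - y_hat) ** 2))
    return 1.0 - rss / tss


@dataclasses.dataclass
class MetricsReport:
    """Per-trait {rmse, nrmse|nrmsep, r_squared} on one split."""

    per_trait: dict  # trait -> {"rmse": .., "nrmse"/"nrmsep": .., "r_squared": ..}
    split_tag: str
    n: int

    @property
    def norm_field(self) -> str:
        return "nrmsep" if self.split_tag == "test" else "nrmse"

    def mean_r_squared(self) -> float:
        return float(np.mean([m["r_squared"] for m in self.per_trait.values()]))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"trait": t, "metric": metric, "split": self.split_tag, "value": v}
            for t, metrics in self.per_trait.items()
            for metric, v in metrics.items()
        ]
        return pd.DataFrame(rows)

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(
                {"split": self.split_tag, "n": self.n, "per_trait": self.per_trait},
                indent=2))
        else:
            self.to_frame().to_csv(path, index=False)


def metrics_report(predictions: np.ndarray, labels: np.ndarray,
                   split_tag: str, round_counts: bool = False) -> MetricsReport:
    """Per-trait report on (n, 3) prediction/label arrays ordered
    (weight, uniformity, count); computed on the original label scale.

    Count metrics use the raw regression output unless ``round_counts``
    (rounding is otherwise only a reporting convention).
    """
    predictions = np.asarray(predictions, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if predictions.shape != labels.shape or predictions.ndim != 2 or predictions.shape[1] != 3:
        raise ValueError("predictions and labels must both be (n, 3) arrays")
    norm_name = "nrmsep" if split_tag == "test" else "nrmse"
    per_trait = {}
    for j, trait in enumerate(TRAIT_NAMES):
        y, y_hat = labels[:, j], predictions[:, j]
        if trait == "count" and round_counts:
            y_hat = np.clip(np.round(y_hat), 0, None)
        per_trait[trait] = {
            "rmse": rmse(y, y_hat),
            norm_name: nrmse(y, y_hat),
            "r_squared": r_squared(y, y_hat),
        }
    return MetricsReport(per_trait=per_trait, split_tag=split_tag, n=labels.shape[0])
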