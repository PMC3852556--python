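"""Confusion counting and the four classification performance measures."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import DataError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN tallies for a two-class problem (positive = +1)."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise DataError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP,
            self.TN + other.TN,
            self.FP + other.FP,
            self.FN + other.FN,
        )


def confusion_counts(
    true_labels: np.ndarray, predicted_labels: np.ndarray
) -> ConfusionCounts:
    """Tally a 2x2 confusion table for labels over {-1, +1}."""
    t = np.asarray(true_labels).ravel()
    p = np.asarray(predicted_labels).ravel()
    if t.shape != p.shape:
        raise DataError(
            f"label vectors differ in length: {t.shape[0]} vs {p.shape[0]}"
        )
    for name, v in (("true", t), ("predicted", p)):
        if not np.all(np.isin(v, (-1, 1))):
            raise DataError(f"{name} labels must be -1 or +1")
    return ConfusionCounts(
        TP=int(np.sum((t == 1) & (p == 1))),
        TN=int(np.sum((t == -1) & (p == -1))),
        FP=int(np.sum((t == -1) & (p == 1))),
        FN=int(np.sum((t == 1) & (p == -1))),
    )


def classification_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, accuracy and Matthews correlation.

    * ``Sn = TP / (TP + FN)`` and ``Sp = TN / (TN + FP)``; an empty
      class yields NaN with a logged warning.
    * ``ACC = (TP + TN) / n``.
    * ``MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FN)(TN+FP))``,
      with MCC = 0 whenever a denominator factor is zero.
    """
    if c.total == 0:
        raise DataError("cannot compute metrics from all-zero counts")
    if c.TP + c.FN == 0:
        logger.warning("no positive samples: sensitivity undefined (NaN)")
        sn = math.nan
    else:
        sn = c.TP / (c.TP + c.FN)
    if c.TN + c.FP == 0:
        logger.warning("no negative samples: specificity undefined (NaN)")
        sp = math.nan
    else:
        sp = c.TN / (c.TN + c.FP)
    acc = (c.TP + c.TN) / c.total
    denom = (
        (c.TP + c.FN) * (c.TP + c.FP) * (c.TN + c.FN) * (c.TN + c.FP)
    )
    if denom == 0:
        mcc = 0.0
    else:
        mcc = (c.TP * c.TN - c.FP * c.FN) / math.sqrt(denom)
    return {"Sn": sn, "Sp": sp, "ACC": acc, "MCC": mcc}
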