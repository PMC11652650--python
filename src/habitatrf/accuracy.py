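"""Thematic accuracy of classified maps: confusion matrix, overall /
producer's / user's accuracy and Cohen's Kappa.

Conventions follow the remote-sensing accuracy-assessment equations as
used here: rows of the confusion matrix are *reference* classes and
columns are *predicted* classes; producer's accuracy divides the
diagonal by the **row** total and user's accuracy by the **column**
total. (This is flipped relative to the common Congalton layout, where
rows are the classification; ``orientation="columns_reference"`` swaps
to that convention.) Kappa is

    K = (N·Σ x_ii − Σ x_i+·x_+i) / (N² − Σ x_i+·x_+i)

with x_i+ / x_+i the row/column marginals and N the pixel total, and is
bucketed as strong (> 0.80), moderate (0.40–0.80) or poor (< 0.40)
agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "confusion",
    "overall_accuracy",
    "producer_accuracy",
    "user_accuracy",
    "kappa",
    "agreement_category",
    "AccuracyReport",
    "assess",
]


@dataclass
class ConfusionMatrix:
    """r x r count matrix; rows = reference classes, columns = predicted."""

    counts: np.ndarray
    classes: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("counts must be >= 0")
        if len(self.classes) != self.counts.shape[0]:
            raise ValueError("class list length must match matrix size")

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:  # x_{i+}: reference marginals
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:  # x_{+i}: predicted marginals
        return self.counts.sum(axis=0)

    @property
    def diagonal(self) -> np.ndarray:  # x_{ii}
        return np.diag(self.counts)


def confusion(pred, ref, classes: list | None = None) -> ConfusionMatrix:
    """Tally ``counts[reference class, predicted class]``."""
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    if pred.shape != ref.shape:
        raise ValueError(f"length mismatch: {pred.shape} predicted vs {ref.shape} reference")
    if classes is None:
        classes = sorted(set(np.unique(pred)) | set(np.unique(ref)))
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for r, p in zip(ref.ravel(), pred.ravel()):
        counts[index[r], index[p]] += 1
    return ConfusionMatrix(counts, list(classes))


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Correctly classified pixels / total reference pixels, in percent."""
    if cm.N == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * cm.diagonal.sum() / cm.N


def _per_class(cm: ConfusionMatrix, marginals: np.ndarray) -> dict:
    out = {}
    for cls, diag, tot in zip(cm.classes, cm.diagonal, marginals):
        out[cls] = 100.0 * diag / tot if tot > 0 else None  # undefined, not 0
    return out


def producer_accuracy(cm: ConfusionMatrix, orientation: str = "rows_reference") -> dict:
    """Per-class correct / reference total; None where the class is unobserved."""
    marg = cm.row_totals if orientation == "rows_reference" else cm.col_totals
    return _per_class(cm, marg)


def user_accuracy(cm: ConfusionMatrix, orientation: str = "rows_reference") -> dict:
    """Per-class correct / predicted total; None where never predicted."""
    marg = cm.col_totals if orientation == "rows_reference" else cm.row_totals
    return _per_class(cm, marg)


def kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement; raises on the degenerate single-class case."""
    if cm.N == 0:
        raise ValueError("empty confusion matrix")
    N = float(cm.N)
    chance = float(np.dot(cm.row_totals.astype(float), cm.col_totals.astype(float)))
    denom = N * N - chance
    if denom == 0:
        raise ValueError("kappa undefined: N^2 equals the chance-agreement term")
    return (N * float(cm.diagonal.sum()) - chance) / denom


def agreement_category(k: float) -> str:
    """strong (> 0.80), moderate (0.40–0.80 inclusive) or poor (< 0.40)."""
    if not np.isfinite(k):
        raise ValueError("kappa must be a finite number")
    if k > 0.80:
        return "strong"
    if k >= 0.40:
        return "moderate"
    return "poor"


@dataclass
class AccuracyReport:
    """Bundled accuracy metrics for one classified map."""

    cm: ConfusionMatrix
    overall_pct: float = field(init=False)
    producer_pct: dict = field(init=False)
    user_pct: dict = field(init=False)
    kappa: float = field(init=False)
    agreement: str = field(init=False)

    def __post_init__(self) -> None:
        self.overall_pct = overall_accuracy(self.cm)
        self.producer_pct = producer_accuracy(self.cm)
        self.user_pct = user_accuracy(self.cm)
        self.kappa = kappa(self.cm)
        self.agreement = agreement_category(self.kappa)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "class": cls,
                "producer_pct": self.producer_pct[cls],
                "user_pct": self.user_pct[cls],
            }
            for cls in self.cm.classes
        ]
        df = pd.DataFrame(rows)
        df["overall_pct"] = self.overall_pct
        df["kappa"] = self.kappa
        df["agreement"] = self.agreement
        return df


def assess(pred, ref, classes: list | None = None) -> AccuracyReport:
    """One-call accuracy assessment from paired label sequences or rasters.

    Accepts two equal-length label sequences, or two
    :class:`~habitatrf.raster.RasterGrid` maps compared cellwise over
    their shared valid cells.
    """
    from .raster import RasterGrid

    if isinstance(pred, RasterGrid) and isinstance(ref, RasterGrid):
        if pred.geometry != ref.geometry:
            raise ValueError("rasters must share one grid for cellwise comparison")
        both = pred.valid_mask & ref.valid_mask
        pred, ref = pred.values[both], ref.values[both]
    return AccuracyReport(confusion(pred, ref, classes))
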