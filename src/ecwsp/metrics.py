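"""Recognition-accuracy metrics and the composite model-selection indicator.

Per class ``i`` with ``M_i`` evaluated spectra of which ``M~_i`` were
correctly identified, the recognition accuracy rate is
``RAR_i = 100 * M~_i / M_i`` (percent); across classes,
``RAR_Total = 100 * sum(M~_i) / sum(M_i)`` — identically the
class-size-weighted mean of the ``RAR_i``. ``RAR_SD`` is the sample
standard deviation (denominator K-1) of the per-class rates and measures
how evenly the classifier treats the classes. Wavelength models are ranked
by the composite indicator ``RAR_Total - RAR_SD`` so that a model must be
both accurate and balanced to win. All values are held at full precision;
rounding to one decimal happens only in display/report helpers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import MetricError


@dataclass
class EvaluationResult:
    """Per-class and overall recognition accuracy for one wavelength model."""

    class_ids: np.ndarray
    class_sizes: np.ndarray  # M_i
    correct_counts: np.ndarray  # M~_i
    eval_set: str | None = None

    def __post_init__(self) -> None:
        self.class_ids = np.asarray(self.class_ids)
        self.class_sizes = np.asarray(self.class_sizes, dtype=int)
        self.correct_counts = np.asarray(self.correct_counts, dtype=int)
        if self.class_sizes.shape != self.correct_counts.shape:
            raise MetricError("class_sizes and correct_counts shapes differ")
        if np.any(self.class_sizes <= 0):
            k = self.class_ids[int(np.argmax(self.class_sizes <= 0))]
            raise MetricError(f"class {k} has no evaluated spectra")
        if np.any((self.correct_counts < 0) | (self.correct_counts > self.class_sizes)):
            raise MetricError("correct counts outside [0, class size]")

    # ------------------------------------------------------------- quantities
    @property
    def rar_per_class(self) -> np.ndarray:
        """RAR_i in percent."""
        return 100.0 * self.correct_counts / self.class_sizes

    @property
    def rar_total(self) -> float:
        """RAR_Total in percent (weighted identity over the class counts)."""
        return float(100.0 * self.correct_counts.sum() / self.class_sizes.sum())

    @property
    def rar_sd(self) -> float:
        """Sample standard deviation (ddof=1) of the per-class RARs, percent."""
        if len(self.class_sizes) < 2:
            return 0.0
        return float(np.std(self.rar_per_class, ddof=1))

    @property
    def composite(self) -> float:
        """RAR_Total - RAR_SD in percentage points, on unrounded values."""
        return self.rar_total - self.rar_sd

    # ---------------------------------------------------------------- display
    def rounded(self, decimals: int = 1) -> dict:
        """One-decimal display row (internal comparisons never use this)."""
        return {
            **{
                f"RAR_{k}": round(float(r), decimals)
                for k, r in zip(self.class_ids, self.rar_per_class)
            },
            "RAR_Total": round(self.rar_total, decimals),
            "RAR_SD": round(self.rar_sd, decimals),
        }


def evaluate(
    true_labels: Sequence[int],
    predicted_labels: Sequence[int],
    class_order: Sequence[int] | None = None,
    eval_set: str | None = None,
) -> EvaluationResult:
    """Score a prediction against truth; every true label must be in class_order."""
    y = np.asarray(true_labels)
    yhat = np.asarray(predicted_labels)
    if y.shape != yhat.shape:
        raise MetricError("label vectors differ in length")
    ks = np.unique(y) if class_order is None else np.asarray(class_order)
    sizes = np.array([(y == k).sum() for k in ks])
    if np.any(sizes == 0):
        k = ks[int(np.argmax(sizes == 0))]
        raise MetricError(f"class {k} has no spectra in the evaluated set")
    unknown = set(np.unique(y)) - set(ks.tolist())
    if unknown:
        raise MetricError(f"true label(s) {sorted(unknown)} missing from class_order")
    correct = np.array([((y == k) & (yhat == k)).sum() for k in ks])
    return EvaluationResult(ks, sizes, correct, eval_set=eval_set)


def from_counts(
    correct_counts: Sequence[int],
    class_sizes: Sequence[int],
    class_ids: Sequence[int] | None = None,
    eval_set: str | None = None,
) -> EvaluationResult:
    """Build a result directly from per-class counts (e.g. published tables)."""
    n = len(class_sizes)
    ks = np.arange(1, n + 1) if class_ids is None else np.asarray(class_ids)
    return EvaluationResult(ks, np.asarray(class_sizes), np.asarray(correct_counts), eval_set)


def composite_score(result: EvaluationResult) -> float:
    """The model-selection indicator RAR_Total - RAR_SD (unrounded)."""
    return result.composite


def result_row(result: EvaluationResult, method: str, **model_fields) -> dict:
    """A report-table row: method, model parameters, then one-decimal RARs."""
    row = {"method": method}
    row.update(model_fields)
    row.update(result.rounded())
    row["composite"] = round(result.composite, 3)
    return row
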