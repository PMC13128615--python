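"""Grade bands and grading-experiment bookkeeping.

Seedlings are graded by cumulative internode length L (mm):

    Grade I   : 100 <= L <= 130
    Grade II  : 130 <  L <= 150
    OUT       : anything else (too short or too leggy)

The bands are non-equidistant by design (agronomic, not statistical) and
partition the positive axis; boundary lengths belong to the lower band
(130 mm is Grade I, 150 mm is Grade II).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GRADES = ("I", "II", "OUT")


@dataclass(frozen=True)
class GradeBands:
    """Closed/half-open interval bounds of the two marketable grades."""

    grade_i: tuple[float, float] = (100.0, 130.0)   # closed [lo, hi]
    grade_ii_hi: float = 150.0                       # (grade_i[1], hi]

    def __post_init__(self) -> None:
        lo, hi = self.grade_i
        if not (0 < lo < hi < self.grade_ii_hi):
            raise ValueError(
                f"bands must satisfy 0 < {lo} < {hi} < {self.grade_ii_hi}"
            )


def grade(length_mm: float, bands: GradeBands | None = None) -> str:
    """Assign a grade to one measured length (mm). Negative lengths are invalid."""
    if length_mm < 0:
        raise ValueError(f"length must be non-negative, got {length_mm}")
    bands = bands or GradeBands()
    lo, hi = bands.grade_i
    if lo <= length_mm <= hi:
        return "I"
    if hi < length_mm <= bands.grade_ii_hi:
        return "II"
    return "OUT"


def out_side(length_mm: float, bands: GradeBands | None = None) -> str | None:
    """For an OUT length, which side it fell on: 'short' or 'long'; else None."""
    bands = bands or GradeBands()
    if length_mm < bands.grade_i[0]:
        return "short"
    if length_mm > bands.grade_ii_hi:
        return "long"
    return None


@dataclass(frozen=True)
class GradingReport:
    """Confusion matrix and error summary of a grading experiment.

    ``confusion[i, j]`` counts seedlings of true grade ``GRADES[i]``
    predicted as ``GRADES[j]``. ``mean_success`` is the count-weighted mean
    (total diagonal / total count); the unweighted across-grade mean is
    also kept since both are meaningful summaries.
    """

    confusion: np.ndarray
    per_grade_success: dict[str, float]
    mean_success: float
    mean_success_unweighted: float
    mean_abs_error_mm: float
    per_grade_abs_error_mm: dict[str, float]
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "confusion": self.confusion.tolist(),
            "grades": list(GRADES),
            "per_grade_success": self.per_grade_success,
            "mean_success": self.mean_success,
            "mean_success_unweighted": self.mean_success_unweighted,
            "mean_abs_error_mm": self.mean_abs_error_mm,
            "per_grade_abs_error_mm": self.per_grade_abs_error_mm,
        }


def evaluate_batch(true_lengths_mm, pred_lengths_mm, true_grades=None,
                   bands: GradeBands | None = None) -> GradingReport:
    """Score predicted lengths against ground truth.

    ``true_grades`` defaults to grading the true lengths; pass explicit
    grades when truth was labeled independently of the bands. Inputs are
    aligned by position and must have equal length.
    """
    bands = bands or GradeBands()
    true_lengths = np.asarray(true_lengths_mm, dtype=float)
    pred_lengths = np.asarray(pred_lengths_mm, dtype=float)
    if true_lengths.shape != pred_lengths.shape or true_lengths.ndim != 1:
        raise ValueError(
            f"truth and prediction must be equal-length 1-D sequences, got "
            f"{true_lengths.shape} vs {pred_lengths.shape}"
        )
    if true_grades is None:
        true_grades = [grade(v, bands) for v in true_lengths]
    elif len(true_grades) != len(true_lengths):
        raise ValueError("true_grades misaligned with true_lengths")
    pred_grades = [grade(v, bands) for v in pred_lengths]

    idx = {g: i for i, g in enumerate(GRADES)}
    confusion = np.zeros((3, 3), dtype=int)
    for tg, pg in zip(true_grades, pred_grades):
        confusion[idx[tg], idx[pg]] += 1

    row_sums = confusion.sum(axis=1)
    per_grade_success = {
        g: float(confusion[i, i] / row_sums[i]) if row_sums[i] else float("nan")
        for i, g in enumerate(GRADES)
    }
    present = row_sums > 0
    diag = np.diag(confusion)
    mean_success = float(diag.sum() / row_sums.sum()) if row_sums.sum() else float("nan")
    rates = diag[present] / row_sums[present]
    mean_unweighted = float(rates.mean()) if present.any() else float("nan")

    abs_err = np.abs(pred_lengths - true_lengths)
    per_grade_err = {}
    tg_arr = np.asarray(true_grades)
    for g in GRADES:
        sel = tg_arr == g
        per_grade_err[g] = float(abs_err[sel].mean()) if sel.any() else float("nan")

    return GradingReport(
        confusion=confusion,
        per_grade_success=per_grade_success,
        mean_success=mean_success,
        mean_success_unweighted=mean_unweighted,
        mean_abs_error_mm=float(abs_err.mean()) if len(abs_err) else float("nan"),
        per_grade_abs_error_mm=per_grade_err,
        n=len(true_lengths),
    )
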