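"""One-vs-rest confusion counts and classifier performance metrics.

Each class of a scheme is evaluated against all others as a 2x2 table
(TP/TN/FP/FN), from which sensitivity (recall), specificity, PPV (precision),
NPV, accuracy, Cohen's kappa, and F1 are computed.  Per-class kappa is the
Cohen's kappa of the 2x2 one-vs-rest table:

    kappa = (p_o - p_e) / (1 - p_e),
    p_o = (TP + TN) / N,
    p_e = [(TP+FP)(TP+FN) + (TN+FN)(TN+FP)] / N^2.

Scheme-level performance is the macro-averaged F1 (arithmetic mean of the
unrounded per-class F1 scores) plus, on the numeric encoding of the classes
(">=8" encoded as 8), the mean squared and mean absolute prediction errors.

Conventions for degenerate tables: PPV = 0 when no positive predictions,
F1 = 0 when PPV + sensitivity = 0 (hence F1 = 0 whenever TP = 0), and
kappa = 0 when expected agreement is exactly 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .scale import (
    ClassValue,
    Scheme,
    impute_pedss_floor,
    numeric_encode,
    scheme_labels,
    to_class,
)

__all__ = [
    "ConfusionCounts",
    "ClassMetrics",
    "EvaluationReport",
    "one_vs_rest_counts",
    "class_metrics",
    "macro_f1",
    "error_summary",
    "evaluate",
    "evaluate_labels",
    "bootstrap_kappa_ci",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.n == 0:
            raise ValueError("confusion table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ClassMetrics:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    kappa: float
    f1: float

    def rounded(self, ndigits: int = 2) -> "ClassMetrics":
        """Display rounding matching 2-dp report tables; metrics themselves
        are always carried unrounded."""
        return ClassMetrics(
            *(round(getattr(self, f), ndigits) for f in self.__dataclass_fields__)
        )


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def one_vs_rest_counts(
    truth: Sequence, pred: Sequence, target
) -> ConfusionCounts:
    """2x2 confusion counts treating ``target`` as the positive class."""
    if len(truth) != len(pred):
        raise ValueError(
            f"truth and prediction lengths differ: {len(truth)} vs {len(pred)}"
        )
    if not truth:
        raise ValueError("need at least one paired observation")
    tp = fn = fp = tn = 0
    for t, p in zip(truth, pred):
        if t == target:
            if p == target:
                tp += 1
            else:
                fn += 1
        elif p == target:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp, tn, fp, fn)


def class_metrics(c: ConfusionCounts) -> ClassMetrics:
    """All per-class metrics from a 2x2 one-vs-rest table."""
    n = c.n
    sensitivity = _safe_div(c.tp, c.tp + c.fn)
    specificity = _safe_div(c.tn, c.fp + c.tn)
    ppv = _safe_div(c.tp, c.tp + c.fp)
    npv = _safe_div(c.tn, c.fn + c.tn)
    accuracy = (c.tp + c.tn) / n
    p_o = accuracy
    p_e = ((c.tp + c.fp) * (c.tp + c.fn) + (c.tn + c.fn) * (c.tn + c.fp)) / n**2
    kappa = 0.0 if math.isclose(p_e, 1.0) else (p_o - p_e) / (1 - p_e)
    f1 = _safe_div(2 * ppv * sensitivity, ppv + sensitivity)
    return ClassMetrics(sensitivity, specificity, ppv, npv, accuracy, kappa, f1)


def macro_f1(f1s: Sequence[float]) -> float:
    """Arithmetic mean of (unrounded) per-class F1 scores."""
    if len(f1s) == 0:
        raise ValueError("macro F1 of an empty class list is undefined")
    return float(np.mean(f1s))


def error_summary(
    truth_numeric: Sequence[float], pred_numeric: Sequence[float]
) -> tuple[float, float]:
    """(MSE, MAE) over numerically encoded paired scores."""
    t = np.asarray(truth_numeric, dtype=float)
    p = np.asarray(pred_numeric, dtype=float)
    if t.shape != p.shape or t.size == 0:
        raise ValueError("need equal-length, non-empty numeric score vectors")
    diff = p - t
    return float(np.mean(diff**2)), float(np.mean(np.abs(diff)))


@dataclass(frozen=True)
class EvaluationReport:
    scheme: Scheme
    per_class: dict[str, tuple[ConfusionCounts, ClassMetrics]]
    macro_f1: float
    mse: float
    mae: float
    n: int

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme.value,
            "n": self.n,
            "macro_f1": self.macro_f1,
            "mse": self.mse,
            "mae": self.mae,
            "per_class": {
                label: {
                    "tp": c.tp,
                    "tn": c.tn,
                    "fp": c.fp,
                    "fn": c.fn,
                    **{f: getattr(m, f) for f in ClassMetrics.__dataclass_fields__},
                }
                for label, (c, m) in self.per_class.items()
            },
        }

    def to_frame(self):
        """Per-class report table (one row per class, metric columns)."""
        import pandas as pd

        rows = []
        for label, (c, m) in self.per_class.items():
            rows.append(
                {
                    "class": label,
                    "tp": c.tp,
                    "tn": c.tn,
                    "fp": c.fp,
                    "fn": c.fn,
                    **{f: getattr(m, f) for f in ClassMetrics.__dataclass_fields__},
                }
            )
        return pd.DataFrame(rows)


def evaluate_labels(
    truth_labels: Sequence[str],
    pred_labels: Sequence[str],
    scheme: Scheme | str,
    *,
    truth_numeric: Sequence[float] | None = None,
    pred_numeric: Sequence[float] | None = None,
) -> EvaluationReport:
    """Per-class counts/metrics and macro F1 for already-classified labels."""
    scheme = Scheme(scheme)
    present = set(truth_labels) | set(pred_labels)
    unknown = present - set(scheme_labels(scheme))
    if unknown:
        raise ValueError(f"labels {sorted(unknown)} not in scheme {scheme.value}")
    # classes absent from both truth and prediction carry no information and
    # are left out of the report (and hence out of the macro average)
    labels = [l for l in scheme_labels(scheme) if l in present]
    per_class = {}
    for label in labels:
        counts = one_vs_rest_counts(truth_labels, pred_labels, label)
        per_class[label] = (counts, class_metrics(counts))
    mf1 = macro_f1([m.f1 for _, m in per_class.values()])
    if truth_numeric is not None and pred_numeric is not None:
        mse, mae = error_summary(truth_numeric, pred_numeric)
    else:
        mse = mae = float("nan")
    return EvaluationReport(scheme, per_class, mf1, mse, mae, len(truth_labels))


def evaluate(
    truth_scores: Sequence[float],
    pred_scores: Sequence[int],
    scheme: Scheme | str,
    *,
    impute: bool = True,
    truth_rescaled: bool = False,
) -> EvaluationReport:
    """Full validation comparison of clinician EDSS vs proxy scores.

    ``truth_scores`` are clinician EDSS values on the half-point grid (or
    already-rescaled class values if ``truth_rescaled``); ``pred_scores``
    are proxy steps 0-9, floored 0 -> 1 when ``impute`` (the validation
    convention).  MSE/MAE always use the eight-fold numeric encoding, with
    any value >= 8 encoded as 8.
    """
    from .scale import rescale_edss

    if len(truth_scores) != len(pred_scores):
        raise ValueError(
            f"paired score lengths differ: {len(truth_scores)} vs {len(pred_scores)}"
        )
    truth_vals: list[ClassValue] = [
        s if truth_rescaled else rescale_edss(s) for s in truth_scores
    ]
    pred_vals: list[int] = [
        impute_pedss_floor(int(p)) if impute else int(p) for p in pred_scores
    ]
    truth_labels = [to_class(v, scheme) for v in truth_vals]
    pred_labels = [to_class(v, scheme) for v in pred_vals]
    truth_num = [min(numeric_encode(v), 8) for v in truth_vals]
    pred_num = [min(numeric_encode(v), 8) for v in pred_vals]
    return evaluate_labels(
        truth_labels,
        pred_labels,
        scheme,
        truth_numeric=truth_num,
        pred_numeric=pred_num,
    )


def bootstrap_kappa_ci(
    truth_labels: Sequence[str],
    pred_labels: Sequence[str],
    target: str,
    *,
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the one-vs-rest kappa of ``target``.

    Provided for exploratory use; the interval estimator is not tied to any
    published reference interval.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(truth_labels)
    p = np.asarray(pred_labels)
    n = len(t)
    stats = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            c = one_vs_rest_counts(list(t[idx]), list(p[idx]), target)
        except ValueError:
            continue
        stats.append(class_metrics(c).kappa)
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)
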