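"""Published validation confusion counts for the claims-based EDSS proxy.

The original clinical validation compared proxy scores against clinician
EDSS from medical records in a 100-patient linked cohort and reported the
complete one-vs-rest confusion counts (TP/TN/FP/FN) for every class of the
three classifier schemes.  Those counts are inputs here: every derived
metric (sensitivity, specificity, PPV, NPV, accuracy, Cohen's kappa, F1,
macro F1) is exactly recomputable from them with
:func:`pedss.evaluation.class_metrics` and :func:`pedss.evaluation.macro_f1`.
"""

from __future__ import annotations

from .evaluation import ConfusionCounts, class_metrics, macro_f1
from .scale import Scheme

__all__ = ["VALIDATION_COUNTS", "validation_macro_f1", "validation_binary_kappa"]

# scheme -> class label -> (TP, TN, FP, FN); N = 100 in every row
VALIDATION_COUNTS: dict[Scheme, dict[str, ConfusionCounts]] = {
    Scheme.EIGHTFOLD: {
        "1": ConfusionCounts(13, 53, 29, 5),
        "2": ConfusionCounts(4, 75, 2, 19),
        "3": ConfusionCounts(8, 63, 10, 19),
        "4": ConfusionCounts(1, 83, 6, 10),
        "5": ConfusionCounts(1, 83, 13, 3),
        "6": ConfusionCounts(1, 90, 1, 8),
        "7": ConfusionCounts(4, 88, 5, 3),
        "8plus": ConfusionCounts(0, 97, 2, 1),
    },
    Scheme.THREEFOLD: {
        "1-3": ConfusionCounts(58, 24, 8, 10),
        "4-5": ConfusionCounts(8, 72, 13, 7),
        "6plus": ConfusionCounts(11, 81, 2, 6),
    },
    Scheme.BINARY: {
        "lt6": ConfusionCounts(81, 11, 6, 2),
        "ge6": ConfusionCounts(11, 81, 2, 6),
    },
}


def validation_macro_f1(scheme: Scheme | str) -> float:
    """Macro F1 recomputed from the published per-class confusion counts."""
    counts = VALIDATION_COUNTS[Scheme(scheme)]
    return macro_f1([class_metrics(c).f1 for c in counts.values()])


def validation_binary_kappa() -> float:
    """One-vs-rest Cohen's kappa of the binary severe-disability class."""
    return class_metrics(VALIDATION_COUNTS[Scheme.BINARY]["ge6"]).kappa
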