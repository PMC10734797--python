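"""Rescaling of clinician EDSS scores and classifier-scheme groupings.

The clinician-rated EDSS runs 0.0-10.0 in half-point steps; the claims proxy
produces integer steps 0-9.  To compare the two on a common footing:

* half-point EDSS scores from 1.0 to 7.5 are floored to the integer step
  below; scores 8.0-9.5 collapse to a single ">=8" class (``8plus``);
* proxy scores of 0 are imputed to 1 for validation comparisons, because a
  reference cohort of treated MS patients contains no EDSS 0.0.

Three classifier schemes group the common class values: ``eightfold``
(steps 1..7 plus 8plus), ``threefold`` (1-3 / 4-5 / >=6), and ``binary``
(<6 / >=6).  Each coarser scheme is a strict coarsening of the finer one.
"""

from __future__ import annotations

import enum
import warnings
from typing import Union

__all__ = [
    "Scheme",
    "EIGHT_PLUS",
    "EDSS_GRID",
    "scheme_labels",
    "validate_edss_score",
    "rescale_edss",
    "impute_pedss_floor",
    "to_class",
    "numeric_encode",
]

EIGHT_PLUS = "8plus"

ClassValue = Union[int, str]  # 1..7, 8, 9, or "8plus"


class Scheme(str, enum.Enum):
    EIGHTFOLD = "eightfold"
    THREEFOLD = "threefold"
    BINARY = "binary"


_LABELS = {
    Scheme.EIGHTFOLD: ("1", "2", "3", "4", "5", "6", "7", EIGHT_PLUS),
    Scheme.THREEFOLD: ("1-3", "4-5", "6plus"),
    Scheme.BINARY: ("lt6", "ge6"),
}

# EDSS grid: 0.0 then 1.0, 1.5, ..., 9.5 (no 0.5 step; 10.0 = death excluded)
EDSS_GRID = tuple([0.0] + [k / 2 for k in range(2, 20)])


def scheme_labels(scheme: Scheme | str) -> tuple[str, ...]:
    """All class labels of a scheme, in scale order."""
    return _LABELS[Scheme(scheme)]


def validate_edss_score(score: float) -> float:
    """Check a clinician EDSS value against the half-point grid (death excluded)."""
    score = float(score)
    if not any(abs(score - g) < 1e-9 for g in EDSS_GRID):
        raise ValueError(
            f"EDSS score {score} is not on the half-point grid 0.0, 1.0-9.5 "
            "(10.0, death, is out of scope)"
        )
    return score


def rescale_edss(score: float) -> ClassValue:
    """Floor a half-point EDSS score to the 10-step proxy scale.

    1.0-7.5 floor to the integer step; 8.0-9.5 collapse to ``8plus``.
    A score of 0.0 maps to class 1 with a warning, mirroring the proxy-side
    imputation, so both scales share a domain.
    """
    score = validate_edss_score(score)
    if score == 0.0:
        warnings.warn(
            "EDSS 0.0 encountered; mapped to class 1 to mirror the proxy-side "
            "imputation (reference cohorts contain no EDSS 0.0)",
            stacklevel=2,
        )
        return 1
    if score >= 8.0:
        return EIGHT_PLUS
    return int(score)


def impute_pedss_floor(pedss: int) -> int:
    """Validation-pathway imputation: a proxy score of 0 becomes 1."""
    if pedss not in range(10):
        raise ValueError(f"pEDSS must be an integer in 0..9, got {pedss!r}")
    return 1 if pedss == 0 else pedss


def numeric_encode(value: ClassValue) -> int:
    """Numeric encoding for error summaries: ``8plus`` -> 8 (its lower bound)."""
    if value == EIGHT_PLUS:
        return 8
    value = int(value)
    if value not in range(1, 10):
        raise ValueError(f"class value out of range: {value!r}")
    return value


def to_class(value: ClassValue, scheme: Scheme | str) -> str:
    """Map a class value (1..7, ``8plus``; proxy 8/9 allowed) to a scheme label."""
    scheme = Scheme(scheme)
    v = numeric_encode(value)  # 9 (proxy-only) folds into the >=8 groupings
    if scheme is Scheme.EIGHTFOLD:
        return EIGHT_PLUS if v >= 8 else str(v)
    if scheme is Scheme.THREEFOLD:
        if v <= 3:
            return "1-3"
        if v <= 5:
            return "4-5"
        return "6plus"
    return "lt6" if v < 6 else "ge6"
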