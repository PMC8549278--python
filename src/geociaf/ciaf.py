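"""Composite index of anthropometric failure (CIAF).

A child is stunted, underweight or wasted when the height-for-age (HAZ),
weight-for-age (WAZ) or weight-for-height (WHZ) z-score falls strictly below
a cutoff (−2 by convention).  The joint pattern of the three failures is
classified into the standard lettered categories:

    A  no failure                     F  stunting only
    B  wasting only                   Y  underweight only
    C  wasting + underweight          X  wasting + stunting, not underweight
    D  wasting + stunting + underweight
    E  stunting + underweight

The classic seven-letter scheme (A–Y) omits the biologically unusual
wasted-and-stunted-but-not-underweight combination; it is kept here as a
separate label ``X`` so that the classification is an exhaustive partition.
The binary CIAF indicator is 1 for every category except A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnthroRecord",
    "CIAFCategory",
    "classify_anthro",
    "classify_table",
    "ciaf_prevalence",
    "CATEGORY_LABELS",
]

#: every label the classifier can emit, in reporting order
CATEGORY_LABELS = ("A", "B", "C", "D", "E", "F", "Y", "X")

DEFAULT_CUTOFF = -2.0

# (wasted, stunted, underweight) -> category label
_TRUTH_TABLE = {
    (False, False, False): "A",
    (True, False, False): "B",
    (True, False, True): "C",
    (True, True, True): "D",
    (False, True, True): "E",
    (False, True, False): "F",
    (False, False, True): "Y",
    (True, True, False): "X",
}


@dataclass(frozen=True)
class AnthroRecord:
    """One child's anthropometric z-scores."""

    haz: float
    waz: float
    whz: float

    def is_complete(self) -> bool:
        return all(math.isfinite(v) for v in (self.haz, self.waz, self.whz))


@dataclass(frozen=True)
class CIAFCategory:
    label: str
    ciaf: int

    def __post_init__(self) -> None:
        if self.label not in CATEGORY_LABELS:
            raise ValueError(f"unknown CIAF category label {self.label!r}")


def classify_anthro(record: AnthroRecord, cutoff: float = DEFAULT_CUTOFF) -> CIAFCategory:
    """Classify a single child into a CIAF category.

    Failure is strict: a z-score exactly at the cutoff is *not* a failure.

    Raises
    ------
    ValueError
        If any z-score is NaN or infinite.
    """
    if not record.is_complete():
        raise ValueError(f"non-finite z-score in {record}")
    wasted = record.whz < cutoff
    stunted = record.haz < cutoff
    underweight = record.waz < cutoff
    label = _TRUTH_TABLE[(wasted, stunted, underweight)]
    return CIAFCategory(label=label, ciaf=0 if label == "A" else 1)


def classify_table(
    table: pd.DataFrame,
    cutoff: float = DEFAULT_CUTOFF,
    *,
    haz: str = "haz",
    waz: str = "waz",
    whz: str = "whz",
    exclude_implausible: bool = False,
    plausible_limit: float = 6.0,
) -> pd.DataFrame:
    """Vectorized classification of a child table.

    Adds ``category`` and ``ciaf`` columns.  Rows with any missing z-score are
    flagged in a boolean ``anthro_missing`` column and receive ``category`` NA
    and ``ciaf`` NA — they are never silently dropped.  With
    ``exclude_implausible`` set, records with any \\|z\\| > ``plausible_limit``
    are flagged the same way (off by default; no such exclusion is part of the
    core definition).
    """
    out = table.copy()
    z = out[[haz, waz, whz]].to_numpy(dtype=float)
    missing = ~np.isfinite(z).all(axis=1)
    if exclude_implausible:
        with np.errstate(invalid="ignore"):
            missing |= (np.abs(z) > plausible_limit).any(axis=1)

    wasted = z[:, 2] < cutoff
    stunted = z[:, 0] < cutoff
    under = z[:, 1] < cutoff
    # index into CATEGORY_LABELS via the truth table
    lut = np.empty((2, 2, 2), dtype="U1")
    for (w, s, u), lab in _TRUTH_TABLE.items():
        lut[int(w), int(s), int(u)] = lab
    labels = lut[wasted.astype(int), stunted.astype(int), under.astype(int)].astype(object)
    ciaf = (labels != "A").astype(float)
    labels[missing] = pd.NA
    ciaf = np.where(missing, np.nan, ciaf)

    out["category"] = labels
    out["ciaf"] = ciaf
    out["anthro_missing"] = missing
    return out


def ciaf_prevalence(
    records: Sequence[AnthroRecord] | Iterable[AnthroRecord],
    weights: Sequence[float] | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> float:
    """(Weighted) fraction of children with any anthropometric failure."""
    records = list(records)
    if not records:
        raise ValueError("ciaf_prevalence needs at least one record")
    flags = np.array([classify_anthro(r, cutoff).ciaf for r in records], dtype=float)
    if weights is None:
        return float(flags.mean())
    w = np.asarray(weights, dtype=float)
    if w.shape != flags.shape:
        raise ValueError("weights must match records in length")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return float(np.average(flags, weights=w))
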