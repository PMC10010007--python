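"""Multi-sector intratumoral-heterogeneity (ITH) analysis.

Each multi-sector patient contributes 2-4 spatially distinct tumor sectors,
each screened and labelled resistant or sensitive.  A patient is class S
(all sensitive), R (all resistant) or H (heterogeneous: both labels
present).  To ask how many sectors must be sampled to notice heterogeneity,
every k-subset of each patient's sectors is enumerated exactly: the
detection rate at k is the fraction of subsets containing both labels, and
the class distribution at k classifies every subset the same way.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

__all__ = [
    "MultiSectorPatient",
    "classify_patient_ith",
    "detection_rate_by_subsample",
    "subsample_class_distribution",
]

VALID_LABELS = frozenset({"resistant", "sensitive"})


@dataclass(frozen=True)
class MultiSectorPatient:
    patient_id: str
    sector_labels: tuple[str, ...]

    def __post_init__(self):
        if not 2 <= len(self.sector_labels) <= 4:
            raise ValueError(
                f"{self.patient_id}: expected 2-4 sectors, got {len(self.sector_labels)}"
            )
        bad = set(self.sector_labels) - VALID_LABELS
        if bad:
            raise ValueError(f"{self.patient_id}: unknown sector labels {bad}")

    @property
    def ith_class(self) -> str:
        return classify_patient_ith(self.sector_labels)


def classify_patient_ith(sector_labels) -> str:
    """S if all sensitive, R if all resistant, H if both labels occur."""
    labels = set(sector_labels)
    if len(sector_labels) < 2:
        raise ValueError("ITH classification needs >= 2 sectors")
    if bad := labels - VALID_LABELS:
        raise ValueError(f"unknown sector labels {bad}")
    if labels == VALID_LABELS:
        return "H"
    return "S" if labels == {"sensitive"} else "R"


def detection_rate_by_subsample(
    cohort: list[MultiSectorPatient], k: int
) -> tuple[int, int, float]:
    """Heterogeneity detection rate when only k sectors are sampled.

    Exact enumeration over every k-subset of every patient with >= k
    sectors; patients with fewer sectors contribute to neither numerator nor
    denominator.  Returns (numerator, denominator, rate).
    """
    if k < 2:
        raise ValueError("detection needs k >= 2 sampled sectors")
    num = den = 0
    for p in cohort:
        if len(p.sector_labels) < k:
            continue
        for subset in combinations(p.sector_labels, k):
            den += 1
            if set(subset) == VALID_LABELS:
                num += 1
    if den == 0:
        raise ValueError(f"no patient has >= {k} sectors")
    return num, den, num / den


def subsample_class_distribution(
    cohort: list[MultiSectorPatient], k: int
) -> pd.Series:
    """Proportions of k-subsets classified S / H / R (they sum to 1)."""
    if k < 2:
        raise ValueError("classification needs k >= 2 sampled sectors")
    counts = {"S": 0, "H": 0, "R": 0}
    total = 0
    for p in cohort:
        if len(p.sector_labels) < k:
            continue
        for subset in combinations(p.sector_labels, k):
            counts[classify_patient_ith(subset)] += 1
            total += 1
    if total == 0:
        raise ValueError(f"no patient has >= {k} sectors")
    return pd.Series({c: counts[c] / total for c in ("S", "H", "R")}, name=f"k={k}")
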