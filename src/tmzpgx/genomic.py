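"""Somatic-variant filters and copy-number-alteration (CNA) calling rules.

Variant retention: nonsynonymous somatic calls (moderate- or high-impact
effect classes) with tumor VAF strictly above 5% and matched-blood VAF equal
to 0.  A WES sample is hypermutated when its somatic mutation count exceeds
350; the rule is not assessable on targeted panels.  EGFRvIII is called from
RNA-seq when two or more reads skip exons 2-7.

CNA classes come from median-centered log2 tumor/normal coverage ratios with
the step function (strict inequalities; boundary values take the milder
class):

    deletion  < -1.58 <= loss < -0.5 <= neutral <= 0.5 < gain <= 1.58 < amp

with one platform-specific exception: on the GliomaSCAN targeted panel the
EGFR gain boundary drops to 0.3.  When several platforms called the same
gene, WES has priority over GliomaSCAN over RNA-based prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SomaticVariantRecord",
    "CnaCall",
    "CnaProfile",
    "filter_somatic_variants",
    "call_hypermutation",
    "detect_egfrviii",
    "compute_cna_log2",
    "call_cna_class",
    "merge_cna_sources",
    "concurrent_cna_flag",
    "HYPERMUTATION_THRESHOLD",
    "SOURCE_PRIORITY",
]

HYPERMUTATION_THRESHOLD = 350
EGFRVIII_MIN_SKIP_READS = 2
SOURCE_PRIORITY = ("WES", "GliomaSCAN", "RNA")

RETAINED_EFFECT_CLASSES = frozenset({"moderate", "high"})
DELETION_CLASSES = frozenset({"deletion", "loss"})
AMPLIFICATION_CLASSES = frozenset({"gain", "amplification"})


@dataclass(frozen=True)
class SomaticVariantRecord:
    sample_id: str
    gene: str
    effect_class: str  # moderate | high | synonymous | other
    vaf_tumor: float
    vaf_blood: float

    def __post_init__(self):
        for name in ("vaf_tumor", "vaf_blood"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class CnaCall:
    gene: str
    log2_ratio: float
    cna_class: str  # deletion | loss | neutral | gain | amplification
    source: str  # WES | GliomaSCAN | RNA


@dataclass
class CnaProfile:
    """Per-gene CNA calls for one sample, after cross-platform merging."""

    sample_id: str
    calls: dict[str, CnaCall] = field(default_factory=dict)
    merged: bool = False

    def cna_class(self, gene: str) -> str | None:
        call = self.calls.get(gene)
        return call.cna_class if call is not None else None


def filter_somatic_variants(
    records: list[SomaticVariantRecord],
) -> list[SomaticVariantRecord]:
    """Keep nonsynonymous somatic variants: moderate/high impact, tumor
    VAF > 0.05 (strict), blood VAF exactly 0."""
    return [
        r
        for r in records
        if r.effect_class in RETAINED_EFFECT_CLASSES
        and r.vaf_tumor > 0.05
        and r.vaf_blood == 0.0
    ]


def call_hypermutation(n_somatic: int, platform: str = "WES") -> bool | None:
    """Hypermutation flag: > 350 somatic mutations, assessable on WES only.

    Returns None (not assessable) for non-WES platforms rather than False,
    so that the missing status propagates into feature tables.
    """
    if n_somatic < 0:
        raise ValueError("mutation count cannot be negative")
    if platform != "WES":
        return None
    return n_somatic > HYPERMUTATION_THRESHOLD


def detect_egfrviii(skip_reads: int) -> bool:
    """EGFRvIII-positive when >= 2 RNA-seq reads skip exons 2-7."""
    if skip_reads < 0:
        raise ValueError("read count cannot be negative")
    return skip_reads >= EGFRVIII_MIN_SKIP_READS


def compute_cna_log2(
    tumor_counts: pd.Series, normal_counts: pd.Series, pseudocount: float = 1.0
) -> pd.Series:
    """Median-centered log2 coverage ratio per gene.

    log2(((t_i + p)/T) / ((n_i + p)/N)) with pseudocount p, then shifted so
    the per-sample median is exactly 0.
    """
    genes = tumor_counts.index.intersection(normal_counts.index)
    if genes.empty:
        raise ValueError("tumor and normal counts share no genes")
    t = tumor_counts.loc[genes].astype(float) + pseudocount
    n = normal_counts.loc[genes].astype(float) + pseudocount
    ratio = np.log2((t / t.sum()) / (n / n.sum()))
    return ratio - ratio.median()


def call_cna_class(log2_ratio: float, gene: str = "", source: str = "WES") -> str:
    """Five-level class from the log2 ratio step function.

    Strict inequalities throughout; values landing exactly on a boundary go
    to the milder class.  EGFR called from the GliomaSCAN panel uses the
    relaxed 0.3 gain cutoff.
    """
    gain_cut = 0.3 if (gene == "EGFR" and source == "GliomaSCAN") else 0.5
    if log2_ratio < -1.58:
        return "deletion"
    if log2_ratio < -0.5:
        return "loss"
    if log2_ratio > 1.58:
        return "amplification"
    if log2_ratio > gain_cut:
        return "gain"
    return "neutral"


def merge_cna_sources(
    sample_id: str, calls_by_source: dict[str, list[CnaCall]]
) -> CnaProfile:
    """Merge per-platform calls: WES beats GliomaSCAN beats RNA, per gene."""
    merged: dict[str, CnaCall] = {}
    for source in reversed(SOURCE_PRIORITY):  # lowest priority first, overwritten
        for call in calls_by_source.get(source, []):
            merged[call.gene] = call
    return CnaProfile(sample_id=sample_id, calls=merged, merged=True)


def concurrent_cna_flag(profile: CnaProfile) -> bool | None:
    """Concurrent PTEN loss/deletion + EGFR gain/amplification + CDKN2A/B
    loss/deletion.  None (not assessable) if any of the three loci is
    missing from the merged profile."""
    if not profile.merged:
        raise ValueError("profile must be merged before the concurrency check")
    pten = profile.cna_class("PTEN")
    egfr = profile.cna_class("EGFR")
    cdkn = profile.cna_class("CDKN2A/B")
    if pten is None or egfr is None or cdkn is None:
        return None
    return (
        pten in DELETION_CLASSES
        and egfr in AMPLIFICATION_CLASSES
        and cdkn in DELETION_CLASSES
    )


_CLASS_SEVERITY = {"neutral": 0, "loss": 1, "gain": 1, "deletion": 2, "amplification": 2}


def collapse_cdkn2ab(call_a: CnaCall | None, call_b: CnaCall | None) -> CnaCall | None:
    """Collapse CDKN2A and CDKN2B to one 'CDKN2A/B' locus, keeping the more
    extreme of the two calls (they are co-deleted in practice)."""
    candidates = [c for c in (call_a, call_b) if c is not None]
    if not candidates:
        return None
    best = max(candidates, key=lambda c: _CLASS_SEVERITY[c.cna_class])
    return CnaCall("CDKN2A/B", best.log2_ratio, best.cna_class, best.source)
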