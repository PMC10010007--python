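"""Transcriptional subtyping of GBM by single-sample GSEA (ssGSEA).

Each sample is scored against the classical / proneural / mesenchymal
signature gene sets with a rank-weighted running-sum enrichment statistic;
per-subtype scores are z-normalised across the cohort and the sample takes
the subtype with the highest normalised score.

The running sum walks the genes ranked by expression, descending.  In-set
genes contribute their rank value raised to a weight exponent (default
0.75), normalised by the in-set total; out-of-set genes contribute uniform
mass 1/(N - n_set).  The score is the sum over all ranked positions of the
difference between the two cumulative distributions, so sets concentrated
at the top of the ranking score positive and sets at the bottom negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "SubtypeScores",
    "ssgsea_score",
    "score_gene_sets",
    "assign_subtype",
    "DEFAULT_SUBTYPE_ORDER",
]

#: Deterministic tie order for assignment.
DEFAULT_SUBTYPE_ORDER = ("classical", "proneural", "mesenchymal")

DEFAULT_WEIGHT_EXPONENT = 0.75


def ssgsea_score(
    expression: pd.Series, gene_set: list[str], weight_exponent: float = DEFAULT_WEIGHT_EXPONENT
) -> float:
    """Rank-weighted running-sum enrichment of one gene set in one sample.

    Genes are ranked by expression descending (rank N = highest).  The score
    is sum_i [ P_in(i) - P_out(i) ] where P_in accumulates
    rank_value^weight_exponent over in-set genes and P_out accumulates
    1/(N - n_set) over the rest.
    """
    members = set(gene_set) & set(expression.index)
    if not members:
        raise ValueError(f"no gene of the set ({gene_set[:5]}...) is in the profile")
    n = len(expression)
    if len(members) == n:
        raise ValueError("gene set covers the whole profile; enrichment undefined")

    ranks = rankdata(expression.values)  # 1 = lowest expression
    order = np.argsort(-expression.values, kind="stable")  # descending walk
    in_set = np.fromiter(
        (g in members for g in expression.index), dtype=bool, count=n
    )

    weights = np.where(in_set, ranks**weight_exponent, 0.0)
    w_ordered = weights[order]
    in_ordered = in_set[order]

    p_in = np.cumsum(w_ordered) / w_ordered.sum()
    p_out = np.cumsum(~in_ordered) / (n - len(members))
    return float(np.sum(p_in - p_out))


def score_gene_sets(
    expression: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    weight_exponent: float = DEFAULT_WEIGHT_EXPONENT,
) -> pd.DataFrame:
    """ssGSEA score of every gene set (columns) in every sample (rows).

    ``expression`` is genes x samples.
    """
    scores = {
        name: [
            ssgsea_score(expression[s], genes, weight_exponent)
            for s in expression.columns
        ]
        for name, genes in gene_sets.items()
    }
    return pd.DataFrame(scores, index=expression.columns)


@dataclass
class SubtypeScores:
    """Raw and cohort-normalised enrichment scores with the assigned subtype."""

    scores: pd.DataFrame  # samples x subtypes, raw
    normalized: pd.DataFrame  # z across samples per subtype
    assignment: pd.Series  # subtype per sample


def assign_subtype(
    scores: pd.DataFrame, tie_order: tuple[str, ...] = DEFAULT_SUBTYPE_ORDER
) -> SubtypeScores:
    """Z-normalise each subtype's scores across samples and take the argmax.

    Ties resolve by ``tie_order`` position.  A subtype with zero variance
    across the cohort gets normalised score 0 (with a warning).
    """
    if len(scores) < 2:
        raise ValueError("normalisation across samples needs >= 2 samples")
    sd = scores.std(axis=0, ddof=1)
    if (sd == 0).any():
        warnings.warn(
            f"zero-variance subtypes set to z = 0: {sd.index[sd == 0].tolist()}",
            stacklevel=2,
        )
    z = (scores - scores.mean(axis=0)).div(sd.replace(0, np.inf), axis=1)

    rank_in_order = {s: i for i, s in enumerate(tie_order)}
    cols = sorted(scores.columns, key=lambda s: rank_in_order.get(s, len(tie_order)))
    z_ordered = z[cols]
    assignment = z_ordered.idxmax(axis=1).rename("subtype")  # first max wins ties
    return SubtypeScores(scores=scores, normalized=z, assignment=assignment)
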