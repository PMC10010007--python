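"""Copy-number class prediction from RNA expression.

For samples with RNA-seq but no DNA sequencing, per-gene copy-number classes
are predicted from expression with a boosted-tree multiclass model.  For
each target gene the predictors are the union of the pathway gene sets that
contain the target (plus the target itself), z-scored per gene; DNA-derived
five-level truth is collapsed to three classes (deletion/loss, neutral,
gain/amplification) for training.  Class-probability cutoffs for the
non-neutral classes are calibrated on samples with matched DNA calls by
maximising the one-vs-rest F1 over a grid of observed probabilities; at
prediction time a sample takes the argmax among classes whose probability
exceeds its cutoff, and neutral otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score
from xgboost import XGBClassifier

__all__ = [
    "PathwayFeatureSet",
    "CnaExpressionModel",
    "build_pathway_features",
    "train_cna_predictor",
    "calibrate_cutoffs",
    "predict_cna_from_expression",
    "collapse_to_three_classes",
    "THREE_CLASSES",
]

THREE_CLASSES = ("deletion/loss", "neutral", "gain/amplification")

_COLLAPSE = {
    "deletion": "deletion/loss",
    "loss": "deletion/loss",
    "neutral": "neutral",
    "gain": "gain/amplification",
    "amplification": "gain/amplification",
}


def collapse_to_three_classes(labels: pd.Series) -> pd.Series:
    """Map the five-level DNA classes onto the three trained classes."""
    unknown = set(labels.unique()) - set(_COLLAPSE)
    if unknown:
        raise ValueError(f"unknown CNA classes: {sorted(unknown)}")
    return labels.map(_COLLAPSE)


@dataclass
class PathwayFeatureSet:
    """Z-scored expression features for one target gene's CNA model."""

    target_gene: str
    predictor_genes: list[str]
    features: pd.DataFrame  # samples x predictors, z-scored per gene
    gene_means: pd.Series
    gene_sds: pd.Series


def build_pathway_features(
    expression: pd.DataFrame,
    target_gene: str,
    gene_sets: dict[str, list[str]],
) -> PathwayFeatureSet:
    """Assemble the predictor matrix for a target gene.

    ``expression`` is genes x samples.  Predictors are the union of all gene
    sets containing the target, intersected with the expression matrix, with
    the target itself always included; expression is z-scored per gene
    across samples (constant genes get z = 0).
    """
    if target_gene not in expression.index:
        raise ValueError(f"target gene {target_gene!r} absent from the matrix")
    members: set[str] = set()
    for genes in gene_sets.values():
        if target_gene in genes:
            members.update(genes)
    if not members:
        warnings.warn(
            f"{target_gene!r} occurs in no gene set; falling back to the "
            "target gene as sole predictor",
            stacklevel=2,
        )
    members.add(target_gene)
    predictors = sorted(members & set(expression.index) | {target_gene})

    sub = expression.loc[predictors].T  # samples x predictors
    means = sub.mean(axis=0)
    sds = sub.std(axis=0, ddof=0).replace(0, 1.0)
    z = (sub - means) / sds
    return PathwayFeatureSet(target_gene, predictors, z, means, sds)


@dataclass
class CnaExpressionModel:
    """Per-target-gene boosted-tree CNA classifier with calibrated cutoffs."""

    target_gene: str
    booster: XGBClassifier
    classes: list[str]  # subset of THREE_CLASSES present in training
    feature_set: PathwayFeatureSet
    cutoffs: dict[str, float | None] = field(default_factory=dict)

    def predict_proba(self, features: pd.DataFrame) -> pd.DataFrame:
        proba = self.booster.predict_proba(features.values)
        return pd.DataFrame(proba, index=features.index, columns=self.classes)


def train_cna_predictor(
    feature_set: PathwayFeatureSet,
    dna_labels: pd.Series,
    seed: int = 0,
    n_estimators: int = 50,
    max_depth: int = 3,
) -> CnaExpressionModel:
    """Fit the multiclass boosted-tree model for one target gene.

    ``dna_labels`` holds five-level DNA classes indexed by sample; they are
    collapsed to the three trained classes.  Deterministic for a fixed seed.
    """
    labels = collapse_to_three_classes(dna_labels.reindex(feature_set.features.index))
    present = [c for c in THREE_CLASSES if c in set(labels)]
    if len(present) < 2:
        raise ValueError(
            f"{feature_set.target_gene}: only one class "
            f"({present}) among training labels"
        )
    y = labels.map({c: i for i, c in enumerate(present)}).values
    booster = XGBClassifier(
        n_estimators=n_estimators,
        max_depth=max_depth,
        learning_rate=0.3,
        objective="multi:softprob",
        random_state=seed,
        n_jobs=1,
    )
    booster.fit(feature_set.features.values, y)
    return CnaExpressionModel(
        target_gene=feature_set.target_gene,
        booster=booster,
        classes=present,
        feature_set=feature_set,
    )


def calibrate_cutoffs(
    class_probabilities: pd.DataFrame, true_classes: pd.Series
) -> dict[str, float | None]:
    """Per-class probability cutoffs maximising one-vs-rest F1.

    The grid is the set of probabilities observed for that class on the
    calibration samples; ties between equally good cutoffs resolve to the
    smallest.  A class absent from the calibration truth gets cutoff None
    (uncalibrated: that class is never predicted).  The neutral class needs
    no cutoff — it is the fallback.
    """
    rowsum = class_probabilities.sum(axis=1)
    if not np.allclose(rowsum, 1.0, atol=1e-6):
        raise ValueError("class probability rows must sum to 1")
    truth = collapse_to_three_classes(true_classes).reindex(class_probabilities.index)
    cutoffs: dict[str, float | None] = {}
    for cls in class_probabilities.columns:
        if cls == "neutral":
            continue
        if cls not in set(truth):
            cutoffs[cls] = None
            continue
        y_true = (truth == cls).values
        p = class_probabilities[cls].values
        best_cut, best_f1 = None, -1.0
        for cut in np.sort(np.unique(p)):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f1 = f1_score(y_true, p >= cut, zero_division=0)
            if f1 > best_f1:
                best_cut, best_f1 = float(cut), f1
        cutoffs[cls] = best_cut
    return cutoffs


def predict_cna_from_expression(
    model: CnaExpressionModel, expression: pd.DataFrame
) -> pd.Series:
    """Predict the three-level CNA class for each sample.

    ``expression`` is genes x samples on the training normalisation scale;
    predictor genes are z-scored with the training means/SDs, missing
    predictors imputed at z = 0 (warning above 20% missing).  A sample is
    assigned the argmax among non-neutral classes whose probability exceeds
    the calibrated cutoff, else neutral.
    """
    if not model.cutoffs:
        raise ValueError("model has no calibrated cutoffs; run calibrate_cutoffs")
    fs = model.feature_set
    present = [g for g in fs.predictor_genes if g in expression.index]
    n_missing = len(fs.predictor_genes) - len(present)
    if n_missing:
        if n_missing / len(fs.predictor_genes) > 0.2:
            warnings.warn(
                f"{model.target_gene}: {n_missing}/{len(fs.predictor_genes)} "
                "predictor genes missing; imputing z = 0",
                stacklevel=2,
            )
    z = pd.DataFrame(
        0.0, index=expression.columns, columns=fs.predictor_genes
    )
    sub = expression.loc[present].T
    z[present] = (sub - fs.gene_means[present]) / fs.gene_sds[present]

    proba = model.predict_proba(z)
    out = pd.Series("neutral", index=proba.index, name=model.target_gene)
    for sample in proba.index:
        best_cls, best_p = None, -1.0
        for cls in model.classes:
            if cls == "neutral":
                continue
            cut = model.cutoffs.get(cls)
            p = proba.at[sample, cls]
            if cut is not None and p >= cut and p > best_p:
                best_cls, best_p = cls, p
        if best_cls is not None:
            out[sample] = best_cls
    return out
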