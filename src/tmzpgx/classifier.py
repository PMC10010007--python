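"""The TMZ-efficacy classifier: feature assembly, imputation, training.

A boosted-tree classifier separates TMZ responders from non-responders from
a 25-column pharmacogenomic feature table: MGMT promoter methylation,
MGMT expression and fusion status, the four resistance-marker expressions
(EGR4, PAPPA, LRRC3, ANXA3), transcriptional-subtype indicators, driver
SNV and CNA indicators, EGFRvIII, and the concurrent PTEN/EGFR/CDKN2A/B
copy-number flag.  Missing binary features are imputed at 0.5 and missing
continuous features by K-nearest-neighbour averaging (K = 5) over the
continuous block.  The ensemble uses 50 trees of depth at most 3, learning
rate 0.74, per-iteration row subsampling of 0.35 and an L2 penalty on leaf
weights; a sample is called resistant when the predicted resistance
probability reaches 0.6.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

__all__ = [
    "FeatureSchema",
    "DEFAULT_SCHEMA",
    "assemble_features",
    "impute_features",
    "TmzResponseModel",
    "TmzResponseResults",
    "train_classifier",
    "predict_response",
    "evaluate_model",
    "PROBABILITY_CUTOFF",
    "DEFAULT_HYPERPARAMETERS",
]

PROBABILITY_CUTOFF = 0.6

DEFAULT_HYPERPARAMETERS = {
    "n_estimators": 50,
    "max_depth": 3,
    "learning_rate": 0.74,
    "subsample": 0.35,
    "reg_lambda": 1.0,
}

_CONTINUOUS = [
    "MGMT_expression",
    "EGR4_expression",
    "PAPPA_expression",
    "LRRC3_expression",
    "ANXA3_expression",
]
_BINARY = [
    "MGMT_promoter_methylation",
    "MGMT_fusion",
    "subtype_CL",
    "subtype_PN",
    "subtype_MES",
    "EGFRvIII",
    "NF1_mutation",
    "PTEN_mutation",
    "TP53_mutation",
    "EGFR_mutation",
    "PIK3R1_mutation",
    "PIK3CA_mutation",
    "RB1_mutation",
    "EGFR_amplification",
    "PDGFRA_amplification",
    "CDK4_amplification",
    "MDM2_amplification",
    "PTEN_deletion",
    "CDKN2AB_deletion",
    "concurrent_PTEN_EGFR_CDKN2AB",
]


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature columns with their binary/continuous kind."""

    continuous: tuple[str, ...]
    binary: tuple[str, ...]

    @property
    def columns(self) -> list[str]:
        return list(self.continuous) + list(self.binary)

    def kind(self, column: str) -> str:
        if column in self.continuous:
            return "continuous"
        if column in self.binary:
            return "binary"
        raise KeyError(column)

    @property
    def hash(self) -> str:
        joined = "|".join(self.columns)
        return hashlib.sha256(joined.encode()).hexdigest()[:16]


#: 25-column default panel: methylation/expression/fusion of MGMT, the four
#: resistance markers, subtype indicators, driver SNV/CNA indicators,
#: EGFRvIII and the concurrent-CNA flag.  NF2 mutation, hypermutation and
#: 5-ALA status are deliberately withheld (unavailable in external cohorts).
DEFAULT_SCHEMA = FeatureSchema(continuous=tuple(_CONTINUOUS), binary=tuple(_BINARY))

EXCLUDED_FEATURES = ("NF2_mutation", "hypermutation", "5ALA_positive", "5ALA_negative")


def assemble_features(
    sources: dict[str, pd.Series | pd.DataFrame],
    schema: FeatureSchema = DEFAULT_SCHEMA,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Join per-module outputs into one table matching the schema.

    ``sources`` maps feature column -> per-sample values (Series indexed by
    sample).  Measurements absent for a sample stay NaN — explicitly missing,
    never silently zero.  Columns in ``sources`` that the schema does not
    know raise a schema error; schema columns missing from ``sources``
    become all-missing columns.
    """
    unmatched = [c for c in sources if c not in schema.columns]
    if unmatched:
        raise ValueError(f"features not in the schema: {unmatched}")
    if sample_ids is None:
        ids: set[str] = set()
        for s in sources.values():
            ids.update(s.index)
        sample_ids = sorted(ids)
    table = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"),
                         columns=schema.columns, dtype=float)
    for col, values in sources.items():
        table[col] = pd.Series(values).reindex(sample_ids).astype(float)
    bad_binary = [
        c for c in schema.binary
        if not table[c].dropna().isin([0.0, 1.0]).all()
    ]
    if bad_binary:
        raise ValueError(f"non-0/1 values in binary features: {bad_binary}")
    return table


def impute_features(
    table: pd.DataFrame, schema: FeatureSchema = DEFAULT_SCHEMA, k: int = 5
) -> pd.DataFrame:
    """Fill missing values: binary -> 0.5, continuous -> KNN mean (K = 5).

    Continuous imputation averages the k nearest samples by Euclidean
    distance over mutually observed continuous features; observed values are
    never altered.
    """
    if len(table) < k + 1:
        raise ValueError(f"KNN imputation with k={k} needs >= {k + 1} samples")
    out = table.copy()
    for col in schema.binary:
        out[col] = out[col].fillna(0.5)
    cont = list(schema.continuous)
    if cont:
        block = out[cont]
        if block.isna().all(axis=0).any():
            dead = block.columns[block.isna().all(axis=0)].tolist()
            raise ValueError(f"continuous features missing in all samples: {dead}")
        imputer = KNNImputer(n_neighbors=k)
        out[cont] = imputer.fit_transform(block.values)
    return out


@dataclass
class TmzResponseResults:
    """Fitted-classifier results: probabilities, labels, metrics, importances."""

    model: "TmzResponseModel"
    probability: pd.Series  # P(resistant) per training sample
    label: pd.Series  # resistant / sensitive at the cutoff
    train_auc: float
    cv_auc: float
    cv_fold_aucs: list[float]
    confusion: pd.DataFrame  # truth x prediction counts
    importances: pd.Series  # gain importance per feature

    @property
    def concordance(self) -> float:
        """Fraction of training samples whose call matches the label."""
        diag = np.diag(self.confusion.values).sum()
        return float(diag) / float(self.confusion.values.sum())

    def summary(self) -> str:
        lines = [
            "TMZ response classifier",
            "=" * 47,
            f"samples:             {len(self.probability)}",
            f"features:            {len(self.model.schema.columns)}"
            f"  (schema {self.model.schema.hash})",
            f"training ROC AUC:    {self.train_auc:.3f}",
            f"5-fold CV ROC AUC:   {self.cv_auc:.3f}",
            f"training concordance:{self.concordance:7.3f} "
            f"({np.diag(self.confusion.values).sum()}/{self.confusion.values.sum()})",
            f"probability cutoff:  {self.model.cutoff:.2f}",
            "",
            "confusion (rows = truth, cols = prediction):",
            self.confusion.to_string(),
            "",
            "top features by gain:",
            self.importances.sort_values(ascending=False).head(5).to_string(),
        ]
        return "\n".join(lines)


class TmzResponseModel:
    """Boosted-tree TMZ-response model over an imputed feature table.

    Parameters
    ----------
    table : DataFrame
        Imputed feature table (samples x schema columns).
    labels : Series
        'resistant' / 'sensitive' per sample.
    schema : FeatureSchema
    hyperparameters : dict
        Boosted-tree settings; defaults to the published configuration.
    cutoff : float
        Resistance-probability cutoff (boundary inclusive).
    seed : int
    """

    def __init__(
        self,
        table: pd.DataFrame,
        labels: pd.Series,
        schema: FeatureSchema = DEFAULT_SCHEMA,
        hyperparameters: dict | None = None,
        cutoff: float = PROBABILITY_CUTOFF,
        seed: int = 0,
    ):
        missing_cols = [c for c in schema.columns if c not in table.columns]
        if missing_cols:
            raise ValueError(f"table lacks schema columns: {missing_cols}")
        if table[schema.columns].isna().any().any():
            raise ValueError("feature table contains missing values; impute first")
        self.table = table[schema.columns]
        self.labels = labels.reindex(table.index)
        if set(self.labels.unique()) != {"resistant", "sensitive"}:
            raise ValueError("labels must contain both 'resistant' and 'sensitive'")
        self.schema = schema
        self.hyperparameters = dict(DEFAULT_HYPERPARAMETERS, **(hyperparameters or {}))
        self.cutoff = cutoff
        self.seed = seed
        self.booster_: XGBClassifier | None = None

    def _make_booster(self) -> XGBClassifier:
        return XGBClassifier(
            objective="binary:logistic",
            random_state=self.seed,
            n_jobs=1,
            **self.hyperparameters,
        )

    def fit(self) -> TmzResponseResults:
        y = (self.labels == "resistant").astype(int).values
        X = self.table.values
        self.booster_ = self._make_booster()
        self.booster_.fit(X, y)

        proba = pd.Series(
            self.booster_.predict_proba(X)[:, 1], index=self.table.index,
            name="p_resistant",
        )
        label = pd.Series(
            np.where(proba >= self.cutoff, "resistant", "sensitive"),
            index=self.table.index, name="predicted",
        )
        train_auc = float(roc_auc_score(y, proba))

        fold_aucs = []
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=self.seed)
        for train_idx, test_idx in skf.split(X, y):
            if len(np.unique(y[test_idx])) < 2:
                continue
            b = self._make_booster()
            b.fit(X[train_idx], y[train_idx])
            fold_aucs.append(
                float(roc_auc_score(y[test_idx], b.predict_proba(X[test_idx])[:, 1]))
            )

        truth = self.labels
        confusion = pd.crosstab(truth, label).reindex(
            index=["resistant", "sensitive"], columns=["resistant", "sensitive"],
            fill_value=0,
        )
        gain = self.booster_.get_booster().get_score(importance_type="gain")
        importances = pd.Series(
            {c: gain.get(f"f{i}", 0.0) for i, c in enumerate(self.schema.columns)},
            name="gain",
        )
        return TmzResponseResults(
            model=self,
            probability=proba,
            label=label,
            train_auc=train_auc,
            cv_auc=float(np.mean(fold_aucs)),
            cv_fold_aucs=fold_aucs,
            confusion=confusion,
            importances=importances,
        )

    def predict(self, table: pd.DataFrame) -> pd.DataFrame:
        """Resistance probability and label for new (imputed) rows."""
        if self.booster_ is None:
            raise ValueError("model is not fitted; call fit() first")
        missing_cols = [c for c in self.schema.columns if c not in table.columns]
        if missing_cols:
            raise ValueError(f"schema mismatch, missing columns: {missing_cols}")
        X = table[self.schema.columns].values
        proba = self.booster_.predict_proba(X)[:, 1]
        return pd.DataFrame(
            {
                "p_resistant": proba,
                "predicted": np.where(
                    proba >= self.cutoff, "resistant", "sensitive"
                ),
            },
            index=table.index,
        )


def train_classifier(
    table: pd.DataFrame,
    labels: pd.Series,
    schema: FeatureSchema = DEFAULT_SCHEMA,
    hyperparameters: dict | None = None,
    seed: int = 0,
) -> tuple[TmzResponseModel, TmzResponseResults]:
    """Convenience wrapper: build the model, fit it, return both."""
    model = TmzResponseModel(
        table, labels, schema=schema, hyperparameters=hyperparameters, seed=seed
    )
    return model, model.fit()


def predict_response(model: TmzResponseModel, table: pd.DataFrame) -> pd.DataFrame:
    return model.predict(table)


def evaluate_model(results: TmzResponseResults) -> dict:
    """Metrics report as a plain dict (JSON-serialisable)."""
    return {
        "train_auc": results.train_auc,
        "cv_auc": results.cv_auc,
        "cv_fold_aucs": results.cv_fold_aucs,
        "concordance": results.concordance,
        "confusion": results.confusion.values.tolist(),
        "importances": results.importances.to_dict(),
    }
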