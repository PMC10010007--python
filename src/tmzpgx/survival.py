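"""Survival and association statistics for the clinical analyses.

Kaplan-Meier curves with (multivariate) log-rank tests, Cox proportional
hazards with Efron tie handling (univariate or multivariate, reproducing
the age / gender / MGMT methylation / extent-of-resection / in vitro
sensitivity design), and the four association tests used throughout:
Fisher's exact (hypergeometric, two-sided), Wilcoxon rank-sum, Welch's
t-test and Spearman rank correlation.  Estimation is delegated to lifelines
and scipy; this module fixes the conventions (two-sided tests, censoring
flag 0, Efron ties) and the result containers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "SurvivalRecord",
    "KmLogrankResult",
    "km_logrank",
    "CoxResult",
    "cox_ph",
    "association_tests",
]


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    time: float  # months
    event: int  # 1 = progression/death observed, 0 = censored
    group: str

    def __post_init__(self):
        if self.time <= 0:
            raise ValueError(f"{self.patient_id}: time must be positive")
        if self.event not in (0, 1):
            raise ValueError(f"{self.patient_id}: event must be 0 or 1")


@dataclass
class KmLogrankResult:
    curves: dict[str, pd.DataFrame]  # per-group KM estimate (timeline, survival)
    statistic: float
    p_value: float
    degenerate: bool  # True when some group had no events

    def summary(self) -> str:
        head = [f"log-rank chi2 = {self.statistic:.4f}, p = {self.p_value:.3g}"]
        if self.degenerate:
            head.append("(degenerate: a group has no observed events)")
        for g, c in self.curves.items():
            head.append(f"  {g}: n timepoints = {len(c)}")
        return "\n".join(head)


def km_logrank(records: list[SurvivalRecord]) -> KmLogrankResult:
    """Product-limit curves per group plus the (multivariate) log-rank test."""
    df = pd.DataFrame(
        {
            "time": [r.time for r in records],
            "event": [r.event for r in records],
            "group": [r.group for r in records],
        }
    )
    groups = df["group"].unique()
    if len(groups) < 2:
        raise ValueError("log-rank needs >= 2 groups")
    if df["event"].sum() < 1:
        raise ValueError("log-rank needs >= 1 observed event")

    curves = {}
    degenerate = False
    for g, sub in df.groupby("group"):
        if sub["event"].sum() == 0:
            degenerate = True
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(g))
        curves[g] = kmf.survival_function_.rename(columns={str(g): "survival"})

    test = multivariate_logrank_test(df["time"], df["group"], df["event"])
    return KmLogrankResult(
        curves=curves,
        statistic=float(test.test_statistic),
        p_value=float(test.p_value),
        degenerate=degenerate,
    )


@dataclass
class CoxResult:
    table: pd.DataFrame  # hr, ci_lower, ci_upper, p per covariate
    fitter: CoxPHFitter

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "hr"])

    def summary(self) -> str:
        return self.table.to_string(float_format=lambda v: f"{v:.4g}")


def cox_ph(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str],
    ties: str = "efron",
) -> CoxResult:
    """Cox proportional-hazards fit with HRs, 95% CIs and Wald p-values.

    ``data`` holds one row per patient with numeric covariate encodings.
    Raises a ConvergenceError (from lifelines) with diagnostics when the
    partial likelihood cannot be maximised, e.g. under complete separation.
    """
    n_events = int(data[event_col].sum())
    if n_events < len(covariates) + 1:
        raise ValueError(
            f"{n_events} events cannot support {len(covariates)} covariates"
        )
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(
            data[[duration_col, event_col] + covariates],
            duration_col=duration_col,
            event_col=event_col,
        )
    s = cph.summary
    table = pd.DataFrame(
        {
            "hr": s["exp(coef)"],
            "ci_lower": s["exp(coef) lower 95%"],
            "ci_upper": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    return CoxResult(table=table, fitter=cph)


def association_tests(x, y, test: str) -> tuple[float, float]:
    """Two-sided association test; returns (statistic, p_value).

    test='fisher'   : x is a 2x2 contingency table (y ignored)
    test='wilcoxon' : rank-sum of two independent samples x, y
    test='ttest'    : Welch two-sample t-test of x, y
    test='spearman' : rank correlation of paired x, y
    """
    if test == "fisher":
        table = np.asarray(x)
        if table.shape != (2, 2):
            raise ValueError("fisher expects a 2x2 table")
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            raise ValueError("fisher table has an empty margin")
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return float(odds), float(p)
    if test == "wilcoxon":
        stat, p = stats.ranksums(x, y)
        return float(stat), float(p)
    if test == "ttest":
        stat, p = stats.ttest_ind(x, y, equal_var=False)
        return float(stat), float(p)
    if test == "spearman":
        rho, p = stats.spearmanr(x, y)
        return float(rho), float(p)
    raise ValueError(f"unknown test {test!r}")
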