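"""Expression normalisation, conserved-gene filtering and marker selection.

The marker-discovery chain: raw gene counts are converted to RPKM, log2(x+1)
transformed and quantile normalised; genes whose expression is conserved
between cultured stem-like cells and the originating tumor tissue are kept
(per-gene Spearman correlation across matched pairs, split into conserved /
non-conserved components by a two-Gaussian mixture); differential expression
between resistant and sensitive tumors is tested with a negative-binomial
Wald test (median-of-ratios size factors, method-of-moments dispersion with
a floor), and markers are the genes passing log2 fold change > 2.5 and
Benjamini-Hochberg adjusted P < 0.01, up in the resistant group.

Once markers exist, a sample is high-risk when any marker's cohort z-score
exceeds 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

__all__ = [
    "normalize_expression",
    "rpkm",
    "quantile_normalize",
    "ConservationResult",
    "conserved_gene_filter",
    "fit_conservation_mixture",
    "MarkerResult",
    "differential_markers",
    "marker_risk_score",
    "LOG2FC_CUTOFF",
    "ADJ_P_CUTOFF",
]

LOG2FC_CUTOFF = 2.5
ADJ_P_CUTOFF = 0.01
DISPERSION_FLOOR = 1e-4


def rpkm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Reads Per Kilobase per Million mapped reads.

    RPKM = count * 1e9 / (gene_length_bp * library_size).
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()[:5]
        raise ValueError(f"gene lengths missing for {missing} ...")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        raise ValueError("zero library size")
    return counts * 1e9 / np.outer(lengths, libsize)


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Map each sample's ranks onto the mean sorted profile.

    After normalisation every column holds the same multiset of values; ties
    within a column receive the mean of the reference values they span.
    """
    ranks = values.rank(method="average")
    reference = np.sort(values.values, axis=0).mean(axis=1)

    def _map(col_ranks):
        # average rank r maps to mean of reference values at the tied positions
        lo = np.floor(col_ranks).astype(int) - 1
        hi = np.ceil(col_ranks).astype(int) - 1
        return (reference[lo] + reference[hi]) / 2.0

    out = {c: _map(ranks[c].values) for c in values.columns}
    return pd.DataFrame(out, index=values.index)


def normalize_expression(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Counts -> RPKM -> log2(x+1) -> quantile normalisation."""
    return quantile_normalize(np.log2(rpkm(counts, gene_lengths) + 1.0))


@dataclass
class ConservationResult:
    """Per-gene conservation correlations and the fitted mixture split."""

    rho: pd.Series
    means: np.ndarray  # component means, ascending
    variances: np.ndarray
    weights: np.ndarray
    threshold: float | None  # None when the mixture is not separable
    conserved_genes: list[str]


def _posterior_crossing(means, variances, weights) -> float | None:
    """Point between the two component means where the posterior flips.

    Solves p(upper | x) = 0.5 for a two-component univariate Gaussian
    mixture; returns None if the posterior difference does not change sign
    between the means (degenerate mixture).
    """
    lo_m, hi_m = means

    def diff(x):
        d_lo = weights[0] * stats.norm.pdf(x, lo_m, np.sqrt(variances[0]))
        d_hi = weights[1] * stats.norm.pdf(x, hi_m, np.sqrt(variances[1]))
        return d_hi - d_lo

    if diff(lo_m) * diff(hi_m) >= 0:
        return None
    return float(brentq(diff, lo_m, hi_m))


def conserved_gene_filter(
    culture_counts: pd.DataFrame,
    tissue_counts: pd.DataFrame,
    random_state: int = 0,
) -> ConservationResult:
    """Identify genes with conserved culture<->tissue expression.

    Per-gene Spearman correlation of log2-transformed raw counts across the
    matched pairs (columns aligned by position: pair i is column i in both
    matrices), then an EM fit of a two-component Gaussian mixture on the
    correlation distribution.  Conserved genes are those above the posterior
    0.5 crossing between the component means.
    """
    if culture_counts.shape[1] != tissue_counts.shape[1]:
        raise ValueError("paired matrices need the same number of samples")
    if culture_counts.shape[1] < 5:
        raise ValueError("need >= 5 matched pairs")
    genes = culture_counts.index.intersection(tissue_counts.index)
    a = np.log2(culture_counts.loc[genes].values + 1.0)
    b = np.log2(tissue_counts.loc[genes].values + 1.0)

    constant = (a.std(axis=1) == 0) | (b.std(axis=1) == 0)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant genes excluded from the "
            "conservation correlation",
            stacklevel=2,
        )
    keep = genes[~constant]
    ra = pd.DataFrame(a[~constant], index=keep).rank(axis=1).values
    rb = pd.DataFrame(b[~constant], index=keep).rank(axis=1).values
    ra = (ra - ra.mean(axis=1, keepdims=True)) / ra.std(axis=1, keepdims=True)
    rb = (rb - rb.mean(axis=1, keepdims=True)) / rb.std(axis=1, keepdims=True)
    rho = pd.Series((ra * rb).mean(axis=1), index=keep, name="spearman_rho")
    return fit_conservation_mixture(rho, random_state=random_state)


def fit_conservation_mixture(
    rho: pd.Series, random_state: int = 0
) -> ConservationResult:
    """Two-component Gaussian mixture split of a correlation distribution.

    The conservation threshold is the posterior-0.5 crossing between the
    component means; genes above it are conserved.  A mixture whose
    posterior never flips between the means (or whose minor component is
    vestigial) is reported as not separable: threshold None, no genes kept.
    """
    gmm = GaussianMixture(n_components=2, random_state=random_state, max_iter=500)
    gmm.fit(rho.values.reshape(-1, 1))
    if not gmm.converged_:
        raise RuntimeError(
            f"mixture EM did not converge (lower bound {gmm.lower_bound_:.4f})"
        )
    order = np.argsort(gmm.means_.ravel())
    means = gmm.means_.ravel()[order]
    variances = gmm.covariances_.ravel()[order]
    weights = gmm.weights_.ravel()[order]

    threshold = _posterior_crossing(means, variances, weights)
    # degenerate mixture: vestigial component, or modes closer than two
    # pooled SDs (EM will happily split a unimodal sample in two)
    separation = (means[1] - means[0]) / np.sqrt(variances.mean())
    if threshold is None or min(weights) < 0.01 or separation < 2.0:
        return ConservationResult(rho, means, variances, weights, None, [])
    conserved = rho.index[rho > threshold].tolist()
    return ConservationResult(rho, means, variances, weights, threshold, conserved)


@dataclass
class MarkerResult:
    """Differential-expression table and the selected marker list."""

    table: pd.DataFrame  # log2_fc, wald_stat, pvalue, padj per gene
    markers: list[str]


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """DESeq-style median-of-ratios size factors."""
    logc = np.log(counts + 0.5)
    ref = logc.mean(axis=1)
    usable = np.isfinite(ref)
    return np.exp(np.median(logc[usable] - ref[usable, None], axis=0))


def differential_markers(
    counts: pd.DataFrame,
    labels: pd.Series,
    log2fc_cutoff: float = LOG2FC_CUTOFF,
    padj_cutoff: float = ADJ_P_CUTOFF,
    test_genes: list[str] | None = None,
) -> MarkerResult:
    """Negative-binomial Wald test for resistant-vs-sensitive expression.

    Size factors are median-of-ratios over all genes; the per-gene dispersion
    is a method-of-moments estimate pooled across groups with a small floor.
    The Wald statistic tests the log2 fold change (resistant over sensitive)
    of size-factor-normalised group means, with a delta-method standard
    error from the NB variance mu + alpha*mu^2.  P-values are BH-adjusted.
    Markers are genes with log2FC > ``log2fc_cutoff`` (resistant up) and
    adjusted P < ``padj_cutoff``.

    ``test_genes`` restricts testing (e.g. to the conserved set) while size
    factors stay estimated from all genes.
    """
    labels = labels.reindex(counts.columns)
    groups = {}
    for lab in ("resistant", "sensitive"):
        cols = labels.index[labels == lab]
        if len(cols) < 3:
            raise ValueError(f"group '{lab}' has fewer than 3 samples")
        groups[lab] = cols

    sf = pd.Series(_size_factors(counts.values.astype(float)), index=counts.columns)
    norm = counts / sf

    sub = counts.loc[test_genes] if test_genes is not None else counts
    norm_sub = norm.loc[sub.index]

    res_cols, sen_cols = groups["resistant"], groups["sensitive"]
    mu_r = norm_sub[res_cols].mean(axis=1)
    mu_s = norm_sub[sen_cols].mean(axis=1)

    # pooled method-of-moments dispersion: Var(K/s) ~ mu/s_bar + alpha*mu^2
    alpha = pd.Series(0.0, index=sub.index)
    n_terms = pd.Series(0.0, index=sub.index)
    for cols in (res_cols, sen_cols):
        x = norm_sub[cols]
        mu = x.mean(axis=1)
        var = x.var(axis=1, ddof=1)
        mean_inv_s = (1.0 / sf[cols]).mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (var - mu * mean_inv_s) / mu**2
        ok = np.isfinite(a)
        alpha[ok] += a[ok] * (len(cols) - 1)
        n_terms[ok] += len(cols) - 1
    alpha = (alpha / n_terms.replace(0, np.nan)).fillna(DISPERSION_FLOOR)
    alpha = alpha.clip(lower=DISPERSION_FLOOR)

    # delta-method SE of log2(mu_r / mu_s)
    eps = 0.5
    var_log = pd.Series(0.0, index=sub.index)
    for mu, cols in ((mu_r, res_cols), (mu_s, sen_cols)):
        v_each = mu * (1.0 / sf[cols]).mean() + alpha * mu**2
        v_mean = v_each / len(cols)
        var_log += v_mean / np.maximum(mu, eps) ** 2
    se_log2 = np.sqrt(var_log) / np.log(2.0)

    log2_fc = np.log2((mu_r + eps) / (mu_s + eps))
    wald = log2_fc / se_log2.replace(0, np.nan)
    pvalue = pd.Series(
        2.0 * stats.norm.sf(np.abs(wald.fillna(0.0))), index=sub.index
    )
    padj = pd.Series(
        multipletests(pvalue.values, method="fdr_bh")[1], index=sub.index
    )

    table = pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "dispersion": alpha,
            "wald_stat": wald,
            "pvalue": pvalue,
            "padj": padj,
        }
    )
    selected = table.index[
        (table.log2_fc > log2fc_cutoff) & (table.padj < padj_cutoff)
    ].tolist()
    return MarkerResult(table=table, markers=selected)


def marker_risk_score(
    expression: pd.DataFrame, marker_genes: list[str], z_cutoff: float = 2.0
) -> pd.Series:
    """High/low risk per sample: high when any marker's cohort z exceeds 2.

    ``expression`` is genes x samples (normalised scale); markers with zero
    cohort variance are skipped with a warning.
    """
    present = [g for g in marker_genes if g in expression.index]
    if not present:
        raise ValueError("none of the marker genes are in the expression matrix")
    sub = expression.loc[present]
    sd = sub.std(axis=1, ddof=1)
    if (sd == 0).any():
        warnings.warn(
            f"zero-variance markers skipped: {sd.index[sd == 0].tolist()}",
            stacklevel=2,
        )
        sub = sub.loc[sd > 0]
        sd = sd[sd > 0]
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    high = (z > z_cutoff).any(axis=0)
    return high.map({True: "high", False: "low"}).rename("risk")
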