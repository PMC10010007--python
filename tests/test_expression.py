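"""Normalisation, conserved-gene mixture filter, marker selection, risk rule."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tmzpgx.expression import (
    conserved_gene_filter,
    differential_markers,
    fit_conservation_mixture,
    marker_risk_score,
    normalize_expression,
    quantile_normalize,
    rpkm,
)
from tmzpgx.synthetic import simulate_expression_counts


class TestNormalization:
    def test_rpkm_hand_arithmetic(self):
        counts = pd.DataFrame({"s": [100.0, 10_000_000 - 100]}, index=["g1", "g2"])
        lengths = pd.Series([1000.0, 1000.0], index=["g1", "g2"])
        assert rpkm(counts, lengths).at["g1", "s"] == pytest.approx(10.0)

    def test_qnorm_identical_columns_stay_identical(self, rng):
        col = rng.lognormal(3, 1, 40)
        df = pd.DataFrame({"a": col, "b": col})
        out = quantile_normalize(df)
        pd.testing.assert_series_equal(out["a"], out["b"], check_names=False)

    def test_qnorm_columns_share_sorted_multiset(self, rng):
        df = pd.DataFrame(rng.lognormal(3, 1, (50, 4)))  # tie-free continuous
        out = quantile_normalize(df)
        ref = np.sort(out[0].values)
        for c in out.columns:
            np.testing.assert_allclose(np.sort(out[c].values), ref)

    def test_qnorm_rank_preserving_perturbation_invariance(self, rng):
        df = pd.DataFrame(rng.lognormal(3, 1, (50, 3)))
        out = quantile_normalize(df)
        warped = df.copy()
        warped[0] = np.exp(df[0] / df[0].max() * 3)  # monotone warp of one column
        out2 = quantile_normalize(warped)
        # identical ranks => identical mapping targets up to the reference
        pd.testing.assert_series_equal(
            out[0].rank(), out2[0].rank(), check_names=False
        )

    def test_full_chain_shape_and_state(self, small_cohort):
        _, bundle, _ = small_cohort
        norm = normalize_expression(bundle.counts, bundle.gene_lengths)
        assert norm.shape == bundle.counts.shape
        assert (norm >= 0).all().all()

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"s": [0, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError):
            rpkm(counts, pd.Series([100.0, 100.0], index=["g1", "g2"]))


class TestConservationFilter:
    def test_mixture_threshold_matches_analytic_crossing(self, rng):
        rho = pd.Series(
            np.concatenate(
                [rng.normal(0.0, 0.15, 2500), rng.normal(0.6, 0.15, 2500)]
            )
        )
        res = fit_conservation_mixture(rho)
        # equal weights and SDs: posterior crossing at the midpoint, 0.3
        assert res.threshold == pytest.approx(0.3, abs=0.07)

    def test_single_component_flagged_not_separable(self, rng):
        rho = pd.Series(rng.normal(0.5, 0.02, 500))
        res = fit_conservation_mixture(rho)
        assert res.threshold is None and res.conserved_genes == []

    def test_conserved_recovery_on_paired_matrices(self, rng):
        n_genes, n_pairs = 800, 12
        latent = rng.normal(5, 2, (n_genes, n_pairs))
        conserved = np.arange(n_genes) < 400
        a = np.where(conserved[:, None], latent + 0.5 * rng.normal(size=(n_genes, n_pairs)),
                     rng.normal(5, 2, (n_genes, n_pairs)))
        b = np.where(conserved[:, None], latent + 0.5 * rng.normal(size=(n_genes, n_pairs)),
                     rng.normal(5, 2, (n_genes, n_pairs)))
        res = conserved_gene_filter(pd.DataFrame(np.exp(a)), pd.DataFrame(np.exp(b)))
        picked = np.isin(np.arange(n_genes), res.conserved_genes)
        assert picked[conserved].mean() > 0.9
        assert picked[~conserved].mean() < 0.1

    def test_spearman_invariant_to_monotone_transform(self, rng):
        a = pd.DataFrame(rng.lognormal(3, 1, (50, 8)))
        b = pd.DataFrame(rng.lognormal(3, 1, (50, 8)))
        r1 = conserved_gene_filter(a, b).rho
        r2 = conserved_gene_filter(a**3, b).rho  # monotone on one member
        np.testing.assert_allclose(r1.values, r2.values, atol=1e-12)

    def test_too_few_pairs_rejected(self, rng):
        a = pd.DataFrame(rng.lognormal(3, 1, (20, 4)))
        with pytest.raises(ValueError):
            conserved_gene_filter(a, a)


class TestDifferentialMarkers:
    def test_null_simulation_selects_at_most_one(self):
        rng = np.random.default_rng(7)
        counts, labs = simulate_expression_counts(2000, (12, 22), dispersion=0.1, rng=rng)
        labels = labs.map({"a": "resistant", "b": "sensitive"})
        res = differential_markers(counts, labels)
        assert len(res.markers) <= 1

    def test_spiked_genes_all_recovered(self):
        rng = np.random.default_rng(8)
        spiked = {5: 3.0, 105: 3.0, 505: 3.0, 1005: 3.0}
        counts, labs = simulate_expression_counts(
            2000, (12, 22), spiked_genes=spiked, dispersion=0.1, rng=rng
        )
        labels = labs.map({"a": "resistant", "b": "sensitive"})
        res = differential_markers(counts, labels)
        assert set(res.markers) == set(spiked)

    def test_direction_is_resistant_over_sensitive(self):
        rng = np.random.default_rng(9)
        counts, labs = simulate_expression_counts(
            500, (10, 10), spiked_genes={3: 3.0}, dispersion=0.05, rng=rng
        )
        # spike is in group 'a'; labelling 'a' sensitive must NOT select it
        labels = labs.map({"a": "sensitive", "b": "resistant"})
        assert 3 not in differential_markers(counts, labels).markers

    def test_small_group_rejected(self, rng):
        counts = pd.DataFrame(rng.integers(0, 100, (50, 5)).astype(float))
        labels = pd.Series(["resistant"] * 2 + ["sensitive"] * 3, index=counts.columns)
        with pytest.raises(ValueError, match="fewer than 3"):
            differential_markers(counts, labels)

    def test_bh_adjustment_monotone(self):
        rng = np.random.default_rng(10)
        counts, labs = simulate_expression_counts(300, (6, 6), rng=rng)
        labels = labs.map({"a": "resistant", "b": "sensitive"})
        t = differential_markers(counts, labels).table.sort_values("pvalue")
        assert (t.padj >= t.pvalue - 1e-12).all()
        assert t.padj.is_monotonic_increasing or (
            t.padj.diff().dropna() >= -1e-12
        ).all()


class TestMarkerRisk:
    def test_all_identical_all_low(self):
        m = pd.DataFrame(1.0, index=["EGR4"], columns=list("abcd"))
        # constant marker is skipped -> no marker left to exceed the cutoff
        with pytest.warns(UserWarning):
            risk = marker_risk_score(m, ["EGR4"])
        assert (risk == "low").all()

    def test_outlier_sample_flagged_high(self):
        rng = np.random.default_rng(11)
        m = pd.DataFrame(
            rng.normal(5, 1, (2, 30)), index=["EGR4", "ANXA3"],
            columns=[f"s{i}" for i in range(30)],
        )
        m.loc["EGR4", "s0"] = m.loc["EGR4"].mean() + 10 * m.loc["EGR4"].std()
        risk = marker_risk_score(m, ["EGR4", "ANXA3"])
        assert risk["s0"] == "high"

    def test_count_matches_brute_force(self, rng):
        m = pd.DataFrame(rng.normal(0, 1, (4, 60)),
                         index=["EGR4", "PAPPA", "LRRC3", "ANXA3"],
                         columns=[f"s{i}" for i in range(60)])
        risk = marker_risk_score(m, list(m.index))
        z = stats.zscore(m.values, axis=1, ddof=1)
        expected = (z > 2).any(axis=0)
        assert (risk.values == np.where(expected, "high", "low")).all()

    def test_affine_rescaling_invariance(self, rng):
        m = pd.DataFrame(rng.normal(0, 1, (2, 40)), index=["EGR4", "PAPPA"])
        r1 = marker_risk_score(m, ["EGR4", "PAPPA"])
        r2 = marker_risk_score(m * 7.5 + 3.0, ["EGR4", "PAPPA"])
        pd.testing.assert_series_equal(r1, r2)

    def test_absent_markers_rejected(self, rng):
        m = pd.DataFrame(rng.normal(0, 1, (2, 10)), index=["a", "b"])
        with pytest.raises(ValueError):
            marker_risk_score(m, ["EGR4"])
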