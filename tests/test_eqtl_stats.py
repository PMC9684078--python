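"""Somatic eQTL regression screen and contingency statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clonescape.eqtl_stats import EQTLModel, classify_clonality, \
    clonality_proportion_test, direction_test, eligible_combinations, \
    enrichment_fisher, filter_expressed, fit_eqtl, required_n, screen, \
    storey_pi0, validate_external, zscore
from clonescape.synthetic_data import make_eqtl_cohort


class TestFilterExpressed:
    def test_gene_at_threshold_in_exactly_five_percent_kept(self):
        tpm = pd.DataFrame(np.zeros((1, 100)), index=["g"])
        tpm.iloc[0, :5] = 10.0
        assert filter_expressed(tpm) == ["g"]

    def test_all_zero_gene_dropped(self):
        tpm = pd.DataFrame(np.zeros((1, 10)), index=["g"])
        assert filter_expressed(tpm) == []

    def test_single_sample_cohort(self):
        tpm = pd.DataFrame([[10.0]], index=["g"])
        assert filter_expressed(tpm) == ["g"]


class TestZscore:
    def test_rows_standardized(self, rng):
        x = pd.DataFrame(rng.normal(5, 3, size=(4, 30)))
        z, flagged = zscore(x)
        assert flagged == []
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=0), 1, atol=1e-12)

    def test_affine_invariance(self, rng):
        x = pd.DataFrame(rng.normal(size=(2, 20)))
        z1, _ = zscore(x)
        z2, _ = zscore(4.0 * x + 3.0)
        pd.testing.assert_frame_equal(z1, z2)

    def test_constant_gene_flagged(self):
        x = pd.DataFrame([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]],
                         index=["flat", "var"])
        z, flagged = zscore(x)
        assert flagged == ["flat"]
        assert z.loc["flat"].isna().all()


class TestEligibility:
    def links(self):
        return pd.DataFrame({
            "locus": ["L1", "L2", "L2", "L3"],
            "gene": ["G1", "G2", "G3", "G1"],
            "class": ["non_synonymous", "enhancer", "enhancer",
                      "non_synonymous"]})

    def test_min_two_mutated_samples(self):
        mut = pd.DataFrame([[1, 0, 0], [1, 1, 0], [1, 1, 1]],
                           index=["L1", "L2", "L3"])
        out = eligible_combinations(mut, self.links())
        assert "L1" not in set(out["locus"])  # single carrier excluded
        assert {"L2", "L3"} <= set(out["locus"])

    def test_locus_linked_to_two_genes_yields_two_combinations(self):
        mut = pd.DataFrame([[1, 1, 0]], index=["L2"])
        out = eligible_combinations(mut, self.links())
        assert len(out) == 2
        assert set(out["gene"]) == {"G2", "G3"}


class TestFit:
    def test_noiseless_mutation_effect_recovered_exactly(self):
        mutv = np.array([1, 1, 0, 0, 1, 0, 0, 1], dtype=float)
        design = pd.DataFrame({
            "Exp": 2.0 * mutv, "Mut": mutv,
            "CNA": np.full(8, 2.0), "Purity": np.zeros(8),
            "Tumour": np.zeros(8)})
        fit = fit_eqtl(design)
        assert fit.params["Mut"] == pytest.approx(2.0)
        assert fit.rsquared == pytest.approx(1.0)

    def test_null_f_pvalues_uniform(self, rng):
        ps = []
        for _ in range(400):
            n = 40
            design = pd.DataFrame({
                "Exp": rng.normal(size=n),
                "Mut": rng.integers(0, 2, n).astype(float),
                "CNA": rng.choice([1.0, 2.0, 3.0], n),
                "Purity": rng.uniform(0.2, 0.9, n),
                "Tumour": np.ones(n)})
            ps.append(fit_eqtl(design).f_pvalue)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_cna_slope_recovery(self, rng):
        hits = 0
        for _ in range(40):
            n = 40
            cna = rng.choice([1.0, 2.0, 3.0, 4.0], n)
            design = pd.DataFrame({
                "Exp": 0.3 * cna + rng.normal(0, 0.5, n),
                "Mut": rng.integers(0, 2, n).astype(float),
                "CNA": cna, "Purity": rng.uniform(0.2, 0.9, n),
                "Tumour": np.ones(n)})
            fit = fit_eqtl(design)
            if abs(fit.params["CNA"] - 0.3) < 0.25:
                hits += 1
        assert hits >= 34  # ~95% within +-0.25

    def test_too_few_observations_flagged(self):
        design = pd.DataFrame({
            "Exp": [1.0, 2.0], "Mut": [0.0, 1.0], "CNA": [2.0, 2.0],
            "Purity": [0.5, 0.6], "Tumour": [1.0, 1.0]})
        assert "few" in fit_eqtl(design).status

    def test_collinear_design_flagged(self):
        n = 10
        mutv = np.arange(n) % 2.0
        design = pd.DataFrame({
            "Exp": np.random.default_rng(0).normal(size=n),
            "Mut": mutv, "CNA": 2 + mutv,  # CNA collinear with Mut
            "Purity": mutv * 0.5, "Tumour": np.ones(n)})
        fit = fit_eqtl(design)
        assert fit.status == "rank deficient"


class TestScreen:
    def test_fully_null_cohort_calibration(self):
        coh = make_eqtl_cohort(n_genes=300, mut_effect=0.0,
                               cna_effect=0.0, purity_effect=0.0,
                               tumour_effect=0.0, seed=5)
        z, _ = zscore(coh.expression)
        combos = eligible_combinations(coh.mut, coh.links)
        scr = screen(combos, z, coh.mut, coh.cna, coh.purity,
                     coh.tumour_of != "normal")
        assert scr.table["explained"].mean() <= 0.02
        assert scr.pi0 > 0.8

    def test_planted_cohort_nearly_all_flagged(self):
        coh = make_eqtl_cohort(n_genes=80, mut_effect=2.5,
                               cna_effect=0.5, seed=6)
        z, _ = zscore(coh.expression)
        combos = eligible_combinations(coh.mut, coh.links)
        scr = screen(combos, z, coh.mut, coh.cna, coh.purity,
                     coh.tumour_of != "normal")
        assert scr.table["explained"].mean() > 0.9
        assert scr.pi0 < 0.2

    def test_flags_recomputable_from_stored_pvalues(self):
        coh = make_eqtl_cohort(n_genes=60, mut_effect=1.0, seed=7)
        z, _ = zscore(coh.expression)
        combos = eligible_combinations(coh.mut, coh.links)
        scr = screen(combos, z, coh.mut, coh.cna, coh.purity,
                     coh.tumour_of != "normal")
        tab = scr.table
        assert (tab["explained"] == (tab["f_fdr"] < 0.01)).all()
        assert (tab["sig_Mut"] == (tab["fdr_Mut"] < 0.05)).all()


class TestClonality:
    def test_present_in_all_matched_samples_is_clonal(self):
        mut = pd.DataFrame([[1, 1, 1, 0, 0]], index=["L"],
                           columns=["a1", "a2", "a3", "b1", "b2"])
        tum = pd.Series(["A", "A", "A", "B", "B"],
                        index=mut.columns)
        assert classify_clonality(mut, tum)["L"] == "clonal"

    def test_partial_tumour_is_subclonal(self):
        mut = pd.DataFrame([[1, 1, 0]], index=["L"],
                           columns=["a1", "a2", "a3"])
        tum = pd.Series(["A", "A", "A"], index=mut.columns)
        assert classify_clonality(mut, tum)["L"] == "subclonal"

    def test_clonal_in_one_tumour_partial_in_other_is_subclonal(self):
        mut = pd.DataFrame([[1, 1, 1, 0]], index=["L"],
                           columns=["a1", "a2", "b1", "b2"])
        tum = pd.Series(["A", "A", "B", "B"], index=mut.columns)
        assert classify_clonality(mut, tum)["L"] == "subclonal"


class TestContingency:
    def test_direction_test_printed_values(self):
        assert direction_test(486, 258) == pytest.approx(6.3e-17,
                                                         rel=0.02)
        assert round(direction_test(33, 27), 1) == 0.4

    def test_direction_symmetric(self):
        assert direction_test(50, 50) == pytest.approx(1.0)
        assert direction_test(30, 70) == direction_test(70, 30)

    def test_direction_requires_observations(self):
        with pytest.raises(ValueError):
            direction_test(0, 0)

    def test_clonality_proportion_printed_value(self):
        assert clonality_proportion_test(89, 3705, 688, 19256) == \
            pytest.approx(3.7e-4, rel=0.02)

    def test_clonality_proportion_symmetry_and_null(self):
        assert clonality_proportion_test(89, 3705, 688, 19256) == \
            clonality_proportion_test(688, 19256, 89, 3705)
        assert clonality_proportion_test(500, 1000, 5000, 10000) > 0.9

    def test_fisher_balanced_table(self):
        orr, p, status = enrichment_fisher(10, 10, 10, 10)
        assert orr == 1.0 and p == 1.0 and status == "ok"

    def test_fisher_matches_hypergeometric_enumeration(self):
        orr, p, _ = enrichment_fisher(8, 2, 2, 8)
        # enumerate all tables with the same margins
        total = 0.0
        obs = stats.hypergeom.pmf(8, 20, 10, 10)
        for a in range(11):
            prob = stats.hypergeom.pmf(a, 20, 10, 10)
            if prob <= obs * (1 + 1e-9):
                total += prob
        assert p == pytest.approx(total)
        assert orr == pytest.approx(16.0)

    def test_fisher_zero_cell_flagged(self):
        orr, p, status = enrichment_fisher(5, 0, 3, 7)
        assert "haldane" in status
        assert orr > 1


class TestValidation:
    def make_cohort(self, beta, n=80, seed=0):
        r = np.random.default_rng(seed)
        mut = pd.Series(r.integers(0, 2, n).astype(float))
        purity = pd.Series(r.uniform(0.3, 0.9, n))
        exp = pd.Series(beta * mut + 0.5 * purity + r.normal(0, 1, n))
        return exp, mut, purity

    def test_same_sign_effect_validates(self):
        hits = 0
        for seed in range(20):
            exp, mut, purity = self.make_cohort(1.5, seed=seed)
            out = validate_external(1.9, exp, mut, purity)
            hits += out["validated"]
        assert hits >= 16

    def test_opposite_sign_never_validates(self):
        exp, mut, purity = self.make_cohort(-2.0, seed=1)
        out = validate_external(+1.9, exp, mut, purity)
        assert out["p"] < 0.05 and not out["validated"]

    def test_null_effect_type_one_rate(self):
        hits = sum(validate_external(
            1.0, *self.make_cohort(0.0, seed=s))["validated"]
            for s in range(60))
        assert hits <= 9  # ~2.5% expected (alpha/2 with the sign rule)

    def test_no_mutated_samples_untestable(self):
        exp = pd.Series([1.0, 2.0, 3.0])
        out = validate_external(1.0, exp, pd.Series([0, 0, 0]),
                                pd.Series([0.5, 0.5, 0.5]))
        assert "untestable" in out["status"]


class TestRequiredN:
    def test_effect_capped_at_304(self):
        assert required_n(5.0, 100) == required_n(3.04, 100)

    def test_monotone_decreasing_in_effect(self):
        ns = [required_n(e, 394) for e in (0.5, 1.0, 2.0, 3.0)]
        assert all(b < a for a, b in zip(ns, ns[1:]))

    def test_uninflated_solution_matches_power_inversion(self):
        # independent check: the returned n1 (inflation=1) achieves the
        # requested power under the noncentral-t formula
        n1 = required_n(1.0, 394, inflation=1.0)
        d, n2, alpha = 1.0, 394, 0.05
        df = n1 + n2 - 2
        ncp = d * np.sqrt(n1 * n2 / (n1 + n2))
        crit = stats.t.ppf(1 - alpha / 2, df)
        achieved = stats.nct.sf(crit, df, ncp) + stats.nct.cdf(-crit, df,
                                                               ncp)
        assert achieved == pytest.approx(0.99, abs=1e-6)

    def test_rejects_nonpositive_effect(self):
        with pytest.raises(ValueError):
            required_n(0.0, 100)


def test_storey_pi0_null_near_one(rng):
    assert storey_pi0(rng.uniform(size=2000)) > 0.9


def test_storey_pi0_with_signal_below_one(rng):
    p = np.concatenate([rng.uniform(size=1000),
                        rng.beta(0.1, 10, size=1000)])
    assert storey_pi0(p) < 0.75
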