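"""Pagel's lambda ML, forest aggregation, purity adjustment, power."""

import numpy as np
import pandas as pd
import pytest

from clonescape.phylo_signal import PagelLambda, forest_signal, \
    pagel_lambda_ml, power_sim, purity_adjust, recurrence
from clonescape.synthetic_data import default_gene_table, \
    simulate_expression
from clonescape.trees import CloneNode, CloneTree
from conftest import make_random_tree, make_star


@pytest.fixture(scope="module")
def tree20():
    return make_random_tree(20, np.random.default_rng(7))


class TestLambdaML:
    def test_iid_traits_give_low_lambda(self, tree20, rng):
        lams = []
        for _ in range(200):
            y = dict(zip(tree20.tip_names(), rng.normal(size=20)))
            lams.append(PagelLambda(tree20, y).fit().lam)
        assert np.median(lams) < 0.1

    def test_brownian_traits_give_high_lambda(self, tree20):
        gt = default_gene_table(n_heritable=1, n_plastic=0,
                                heritable_sd=1.0, residual_sd=0.05)
        lams = []
        for seed in range(100):
            expr, _ = simulate_expression(tree20, gt, seed=seed)
            lams.append(PagelLambda(tree20, expr.iloc[0]).fit().lam)
        assert np.median(lams) > 0.8

    def test_star_tree_flagged_non_identifiable(self):
        star = make_star("ABCDE")
        res = PagelLambda(star, {t: float(i) for i, t
                                 in enumerate(star.tip_names())}).fit()
        assert "non-identifiable" in res.status

    def test_constant_trait_flagged(self, tree20):
        res = PagelLambda(tree20,
                          {t: 1.0 for t in tree20.tip_names()}).fit()
        assert res.status == "constant trait"

    def test_affine_invariance_of_lambda(self, tree20, rng):
        y = dict(zip(tree20.tip_names(), rng.normal(size=20)))
        base = PagelLambda(tree20, y).fit()
        shifted = {k: 3.0 * v - 7.0 for k, v in y.items()}
        res = PagelLambda(tree20, shifted).fit()
        assert res.lam == pytest.approx(base.lam, abs=1e-4)
        assert res.pvalue == pytest.approx(base.pvalue, abs=1e-6)

    def test_lrt_nonnegative_and_p_valid(self, tree20, rng):
        for _ in range(20):
            y = dict(zip(tree20.tip_names(), rng.normal(size=20)))
            res = PagelLambda(tree20, y).fit()
            assert res.lrt >= 0
            assert 0 < res.pvalue <= 1

    def test_needs_four_tips(self):
        tree = make_random_tree(3, np.random.default_rng(0))
        with pytest.raises(ValueError):
            PagelLambda(tree, {t: 0.0 for t in tree.tip_names()})

    def test_ml_matches_dense_grid_oracle_on_five_tips(self, rng):
        from clonescape.phylo_signal import _profile_loglik

        for _ in range(5):
            tree = make_random_tree(5, rng)
            model = PagelLambda(tree, dict(zip(tree.tip_names(),
                                               rng.normal(size=5))))
            res = model.fit()
            grid = np.linspace(0, model.lam_max, 4001)
            oracle = max(_profile_loglik(model.y, model.c, lam)
                         for lam in grid)
            assert res.loglik >= oracle - 1e-4

    def test_matches_phytools_reference(self, tmp_path, tree20):
        # independent oracle: phytools::phylosig on a shared fixture
        import subprocess

        gt = default_gene_table(n_heritable=1, n_plastic=1,
                                heritable_sd=1.0, plastic_sd=1.0,
                                residual_sd=0.1)
        expr, _ = simulate_expression(tree20, gt, seed=5)
        (tmp_path / "tree.nwk").write_text(tree20.to_newick())
        expr.T.to_csv(tmp_path / "traits.csv")
        script = tmp_path / "check.R"
        script.write_text("""
            suppressMessages(library(phytools))
            args <- commandArgs(trailingOnly=TRUE)
            tr <- read.tree(file.path(args[1], "tree.nwk"))
            X <- read.csv(file.path(args[1], "traits.csv"), row.names=1)
            for (j in 1:ncol(X)) {
              x <- setNames(X[,j], rownames(X))
              r <- phylosig(tr, x, method="lambda", test=TRUE)
              cat(sprintf("%.6f %.6f\\n", r$lambda, r$logL))
            }
        """)
        out = subprocess.run(["Rscript", str(script), str(tmp_path)],
                             capture_output=True, text=True, check=True)
        ref = [tuple(map(float, line.split()))
               for line in out.stdout.strip().splitlines()]
        for (ref_lam, ref_ll), (_, row) in zip(ref, expr.iterrows()):
            res = PagelLambda(tree20, row).fit()
            assert res.loglik == pytest.approx(ref_ll, abs=1e-2)
            assert res.lam == pytest.approx(ref_lam, abs=0.02)


class TestForest:
    def test_identical_trees_equal_single_tree_medians(self, tree20):
        gt = default_gene_table(2, 2)
        expr, _ = simulate_expression(tree20, gt, seed=1)
        forest = [tree20.copy() for _ in range(5)]
        tab = forest_signal(forest, expr)
        for gene, row in expr.iterrows():
            single = PagelLambda(tree20, row).fit()
            assert tab.loc[gene, "med_lambda"] == pytest.approx(single.lam)
            assert tab.loc[gene, "med_pval"] == \
                pytest.approx(single.pvalue)

    def test_heritable_flagged_more_than_plastic(self, tree20):
        gt = default_gene_table(n_heritable=25, n_plastic=25,
                                heritable_sd=1.0, plastic_sd=1.0,
                                residual_sd=0.1)
        expr, truth = simulate_expression(tree20, gt, seed=2)
        forest = [tree20.copy() for _ in range(7)]
        tab = forest_signal(forest, expr)
        heritable = truth.loc[truth.lambda_true == 1, "gene"]
        plastic = truth.loc[truth.lambda_true == 0, "gene"]
        rate_h = tab.loc[heritable, "signal"].mean()
        rate_p = tab.loc[plastic, "signal"].mean()
        assert rate_h >= 5 * max(rate_p, 1e-9) or \
            (rate_h > 0.5 and rate_p == 0)

    def test_missing_expression_rejected(self, tree20):
        expr = pd.DataFrame(np.zeros((1, 3)),
                            columns=tree20.tip_names()[:3], index=["g"])
        with pytest.raises(ValueError):
            forest_signal([tree20], expr)


class TestPurityAdjust:
    def test_zero_coefficient_is_identity(self):
        x = np.array([1.0, 2.0])
        assert np.array_equal(purity_adjust(x, 0.0, np.array([0.5, 0.9])),
                              x)

    def test_printed_formula(self):
        assert purity_adjust(0.0, 1.0, 0.5) == 2.0
        assert purity_adjust(3.0, 0.7, 1.0) == pytest.approx(3.7)

    def test_nonpositive_purity_rejected(self):
        with pytest.raises(ValueError):
            purity_adjust(1.0, 1.0, 0.0)


class TestRecurrence:
    def make_tab(self, flags):
        return pd.DataFrame({"signal": flags},
                            index=[f"g{i}" for i in range(len(flags))])

    def test_three_of_eight_tumours_is_recurrent(self):
        results = {f"T{i}": self.make_tab([i < 3]) for i in range(8)}
        tab = recurrence(results, min_tumours=3)
        assert tab.loc["g0", "num_rec"] == 3
        assert bool(tab.loc["g0", "recurrent"])

    def test_two_tumours_not_recurrent(self):
        results = {f"T{i}": self.make_tab([i < 2]) for i in range(8)}
        tab = recurrence(results)
        assert not tab.loc["g0", "recurrent"]

    def test_empty_input_is_empty(self):
        assert recurrence({}).empty


class TestPowerSim:
    def test_power_increases_with_effect(self, tree20):
        forest = [tree20.copy() for _ in range(5)]
        clade = tree20.tip_names()[:8]
        tab = power_sim(forest, clade, effects=(0.0, 1.0, 3.0),
                        reps=40, seed=3)
        assert tab.power.iloc[0] <= 0.15
        assert tab.power.iloc[2] >= tab.power.iloc[1] - 0.1
        assert tab.power.iloc[2] > 0.5
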