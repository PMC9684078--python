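"""CCF estimation, binarization, Fitch parsimony, ratchet and acctran."""

import numpy as np
import pytest

from clonescape.phylo_build import BinaryCharacterMatrix, acctran_states, \
    attach_edge_mutations, binarize, enumerate_topologies, estimate_ccf, \
    parsimony_score, ratchet_search


def perfect_matrix():
    """Nested clades on 6 samples: a perfect phylogeny."""
    names = list("abcdef")
    cols = {"m1": "ab", "m2": "abc", "m3": "de", "m4": "abcdef",
            "m5": "a"}
    x = np.array([[1 if s in members else 0 for members in cols.values()]
                  for s in names])
    return names, list(cols), x


class TestCCF:
    def test_clonal_diploid_het(self):
        assert estimate_ccf(50, 100, 1.0) == pytest.approx(1.0)

    def test_purity_diluted(self):
        # vaf 0.25 at purity 0.5: 0.25 * (2-1+1) / 0.5 = 1.0
        assert estimate_ccf(25, 100, 0.5) == pytest.approx(1.0)

    def test_zero_reads(self):
        assert estimate_ccf(0, 100, 0.8) == 0.0

    def test_missing_when_uncovered(self):
        assert np.isnan(estimate_ccf(0, 0, 0.8))

    def test_clamped_to_1p5(self):
        assert estimate_ccf(100, 100, 0.3) == 1.5

    def test_bad_purity(self):
        with pytest.raises(ValueError):
            estimate_ccf(1, 2, 0.0)


class TestBinarize:
    def test_threshold_is_strict(self):
        mat = binarize(np.array([[0.25, 0.26], [0.0, 1.0]]), ["s1", "s2"],
                       ["m1", "m2"], drop_constant=False)
        assert mat.matrix[0, 0] == 0  # exactly 0.25 is NOT mutated
        assert mat.matrix[0, 1] == 1

    def test_constant_columns_recorded(self):
        ccf = np.array([[0.0, 1.0, 0.9], [0.0, 1.0, 0.1]])
        mat = binarize(ccf, ["s1", "s2"], ["z", "t", "v"])
        assert list(mat.dropped) == ["z"]
        assert list(mat.truncal) == ["t"]
        assert list(mat.mutation_ids) == ["v"]

    def test_all_zero_matrix_leaves_no_sites(self):
        mat = binarize(np.zeros((3, 4)), list("abc"), range(4))
        assert mat.n_sites == 0
        with pytest.raises(ValueError):
            ratchet_search(BinaryCharacterMatrix(
                np.zeros((2, 0), dtype=int), ["a", "b"], []))


class TestParsimonyScore:
    def test_perfect_phylogeny_scores_column_count(self):
        names, ids, x = perfect_matrix()
        mat = BinaryCharacterMatrix(x, names, ids)
        tree = ratchet_search(mat, min_iter=10, stop_no_improve=10, seed=0)
        assert parsimony_score(tree, mat) == mat.n_sites

    def test_singleton_character_costs_one_on_any_tree(self, rng):
        x = np.zeros((5, 1), dtype=int)
        x[2, 0] = 1
        mat = BinaryCharacterMatrix(x, list("abcde"), ["m"])
        for tree in enumerate_topologies(list("abcde"))[:20]:
            assert parsimony_score(tree, mat) == 1

    def test_matches_exhaustive_minimum_on_random_matrices(self, rng):
        for rep in range(5):
            x = rng.integers(0, 2, size=(5, 8))
            mat = BinaryCharacterMatrix(x, list("abcde"), np.arange(8))
            topos = enumerate_topologies(list("abcde"))
            assert len(topos) == 15  # (2*5-5)!! unrooted topologies
            best = min(parsimony_score(t, mat) for t in topos)
            found = parsimony_score(
                ratchet_search(mat, min_iter=15, stop_no_improve=15,
                               seed=rep), mat)
            assert found == best

    def test_tip_mismatch_rejected(self, rng):
        x = rng.integers(0, 2, size=(4, 3))
        mat = BinaryCharacterMatrix(x, list("abcd"), range(3))
        tree = enumerate_topologies(list("abce"))[0]
        with pytest.raises(ValueError):
            parsimony_score(tree, mat)


class TestRatchet:
    def test_recovers_generating_topology_on_perfect_data(self):
        names, ids, x = perfect_matrix()
        mat = BinaryCharacterMatrix(x, names, ids)
        from clonescape import CloneTree

        tree = ratchet_search(mat, min_iter=10, stop_no_improve=10, seed=1)
        tip_sets = {frozenset(t.name for t in CloneTree(e).tips())
                    for e in tree.edges() if not e.is_tip}
        assert frozenset("ab") in tip_sets
        assert frozenset("de") in tip_sets

    def test_identical_samples_score_zero(self):
        x = np.ones((4, 5), dtype=int)
        mat = BinaryCharacterMatrix(x, list("abcd"), range(5))
        assert mat.n_sites == 0  # truncal only
        tree = ratchet_search(mat, min_iter=5, stop_no_improve=5, seed=2)
        assert parsimony_score(tree, mat) == 0

    def test_score_invariant_to_column_order(self, rng):
        x = rng.integers(0, 2, size=(6, 10))
        mat = BinaryCharacterMatrix(x, list("abcdef"), np.arange(10))
        perm = rng.permutation(mat.n_sites)
        mat_p = BinaryCharacterMatrix(mat.matrix[:, perm], list("abcdef"),
                                      mat.mutation_ids[perm])
        s1 = parsimony_score(ratchet_search(mat, min_iter=10,
                                            stop_no_improve=10, seed=3),
                             mat)
        s2 = parsimony_score(ratchet_search(mat_p, min_iter=10,
                                            stop_no_improve=10, seed=3),
                             mat_p)
        assert s1 == s2

    def test_duplicate_sample_never_increases_score(self, rng):
        x = rng.integers(0, 2, size=(5, 8))
        mat = BinaryCharacterMatrix(x, list("abcde"), np.arange(8))
        s1 = parsimony_score(ratchet_search(mat, min_iter=10,
                                            stop_no_improve=10, seed=4),
                             mat)
        x2 = np.vstack([x, x[-1]])
        mat2 = BinaryCharacterMatrix(x2, list("abcde") + ["e2"],
                                     np.arange(8))
        s2 = parsimony_score(ratchet_search(mat2, min_iter=10,
                                            stop_no_improve=10, seed=4),
                             mat2)
        assert s2 <= s1 + 0  # duplicating a tip adds no change

    def test_too_few_samples_rejected(self):
        mat = BinaryCharacterMatrix(np.array([[0, 1], [1, 0]]),
                                    ["a", "b"], ["m1", "m2"])
        with pytest.raises(ValueError):
            ratchet_search(mat)


class TestAcctran:
    def test_clade_character_lands_on_stem_edge(self):
        names, ids, x = perfect_matrix()
        mat = BinaryCharacterMatrix(x, names, ids)
        tree = ratchet_search(mat, min_iter=10, stop_no_improve=10, seed=5)
        gains, losses = acctran_states(tree, mat)
        # homoplasy-free: total gains = column count, no losses
        assert sum(len(v) for v in gains.values()) == mat.n_sites
        assert sum(len(v) for v in losses.values()) == 0
        from clonescape import CloneTree
        for edge, muts in gains.items():
            if "m1" in muts:
                below = {t.name for t in CloneTree(edge).tips()}
                assert below == {"a", "b"}

    def test_homoplastic_character_appears_in_two_edge_sets(self):
        # a 1 0 / b 1 0 / c 0 1 / d 1 1: second char needs repeat gains
        # on the ((a,b),(c,d)) shape; total changes equal the Fitch score
        x = np.array([[1, 0], [1, 0], [0, 1], [1, 1]])
        mat = BinaryCharacterMatrix(x, list("abcd"), ["u", "v"])
        tree = ratchet_search(mat, min_iter=20, stop_no_improve=20, seed=6)
        gains, losses = acctran_states(tree, mat)
        total_changes = sum(len(v) for v in gains.values()) + \
            sum(len(v) for v in losses.values())
        assert total_changes == parsimony_score(tree, mat, rooted=True)

    def test_conservation_on_random_matrices(self, rng):
        for rep in range(5):
            x = rng.integers(0, 2, size=(6, 12))
            mat = BinaryCharacterMatrix(x, list("abcdef"), np.arange(12))
            tree = ratchet_search(mat, min_iter=10, stop_no_improve=10,
                                  seed=rep)
            gains, losses = acctran_states(tree, mat)
            total = sum(len(v) for v in gains.values()) + \
                sum(len(v) for v in losses.values())
            assert total == parsimony_score(tree, mat, rooted=True)

    def test_attach_edge_mutations_sets_lengths(self):
        names, ids, x = perfect_matrix()
        mat = BinaryCharacterMatrix(x, names, ids)
        tree = ratchet_search(mat, min_iter=10, stop_no_improve=10, seed=7)
        attach_edge_mutations(tree, mat)
        for e in tree.edges():
            assert e.length == len(e.muts)
        all_muts = set().union(*(e.muts for e in tree.edges()))
        assert all_muts == set(ids) - set(mat.dropped)
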