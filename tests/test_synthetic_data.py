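"""Synthetic sampling, sequencing and expression generators."""

import numpy as np
import pandas as pd
import pytest

from clonescape.spatial_sim import SimParams, run_to_size
from clonescape.synthetic_data import SamplingScheme, default_gene_table, \
    make_eqtl_cohort, make_variant_call_set, sample_tumour, \
    sequence_sample, simulate_expression
from conftest import make_random_tree


class TestSampling:
    def test_samples_cluster_within_radius(self, small_sim):
        scheme = SamplingScheme(glands_per_region=2, cluster_radius=6)
        samples = sample_tumour(small_sim, scheme, seed=1)
        assert len(samples) == 8
        pos = {int(g): p for g, p in zip(small_sim.live_nodes,
                                         small_sim.live_pos)}
        for region in "ABCD":
            pts = np.array([pos[s.gland] for s in samples
                            if s.region == region])
            spread = np.abs(pts - pts[0]).max()
            assert spread <= 2 * scheme.cluster_radius

    def test_oversampling_a_quadrant_errors_with_its_name(self, small_sim):
        scheme = SamplingScheme(glands_per_region=10_000)
        with pytest.raises(ValueError, match="quadrant [ABCD]"):
            sample_tumour(small_sim, scheme, seed=1)

    def test_same_seed_same_samples(self, small_sim):
        scheme = SamplingScheme()
        a = sample_tumour(small_sim, scheme, seed=5)
        b = sample_tumour(small_sim, scheme, seed=5)
        assert [(s.gland, s.region, s.mode, s.purity) for s in a] == \
            [(s.gland, s.region, s.mode, s.purity) for s in b]

    def test_deep_and_lowpass_modes_assigned(self, small_sim):
        scheme = SamplingScheme(glands_per_region=3, deep_per_region=1)
        samples = sample_tumour(small_sim, scheme, seed=2)
        per_region = {}
        for s in samples:
            per_region.setdefault(s.region, []).append(s.mode)
        for modes in per_region.values():
            assert modes.count("deep") == 1
            assert modes.count("lowpass") == 2


class TestSequencing:
    def test_pure_diploid_het_vaf_is_half(self, small_sim):
        gland = int(small_sim.live_nodes[0])
        carried = sorted(small_sim.lineage_mutations(gland))[:200]
        ids = np.array(carried)
        y, n = sequence_sample(small_sim, gland, depth=100, purity=1.0,
                               seed=3, mutation_ids=ids,
                               c=np.full(len(ids), 2.0),
                               mult=np.ones(len(ids)))
        vaf = y.sum() / n.sum()
        assert abs(vaf - 0.5) < 0.02

    def test_zero_depth_gives_zero_counts(self, small_sim):
        gland = int(small_sim.live_nodes[0])
        ids = np.arange(10)
        y, n = sequence_sample(small_sim, gland, depth=0, purity=0.8,
                               seed=4, mutation_ids=ids,
                               c=np.full(10, 2.0), mult=np.ones(10))
        assert n.sum() == 0 and y.sum() == 0

    def test_no_noise_means_no_reads_at_uncarried_sites(self, small_sim):
        gland = int(small_sim.live_nodes[0])
        ids = np.array([10**9 + i for i in range(50)])  # not real mutations
        y, _ = sequence_sample(small_sim, gland, depth=50, purity=0.8,
                               seed=5, mutation_ids=ids,
                               c=np.full(50, 2.0), mult=np.ones(50),
                               p0=0.0)
        assert y.sum() == 0

    def test_invalid_purity_rejected(self, small_sim):
        with pytest.raises(ValueError):
            sequence_sample(small_sim, int(small_sim.live_nodes[0]),
                            depth=10, purity=0.0, seed=1,
                            mutation_ids=np.arange(3),
                            c=np.full(3, 2.0), mult=np.ones(3))


@pytest.fixture(scope="module")
def vcs(small_sim):
    scheme = SamplingScheme(glands_per_region=2, deep_per_region=1,
                            purity_range=(0.6, 0.6))
    samples = sample_tumour(small_sim, scheme, seed=6)
    return make_variant_call_set(small_sim, samples, seed=7)


class TestVariantCallSet:
    def test_clonal_mutations_have_vaf_near_half_purity(self, vcs,
                                                        small_sim):
        deep = vcs.subset("deep")
        carried = np.array([
            [m in small_sim.lineage_mutations(s.gland)
             for m in deep.mutation_ids] for s in deep.samples])
        clonal = carried.all(axis=0)
        vaf = deep.y[:, clonal].sum() / deep.n[:, clonal].sum()
        # expected VAF = rho/2 = 0.3 for rho = 0.6 diploid heterozygous
        assert abs(vaf - 0.3) < 0.02

    def test_lowpass_coverage_is_sparse(self, vcs):
        low = vcs.subset("lowpass")
        assert abs(low.n.mean() - 1.2) < 0.1
        assert np.mean(low.n <= 2) > 0.85

    def test_same_seed_identical_output(self, small_sim):
        scheme = SamplingScheme()
        samples = sample_tumour(small_sim, scheme, seed=8)
        a = make_variant_call_set(small_sim, samples, seed=9)
        b = make_variant_call_set(small_sim, samples, seed=9)
        assert np.array_equal(a.y, b.y) and np.array_equal(a.n, b.n)

    def test_tsv_and_vcf_round_trip_counts(self, vcs, tmp_path):
        import pysam

        path = tmp_path / "calls.vcf"
        vcs.to_vcf(path)
        with pysam.VariantFile(str(path)) as fh:
            recs = list(fh)
        assert len(recs) == len(vcs.mutation_ids)
        name = vcs.sample_names[0]
        ad0 = np.array([r.samples[name]["AD"][1] for r in recs])
        assert np.array_equal(ad0, vcs.y[0])


class TestExpression:
    def test_noiseless_eqtl_effect_is_exact(self, rng):
        tree = make_random_tree(8, rng)
        tab = default_gene_table(n_heritable=0, n_plastic=1,
                                 plastic_sd=0.0,
                                 eqtl_links={"P0000": (42, 2.0)})
        carriers = {42: set(tree.tip_names()[:4])}
        expr, _ = simulate_expression(tree, tab, seed=0,
                                      mutation_carriers=carriers)
        x = expr.iloc[0]
        carrier_mean = x[tree.tip_names()[:4]].mean()
        rest_mean = x[tree.tip_names()[4:]].mean()
        assert carrier_mean - rest_mean == pytest.approx(2.0)

    def test_purity_distortion_is_undone_by_adjustment(self, rng):
        from clonescape.phylo_signal import purity_adjust

        tree = make_random_tree(6, rng)
        purity = {t: 0.5 + 0.05 * i
                  for i, t in enumerate(tree.tip_names())}
        tab = default_gene_table(n_heritable=0, n_plastic=1,
                                 plastic_sd=0.0, purity_coefficient=1.5)
        expr, _ = simulate_expression(tree, tab, seed=0, purity=purity)
        adj = purity_adjust(expr.iloc[0].to_numpy(), 1.5,
                            np.array([purity[t]
                                      for t in tree.tip_names()]))
        assert np.allclose(adj, 0.0)

    def test_same_seed_byte_identical(self, rng):
        tree = make_random_tree(6, rng)
        tab = default_gene_table(5, 5)
        a, _ = simulate_expression(tree, tab, seed=3)
        b, _ = simulate_expression(tree, tab, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_mismatched_tips_rejected(self, rng):
        tree = make_random_tree(6, rng)
        tab = default_gene_table(1, 0, purity_coefficient=1.0)
        with pytest.raises(ValueError):
            simulate_expression(tree, tab, seed=0, purity={"nope": 0.5})


def test_eqtl_cohort_shapes_and_eligibility():
    coh = make_eqtl_cohort(n_genes=40, seed=3)
    assert coh.expression.shape == (40, 167)
    assert (coh.mut.sum(axis=1) >= 2).all()
    assert (coh.purity[coh.tumour_of == "normal"] == 0).all()
    assert (coh.cna.loc[:, coh.tumour_of == "normal"] == 2).all().all()
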