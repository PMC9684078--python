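# clonescape

Inference of clonal evolution and the genetic control of gene expression
in multi-region tumour sequencing data — with a built-in synthetic data
generator so every stage can be exercised and validated without access to
patient data.

The package implements the computational machinery of a multi-omic
colorectal-cancer study design: several spatially separated regions of a
tumour are sampled at the level of individual glands, a few glands per
region receive deep whole-genome sequencing (~35x) and the rest low-pass
WGS (~1.2x), with matched RNA-seq. From these data the package:

- simulates spatial tumour growth at gland resolution (2D lattice,
  pushing-limited growth of width `d_push`, negative-binomial mutation
  accrual with overdispersion `D`, up to two selected subclones with
  advantages `lambda2`, `lambda3` introduced at sizes `t2`, `t3`);
- builds maximum-parsimony trees from deep samples (CCF > 0.25
  binarization, parsimony ratchet, acctran ancestral states giving the
  per-edge mutation sets `M_e`);
- places low-pass samples on the tree by maximum likelihood: variant
  reads are binomial with success probability
  `p_i = rho*m_i / (2 - 2*rho + rho*c_i)`, and a sample sits on edge `e`
  carrying a fraction `pi_m` of that edge's mutations, everything
  ancestral, and nothing else;
- fits the spatial growth model to an observed tree by ABC–SMC and
  selects among neutral / one-subclone / two-subclone models with
  `AIC = 2k + 2*NLL` (DeltaAIC > 4 = strong support);
- quantifies the heritability of gene expression along the tree with
  Pagel's lambda (ML + likelihood-ratio test, aggregated over a forest of
  100 leaf-length-imputed trees, median p < 0.05 flags signal);
- screens somatic cis-eQTLs with per-combination OLS
  `Exp ~ Mut + CNA + Purity + Tumour` at FDR 0.01, plus the clonality,
  direction and enrichment contrasts and an external-cohort validation
  rule.

See `docs/methods.md` for models, assumptions and numerical choices.

## Worked example

```python
import numpy as np
from clonescape import (SimParams, run_to_size, SamplingScheme,
                        sample_tumour, true_sample_tree, tree_summary,
                        fit_models)
from clonescape.evo_inference import ABCConfig

# a 1,000-gland tumour with a strongly selected subclone (12x advantage,
# introduced at 50 glands), surface growth
sim = run_to_size(SimParams(N_end=1000, d_push=3, D=2.0, m=1e-8,
                            lambda2=12.0, t2=50, seed=1))
print(round(sim.clone_frequency(1), 2))          # 0.91

# sample 6 glands from each lattice quadrant, build the true sample tree
scheme = SamplingScheme(glands_per_region=6, deep_per_region=6,
                        cluster_radius=14)
samples = sample_tumour(sim, scheme, seed=2)
tree = true_sample_tree(sim, [s.gland for s in samples])
for tip in tree.tips():
    tip.label = next(s.region for s in samples if f"g{s.gland}" == tip.name)

# ABC-SMC model selection: neutral vs selected growth
cfg = ABCConfig()   # 1,000 glands, 200 particles, 5 generations
table, fits = fit_models(tree_summary(tree), ("neutral", "selected"),
                         cfg, seed=3)
print(table[["model", "k", "nll", "aic", "delta_aic"]].to_string(index=False))
#    model  k      nll       aic  delta_aic
# selected  5 1.055553 12.111106   0.000000
#  neutral  3 6.214608 18.429216   6.318111
print(table.attrs["best"], table.attrs["verdict"])
# selected strong
```

The AIC table reads as in the study design: the selected model reduces
the negative log-likelihood by far more than the cost of its two extra
parameters (`lambda2`, `t2`), and the DeltaAIC of the neutral model
(6.3 > 4) means the tumour is called as containing a selected subclone
with strong support.

A full synthetic pipeline (simulate, sequence, tree, placement, forest,
expression, phylogenetic signal, ABC, eQTL screen) runs from one config:

```bash
clonescape run --out demo_run --seed 7
```

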