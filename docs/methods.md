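# Methods

This note documents the models and procedures implemented in `clonescape`,
the assumptions behind them, the synthetic data they are exercised on, and
the numerical and design choices that were genuinely open.

## Spatial gland simulator (`spatial_sim`)

The tumour is modelled as a population of glands (crypt-like clonal units)
on a 2D square lattice, one gland per site. The simulation is a sequence
of discrete birth-attempt events:

1. With probability `death_rate` a uniformly chosen live gland dies
   (checked before the attempt, so a lone founder can go extinct).
2. A mother gland is chosen proportionally to its clone's birth-rate
   multiplier (rejection sampling; the background clone has multiplier 1).
3. The mother looks for the nearest empty site along the eight straight
   compass rays, up to Chebyshev distance `d_push`. If one exists, the
   glands between mother and gap shift one step outwards and the daughter
   is placed next to the mother; otherwise the division silently fails
   (the gland is quiescent this event). Small `d_push` therefore restricts
   growth to the proliferative rim (surface growth), while `d_push` of the
   order of the tumour diameter gives effectively unconstrained,
   exponential growth.
4. Both daughter lineages acquire new mutations. Per-division mutation
   counts are negative binomial with mean `m * genome_size` and variance
   `mean * D`, implemented as a gamma–Poisson mixture; `D = 1` is drawn as
   an exact Poisson. Every mutation is new (infinite sites), so mutation
   identifiers are disjoint integer ranges per genealogy edge.

Up to two selected subclones are introduced by converting one uniformly
chosen live gland when the population first reaches `t2` (and `t3`)
glands, recording the conversion node. An interior conversion under
surface growth can leave the subclone trapped — that is a real outcome of
the model, not an error. Subclone–subclone interactions are not modelled.

Default study conditions: mutation rate `m = 1e-8` per bp per division
over `genome_size = 3e9` (about 30 mutations per division), `D` in the
low single digits, `d_push = 3`, final sizes 300–2,000 glands. A single
seeded RNG drives each run; reruns are bit-identical.

The diagnostic `spatial_growth_mode` reports the fraction of successful
divisions whose mother was within `d_push` (Chebyshev) of the nearest
empty site; with `d_push = 1` the interior-division fraction is below 5%.

## Multi-region synthetic data (`synthetic_data`)

Sampling emulates the multi-region protocol: the lattice is split into
quadrants (regions A–D), a random seed gland is drawn per quadrant, and
`glands_per_region` glands are drawn at random within `cluster_radius`
(Chebyshev) of it — dispersed within the region rather than contiguous,
as in multi-gland sampling of a tumour piece. The glands closest to the
seed are assigned deep WGS (mean 35x), the rest low-pass WGS (mean 1.2x).

Sequencing: per site, coverage is Poisson(depth) (the coverage model is
this package's choice) and variant reads are binomial with success
probability `p = rho*mult / (2 - 2*rho + rho*c)` at carried sites (purity
`rho`, multiplicity `mult`, tumour copy number `c`, diploid normal
contamination) and a background noise `p0 = 1e-3` elsewhere. Copy-number
states default to diploid heterozygous; clonal states in {1..4} can be
injected per mutation to exercise multiplicity estimation. Subclonal
copy-number change is deliberately absent: placement input excludes such
regions. No read-level or count-level (negative binomial RNA) realism is
attempted.

Expression matrices are generated directly on a variance-stabilized-like
continuous scale: per gene a Brownian-motion component along the tree
(rate = trait s.d. per mean tree height) for heritable genes, iid noise
for plastic genes, optional region shifts, a purity distortion
`-coef/purity` (so the standard adjustment `+coef/purity` undoes it) and
additive cis-eQTL effects for mutation carriers. Every planted parameter
is returned in a truth table.

The eQTL cohort generator reproduces the study scale by default: 19
tumours, 153 tumour samples, 14 matched normals (167 in total), one
linked locus per gene, clonal or subclonal mutation patterns with at
least two carriers, clonal per-tumour copy-number states and uniform
purities; normals are coded Mut = 0, CNA = 2, Purity = 0, Tumour = 0.

What passing tests on these data do **not** show: robustness to mapping
artefacts, germline contamination, subclonal copy number, RNA count
noise, or batch structure — none of which the generator emulates.

## Maximum-parsimony trees (`phylo_build`)

Deep-sample variant calls are converted to cancer cell fractions,
`ccf = vaf * (2 - 2*rho + rho*c) / (rho*mult)` clamped to [0, 1.5]
(uncovered sites are missing, not zero), and binarized at CCF strictly
greater than 0.25. Constant columns are dropped (all-one columns recorded
as truncal). The tree search is a parsimony ratchet: iterations upweight
a random 25% of characters (x3), hill-climb with nearest-neighbour
interchange from a jittered copy of the incumbent (two random NNI moves
— plain NNI alone stalls in local optima on noisy data), restore the
weights, climb again and keep improvements; at least 100 and at most 1e6
iterations, stopping after 100 without improvement. The starting tree is
average-linkage on Hamming distances.

`parsimony_score` is the standard free-root Fitch count (invariant to
rooting); with `rooted=True` the germline root is forced to state 0,
which is the count that ancestral-state assignments conserve. After the
search the tree is rooted where an all-zero germline outgroup attaches
most parsimoniously (first-found on ties), with an explicit unary
germline root so the trunk is a real edge.

Ancestral states use accelerated transformation: a unit-cost dynamic
program computes per-node, per-state subtree costs, and the preorder
resolution picks the cheapest state, preferring a change on ties so that
changes sit as close to the root as possible. `M_e` is the set of
mutations gained (0 -> 1) on edge `e`; homoplastic characters appear in
several `M_e` and losses are tracked separately. Gains plus losses equal
the rooted Fitch score.

## Low-pass placement (`lowpass_placement`)

A low-pass sample is placed on the deep tree by maximum likelihood over
(edge, pi_m, p0, rho): the focal edge's mutations are present with
probability `pi_m` (per-site binomial mixture), everything ancestral is
present, everything else absent (mutations are never lost). Sites with
zero coverage contribute log 1; an empty `M_e` contributes an empty
product. Optimization is a coarse grid (20 purity x 7 noise x 21 fraction
points) followed by bounded L-BFGS-B refinement at the three best edges;
ties between edges break toward the rootmost edge. A flat likelihood
profile (e.g. zero coverage everywhere, or zero purity) is flagged
`unplaceable` rather than returning an arbitrary edge. The optimum is
never worse than an exhaustive 101-point-per-parameter grid search
(asserted in the acceptance suite); whether purity is fixed from an
external estimate or free is a caller choice (`fixed_rho`).

Multiplicity is estimated across samples as the argmin over
`m in {1..c}` of the summed binomial negative log-likelihood at
`p_s(m)`, restricted to detected samples and to sites with `0 < c < 4`.
Success probabilities are clipped to [1e-6, 1-1e-6] so a handful of
discordant reads cannot veto a state outright.

Because private mutations of a ~1.2x sample cannot be called, low-pass
terminal branch lengths are imputed: each low-pass tip's length is drawn
from a Poisson whose mean is the average number of unique (terminal)
mutations of the deep samples from the same region, repeated to give a
forest of 100 trees of fixed topology.

## Tree summaries, intermixing and the ABC distance (`tree_metrics`)

The intermixing score I(T) is the mean over tips v of the fraction of
differently-labelled tips among all tips descending from v's parent (v
itself included; the printed set definition is read as including v, which
only rescales each term by (|D|-1)/|D|). It is invariant to edge lengths
and consistent relabelling: 0 for monophyletic regions, (k-1)/k for an
all-distinct star.

The summary vector feeding ABC has 14 entries: overall terminal-length
mean and s.d.; smallest and largest per-region terminal means; trunk
fraction; smallest and largest per-region-pair mean patristic distance;
longest-internal-edge fraction; coefficient of variation of tip depths;
mean pairwise MRCA depth over mean tip depth; fraction of tip pairs
coalescing below 15% of the mean tip depth; intermixing; tip count;
total length. Region-wise entries enter as extremes so the vector is
invariant to the arbitrary identity of regions. The composition was
chosen after simulation experiments: a partial selective sweep's robust
signature at this scale is *late coalescence* (most sampled pairs meet at
the subclone conversion, deep in the tree), captured by the MRCA-depth
statistics and trunk fraction, whereas plain per-region length statistics
are dominated by realization noise. Distances are Euclidean after robust
scaling (median/1.4826*MAD frozen from the prior-predictive set; zero-MAD
entries fall back to unit scale) with the six scale-free shape statistics
upweighted 9x in squared distance (3x in distance units): shape carries
the identity of the growth model, lengths mostly calibrate the mutation
rate. A noise baseline (edge lengths jittered by Uniform(0.5, 2)) gives
the reference distance scale for judging fits.

A numba kernel computes the identical summary directly from genealogy
arrays for the ABC hot loop; its equality with the explicit tree route is
asserted in the tests.

## ABC–SMC growth-model selection (`evo_inference`)

Three nested models are fitted per tumour: neutral (k = 3: D, m,
d_push), selected (k = 5: + lambda2, t2) and selected x 2 (k = 7: +
lambda3, t3). Priors are uniform on transformed scales: D on [1, 20],
log10 m on [-9, -7], d_push on [1, 30], lambda on [1, 50], log10 t on
[log10 4, log10 N/2] (t2 < t3 enforced by sorting). The SMC follows the
standard scheme: prior-predictive generation 0 (which also freezes the
robust scale), tolerance set to the 0.5 quantile of accepted distances,
component-wise Gaussian perturbation with variance twice the weighted
particle variance, kernel-density importance weights, five generations
of 200 particles by default.

Each particle's summary is the average of 2 simulated tumours x 2
sampling draws (expected-summary ABC). This damps simulation noise so a
model that systematically cannot reach the target is distinguishable
from one that can; the observed target remains a single realization.

The NLL of a fitted model is `-log` of its posterior-predictive
acceptance fraction at a reference distance shared across models — 1.3x
the tightest final SMC tolerance any model achieved — with a pseudo-count
floor of `1/(2*reps)` so the NLL is finite. Then `AIC = 2k + 2*NLL`, and
a model is strongly preferred when the runner-up's DeltaAIC exceeds 4.
The one-sided posterior-predictive p is the fraction of simulation pairs
whose mutual distance is at least the mean target-to-simulation distance.

Under the scaled-down study conditions (1,000 glands, 24 sampled glands
in 4 regions, lambda2 = 12 introduced at 5% of final size), the selected
model is strongly preferred on the large majority of selected targets
while neutral targets are essentially never strongly rejected. Selected
targets remain undetectable when the sampling happens to miss the
background remnant or the subclone was trapped in the interior — a
property of the biology, not the inference.

## Phylogenetic signal (`phylo_signal`)

Pagel's lambda scales the off-diagonal entries of the Brownian-motion
covariance; the likelihood profiles out the root mean (GLS) and rate (ML)
analytically and optimizes lambda on [0, lambda_max] where lambda_max is
found by Cholesky bisection (the diagonal-fixed transform can stay
positive definite well beyond 1 on non-ultrametric trees). The test
against lambda = 0 is a plain chi-square(1) LRT — the same convention as
phytools' `phylosig`, against which the implementation is verified on a
shared fixture. The boundary at lambda = 0 makes the null p distribution
conservative (about half its mass sits at p = 1, and the type-I error at
0.05 is ~0.01–0.02); no p convention removes this, and it is why the
null-calibration acceptance check is reported as conservative rather
than uniform. Star trees (lambda non-identifiable) and constant traits
return flagged null results.

Per gene the fit runs over the 100-tree leaf-length forest; the medians
MedLambda and MedPval are stored and MedPval < 0.05 flags signal
(Benjamini–Hochberg q-values are reported alongside, as most signals do
not survive correction). Recurrence counts flags across tumours (>= 3
tumours by default). The power simulation draws Poisson expression
(mean 50) across tips, inflates a chosen clade by 5–100%, and reports
the fraction of replicates with forest-median p < 0.05.

## Somatic eQTL screen (`eqtl_stats`)

Genes are kept when at least 5% of tumour samples have >= 10 TPM.
Expression is z-scored over all samples; combinations are loci mutated in
at least two samples linked to an expressed gene (enhancer and
non-synonymous classes; dually annotated loci appear under both). Each
combination is an OLS fit of `Exp ~ Mut + CNA + Purity + Tumour` with
normals coded WT/2/0/0; constant columns are dropped from the design (and
noted), rank-deficient designs are skipped with a reason. The overall
F-test is full-model-vs-intercept; combinations are "explained" at
Benjamini–Hochberg FDR < 0.01 of the F p-value, and per-variable calls
use coefficient FDR < 0.05. Storey's pi0 uses the cubic-smoother lambda
grid 0.05–0.95; because the study's "Storey's pi" could denote pi0 or
1 - pi0, both are exposed.

Clonality: a mutation is clonal iff present in every matched sample of
every tumour that carries it. The sign contrast uses a two-sided normal
test of the up/down proportion against 0.5 without continuity correction,
and the clonal-vs-subclonal rate contrast a two-proportion chi-square
with continuity correction — these variants reproduce the published
p-values from the published counts to two significant figures. Enrichment
uses two-sided Fisher exact tests (sample OR, Haldane 0.5 correction
flagged on zero cells). External validation refits `Exp ~ Mut + Purity`
vs `Exp ~ Purity` in a second cohort (LRT, chi-square(1)) and requires
sign concordance. The post hoc power rule solves the two-sample
noncentral-t power equation for n1 at power 0.99, capping the absolute
effect at 3.04 and inflating the result by 1.15.

The linear mixed-effects purity gene filter of the original analysis is
out of scope; the fixed-effects screen above carries the purity
covariate instead.

## Pipeline (`pipeline`) and problem sizes

`run_all` executes simulate -> sample -> tree -> place -> forest ->
expression -> signal -> infer -> eqtl from one config, with one global
seed fanned out per stage through SHA-256, text-only outputs and a
checksummed manifest; reruns are bit-identical. The demo configuration
(500-gland neutral tumour, 12 samples, 10-tree forest, 20-particle ABC,
120-gene cohort) runs in well under a minute.

Problem sizes used by the test and acceptance suites — chosen as
desk-scale versions of the study design: tumours of 300–2,000 glands;
8–24 sampled glands in 4 regions; 20-tip trees and 100-tree forests for
signal analysis; 8-tip exhaustive parsimony oracles (10,395 topologies);
200-particle, 5-generation ABC on 1,000-gland tumours; eQTL cohorts of
167 samples. The headline tumour-cohort numbers of the original study
(selection calls across 27 patients, 61 recurrent phylogenetic genes,
per-patient mutation rates) depend on restricted patient data and are
not reproduced here.

## Known limitations

- 2D lattice only; no microenvironment, no subclone interactions.
- The ABC summary composition and NLL estimator are this package's
  concrete choices where the original's are unpublished; results are
  reproducible but not numerically comparable to the original fits.
- Selection detection requires the sweep to leave a sampled signature;
  completed sweeps and trapped subclones are indistinguishable from
  neutrality, and the boundary-constrained lambda LRT is conservative.
- The expression generator has no count-level noise model, so
  signal-analysis power on real RNA-seq may be lower than on synthetic
  matrices.
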