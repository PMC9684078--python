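"""Synthetic multi-region sequencing and expression data.

Emulates the study design every downstream stage expects: gland sampling
from four spatial tumour regions (lattice quadrants A-D), deep (~35x) and
low-pass (~1.2x) whole-genome sequencing with binomial variant read counts
under purity and copy-number dilution, and expression matrices with planted
heritable (Brownian-on-tree), plastic (iid), regional, purity and cis-eQTL
components.  Every planted parameter is recorded in a truth table so that
recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spatial_sim import SimResult
from .trees import CloneTree

__all__ = [
    "SamplingScheme",
    "Sample",
    "VariantCallSet",
    "sample_tumour",
    "sequence_sample",
    "make_variant_call_set",
    "default_gene_table",
    "simulate_expression",
    "make_eqtl_cohort",
]

REGION_LABELS = ("A", "B", "C", "D")


@dataclass
class SamplingScheme:
    """Multi-region gland sampling design.

    Defaults mirror the study conditions: 4 regions, deep WGS at mean 35x
    coverage and low-pass WGS at mean 1.2x, with one deep sample per region.
    """

    n_regions: int = 4
    glands_per_region: int = 2
    cluster_radius: int = 6
    deep_depth: float = 35.0
    lowpass_depth: float = 1.2
    deep_per_region: int = 1
    purity_range: tuple[float, float] = (0.5, 0.9)

    def __post_init__(self):
        if not 1 <= self.n_regions <= 4:
            raise ValueError("n_regions must be in 1..4 (lattice quadrants)")
        if self.deep_depth <= 0 or self.lowpass_depth <= 0:
            raise ValueError("depths must be > 0")
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("purity_range must lie in (0, 1]")


@dataclass
class Sample:
    name: str
    gland: int
    region: str
    mode: str          # "deep" | "lowpass"
    depth: float
    purity: float


def sample_tumour(sim: SimResult, scheme: SamplingScheme, seed: int = 0
                  ) -> list[Sample]:
    """Pick spatially clustered glands from each lattice quadrant.

    Each region contributes ``glands_per_region`` glands within
    ``cluster_radius`` (Chebyshev) of a randomly chosen seed gland of that
    quadrant; the ``deep_per_region`` glands closest to the seed are deep
    WGS, the rest low-pass.
    """
    rng = np.random.default_rng(seed)
    pos = sim.live_pos
    centre = pos.mean(axis=0)
    quadrant = (pos[:, 0] >= centre[0]).astype(int) * 2 + (
        pos[:, 1] >= centre[1]).astype(int)
    samples: list[Sample] = []
    for q in range(scheme.n_regions):
        label = REGION_LABELS[q]
        idx = np.flatnonzero(quadrant == q)
        if len(idx) < scheme.glands_per_region:
            raise ValueError(
                f"region quadrant {label} holds only {len(idx)} glands; "
                f"{scheme.glands_per_region} requested")
        # try seed glands until one has a big enough cluster around it
        order = rng.permutation(idx)
        chosen = None
        for s in order[:50]:
            d = np.max(np.abs(pos[idx] - pos[s]), axis=1)
            near = idx[d <= scheme.cluster_radius]
            if len(near) >= scheme.glands_per_region:
                # glands are spread over the region, not taken contiguously:
                # multi-region protocols pick dispersed glands per region
                chosen = rng.choice(near, scheme.glands_per_region,
                                    replace=False)
                dd = np.max(np.abs(pos[chosen] - pos[s]), axis=1)
                chosen = chosen[np.argsort(dd, kind="stable")]
                break
        if chosen is None:
            raise ValueError(
                f"region quadrant {label}: no cluster of "
                f"{scheme.glands_per_region} glands within radius "
                f"{scheme.cluster_radius}")
        for j, gi in enumerate(chosen):
            mode = "deep" if j < scheme.deep_per_region else "lowpass"
            purity = rng.uniform(*scheme.purity_range)
            depth = scheme.deep_depth if mode == "deep" else scheme.lowpass_depth
            samples.append(Sample(
                name=f"{label}{j + 1}", gland=int(sim.live_nodes[gi]),
                region=label, mode=mode, depth=depth, purity=float(purity)))
    return samples


class VariantCallSet:
    """Per-sample variant read counts over a shared mutation universe.

    Arrays are samples x mutations: ``y`` variant reads, ``n`` total reads.
    ``c`` and ``mult`` are the (clonal) total copy number and mutated-allele
    multiplicity per mutation; ``purity`` is per sample.
    """

    def __init__(self, samples: list[Sample], mutation_ids: np.ndarray,
                 y: np.ndarray, n: np.ndarray,
                 c: np.ndarray, mult: np.ndarray):
        if np.any(y > n) or np.any(y < 0):
            raise ValueError("need 0 <= y <= n")
        if np.any(mult > c):
            raise ValueError("multiplicity cannot exceed copy number")
        self.samples = samples
        self.mutation_ids = np.asarray(mutation_ids)
        self.y = y
        self.n = n
        self.c = np.asarray(c, dtype=float)
        self.mult = np.asarray(mult, dtype=float)

    @property
    def purity(self) -> np.ndarray:
        return np.array([s.purity for s in self.samples])

    @property
    def sample_names(self) -> list[str]:
        return [s.name for s in self.samples]

    def vaf(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n > 0, self.y / np.maximum(self.n, 1), np.nan)

    def subset(self, mode: str) -> "VariantCallSet":
        keep = [i for i, s in enumerate(self.samples) if s.mode == mode]
        return VariantCallSet([self.samples[i] for i in keep],
                              self.mutation_ids, self.y[keep], self.n[keep],
                              self.c, self.mult)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.samples):
            for j, mid in enumerate(self.mutation_ids):
                rows.append((s.name, s.region, s.mode, s.purity, int(mid),
                             int(self.y[i, j]), int(self.n[i, j]),
                             self.c[j], self.mult[j]))
        return pd.DataFrame(rows, columns=[
            "sample", "region", "mode", "purity", "mutation_id",
            "y", "n", "c", "mult"])

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def to_vcf(self, path) -> None:
        """Minimal single-chromosome VCF with per-sample AD/DP."""
        import pysam

        header = pysam.VariantHeader()
        header.contigs.add("chr1", length=int(self.mutation_ids.max()) + 2)
        header.formats.add("AD", "R", "Integer", "Ref and alt read depth")
        header.formats.add("DP", 1, "Integer", "Total depth")
        for s in self.samples:
            header.add_sample(s.name)
        with pysam.VariantFile(str(path), "w", header=header) as vcf:
            for j, mid in enumerate(self.mutation_ids):
                rec = vcf.new_record(contig="chr1", start=int(mid),
                                     alleles=("A", "T"))
                for i, s in enumerate(self.samples):
                    rec.samples[s.name]["AD"] = (
                        int(self.n[i, j] - self.y[i, j]), int(self.y[i, j]))
                    rec.samples[s.name]["DP"] = int(self.n[i, j])
                vcf.write(rec)


def sequence_sample(sim: SimResult, gland: int, depth: float, purity: float,
                    seed: int, mutation_ids: np.ndarray,
                    c: np.ndarray, mult: np.ndarray,
                    p0: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
    """Binomial read counts for one gland over a mutation universe.

    Coverage is Poisson(depth) per site; variant reads are
    Binomial(n, p_i) with p_i = purity*mult / (2 - 2*purity + purity*c) at
    carried sites and the sequencing-noise probability ``p0`` elsewhere.
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    carried = sim.lineage_mutations(gland)
    is_carried = np.fromiter((m in carried for m in mutation_ids),
                             dtype=bool, count=len(mutation_ids))
    n = rng.poisson(depth, size=len(mutation_ids))
    p = np.where(is_carried,
                 purity * mult / (2.0 - 2.0 * purity + purity * c), p0)
    y = rng.binomial(n, p)
    return y, n


def make_variant_call_set(sim: SimResult, samples: list[Sample], seed: int = 0,
                          p0: float = 1e-3,
                          cn_states: dict[int, tuple[int, int]] | None = None,
                          ) -> VariantCallSet:
    """Sequence every sample over the union of sampled-lineage mutations.

    ``cn_states`` optionally maps mutation id -> (total copy number,
    multiplicity) for clonal copy-number segments; the default is diploid
    heterozygous (c=2, mult=1).  Subclonal copy number is deliberately not
    modelled (placement input excludes such regions).
    """
    universe = set()
    for s in samples:
        universe |= sim.lineage_mutations(s.gland)
    mutation_ids = np.array(sorted(universe), dtype=np.int64)
    m = len(mutation_ids)
    c = np.full(m, 2.0)
    mult = np.ones(m)
    if cn_states:
        for j, mid in enumerate(mutation_ids):
            if int(mid) in cn_states:
                c[j], mult[j] = cn_states[int(mid)]
    y = np.zeros((len(samples), m), dtype=np.int64)
    n = np.zeros_like(y)
    root = np.random.default_rng(seed)
    for i, s in enumerate(samples):
        sub = int(root.integers(2**31 - 1))
        y[i], n[i] = sequence_sample(sim, s.gland, s.depth, s.purity, sub,
                                     mutation_ids, c, mult, p0=p0)
    return VariantCallSet(samples, mutation_ids, y, n, c, mult)


# --------------------------------------------------------------------- #
# expression
# --------------------------------------------------------------------- #

def default_gene_table(n_heritable: int = 50, n_plastic: int = 50,
                       heritable_sd: float = 1.0, plastic_sd: float = 1.0,
                       residual_sd: float = 0.1,
                       region_sd: float = 0.0,
                       purity_coefficient: float = 0.0,
                       eqtl_links: dict[str, tuple[int, float]] | None = None,
                       ) -> pd.DataFrame:
    """Gene-level planting table for :func:`simulate_expression`.

    Heritable genes evolve as Brownian motion along the tree with rate
    ``heritable_sd`` (per unit tree height) plus a small residual; plastic
    genes are iid noise with s.d. ``plastic_sd``.
    """
    rows = []
    for i in range(n_heritable):
        rows.append((f"H{i:04d}", 1, heritable_sd, residual_sd,
                     region_sd, purity_coefficient))
    for i in range(n_plastic):
        rows.append((f"P{i:04d}", 0, 0.0, plastic_sd,
                     region_sd, purity_coefficient))
    tab = pd.DataFrame(rows, columns=[
        "gene", "lambda_true", "heritable_sd", "plastic_sd",
        "region_sd", "purity_coefficient"])
    tab["eqtl_mutation"] = -1
    tab["eqtl_effect"] = 0.0
    if eqtl_links:
        for gene, (mid, eff) in eqtl_links.items():
            tab.loc[tab.gene == gene, ["eqtl_mutation", "eqtl_effect"]] = \
                (mid, eff)
    return tab


def _brownian_tips(tree: CloneTree, rate: float, rng) -> dict[str, float]:
    """One Brownian-motion realization along the tree, returned per tip.

    Edge lengths are normalized by the mean root-to-tip depth so that
    ``rate`` is the trait s.d. accumulated over one average tree height.
    """
    depths = tree.depths()
    tip_depths = [depths[t] for t in tree.tips()]
    height = float(np.mean(tip_depths))
    if height <= 0:
        raise ValueError("tree has zero height; cannot plant heritable signal")
    value = {tree.root: 0.0}
    for node in tree.preorder():
        if node.parent is None:
            continue
        sd = rate * np.sqrt(node.length / height)
        value[node] = value[node.parent] + rng.normal(0.0, sd)
    return {t.name: value[t] for t in tree.tips()}


def simulate_expression(tree: CloneTree, gene_table: pd.DataFrame,
                        seed: int = 0,
                        purity: dict[str, float] | None = None,
                        region_of: dict[str, str] | None = None,
                        mutation_carriers: dict[int, set[str]] | None = None,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression matrix (genes x samples) with planted structure.

    Per gene: Brownian component along ``tree`` (heritable), iid plastic
    noise, a region shift, a purity distortion ``-coef/purity`` (so that the
    downstream purity adjustment, which adds ``coef/purity``, undoes it) and
    an additive eQTL effect for carrier samples.  Returns the matrix and the
    truth table.
    """
    rng = np.random.default_rng(seed)
    tips = tree.tip_names()
    if len(set(tips)) != len(tips):
        raise ValueError("duplicate tip names")
    if purity is not None and set(tips) - set(purity):
        raise ValueError("purity missing for some tips")
    regions = sorted({region_of[t] for t in tips}) if region_of else []
    mat = np.zeros((len(gene_table), len(tips)))
    for gi, row in enumerate(gene_table.itertuples(index=False)):
        x = np.zeros(len(tips))
        if row.lambda_true and row.heritable_sd > 0:
            bm = _brownian_tips(tree, row.heritable_sd, rng)
            x += np.array([bm[t] for t in tips])
        if row.plastic_sd > 0:
            x += rng.normal(0.0, row.plastic_sd, size=len(tips))
        if row.region_sd > 0 and regions:
            shift = {r: rng.normal(0.0, row.region_sd) for r in regions}
            x += np.array([shift[region_of[t]] for t in tips])
        if row.purity_coefficient != 0 and purity is not None:
            x -= np.array([row.purity_coefficient / purity[t] for t in tips])
        if row.eqtl_mutation >= 0 and mutation_carriers is not None:
            carriers = mutation_carriers.get(int(row.eqtl_mutation), set())
            x += row.eqtl_effect * np.array(
                [1.0 if t in carriers else 0.0 for t in tips])
        mat[gi] = x
    expr = pd.DataFrame(mat, index=list(gene_table.gene), columns=tips)
    return expr, gene_table.copy()


# --------------------------------------------------------------------- #
# eQTL cohort
# --------------------------------------------------------------------- #

@dataclass
class EQTLCohort:
    """A synthetic multi-tumour cohort for the somatic eQTL screen."""

    expression: pd.DataFrame        # genes x samples (pre z-scoring)
    mut: pd.DataFrame               # loci x samples, binary
    cna: pd.DataFrame               # genes x samples, total copy number
    purity: pd.Series               # per sample
    tumour_of: pd.Series            # per sample tumour id ("normal" for normals)
    links: pd.DataFrame             # locus, gene, class
    truth: pd.DataFrame = field(default=None)


def make_eqtl_cohort(n_genes: int = 200,
                     n_tumours: int = 19,
                     n_tumour_samples: int = 153,
                     n_normals: int = 14,
                     mut_effect: float = 0.0,
                     cna_effect: float = 0.0,
                     purity_effect: float = 0.3,
                     tumour_effect: float = 0.5,
                     noise_sd: float = 1.0,
                     frac_subclonal: float = 0.4,
                     seed: int = 0) -> EQTLCohort:
    """Simulate a cohort at the scale of the real study (167 samples from
    19 tumours plus 14 matched normals by default).

    Each gene gets one linked locus, mutated clonally or subclonally in a
    random subset of tumours (always >= 2 mutated samples), a clonal
    per-tumour copy-number state in {1..4}, and expression
    ``mut_effect*Mut + cna_effect*CNA + purity_effect*Purity +
    tumour_effect*Tumour + noise``.  ``mut_effect = cna_effect = 0`` gives a
    fully null cohort for calibration.
    """
    rng = np.random.default_rng(seed)
    # tumour sample sizes: at least 2 each, median a handful
    sizes = np.full(n_tumours, 2)
    extra = rng.multinomial(n_tumour_samples - 2 * n_tumours,
                            np.ones(n_tumours) / n_tumours)
    sizes = sizes + extra
    sample_names, tumour_of = [], []
    for t in range(n_tumours):
        for i in range(sizes[t]):
            sample_names.append(f"T{t:02d}_S{i}")
            tumour_of.append(f"T{t:02d}")
    for i in range(n_normals):
        sample_names.append(f"N{i:02d}")
        tumour_of.append("normal")
    tumour_of = pd.Series(tumour_of, index=sample_names)
    is_tumour = (tumour_of != "normal").to_numpy()
    s = len(sample_names)

    purity = pd.Series(np.where(is_tumour, rng.uniform(0.4, 0.9, s), 0.0),
                       index=sample_names)

    genes = [f"G{i:04d}" for i in range(n_genes)]
    loci = [f"L{i:04d}" for i in range(n_genes)]
    mut = np.zeros((n_genes, s), dtype=int)
    cna = np.full((n_genes, s), 2.0)
    cna[:, ~is_tumour] = 2.0
    clonal_flags = np.zeros(n_genes, dtype=bool)
    tum_ids = [f"T{t:02d}" for t in range(n_tumours)]
    for g in range(n_genes):
        # copy number: per tumour clonal state, mostly diploid
        for t, tid in enumerate(tum_ids):
            cols = (tumour_of == tid).to_numpy()
            state = rng.choice([1, 2, 2, 2, 3, 4])
            cna[g, cols] = state
        # mutation: pick tumours, clonal or subclonal pattern
        subclonal = rng.random() < frac_subclonal
        n_mut_tum = int(rng.integers(1, 4))
        for tid in rng.choice(tum_ids, n_mut_tum, replace=False):
            cols = np.flatnonzero((tumour_of == tid).to_numpy())
            if subclonal and len(cols) > 2:
                k = int(rng.integers(2, len(cols)))
                mut[g, rng.choice(cols, k, replace=False)] = 1
            else:
                mut[g, cols] = 1
        if mut[g].sum() < 2:  # enforce eligibility
            cols = np.flatnonzero(is_tumour)
            mut[g, rng.choice(cols, 2, replace=False)] = 1
        clonal_flags[g] = not subclonal

    noise = rng.normal(0.0, noise_sd, size=(n_genes, s))
    expr = (mut_effect * mut + cna_effect * cna
            + purity_effect * purity.to_numpy()
            + tumour_effect * is_tumour + noise)
    expression = pd.DataFrame(expr, index=genes, columns=sample_names)
    mut_df = pd.DataFrame(mut, index=loci, columns=sample_names)
    cna_df = pd.DataFrame(cna, index=genes, columns=sample_names)
    links = pd.DataFrame({"locus": loci, "gene": genes,
                          "class": rng.choice(["non_synonymous", "enhancer"],
                                              n_genes)})
    truth = pd.DataFrame({"gene": genes, "locus": loci,
                          "mut_effect": mut_effect, "cna_effect": cna_effect,
                          "clonal": clonal_flags})
    return EQTLCohort(expression, mut_df, cna_df, purity, tumour_of,
                      links, truth)
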