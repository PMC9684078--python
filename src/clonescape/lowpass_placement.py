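"""Maximum-likelihood placement of low-pass samples onto a deep-sample tree.

A shallow-WGS sample provides variant/total read counts (y_i, n_i) for every
mutation mapped to the tree.  Reads are binomial: at a carried site the
success probability is p_i = rho*m_i / (2 - 2*rho + rho*c_i) (purity rho,
multiplicity m_i, tumour copy number c_i, diploid normal contamination); at
an uncarried site it is the background noise p_0.  For a candidate edge
e = (s, t), all mutations on the root-to-s path are present, a fraction
pi_m of the focal edge's mutations are present, and every other mutation is
absent.  The sample is placed by minimizing the negative log-likelihood over
edges x (pi_m, p_0, rho).

Also provides multiplicity estimation across samples and the Poisson
leaf-length imputation forest used by phylogenetic-signal analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .trees import CloneNode, CloneTree

__all__ = [
    "success_prob",
    "edge_marginal_loglik",
    "placement_loglik",
    "SamplePlacement",
    "PlacementResult",
    "place_sample",
    "estimate_multiplicity",
    "impute_leaf_forest",
]


def success_prob(rho, mult, c):
    """Expected VAF of a carried mutation under purity/copy-number dilution."""
    rho = np.asarray(rho, dtype=float)
    c = np.asarray(c, dtype=float)
    denom = 2.0 - 2.0 * rho + rho * c
    if np.any(denom <= 0):
        raise ZeroDivisionError("denominator 2-2*rho+rho*c is not positive")
    return rho * np.asarray(mult, dtype=float) / denom


def _binom_logpmf(y, n, p):
    # probabilities are kept away from {0, 1} so that a handful of
    # discordant reads (sequencing error) cannot veto a state outright
    p = np.clip(p, 1e-6, 1 - 1e-6)
    return stats.binom.logpmf(y, n, p)


def edge_marginal_loglik(y, n, p_i, p0, pi_m):
    """log p(D_e | pi_m): mixture of present/absent binomials per site.

    Sites with n = 0 contribute log 1 = 0; an empty mutation set gives 0
    (empty product).
    """
    y = np.asarray(y)
    n = np.asarray(n)
    if len(y) == 0:
        return 0.0
    l1 = _binom_logpmf(y, n, p_i)
    l0 = _binom_logpmf(y, n, np.broadcast_to(p0, y.shape))
    return float(np.sum(_mix(l1, l0, pi_m)))


def _mix(l1, l0, pi_m):
    if pi_m >= 1.0:
        return l1
    if pi_m <= 0.0:
        return l0
    return np.logaddexp(np.log(pi_m) + l1, np.log1p(-pi_m) + l0)


def edge_name(edge: CloneNode) -> str:
    """Stable display name for a tree edge (its child node)."""
    if edge.name is not None:
        return str(edge.name)
    below = sorted(t.name for t in CloneTree(edge).tips())
    return "edge_to_{" + ",".join(map(str, below)) + "}"


class SamplePlacement:
    """Model for placing one low-pass sample on a mutation-annotated tree.

    Parameters
    ----------
    tree : CloneTree
        Tree whose edges carry mutation-id sets (``node.muts``).
    mutation_ids, y, n : arrays
        Read counts of the sample, aligned on ``mutation_ids``.
    c, mult : arrays or scalars
        Tumour copy number and multiplicity per mutation (default diploid
        heterozygous).
    """

    def __init__(self, tree: CloneTree, mutation_ids, y, n, c=2.0, mult=1.0):
        self.tree = tree
        self.mutation_ids = np.asarray(mutation_ids)
        self.y = np.asarray(y, dtype=np.int64)
        self.n = np.asarray(n, dtype=np.int64)
        self.c = np.broadcast_to(np.asarray(c, dtype=float),
                                 self.y.shape).copy()
        self.mult = np.broadcast_to(np.asarray(mult, dtype=float),
                                    self.y.shape).copy()
        index = {int(m): j for j, m in enumerate(self.mutation_ids)}
        self.edges: list[CloneNode] = []
        self._edge_idx: list[np.ndarray] = []
        for node in tree.edges():
            if node.muts is None:
                raise ValueError("tree edges must carry mutation sets (muts)")
            idx = np.array(sorted(index[m] for m in node.muts if m in index),
                           dtype=np.int64)
            self.edges.append(node)
            self._edge_idx.append(idx)
        if not self.edges:
            raise ValueError("tree has no edges")

    # ---------------------------------------------------------------- #
    def _site_logliks(self, rho, p0):
        p_i = success_prob(rho, self.mult, self.c) if rho > 0 else \
            np.zeros_like(self.c)
        l1 = _binom_logpmf(self.y, self.n, p_i)
        l0 = _binom_logpmf(self.y, self.n, np.full_like(self.c, p0))
        return l1, l0

    def _anc(self, node: CloneNode) -> list[CloneNode]:
        out = []
        p = node.parent
        while p is not None and p.parent is not None:
            out.append(p)
            p = p.parent
        return out

    def loglik(self, edge: CloneNode, pi_m, p0, rho) -> float:
        """log L(e, pi_m, p0, rho) for one candidate edge."""
        if edge not in self.edges:
            raise ValueError("edge not in tree")
        l1, l0 = self._site_logliks(rho, p0)
        j = self.edges.index(edge)
        focal = self._edge_idx[j]
        anc = {id(a) for a in self._anc(edge)}
        total = float(np.sum(_mix(l1[focal], l0[focal], pi_m)))
        for jj, node in enumerate(self.edges):
            if node is edge:
                continue
            idx = self._edge_idx[jj]
            if id(node) in anc:
                total += float(np.sum(l1[idx]))
            else:
                total += float(np.sum(l0[idx]))
        return total

    # ---------------------------------------------------------------- #
    def _profile(self, rho_grid, p0_grid, pi_grid):
        """Best (pi_m, p0, rho) per edge over the coarse grid."""
        n_edges = len(self.edges)
        anc_sets = [
            {id(a) for a in self._anc(e)} for e in self.edges]
        best = np.full(n_edges, np.inf)
        best_par = np.zeros((n_edges, 3))
        pi_grid = np.asarray(pi_grid, dtype=float)
        with np.errstate(divide="ignore"):
            log_pi = np.log(pi_grid)
            log_1mpi = np.log1p(-pi_grid)
        for rho in rho_grid:
            for p0 in p0_grid:
                l1, l0 = self._site_logliks(rho, p0)
                s1 = np.array([l1[idx].sum() for idx in self._edge_idx])
                s0 = np.array([l0[idx].sum() for idx in self._edge_idx])
                t0 = s0.sum()
                for j, edge in enumerate(self.edges):
                    ancs = [jj for jj in range(n_edges)
                            if id(self.edges[jj]) in anc_sets[j]]
                    base = t0 - s0[j] - sum(s0[a] for a in ancs) + \
                        sum(s1[a] for a in ancs)
                    focal = self._edge_idx[j]
                    if len(focal):
                        mix = np.logaddexp(
                            log_pi[None, :] + l1[focal][:, None],
                            log_1mpi[None, :] + l0[focal][:, None]).sum(0)
                    else:
                        mix = np.zeros_like(pi_grid)
                    nlls = -(base + mix)
                    k = int(np.argmin(nlls))
                    if nlls[k] < best[j]:
                        best[j] = nlls[k]
                        best_par[j] = (pi_grid[k], p0, rho)
        return best, best_par

    def fit(self, rho_grid=None, p0_grid=None, pi_grid=None,
            refine: bool = True, fixed_rho: float | None = None
            ) -> "PlacementResult":
        """Minimize the NLL over edges x (pi_m, p0, rho).

        Coarse grid per edge followed by bounded local refinement of the
        continuous parameters at the best edges.  Ties between edges are
        broken toward the rootmost edge (smallest root distance).
        """
        if rho_grid is None:
            rho_grid = ([fixed_rho] if fixed_rho is not None
                        else np.linspace(0.05, 1.0, 20))
        if p0_grid is None:
            p0_grid = np.array([1e-4, 1e-3, 3e-3, 0.01, 0.03, 0.1, 0.3])
        if pi_grid is None:
            pi_grid = np.linspace(0.0, 1.0, 21)
        best, best_par = self._profile(rho_grid, p0_grid, pi_grid)

        if refine:
            order = np.argsort(best)[:3]
            for j in order:
                x0 = best_par[j]

                def nll_fun(x, j=j):
                    return -self.loglik(self.edges[j], x[0], x[1], x[2])

                if fixed_rho is not None:
                    def nll_fun(x, j=j):  # noqa: F811
                        return -self.loglik(self.edges[j], x[0], x[1],
                                            fixed_rho)
                    x0 = x0[:2]
                    bounds = [(0, 1), (1e-6, 1)]
                else:
                    bounds = [(0, 1), (1e-6, 1), (1e-3, 1)]
                res = optimize.minimize(nll_fun, x0, method="L-BFGS-B",
                                        bounds=bounds)
                if res.fun < best[j]:
                    best[j] = res.fun
                    if fixed_rho is not None:
                        best_par[j] = (res.x[0], res.x[1], fixed_rho)
                    else:
                        best_par[j] = res.x

        # tie-break toward rootmost edge
        depth = self.tree.depths()
        root_dist = np.array([depth[e.parent] for e in self.edges])
        cand = np.flatnonzero(best <= best.min() + 1e-9)
        jbest = cand[np.argmin(root_dist[cand])]

        flat = bool(best.max() - best.min() < 1e-6)
        status = "ok"
        if flat:
            status = "unplaceable: flat likelihood across edges"
        pi_m, p0, rho = best_par[jbest]
        return PlacementResult(
            model=self, edge=self.edges[jbest], pi_m=float(pi_m),
            p0=float(p0), rho=float(rho), nll=float(best[jbest]),
            profile=pd.DataFrame({
                "edge": [self._edge_name(e) for e in self.edges],
                "nll": best, "pi_m": best_par[:, 0],
                "p0": best_par[:, 1], "rho": best_par[:, 2]}),
            status=status)

    def _edge_name(self, edge: CloneNode) -> str:
        return edge_name(edge)


@dataclass
class PlacementResult:
    """MLE placement of one low-pass sample."""

    model: SamplePlacement
    edge: CloneNode
    pi_m: float
    p0: float
    rho: float
    nll: float
    profile: pd.DataFrame
    status: str

    @property
    def placeable(self) -> bool:
        return self.status == "ok"

    def summary(self) -> str:
        lines = [
            "Low-pass sample placement (maximum likelihood)",
            f"  edge:       {self.model._edge_name(self.edge)}",
            f"  pi_m:       {self.pi_m:.3f}",
            f"  purity rho: {self.rho:.3f}",
            f"  noise p0:   {self.p0:.4g}",
            f"  NLL:        {self.nll:.3f}",
            f"  status:     {self.status}",
        ]
        return "\n".join(lines)


def placement_loglik(tree, mutation_ids, y, n, edge, pi_m, p0, rho,
                     c=2.0, mult=1.0) -> float:
    """Functional wrapper: log L of one (edge, pi_m, p0, rho) combination."""
    return SamplePlacement(tree, mutation_ids, y, n, c=c, mult=mult).loglik(
        edge, pi_m, p0, rho)


def place_sample(tree, mutation_ids, y, n, c=2.0, mult=1.0,
                 **fit_kw) -> PlacementResult:
    """Functional wrapper: build the model and fit it."""
    return SamplePlacement(tree, mutation_ids, y, n, c=c, mult=mult).fit(
        **fit_kw)


# --------------------------------------------------------------------- #
# multiplicity estimation
# --------------------------------------------------------------------- #

def estimate_multiplicity(y, n, c, rho, detected=None) -> int:
    """Estimate the mutated-allele multiplicity across samples.

    argmin over m in {1..c} of the summed binomial NLL at
    p_s(m) = rho_s*m / (2 - 2*rho_s + rho_s*c), restricted to samples where
    the mutation was detected.  Only sites with 0 < c < 4 are eligible.
    """
    c = int(c)
    if not 0 < c < 4:
        raise ValueError(f"copy number {c} outside the open interval (0, 4)")
    y = np.asarray(y)
    n = np.asarray(n)
    rho = np.asarray(rho, dtype=float)
    det = np.ones_like(y, dtype=bool) if detected is None \
        else np.asarray(detected, dtype=bool)
    if not det.any():
        raise ValueError("mutation detected in no sample")
    best_m, best_nll = None, np.inf
    for m in range(1, c + 1):
        p = success_prob(rho[det], m, c)
        nll = -float(np.sum(_binom_logpmf(y[det], n[det], p)))
        if nll < best_nll:
            best_m, best_nll = m, nll
    return best_m


# --------------------------------------------------------------------- #
# leaf-length imputation forest
# --------------------------------------------------------------------- #

def impute_leaf_forest(tree: CloneTree, region_unique_counts: dict,
                       lowpass_tips, tip_regions: dict,
                       n_trees: int = 100, seed: int = 0,
                       drop: list | None = None) -> list[CloneTree]:
    """Forest of trees with Poisson-imputed low-pass terminal lengths.

    Low-pass tips carry no private mutations (they cannot be called at
    ~1.2x), so their terminal edge length is drawn from a Poisson whose mean
    is the average number of unique mutations of the deep samples from the
    same spatial region.  Topology and deep-tip lengths are unchanged; the
    forest holds ``n_trees`` independent draws.  Tips listed in ``drop``
    (e.g. without expression data) are removed first.
    """
    lowpass_tips = set(lowpass_tips)
    base = tree.drop_tips(drop) if drop else tree.copy()
    means = {}
    for t in base.tips():
        if t.name in lowpass_tips:
            region = tip_regions.get(t.name)
            if region not in region_unique_counts or \
                    len(region_unique_counts[region]) == 0:
                raise ValueError(
                    f"region {region!r} has no deep sample to impute from")
            means[t.name] = float(np.mean(region_unique_counts[region]))
    rng = np.random.default_rng(seed)
    forest = []
    for _ in range(n_trees):
        t2 = base.copy()
        for tip in t2.tips():
            if tip.name in means:
                tip.length = float(rng.poisson(means[tip.name]))
        forest.append(t2)
    return forest
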