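"""Gland-level spatial agent-based simulator of tumour growth.

Each agent is one tumour gland (a clonal unit occupying one site of a 2D
square lattice).  Glands divide, die and accumulate somatic mutations; the
width ``d_push`` of the proliferative outer rim controls whether growth is
boundary-restricted (small ``d_push``) or effectively exponential (``d_push``
of the order of the tumour diameter).  Up to two selected subclones with
birth-rate multipliers ``lambda2``/``lambda3`` are introduced by converting a
uniformly chosen live gland once the population reaches ``t2``/``t3`` glands.

Per-division mutation counts are negative-binomially distributed with mean
``m * genome_size`` and variance ``mean * D`` (``D = 1`` is the exact Poisson
limit).  Every mutation is unique (infinite-sites): mutation identifiers are
assigned as disjoint integer ranges per genealogy edge.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from . import _spatial_core as _core
from .trees import CloneNode, CloneTree

__all__ = [
    "SimParams",
    "SimResult",
    "ExtinctionError",
    "run_to_size",
    "spatial_growth_mode",
    "true_sample_tree",
]


class ExtinctionError(RuntimeError):
    """The gland population died out before reaching ``N_end``."""


@dataclass
class SimParams:
    """Parameters of the spatial gland simulator.

    Parameters
    ----------
    m : float
        Mutation rate per base pair per division.
    genome_size : float
        Number of base pairs considered; the per-division mutation count has
        mean ``m * genome_size``.
    D : float
        Overdispersion of per-division mutation counts (variance = mean * D);
        1 is the Poisson limit.
    d_push : int
        Width of the proliferative rim, in lattice cells (Chebyshev
        distance).  A dividing gland needs an empty site within ``d_push``
        along a straight ray to place its daughter.
    lambda2, lambda3 : float
        Birth-rate multipliers of subclones 1 and 2 (1 = inactive/neutral).
    t2, t3 : int
        Population sizes (gland counts) at which each subclone is introduced.
    death_rate : float
        Probability of a death side-event per birth attempt.
    N_end : int
        Final number of live glands.
    grid_side : int or None
        Lattice dimension; by default sized generously for ``N_end``.
    seed : int
        RNG seed (single global stream per run).
    """

    m: float = 1e-8
    genome_size: float = 3e9
    D: float = 1.0
    d_push: int = 1
    lambda2: float = 1.0
    lambda3: float = 1.0
    t2: int = 0
    t3: int = 0
    death_rate: float = 0.0
    N_end: int = 1000
    grid_side: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.m < 0 or self.genome_size < 0:
            raise ValueError("mutation rate and genome size must be >= 0")
        if self.D < 1:
            raise ValueError("overdispersion D must be >= 1")
        if self.d_push < 1:
            raise ValueError("d_push must be >= 1")
        if self.lambda2 < 1 or self.lambda3 < 1:
            raise ValueError("subclone multipliers must be >= 1")
        if not 0 <= self.death_rate < 1:
            raise ValueError("death_rate must be in [0, 1)")
        if self.N_end < 1:
            raise ValueError("N_end must be >= 1")
        if self.lambda2 > 1 and self.lambda3 > 1 and not (
                self.t2 < self.t3 < self.N_end):
            raise ValueError("need t2 < t3 < N_end when both subclones active")
        side = self.grid_side or default_grid_side(self.N_end)
        if side * side < self.N_end:
            raise ValueError(f"grid {side}x{side} cannot hold {self.N_end} glands")
        self.grid_side = side

    def replace(self, **kw) -> "SimParams":
        return dataclasses.replace(self, **kw)


def default_grid_side(n_end: int) -> int:
    """A lattice comfortably holding a round tumour of ``n_end`` glands."""
    return max(8, int(3 * math.sqrt(n_end)) + 4)


class SimResult:
    """Outcome of one simulator run.

    Attributes
    ----------
    parent : ndarray
        Parent pointer per genealogy node (-1 for the founder, node 0).
    nmut : ndarray
        Mutations acquired on the edge above each node.
    node_clone : ndarray
        Clone index of the lineage at each node (0 background, 1, 2).
    live_nodes : ndarray
        Genealogy node id of each live gland (these are the gland ids).
    live_pos : ndarray, shape (n_live, 2)
        Lattice coordinates of live glands.
    clone_of : dict
        Live gland id -> clone index.
    pop_history : ndarray
        Live population size after each event.
    boundary_dist : ndarray
        Per successful division, the Chebyshev distance from the mother to
        the nearest empty lattice site (recorded when requested).
    subclone_nodes : ndarray
        Genealogy node at which each subclone conversion occurred (-1 none).
    """

    def __init__(self, params, parent, nmut, node_clone, live_nodes, live_pos,
                 live_clones, pop_history, boundary_dist, subclone_nodes):
        self.params = params
        self.parent = parent
        self.nmut = nmut
        self.node_clone = node_clone
        self.live_nodes = live_nodes
        self.live_pos = live_pos
        self.live_clones = live_clones
        self.pop_history = pop_history
        self.boundary_dist = boundary_dist
        self.subclone_nodes = subclone_nodes
        # mutation ids of edge above node i: [mut_offset[i], mut_offset[i+1])
        self.mut_offset = np.concatenate([[0], np.cumsum(nmut)])

    @property
    def n_live(self) -> int:
        return len(self.live_nodes)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_mutations(self) -> int:
        return int(self.mut_offset[-1])

    @property
    def clone_of(self) -> dict[int, int]:
        return {int(g): int(c)
                for g, c in zip(self.live_nodes, self.live_clones)}

    def mutation_ids(self, node: int) -> range:
        """Mutation ids acquired on the genealogy edge above ``node``."""
        return range(int(self.mut_offset[node]), int(self.mut_offset[node + 1]))

    def lineage_mutations(self, gland: int) -> set[int]:
        """All mutation ids carried by a live gland (root-to-leaf union)."""
        if gland < 0 or gland >= self.n_nodes:
            raise KeyError(f"unknown gland id {gland}")
        out: set[int] = set()
        node = int(gland)
        while node >= 0:
            out.update(self.mutation_ids(node))
            node = int(self.parent[node])
        return out

    def lattice(self) -> np.ndarray:
        """Lattice snapshot: gland id + 1 per occupied site, 0 empty."""
        side = self.params.grid_side
        grid = np.zeros((side, side), dtype=np.int64)
        for g, (r, c) in zip(self.live_nodes, self.live_pos):
            grid[r, c] = g + 1
        return grid

    def clone_frequency(self, clone: int) -> float:
        return float(np.mean(self.live_clones == clone)) if self.n_live else 0.0


def run_to_size(params: SimParams, record_boundary: bool = True,
                max_events: int | None = None) -> SimResult:
    """Run the simulator until ``N_end`` live glands exist.

    Raises
    ------
    ExtinctionError
        If the population dies out first.
    RuntimeError
        On lattice overflow or a stalled run (no legal division for a very
        long time).
    """
    p = params
    if max_events is None:
        max_events = 80 * p.N_end + 4000
    max_nodes = 4 * p.N_end + 16 + 2 * int(p.death_rate * max_events + 1)
    out = _core.grow(
        p.grid_side, p.N_end, p.m * p.genome_size, p.D, p.d_push,
        p.lambda2, p.lambda3, p.t2, p.t3, p.death_rate,
        int(p.seed) % (2**31 - 1), record_boundary, max_events, max_nodes,
    )
    (parent, nmut, node_clone, pos_r, pos_c, live_nodes, live_clones,
     pop_hist, bdist, sub_nodes, status) = out
    if status == _core.EXTINCT:
        raise ExtinctionError(
            f"population extinct before reaching N_end={p.N_end} "
            f"(death_rate={p.death_rate})")
    if status == _core.OVERFLOW:
        raise RuntimeError("genealogy buffer overflow; increase max_events bound")
    if status == _core.STALLED:
        raise RuntimeError(
            f"no progress after {max_events} events (lattice jammed?)")
    live_pos = np.column_stack([pos_r, pos_c])
    return SimResult(p, parent.copy(), nmut.copy(), node_clone.copy(),
                     live_nodes.copy(), live_pos, live_clones.copy(),
                     pop_hist.copy(), bdist.copy() if record_boundary else None,
                     sub_nodes.copy())


def spatial_growth_mode(result: SimResult) -> float | None:
    """Fraction of divisions that occurred within ``d_push`` of the tumour
    boundary (the nearest empty lattice site).

    Returns None when no divisions occurred or boundary distances were not
    recorded.  Values near 1 with small ``d_push`` indicate rim-restricted
    (surface) growth; a large ``d_push`` lets interior glands divide too.
    """
    bd = result.boundary_dist
    if bd is None or len(bd) == 0:
        return None
    return float(np.mean(bd <= result.params.d_push))


def true_sample_tree(result: SimResult, gland_ids,
                     with_mutations: bool = True) -> CloneTree:
    """Genealogy restricted to the sampled glands.

    Internal unary nodes are suppressed; edge lengths are the summed mutation
    counts along collapsed paths, and (optionally) the edge mutation-id sets
    are attached.  The root of the returned tree is the germline/founder.
    """
    gland_ids = [int(g) for g in gland_ids]
    live = set(int(g) for g in result.live_nodes)
    for g in gland_ids:
        if g not in live:
            raise KeyError(f"gland {g} is not a live gland")
    parent = result.parent
    nmut = result.nmut

    # induced subtree node set: all ancestors of sampled leaves
    keep: set[int] = set()
    for g in gland_ids:
        node = g
        while node >= 0 and node not in keep:
            keep.add(node)
            node = int(parent[node])

    children: dict[int, list[int]] = {n: [] for n in keep}
    for n in keep:
        pa = int(parent[n])
        if pa >= 0:
            children[pa].append(n)

    sampled = set(gland_ids)

    def build(node: int) -> CloneNode:
        # walk down chains of unary, unsampled nodes, accumulating length
        length = nmut[node]
        muts = set(result.mutation_ids(node)) if with_mutations else None
        while len(children[node]) == 1 and node not in sampled:
            node = children[node][0]
            length += nmut[node]
            if with_mutations:
                muts.update(result.mutation_ids(node))
        name = f"g{node}" if node in sampled else None
        out = CloneNode(name=name, length=float(length), muts=muts)
        for c in sorted(children[node]):
            out.add_child(build(c))
        return out

    # root: keep the founder-side edge as the trunk
    root = CloneNode(name=None, length=0.0, muts=set() if with_mutations else None)
    root.add_child(build(0))
    return CloneTree(root)
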