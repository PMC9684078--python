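"""Maximum-parsimony tree building from binarized mutation profiles.

Deep-sample variant calls are converted to cancer cell fractions (CCF),
binarized at CCF > 0.25, and a maximum-parsimony tree is searched with a
parsimony ratchet (weight perturbation + nearest-neighbour-interchange hill
climbing).  Trees are rooted on an implicit all-zero germline outgroup.
Ancestral states are resolved with accelerated transformation (acctran),
yielding the per-edge sets of uniquely acquired mutations ``M_e`` used by
low-pass placement.
"""

from __future__ import annotations

import itertools

import numpy as np

from .trees import CloneNode, CloneTree

__all__ = [
    "estimate_ccf",
    "binarize",
    "BinaryCharacterMatrix",
    "parsimony_score",
    "ratchet_search",
    "acctran_states",
    "attach_edge_mutations",
    "enumerate_topologies",
]


def estimate_ccf(y, n, purity, c=2.0, mult=1.0):
    """Cancer cell fraction from read counts: VAF scaled by purity/copy-number.

    ccf = (y/n) * (2 - 2*purity + purity*c) / (purity * mult), clamped to
    [0, 1.5].  Sites with n = 0 are missing (NaN), not zero.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    purity = np.asarray(purity, dtype=float)
    if np.any((purity <= 0) | (purity > 1)):
        raise ValueError("purity must be in (0, 1]")
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(n > 0, y / np.where(n > 0, n, 1), np.nan)
        ccf = vaf * (2.0 - 2.0 * purity + purity * c) / (purity * mult)
    return np.clip(ccf, 0.0, 1.5)


class BinaryCharacterMatrix:
    """Samples x mutations 0/1 matrix for parsimony.

    Constant columns (same state in all samples) are dropped and recorded in
    ``dropped`` since they carry no topological information; all-one columns
    are truncal given the germline root and count 1 change each (kept in
    ``truncal``).
    """

    def __init__(self, matrix: np.ndarray, sample_names, mutation_ids,
                 drop_constant: bool = True):
        matrix = np.asarray(matrix, dtype=np.int8)
        if matrix.ndim != 2 or matrix.shape[0] < 2:
            raise ValueError("need a 2D matrix with at least 2 samples")
        if not np.isin(matrix, (0, 1)).all():
            raise ValueError("matrix must be binary")
        self.sample_names = list(sample_names)
        mutation_ids = np.asarray(mutation_ids)
        keep = np.ones(matrix.shape[1], dtype=bool)
        self.dropped = np.array([], dtype=mutation_ids.dtype)
        self.truncal = np.array([], dtype=mutation_ids.dtype)
        if drop_constant:
            colsum = matrix.sum(axis=0)
            allzero = colsum == 0
            allone = colsum == matrix.shape[0]
            keep = ~allzero & ~allone
            self.dropped = mutation_ids[allzero]
            self.truncal = mutation_ids[allone]
        self.matrix = matrix[:, keep]
        self.mutation_ids = mutation_ids[keep]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]


def binarize(ccf_matrix, sample_names, mutation_ids,
             threshold: float = 0.25, **kw) -> BinaryCharacterMatrix:
    """State 1 iff CCF strictly above ``threshold``; missing (NaN) is 0."""
    ccf = np.asarray(ccf_matrix, dtype=float)
    mat = np.where(np.isnan(ccf), 0, (ccf > threshold).astype(int))
    return BinaryCharacterMatrix(mat, sample_names, mutation_ids, **kw)


# --------------------------------------------------------------------- #
# Fitch scoring
# --------------------------------------------------------------------- #

def _tip_index(tree: CloneTree, sample_names) -> dict:
    pos = {name: i for i, name in enumerate(sample_names)}
    out = {}
    for tip in tree.tips():
        if tip.name not in pos:
            raise ValueError(f"tip {tip.name!r} not among samples")
        out[tip] = pos[tip.name]
    if len(out) != len(sample_names):
        raise ValueError("tree tips and samples do not match")
    return out


def parsimony_score(tree: CloneTree, matrix: BinaryCharacterMatrix,
                    weights: np.ndarray | None = None,
                    rooted: bool = False) -> float:
    """Fitch small-parsimony change count summed over characters.

    With ``rooted=False`` (default) the root state is free, so the score is
    the standard unrooted Fitch count and invariant to the germline
    attachment point.  With ``rooted=True`` the germline root is forced to
    state 0, adding one change for every character whose root state set
    excludes 0; this is the count that acctran edge assignments conserve.
    """
    tips = _tip_index(tree, matrix.sample_names)
    x = matrix.matrix
    k = x.shape[1]
    if weights is None:
        weights = np.ones(k)
    # state sets encoded as bitmasks: 1 -> {0}, 2 -> {1}, 3 -> {0,1}
    masks: dict[CloneNode, np.ndarray] = {}
    changes = np.zeros(k)
    for node in tree.postorder():
        if node.is_tip:
            masks[node] = np.where(x[tips[node]] == 1, 2, 1).astype(np.int8)
        else:
            m = None
            for c in node.children:
                cm = masks[c]
                if m is None:
                    m = cm.copy()
                else:
                    inter = m & cm
                    union = m | cm
                    empty = inter == 0
                    changes += weights * empty
                    m = np.where(empty, union, inter).astype(np.int8)
            masks[node] = m
    if rooted:
        # germline root: state 0 must be attainable at the root set
        changes += weights * ((masks[tree.root] & 1) == 0)
    return float(changes.sum())


# --------------------------------------------------------------------- #
# tree search
# --------------------------------------------------------------------- #

def _upgma_start(matrix: BinaryCharacterMatrix, rng) -> CloneTree:
    """Average-linkage starting tree on jittered Hamming distances."""
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import pdist

    x = matrix.matrix.astype(float)
    n_pairs = x.shape[0] * (x.shape[0] - 1) // 2
    jitter = rng.uniform(0, 1e-6, size=n_pairs)
    if x.shape[1] == 0:  # all samples identical: any tree scores 0
        d = jitter
    else:
        d = pdist(x, metric="hamming") + jitter
    z = hierarchy.linkage(d, method="average")
    nodes = [CloneNode(name=s) for s in matrix.sample_names]
    for a, b, _, _ in z:
        parent = CloneNode()
        parent.add_child(nodes[int(a)])
        parent.add_child(nodes[int(b)])
        nodes.append(parent)
    root = CloneNode()
    root.add_child(nodes[-1])
    return CloneTree(root)


def _nni_neighbours(tree: CloneTree):
    """Yield trees one nearest-neighbour interchange away.

    For every internal edge (u, v) with v internal, swap one child of v with
    one sibling subtree of v (two distinct rearrangements per edge).
    """
    for v in tree.edges():
        if v.is_tip:
            continue
        u = v.parent
        siblings = [c for c in u.children if c is not v]
        for sib in siblings:
            for i in range(len(v.children)):
                t2 = tree.copy()
                # find corresponding nodes in the copy by traversal order
                order = list(tree.preorder())
                order2 = list(t2.preorder())
                idx = {id(n): j for j, n in enumerate(order)}
                u2 = order2[idx[id(u)]]
                v2 = order2[idx[id(v)]]
                sib2 = order2[idx[id(sib)]]
                child2 = order2[idx[id(v.children[i])]]
                u2.children[u2.children.index(sib2)] = child2
                v2.children[v2.children.index(child2)] = sib2
                sib2.parent, child2.parent = v2, u2
                yield t2


def ratchet_search(matrix: BinaryCharacterMatrix, min_iter: int = 100,
                   max_iter: int = 1_000_000, stop_no_improve: int = 100,
                   seed: int = 0) -> CloneTree:
    """Parsimony-ratchet search for a minimum-change tree.

    Each iteration upweights a random 25% of characters, hill-climbs with
    NNI under the perturbed weights, restores the original weights and
    hill-climbs again, keeping the result if it improves the score.  Runs at
    least ``min_iter`` iterations and stops after ``stop_no_improve``
    consecutive iterations without improvement (or at ``max_iter``).
    """
    if matrix.n_samples < 3:
        raise ValueError("need at least 3 samples for tree search")
    rng = np.random.default_rng(seed)
    k = matrix.n_sites

    def climb(tree, weights):
        best = tree
        best_score = parsimony_score(best, matrix, weights)
        improved = True
        while improved:
            improved = False
            for cand in _nni_neighbours(best):
                s = parsimony_score(cand, matrix, weights)
                if s < best_score - 1e-9:
                    best, best_score = cand, s
                    improved = True
                    break
        return best, best_score

    def random_jitter(tree, moves=2):
        """A short random NNI walk, used to escape local optima."""
        for _ in range(moves):
            neighbours = list(_nni_neighbours(tree))
            if not neighbours:
                return tree
            tree = neighbours[rng.integers(len(neighbours))]
        return tree

    best, best_score = climb(_upgma_start(matrix, rng), None)
    since_improve = 0
    for it in range(max_iter):
        if it >= min_iter and since_improve >= stop_no_improve:
            break
        w = np.ones(k)
        if k:
            w[rng.random(k) < 0.25] = 3.0
        pert, _ = climb(random_jitter(best), w)
        cand, cand_score = climb(pert, None)
        if cand_score < best_score - 1e-9:
            best, best_score = cand, cand_score
            since_improve = 0
        else:
            since_improve += 1
    return root_by_germline(best, matrix)


def root_by_germline(tree: CloneTree, matrix: BinaryCharacterMatrix
                     ) -> CloneTree:
    """Root on the edge where the all-zero germline outgroup attaches most
    parsimoniously (minimal rooted score; first-found on ties)."""
    best, best_score = None, np.inf
    for i in range(len(tree.edges())):
        cand = tree.copy()
        cand.reroot_above(cand.edges()[i])
        s = parsimony_score(cand, matrix, rooted=True)
        if s < best_score - 1e-9:
            best, best_score = cand, s
    if best is None:
        return tree
    # unary germline root above the attachment point, so the MRCA's edge
    # is an explicit trunk that acctran can hang truncal mutations on
    germ = CloneNode()
    germ.add_child(best.root)
    best.root = germ
    return best


def enumerate_topologies(sample_names):
    """All unrooted binary topologies over the samples ((2n-5)!! for n >= 3).

    Returned as arbitrarily rooted CloneTrees (the first sample attached at
    the root); the free-root Fitch score of such a tree is the unrooted
    parsimony score.  Brute-force oracle for small n.
    """
    names = list(sample_names)
    if len(names) < 2:
        raise ValueError("need at least 2 samples")
    first, names = names[0], names[1:]

    def grow(trees, name):
        out = []
        for t in trees:
            for v in t.edges():
                t2 = t.copy()
                order = list(t.preorder())
                order2 = list(t2.preorder())
                v2 = order2[order.index(v)]
                u2 = v2.parent
                mid = CloneNode()
                u2.children[u2.children.index(v2)] = mid
                mid.parent = u2
                mid.add_child(v2)
                mid.add_child(CloneNode(name=name))
                out.append(t2)
        return out

    root = CloneNode()
    root.add_child(CloneNode(name=names[0]))
    trees = [CloneTree(root)]
    for name in names[1:]:
        trees = grow(trees, name)
    for t in trees:
        t.root.add_child(CloneNode(name=first))
    return trees


# --------------------------------------------------------------------- #
# acctran ancestral states and edge mutation sets
# --------------------------------------------------------------------- #

def acctran_states(tree: CloneTree, matrix: BinaryCharacterMatrix
                   ) -> tuple[dict[CloneNode, set], dict[CloneNode, set]]:
    """Accelerated-transformation ancestral states.

    A unit-cost Sankoff pass computes, per node and state, the minimal
    number of changes in its subtree; the preorder resolution then picks the
    cheapest state, breaking ties in favour of a state different from the
    parent so changes are placed as close to the root as possible
    (accelerated transformation).

    Returns ``(gains, losses)``: per edge (keyed by child node) the set of
    mutation ids changing 0->1 (``M_e``) and 1->0.
    """
    tips = _tip_index(tree, matrix.sample_names)
    x = matrix.matrix
    k = x.shape[1]
    big = 10**9
    cost: dict[CloneNode, np.ndarray] = {}  # (2, k) costs per state
    for node in tree.postorder():
        if node.is_tip:
            c = np.zeros((2, k), dtype=np.int64)
            c[0] = np.where(x[tips[node]] == 1, big, 0)
            c[1] = np.where(x[tips[node]] == 1, 0, big)
        else:
            c = np.zeros((2, k), dtype=np.int64)
            for ch in node.children:
                cc = cost[ch]
                c[0] += np.minimum(cc[0], cc[1] + 1)
                c[1] += np.minimum(cc[1], cc[0] + 1)
        cost[node] = c

    state: dict[CloneNode, np.ndarray] = {}
    gains: dict[CloneNode, set] = {}
    losses: dict[CloneNode, set] = {}
    # germline root fixed at state 0
    state[tree.root] = np.zeros(k, dtype=np.int8)
    for node in tree.preorder():
        if node.parent is None:
            continue
        ps = state[node.parent]
        c = cost[node]
        stay = np.take_along_axis(c, ps[None, :].astype(np.int64), 0)[0]
        flip = np.take_along_axis(c, (1 - ps)[None, :].astype(np.int64), 0)[0] + 1
        # acctran: on ties prefer the change (flip <= stay -> flip)
        s = np.where(flip <= stay, 1 - ps, ps).astype(np.int8)
        state[node] = s
        gained = np.flatnonzero((ps == 0) & (s == 1))
        lost = np.flatnonzero((ps == 1) & (s == 0))
        gains[node] = set(matrix.mutation_ids[gained])
        losses[node] = set(matrix.mutation_ids[lost])
    return gains, losses


def attach_edge_mutations(tree: CloneTree, matrix: BinaryCharacterMatrix,
                          include_truncal: bool = True) -> CloneTree:
    """Annotate each edge with its acctran M_e set and set lengths |M_e|.

    Truncal mutations (state 1 in every sample) attach to the edge below the
    root.
    """
    gains, _ = acctran_states(tree, matrix)
    for node in tree.preorder():
        if node.parent is None:
            node.muts = set()
            node.length = 0.0
            continue
        node.muts = set(gains[node])
        if include_truncal and node.parent is tree.root and \
                len(tree.root.children) == 1:
            node.muts |= set(matrix.truncal)
        node.length = float(len(node.muts))
    return tree
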