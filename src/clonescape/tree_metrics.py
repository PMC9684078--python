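"""Tree summary statistics for ABC, including the region-intermixing score.

The intermixing score I(T) quantifies spatial clone mixing: for each tip v,
take all tips descending from v's parent (v included) and count the
fraction with a region label different from v's; I(T) is the mean over
tips.  Monophyletic regions give 0; a star tree with all-distinct labels
gives (k-1)/k.

The summary vector feeding ABC distances combines per-region terminal-edge
statistics, the trunk (clonal) fraction, between-region patristic
distances, the intermixing score, tip count and total length.  Distances
between summary vectors are Euclidean after robust (median/MAD) scaling
computed from a reference (prior-predictive) set.
"""

from __future__ import annotations

import itertools

import numpy as np

from .trees import CloneTree

__all__ = [
    "intermixing_score",
    "tree_summary",
    "summary_labels",
    "RobustScale",
    "tree_distance",
    "noise_baseline",
]


def intermixing_score(tree: CloneTree) -> float:
    """Mean fraction of differently-labelled tips among each tip's parent's
    descendant tips (the tip itself included, contributing 0)."""
    tips = tree.tips()
    for t in tips:
        if t.label is None:
            raise ValueError(f"tip {t.name!r} has no region label")
    if len(tips) < 2:
        return 0.0
    # tips under each node, computed once
    under: dict = {}
    for node in tree.postorder():
        if node.is_tip:
            under[node] = [node]
        else:
            under[node] = [t for c in node.children for t in under[c]]
    total = 0.0
    for v in tips:
        parent = v.parent if v.parent is not None else v
        group = under[parent]
        diff = sum(1 for s in group if s.label != v.label)
        total += diff / len(group)
    return total / len(tips)


def summary_labels(regions=None) -> list[str]:
    """Names of the entries of the summary vector."""
    return ["terminal_mean", "terminal_sd",
            "terminal_region_min", "terminal_region_max",
            "trunk_fraction", "patristic_min", "patristic_max",
            "max_internal_frac", "depth_cv", "mrca_frac",
            "late_coalesce_frac", "intermixing", "n_tips", "total_length"]


def tree_summary(tree: CloneTree) -> np.ndarray:
    """Fixed-length numeric summary of a region-labelled tree.

    Entries (see :func:`summary_labels`): overall mean and s.d. of terminal
    edge lengths; smallest and largest per-region terminal-length means
    (extremes rather than the full sorted list, so the vector is invariant
    to region relabelling and tree-shape statistics are not diluted by
    redundant length entries); trunk fraction (clonal length below the
    root over total length); smallest and largest per-region-pair mean
    patristic distance; fraction of total length in the single longest
    internal edge (a partial selective sweep leaves one long edge
    subtending the swept clade); coefficient of variation of root-to-tip
    depths; mean pairwise MRCA depth over mean tip depth, and the fraction
    of tip pairs coalescing later than 15% of the mean tip depth (a sweep
    forces most pairs to coalesce at the subclone conversion, deep in the
    tree, whereas neutral spatial growth splits regions early);
    intermixing score; tip count; total length.  Length-type entries scale
    with the mutation rate; ratio-type entries are scale-free.
    """
    tips = tree.tips()
    regions = sorted({t.label for t in tips})
    if None in regions:
        raise ValueError("all tips must carry region labels")
    term = np.array([t.length for t in tips], dtype=float)
    out = [float(term.mean()), float(term.std())]
    region_means = []
    for r in regions:
        lens = np.array([t.length for t in tips if t.label == r], dtype=float)
        region_means.append(float(lens.mean()) if len(lens) else 0.0)
    out += [min(region_means), max(region_means)]
    total = tree.total_length()
    trunk = 0.0
    node = tree.root
    while len(node.children) == 1:
        node = node.children[0]
        trunk += node.length
    out.append(trunk / total if total > 0 else 0.0)
    names, cov = tree.vcv()
    diag = np.diag(cov)
    dmat = diag[:, None] + diag[None, :] - 2 * cov  # patristic from MRCA depths
    label_of = {t.name: t.label for t in tips}
    pair_means = []
    for a, b in itertools.combinations(regions, 2):
        ia = [i for i, nm in enumerate(names) if label_of[nm] == a]
        ib = [i for i, nm in enumerate(names) if label_of[nm] == b]
        pair_means.append(float(dmat[np.ix_(ia, ib)].mean()))
    if pair_means:
        out += [min(pair_means), max(pair_means)]
    else:
        out += [0.0, 0.0]
    internal = [e.length for e in tree.edges()
                if not e.is_tip and e.parent is not tree.root]
    out.append(max(internal) / total if internal and total > 0 else 0.0)
    tip_depths = diag
    mean_depth = float(tip_depths.mean())
    out.append(float(tip_depths.std() / mean_depth) if mean_depth > 0 else 0.0)
    mrca = cov[np.triu_indices(len(tips), 1)]
    if len(mrca) and mean_depth > 0:
        out.append(float(mrca.mean() / mean_depth))
        out.append(float(np.mean(mrca > 0.15 * mean_depth)))
    else:
        out += [0.0, 0.0]
    out.append(intermixing_score(tree))
    out.append(float(len(tips)))
    out.append(float(total))
    return np.array(out)


class RobustScale:
    """Median/MAD scaling of summary vectors, frozen from a reference set.

    Statistics with zero MAD in the reference set fall back to a unit
    scale so that they still contribute (in absolute units) rather than
    exploding the distance.
    """

    def __init__(self, reference: np.ndarray):
        reference = np.atleast_2d(np.asarray(reference, dtype=float))
        self.center = np.median(reference, axis=0)
        mad = np.median(np.abs(reference - self.center), axis=0)
        self.scale = np.where(mad > 0, 1.4826 * mad, 1.0)

    def __call__(self, s: np.ndarray) -> np.ndarray:
        return (np.asarray(s, dtype=float) - self.center) / self.scale


def default_summary_weights() -> np.ndarray:
    """Weights used in the ABC summary distance.

    Scale-free tree-shape statistics (trunk fraction, longest-internal-edge
    fraction, depth CV, MRCA-depth statistics, intermixing) carry the
    identity of the growth model, whereas length-type entries mostly
    calibrate the mutation rate and overdispersion; the shape block is
    therefore upweighted (9x in squared distance, i.e. 3x in distance
    units).
    """
    labels = summary_labels()
    shape = {"trunk_fraction", "max_internal_frac", "depth_cv",
             "mrca_frac", "late_coalesce_frac", "intermixing"}
    return np.array([9.0 if lab in shape else 1.0 for lab in labels])


def tree_distance(s1, s2, scale: RobustScale | None = None,
                  weights=None) -> float:
    """Weighted Euclidean distance between (robust-scaled) summary vectors."""
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("summary vectors disagree in length "
                         "(mismatched region sets?)")
    if scale is not None:
        s1, s2 = scale(s1), scale(s2)
    d = s1 - s2
    if weights is not None:
        d = d * np.sqrt(np.asarray(weights, dtype=float))
    return float(np.sqrt(np.sum(d * d)))


def noise_baseline(tree: CloneTree, factor_range=(0.5, 2.0), reps: int = 100,
                   seed: int = 0, scale: RobustScale | None = None
                   ) -> np.ndarray:
    """Distance distribution between a tree and length-jittered copies.

    Each replicate multiplies every edge length by an independent
    Uniform(factor_range) draw and records the summary distance to the
    original; used as the reference noise floor when judging ABC fits.
    """
    rng = np.random.default_rng(seed)
    s0 = tree_summary(tree)
    out = np.empty(reps)
    for i in range(reps):
        t2 = tree.copy()
        for e in t2.edges():
            e.length *= rng.uniform(*factor_range)
        out[i] = tree_distance(s0, tree_summary(t2), scale=scale)
    return out
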