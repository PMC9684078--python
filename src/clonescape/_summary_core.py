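"""Numba kernel computing sampled-tree summary statistics from genealogy
arrays, bypassing explicit tree construction in the ABC hot loop.

Computes the same 14-entry vector as
:func:`clonescape.tree_metrics.tree_summary` applied to
:func:`clonescape.spatial_sim.true_sample_tree`; equality of the two routes
is asserted in the test suite.  Relies on parent[v] < v (children are
appended after their parents during simulation).
"""

import numpy as np
from numba import njit


@njit(cache=True)
def sampled_summary(parent, nmut, tips, regions, n_regions,
                    late_threshold=0.15):
    n = len(tips)
    nn = len(parent)
    out = np.zeros(14)

    # visit counts: number of sampled tips whose root path passes each node
    visit = np.zeros(nn, dtype=np.int64)
    for i in range(n):
        v = tips[i]
        while v >= 0:
            visit[v] += 1
            v = parent[v]

    # node depths (root -> node mutation counts); parents precede children
    nodedepth = np.zeros(nn)
    for v in range(nn):
        p = parent[v]
        nodedepth[v] = nmut[v] + (nodedepth[p] if p >= 0 else 0.0)

    # per-tip depth and terminal (private-chain) length
    depth = np.zeros(n)
    term = np.zeros(n)
    for i in range(n):
        v = tips[i]
        d = 0.0
        t = 0.0
        while v >= 0:
            d += nmut[v]
            if visit[v] == 1:
                t += nmut[v]
            v = parent[v]
        depth[i] = d
        term[i] = t

    total = 0.0
    trunk = 0.0
    for v in range(nn):
        if visit[v] > 0:
            total += nmut[v]
            if visit[v] == n:
                trunk += nmut[v]

    # pairwise MRCA depths by path stamping
    stamp = np.full(nn, -1, dtype=np.int64)
    mrca = np.zeros((n, n))
    for i in range(n):
        v = tips[i]
        while v >= 0:
            stamp[v] = i
            v = parent[v]
        for j in range(i + 1, n):
            v = tips[j]
            while v >= 0 and stamp[v] != i:
                v = parent[v]
            md = nodedepth[v] if v >= 0 else 0.0
            mrca[i, j] = md
            mrca[j, i] = md

    # induced child counts -> key nodes (tips or branch points)
    child_count = np.zeros(nn, dtype=np.int64)
    for v in range(nn):
        if visit[v] > 0 and parent[v] >= 0:
            child_count[parent[v]] += 1
    is_tip_node = np.zeros(nn, dtype=np.int64)
    for i in range(n):
        is_tip_node[tips[i]] = 1
    is_key = np.zeros(nn, dtype=np.int64)
    for v in range(nn):
        if visit[v] > 0 and (is_tip_node[v] == 1 or child_count[v] >= 2):
            is_key[v] = 1

    # longest internal collapsed edge (not terminal, not the trunk)
    max_internal = 0.0
    for v in range(nn):
        if is_key[v] == 1 and is_tip_node[v] == 0:
            length = float(nmut[v])
            p = parent[v]
            while p >= 0 and is_key[p] == 0:
                length += nmut[p]
                p = parent[p]
            if p >= 0 and length > max_internal:  # p == -1 -> trunk edge
                max_internal = length

    # collapsed parent depth of each tip: first ancestor shared with others
    pdepth = np.zeros(n)
    for i in range(n):
        v = parent[tips[i]]
        while v >= 0 and visit[v] == 1:
            v = parent[v]
        pdepth[i] = nodedepth[v] if v >= 0 else 0.0

    # intermixing: for tip i, tips under its collapsed parent are those j
    # with mrca(i, j) at least as deep as that parent (both on i's path)
    inter = 0.0
    if n > 1:
        for i in range(n):
            same = 0
            size = 1
            for j in range(n):
                if j == i:
                    continue
                if mrca[i, j] >= pdepth[i] - 1e-9:
                    size += 1
                    if regions[j] != regions[i]:
                        same += 1
            inter += same / size
        inter /= n

    # region terminal means and per-region-pair mean patristic distances
    reg_mean = np.zeros(n_regions)
    reg_cnt = np.zeros(n_regions)
    for i in range(n):
        reg_mean[regions[i]] += term[i]
        reg_cnt[regions[i]] += 1
    for r in range(n_regions):
        if reg_cnt[r] > 0:
            reg_mean[r] /= reg_cnt[r]
    pat_min = np.inf
    pat_max = -np.inf
    for a in range(n_regions):
        for b in range(a + 1, n_regions):
            s = 0.0
            cnt = 0
            for i in range(n):
                if regions[i] != a:
                    continue
                for j in range(n):
                    if regions[j] != b:
                        continue
                    s += depth[i] + depth[j] - 2.0 * mrca[i, j]
                    cnt += 1
            if cnt > 0:
                m = s / cnt
                if m < pat_min:
                    pat_min = m
                if m > pat_max:
                    pat_max = m
    if not np.isfinite(pat_min):
        pat_min = 0.0
        pat_max = 0.0

    mean_depth = depth.mean()
    off_sum = 0.0
    off_cnt = 0
    late = 0
    for i in range(n):
        for j in range(i + 1, n):
            off_sum += mrca[i, j]
            off_cnt += 1
            if mrca[i, j] > late_threshold * mean_depth:
                late += 1

    out[0] = term.mean()
    out[1] = term.std()
    out[2] = reg_mean.min()
    out[3] = reg_mean.max()
    out[4] = trunk / total if total > 0 else 0.0
    out[5] = pat_min
    out[6] = pat_max
    out[7] = max_internal / total if total > 0 else 0.0
    out[8] = depth.std() / mean_depth if mean_depth > 0 else 0.0
    if off_cnt > 0 and mean_depth > 0:
        out[9] = (off_sum / off_cnt) / mean_depth
        out[10] = late / off_cnt
    out[11] = inter
    out[12] = float(n)
    out[13] = total
    return out
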