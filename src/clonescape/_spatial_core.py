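"""Numba event-loop kernel for the gland-level lattice simulator.

Kept separate from the user-facing module so that the jitted function has a
flat array signature.  The kernel simulates birth (with pushing), death and
subclone conversion on a 2D square lattice and records the full gland
genealogy as parent-pointer arrays.
"""

import numpy as np
from numba import njit

# status codes returned by the kernel
OK = 0
EXTINCT = 1
OVERFLOW = 2
STALLED = 3

_DIRS = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)


@njit(cache=True)
def _draw_nmut(mu, d_disp):
    """Per-division mutation count: Poisson for D=1, gamma-Poisson (negative
    binomial with variance = mean*D) otherwise."""
    if mu <= 0.0:
        return 0
    if d_disp <= 1.0:
        return np.random.poisson(mu)
    # NB with mean mu, var mu*D: shape r = mu/(D-1), scale (D-1)
    lam = np.random.gamma(mu / (d_disp - 1.0), d_disp - 1.0)
    return np.random.poisson(lam)


@njit(cache=True)
def _nearest_empty_ring(grid, side, r0, c0, rmax):
    """Chebyshev distance from (r0, c0) to the nearest empty site, searching
    expanding square rings; returns rmax + 1 if none found within rmax."""
    for rad in range(1, rmax + 1):
        rlo = r0 - rad
        rhi = r0 + rad
        clo = c0 - rad
        chi = c0 + rad
        for c in range(clo, chi + 1):
            if 0 <= rlo < side and 0 <= c < side and grid[rlo, c] == 0:
                return rad
            if 0 <= rhi < side and 0 <= c < side and grid[rhi, c] == 0:
                return rad
        for r in range(rlo + 1, rhi):
            if 0 <= r < side and 0 <= clo < side and grid[r, clo] == 0:
                return rad
            if 0 <= r < side and 0 <= chi < side and grid[r, chi] == 0:
                return rad
    return rmax + 1


@njit(cache=True)
def grow(
    side,
    n_end,
    mu,
    d_disp,
    d_push,
    lam2,
    lam3,
    t2,
    t3,
    death_rate,
    seed,
    record_boundary,
    max_events,
    max_nodes,
):
    """Run the lattice birth-death-mutation process to n_end live glands.

    Returns a tuple of genealogy arrays, live-gland state, event traces and a
    status code.  Node 0 is the founder; every division appends two child
    nodes (continuing mother lineage and daughter).
    """
    np.random.seed(seed)

    parent = np.full(max_nodes, -1, dtype=np.int64)
    nmut = np.zeros(max_nodes, dtype=np.int64)
    node_clone = np.zeros(max_nodes, dtype=np.int8)
    n_nodes = 1  # founder

    grid = np.zeros((side, side), dtype=np.int64)  # 0 empty else slot+1

    cap = n_end + 2
    pos_r = np.zeros(cap, dtype=np.int64)
    pos_c = np.zeros(cap, dtype=np.int64)
    node_of = np.zeros(cap, dtype=np.int64)
    clone_of = np.zeros(cap, dtype=np.int8)

    mid = side // 2
    pos_r[0] = mid
    pos_c[0] = mid
    node_of[0] = 0
    clone_of[0] = 0
    grid[mid, mid] = 1
    n_live = 1

    nmut[0] = _draw_nmut(mu, d_disp)  # truncal mutations of the founder

    lam = np.ones(3)
    lam[1] = lam2
    lam[2] = lam3
    lam_max = max(lam2, max(lam3, 1.0))

    sub_intro_node = np.full(2, -1, dtype=np.int64)  # conversion nodes

    pop_hist = np.zeros(max_events, dtype=np.int64)
    bdist = np.zeros(max_events, dtype=np.int64)  # boundary dist per division
    n_div = 0
    n_events = 0

    dirs = _DIRS
    rmax_ring = side  # cap for ring search

    while n_live < n_end:
        if n_events >= max_events:
            return (parent[:n_nodes], nmut[:n_nodes], node_clone[:n_nodes],
                    pos_r[:n_live], pos_c[:n_live], node_of[:n_live],
                    clone_of[:n_live], pop_hist[:n_events], bdist[:n_div],
                    sub_intro_node, STALLED)

        # subclone conversions fire on the first event at/after threshold
        if lam2 > 1.0 and sub_intro_node[0] < 0 and n_live >= t2:
            g = np.random.randint(n_live)
            clone_of[g] = 1
            sub_intro_node[0] = node_of[g]
        if lam3 > 1.0 and sub_intro_node[1] < 0 and n_live >= t3:
            g = np.random.randint(n_live)
            clone_of[g] = 2
            sub_intro_node[1] = node_of[g]

        # death side-event per birth attempt (before the attempt, so a
        # lone founder can die out)
        if death_rate > 0.0 and np.random.random() < death_rate:
            g = np.random.randint(n_live)
            grid[pos_r[g], pos_c[g]] = 0
            last = n_live - 1
            if g != last:
                pos_r[g] = pos_r[last]
                pos_c[g] = pos_c[last]
                node_of[g] = node_of[last]
                clone_of[g] = clone_of[last]
                grid[pos_r[g], pos_c[g]] = g + 1
            n_live -= 1
            if n_live == 0:
                return (parent[:n_nodes], nmut[:n_nodes],
                        node_clone[:n_nodes],
                        pos_r[:0], pos_c[:0], node_of[:0], clone_of[:0],
                        pop_hist[:n_events], bdist[:n_div],
                        sub_intro_node, EXTINCT)

        # pick mother: uniform gland, accept with prob lam[clone]/lam_max
        while True:
            m = np.random.randint(n_live)
            if np.random.random() * lam_max <= lam[clone_of[m]]:
                break

        r0 = pos_r[m]
        c0 = pos_c[m]

        # nearest empty along the 8 straight rays, within d_push
        best = d_push + 1
        n_best = 0
        best_dirs = np.zeros(8, dtype=np.int64)
        for k in range(8):
            dr = dirs[k, 0]
            dc = dirs[k, 1]
            for step in range(1, d_push + 1):
                r = r0 + dr * step
                c = c0 + dc * step
                if r < 0 or r >= side or c < 0 or c >= side:
                    break
                if grid[r, c] == 0:
                    if step < best:
                        best = step
                        n_best = 1
                        best_dirs[0] = k
                    elif step == best:
                        best_dirs[n_best] = k
                        n_best += 1
                    break

        if n_best > 0:
            k = best_dirs[np.random.randint(n_best)]
            dr = dirs[k, 0]
            dc = dirs[k, 1]
            # push: shift glands one step outward along the ray
            for step in range(best, 1, -1):
                rs = r0 + dr * (step - 1)
                cs = c0 + dc * (step - 1)
                slot = grid[rs, cs] - 1
                pos_r[slot] = r0 + dr * step
                pos_c[slot] = c0 + dc * step
                grid[pos_r[slot], pos_c[slot]] = slot + 1
            # daughter adjacent to mother
            rd = r0 + dr
            cd = c0 + dc

            if record_boundary:
                bd = _nearest_empty_ring(grid, side, r0, c0, rmax_ring)
                bdist[n_div] = bd
            n_div += 1

            u = node_of[m]
            v1 = n_nodes
            v2 = n_nodes + 1
            if v2 >= max_nodes:
                return (parent[:n_nodes], nmut[:n_nodes], node_clone[:n_nodes],
                        pos_r[:n_live], pos_c[:n_live], node_of[:n_live],
                        clone_of[:n_live], pop_hist[:n_events], bdist[:n_div],
                        sub_intro_node, OVERFLOW)
            n_nodes += 2
            parent[v1] = u
            parent[v2] = u
            nmut[v1] = _draw_nmut(mu, d_disp)
            nmut[v2] = _draw_nmut(mu, d_disp)
            node_clone[v1] = clone_of[m]
            node_clone[v2] = clone_of[m]
            node_of[m] = v1

            slot = n_live
            pos_r[slot] = rd
            pos_c[slot] = cd
            node_of[slot] = v2
            clone_of[slot] = clone_of[m]
            grid[rd, cd] = slot + 1
            n_live += 1

        pop_hist[n_events] = n_live
        n_events += 1

    return (parent[:n_nodes], nmut[:n_nodes], node_clone[:n_nodes],
            pos_r[:n_live], pos_c[:n_live], node_of[:n_live],
            clone_of[:n_live], pop_hist[:n_events], bdist[:n_div],
            sub_intro_node, OK)
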