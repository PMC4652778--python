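"""Independent reference implementations used to cross-check the package.

Each oracle is deliberately written with a different algorithm (or a
closed form) than the production code path it checks.
"""

import heapq
import itertools

import numpy as np


def rotated_dihedral_point(b, c, theta_deg, radius=1.0):
    """Construct point d so that dihedral(a, b, c, d) = theta for the
    cis reference a; d is produced by explicitly rotating the cis direction
    about the b->c axis with a Rodrigues rotation matrix."""
    b, c = np.asarray(b, float), np.asarray(c, float)
    axis = c - b
    axis = axis / np.linalg.norm(axis)
    # reference direction perpendicular to the axis (cis side for a given a)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    ref = ref - np.dot(ref, axis) * axis
    ref = ref / np.linalg.norm(ref)
    t = np.radians(theta_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)
    a = b + radius * ref            # cis reference position for a
    d = c + radius * (R @ ref)
    return a, d


def minimax_value_dijkstra(F, mask, start, end, periodic_chi, allowed=None):
    """Widest-path (minimax) value via a Dijkstra variant on the bin graph."""
    nc, nx = F.shape
    ok = mask if allowed is None else (mask & allowed)
    dist = np.full((nc, nx), np.inf)
    if not (ok[start] and ok[end]):
        return np.inf
    dist[start] = F[start]
    pq = [(F[start], start)]
    while pq:
        d, (i, j) = heapq.heappop(pq)
        if d > dist[i, j]:
            continue
        if (i, j) == end:
            return d
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                ni, nj = i + di, j + dj
                if ni < 0 or ni >= nc:
                    continue
                if periodic_chi:
                    nj %= nx
                elif nj < 0 or nj >= nx:
                    continue
                if not ok[ni, nj]:
                    continue
                nd = max(d, F[ni, nj])
                if nd < dist[ni, nj]:
                    dist[ni, nj] = nd
                    heapq.heappush(pq, (nd, (ni, nj)))
    return dist[end]


def minimax_value_exhaustive(F, start, end, periodic_chi):
    """Minimax value by enumerating every simple path (tiny grids only)."""
    nc, nx = F.shape
    best = [np.inf]

    def neighbors(i, j):
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                ni, nj = i + di, j + dj
                if ni < 0 or ni >= nc:
                    continue
                if periodic_chi:
                    nj %= nx
                elif nj < 0 or nj >= nx:
                    continue
                yield ni, nj

    def dfs(node, visited, running_max):
        running_max = max(running_max, F[node])
        if running_max >= best[0]:
            return
        if node == end:
            best[0] = running_max
            return
        for nb in neighbors(*node):
            if nb not in visited:
                dfs(nb, visited | {nb}, running_max)

    dfs(start, {start}, -np.inf)
    return best[0]


def brute_force_cluster_sizes(positions, box, cutoff):
    """All-pairs minimum-image distances + hand-rolled union-find."""
    n = len(positions)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in itertools.combinations(range(n), 2):
        d = positions[i] - positions[j]
        if box is not None:
            d = d - box * np.round(d / box)
        if np.linalg.norm(d) <= cutoff:
            parent[find(i)] = find(j)
    from collections import Counter
    comp = Counter(find(i) for i in range(n))
    return dict(Counter(comp.values()))
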