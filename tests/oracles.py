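"""Independent oracles used by the unit and acceptance tests.

Everything here is deliberately naive — per-site loops, exhaustive topology
enumeration with least-squares branch fitting — and shares no code with the
implementations it checks.
"""

import itertools

import numpy as np
from scipy.optimize import nnls

from introscan.io import MISSING


def brute_force_distance(X: np.ndarray) -> np.ndarray:
    """Allele-sharing distance by an explicit site-by-site loop."""
    n = X.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            num = 0.0
            cnt = 0
            for s in range(X.shape[1]):
                if X[i, s] != MISSING and X[j, s] != MISSING:
                    num += abs(int(X[i, s]) - int(X[j, s]))
                    cnt += 1
            d[i, j] = d[j, i] = num / (2 * cnt)
    return d


def brute_force_dstat(p: np.ndarray) -> tuple[float, float, float]:
    """Term-by-term ABBA/BABA summation over an (n, 4) frequency table."""
    abba = baba = 0.0
    for p1, p2, p3, p4 in p:
        abba += (1 - p1) * p2 * p3 * (1 - p4)
        baba += p1 * (1 - p2) * p3 * (1 - p4)
    return abba, baba, (abba - baba) / (abba + baba)


# ---------------------------------------------------------------------------
# random additive trees and exhaustive topology search


def random_additive_tree(names, rng):
    """Random topology by sequential edge insertion with uniform branch
    lengths; returns (adjacency dict with edge lengths, leaf names)."""
    adj: dict = {}

    def connect(u, v, length):
        adj.setdefault(u, {})[v] = length
        adj.setdefault(v, {})[u] = length

    def disconnect(u, v):
        del adj[u][v]
        del adj[v][u]

    internal = [0]
    for leaf in names[:3]:
        connect(0, leaf, rng.uniform(0.1, 1.0))
    edges = [(0, leaf) for leaf in names[:3]]
    for leaf in names[3:]:
        u, v = edges[rng.integers(len(edges))]
        length = adj[u][v]
        w = internal[-1] + 1
        internal.append(w)
        split = rng.uniform(0.2, 0.8)
        disconnect(u, v)
        connect(u, w, length * split)
        connect(w, v, length * (1 - split))
        connect(w, leaf, rng.uniform(0.1, 1.0))
        edges.remove((u, v))
        edges.extend([(u, w), (w, v), (w, leaf)])
    return adj


def tree_distances(adj, names) -> np.ndarray:
    """All-pairs path lengths by per-leaf Dijkstra-free DFS (tree metric)."""
    n = len(names)
    dist = np.zeros((n, n))
    index = {name: i for i, name in enumerate(names)}
    for src in names:
        seen = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, length in adj[u].items():
                if v not in seen:
                    seen[v] = seen[u] + length
                    stack.append(v)
        for name in names:
            dist[index[src], index[name]] = seen[name]
    return (dist + dist.T) / 2.0  # exact symmetry despite float path order


def adjacency_splits(adj, names) -> set[frozenset]:
    """Non-trivial bipartitions of an adjacency-dict tree, canonicalized to
    the side not containing the smallest leaf name."""
    smallest = min(names)
    out = set()
    for u in adj:
        for v in adj[u]:
            side = _side_leaves(adj, u, v, names)
            if 2 <= len(side) <= len(names) - 2:
                if smallest in side:
                    side = frozenset(set(names) - side)
                out.add(frozenset(side))
    return out


def _side_leaves(adj, u, v, names):
    seen = {v}
    stack = [v]
    leaves = set()
    nameset = set(names)
    while stack:
        x = stack.pop()
        if x in nameset:
            leaves.add(x)
        for y in adj[x]:
            if y not in seen and not (x == v and y == u):
                seen.add(y)
                stack.append(y)
    return frozenset(leaves)


def skbio_tree_splits(tree, names) -> set[frozenset]:
    """Canonical non-trivial splits of an skbio TreeNode."""
    smallest = min(names)
    nameset = set(names)
    out = set()
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= len(names) - 2:
            if smallest in side:
                side = frozenset(nameset - side)
            out.add(side)
    return out


def enumerate_topologies(names):
    """All unrooted binary topologies as adjacency dicts (no lengths)."""

    def connect(adj, u, v):
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)

    base: dict = {}
    for leaf in names[:3]:
        connect(base, 0, leaf)
    trees = [base]
    next_internal = 1
    for leaf in names[3:]:
        grown = []
        for adj in trees:
            edges = {tuple(sorted((u, v), key=str)) for u in adj for v in adj[u]}
            for u, v in edges:
                new = {k: set(s) for k, s in adj.items()}
                w = next_internal
                new[u].discard(v)
                new[v].discard(u)
                connect(new, u, w)
                connect(new, w, v)
                connect(new, w, leaf)
                grown.append(new)
        trees = grown
        next_internal += 1
    return trees


def ls_fit_residual(adj, names, D) -> float:
    """Least-squares (nonnegative) branch-length fit of a topology to a
    distance matrix; returns the residual norm."""
    edges = sorted(
        {tuple(sorted((u, v), key=str)) for u in adj for v in adj[u]}, key=str
    )
    sides = [_side_set(adj, u, v) for u, v in edges]
    pairs = list(itertools.combinations(range(len(names)), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for row, (i, j) in enumerate(pairs):
        y[row] = D[i, j]
        for col, side in enumerate(sides):
            if (names[i] in side) != (names[j] in side):
                A[row, col] = 1.0
    _, resid = nnls(A, y)
    return float(resid)


def _side_set(adj, u, v):
    seen = {v}
    stack = [v]
    while stack:
        x = stack.pop()
        for y in adj[x]:
            if y not in seen and not (x == v and y == u):
                seen.add(y)
                stack.append(y)
    return {x for x in seen if isinstance(x, str)}
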