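"""Independent oracles used by the test suite.

These deliberately avoid the package's own algorithms: alignment scores are
found by exhaustive enumeration of monotone alignments, and tree distances
come from explicit path sums on randomly built trees.
"""

from __future__ import annotations

import numpy as np


def brute_force_align_score(a: str, b: str, scheme) -> int:
    """Maximum score over every monotone alignment (exhaustive enumeration).

    Affine convention mirrors the package contract: the first residue of a
    gap costs gap_open, each additional one gap_extend; a gap in the other
    sequence immediately after counts as a fresh gap.
    """
    go, ge = scheme.gap_open, scheme.gap_extend
    la, lb = len(a), len(b)
    sub = [[scheme.score(ca, cb) for cb in b] for ca in a]
    best = [-(10**9)]

    def rec(i: int, j: int, last: str, acc: int) -> None:
        if i == la and j == lb:
            if acc > best[0]:
                best[0] = acc
            return
        if i < la and j < lb:
            rec(i + 1, j + 1, "M", acc + sub[i][j])
        if i < la:
            rec(i + 1, j, "X", acc + (ge if last == "X" else go))
        if j < lb:
            rec(i, j + 1, "Y", acc + (ge if last == "Y" else go))

    rec(0, 0, "", 0)
    return best[0]


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Random unrooted binary tree with positive branch lengths.

    Returns (ids, distance_matrix, bipartitions) where distances are exact
    path sums and bipartitions are canonical frozensets (smaller side).
    """
    # adjacency: node -> {neighbor: weight}
    adj: dict[int, dict[int, float]] = {0: {}, 1: {}, 2: {}, 3: {}}
    next_id = 4
    leaves = [0, 1, 2]
    for leaf in leaves:
        w = float(rng.uniform(0.5, 2.0))
        adj[leaf][3] = w
        adj[3][leaf] = w
    for _ in range(n_taxa - 3):
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[rng.integers(len(edges))]
        mid, leaf = next_id, next_id + 1
        next_id += 2
        w = adj[u].pop(v)
        adj[v].pop(u)
        w1 = float(rng.uniform(0.2, w - 0.1)) if w > 0.4 else w / 2
        adj[mid] = {u: w1, v: w - w1}
        adj[u][mid] = w1
        adj[v][mid] = w - w1
        wl = float(rng.uniform(0.5, 2.0))
        adj[leaf] = {mid: wl}
        adj[mid][leaf] = wl
        leaves.append(leaf)

    ids = [f"t{k}" for k in range(len(leaves))]
    label = dict(zip(leaves, ids))

    def path_lengths(src: int) -> dict[int, float]:
        out = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in out:
                    out[v] = out[u] + w
                    stack.append(v)
        return out

    n = len(leaves)
    d = np.zeros((n, n))
    for i, u in enumerate(leaves):
        pl = path_lengths(u)
        for j, v in enumerate(leaves):
            d[i, j] = pl[v]

    leafset = frozenset(ids)
    bips = set()
    for u in adj:
        for v in adj[u]:
            if u < v:
                # leaves on u's side with edge (u,v) removed
                seen = {u}
                stack = [u]
                while stack:
                    x = stack.pop()
                    for y in adj[x]:
                        # removing edge (u,v) disconnects v's side entirely
                        if y != v and y not in seen:
                            seen.add(y)
                            stack.append(y)
                side = frozenset(label[x] for x in seen if x in label)
                if 0 < len(side) < n:
                    other = leafset - side
                    bips.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return ids, d, bips
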