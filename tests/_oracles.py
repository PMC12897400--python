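"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written against different data structures
and algorithms than the package: nested-tuple trees with explicit
root-path enumeration for patristic distances, exhaustive subset
enumeration for null MPD distributions, and an exhaustive path-blocking
check for d-separation.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

# ---------------------------------------------------------------------------
# random trees as nested tuples: leaf = ("name", bl); internal = (children, bl)


def random_tree(rng: np.random.Generator, n_tips: int):
    """Random binary topology with uniform-random branch lengths.

    Returns (newick string, nested structure).  Structure: a leaf is
    ``(label, branch_length)``, an internal node ``(list_of_children,
    branch_length)``; the root's branch length is ignored.
    """
    nodes = [(f"t{i}", float(rng.uniform(0.05, 3.0))) for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(([a, b], float(rng.uniform(0.05, 3.0))))
    root = nodes[0]
    return _to_newick(root, is_root=True) + ";", root


def _to_newick(node, is_root=False) -> str:
    payload, bl = node
    if isinstance(payload, str):
        return f"{payload}:{bl!r}"
    inner = ",".join(_to_newick(c) for c in payload)
    return f"({inner})" if is_root else f"({inner}):{bl!r}"


def oracle_patristic(structure) -> dict[frozenset, float]:
    """Tip-pair distances by explicit LCA path enumeration.

    For each pair, walk both root paths until they diverge (the lowest
    common ancestor), then sum the remaining branch lengths on each side.
    """
    # path entries: internal steps are (node_id, child_idx, bl); leaf step is bl
    paths = _paths_with_lengths(structure)
    out = {}
    for a, b in combinations(paths, 2):
        pa, pb = paths[a], paths[b]
        k = 0  # longest shared prefix of steps = path down to the LCA
        while k < min(len(pa), len(pb)) and pa[k][:2] == pb[k][:2]:
            k += 1
        da = sum(step[2] for step in pa[k:])
        db = sum(step[2] for step in pb[k:])
        out[frozenset((a, b))] = da + db
    return out


def _paths_with_lengths(node, prefix=()):
    """Root-to-leaf step lists; each step is (parent id, child index,
    branch length of the entered child)."""
    payload, bl = node
    if isinstance(payload, str):
        return {payload: prefix}
    out = {}
    for idx, child in enumerate(payload):
        out.update(
            _paths_with_lengths(child, prefix + ((id(node), idx, child[1]),))
        )
    return out


# ---------------------------------------------------------------------------


def exhaustive_subset_mpds(d: np.ndarray, k: int) -> np.ndarray:
    """MPD of every k-subset of the pool (equal weight each)."""
    n = d.shape[0]
    vals = []
    for subset in combinations(range(n), k):
        idx = np.array(subset)
        sub = d[np.ix_(idx, idx)]
        vals.append(sub.sum() / (k * (k - 1)))
    return np.array(vals)


def ks_distance(sample_a: np.ndarray, sample_b: np.ndarray) -> float:
    """Two-sample Kolmogorov–Smirnov distance (max ECDF gap).

    Values are rounded to 9 decimals first: MPD distributions are discrete,
    and the same atom computed through different summation orders must not
    be split by 1e-16 float noise (that alone would inflate the gap by the
    atom's probability mass).
    """
    sample_a = np.round(np.asarray(sample_a), 9)
    sample_b = np.round(np.asarray(sample_b), 9)
    grid = np.unique(np.concatenate([sample_a, sample_b]))
    fa = np.searchsorted(np.sort(sample_a), grid, side="right") / len(sample_a)
    fb = np.searchsorted(np.sort(sample_b), grid, side="right") / len(sample_b)
    return float(np.max(np.abs(fa - fb)))


# ---------------------------------------------------------------------------
# exhaustive d-separation by path blocking


def d_separated(nodes, edges, x: str, y: str, z: set[str]) -> bool:
    """True if every undirected path between x and y is blocked given z.

    A path is blocked if some non-collider on it is in z, or some collider
    on it has no descendant (including itself) in z.  Paths are enumerated
    exhaustively — fine for the <= 5-node graphs this oracle serves.
    """
    edges = [tuple(e) for e in edges]
    adj: dict[str, set] = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    desc = {n: _descendants(edges, n) | {n} for n in nodes}
    z = set(z)

    def blocked(path) -> bool:
        for i in range(1, len(path) - 1):
            prev, mid, nxt = path[i - 1], path[i], path[i + 1]
            into_mid_left = (prev, mid) in edges
            into_mid_right = (nxt, mid) in edges
            collider = into_mid_left and into_mid_right
            if collider:
                if not (desc[mid] & z):
                    return True
            else:
                if mid in z:
                    return True
        return False

    def all_paths(cur, target, visited):
        if cur == target:
            yield tuple(visited)
            return
        for nbr in adj[cur]:
            if nbr not in visited:
                yield from all_paths(nbr, target, visited + [nbr])

    for path in all_paths(x, y, [x]):
        if len(path) >= 2 and not blocked(path):
            return False
    return True


def _descendants(edges, node) -> set:
    out = set()
    frontier = [node]
    while frontier:
        cur = frontier.pop()
        for a, b in edges:
            if a == cur and b not in out:
                out.add(b)
                frontier.append(b)
    return out
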