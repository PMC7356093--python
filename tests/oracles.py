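"""Independent brute-force reference implementations used only by tests."""

from itertools import combinations

import numpy as np

MATCH, MISMATCH, GAP = 1, -1, -2


def nw_oracle_transcript(x: str, y: str) -> str:
    """Plain-Python Needleman-Wunsch with the same scoring and traceback
    preferences (diagonal, up, left) as the package's aligner, but a naive
    cell-by-cell fill."""
    n, m = len(x), len(y)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        H[i][0] = i * GAP
    for j in range(1, m + 1):
        H[0][j] = j * GAP
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            match = x[i - 1] == y[j - 1] and x[i - 1] != "N"
            s = MATCH if match else MISMATCH
            H[i][j] = max(H[i - 1][j - 1] + s, H[i - 1][j] + GAP, H[i][j - 1] + GAP)
    ops = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            match = x[i - 1] == y[j - 1] and x[i - 1] != "N"
            s = MATCH if match else MISMATCH
            if H[i][j] == H[i - 1][j - 1] + s:
                ops.append("M" if match else "X")
                i, j = i - 1, j - 1
                continue
        if i > 0 and H[i][j] == H[i - 1][j] + GAP:
            ops.append("D")
            i -= 1
            continue
        ops.append("I")
        j -= 1
    return "".join(reversed(ops))


def lis_oracle(anchors: list[tuple[int, int]]) -> int:
    """O(n^2) longest-chain DP: max #anchors strictly increasing in both."""
    pts = sorted(anchors)
    n = len(pts)
    best = [1] * n
    for i in range(n):
        for j in range(i):
            if pts[j][0] < pts[i][0] and pts[j][1] < pts[i][1]:
                best[i] = max(best[i], best[j] + 1)
    return max(best, default=0)


def census_oracle(seq: str, tir: str, rc_tir: str, lo: int, hi: int) -> list[tuple[int, int]]:
    """Quadratic copy scan: test every position pair by direct slicing, then
    apply the same greedy shortest-span non-overlap rule."""
    L = len(tir)
    lefts = [i for i in range(len(seq) - L + 1) if seq[i : i + L] == tir]
    rights = [j for j in range(len(seq) - L + 1) if seq[j : j + L] == rc_tir]
    cands = []
    for i in lefts:
        for j in rights:
            end = j + L
            if lo <= end - i <= hi and end - i >= 2 * L:
                cands.append((i, end))
    cands.sort(key=lambda c: (c[1] - c[0], c[0]))
    accepted: list[tuple[int, int]] = []
    for s, e in cands:
        if all(e <= s2 or e2 <= s for s2, e2 in accepted):
            accepted.append((s, e))
    return sorted(accepted)


def four_leaf_topologies(labels):
    a, b, c, d = labels
    return [((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c))]


def ls_fit_residual(dm: np.ndarray, labels, split) -> float:
    """Least-squares branch-length fit of a 4-leaf topology; residual is zero
    exactly when the matrix is additive on that topology."""
    (p, q), (r, s) = split
    idx = {lab: i for i, lab in enumerate(labels)}
    # edges: pendant x4 + internal; rows = 6 pairwise distances
    pairs = list(combinations(labels, 2))
    A = np.zeros((len(pairs), 5))
    y = np.zeros(len(pairs))
    pendant = {p: 0, q: 1, r: 2, s: 3}
    for row, (u, v) in enumerate(pairs):
        A[row, pendant[u]] = 1
        A[row, pendant[v]] = 1
        same_side = {u, v} in ({p, q}, {r, s})
        if not same_side:
            A[row, 4] = 1
        y[row] = dm[idx[u], idx[v]]
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(np.sum((A @ coef - y) ** 2))


def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """Random binary topology with positive branch lengths; returns
    (labels, distance matrix, set of non-trivial bipartitions)."""
    from straindiff.phylo import TreeNode, bipartitions

    labels = [f"t{i}" for i in range(n_leaves)]
    nodes = [TreeNode(name=lab, length=float(rng.uniform(0.05, 1.0))) for lab in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=float(rng.uniform(0.05, 1.0)))
        parent.children = [nodes[i], nodes[j]]
        rest = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes = rest + [parent]
    root = TreeNode()
    root.children = nodes
    dists = root.leaf_distances()
    n = len(labels)
    dm = np.zeros((n, n))
    for (u, v), d in dists.items():
        iu, iv = labels.index(u), labels.index(v)
        dm[iu, iv] = dm[iv, iu] = d
    return labels, dm, bipartitions(root)
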