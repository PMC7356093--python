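"""Neighbor joining on p-distances, with column-bootstrap support values.

This is the canonical Saitou–Nei agglomeration: at each step join the pair
minimising Q(i,j) = (n-2) d(i,j) - r_i - r_j, with pendant branch lengths
from the two-point formulas.  Ties on Q are broken by the lexicographically
smallest pair of cluster labels (a cluster is labelled by its smallest leaf),
so the tree is a pure function of the distance matrix.  Negative pendant
lengths are clamped to zero with the deficit moved to the sister branch,
preserving their sum.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Sequence

import numpy as np

from .align import GAP_CHAR, align_pair


@dataclasses.dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray  # symmetric, zero diagonal, entries in [0, 1] for p-distances

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(self.d)) > 1e-12):
            raise ValueError("distance matrix diagonal must be zero")


@dataclasses.dataclass
class TreeNode:
    """Node of an unrooted tree serialised with a trifurcating root."""

    name: str | None = None
    length: float = 0.0  # branch length to parent
    support: float | None = None  # bootstrap %, internal edges only
    children: list["TreeNode"] = dataclasses.field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name or ""]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self

    def to_newick(self) -> str:
        return self._newick_node() + ";"

    def _newick_node(self) -> str:
        if self.is_leaf():
            return f"{self.name}:{self.length:.10g}"
        inner = ",".join(c._newick_node() for c in self.children)
        label = "" if self.support is None else f"{self.support:.10g}"
        return f"({inner}){label}:{self.length:.10g}"

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Path lengths between all leaf pairs (for testing additivity)."""
        pair_acc: dict[tuple[str, str], float] = {}

        def walk(node: TreeNode) -> dict[str, float]:
            if node.is_leaf():
                return {node.name or "": 0.0}
            below: dict[str, float] = {}
            done: list[dict[str, float]] = []
            for child in node.children:
                sub = {k: v + child.length for k, v in walk(child).items()}
                for prev in done:
                    for x, dx in prev.items():
                        for y, dy in sub.items():
                            key = (x, y) if x < y else (y, x)
                            pair_acc[key] = dx + dy
                done.append(sub)
                below.update(sub)
            return below

        walk(self)
        return pair_acc


def parse_newick(text: str) -> TreeNode:
    """Minimal Newick reader (names, branch lengths, internal labels)."""
    tokens = re.findall(r"[(),;]|[^(),;:]+|:", text.replace(" ", ""))
    pos = 0

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if tokens[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if tokens[pos] == ",":
                    pos += 1
                    continue
                break
            assert tokens[pos] == ")", "unbalanced newick"
            pos += 1
        if pos < len(tokens) and tokens[pos] not in "(),;:":
            label = tokens[pos]
            pos += 1
            if node.is_leaf():
                node.name = label
            else:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
        if pos < len(tokens) and tokens[pos] == ":":
            pos += 1
            node.length = float(tokens[pos])
            pos += 1
        return node

    root = parse_node()
    return root


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining; see module docstring for conventions."""
    n = len(dm.labels)
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 labels")
    if n == 2:
        root = TreeNode()
        root.children = [
            TreeNode(name=dm.labels[0], length=dm.d[0, 1] / 2.0),
            TreeNode(name=dm.labels[1], length=dm.d[0, 1] / 2.0),
        ]
        return root

    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in dm.labels]
    tie_labels: list[str] = list(dm.labels)
    d = dm.d.astype(float).copy()
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best: tuple[float, str, str, int, int] | None = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                q = (m - 2) * sub[ii, jj] - r[ii] - r[jj]
                la, lb = tie_labels[active[ii]], tie_labels[active[jj]]
                key = (q, min(la, lb), max(la, lb))
                if best is None or key < (best[0], best[1], best[2]):
                    best = (q, key[1], key[2], ii, jj)
        assert best is not None
        ii, jj = best[3], best[4]
        i, j = active[ii], active[jj]
        dij = d[i, j]
        li = dij / 2.0 + (r[ii] - r[jj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)

        parent = TreeNode()
        ni, nj = nodes[i], nodes[j]
        ni.length, nj.length = li, lj
        parent.children = [ni, nj]

        new_row = np.zeros(d.shape[0] + 1)
        for kk in active:
            if kk in (i, j):
                continue
            new_row[kk] = 0.5 * (d[i, kk] + d[j, kk] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : len(new_row) - 1] = new_row[:-1]
        d[: len(new_row) - 1, -1] = new_row[:-1]
        nodes.append(parent)
        tie_labels.append(min(tie_labels[i], tie_labels[j]))
        active = [k for k in active if k not in (i, j)] + [d.shape[0] - 1]

    # final three-point join
    i, j, k = active
    root = TreeNode()
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(ln, 0.0)
        root.children.append(nodes[idx])
    return root


# ---------------------------------------------------------------------------
# bipartitions and bootstrap

def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial splits, each canonicalised as the side excluding the
    lexicographically smallest leaf."""
    all_leaves = set(tree.leaves())
    anchor = min(all_leaves)
    out: set[frozenset[str]] = set()
    for node in tree.postorder():
        if node is tree or node.is_leaf():
            continue
        side = set(node.leaves())
        if anchor in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            out.add(frozenset(side))
    return out


def msa_p_distances(labels: Sequence[str], rows: Sequence[str]) -> DistanceMatrix:
    """Pairwise p-distances over a multiple alignment (gap columns excluded
    pairwise; a pair with no comparable columns gets distance 0)."""
    n = len(labels)
    mat = np.array([[ord(c) for c in row] for row in rows], dtype=np.int16)
    gap = ord(GAP_CHAR)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (mat[i] != gap) & (mat[j] != gap)
            comp = int(ok.sum())
            if comp:
                d[i, j] = d[j, i] = float(((mat[i] != mat[j]) & ok).sum()) / comp
    return DistanceMatrix(list(labels), d)


def star_msa(labels: Sequence[str], seqs: Sequence[str]) -> list[str]:
    """Star multiple alignment anchored on the longest member.

    Every sequence is globally aligned to the reference; insertions relative
    to the reference are merged column-block-wise.  Adequate for the nearly
    identical element sequences this package types.
    """
    if len(seqs) < 2:
        raise ValueError("star MSA needs >= 2 sequences")
    ref_idx = max(range(len(seqs)), key=lambda i: (len(seqs[i]), -i))
    ref = seqs[ref_idx]
    L = len(ref)
    # per sequence: aligned char per ref column, insertions after ref col r
    per_col: list[list[str]] = []
    per_ins: list[list[str]] = []
    for s in seqs:
        cols = [GAP_CHAR] * L
        ins = [""] * (L + 1)
        if s == ref:
            cols = list(ref)
        else:
            ar, as_ = align_pair(ref, s)
            r = 0
            for cr, cs in zip(ar, as_):
                if cr == GAP_CHAR:
                    ins[r] += cs
                else:
                    cols[r] = cs
                    r += 1
        per_col.append(cols)
        per_ins.append(ins)
    widths = [max(len(per_ins[i][r]) for i in range(len(seqs))) for r in range(L + 1)]
    rows: list[str] = []
    for i in range(len(seqs)):
        parts: list[str] = []
        for r in range(L + 1):
            parts.append(per_ins[i][r].ljust(widths[r], GAP_CHAR))
            if r < L:
                parts.append(per_col[i][r])
        rows.append("".join(parts))
    return rows


def bootstrap_support(
    labels: Sequence[str],
    aligned_rows: Sequence[str],
    n_replicates: int = 1000,
    seed: int = 0,
) -> TreeNode:
    """NJ tree of the alignment with bootstrap support on internal edges.

    Columns are resampled with replacement ``n_replicates`` times; each
    internal edge of the master tree is annotated with the percentage of
    replicate trees containing the same bipartition.  When every pairwise
    distance is zero the topology carries no signal and supports are set to
    100 by convention.
    """
    if len(labels) < 4:
        raise ValueError("bootstrap support needs >= 4 sequences")
    length = len(aligned_rows[0])
    if length < 1 or any(len(r) != length for r in aligned_rows):
        raise ValueError("rows must form a non-empty multiple alignment")
    master_dm = msa_p_distances(labels, aligned_rows)
    master = neighbor_joining(master_dm)
    master_bips = {bip: 0 for bip in bipartitions(master)}

    if np.allclose(master_dm.d, 0.0):
        for node in master.postorder():
            if not node.is_leaf() and node is not master:
                node.support = 100.0
        return master

    rng = np.random.default_rng(seed)
    arr = np.array([list(r) for r in aligned_rows])
    for _ in range(n_replicates):
        idx = rng.integers(0, length, size=length)
        rep_rows = ["".join(row) for row in arr[:, idx]]
        rep_tree = neighbor_joining(msa_p_distances(labels, rep_rows))
        rep_bips = bipartitions(rep_tree)
        for bip in master_bips:
            if bip in rep_bips:
                master_bips[bip] += 1

    for node in master.postorder():
        if node.is_leaf() or node is master:
            continue
        side = frozenset(node.leaves())
        all_leaves = set(master.leaves())
        if min(all_leaves) in side:
            side = frozenset(all_leaves - side)
        if side in master_bips:
            node.support = 100.0 * master_bips[side] / n_replicates
    return master
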