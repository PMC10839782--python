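"""Population structure: classical MDS and neighbour-joining trees.

Classical (Torgerson) multidimensional scaling double-centers the squared
distance matrix, eigendecomposes it, and places populations at the top
eigenvectors scaled by the square roots of their (positive) eigenvalues.
On a Euclidean input the embedding reproduces the distances exactly;
negative eigenvalues (non-Euclidean input) are reported but never used for
coordinates.

Neighbour-joining follows the Saitou-Nei agglomeration with the Q-matrix
criterion and the standard two-point branch-length formulas.  Tie-breaking
is deterministic (lexicographically smallest pair of clade labels), so a
given matrix always yields the same tree.  Negative branch lengths are
floored at zero with the deficit moved to the sibling branch; raw values
are retained on the edges.  NJ is exact on additive matrices: leaf-to-leaf
path lengths then equal the input distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distance import DistanceMatrix

__all__ = [
    "MdsResult",
    "classical_mds",
    "TreeNode",
    "neighbor_joining",
    "to_newick",
    "tree_distances",
    "heatmap_export",
]


@dataclass
class MdsResult:
    labels: list[str]
    coordinates: np.ndarray  # (n, dims)
    eigenvalues: np.ndarray  # all n, descending
    proportion_explained: np.ndarray  # per used axis, of positive mass

    def to_frame(self) -> pd.DataFrame:
        dims = self.coordinates.shape[1]
        return pd.DataFrame(
            self.coordinates,
            index=pd.Index(self.labels, name="label"),
            columns=[f"dim{i + 1}" for i in range(dims)],
        )


def classical_mds(matrix: DistanceMatrix, dims: int = 2) -> MdsResult:
    """Metric MDS: coordinates from -1/2 J D^2 J eigendecomposition."""
    if dims < 1:
        raise ValueError("dims must be >= 1")
    D = matrix.values
    n = D.shape[0]
    if dims > n - 1:
        raise ValueError("dims must be <= n - 1")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-12
    n_pos = int(np.sum(eigvals > tol))
    use = dims
    if dims > n_pos:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; truncating {dims} -> {n_pos} dims"
        )
        use = max(n_pos, 1)
    lam = np.clip(eigvals[:use], 0.0, None)
    coords = eigvecs[:, :use] * np.sqrt(lam)
    coords = coords - coords.mean(axis=0)  # numerically re-center
    pos_mass = float(np.sum(eigvals[eigvals > tol])) or 1.0
    prop = lam / pos_mass
    return MdsResult(list(matrix.labels), coords, eigvals, prop)


# -- neighbour joining ----------------------------------------------------


@dataclass
class TreeNode:
    """Node of an unrooted tree (rendered with a trifurcating root)."""

    name: str | None = None
    children: list[tuple["TreeNode", float, float]] = field(default_factory=list)
    # each child entry: (node, branch_length, raw_branch_length)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name or ""]
        out: list[str] = []
        for child, _, _ in self.children:
            out.extend(child.leaves())
        return out


def _floor_pair(f: float, g: float) -> tuple[float, float, float, float]:
    """Floor negative branch lengths, moving the deficit to the sibling."""
    rf, rg = f, g
    if f < 0:
        g += f
        f = 0.0
    if g < 0:
        f += g
        g = 0.0
    return max(f, 0.0), max(g, 0.0), rf, rg


def neighbor_joining(matrix: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbour joining with deterministic tie-breaking."""
    n = len(matrix.labels)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 populations")
    D = matrix.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in matrix.labels]
    # sort key of a clade: its lexicographically smallest leaf label
    keys: list[str] = list(matrix.labels)
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
                pair_key = tuple(sorted((keys[active[ai]], keys[active[aj]])))
                cand = (q, pair_key, ai, aj)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        f = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        g = dij - f
        f, g, rf, rg = _floor_pair(f, g)
        parent = TreeNode(children=[(nodes[i], f, rf), (nodes[j], g, rg)])
        # new distances to remaining nodes
        new_row = np.zeros(D.shape[0] + 1)
        for ak in range(m):
            k = active[ak]
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (sub[ai, ak] + sub[aj, ak] - dij)
        D = np.vstack([D, new_row[:-1][None, :]])
        D = np.hstack([D, new_row[:, None]])
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [D.shape[0] - 1]

    # resolve the final three nodes around a trifurcating root
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    children = []
    for node_idx, length in ((a, la), (b, lb), (c, lc)):
        raw = length
        children.append((nodes[node_idx], max(length, 0.0), raw))
    # order children deterministically by clade key
    children.sort(key=lambda t: min(t[0].leaves()))
    return TreeNode(children=children)


_NEWICK_RESERVED = set("():;,'[] \t\n")


def _quote(label: str) -> str:
    if any(ch in _NEWICK_RESERVED for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: TreeNode, decimals: int = 6) -> str:
    """Serialize to Newick with branch lengths at fixed precision."""

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            return _quote(node.name or "")
        parts = [
            f"{render(child)}:{length:.{decimals}f}"
            for child, length, _ in node.children
        ]
        return "(" + ",".join(parts) + ")"

    return render(tree) + ";"


def tree_distances(tree: TreeNode) -> pd.DataFrame:
    """Leaf-to-leaf path-length matrix of a tree (for additivity checks)."""
    # build adjacency over object ids
    adj: dict[int, list[tuple[int, float]]] = {}
    names: dict[int, str] = {}

    def walk(node: TreeNode) -> None:
        nid = id(node)
        adj.setdefault(nid, [])
        if node.is_leaf:
            names[nid] = node.name or ""
        for child, length, _ in node.children:
            cid = id(child)
            adj[nid].append((cid, length))
            adj.setdefault(cid, []).append((nid, length))
            walk(child)

    walk(tree)
    leaf_ids = sorted(names, key=lambda i: names[i])
    labels = [names[i] for i in leaf_ids]
    n = len(leaf_ids)
    out = np.zeros((n, n))
    for si, start in enumerate(leaf_ids):
        dist = {start: 0.0}
        stack = [start]
        while stack:
            cur = stack.pop()
            for nxt, w in adj[cur]:
                if nxt not in dist:
                    dist[nxt] = dist[cur] + w
                    stack.append(nxt)
        for sj, end in enumerate(leaf_ids):
            out[si, sj] = dist[end]
    return pd.DataFrame(out, index=labels, columns=labels)


def heatmap_export(
    matrix: DistanceMatrix, ordering: list[str] | None = None
) -> pd.DataFrame:
    """Square matrix as a DataFrame in a stated row/column order."""
    df = matrix.to_frame()
    if ordering is not None:
        missing = set(ordering) - set(matrix.labels)
        if missing:
            raise KeyError(f"unknown labels in ordering: {sorted(missing)}")
        df = df.loc[ordering, ordering]
    return df
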