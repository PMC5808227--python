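"""Neighbor-joining trees from K2P matrices, with column-bootstrap support.

The Saitou–Nei agglomeration in the O(n^3) Studier–Keppler formulation: at
each step join the pair (i, j) minimizing

    Q(i, j) = (r - 2) d(i, j) - R_i - R_j

where R_i is the row sum over the r active clusters.  Ties break
deterministically on the lexicographically smallest pair of cluster labels
(a cluster is labelled by its smallest leaf).  NJ recovers the unique tree
exactly when the input matrix is additive; negative branch-length estimates
on noisy matrices are clamped to zero with the deficit transferred to the
sister edge.  Bootstrap support resamples alignment columns with replacement
(the standard Felsenstein bootstrap) and reports, per internal edge, the
percentage of replicate trees containing the same bipartition.

Trees here are built on per-case subsets (a flagged species and its
neighbours), not on tens of thousands of rows, so no join heuristics are used.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .distance import CODE_OK, DistanceMatrix, distance_matrix

logger = logging.getLogger(__name__)


@dataclass
class TreeNode:
    name: str | None = None  # leaf label; None for internal nodes
    length: float = 0.0  # edge length to parent
    support: float | None = None  # bootstrap percent, internal nodes only
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Tree:
    """Unrooted tree held at an arbitrary (trifurcating) root."""

    root: TreeNode

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.root.leaves()]

    def __len__(self) -> int:
        return len(self.root.leaves())

    # -- bipartitions -----------------------------------------------------
    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each canonicalized as the side NOT containing
        the overall smallest leaf label."""
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        splits: set[frozenset[str]] = set()

        def walk(node: TreeNode):
            below = set()
            if node.is_leaf:
                return {node.name}
            for c in node.children:
                below |= walk(c)
            if node is not self.root and 1 < len(below) < len(all_leaves) - 1:
                side = frozenset(below)
                if anchor in side:
                    side = all_leaves - side
                splits.add(side)
            return below

        walk(self.root)
        return splits

    def _split_of(self, node: TreeNode, all_leaves: frozenset[str], anchor: str):
        below = frozenset(n.name for n in node.leaves())
        if not 1 < len(below) < len(all_leaves) - 1:
            return None
        return all_leaves - below if anchor in below else below

    def annotate_support(self, support: dict[frozenset[str], float]) -> None:
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)

        def walk(node: TreeNode):
            for c in node.children:
                if not c.is_leaf:
                    split = self._split_of(c, all_leaves, anchor)
                    if split is not None:
                        c.support = support.get(split, 0.0)
                    walk(c)

        walk(self.root)

    # -- path distances ----------------------------------------------------
    def path_distance_matrix(self) -> tuple[list[str], np.ndarray]:
        """Leaf-to-leaf path-length matrix (sums of edge lengths)."""
        adj: dict[int, list[tuple[int, float]]] = {}
        names: list[str] = []
        leaf_ids: list[int] = []

        def walk(node: TreeNode):
            adj.setdefault(id(node), [])
            if node.is_leaf:
                names.append(node.name)
                leaf_ids.append(id(node))
            for c in node.children:
                adj[id(node)].append((id(c), c.length))
                adj.setdefault(id(c), []).append((id(node), c.length))
                walk(c)

        walk(self.root)
        n = len(names)
        mat = np.zeros((n, n))
        for i, src in enumerate(leaf_ids):
            dist = {src: 0.0}
            stack = [src]
            while stack:
                u = stack.pop()
                for v, w in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for j, dst in enumerate(leaf_ids):
                mat[i, j] = dist[dst]
        return names, mat


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

class SentinelDistanceError(ValueError):
    def __init__(self, a: str, b: str):
        super().__init__(
            f"distance between {a!r} and {b!r} is undefined; "
            "subset the matrix (imputation is refused)"
        )


def _check_defined(dm: DistanceMatrix) -> None:
    n = len(dm)
    for i in range(n):
        for j in range(i + 1, n):
            if dm.codes[i, j] != CODE_OK:
                raise SentinelDistanceError(dm.labels[i], dm.labels[j])


def nj(dm: DistanceMatrix) -> Tree:
    """Neighbor-joining tree from a fully defined distance matrix (n >= 3)."""
    n = len(dm)
    if n < 3:
        raise ValueError("need at least 3 labels")
    _check_defined(dm)
    D = dm.d.copy()
    nodes = [TreeNode(name=lab) for lab in dm.labels]
    tags = list(dm.labels)  # cluster label = smallest leaf below, for ties
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (r - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cands = np.argwhere(Q <= qmin + 1e-12)
        best = min(
            (tuple(sorted((tags[active[i]], tags[active[j]]))), (i, j))
            for i, j in cands
            if i < j
        )[1]
        ai, aj = best
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = dij / 2 + (R[ai] - R[aj]) / (2 * (r - 2))
        lj = dij - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        new = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        new.children = [nodes[i], nodes[j]]
        # distances from the new cluster to every other active cluster
        for ak in active:
            if ak in (i, j):
                continue
            D[i, ak] = D[ak, i] = (D[i, ak] + D[j, ak] - dij) / 2
        nodes[i] = new
        tags[i] = min(tags[i], tags[j])
        active.remove(j)

    # resolve the final three clusters around a central node
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = (dab + dac - dbc) / 2
    lb = (dab + dbc - dac) / 2
    lc = (dac + dbc - dab) / 2
    lens = [la, lb, lc]
    deficit = 0.0
    for k in range(3):
        if lens[k] < 0:
            deficit += -lens[k]
            lens[k] = 0.0
    if deficit > 0:  # spread across the remaining positive edges
        pos = [k for k in range(3) if lens[k] > 0]
        for k in pos:
            lens[k] += deficit / len(pos)
    root = TreeNode()
    for idx, ln in zip((a, b, c), lens):
        nodes[idx].length = ln
        root.children.append(nodes[idx])
    return Tree(root)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(
    alignment,
    reps: int = 1000,
    seed: int | None = None,
    min_overlap: int = 100,
) -> Tree:
    """NJ tree with Felsenstein column-bootstrap supports (percent).

    Replicates whose resampled matrix contains an undefined distance are
    dropped and counted; a warning is issued when more than 10% drop.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    base_dm = distance_matrix(alignment, min_overlap=min_overlap)
    tree = nj(base_dm)
    target = tree.bipartitions()
    counts = {split: 0 for split in target}
    n_sites = alignment.n_sites
    dropped = 0
    done = 0
    for _ in range(reps):
        cols = rng.integers(0, n_sites, size=n_sites)
        rep_aln = alignment.resample_columns(cols)
        rep_dm = distance_matrix(rep_aln, min_overlap=min_overlap)
        try:
            rep_tree = nj(rep_dm)
        except SentinelDistanceError:
            dropped += 1
            continue
        done += 1
        rep_splits = rep_tree.bipartitions()
        for split in target:
            if split in rep_splits:
                counts[split] += 1
    if dropped > 0.1 * reps:
        warnings.warn(f"{dropped}/{reps} bootstrap replicates dropped (undefined distances)")
    if done == 0:
        raise RuntimeError("all bootstrap replicates dropped")
    support = {split: 100.0 * c / done for split, c in counts.items()}
    tree.annotate_support(support)
    return tree


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

class NewickParseError(ValueError):
    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


def to_newick(tree: Tree) -> str:
    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return f"{node.name}:{node.length:.6f}"
        inner = ",".join(fmt(c) for c in node.children)
        label = "" if node.support is None else str(int(round(node.support)))
        return f"({inner}){label}:{node.length:.6f}"

    inner = ",".join(fmt(c) for c in tree.root.children)
    label = "" if tree.root.support is None else str(int(round(tree.root.support)))
    return f"({inner}){label};"


def write_newick(tree: Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")


def from_newick(text: str) -> Tree:
    text = text.strip()
    if not text:
        raise NewickParseError("empty input", 0)
    pos = 0

    def error(msg):
        raise NewickParseError(msg, pos)

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < len(text) and text[pos] == "(":
            pos += 1
            node.children.append(parse_node())
            while pos < len(text) and text[pos] == ",":
                pos += 1
                node.children.append(parse_node())
            if pos >= len(text) or text[pos] != ")":
                error("expected ')'")
            pos += 1
        # label (leaf name or internal support)
        start = pos
        while pos < len(text) and text[pos] not in ":,();":
            pos += 1
        label = text[start:pos].strip()
        if node.children:
            if label:
                node.support = float(label)
        else:
            if not label:
                error("leaf without a name")
            node.name = label
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] not in ",();":
                pos += 1
            try:
                node.length = float(text[start:pos])
            except ValueError:
                error(f"bad branch length {text[start:pos]!r}")
        return node

    root = parse_node()
    if pos >= len(text) or text[pos] != ";":
        error("expected ';'")
    return Tree(root)


def read_newick(path) -> Tree:
    with open(path) as fh:
        return from_newick(fh.read())
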