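"""Neighbor-joining trees from species distance matrices.

Classic Saitou-Nei agglomeration: repeatedly join the pair minimizing the
Q criterion, estimate branch lengths from the three-point formulas, and
reduce the matrix, ending with a single 3-way join that roots the written
Newick string (the tree itself is unrooted).  Negative estimated branch
lengths are clamped to zero with the deficit moved to the sister branch,
matching NEIGHBOR's default behaviour, and Q ties are broken toward the
lowest index pair so output is deterministic.

The distances fed in here are trigram-composition distances, not
substitutions per site; the trees are cladogram-style summaries of
compositional relatedness, not model-based phylogenies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .species_io import ValidationError


@dataclass
class TreeNode:
    """A rooted rendering of the unrooted NJ tree (root = final 3-way join)."""

    name: str = ""
    length: float = 0.0          # branch to parent; meaningless at the root
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [lf for ch in self.children for lf in ch.leaves()]


def neighbor_joining(matrix, labels: Sequence[str]) -> TreeNode:
    """Build an unrooted NJ tree from a symmetric distance matrix.

    Accepts a raw square array plus labels, or a ``DistanceMatrix`` (pass
    ``matrix.values`` and ``matrix.species_order``).  Requires n >= 3.
    """
    D = np.array(matrix, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")
    if D.shape != (n, n) or len(labels) != n:
        raise ValidationError("matrix must be square with one label per taxon")
    if np.any(np.isnan(D)):
        raise ValidationError("NaN in distance matrix")
    if np.max(np.abs(D - D.T)) > 1e-9 or np.max(np.abs(np.diag(D))) > 1e-9:
        raise ValidationError("matrix must be symmetric with zero diagonal")

    nodes: list[TreeNode] = [TreeNode(name=str(lab)) for lab in labels]

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest-index pair on ties: argmin of the flattened upper triangle
        iu, ju = np.triu_indices(m, k=1)
        best = int(np.argmin(Q[iu, ju]))
        i, j = int(iu[best]), int(ju[best])

        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        li, lj = _clamp_pair(li, lj)

        parent = TreeNode()
        nodes[i].length, nodes[j].length = li, lj
        parent.children = [nodes[i], nodes[j]]

        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        D = np.vstack([D[keep][:, keep], dnew[keep][None, :]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[x] for x in keep] + [parent]

    # final 3-way join via the three-point formulas
    a, b, c = nodes
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    la, lb = _clamp_pair(la, lb)
    lb, lc = _clamp_pair(lb, lc)
    la, lc = _clamp_pair(la, lc)
    a.length, b.length, c.length = la, lb, lc
    root = TreeNode()
    root.children = [a, b, c]
    return root


def _clamp_pair(x: float, y: float) -> tuple[float, float]:
    """Clamp a negative branch to 0, shifting the deficit to its sister."""
    if x < 0.0:
        y += x
        x = 0.0
    if y < 0.0:
        x += y
        y = 0.0
    return x, max(y, 0.0)


def to_newick(tree: TreeNode) -> str:
    """Serialize with branch lengths at 6 decimals, ';'-terminated."""

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            return f"{node.name}:{node.length:.6f}"
        inner = ",".join(render(ch) for ch in node.children)
        return f"({inner}):{node.length:.6f}"

    inner = ",".join(render(ch) for ch in tree.children)
    return f"({inner});"


def leaf_distances(tree: TreeNode) -> dict[tuple[str, str], float]:
    """Pairwise path lengths between leaves (for additivity checks)."""
    paths: dict[str, float] = {}
    out: dict[tuple[str, str], float] = {}

    def walk(node: TreeNode, acc: dict[str, float]) -> dict[str, float]:
        if node.is_leaf:
            return {node.name: node.length}
        below: dict[str, float] = {}
        child_maps = [walk(ch, acc) for ch in node.children]
        for a in range(len(child_maps)):
            for b in range(a + 1, len(child_maps)):
                for la, da in child_maps[a].items():
                    for lb, db in child_maps[b].items():
                        key = (min(la, lb), max(la, lb))
                        out[key] = da + db
        for cm in child_maps:
            for name, dist in cm.items():
                below[name] = dist + node.length
        return below

    walk(tree, paths)
    return out
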