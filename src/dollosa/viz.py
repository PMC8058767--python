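"""Display-only tree post-processing.

These transformations change how an inferred progression is *drawn*,
never the inferred history itself: simple non-branching paths can be
collapsed into single display nodes, and nodes with low cell support can
be merged into their parents.  The support of a node i with parent p is

    s_i = sum_{u in st(i)} C(u) / (sum_{v in st(p)} C(v) - C(p))

where st(x) is the subtree of x and C(x) the number of cells attached to
x — i.e. the share of p's informative (non-p) subtree cells that fall
under i, always in [0, 1].  When the denominator is zero (no informative
cells) the support is defined as 1 so that structure carrying no cells is
never silently deleted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dollo_tree import DolloPhylogeny, NodeKind

__all__ = [
    "CellCounts",
    "DisplayTree",
    "node_support",
    "collapse_simple_paths",
    "collapse_low_support",
    "write_display_dot",
]


@dataclass
class CellCounts:
    """Per-node attached-cell counts C plus the subtree map st of a tree."""

    tree: DolloPhylogeny
    C: dict[int, int]

    @classmethod
    def from_attachment(cls, tree: DolloPhylogeny, sigma) -> "CellCounts":
        nodes = np.asarray(getattr(sigma, "sigma", sigma)).ravel()
        C = {u: 0 for u in tree.nodes()}
        for u in nodes:
            C[int(u)] += 1
        return cls(tree=tree, C=C)

    def st(self, node: int) -> list[int]:
        return self.tree.subtree(node)

    def subtree_count(self, node: int) -> int:
        return sum(self.C.get(u, 0) for u in self.st(node))


def node_support(counts: CellCounts, node: int) -> float:
    """Mutation support s_i of a non-root node (see module docstring)."""
    tree = counts.tree
    parent = tree.parent(node)
    if parent is None:
        raise ValueError("the root has no support")
    num = counts.subtree_count(node)
    den = counts.subtree_count(parent) - counts.C.get(parent, 0)
    if den <= 0:
        return 1.0
    return num / den


# ----------------------------------------------------------------------
# display trees
# ----------------------------------------------------------------------

@dataclass
class DisplayTree:
    """Presentation-layer tree: nodes carry label lists (merged mutation
    names, losses marked with a trailing '-') and attached-cell counts."""

    parent: dict[int, int | None] = field(default_factory=dict)
    children: dict[int, list[int]] = field(default_factory=dict)
    labels: dict[int, list[str]] = field(default_factory=dict)
    cells: dict[int, int] = field(default_factory=dict)
    root: int = 0

    @classmethod
    def from_phylogeny(
        cls, tree: DolloPhylogeny, counts: CellCounts | None = None
    ) -> "DisplayTree":
        dt = cls(root=tree.root)
        for u in tree.nodes():
            lab = tree.label(u)
            if lab.kind is NodeKind.ROOT:
                labels: list[str] = []
            elif lab.kind is NodeKind.GAIN:
                labels = [tree.mutation_names[lab.mutation]]
            else:
                labels = [tree.mutation_names[lab.mutation] + "-"]
            dt.parent[u] = tree.parent(u)
            dt.children[u] = tree.children(u)
            dt.labels[u] = labels
            dt.cells[u] = counts.C.get(u, 0) if counts is not None else 0
        return dt

    def nodes(self) -> list[int]:
        return sorted(self.parent)

    def subtree_cells(self, node: int) -> int:
        total = 0
        stack = [node]
        while stack:
            u = stack.pop()
            total += self.cells[u]
            stack.extend(self.children[u])
        return total

    def depth(self, node: int) -> int:
        d = 0
        p = self.parent[node]
        while p is not None:
            d += 1
            p = self.parent[p]
        return d

    def support(self, node: int) -> float:
        p = self.parent[node]
        if p is None:
            raise ValueError("the root has no support")
        den = self.subtree_cells(p) - self.cells[p]
        if den <= 0:
            return 1.0
        return self.subtree_cells(node) / den

    def merge_into_parent(self, node: int) -> None:
        """Parent absorbs node's labels, cells and children."""
        p = self.parent[node]
        if p is None:
            raise ValueError("cannot merge the root")
        self.labels[p] = self.labels[p] + self.labels[node]
        self.cells[p] += self.cells[node]
        idx = self.children[p].index(node)
        self.children[p][idx : idx + 1] = self.children[node]
        for c in self.children[node]:
            self.parent[c] = p
        del self.parent[node], self.children[node], self.labels[node], self.cells[node]

    def merge_child_into(self, node: int) -> None:
        """Node absorbs its only child (simple-path collapse step)."""
        (child,) = self.children[node]
        self.labels[node] = self.labels[node] + self.labels[child]
        self.cells[node] += self.cells[child]
        self.children[node] = self.children[child]
        for c in self.children[child]:
            self.parent[c] = node
        del self.parent[child], self.children[child], self.labels[child], self.cells[child]


def _as_display(tree, counts=None) -> DisplayTree:
    if isinstance(tree, DisplayTree):
        return tree
    return DisplayTree.from_phylogeny(tree, counts)


def collapse_simple_paths(tree, counts: CellCounts | None = None) -> DisplayTree:
    """Merge every non-root node that has exactly one child with that
    child, until no simple path remains (idempotent)."""
    dt = _as_display(tree, counts)
    changed = True
    while changed:
        changed = False
        for u in dt.nodes():
            if u != dt.root and len(dt.children[u]) == 1:
                dt.merge_child_into(u)
                changed = True
                break
    return dt


def collapse_low_support(tree, counts: CellCounts | None, threshold: float) -> DisplayTree:
    """Repeatedly merge the deepest node whose support is below
    ``threshold`` into its parent, recomputing supports after each merge,
    until no node falls below the threshold."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    dt = _as_display(tree, counts)
    while True:
        low = [
            u
            for u in dt.nodes()
            if u != dt.root and dt.support(u) < threshold
        ]
        if not low:
            return dt
        low.sort(key=lambda u: (-dt.depth(u), u))
        dt.merge_into_parent(low[0])


def write_display_dot(dtree: DisplayTree, path=None) -> str:
    """Emit a display tree as a Graphviz digraph; merged nodes list their
    mutations, pure-loss nodes are styled red."""

    def esc(s: str) -> str:
        return s.replace("\\", "\\\\").replace('"', '\\"')

    lines = ["digraph dollo_display {"]
    for u in dtree.nodes():
        labels = dtree.labels[u]
        text = esc(", ".join(labels) if labels else "germline")
        if dtree.cells.get(u, 0):
            text += f"\\n({dtree.cells[u]} cells)"
        red = labels and all(l.endswith("-") for l in labels)
        extra = ", color=red, fontcolor=red" if red else ""
        shape = ", shape=box" if u == dtree.root else ""
        lines.append(f'  n{u} [label="{text}"{extra}{shape}];')
    for u in dtree.nodes():
        for c in dtree.children[u]:
            lines.append(f"  n{u} -> n{c};")
    lines.append("}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
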