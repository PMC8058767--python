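"""Dollo-k phylogeny data structure.

A cancer progression tree over *m* mutations in which every mutation is
gained exactly once and may be lost at most *k* times, with at most *d*
losses in total across all mutations (a restricted Dollo parsimony model:
Dollo-0 is the perfect phylogeny, Dollo-1 the persistent phylogeny).

Nodes carry one of three labels: an unlabeled germline ROOT, a GAIN of a
mutation, or a LOSS of a mutation.  Every loss node must be a strict
descendant of the gain node of the same mutation.  Node identity is a
stable integer id independent of the label, so label swaps do not disturb
topology bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "NodeKind",
    "NodeLabel",
    "ValidityReport",
    "DolloPhylogeny",
    "random_init",
]


class NodeKind(Enum):
    ROOT = "root"
    GAIN = "gain"
    LOSS = "loss"


@dataclass(frozen=True)
class NodeLabel:
    """Label of a tree node: the germline root, a mutation gain, or one of
    the up-to-k losses of a mutation (distinguished by ``loss_ordinal``)."""

    kind: NodeKind
    mutation: int | None = None
    loss_ordinal: int | None = None

    def __post_init__(self) -> None:
        if self.kind is NodeKind.ROOT:
            if self.mutation is not None or self.loss_ordinal is not None:
                raise ValueError("ROOT label carries no mutation")
        elif self.kind is NodeKind.GAIN:
            if self.mutation is None or self.loss_ordinal is not None:
                raise ValueError("GAIN label needs a mutation and no ordinal")
        else:
            if self.mutation is None or self.loss_ordinal is None:
                raise ValueError("LOSS label needs a mutation and an ordinal")


@dataclass
class ValidityReport:
    ok: bool
    violations: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.ok


class DolloPhylogeny:
    """Rooted tree with gain/loss labels and Dollo bounds ``k`` and ``d``.

    The root (id 0) is an unlabeled germline state with an all-zero genotype
    profile, so fully wild-type cells can attach above all mutations.
    """

    ROOT_ID = 0

    def __init__(
        self,
        m: int,
        k: int = 0,
        d: int = 0,
        mutation_names: list[str] | None = None,
    ) -> None:
        if m < 1:
            raise ValueError("need at least one mutation")
        if k < 0 or d < 0:
            raise ValueError("k and d must be non-negative")
        self.m = int(m)
        self.k = int(k)
        self.d = int(d)
        if mutation_names is None:
            mutation_names = [f"mut{j}" for j in range(m)]
        if len(mutation_names) != m:
            raise ValueError("mutation_names length must equal m")
        self.mutation_names = list(mutation_names)
        self._parent: dict[int, int | None] = {self.ROOT_ID: None}
        self._children: dict[int, list[int]] = {self.ROOT_ID: []}
        self._labels: dict[int, NodeLabel] = {self.ROOT_ID: NodeLabel(NodeKind.ROOT)}
        self._next_id = 1

    # ------------------------------------------------------------------
    # basic structure
    # ------------------------------------------------------------------

    @property
    def root(self) -> int:
        return self.ROOT_ID

    def __len__(self) -> int:
        return len(self._parent)

    def __contains__(self, node: int) -> bool:
        return node in self._parent

    def nodes(self) -> list[int]:
        """All node ids, ascending (stable tie-break order for attachment)."""
        return sorted(self._parent)

    def parent(self, node: int) -> int | None:
        self._check(node)
        return self._parent[node]

    def children(self, node: int) -> list[int]:
        self._check(node)
        return list(self._children[node])

    def label(self, node: int) -> NodeLabel:
        self._check(node)
        return self._labels[node]

    def set_label(self, node: int, label: NodeLabel) -> None:
        self._check(node)
        if node == self.ROOT_ID or label.kind is NodeKind.ROOT:
            raise ValueError("cannot relabel the root")
        self._labels[node] = label

    def _check(self, node: int) -> None:
        if node not in self._parent:
            raise KeyError(f"node {node} not in tree")

    def add_child(self, parent: int, label: NodeLabel) -> int:
        self._check(parent)
        node = self._next_id
        self._next_id += 1
        self._parent[node] = parent
        self._children[node] = []
        self._children[parent].append(node)
        self._labels[node] = label
        return node

    def detach(self, node: int) -> None:
        """Cut the edge to the parent (node keeps its subtree)."""
        self._check(node)
        if node == self.ROOT_ID:
            raise ValueError("cannot detach the root")
        p = self._parent[node]
        self._children[p].remove(node)
        self._parent[node] = None

    def attach(self, node: int, new_parent: int) -> None:
        self._check(node)
        self._check(new_parent)
        if self._parent[node] is not None:
            raise ValueError("node already attached; detach first")
        self._parent[node] = new_parent
        self._children[new_parent].append(node)

    def splice_above(self, node: int, label: NodeLabel) -> int:
        """Insert a new labeled node between ``node`` and its parent."""
        self._check(node)
        if node == self.ROOT_ID:
            raise ValueError("cannot splice above the root")
        p = self._parent[node]
        new = self._next_id
        self._next_id += 1
        idx = self._children[p].index(node)
        self._children[p][idx] = new
        self._parent[new] = p
        self._children[new] = [node]
        self._parent[node] = new
        self._labels[new] = label
        return new

    def remove_node_keep_children(self, node: int) -> None:
        """Delete ``node``; its children become children of its parent."""
        self._check(node)
        if node == self.ROOT_ID:
            raise ValueError("cannot remove the root")
        p = self._parent[node]
        idx = self._children[p].index(node)
        kids = self._children[node]
        self._children[p][idx : idx + 1] = kids
        for c in kids:
            self._parent[c] = p
        del self._parent[node], self._children[node], self._labels[node]

    # ------------------------------------------------------------------
    # queries
    # ------------------------------------------------------------------

    def root_path(self, node: int) -> list[int]:
        """Nodes on the path root → ``node``, inclusive."""
        self._check(node)
        path = []
        cur: int | None = node
        while cur is not None:
            path.append(cur)
            cur = self._parent[cur]
        path.reverse()
        return path

    def is_ancestor(self, a: int, u: int) -> bool:
        """True iff ``a`` is a *strict* ancestor of ``u``."""
        self._check(a)
        cur = self._parent[u]
        while cur is not None:
            if cur == a:
                return True
            cur = self._parent[cur]
        return False

    def subtree(self, node: int) -> list[int]:
        """Nodes of the subtree rooted at ``node`` (preorder, incl. node)."""
        self._check(node)
        out = []
        stack = [node]
        while stack:
            u = stack.pop()
            out.append(u)
            stack.extend(self._children[u])
        return out

    def gain_node(self, mutation: int) -> int:
        for u, lab in self._labels.items():
            if lab.kind is NodeKind.GAIN and lab.mutation == mutation:
                return u
        raise KeyError(f"no gain node for mutation {mutation}")

    def gain_nodes(self) -> dict[int, int]:
        """Map mutation index → gain node id."""
        out: dict[int, int] = {}
        for u, lab in self._labels.items():
            if lab.kind is NodeKind.GAIN:
                out[lab.mutation] = u
        return out

    def loss_nodes(self, mutation: int | None = None) -> list[int]:
        return [
            u
            for u, lab in self._labels.items()
            if lab.kind is NodeKind.LOSS
            and (mutation is None or lab.mutation == mutation)
        ]

    def loss_counts(self) -> np.ndarray:
        """c_j: number of loss nodes per mutation (length m)."""
        c = np.zeros(self.m, dtype=np.int64)
        for lab in self._labels.values():
            if lab.kind is NodeKind.LOSS:
                c[lab.mutation] += 1
        return c

    def copy(self) -> "DolloPhylogeny":
        new = DolloPhylogeny.__new__(DolloPhylogeny)
        new.m, new.k, new.d = self.m, self.k, self.d
        new.mutation_names = list(self.mutation_names)
        new._parent = dict(self._parent)
        new._children = {u: list(cs) for u, cs in self._children.items()}
        new._labels = dict(self._labels)
        new._next_id = self._next_id
        return new

    # ------------------------------------------------------------------
    # genotype profiles
    # ------------------------------------------------------------------

    def genotype_profile(self, node: int) -> np.ndarray:
        """D(T, node): bit j is 1 iff mutation j was gained and not lost on
        the root → node path."""
        self._check(node)
        prof = np.zeros(self.m, dtype=np.int8)
        for u in self.root_path(node):
            lab = self._labels[u]
            if lab.kind is NodeKind.GAIN:
                prof[lab.mutation] = 1
            elif lab.kind is NodeKind.LOSS:
                prof[lab.mutation] = 0
        return prof

    def all_profiles(self) -> tuple[list[int], np.ndarray]:
        """Genotype profiles of every node, rows in ascending node-id order.

        Computed by one DFS, each profile derived from the parent's by
        flipping the labeled mutation's bit.
        """
        ids = self.nodes()
        pos = {u: i for i, u in enumerate(ids)}
        P = np.zeros((len(ids), self.m), dtype=np.int8)
        stack = [self.ROOT_ID]
        while stack:
            u = stack.pop()
            p = self._parent[u]
            row = P[pos[u]]
            if p is not None:
                row[:] = P[pos[p]]
            lab = self._labels[u]
            if lab.kind is NodeKind.GAIN:
                row[lab.mutation] = 1
            elif lab.kind is NodeKind.LOSS:
                row[lab.mutation] = 0
            stack.extend(self._children[u])
        return ids, P

    # ------------------------------------------------------------------
    # validity
    # ------------------------------------------------------------------

    def validate(self) -> ValidityReport:
        """Check every Dollo-k structural invariant; returns a report, never
        raises.  Violation strings name the offending node(s) and rule."""
        v: list[str] = []
        # single root, reachability
        roots = [u for u, p in self._parent.items() if p is None]
        if roots != [self.ROOT_ID]:
            v.append(f"root: expected single root {self.ROOT_ID}, found {roots}")
        if self._labels[self.ROOT_ID].kind is not NodeKind.ROOT:
            v.append("root: node 0 must carry the ROOT label")
        reached = set(self.subtree(self.ROOT_ID)) if self.ROOT_ID in self._parent else set()
        if len(reached) != len(self._parent):
            stranded = sorted(set(self._parent) - reached)
            v.append(f"connectivity: nodes {stranded} unreachable from the root")
        # unique labels
        seen: dict[NodeLabel, int] = {}
        for u, lab in self._labels.items():
            if lab in seen:
                v.append(f"unique-label: nodes {seen[lab]} and {u} share label {lab}")
            seen[lab] = u
        # exactly one gain per mutation
        gains: dict[int, list[int]] = {}
        for u, lab in self._labels.items():
            if lab.kind is NodeKind.GAIN:
                gains.setdefault(lab.mutation, []).append(u)
        for j in range(self.m):
            got = gains.get(j, [])
            if len(got) != 1:
                v.append(f"gain-count: mutation {j} has gain nodes {got}, expected 1")
        # losses below their gain
        for u, lab in self._labels.items():
            if lab.kind is not NodeKind.LOSS:
                continue
            g = gains.get(lab.mutation, [None])[0]
            if g is None or not self.is_ancestor(g, u):
                v.append(
                    f"loss-below-gain: loss node {u} of mutation {lab.mutation} "
                    f"is not a strict descendant of its gain node {g}"
                )
        # loss bounds
        c = self.loss_counts()
        for j in range(self.m):
            if c[j] > self.k:
                v.append(
                    f"per-mutation-bound: mutation {j} lost {c[j]} times, k={self.k}"
                )
        if int(c.sum()) > self.d:
            v.append(f"total-bound: {int(c.sum())} total losses, d={self.d}")
        return ValidityReport(ok=not v, violations=v)


def random_init(
    m: int,
    rng: np.random.Generator | int,
    k: int = 0,
    d: int = 0,
    mutation_names: list[str] | None = None,
) -> DolloPhylogeny:
    """Random gain-only Dollo tree used as the annealing start state.

    Gain nodes are placed sequentially, each attached to a uniformly chosen
    previously placed node (root included), giving a random recursive tree.
    No losses are planted, so the result is valid for any k, d.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    tree = DolloPhylogeny(m, k=k, d=d, mutation_names=mutation_names)
    placed = [tree.root]
    for j in range(m):
        parent = placed[int(rng.integers(len(placed)))]
        placed.append(tree.add_child(parent, NodeLabel(NodeKind.GAIN, j)))
    return tree
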