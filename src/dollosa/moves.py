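"""Neighborhood operations for the simulated-annealing tree search.

Four moves define the search topology, each closed over the set of valid
Dollo-k phylogenies:

* ``spr`` — prune the subtree at u and reattach it as a new child of any
  node outside that subtree;
* ``add_deletion`` — splice a loss node of an ancestral mutation above u,
  subject to the per-mutation bound k and the total bound d;
* ``remove_deletion`` — delete a loss node, reparenting its children;
* ``swap_labels`` — exchange the mutations of two gain nodes.

Moves that strand a loss node (its gain no longer a strict ancestor)
repair the tree by removing the orphaned loss.  ``propose`` draws a move
kind uniformly among the kinds with at least one valid instance, then an
instance uniformly within the kind; the alternative reading (uniform over
all instances pooled) would let SPR's quadratically many instances drown
out deletion moves.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations

import numpy as np

from .dollo_tree import DolloPhylogeny, NodeKind, NodeLabel

__all__ = [
    "MoveKind",
    "MoveProposal",
    "InvalidMove",
    "spr",
    "add_deletion",
    "remove_deletion",
    "swap_labels",
    "propose",
]


class InvalidMove(ValueError):
    """A move's precondition does not hold; callers may resample."""


class MoveKind(Enum):
    SPR = "spr"
    ADD_DELETION = "add_deletion"
    REMOVE_DELETION = "remove_deletion"
    SWAP_LABELS = "swap_labels"


@dataclass
class MoveProposal:
    kind: MoveKind
    operands: tuple[int, ...]
    resulting_tree: DolloPhylogeny


def _repair_orphan_losses(tree: DolloPhylogeny) -> list[int]:
    """Remove every loss node whose gain is no longer a strict ancestor;
    children are reparented.  Returns the removed node ids."""
    removed: list[int] = []
    changed = True
    while changed:
        changed = False
        gains = tree.gain_nodes()
        for u in tree.loss_nodes():
            g = gains.get(tree.label(u).mutation)
            if g is None or not tree.is_ancestor(g, u):
                tree.remove_node_keep_children(u)
                removed.append(u)
                changed = True
                break
    return removed


def spr(tree: DolloPhylogeny, u: int, v: int) -> DolloPhylogeny:
    """Subtree Prune and Reattach: detach the subtree rooted at u and make
    u a child of v.  v may be any node outside u's subtree (the root and
    loss nodes included); losses stranded by the move are removed."""
    if u == tree.root:
        raise InvalidMove("cannot prune the root")
    if v == u or v in set(tree.subtree(u)):
        raise InvalidMove("cannot reattach a subtree below itself")
    new = tree.copy()
    new.detach(u)
    new.attach(u, v)
    _repair_orphan_losses(new)
    return new


def add_deletion(tree: DolloPhylogeny, u: int, v: int) -> DolloPhylogeny:
    """Insert a loss of the mutation gained at node v as the new parent of
    u.  Requires: v is a gain node and a strict ancestor of u; the mutation
    has been lost at most k-1 times, never on u's root path or inside u's
    subtree; and fewer than d losses exist in total."""
    lab = tree.label(v)
    if lab.kind is not NodeKind.GAIN:
        raise InvalidMove("v must be a gain node")
    if not tree.is_ancestor(v, u):
        raise InvalidMove("v must be a strict ancestor of u")
    j = lab.mutation
    c = tree.loss_counts()
    if c[j] >= tree.k:
        raise InvalidMove(f"mutation {j} already lost {int(c[j])} times (k={tree.k})")
    if int(c.sum()) >= tree.d:
        raise InvalidMove(f"total loss bound d={tree.d} reached")
    blocked = set(tree.root_path(u)) | set(tree.subtree(u))
    for w in tree.loss_nodes(j):
        if w in blocked:
            raise InvalidMove(
                f"mutation {j} already lost in an ancestor or descendant of the new node"
            )
    used = {tree.label(w).loss_ordinal for w in tree.loss_nodes(j)}
    ordinal = min(set(range(1, tree.k + 1)) - used)
    new = tree.copy()
    new.splice_above(u, NodeLabel(NodeKind.LOSS, j, ordinal))
    return new


def remove_deletion(tree: DolloPhylogeny, u: int) -> DolloPhylogeny:
    """Delete the loss node u; its children become children of its parent."""
    if tree.label(u).kind is not NodeKind.LOSS:
        raise InvalidMove(f"node {u} is not a loss node")
    new = tree.copy()
    new.remove_node_keep_children(u)
    return new


def swap_labels(tree: DolloPhylogeny, u: int, v: int) -> DolloPhylogeny:
    """Exchange the mutations of two gain nodes; any loss node whose gain
    is no longer a strict ancestor is removed."""
    if u == v:
        raise InvalidMove("operands must differ")
    lu, lv = tree.label(u), tree.label(v)
    if lu.kind is not NodeKind.GAIN or lv.kind is not NodeKind.GAIN:
        raise InvalidMove("both operands must be gain nodes")
    new = tree.copy()
    new.set_label(u, NodeLabel(NodeKind.GAIN, lv.mutation))
    new.set_label(v, NodeLabel(NodeKind.GAIN, lu.mutation))
    _repair_orphan_losses(new)
    return new


def _spr_candidates(tree: DolloPhylogeny) -> list[tuple[int, int]]:
    nodes = tree.nodes()
    out = []
    for u in nodes:
        if u == tree.root:
            continue
        sub = set(tree.subtree(u))
        p = tree.parent(u)
        out.extend((u, v) for v in nodes if v not in sub and v != p)
    return out


def _add_deletion_candidates(tree: DolloPhylogeny) -> list[tuple[int, int]]:
    c = tree.loss_counts()
    if tree.k == 0 or int(c.sum()) >= tree.d:
        return []
    out = []
    for j, g in tree.gain_nodes().items():
        if c[j] >= tree.k:
            continue
        losses = set(tree.loss_nodes(j))
        for u in tree.subtree(g):
            if u == g:
                continue
            blocked = set(tree.root_path(u)) | set(tree.subtree(u))
            if losses & blocked:
                continue
            out.append((u, g))
    return out


def propose(tree: DolloPhylogeny, rng: np.random.Generator) -> MoveProposal:
    """Draw one valid move: kind uniform over feasible kinds, instance
    uniform within the kind.  Deterministic given the rng state."""
    candidates: dict[MoveKind, list[tuple[int, ...]]] = {}
    sprs = _spr_candidates(tree)
    if sprs:
        candidates[MoveKind.SPR] = sprs
    adds = _add_deletion_candidates(tree)
    if adds:
        candidates[MoveKind.ADD_DELETION] = adds
    losses = tree.loss_nodes()
    if losses:
        candidates[MoveKind.REMOVE_DELETION] = [(u,) for u in sorted(losses)]
    gains = sorted(tree.gain_nodes().values())
    if len(gains) >= 2:
        candidates[MoveKind.SWAP_LABELS] = list(combinations(gains, 2))
    if not candidates:
        raise InvalidMove("no valid move exists on this tree")
    kinds = sorted(candidates, key=lambda k: k.value)
    kind = kinds[int(rng.integers(len(kinds)))]
    ops = candidates[kind][int(rng.integers(len(candidates[kind])))]
    if kind is MoveKind.SPR:
        new = spr(tree, *ops)
    elif kind is MoveKind.ADD_DELETION:
        new = add_deletion(tree, *ops)
    elif kind is MoveKind.REMOVE_DELETION:
        new = remove_deletion(tree, *ops)
    else:
        new = swap_labels(tree, *ops)
    return MoveProposal(kind=kind, operands=tuple(ops), resulting_tree=new)
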