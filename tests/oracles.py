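"""Independent brute-force oracles used to cross-check the implementation.

Everything here recomputes quantities by direct enumeration or naive
loops, sharing no code path with the routines under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from dollosa.dollo_tree import DolloPhylogeny, NodeKind, NodeLabel
from dollosa.io_matrix import MISSING, ErrorRates, SCSMatrix


# ----------------------------------------------------------------------
# genotype profile by explicit path walk
# ----------------------------------------------------------------------

def brute_profile(tree: DolloPhylogeny, node: int) -> np.ndarray:
    """Count gains minus losses per mutation along the root path."""
    gains = np.zeros(tree.m, dtype=int)
    losses = np.zeros(tree.m, dtype=int)
    cur = node
    while cur is not None:
        lab = tree.label(cur)
        if lab.kind is NodeKind.GAIN:
            gains[lab.mutation] += 1
        elif lab.kind is NodeKind.LOSS:
            losses[lab.mutation] += 1
        cur = tree.parent(cur)
    return ((gains - losses) > 0).astype(np.int8)


# ----------------------------------------------------------------------
# attachment by exhaustive per-node scoring
# ----------------------------------------------------------------------

def brute_entry_loglik(obs: int, truth: int, alpha_j: float, beta: float) -> float:
    if obs == MISSING:
        return 0.0
    table = {
        (0, 0): 1.0 - beta,
        (0, 1): alpha_j,
        (1, 0): beta,
        (1, 1): 1.0 - alpha_j,
    }
    p = table[(obs, truth)]
    return math.log(p) if p > 0 else -math.inf


def brute_best_attachment(
    tree: DolloPhylogeny, row: np.ndarray, rates: ErrorRates
) -> tuple[int, float]:
    """(best node id, best score) by scoring every node with python loops;
    ties go to the smallest node id."""
    best_node, best_score = None, -math.inf
    for u in sorted(tree.nodes()):
        prof = brute_profile(tree, u)
        s = 0.0
        for j in range(tree.m):
            s += brute_entry_loglik(int(row[j]), int(prof[j]), rates.alpha[j], rates.beta)
        if s > best_score:
            best_node, best_score = u, s
    return best_node, best_score


# ----------------------------------------------------------------------
# three-gamete conflicts by triple scan
# ----------------------------------------------------------------------

def brute_count_conflicts(entries: np.ndarray) -> int:
    n, m = entries.shape
    count = 0
    for p in range(m):
        for q in range(p + 1, m):
            seen = set()
            for i in range(n):
                a, b = entries[i, p], entries[i, q]
                if a != MISSING and b != MISSING:
                    seen.add((int(a), int(b)))
            if {(1, 0), (0, 1), (1, 1)} <= seen:
                count += 1
    return count


# ----------------------------------------------------------------------
# pairwise gain relations by direct ancestor walks
# ----------------------------------------------------------------------

def brute_gain_relations(tree: DolloPhylogeny):
    """(ad_pairs, dl_pairs) over mutation indices via explicit walks."""
    gains = {tree.label(u).mutation: u for u in tree.nodes()
             if tree.label(u).kind is NodeKind.GAIN}

    def ancestors(u):
        out = set()
        p = tree.parent(u)
        while p is not None:
            out.add(p)
            p = tree.parent(p)
        return out

    anc = {j: ancestors(g) for j, g in gains.items()}
    ad, dl = set(), set()
    for p, q in itertools.permutations(sorted(gains), 2):
        if gains[p] in anc[q]:
            ad.add((p, q))
    for p, q in itertools.combinations(sorted(gains), 2):
        if gains[p] not in anc[q] and gains[q] not in anc[p]:
            dl.add(frozenset((p, q)))
    return ad, dl


# ----------------------------------------------------------------------
# exhaustive enumeration of small Dollo trees
# ----------------------------------------------------------------------

def _trees_from_parent_vectors(node_labels: list[NodeLabel], m: int, k: int, d: int):
    """Yield every rooted tree over [root] + node_labels, enumerating all
    parent assignments and keeping the acyclic, fully connected ones."""
    nn = len(node_labels)  # non-root nodes
    ids = list(range(nn + 1))  # 0 = root
    for parents in itertools.product(ids, repeat=nn):
        # parent of node i+1 is parents[i]; reject self-parenting and cycles
        if any(parents[i] == i + 1 for i in range(nn)):
            continue
        children: dict[int, list[int]] = {u: [] for u in ids}
        for i, p in enumerate(parents):
            children[p].append(i + 1)
        # connectivity check
        seen = [0]
        stack = [0]
        while stack:
            u = stack.pop()
            for c in children[u]:
                seen.append(c)
                stack.append(c)
        if len(seen) != nn + 1:
            continue
        tree = DolloPhylogeny(m, k=k, d=d)
        id_map = {0: tree.root}
        stack = [0]
        while stack:
            u = stack.pop()
            for c in children[u]:
                id_map[c] = tree.add_child(id_map[u], node_labels[c - 1])
                stack.append(c)
        yield tree


def enumerate_dollo_trees(m: int, k: int, d: int):
    """All valid Dollo trees with at most one loss in total (k <= 1, d <= 1
    supported — the small-instance oracle regime)."""
    assert k <= 1 and d <= 1
    gains = [NodeLabel(NodeKind.GAIN, j) for j in range(m)]
    yield from _trees_from_parent_vectors(gains, m, k, d)
    if k == 1 and d == 1:
        for j in range(m):
            labels = gains + [NodeLabel(NodeKind.LOSS, j, 1)]
            for tree in _trees_from_parent_vectors(labels, m, k, d):
                if tree.validate().ok:
                    yield tree


def exhaustive_best_objective(
    I: SCSMatrix, rates: ErrorRates, k: int, d: int, loss_prior_mode: str = "penalty"
) -> float:
    """Global optimum of the tree objective by complete enumeration."""
    from dollosa.likelihood import objective

    best = -math.inf
    for tree in enumerate_dollo_trees(I.m, k, d):
        best = max(best, objective(tree, I, rates, loss_prior_mode))
    return best
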