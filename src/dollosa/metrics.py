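"""Evaluation measures for inferred progression trees.

Ancestor–Descendant (AD) and Different-Lineage (DL) accuracies compare the
pairwise ordering of mutation *gains* between a ground-truth tree and an
inferred one; loss nodes are excluded from the pair relations because loss
placement can be non-identifiable (swapping two loss labels can yield an
equally likely tree).  The flip-parsimony score compares the number of
corrections a method applied with the noise actually injected, and the
conflict counter performs the classic three-gamete test for perfect
phylogeny on incomplete matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dollo_tree import DolloPhylogeny
from .io_matrix import MISSING, SCSMatrix

__all__ = [
    "MutationOrder",
    "mutation_order",
    "ancestor_descendant_accuracy",
    "different_lineage_accuracy",
    "flip_parsimony_delta",
    "fn_rate_errors",
    "count_conflicts",
]


@dataclass
class MutationOrder:
    """Pairwise gain relations of a tree, keyed by mutation name:
    ordered ancestor→descendant pairs and unordered different-lineage
    pairs (same-node pairs cannot occur — gains are unique)."""

    ancestor_descendant: set[tuple[str, str]]
    different_lineage: set[frozenset]


def mutation_order(tree: DolloPhylogeny) -> MutationOrder:
    gains = tree.gain_nodes()
    names = tree.mutation_names
    ad: set[tuple[str, str]] = set()
    dl: set[frozenset] = set()
    muts = sorted(gains)
    for i, p in enumerate(muts):
        for q in muts[i + 1 :]:
            if tree.is_ancestor(gains[p], gains[q]):
                ad.add((names[p], names[q]))
            elif tree.is_ancestor(gains[q], gains[p]):
                ad.add((names[q], names[p]))
            else:
                dl.add(frozenset((names[p], names[q])))
    return MutationOrder(ancestor_descendant=ad, different_lineage=dl)


def _check_same_mutations(true_tree: DolloPhylogeny, inferred_tree: DolloPhylogeny) -> None:
    a, b = set(true_tree.mutation_names), set(inferred_tree.mutation_names)
    if a != b:
        raise ValueError(
            f"mutation sets differ: only in truth {sorted(a - b)}, "
            f"only in inference {sorted(b - a)}"
        )


def ancestor_descendant_accuracy(
    true_tree: DolloPhylogeny, inferred_tree: DolloPhylogeny
) -> float:
    """Fraction of true ancestor→descendant gain pairs preserved in the
    inferred tree; 1.0 when the true tree has no such pair."""
    _check_same_mutations(true_tree, inferred_tree)
    truth = mutation_order(true_tree).ancestor_descendant
    if not truth:
        return 1.0
    inferred = mutation_order(inferred_tree).ancestor_descendant
    return len(truth & inferred) / len(truth)


def different_lineage_accuracy(
    true_tree: DolloPhylogeny, inferred_tree: DolloPhylogeny
) -> float:
    """Fraction of true different-lineage (unordered, neither ancestral)
    gain pairs that are also on different branches in the inferred tree;
    1.0 when the true tree has no such pair."""
    _check_same_mutations(true_tree, inferred_tree)
    truth = mutation_order(true_tree).different_lineage
    if not truth:
        return 1.0
    inferred = mutation_order(inferred_tree).different_lineage
    return len(truth & inferred) / len(truth)


def flip_parsimony_delta(estimated_flips: int, true_flips: int) -> int:
    """|flips a method applied − flips the simulation injected|."""
    return abs(int(estimated_flips) - int(true_flips))


def fn_rate_errors(
    estimated: np.ndarray, true: np.ndarray
) -> tuple[float, float]:
    """(avg_error, mse) of false-negative rate estimates: the absolute
    error of the average rate, and the per-mutation mean squared error."""
    est = np.asarray(estimated, dtype=float)
    tru = np.asarray(true, dtype=float)
    if est.shape != tru.shape:
        raise ValueError("estimate and truth must have equal length")
    return float(abs(est.mean() - tru.mean())), float(((est - tru) ** 2).mean())


def count_conflicts(matrix: SCSMatrix | np.ndarray) -> int:
    """Number of mutation pairs violating the three-gamete test.

    A pair (p, q) conflicts with a perfect phylogeny iff cells exhibiting
    the patterns (1,0), (0,1) and (1,1) all exist; missing entries are
    compatible with anything and ignored."""
    A = matrix.entries if isinstance(matrix, SCSMatrix) else np.asarray(matrix)
    O1 = (A == 1).astype(np.int64)
    O0 = (A == 0).astype(np.int64)
    g11 = (O1.T @ O1) > 0
    g10 = (O1.T @ O0) > 0
    g01 = (O0.T @ O1) > 0
    conflict = g11 & g10 & g01
    return int(np.triu(conflict, k=1).sum())
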