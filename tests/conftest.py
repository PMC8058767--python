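from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from dollosa.dollo_tree import DolloPhylogeny, NodeKind, NodeLabel, random_init
from dollosa.moves import InvalidMove, propose

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def fig_tree() -> DolloPhylogeny:
    """Synthetic Dollo-1 example tree over mutations a..g.

    Reconstructed from its textual description (the original drawing is
    not available): mutation a is gained at the top of the progression;
    the path to the node gaining f also gains b and d and loses a, so
    that node's state is {b, d, f} and its genotype profile in mutation
    order a..g is 0101010.  Losses of a, b and d are present (one each),
    so with k = 1 the tree is a valid Dollo-1 phylogeny.
    """
    names = list("abcdefg")
    t = DolloPhylogeny(7, k=1, d=4, mutation_names=names)
    G, L = NodeKind.GAIN, NodeKind.LOSS
    a = t.add_child(t.root, NodeLabel(G, 0))
    b = t.add_child(a, NodeLabel(G, 1))
    d = t.add_child(b, NodeLabel(G, 3))
    a_loss = t.add_child(d, NodeLabel(L, 0, 1))
    f = t.add_child(a_loss, NodeLabel(G, 5))
    b_loss = t.add_child(f, NodeLabel(L, 1, 1))
    t.add_child(b_loss, NodeLabel(G, 6))        # g
    d_loss = t.add_child(f, NodeLabel(L, 3, 1))
    c = t.add_child(a, NodeLabel(G, 2))
    t.add_child(c, NodeLabel(G, 4))             # e
    t.fig_nodes = {"a": a, "b": b, "c": c, "d": d, "f": f,
                   "a-": a_loss, "b-": b_loss, "d-": d_loss}
    return t


def random_valid_tree(
    rng: np.random.Generator, m: int = 6, k: int = 1, d: int = 2, steps: int = 15
) -> DolloPhylogeny:
    """A random valid Dollo tree obtained by walking the move graph."""
    tree = random_init(m, rng, k=k, d=d)
    for _ in range(steps):
        try:
            tree = propose(tree, rng).resulting_tree
        except InvalidMove:
            break
    return tree
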