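import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dollosa import (
    MISSING,
    AnnealConfig,
    DolloPhylogeny,
    ErrorRates,
    NodeKind,
    NodeLabel,
    SCSMatrix,
    best_attachment,
    corrected_matrix,
    count_flips,
    entry_log_likelihood,
    estimate_fn_rates,
    objective,
    random_init,
)
from conftest import random_valid_tree
from oracles import brute_best_attachment


class TestEntryLogLikelihood:
    def test_true_positive(self):
        assert entry_log_likelihood(1, 1, 0.1, 0.01) == pytest.approx(math.log(0.9))

    def test_missing_is_free(self):
        assert entry_log_likelihood(MISSING, 0, 0.1, 0.01) == 0.0
        assert entry_log_likelihood(MISSING, 1, 0.9, 0.5) == 0.0

    def test_true_negative_beta_zero(self):
        assert entry_log_likelihood(0, 0, 0.1, 0.0) == 0.0

    def test_impossible_events_are_minus_inf(self):
        assert entry_log_likelihood(0, 1, 0.0, 0.01) == -math.inf
        assert entry_log_likelihood(1, 0, 0.1, 0.0) == -math.inf

    def test_four_cases_sum_to_one(self):
        a, b = 0.27, 0.03
        for truth in (0, 1):
            total = sum(
                math.exp(entry_log_likelihood(o, truth, a, b)) for o in (0, 1)
            )
            assert total == pytest.approx(1.0)


class TestBestAttachment:
    def test_exact_profile_match(self, fig_tree):
        """A noise-free cell equal to a node's profile attaches there."""
        row = fig_tree.genotype_profile(fig_tree.fig_nodes["f"])
        I = SCSMatrix(row[None, :])
        rates = ErrorRates.homogeneous(7, 0.1, 0.1, 0.05)
        att = best_attachment(fig_tree, I, rates)
        assert np.array_equal(
            fig_tree.genotype_profile(int(att.sigma[0])), row
        )

    def test_fig_cell_0101010_attaches_to_f_node(self, fig_tree):
        I = SCSMatrix(np.array([[0, 1, 0, 1, 0, 1, 0]]))
        rates = ErrorRates.homogeneous(7, 0.1, 0.01, 0.05)
        att = best_attachment(fig_tree, I, rates)
        assert int(att.sigma[0]) == fig_tree.fig_nodes["f"]

    def test_tie_breaks_to_smallest_node_id(self):
        # two nodes share the all-zero profile: root and a gain+loss pair below
        t = DolloPhylogeny(1, k=1, d=1)
        g = t.add_child(t.root, NodeLabel(NodeKind.GAIN, 0))
        t.add_child(g, NodeLabel(NodeKind.LOSS, 0, 1))
        I = SCSMatrix(np.array([[0]]))
        att = best_attachment(t, I, ErrorRates.homogeneous(1, 0.2, 0.1, 0.1))
        assert int(att.sigma[0]) == t.root

    def test_impossible_row_raises_with_cell_name(self):
        # two sibling gains: no node carries both mutations, so a [1,1]
        # cell is impossible under zero error rates
        t = DolloPhylogeny(2)
        t.add_child(t.root, NodeLabel(NodeKind.GAIN, 0))
        t.add_child(t.root, NodeLabel(NodeKind.GAIN, 1))
        I = SCSMatrix(np.array([[1, 1]]), cell_labels=["sX"])
        rates = ErrorRates.homogeneous(2, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError, match="sX"):
            best_attachment(t, I, rates)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_bruteforce_over_all_nodes(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_valid_tree(rng, m=5, k=1, d=2)
        rates = ErrorRates(rng.uniform(0.05, 0.6, 5), 0.05, np.full(5, 0.1))
        rows = rng.choice([0, 1, MISSING], size=(4, 5))
        I = SCSMatrix(rows)
        att = best_attachment(tree, I, rates)
        for i in range(4):
            node, score = brute_best_attachment(tree, rows[i], rates)
            assert int(att.sigma[i]) == node
            assert att.per_cell_loglik[i] == pytest.approx(score)


class TestObjective:
    def test_no_losses_equals_data_term(self):
        t = random_init(4, 3)
        rng = np.random.default_rng(0)
        I = SCSMatrix(rng.choice([0, 1], size=(6, 4)))
        rates = ErrorRates(np.full(4, 0.2), 0.05, rng.uniform(0.01, 0.5, 4))
        att = best_attachment(t, I, rates)
        data = float(att.per_cell_loglik.sum())
        assert objective(t, I, rates, "penalty") == pytest.approx(data)
        assert objective(t, I, rates, "as-printed") == pytest.approx(data)

    def test_noise_free_perfect_phylogeny_scores_zero(self):
        t = random_init(5, 9)
        ids, P = t.all_profiles()
        I = SCSMatrix(P[np.array([0, 2, 4, 1])])
        rates = ErrorRates.homogeneous(5, 0.0, 0.0, 0.0)
        assert objective(t, I, rates, "penalty") == 0.0

    def test_loss_term_signs(self, fig_tree):
        I = SCSMatrix(np.array([[0, 1, 0, 1, 0, 1, 0]]))
        rates = ErrorRates.homogeneous(7, 0.1, 0.01, 0.05)
        att = best_attachment(fig_tree, I, rates)
        data = float(att.per_cell_loglik.sum())
        assert objective(fig_tree, I, rates, "as-printed") > data  # reward
        assert objective(fig_tree, I, rates, "penalty") < data  # penalty

    def test_penalty_minus_inf_for_unlosable_mutation(self, fig_tree):
        I = SCSMatrix(np.array([[0, 1, 0, 1, 0, 1, 0]]))
        rates = ErrorRates.homogeneous(7, 0.1, 0.01, 0.0)  # gamma = 0, losses used
        assert objective(fig_tree, I, rates, "penalty") == -math.inf

    def test_invariant_under_node_id_relabeling(self, fig_tree):
        """Rebuilding the same labeled topology with different node ids
        leaves the objective unchanged."""
        rng = np.random.default_rng(5)
        I = SCSMatrix(rng.choice([0, 1, MISSING], size=(5, 7)))
        rates = ErrorRates.homogeneous(7, 0.15, 0.02, 0.05)
        rebuilt = DolloPhylogeny(7, k=1, d=3, mutation_names=list("abcdefg"))
        # insert children in reversed order → different ids, same topology
        def clone(src_node, dst_parent):
            for child in reversed(fig_tree.children(src_node)):
                nid = rebuilt.add_child(dst_parent, fig_tree.label(child))
                clone(child, nid)
        clone(fig_tree.root, rebuilt.root)
        assert objective(rebuilt, I, rates) == pytest.approx(
            objective(fig_tree, I, rates)
        )


class TestFlipsAndRates:
    def test_identical_matrices_no_flips(self):
        t = random_init(4, 1)
        ids, P = t.all_profiles()
        I = SCSMatrix(P[:3])
        rates = ErrorRates.homogeneous(4, 0.1, 0.01, 0.05)
        att = best_attachment(t, I, rates)
        assert count_flips(I, t, att) == (0, 0)

    def test_one_flip_each_direction(self):
        t = DolloPhylogeny(2)
        a = t.add_child(t.root, NodeLabel(NodeKind.GAIN, 0))
        t.add_child(t.root, NodeLabel(NodeKind.GAIN, 1))
        from dollosa import AttachmentMap

        # cell attached at gain-0 node: E row = [1, 0]; observed [0, 1]
        att = AttachmentMap(np.array([a]), np.array([0.0]))
        I = SCSMatrix(np.array([[0, 1]]))
        assert count_flips(I, t, att) == (1, 1)

    @given(st.integers(0, 2**31 - 1))
    def test_counts_match_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_valid_tree(rng, m=5)
        rates = ErrorRates.homogeneous(5, 0.2, 0.05, 0.1)
        I = SCSMatrix(rng.choice([0, 1, MISSING], size=(6, 5)))
        att = best_attachment(tree, I, rates)
        E = corrected_matrix(tree, att)
        fn = fp = 0
        for i in range(6):
            for j in range(5):
                if I.entries[i, j] == 0 and E[i, j] == 1:
                    fn += 1
                if I.entries[i, j] == 1 and E[i, j] == 0:
                    fp += 1
        assert count_flips(I, tree, att) == (fn, fp)

    def test_fn_estimates_zero_without_flips(self):
        t = random_init(3, 2)
        ids, P = t.all_profiles()
        I = SCSMatrix(P)
        rates = ErrorRates.homogeneous(3, 0.1, 0.01, 0.05)
        att = best_attachment(t, I, rates)
        assert not estimate_fn_rates(I, t, att).any()

    def test_fn_estimate_direct_ratio(self):
        t = DolloPhylogeny(1)
        g = t.add_child(t.root, NodeLabel(NodeKind.GAIN, 0))
        from dollosa import AttachmentMap

        att = AttachmentMap(np.full(10, g), np.zeros(10))
        col = np.ones((10, 1), dtype=np.int8)
        col[:3, 0] = 0  # 3 of 10 attached cells observed 0
        I = SCSMatrix(col)
        assert estimate_fn_rates(I, t, att)[0] == pytest.approx(0.3)


class TestLocality:
    def test_added_loss_leaves_outside_cells_untouched(self, fig_tree):
        """Adding a loss inside one branch does not change the data term of
        cells attached outside the affected subtree."""
        from dollosa.moves import add_deletion

        t = fig_tree
        c = t.fig_nodes["c"]
        rates = ErrorRates.homogeneous(7, 0.1, 0.02, 0.1)
        # cell that sits at gain c's branch vs cell on the f branch
        I = SCSMatrix(
            np.vstack([t.genotype_profile(c), t.genotype_profile(t.fig_nodes["f"])])
        )
        before = best_attachment(t, I, rates)
        # new deletion of c above its child e (inside c's subtree)
        (e,) = t.children(c)
        t2 = add_deletion(t, e, c)
        after = best_attachment(t2, I, rates)
        assert after.per_cell_loglik[1] == pytest.approx(before.per_cell_loglik[1])
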