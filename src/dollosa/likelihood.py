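"""Error model, optimal cell attachment and the tree objective.

Observed entries I_ij are noisy reads of the latent corrected matrix
E_ij = D(T, sigma_i)_j:

    P(I=0 | E=0) = 1 - beta      P(I=0 | E=1) = alpha_j
    P(I=1 | E=0) = beta          P(I=1 | E=1) = 1 - alpha_j
    P(I=? | E)   = 1             (missing entries are uninformative)

with mutation-specific false-negative rates alpha_j (allelic dropout) and
a global false-positive rate beta.  Each cell attaches to the tree node
maximizing its row log-likelihood, computed exactly over all nodes.

The tree objective adds a loss-prior term over the per-mutation loss
counts c_j.  Two variants are provided: ``penalty`` (default), the
standard per-event log-prior c_j * log(gamma_j), which penalizes each
deletion; and ``as-printed``, the literal form -c_j * log(1 - gamma_j),
which is non-negative and therefore *rewards* deletions up to the d cap —
kept selectable for fidelity, not recommended for inference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dollo_tree import DolloPhylogeny
from .io_matrix import MISSING, ErrorRates, SCSMatrix

__all__ = [
    "AttachmentMap",
    "entry_log_likelihood",
    "best_attachment",
    "objective",
    "corrected_matrix",
    "count_flips",
    "estimate_fn_rates",
]

# stand-in for log 0 inside vectorized sums; one impossible entry drives a
# node's score below _IMPOSSIBLE, far under any feasible finite score
_NEG = -1.0e18
_IMPOSSIBLE = -1.0e17


@dataclass
class AttachmentMap:
    """sigma: cell index -> tree node id, with the attained per-cell row
    log-likelihoods; induces the corrected matrix E_i = D(T, sigma_i)."""

    sigma: np.ndarray
    per_cell_loglik: np.ndarray

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=np.int64)
        self.per_cell_loglik = np.asarray(self.per_cell_loglik, dtype=float)
        if self.sigma.shape != self.per_cell_loglik.shape or self.sigma.ndim != 1:
            raise ValueError("sigma and per_cell_loglik must be equal-length 1-D")

    @property
    def n(self) -> int:
        return self.sigma.shape[0]


def entry_log_likelihood(observed: int, truth: int, alpha_j: float, beta: float) -> float:
    """log P(I_ij = observed | E_ij = truth); 0 for missing entries.

    A zero rate makes the corresponding mismatch impossible: the result is
    ``-inf`` (e.g. observed 0 with truth 1 at alpha_j = 0).
    """
    if observed == MISSING:
        return 0.0
    if truth not in (0, 1) or observed not in (0, 1):
        raise ValueError(f"invalid observed/truth pair ({observed}, {truth})")
    if observed == 1:
        p = 1.0 - alpha_j if truth == 1 else beta
    else:
        p = alpha_j if truth == 1 else 1.0 - beta
    return math.log(p) if p > 0 else -math.inf


def _weight_tables(I: SCSMatrix, rates: ErrorRates) -> tuple[np.ndarray, np.ndarray]:
    """Per-entry log-likelihood weights W0 (truth 0) and W1 (truth 1),
    with -inf replaced by the _NEG sentinel so matmuls stay NaN-free."""
    if rates.m != I.m:
        raise ValueError("rate vector length does not match matrix columns")
    obs = I.entries
    with np.errstate(divide="ignore"):
        la, l1a = np.log(rates.alpha), np.log1p(-rates.alpha)
        lb = math.log(rates.beta) if rates.beta > 0 else -math.inf
        l1b = math.log1p(-rates.beta)
    W0 = np.zeros(obs.shape)
    W1 = np.zeros(obs.shape)
    is0, is1 = obs == 0, obs == 1
    W0[is0] = l1b
    W0[is1] = lb
    W1[is0] = np.broadcast_to(la, obs.shape)[is0]
    W1[is1] = np.broadcast_to(l1a, obs.shape)[is1]
    np.nan_to_num(W0, copy=False, neginf=_NEG)
    np.nan_to_num(W1, copy=False, neginf=_NEG)
    return W0, W1


def attachment_scores(tree: DolloPhylogeny, I: SCSMatrix, rates: ErrorRates):
    """n × |nodes| matrix of row log-likelihoods, node columns in ascending
    id order (impossible attachments appear as scores below ``-1e17``)."""
    ids, P = tree.all_profiles()
    W0, W1 = _weight_tables(I, rates)
    Pf = P.astype(float)
    S = W1 @ Pf.T + W0 @ (1.0 - Pf).T
    return ids, S


def best_attachment(tree: DolloPhylogeny, I: SCSMatrix, rates: ErrorRates) -> AttachmentMap:
    """Optimal attachment: each cell is mapped to the node (any node —
    root, gain or loss) maximizing its row log-likelihood; ties are broken
    by the smallest node id."""
    ids, S = attachment_scores(tree, I, rates)
    best_idx = np.argmax(S, axis=1)  # first occurrence = smallest node id
    best_val = S[np.arange(S.shape[0]), best_idx]
    if (best_val <= _IMPOSSIBLE).any():
        cell = int(np.argmax(best_val <= _IMPOSSIBLE))
        raise ValueError(
            f"cell {I.cell_labels[cell]!r} (row {cell}) has no possible "
            f"attachment: every node has zero likelihood"
        )
    sigma = np.asarray(ids, dtype=np.int64)[best_idx]
    return AttachmentMap(sigma=sigma, per_cell_loglik=best_val)


def objective(
    tree: DolloPhylogeny,
    I: SCSMatrix,
    rates: ErrorRates,
    loss_prior_mode: str = "penalty",
    attachment: AttachmentMap | None = None,
) -> float:
    """Tree score: attachment log-likelihood plus the loss-prior term.

    ``penalty`` mode adds sum_j c_j * log(gamma_j) (-inf if a loss was used
    for a mutation with gamma_j = 0); ``as-printed`` adds
    sum_j -c_j * log(1 - gamma_j).
    """
    if attachment is None:
        attachment = best_attachment(tree, I, rates)
    data = float(attachment.per_cell_loglik.sum())
    c = tree.loss_counts()
    if loss_prior_mode == "as-printed":
        loss = float(-(c * np.log1p(-rates.gamma)).sum())
    elif loss_prior_mode == "penalty":
        used = c > 0
        if (rates.gamma[used] == 0).any():
            return -math.inf
        loss = float((c[used] * np.log(rates.gamma[used])).sum())
    else:
        raise ValueError(f"unknown loss_prior_mode {loss_prior_mode!r}")
    return data + loss


def corrected_matrix(tree: DolloPhylogeny, sigma: AttachmentMap) -> np.ndarray:
    """E: row i is the genotype profile of the node cell i attaches to."""
    return np.vstack([tree.genotype_profile(int(s)) for s in sigma.sigma])


def count_flips(
    I: SCSMatrix, tree: DolloPhylogeny, sigma: AttachmentMap
) -> tuple[int, int]:
    """(fn_flips, fp_flips): corrections 0→1 (false negatives explained)
    and 1→0 (false positives explained) from input I to output E; missing
    entries contribute to neither."""
    E = corrected_matrix(tree, sigma)
    obs = I.entries
    fn = int(((obs == 0) & (E == 1)).sum())
    fp = int(((obs == 1) & (E == 0)).sum())
    return fn, fp


def estimate_fn_rates(
    I: SCSMatrix, tree: DolloPhylogeny, sigma: AttachmentMap
) -> np.ndarray:
    """Per-mutation false-negative rate estimates: among cells whose
    corrected genotype carries mutation j (and whose entry is observed),
    the fraction read as 0; zero when no such cell exists."""
    E = corrected_matrix(tree, sigma)
    obs = I.entries
    num = ((obs == 0) & (E == 1)).sum(axis=0).astype(float)
    den = ((E == 1) & (obs != MISSING)).sum(axis=0).astype(float)
    out = np.zeros(I.m)
    np.divide(num, den, out=out, where=den > 0)
    return out
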