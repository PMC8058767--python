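"""Synthetic single-cell dataset generator for recovery experiments.

Ground truth is a random Dollo tree: a random recursive gain tree with,
for each mutation j independently, one loss planted with probability
gamma_j at a uniformly chosen valid location (respecting the k and d
bounds).  Cells attach uniformly at random to tree nodes and inherit the
node's genotype profile.

Noise follows the observation error model applied generatively, entry by
entry: first the entry goes missing with probability ``missing_rate``
(low-coverage dropout of the site), otherwise a true 1 flips to 0 with
the mutation-specific false-negative rate alpha_j (allelic dropout) and a
true 0 flips to 1 with ``fp_rate``.  The missing-before-flip order is
fixed: flips are only ever applied to entries that remain observed, so
the flip log exactly lists the noise the inference must undo.

Mutation-specific false-negative rates are drawn from a Beta distribution
with both shapes < 1 — the default Beta(0.3, 0.3) reproduces the strongly
bimodal dropout profile seen in scRNA-seq mutation calls (spikes of rates
near 0.1 and 0.9).  Loss priors come from a Triangular distribution, the
usual choice when only a mode and bounds are defensible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dollo_tree import DolloPhylogeny, random_init
from .io_matrix import MISSING, SCSMatrix
from .moves import add_deletion, _add_deletion_candidates

__all__ = [
    "SimConfig",
    "SimDataset",
    "draw_rates",
    "simulate_phylogeny",
    "sample_observed_matrix",
    "simulate_dataset",
]


@dataclass
class SimConfig:
    """Study conditions for the synthetic experiments.

    Defaults describe the base recovery setting: 100 cells, 20 mutations,
    at most one loss per mutation (k=1) and three overall (d=3),
    Beta(0.3, 0.3) false-negative rates, Triangular(0, 0.05, 0.1) loss
    priors, a 1e-5 false-positive rate and 1% missing entries.
    """

    n: int = 100
    m: int = 20
    k: int = 1
    d: int = 3
    beta_shape_a: float = 0.3
    beta_shape_b: float = 0.3
    tri_low: float = 0.0
    tri_mode: float = 0.05
    tri_high: float = 0.1
    fp_rate: float = 1.0e-5
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.m < 1:
            raise ValueError("need n >= 1 cells and m >= 1 mutations")
        if not (0 < self.beta_shape_a < 1 and 0 < self.beta_shape_b < 1):
            raise ValueError("Beta shapes must lie in (0, 1)")
        if not self.tri_low <= self.tri_mode <= self.tri_high:
            raise ValueError("need tri_low <= tri_mode <= tri_high")


@dataclass
class SimDataset:
    alpha: np.ndarray
    gamma: np.ndarray
    tree: DolloPhylogeny
    true_matrix: np.ndarray
    attachment: np.ndarray
    observed: SCSMatrix
    flip_log: list[tuple[int, int, int, int]]


def _as_rng(rng) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


def draw_rates(
    cfg: SimConfig, rng: np.random.Generator | int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-mutation false-negative rates alpha_j ~ Beta(a, b) and loss
    priors gamma_j ~ Triangular(low, mode, high), i.i.d."""
    rng = _as_rng(cfg.seed if rng is None else rng)
    alpha = rng.beta(cfg.beta_shape_a, cfg.beta_shape_b, size=cfg.m)
    if cfg.tri_low == cfg.tri_high:
        gamma = np.full(cfg.m, float(cfg.tri_low))
    else:
        gamma = rng.triangular(cfg.tri_low, cfg.tri_mode, cfg.tri_high, size=cfg.m)
    return alpha, gamma


def simulate_phylogeny(
    cfg: SimConfig,
    gamma: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[DolloPhylogeny, np.ndarray, np.ndarray]:
    """Ground-truth tree, true binary matrix and true cell attachment.

    For each mutation j (in index order), with probability gamma_j one
    loss is planted at a location chosen uniformly among the placements
    that keep the tree a valid Dollo-k phylogeny within the d budget;
    mutations whose trigger fires but which have no valid placement are
    left unlost.
    """
    rng = _as_rng(cfg.seed if rng is None else rng)
    if gamma is None:
        _, gamma = draw_rates(cfg, rng)
    gamma = np.asarray(gamma, dtype=float)
    tree = random_init(cfg.m, rng, k=cfg.k, d=cfg.d)
    for j in range(cfg.m):
        if rng.random() >= gamma[j]:
            continue
        gain = tree.gain_node(j)
        cands = [(u, g) for u, g in _add_deletion_candidates(tree) if g == gain]
        if not cands:
            continue
        u, g = cands[int(rng.integers(len(cands)))]
        tree = add_deletion(tree, u, g)
    ids, profiles = tree.all_profiles()
    attach_idx = rng.integers(len(ids), size=cfg.n)
    attachment = np.asarray(ids, dtype=np.int64)[attach_idx]
    true_matrix = profiles[attach_idx].astype(np.int8)
    return tree, true_matrix, attachment


def sample_observed_matrix(
    true_matrix: np.ndarray,
    alpha: np.ndarray,
    fp_rate: float,
    missing_rate: float,
    rng: np.random.Generator | int,
) -> tuple[SCSMatrix, list[tuple[int, int, int, int]]]:
    """Apply the error model generatively: missing first, then flips.

    Returns the observed ternary matrix and a flip log of
    ``(cell, mutation, true, observed)`` for every flipped (non-missing)
    entry — the ground truth for the flip-parsimony score.
    """
    rng = _as_rng(rng)
    true_matrix = np.asarray(true_matrix, dtype=np.int8)
    n, m = true_matrix.shape
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (n, m))
    obs = true_matrix.copy()
    miss = rng.random((n, m)) < missing_rate
    u = rng.random((n, m))
    flip1to0 = (~miss) & (true_matrix == 1) & (u < alpha)
    flip0to1 = (~miss) & (true_matrix == 0) & (u < fp_rate)
    obs[flip1to0] = 0
    obs[flip0to1] = 1
    obs[miss] = MISSING
    flips = [
        (int(i), int(j), int(true_matrix[i, j]), int(obs[i, j]))
        for i, j in np.argwhere(flip1to0 | flip0to1)
    ]
    return SCSMatrix(obs), flips


def simulate_dataset(
    cfg: SimConfig, rng: np.random.Generator | int | None = None
) -> SimDataset:
    """End-to-end draw: rates, ground-truth phylogeny, cells and noise."""
    rng = _as_rng(cfg.seed if rng is None else rng)
    alpha, gamma = draw_rates(cfg, rng)
    tree, true_matrix, attachment = simulate_phylogeny(cfg, gamma=gamma, rng=rng)
    observed, flips = sample_observed_matrix(
        true_matrix, alpha, cfg.fp_rate, cfg.missing_rate, rng
    )
    return SimDataset(
        alpha=alpha,
        gamma=gamma,
        tree=tree,
        true_matrix=true_matrix,
        attachment=attachment,
        observed=observed,
        flip_log=flips,
    )
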