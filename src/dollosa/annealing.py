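"""Simulated-annealing search for the maximum-likelihood Dollo-k tree.

Geometric cooling T_i = T0 * (1 - cr)^i with Metropolis acceptance
min{exp(dv / T), 1}; one move proposal per temperature step, stopping
when the temperature falls below Tmin.  With the default constants
(T0 = 1e4, cr = 1e-2, Tmin = 1e-3) each restart runs exactly 1604
proposals.  Restarts are independent chains from fresh random gain-only
trees; the reported solution is the incumbent best across all restarts,
not the final state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dollo_tree import DolloPhylogeny, random_init
from .io_matrix import ErrorRates, SCSMatrix
from .likelihood import AttachmentMap, best_attachment, objective
from .moves import InvalidMove, propose

__all__ = [
    "AnnealConfig",
    "AnnealResult",
    "TraceRecord",
    "temperature",
    "chain_length",
    "accept",
    "anneal",
]


@dataclass
class AnnealConfig:
    """Cooling schedule, Dollo bounds and reproducibility settings."""

    T0: float = 1.0e4
    cr: float = 1.0e-2
    Tmin: float = 1.0e-3
    restarts: int = 3
    seed: int = 0
    k: int = 0
    d: int = 0
    loss_prior_mode: str = "penalty"

    def __post_init__(self) -> None:
        if not 0 < self.cr < 1:
            raise ValueError("cooling rate must lie in (0, 1)")
        if not 0 < self.Tmin < self.T0:
            raise ValueError("need 0 < Tmin < T0")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


@dataclass
class TraceRecord:
    restart: int
    iteration: int
    temperature: float
    current: float
    best: float


@dataclass
class AnnealResult:
    tree: DolloPhylogeny
    attachment: AttachmentMap
    objective: float
    trace: list[TraceRecord] = field(default_factory=list)


def temperature(i: int, cfg: AnnealConfig) -> float:
    """Temperature at iteration i: T0 * (1 - cr)^i."""
    if i < 0:
        raise ValueError("iteration index must be >= 0")
    return cfg.T0 * (1.0 - cfg.cr) ** i


def chain_length(cfg: AnnealConfig) -> int:
    """Number of proposals per restart: iterations with temperature >= Tmin."""
    i = 0
    while temperature(i, cfg) >= cfg.Tmin:
        i += 1
    return i


def accept(delta_v: float, T: float, rng: np.random.Generator) -> bool:
    """Metropolis rule: accept with probability min{exp(delta_v / T), 1};
    improving or neutral moves (delta_v >= 0) are always accepted."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    if delta_v >= 0:
        return True
    if delta_v == -math.inf:
        return False
    return float(rng.random()) < math.exp(delta_v / T)


def anneal(I: SCSMatrix, rates: ErrorRates, cfg: AnnealConfig) -> AnnealResult:
    """Run the full search and return the best tree ever visited.

    Each restart seeds its own generator from (seed, restart index), starts
    from a fresh random gain-only tree, and anneals through the cooling
    schedule; the incumbent best objective across all restarts is tracked
    and returned together with its attachment map and the search trace.
    """
    if rates.m != I.m:
        raise ValueError("rates do not match matrix dimensions")
    best_tree: DolloPhylogeny | None = None
    best_att: AttachmentMap | None = None
    best_obj = -math.inf
    trace: list[TraceRecord] = []
    for r in range(cfg.restarts):
        rng = np.random.default_rng([cfg.seed % 2**31, r])
        cur = random_init(
            I.m, rng, k=cfg.k, d=cfg.d, mutation_names=list(I.mutation_labels)
        )
        cur_att = best_attachment(cur, I, rates)
        cur_obj = objective(cur, I, rates, cfg.loss_prior_mode, attachment=cur_att)
        if cur_obj > best_obj:
            best_tree, best_att, best_obj = cur, cur_att, cur_obj
        i = 0
        while True:
            T = temperature(i, cfg)
            if T < cfg.Tmin:
                break
            try:
                prop = propose(cur, rng)
            except InvalidMove:
                break  # degenerate tree with no neighbors
            cand = prop.resulting_tree
            cand_att = best_attachment(cand, I, rates)
            cand_obj = objective(
                cand, I, rates, cfg.loss_prior_mode, attachment=cand_att
            )
            if accept(cand_obj - cur_obj, T, rng):
                cur, cur_att, cur_obj = cand, cand_att, cand_obj
                if cur_obj > best_obj:
                    best_tree, best_att, best_obj = cur, cur_att, cur_obj
            trace.append(TraceRecord(r, i, T, cur_obj, best_obj))
            i += 1
    assert best_tree is not None and best_att is not None
    return AnnealResult(
        tree=best_tree, attachment=best_att, objective=best_obj, trace=trace
    )
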