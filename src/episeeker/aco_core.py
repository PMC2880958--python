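"""Generic ant colony optimization over SNP sets.

Each iteration, every ant draws a set of ``n`` distinct loci without
replacement with probabilities proportional to pheromone weight
``tau_k**alpha`` (times a flat prior ``eta_k = 1``); the set is scored by
the chi-square association test, and pheromone is updated once per
iteration: an evaporation factor ``(1 - rho)`` followed by a deposit of
``0.1 * chi2`` on each member locus of each ant's set.  High-scoring loci
therefore accumulate weight and are resampled — the positive feedback that
lets the colony concentrate on associated regions.

The update is synchronous: all ants of an iteration sample from the same
probability vector and their deposits are summed, which makes the
procedure independent of ant order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .data_io import GenotypeMatrix, RunParameters
from .scoring import ScoredSnpSet, score_sets

__all__ = [
    "PheromoneState",
    "AcoRunResult",
    "selection_probabilities",
    "sample_snp_set",
    "update_pheromones",
    "run_aco",
]

#: fraction of a set's chi-square statistic deposited on each member locus
DEPOSIT_RATE = 0.1


@dataclass(frozen=True)
class PheromoneState:
    """Per-locus pheromone levels ``tau`` and flat prior ``eta`` at one
    iteration of the colony."""

    tau: np.ndarray
    eta: np.ndarray
    iteration: int = 0

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau, dtype=np.float64)
        eta = np.asarray(self.eta, dtype=np.float64)
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "eta", eta)
        if tau.ndim != 1 or eta.shape != tau.shape:
            raise ValueError("tau and eta must be 1-D vectors of equal length")
        if not (tau > 0).all():
            raise ValueError("pheromone levels must stay positive")
        if self.iteration < 0:
            raise ValueError("iteration must be nonnegative")

    @classmethod
    def initial(cls, L: int, tau0: float) -> "PheromoneState":
        return cls(np.full(L, float(tau0)), np.ones(L), 0)


@dataclass(frozen=True)
class AcoRunResult:
    """Outcome of one colony run.

    ``top_sets`` holds the best distinct sets seen (descending chi-square),
    ``final_tau`` the pheromone vector after the last update and
    ``iteration_best`` the best chi-square per iteration (diagnostics for
    the run log).
    """

    top_sets: tuple[ScoredSnpSet, ...]
    final_tau: np.ndarray
    iteration_best: np.ndarray


def selection_probabilities(state: PheromoneState, alpha: float) -> np.ndarray:
    """Locus-selection distribution ``tau_k**alpha * eta_k`` normalized."""
    weights = state.tau**alpha * state.eta
    return weights / weights.sum()


def _sample_sets(
    probs: np.ndarray, n: int, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``count`` sorted sets of ``n`` distinct loci, each by
    probability-proportional sampling without replacement.

    Uses the exponential-race formulation: ordering loci by
    ``E_k / p_k`` with i.i.d. standard-exponential ``E_k`` reproduces
    sequential sampling with renormalization exactly, and vectorizes.
    """
    L = probs.shape[0]
    if n > L:
        raise ValueError(f"cannot draw {n} distinct loci from {L}")
    keys = rng.standard_exponential((count, L)) / probs
    if n == L:
        picked = np.tile(np.arange(L), (count, 1))
    else:
        picked = np.argpartition(keys, n - 1, axis=1)[:, :n]
    return np.sort(picked, axis=1)


def sample_snp_set(
    probs: np.ndarray, n: int, rng: np.random.Generator
) -> tuple[int, ...]:
    """Draw one sorted set of ``n`` distinct loci proportional to ``probs``."""
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 1 or not np.isclose(probs.sum(), 1.0):
        raise ValueError("probs must be a 1-D probability vector")
    return tuple(int(k) for k in _sample_sets(probs, n, 1, rng)[0])


def _apply_update(
    state: PheromoneState,
    sets: np.ndarray,
    chi2: np.ndarray,
    rho: float,
) -> PheromoneState:
    deposit = np.zeros_like(state.tau)
    np.add.at(
        deposit,
        sets.ravel(),
        np.repeat(DEPOSIT_RATE * chi2, sets.shape[1]),
    )
    return PheromoneState(
        (1.0 - rho) * state.tau + deposit, state.eta, state.iteration + 1
    )


def update_pheromones(
    state: PheromoneState,
    ant_sets: Iterable[tuple[Sequence[int], float]],
    rho: float,
) -> PheromoneState:
    """One synchronous pheromone update.

    ``tau' = (1 - rho) * tau + sum_m dtau_m`` where ant ``m`` deposits
    ``0.1 * chi2(S_m)`` on each locus of its set ``S_m`` and nothing
    elsewhere.
    """
    if not 0 < rho < 1:
        raise ValueError("rho must lie strictly in (0, 1)")
    pairs = list(ant_sets)
    if not pairs:
        return PheromoneState((1.0 - rho) * state.tau, state.eta, state.iteration + 1)
    chi2 = np.array([float(c) for _, c in pairs])
    if (chi2 < 0).any():
        raise ValueError("chi-square scores must be nonnegative")
    sets = np.array([list(s) for s, _ in pairs], dtype=np.int64)
    return _apply_update(state, sets, chi2, rho)


def run_aco(
    panel: GenotypeMatrix,
    set_size: int,
    iterations: int,
    params: RunParameters,
    rng: np.random.Generator,
    keep_p_max: float | None = None,
) -> AcoRunResult:
    """Run the colony for a fixed number of iterations.

    Per iteration: compute the selection distribution once, draw
    ``params.iAntCount`` sets of ``set_size`` loci, score them all, and
    apply one synchronous pheromone update.  The best
    ``params.iTopModel`` *distinct* sets across the whole run (by raw
    chi-square, first score kept) are returned together with the final
    pheromone vector.

    ``keep_p_max`` optionally restricts bookkeeping to sets with
    ``p_value < keep_p_max`` (used by the single-stage baseline, which
    reports every distinct sampled set below the threshold — pass a large
    ``iTopModel`` alongside).
    """
    L = panel.n_snps
    if set_size > L:
        raise ValueError(f"set size {set_size} exceeds panel size {L}")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    state = PheromoneState.initial(L, params.tau0)
    best: dict[tuple[int, ...], tuple[float, int, float]] = {}
    iteration_best = np.zeros(iterations)
    prune_at = max(4 * params.iTopModel, 4096)
    for it in range(iterations):
        probs = selection_probabilities(state, params.alpha)
        sets = _sample_sets(probs, set_size, params.iAntCount, rng)
        chi2, df, p = score_sets(panel, sets)
        iteration_best[it] = chi2.max() if chi2.size else 0.0
        keep = np.arange(len(chi2)) if keep_p_max is None else np.flatnonzero(p < keep_p_max)
        for k in keep:
            key = tuple(int(i) for i in sets[k])
            if key not in best:
                best[key] = (float(chi2[k]), int(df[k]), float(p[k]))
        if len(best) > prune_at:
            ranked = sorted(best.items(), key=lambda kv: (-kv[1][0], kv[0]))
            best = dict(ranked[: params.iTopModel])
        state = _apply_update(state, sets, chi2, params.rho)
    ranked = sorted(best.items(), key=lambda kv: (-kv[1][0], kv[0]))
    top = tuple(
        ScoredSnpSet(loci, c, d, pv)
        for loci, (c, d, pv) in ranked[: params.iTopModel]
    )
    return AcoRunResult(top, state.tau, iteration_best)
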