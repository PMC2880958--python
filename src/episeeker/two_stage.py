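"""The two-stage epistasis search.

Stage 1 runs the generic colony twice from a fresh pheromone field: once
with a relatively large set size (sensitive to strong signals) and once
with a small set size (sensitive to weak ones).  Each round contributes
its top-scoring sets ("highly suspected" sets) and the top half of the
reduced locus budget by its own final pheromone ranking; the union of the
two half-budgets is the reduced top-pheromone set.  Ranking within each
round avoids comparing pheromone magnitudes across rounds, whose scales
differ by orders of magnitude with set size.

Stage 2 exhaustively scores every interaction-order-sized subset of each
suspected set and of the top-pheromone set — a few tens of thousands of
combinations instead of C(L, order) — and reports those below the p-value
threshold (``EI_all``), which the false-positive minimizer then prunes to
``EI_m``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np

from .aco_core import run_aco
from .data_io import GenotypeMatrix, RunParameters
from .postprocess import Interaction, minimize_false_positives, write_outputs
from .scoring import ScoredSnpSet, score_sets

__all__ = ["StageOneHarvest", "stage_one", "stage_two", "antepiseeker"]


@dataclass(frozen=True)
class StageOneHarvest:
    """Stage-1 output: suspected sets from both rounds, the reduced
    top-pheromone locus set, and per-round diagnostics for the log."""

    suspected_sets: tuple[ScoredSnpSet, ...]
    top_pheromone_loci: tuple[int, ...]
    round_iteration_best: tuple[np.ndarray, np.ndarray]

    def __post_init__(self) -> None:
        if len(set(self.top_pheromone_loci)) != len(self.top_pheromone_loci):
            raise ValueError("top-pheromone loci must be distinct")


def _top_by_tau(tau: np.ndarray, k: int) -> list[int]:
    order = np.lexsort((np.arange(tau.shape[0]), -tau))
    return [int(i) for i in order[:k]]


def stage_one(
    panel: GenotypeMatrix, params: RunParameters, rng: np.random.Generator
) -> StageOneHarvest:
    """Two colony rounds (large then small set size), fresh pheromone each.

    The reduced locus set merges the two rounds' own final-pheromone
    rankings (ties break on locus index) by alternating picks until
    ``iTopLoci`` distinct loci are collected, so both searches contribute
    their most reinforced loci on equal footing without comparing
    pheromone magnitudes across rounds, whose scales differ with set
    size.
    """
    large = run_aco(panel, params.largesetsize, params.iItCountLarge, params, rng)
    small = run_aco(panel, params.smallsetsize, params.iItCountSmall, params, rng)
    budget = min(params.iTopLoci, panel.n_snps)
    rank_l = _top_by_tau(large.final_tau, budget)
    rank_s = _top_by_tau(small.final_tau, budget)
    union: dict[int, None] = {}
    for kl, ks in zip(rank_l, rank_s):
        union.setdefault(kl)
        union.setdefault(ks)
        if len(union) >= budget:
            break
    top_loci = tuple(union)[:budget]
    return StageOneHarvest(
        suspected_sets=large.top_sets + small.top_sets,
        top_pheromone_loci=top_loci,
        round_iteration_best=(large.iteration_best, small.iteration_best),
    )


def stage_two(
    panel: GenotypeMatrix, harvest: StageOneHarvest, params: RunParameters
) -> list[Interaction]:
    """Exhaustive search within the suspected sets and top-pheromone set.

    Candidates are all ``iEpiModel``-sized subsets of every suspected set
    plus all such subsets of the top-pheromone locus set, deduplicated.
    Returns ``EI_all``: candidates with ``p_value < params.pvalue``,
    ascending by p-value (ties lexicographic).
    """
    order = params.iEpiModel
    candidates: set[tuple[int, ...]] = set()
    for s in harvest.suspected_sets:
        candidates.update(combinations(s.loci, order))
    candidates.update(combinations(sorted(harvest.top_pheromone_loci), order))
    if not candidates:
        return []
    sets = np.array(sorted(candidates), dtype=np.int64)
    chi2, df, p = score_sets(panel, sets)
    ei_all = [
        Interaction(
            tuple(int(i) for i in sets[k]),
            tuple(panel.snp_names[i] for i in sets[k]),
            float(chi2[k]),
            int(df[k]),
            float(p[k]),
        )
        for k in np.flatnonzero(p < params.pvalue)
    ]
    ei_all.sort(key=lambda it: (it.p_value, it.loci))
    return ei_all


def antepiseeker(
    panel: GenotypeMatrix,
    params: RunParameters,
    rng: np.random.Generator,
    output_dir: str | Path | None = None,
) -> tuple[list[Interaction], list[Interaction]]:
    """Full two-stage search; returns ``(EI_all, EI_m)``.

    When ``output_dir`` is given, the run log, the full result list and
    the pruned result list are written there as well.
    """
    harvest = stage_one(panel, params, rng)
    ei_all = stage_two(panel, harvest, params)
    ei_m = minimize_false_positives(ei_all)
    if output_dir is not None:
        records = [
            f"round {name}: iteration {i + 1} best chi2 {b:.6g}"
            for name, bests in zip(("large", "small"), harvest.round_iteration_best)
            for i, b in enumerate(bests)
        ]
        records.append(f"stage 2: {len(ei_all)} interactions below p < {params.pvalue}")
        write_outputs(ei_all, ei_m, records, params, output_dir)
    return ei_all, ei_m
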