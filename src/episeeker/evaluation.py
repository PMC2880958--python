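"""Benchmark orchestration: power, null false-positive rate, TPR/FDR.

Three desk-scale experiments mirror the original evaluation designs:

* ``power``      — replicated single-interaction panels; detection power
  is the fraction of replicates whose planted marker pair is reported at
  significance 0.01 after Bonferroni correction over all C(L, order)
  combinations.
* ``null``       — one panel with no genetic effect; the false-positive
  rate of a method at threshold t is (reported interactions with p < t)
  divided by C(L, order), the same denominator for every method.
* ``largescale`` — one big panel with many disjoint planted interactions;
  methods are compared by true-positive rate (exact-tuple matches over
  truths) and false-discovery rate.

The single-stage colony baseline ("generic ACO") runs the same engine
directly at the interaction order, with twice the two-stage search's
total iteration count, and reports every distinct sampled set below the
p-value threshold.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .aco_core import run_aco
from .data_io import GenotypeMatrix, RunParameters, suggest_parameters
from .postprocess import Interaction, minimize_false_positives
from .scoring import exhaustive_pair_scan
from .simulator import (
    DEFAULT_LAMBDA,
    EpistasisModelSpec,
    calibrate,
    embed_interactions,
    simulate_case_control,
    simulate_null,
)
from .two_stage import antepiseeker

__all__ = [
    "EvaluationReport",
    "ExperimentConfig",
    "detection_power",
    "null_fp_rate",
    "tpr_fdr",
    "generic_aco_search",
    "run_experiment",
]


@dataclass(frozen=True)
class EvaluationReport:
    """Aggregated detection metrics for one method under one condition."""

    power: float | None = None
    fp_rate: dict | None = None
    tpr: float | None = None
    fdr: float | None = None
    n_replicates: int = 1
    per_replicate: tuple = ()

    def to_dict(self) -> dict:
        return {
            "power": self.power,
            "fp_rate": {str(k): v for k, v in self.fp_rate.items()}
            if self.fp_rate is not None
            else None,
            "tpr": self.tpr,
            "fdr": self.fdr,
            "n_replicates": self.n_replicates,
            "per_replicate": list(self.per_replicate),
        }


@dataclass(frozen=True)
class ExperimentConfig:
    """Scale and design knobs of one experiment run.

    Defaults are the desk-scale analogues of the original designs
    (10 replicates, L = 1000 or 5000, 2000 cases + 2000 controls).
    """

    experiment: str
    L: int = 1000
    n_case: int = 2000
    n_control: int = 2000
    n_replicates: int = 10
    models: tuple[str, ...] = ("multiplicative", "threshold")
    maf: float = 0.5
    r2: float = 1.0
    alpha: float = 0.01
    thresholds: tuple[float, ...] = (1e-5, 1e-4, 1e-3, 1e-2)
    n_interactions: int = 20
    params: RunParameters | None = None
    pvalue: float | None = None

    def run_parameters(self) -> RunParameters:
        params = self.params if self.params is not None else suggest_parameters(self.L)
        if self.pvalue is not None:
            params = params.replace(pvalue=self.pvalue)
        return params


def _found_with_p(reported: Sequence[Interaction], pair, p_max: float) -> bool:
    pair = tuple(sorted(pair))
    return any(it.loci == pair and it.p_value < p_max for it in reported)


def detection_power(
    results: Sequence[Sequence[Interaction]],
    truths: Sequence[Sequence[tuple]],
    L: int,
    order: int = 2,
    alpha: float = 0.01,
) -> float:
    """Fraction of replicates whose every truth pair is reported at the
    Bonferroni-corrected level ``alpha / C(L, order)``."""
    if len(results) != len(truths):
        raise ValueError("one truth list per replicate result required")
    bonf = alpha / math.comb(L, order)
    successes = sum(
        all(_found_with_p(rep, t, bonf) for t in truth)
        for rep, truth in zip(results, truths)
    )
    return successes / len(results)


def null_fp_rate(
    reported: Sequence[Interaction], L: int, threshold: float, order: int = 2
) -> float:
    """Reported interactions with ``p < threshold`` over all C(L, order)
    combinations (the common denominator across methods)."""
    hits = sum(1 for it in reported if it.p_value < threshold)
    return hits / math.comb(L, order)


def tpr_fdr(
    reported: Sequence[Interaction], truth: Sequence[tuple]
) -> tuple[float, float]:
    """Exact-tuple true-positive rate over truths and false-discovery rate
    over reports (0 for an empty report)."""
    truth_set = {tuple(sorted(t)) for t in truth}
    found = {it.loci for it in reported}
    tpr = len(truth_set & found) / len(truth_set) if truth_set else 0.0
    n_rep = len({it.loci for it in reported})
    fdr = (n_rep - len(truth_set & found)) / n_rep if n_rep else 0.0
    return tpr, fdr


def generic_aco_search(
    panel: GenotypeMatrix,
    params: RunParameters,
    iterations: int,
    rng: np.random.Generator,
) -> list[Interaction]:
    """Single-stage colony baseline at the interaction order itself.

    Reports every distinct sampled set with ``p < params.pvalue``,
    ascending by p-value.
    """
    run = run_aco(
        panel,
        params.iEpiModel,
        iterations,
        params.replace(iTopModel=10**9),
        rng,
        keep_p_max=params.pvalue,
    )
    out = [
        Interaction(
            s.loci,
            tuple(panel.snp_names[i] for i in s.loci),
            s.chi2,
            s.df,
            s.p_value,
        )
        for s in run.top_sets
    ]
    out.sort(key=lambda it: (it.p_value, it.loci))
    return out


def _generic_iterations(params: RunParameters) -> int:
    # the original baseline ran 900 iterations against the two-stage
    # search's 150 + 300: keep the 2x ratio at any scale
    return 2 * (params.iItCountLarge + params.iItCountSmall)


def _largescale_specs(config: ExperimentConfig) -> list[EpistasisModelSpec]:
    grid = [
        (model, maf)
        for model in ("additive", "multiplicative", "threshold")
        for maf in (0.1, 0.2, 0.5)
    ]
    specs = []
    for k in range(config.n_interactions):
        model, maf = grid[k % len(grid)]
        specs.append(
            calibrate(
                EpistasisModelSpec(model, DEFAULT_LAMBDA[model], maf, r2=config.r2)
            )
        )
    return specs


def run_experiment(
    config: ExperimentConfig,
    rng: np.random.Generator,
    out: str | Path | None = None,
) -> dict[str, EvaluationReport]:
    """Run one of the three benchmark experiments.

    Returns a report per condition key (``model:method`` for the power
    study, ``method`` otherwise) and optionally writes the whole mapping
    as JSON.
    """
    if config.experiment == "power":
        reports = _power_study(config, rng)
    elif config.experiment == "null":
        reports = _null_study(config, rng)
    elif config.experiment == "largescale":
        reports = _largescale_study(config, rng)
    else:
        raise ValueError(f"unknown experiment {config.experiment!r}")
    if out is not None:
        Path(out).write_text(
            json.dumps({k: r.to_dict() for k, r in reports.items()}, indent=2)
        )
    return reports


def _power_study(
    config: ExperimentConfig, rng: np.random.Generator
) -> dict[str, EvaluationReport]:
    params = config.run_parameters()
    reports: dict[str, EvaluationReport] = {}
    for model in config.models:
        spec = calibrate(
            EpistasisModelSpec(model, DEFAULT_LAMBDA[model], config.maf, r2=config.r2)
        )
        results = {"antepiseeker": [], "generic_aco": []}
        truths = []
        for _ in range(config.n_replicates):
            sim = simulate_case_control(
                spec, config.L, config.n_case, config.n_control, rng
            )
            truths.append(sim.truth)
            ei_all, _ = antepiseeker(sim.panel, params, rng)
            results["antepiseeker"].append(ei_all)
            results["generic_aco"].append(
                generic_aco_search(sim.panel, params, _generic_iterations(params), rng)
            )
        bonf = config.alpha / math.comb(config.L, params.iEpiModel)
        for method, reps in results.items():
            per_rep = tuple(
                (
                    all(_found_with_p(rep, t, bonf) for t in truth),
                    len(rep),
                    sum(_found_with_p(rep, t, bonf) for t in truth),
                )
                for rep, truth in zip(reps, truths)
            )
            reports[f"{model}:{method}"] = EvaluationReport(
                power=detection_power(
                    reps, truths, config.L, params.iEpiModel, config.alpha
                ),
                n_replicates=config.n_replicates,
                per_replicate=per_rep,
            )
    return reports


def _null_study(
    config: ExperimentConfig, rng: np.random.Generator
) -> dict[str, EvaluationReport]:
    params = config.run_parameters()
    sim = simulate_null(config.L, config.n_case, config.n_control, rng=rng)
    report_threshold = max(config.thresholds)
    exhaustive = exhaustive_pair_scan(
        sim.panel, params.iEpiModel, threshold=report_threshold
    )
    ei_all, ei_m = antepiseeker(
        sim.panel, params.replace(pvalue=report_threshold), rng
    )
    generic = generic_aco_search(
        sim.panel,
        params.replace(pvalue=report_threshold),
        _generic_iterations(params),
        rng,
    )
    reports = {}
    for name, reported in (
        ("exhaustive", exhaustive),
        ("antepiseeker_all", ei_all),
        ("antepiseeker_minimized", ei_m),
        ("generic_aco", generic),
    ):
        reports[name] = EvaluationReport(
            fp_rate={
                t: null_fp_rate(reported, config.L, t, params.iEpiModel)
                for t in config.thresholds
            },
            per_replicate=((True, len(reported), 0),),
        )
    return reports


def _largescale_study(
    config: ExperimentConfig, rng: np.random.Generator
) -> dict[str, EvaluationReport]:
    params = config.run_parameters()
    specs = _largescale_specs(config)
    sim = embed_interactions(
        config.n_interactions, specs, config.L, config.n_case, config.n_control, rng
    )
    ei_all, ei_m = antepiseeker(sim.panel, params, rng)
    generic = generic_aco_search(
        sim.panel, params, _generic_iterations(params), rng
    )
    reports = {}
    for name, reported in (
        ("antepiseeker", ei_all),
        ("antepiseeker_minimized", ei_m),
        ("generic_aco", generic),
    ):
        tpr, fdr = tpr_fdr(reported, sim.truth)
        reports[name] = EvaluationReport(
            tpr=tpr, fdr=fdr, per_replicate=((True, len(reported), 0),)
        )
    return reports
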