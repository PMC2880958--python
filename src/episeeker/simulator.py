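"""Synthetic case-control panels with planted two-locus epistasis.

Disease models
--------------
Three classic two-locus penetrance models are supported, written on the
odds scale as ``odds(g1, g2) = gamma * (1 + theta) ** e`` with

* ``additive``        ``e = g1 + g2``          (multiplicative per allele
  across both loci; additive on the log-odds scale),
* ``multiplicative``  ``e = g1 * g2``          (pure interaction with
  multiplicative effects),
* ``threshold``       ``e = 1[g1 >= 1 and g2 >= 1]`` (risk only when both
  loci carry at least one risk allele),

and penetrance ``odds / (1 + odds)``.

Effect-size calibration
-----------------------
A model is specified by its marginal effect size ``lam`` per causal locus.
Operationally, ``theta`` is solved so that the *per-allele (allelic) odds
ratio* of the marginal single-locus disease table under HWE equals
``1 + lam``, and ``gamma`` is solved so the population prevalence matches
the requested value.  The per-allele odds ratio is the standard
single-marker effect measure in association studies and is exact for the
reference single-locus model ``odds = gamma * (1 + lam) ** g``.

Marker LD
---------
Each causal locus may be observed only through a marker in linkage
disequilibrium ``r2`` with it; marker and causal allele frequencies are
equal, with haplotype frequency ``p11 = f^2 + sqrt(r2) f (1 - f)``.  At
``r2 = 1`` the marker coincides with the causal locus and the causal pair
itself is in the panel; below 1 the panel contains the tag markers only.

Background SNPs are independent, in HWE, with MAF uniform on a range —
the null design of the false-positive study.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .data_io import GenotypeMatrix

__all__ = [
    "EpistasisModelSpec",
    "SimulatedPanel",
    "penetrance_table",
    "calibrate",
    "ld_marker_haplotypes",
    "simulate_null",
    "simulate_case_control",
    "embed_interactions",
]

MODELS = ("additive", "multiplicative", "threshold")
#: paper grid: marginal effect 0.3 for the additive model, 0.2 otherwise
DEFAULT_LAMBDA = {"additive": 0.3, "multiplicative": 0.2, "threshold": 0.2}


@dataclass(frozen=True)
class EpistasisModelSpec:
    """One planted two-locus disease model.

    ``gamma`` (baseline odds) and ``theta`` (per-step odds multiplier)
    are the calibrated parameters; leave them ``None`` and call
    :func:`calibrate`.
    """

    model: str
    lam: float
    maf: float
    r2: float = 1.0
    prevalence: float = 0.01
    gamma: float | None = None
    theta: float | None = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must lie in (0, 0.5]")
        if not 0 < self.r2 <= 1:
            raise ValueError("r2 must lie in (0, 1]")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")

    @property
    def calibrated(self) -> bool:
        return self.gamma is not None and self.theta is not None


@dataclass(frozen=True)
class SimulatedPanel:
    """A genotype panel plus ground truth: the marker-pair indices of each
    planted interaction and the model spec behind each."""

    panel: GenotypeMatrix
    truth: tuple[tuple[int, ...], ...]
    spec_per_truth: tuple[EpistasisModelSpec, ...]

    def __post_init__(self) -> None:
        for pair in self.truth:
            if any(not 0 <= k < self.panel.n_snps for k in pair):
                raise ValueError(f"truth indices {pair} out of range")
        if len(self.truth) != len(self.spec_per_truth):
            raise ValueError("one spec per truth pair required")


def hwe_probs(maf: float) -> np.ndarray:
    """Genotype probabilities ((1-f)^2, 2f(1-f), f^2) under HWE."""
    return np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])


def _exponents(model: str) -> np.ndarray:
    g = np.arange(3)
    if model == "additive":
        return g[:, None] + g[None, :]
    if model == "multiplicative":
        return g[:, None] * g[None, :]
    return ((g[:, None] >= 1) & (g[None, :] >= 1)).astype(np.int64)


def penetrance_table(spec: EpistasisModelSpec) -> np.ndarray:
    """3x3 table of P(disease | g1, g2) from the calibrated odds model."""
    if not spec.calibrated:
        raise ValueError("spec is not calibrated; call calibrate() first")
    odds = spec.gamma * (1.0 + spec.theta) ** _exponents(spec.model)
    return odds / (1.0 + odds)


def _prevalence(spec: EpistasisModelSpec) -> float:
    pg = hwe_probs(spec.maf)
    return float(np.outer(pg, pg).ravel() @ penetrance_table(spec).ravel())


def _marginal_penetrance(spec: EpistasisModelSpec) -> np.ndarray:
    return penetrance_table(spec) @ hwe_probs(spec.maf)


def _allelic_odds_ratio(spec: EpistasisModelSpec) -> float:
    """Per-allele case/control odds ratio of the marginal single-locus table."""
    pg = hwe_probs(spec.maf)
    marg = _marginal_penetrance(spec)
    p_case = pg * marg
    p_ctrl = pg * (1 - marg)
    dose = np.array([0.0, 0.5, 1.0])
    f_case = (p_case * dose).sum() / p_case.sum()
    f_ctrl = (p_ctrl * dose).sum() / p_ctrl.sum()
    return (f_case / (1 - f_case)) / (f_ctrl / (1 - f_ctrl))


def _solve_gamma(spec: EpistasisModelSpec, theta: float) -> float:
    def gap(gamma: float) -> float:
        return _prevalence(replace(spec, gamma=gamma, theta=theta)) - spec.prevalence

    lo, hi = 1e-12, 1e6
    if gap(lo) > 0 or gap(hi) < 0:
        raise RuntimeError(
            f"prevalence {spec.prevalence} not bracketed for theta={theta}"
        )
    return brentq(gap, lo, hi, xtol=1e-300, rtol=1e-12)


def calibrate(spec: EpistasisModelSpec) -> EpistasisModelSpec:
    """Solve ``(gamma, theta)`` so the marginal per-allele odds ratio is
    ``1 + lam`` and the population prevalence matches the spec.

    Both roots are bracketed and solved to relative tolerance below 1e-8;
    ``lam = 0`` yields ``theta = 0`` and a flat penetrance table.
    """
    if spec.lam == 0:
        return replace(spec, theta=0.0, gamma=_solve_gamma(spec, 0.0))

    def gap(theta: float) -> float:
        gamma = _solve_gamma(spec, theta)
        full = replace(spec, gamma=gamma, theta=theta)
        return _allelic_odds_ratio(full) - (1.0 + spec.lam)

    lo, hi = 0.0, 1.0
    while gap(hi) < 0:
        hi *= 2
        if hi > 1e6:
            raise RuntimeError(
                f"marginal effect 1+lam={1 + spec.lam} unreachable for "
                f"model={spec.model}, maf={spec.maf}"
            )
    theta = brentq(gap, lo, hi, xtol=1e-12, rtol=1e-10)
    return replace(spec, theta=theta, gamma=_solve_gamma(spec, theta))


def ld_marker_haplotypes(maf: float, r2: float) -> np.ndarray:
    """Two-locus haplotype frequencies linking a causal locus to its marker.

    Returns a 2x2 array ``h[c, m]`` over causal allele ``c`` and marker
    allele ``m`` with equal allele frequencies at both loci and
    ``h[1, 1] = f^2 + sqrt(r2) f (1 - f)``, so the squared allelic
    correlation equals ``r2`` exactly.
    """
    if not 0 < r2 <= 1:
        raise ValueError("r2 must lie in (0, 1]")
    if not 0 < maf <= 0.5:
        raise ValueError("maf must lie in (0, 0.5]")
    r = np.sqrt(r2)
    f = maf
    h11 = f * f + r * f * (1 - f)
    h = np.array([[1 - 2 * f + h11, f - h11], [f - h11, h11]])
    if (h < -1e-12).any():
        raise ValueError(f"infeasible haplotype frequencies for maf={maf}, r2={r2}")
    return np.clip(h, 0.0, 1.0)


def _background(
    L: int, N: int, maf_low: float, maf_high: float, rng: np.random.Generator
) -> np.ndarray:
    maf = rng.uniform(maf_low, maf_high, size=L)
    return rng.binomial(2, maf[:, None], size=(L, N)).astype(np.uint8)


def _status_vector(n_case: int, n_control: int) -> np.ndarray:
    return np.r_[np.zeros(n_control, dtype=np.int8), np.ones(n_case, dtype=np.int8)]


def simulate_null(
    L: int,
    n_case: int,
    n_control: int,
    maf_low: float = 0.1,
    maf_high: float = 0.5,
    rng: np.random.Generator | None = None,
) -> SimulatedPanel:
    """Panel with no genetic effect: every SNP independent of status and
    of every other SNP, HWE, MAF uniform on ``[maf_low, maf_high]``."""
    if not 0 < maf_low <= maf_high <= 0.5:
        raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
    rng = np.random.default_rng() if rng is None else rng
    genotypes = _background(L, n_case + n_control, maf_low, maf_high, rng)
    names = tuple(f"SNP{i + 1}" for i in range(L))
    panel = GenotypeMatrix(names, genotypes, _status_vector(n_case, n_control))
    return SimulatedPanel(panel, (), ())


def _conditional_pair_dists(spec: EpistasisModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """P(g1, g2 | case) and P(g1, g2 | control) as flat length-9 vectors."""
    pg = hwe_probs(spec.maf)
    joint = np.outer(pg, pg).ravel()
    pen = penetrance_table(spec).ravel()
    p_case = joint * pen
    p_ctrl = joint * (1 - pen)
    if p_case.sum() <= 0:
        raise RuntimeError("penetrance is zero everywhere; cases unreachable")
    return p_case / p_case.sum(), p_ctrl / p_ctrl.sum()


def _markers_from_causal(
    causal_genotypes: np.ndarray, spec: EpistasisModelSpec, rng: np.random.Generator
) -> np.ndarray:
    """Sample marker genotypes chromosome-wise given causal genotypes."""
    h = ld_marker_haplotypes(spec.maf, spec.r2)
    f = spec.maf
    p_m_given_c1 = h[1, 1] / f
    p_m_given_c0 = h[0, 1] / (1 - f)
    g = causal_genotypes
    # allele on each of the two chromosomes: g=2 -> (1,1), g=1 -> (1,0), g=0 -> (0,0)
    hapA = (g >= 1).astype(np.uint8)
    hapB = (g == 2).astype(np.uint8)
    out = np.zeros_like(g)
    for hap in (hapA, hapB):
        p = np.where(hap == 1, p_m_given_c1, p_m_given_c0)
        out += rng.random(g.shape) < p
    return out.astype(np.uint8)


def _draw_interaction_genotypes(
    spec: EpistasisModelSpec, status: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Observed genotype columns (two loci) for every sample, conditional
    on case/control status; returns ``(locus_a, locus_b)`` rows.

    Causal two-locus genotypes are drawn from the exact conditional
    distributions P(g1, g2 | status) — equivalent to rejection sampling
    population draws against case/control quotas.  When ``r2 < 1`` the
    returned columns are the LD tag markers; at ``r2 = 1`` they are the
    causal genotypes themselves.
    """
    p_case, p_ctrl = _conditional_pair_dists(spec)
    N = status.shape[0]
    codes = np.empty(N, dtype=np.int64)
    for s, dist in ((1, p_case), (0, p_ctrl)):
        sel = np.flatnonzero(status == s)
        codes[sel] = rng.choice(9, size=sel.size, p=dist)
    g1, g2 = (codes // 3).astype(np.uint8), (codes % 3).astype(np.uint8)
    if spec.r2 < 1.0:
        g1 = _markers_from_causal(g1, spec, rng)
        g2 = _markers_from_causal(g2, spec, rng)
    return g1, g2


def simulate_case_control(
    spec: EpistasisModelSpec,
    L: int,
    n_case: int,
    n_control: int,
    rng: np.random.Generator | None = None,
    maf_low: float = 0.1,
    maf_high: float = 0.5,
) -> SimulatedPanel:
    """Panel with one planted two-locus interaction.

    The two observed interaction columns (causal loci at ``r2 = 1``, tag
    markers below) sit at random positions among independent HWE
    background SNPs; the truth records their sorted indices.
    """
    if L < 2:
        raise ValueError("need L >= 2 for a two-locus interaction")
    return embed_interactions(1, [spec], L, n_case, n_control, rng,
                              maf_low=maf_low, maf_high=maf_high)


def embed_interactions(
    n_interactions: int,
    specs: Sequence[EpistasisModelSpec],
    L: int,
    n_case: int,
    n_control: int,
    rng: np.random.Generator | None = None,
    maf_low: float = 0.1,
    maf_high: float = 0.5,
) -> SimulatedPanel:
    """Panel with several disjoint planted interactions.

    Case/control labels are fixed by the design (``n_control`` controls
    then ``n_case`` cases) and each interaction is injected independently:
    the genotypes at its randomly chosen pair of positions are drawn from
    that model's conditional distribution given the sample's status.  Each
    planted pair therefore carries its full association signal — the
    "interactions added to the data" design of the large-scale study.
    """
    if len(specs) not in (1, n_interactions):
        raise ValueError("provide one spec or one per interaction")
    if 2 * n_interactions > L:
        raise ValueError(
            f"cannot place {n_interactions} disjoint pairs in {L} loci"
        )
    rng = np.random.default_rng() if rng is None else rng
    specs = [calibrate(s) if not s.calibrated else s for s in specs]
    if len(specs) == 1:
        specs = list(specs) * n_interactions
    status = _status_vector(n_case, n_control)
    genotypes = _background(L, n_case + n_control, maf_low, maf_high, rng)
    positions = rng.choice(L, size=2 * n_interactions, replace=False)
    truth = []
    for k, spec in enumerate(specs):
        pair = tuple(sorted(int(i) for i in positions[2 * k: 2 * k + 2]))
        ga, gb = _draw_interaction_genotypes(spec, status, rng)
        genotypes[pair[0]] = ga
        genotypes[pair[1]] = gb
        truth.append(pair)
    names = tuple(f"SNP{i + 1}" for i in range(L))
    panel = GenotypeMatrix(names, genotypes, status)
    return SimulatedPanel(panel, tuple(truth), tuple(specs))
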