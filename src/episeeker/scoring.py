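"""Chi-square association scoring of SNP sets.

A set of ``n`` loci partitions the samples into at most ``3**n`` genotype
combinations; association with case/control status is measured by the
Pearson chi-square statistic of the (observed combinations) x 2 table.
Degrees of freedom use the number of *observed* combinations K, i.e.
``df = K - 1`` (capped at ``3**n - 1``): with large sets most of the
``3**n`` cells are empty and counting only observed rows keeps p-values
defined.  Stage-1 ranking uses the raw statistic, so the df convention
only affects reported p-values.

All heavy paths (the exhaustive pair scan and the per-iteration scoring of
thousands of ant-selected sets) are vectorized and funnel into the single
kernel :func:`_chi2_from_counts`, so a pair scored by any route yields
bit-identical statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.stats import chi2 as _chi2_dist

from .data_io import GenotypeMatrix
from .postprocess import Interaction

__all__ = [
    "ContingencyTable",
    "ScoredSnpSet",
    "contingency_table",
    "chi2_score",
    "score_sets",
    "exhaustive_pair_scan",
]

#: refuse exhaustive scans beyond this many combinations (a genome-scale
#: panel of 1e5 SNPs already implies ~5e9 pairs)
MAX_EXHAUSTIVE_COMBINATIONS = 20_000_000


@dataclass(frozen=True)
class ContingencyTable:
    """Observed genotype-combination x status counts for one SNP set.

    ``counts`` is ``K x 2`` with column 0 = controls, column 1 = cases;
    rows are the ``K`` genotype combinations observed in at least one
    sample (unobserved combinations are dropped).
    """

    counts: np.ndarray
    set_size: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[1] != 2:
            raise ValueError("counts must be a K x 2 array")
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if counts.shape[0] and not (counts.sum(axis=1) > 0).all():
            raise ValueError("every row must be an observed combination")

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ScoredSnpSet:
    """An ant-selected locus set with its chi-square association score."""

    loci: tuple[int, ...]
    chi2: float
    df: int
    p_value: float

    def __post_init__(self) -> None:
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("loci must be distinct")
        if tuple(sorted(self.loci)) != tuple(self.loci):
            raise ValueError("loci must be sorted")


def _check_loci(panel: GenotypeMatrix, loci: Sequence[int]) -> tuple[int, ...]:
    loci = tuple(int(k) for k in loci)
    if len(loci) == 0:
        raise ValueError("locus set must not be empty")
    if len(set(loci)) != len(loci):
        raise ValueError(f"duplicated locus in set {loci}")
    if min(loci) < 0 or max(loci) >= panel.n_snps:
        raise IndexError(f"locus out of range in {loci}")
    return loci


def contingency_table(panel: GenotypeMatrix, loci: Sequence[int]) -> ContingencyTable:
    """Tabulate observed genotype combinations of ``loci`` against status."""
    loci = _check_loci(panel, loci)
    n = len(loci)
    codes = _combination_codes(panel.genotypes, np.array([loci]))[0]
    K = 3**n
    flat = np.bincount(codes * 2 + panel.status, minlength=2 * K).reshape(K, 2)
    observed = flat.sum(axis=1) > 0
    return ContingencyTable(flat[observed], set_size=n)


def _chi2_from_counts(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pearson chi-square over batched ``(..., K, 2)`` count tables.

    Empty combination rows contribute nothing and reduce the degrees of
    freedom; a table with an empty status column (or a single observed
    row) is degenerate and scores ``chi2 = 0, p = 1``.
    """
    counts = np.asarray(counts, dtype=np.float64)
    O0 = counts[..., 0]
    O1 = counts[..., 1]
    row = O0 + O1
    n0 = O0.sum(axis=-1, keepdims=True)
    n1 = O1.sum(axis=-1, keepdims=True)
    total = n0 + n1
    with np.errstate(divide="ignore", invalid="ignore"):
        e0 = row * n0 / total
        e1 = row * n1 / total
        term = np.where(row > 0, (O0 - e0) ** 2 / e0 + (O1 - e1) ** 2 / e1, 0.0)
    chi2 = term.sum(axis=-1)
    K = (row > 0).sum(axis=-1)
    df = np.maximum(K - 1, 1)
    degenerate = (n0[..., 0] == 0) | (n1[..., 0] == 0) | (K <= 1)
    chi2 = np.where(degenerate, 0.0, chi2)
    p = _chi2_dist.sf(chi2, df)
    p = np.where(degenerate, 1.0, p)
    return chi2, df.astype(np.int64), p


def chi2_score(table: ContingencyTable) -> tuple[float, int, float]:
    """Score one contingency table; returns ``(chi2, df, p_value)``."""
    if table.counts.shape[0] == 0:
        return 0.0, 1, 1.0
    chi2, df, p = _chi2_from_counts(table.counts[None, :, :])
    return float(chi2[0]), int(df[0]), float(p[0])


def _combination_codes(genotypes: np.ndarray, sets: np.ndarray) -> np.ndarray:
    """Base-3 genotype-combination code per (set, sample).

    ``sets`` is ``(M, n)``; the code of sample ``j`` for set
    ``(k_1 .. k_n)`` is ``sum_i g[k_i, j] * 3**(n - 1 - i)``, matching the
    row order of the pairwise scan for ``n = 2``.
    """
    n = sets.shape[1]
    weights = 3 ** np.arange(n - 1, -1, -1, dtype=np.int32)
    sub = genotypes[sets]  # (M, n, N)
    return np.einsum("i,min->mn", weights, sub, dtype=np.int32)


def score_sets(
    panel: GenotypeMatrix, sets: np.ndarray, chunk: int = 2048
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized chi-square scoring of many locus sets of equal size.

    Parameters
    ----------
    panel
        The genotype panel.
    sets
        ``(M, n)`` integer array; loci within a row must be distinct.
    chunk
        Number of sets tabulated per pass (memory control).

    Returns
    -------
    chi2, df, p_value
        Length-``M`` arrays.
    """
    sets = np.asarray(sets, dtype=np.int64)
    if sets.ndim != 2:
        raise ValueError("sets must be a (M, n) array")
    M, n = sets.shape
    if n == 0:
        raise ValueError("locus sets must not be empty")
    if 3**n * 2 > 500_000:
        raise ValueError(f"set size {n} is too large for dense tabulation")
    K = 3**n
    status = panel.status.astype(np.int32)
    chi2 = np.empty(M)
    df = np.empty(M, dtype=np.int64)
    p = np.empty(M)
    for lo in range(0, M, chunk):
        hi = min(lo + chunk, M)
        codes = _combination_codes(panel.genotypes, sets[lo:hi])
        m = hi - lo
        keys = codes * 2 + status[None, :]
        keys += (np.arange(m, dtype=np.int32) * (2 * K))[:, None]
        counts = np.bincount(keys.ravel(), minlength=m * 2 * K).reshape(m, K, 2)
        chi2[lo:hi], df[lo:hi], p[lo:hi] = _chi2_from_counts(counts)
    return chi2, df, p


def _pairwise_count_tables(
    panel: GenotypeMatrix, row_block: int = 256
) -> "np.ndarray":
    """Yield ``(pair_index_arrays, counts)`` blocks for all pairs i < j.

    Counts come from 18 one-hot matrix products per block (one per
    genotype-code pair and status group), the standard trick that turns
    the O(L^2 N) tally into BLAS calls.
    """
    L = panel.n_snps
    onehot = {}
    for s in (0, 1):
        sel = panel.status == s
        for a in (0, 1, 2):
            onehot[(a, s)] = (panel.genotypes[:, sel] == a).astype(np.float32)
    for i0 in range(0, L, row_block):
        i1 = min(i0 + row_block, L)
        nb = i1 - i0
        counts = np.empty((nb, L, 9, 2), dtype=np.float64)
        for a in (0, 1, 2):
            for b in (0, 1, 2):
                for s in (0, 1):
                    counts[:, :, a * 3 + b, s] = onehot[(a, s)][i0:i1] @ onehot[(b, s)].T
        rows, cols = np.nonzero(np.arange(i0, i1)[:, None] < np.arange(L)[None, :])
        yield (rows + i0, cols), np.rint(counts[rows, cols]).astype(np.int64)


def exhaustive_pair_scan(
    panel: GenotypeMatrix,
    order: int = 2,
    threshold: float = 1.0,
    max_combinations: int = MAX_EXHAUSTIVE_COMBINATIONS,
) -> list[Interaction]:
    """Score every ``order``-sized locus combination of the panel.

    Returns the combinations with ``p_value < threshold`` sorted by
    ascending p-value (ties broken lexicographically by loci).  Refuses
    panels whose combination count exceeds ``max_combinations`` — the
    reason this search needs a heuristic in the first place.
    """
    if order < 2:
        raise ValueError("interaction order must be >= 2")
    L = panel.n_snps
    n_comb = math.comb(L, order)
    if n_comb > max_combinations:
        raise ValueError(
            f"exhaustive scan of C({L},{order}) = {n_comb} combinations "
            f"exceeds the limit of {max_combinations}; use the two-stage "
            "search instead"
        )
    results: list[Interaction] = []
    if order == 2:
        for (rows, cols), counts in _pairwise_count_tables(panel):
            chi2, df, p = _chi2_from_counts(counts)
            keep = np.flatnonzero(p < threshold)
            for k in keep:
                loci = (int(rows[k]), int(cols[k]))
                results.append(
                    Interaction(
                        loci,
                        tuple(panel.snp_names[i] for i in loci),
                        float(chi2[k]),
                        int(df[k]),
                        float(p[k]),
                    )
                )
    else:
        sets = np.array(list(combinations(range(L), order)), dtype=np.int64)
        chi2, df, p = score_sets(panel, sets)
        for k in np.flatnonzero(p < threshold):
            loci = tuple(int(i) for i in sets[k])
            results.append(
                Interaction(
                    loci,
                    tuple(panel.snp_names[i] for i in loci),
                    float(chi2[k]),
                    int(df[k]),
                    float(p[k]),
                )
            )
    results.sort(key=lambda it: (it.p_value, it.loci))
    return results
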