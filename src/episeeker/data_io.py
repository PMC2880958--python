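"""Genotype-panel and parameter-file input/output.

The genotype dialect is a plain comma-delimited table: the first row names
the SNPs, every subsequent row is one sample's genotypes coded 0/1/2
(copies of one designated allele) followed by a final case/control status
column (1 = case, 0 = control).  The header may optionally carry one extra
trailing label (e.g. ``Class``) for the status column; it is ignored.

The run-parameter file is the classic one ``name value`` pair per line,
order-free, with ``#`` comments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "RunParameters",
    "read_genotype_csv",
    "write_genotype_csv",
    "read_parameters",
    "suggest_parameters",
]


class PanelFormatError(ValueError):
    """Raised when a genotype file violates the expected dialect."""


@dataclass(frozen=True)
class GenotypeMatrix:
    """A case-control genotype panel.

    Parameters
    ----------
    snp_names
        Unique identifiers for the ``L`` loci.
    genotypes
        ``L x N`` array of codes in ``{0, 1, 2}`` counting copies of one
        designated allele at each locus.
    status
        Length-``N`` vector, 0 for controls and 1 for cases.
    """

    snp_names: tuple[str, ...]
    genotypes: np.ndarray
    status: np.ndarray

    def __post_init__(self) -> None:
        genotypes = np.ascontiguousarray(self.genotypes, dtype=np.uint8)
        status = np.asarray(self.status, dtype=np.int8)
        object.__setattr__(self, "snp_names", tuple(str(s) for s in self.snp_names))
        object.__setattr__(self, "genotypes", genotypes)
        object.__setattr__(self, "status", status)
        if genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D (L x N) array")
        L, N = genotypes.shape
        if L < 1:
            raise ValueError("panel must contain at least one SNP")
        if N < 2:
            raise ValueError("panel must contain at least two samples")
        if len(self.snp_names) != L:
            raise ValueError(
                f"{len(self.snp_names)} SNP names for {L} genotype rows"
            )
        if len(set(self.snp_names)) != L:
            raise PanelFormatError("duplicate SNP names in header")
        if status.shape != (N,):
            raise ValueError("status length must match the number of samples")
        if genotypes.max(initial=0) > 2:
            bad = np.argwhere(genotypes > 2)[0]
            raise PanelFormatError(
                f"genotype code {genotypes[bad[0], bad[1]]} at SNP "
                f"{self.snp_names[bad[0]]!r}, sample {bad[1]} is not 0/1/2"
            )
        if not np.isin(status, (0, 1)).all():
            bad = int(np.flatnonzero(~np.isin(status, (0, 1)))[0])
            raise PanelFormatError(f"status of sample {bad} is not 0/1")
        if not (status == 1).any() or not (status == 0).any():
            raise PanelFormatError("panel needs at least one case and one control")

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int((self.status == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.status == 0).sum())


@dataclass(frozen=True)
class RunParameters:
    """All named parameters of a two-stage search run.

    Defaults are the medium-panel settings of the simulation studies
    (1000 ants, α=1, ρ=0.05, τ0=100, 150/300 iterations, set sizes 6/3,
    two-locus interactions, reporting threshold 0.01).
    """

    iAntCount: int = 1000
    iItCountLarge: int = 150
    iItCountSmall: int = 300
    alpha: float = 1.0
    iTopModel: int = 1000
    iTopLoci: int = 200
    rho: float = 0.05
    tau0: float = 100.0
    largesetsize: int = 6
    smallsetsize: int = 3
    iEpiModel: int = 2
    pvalue: float = 0.01
    inp_file: str | None = None
    out_file: str = "results.txt"

    def __post_init__(self) -> None:
        for name in ("iAntCount", "iItCountLarge", "iItCountSmall",
                     "iTopModel", "iTopLoci"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if not 0 < self.rho < 1:
            raise ValueError("rho (evaporation rate) must lie strictly in (0, 1)")
        if self.tau0 <= 0:
            raise ValueError("tau0 (initial pheromone) must be positive")
        if self.iEpiModel < 2:
            raise ValueError("iEpiModel (interaction order) must be >= 2")
        if self.largesetsize <= self.iEpiModel:
            raise ValueError("largesetsize must be greater than iEpiModel")
        if self.smallsetsize <= self.iEpiModel:
            raise ValueError("smallsetsize must be greater than iEpiModel")
        if not 0 < self.pvalue <= 1:
            raise ValueError("pvalue must lie in (0, 1]")

    def replace(self, **changes) -> "RunParameters":
        return replace(self, **changes)


def read_genotype_csv(path: str | Path) -> GenotypeMatrix:
    """Read a comma-delimited 0/1/2 genotype panel with a status column.

    The last column of each data row is the case/control status; the header
    names only the SNPs (an optional extra trailing header label is
    tolerated and dropped).
    """
    path = Path(path)
    with path.open() as fh:
        header_line = fh.readline().strip()
        if not header_line:
            raise PanelFormatError(f"{path}: file is empty")
        header = [h.strip() for h in header_line.split(",") if h.strip()]
        try:
            data = pd.read_csv(fh, header=None, dtype=str, skipinitialspace=True)
        except pd.errors.EmptyDataError:
            raise PanelFormatError(
                f"{path}: need a header row and at least one sample"
            ) from None
    ncol = data.shape[1]
    if len(header) == ncol - 1:
        snp_names = header
    elif len(header) == ncol:
        # header labels the status column too; drop the trailing label
        snp_names = header[:-1]
    else:
        raise PanelFormatError(
            f"{path}: header names {len(header)} columns but data rows have {ncol}"
        )
    values = data.to_numpy()
    if pd.isna(values).any():
        r, c = np.argwhere(pd.isna(values))[0]
        raise PanelFormatError(f"{path}: missing value at data row {r + 1}, column {c + 1}")
    try:
        codes = values.astype(np.int64)
    except ValueError:
        for r in range(values.shape[0]):
            for c in range(ncol):
                try:
                    int(values[r, c])
                except ValueError:
                    raise PanelFormatError(
                        f"{path}: non-integer entry {values[r, c]!r} at data row "
                        f"{r + 1}, column {c + 1}"
                    ) from None
        raise
    genotypes = codes[:, :-1]
    status = codes[:, -1]
    bad = np.argwhere((genotypes < 0) | (genotypes > 2))
    if bad.size:
        r, c = bad[0]
        raise PanelFormatError(
            f"{path}: genotype code {genotypes[r, c]} at data row {r + 1}, "
            f"column {c + 1} (SNP {snp_names[c]!r}) is not 0/1/2"
        )
    bad = np.flatnonzero((status < 0) | (status > 1))
    if bad.size:
        raise PanelFormatError(
            f"{path}: status {status[bad[0]]} at data row {bad[0] + 1} is not 0/1"
        )
    return GenotypeMatrix(tuple(snp_names), genotypes.T.astype(np.uint8), status)


def write_genotype_csv(panel: GenotypeMatrix, path: str | Path) -> None:
    """Write a panel back in the comma-delimited dialect (SNP header,
    one row per sample, trailing status column)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(",".join(panel.snp_names) + "\n")
        table = np.column_stack([panel.genotypes.T, panel.status.astype(np.uint8)])
        for row in table:
            fh.write(",".join(map(str, row)) + "\n")


_INT_FIELDS = {"iAntCount", "iItCountLarge", "iItCountSmall", "iTopModel",
               "iTopLoci", "largesetsize", "smallsetsize", "iEpiModel"}
_FLOAT_FIELDS = {"alpha", "rho", "tau0", "pvalue"}
_STR_FIELDS = {"inp_file", "out_file", "INPFILE", "OUTFILE"}


def read_parameters(path: str | Path) -> RunParameters:
    """Read a ``parameters.txt``-style file into :class:`RunParameters`.

    One ``name value`` pair per line, order-free, ``#`` starts a comment.
    Missing fields take the package defaults.  ``INPFILE``/``OUTFILE`` are
    accepted as aliases of ``inp_file``/``out_file``.
    """
    path = Path(path)
    fields: dict[str, object] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'name value', got {raw!r}")
        name, value = parts
        if name in _INT_FIELDS:
            fields[name] = int(value)
        elif name in _FLOAT_FIELDS:
            fields[name] = float(value)
        elif name in _STR_FIELDS:
            key = {"INPFILE": "inp_file", "OUTFILE": "out_file"}.get(name, name)
            fields[key] = value
        else:
            raise ValueError(f"{path}:{lineno}: unknown parameter {name!r}")
    return RunParameters(**fields)


def suggest_parameters(L: int, iEpiModel: int = 2) -> RunParameters:
    """Suggest run parameters for a panel of ``L`` SNPs.

    Follows the published rules: ``iItCountSmall >= 0.1 L`` with
    ``iItCountLarge`` half of it, 500-5000 ants growing with ``L`` and an
    evaporation rate in [0.01, 0.1] shrinking with ``L``; set sizes 6/3 for
    pairs and 6/4 for triples.  The rules reproduce the reference settings
    used at L = 2000 (1000 ants, rho = 0.05, 150/300 iterations).
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    small = max(1, math.ceil(0.1 * L))
    large = max(1, round(0.5 * small))
    return RunParameters(
        iAntCount=int(np.clip(L // 2, 500, 5000)),
        iItCountLarge=large,
        iItCountSmall=small,
        rho=float(np.clip(100.0 / L, 0.01, 0.1)),
        largesetsize=max(6, iEpiModel + 2),
        smallsetsize=3 if iEpiModel == 2 else iEpiModel + 1,
        iEpiModel=iEpiModel,
        iTopLoci=min(200, L),
    )
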