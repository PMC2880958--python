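"""False-positive minimization and result files.

The search reports every candidate interaction below the p-value threshold
(``EI_all``).  Because a genuinely associated locus drags many of its
pairings below the threshold, ``EI_all`` is pruned greedily into ``EI_m``:
interactions are visited in order of increasing p-value and kept only if
they share no locus with an interaction kept earlier.  The pruned list
never contains two interactions with a common locus, and the single best
interaction always survives.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = ["Interaction", "minimize_false_positives", "write_outputs"]

#: exact name of the intermediate-results log file
LOG_FILENAME = "AntEpiSeeker.log"
#: exact name of the file carrying every detected interaction (EI_all)
ALL_RESULTS_FILENAME = "results_maximized.txt"


@dataclass(frozen=True, order=True)
class Interaction:
    """A scored locus tuple of the interaction order under study.

    ``loci`` are sorted panel indices; ``snp_names`` the matching
    identifiers; ``p_value`` is the upper-tail probability of ``chi2``
    under a chi-square law with ``df`` degrees of freedom.
    """

    loci: tuple[int, ...]
    snp_names: tuple[str, ...]
    chi2: float
    df: int
    p_value: float

    def __post_init__(self) -> None:
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("interaction loci must be distinct")
        if tuple(sorted(self.loci)) != tuple(self.loci):
            raise ValueError("interaction loci must be sorted")


def _sort_key(interaction: Interaction) -> tuple[float, tuple[int, ...]]:
    return (interaction.p_value, interaction.loci)


def minimize_false_positives(ei_all: Sequence[Interaction]) -> list[Interaction]:
    """Prune ``EI_all`` into the overlap-free set ``EI_m``.

    Interactions are processed in ascending p-value order (ties broken by
    locus tuple).  An interaction sharing no locus with the kept set is
    added.  One that overlaps is kept only if its p-value beats *every*
    overlapped member, in which case it replaces them all; otherwise it is
    dropped.  Under ascending-p processing earlier members never have a
    larger p-value, so the result is the classic greedy disjoint cover; the
    replacement branch is kept for use with externally ordered input.
    """
    ei_m: list[Interaction] = []
    for cand in sorted(ei_all, key=_sort_key):
        cand_loci = set(cand.loci)
        overlapped = [kept for kept in ei_m if cand_loci & set(kept.loci)]
        if not overlapped:
            ei_m.append(cand)
        elif all(cand.p_value < kept.p_value for kept in overlapped):
            ei_m = [kept for kept in ei_m if kept not in overlapped]
            ei_m.append(cand)
    ei_m.sort(key=_sort_key)
    return ei_m


def _format_rows(interactions: Iterable[Interaction], order: int) -> list[str]:
    header = [f"SNP{i + 1}" for i in range(order)] + ["chi2", "pvalue"]
    rows = ["\t".join(header)]
    for it in interactions:
        rows.append(
            "\t".join([*it.snp_names, f"{it.chi2:.6g}", f"{it.p_value:.6g}"])
        )
    return rows


def write_outputs(
    ei_all: Sequence[Interaction],
    ei_m: Sequence[Interaction],
    log_records: Sequence[str],
    params,
    output_dir: str | Path = ".",
) -> dict[str, Path]:
    """Write the three result files of a search run.

    ``AntEpiSeeker.log`` records the parameter echo and per-iteration
    summaries, ``results_maximized.txt`` lists every detected interaction
    (``EI_all``) and the user-named output file lists the pruned set
    (``EI_m``).  Returns the paths keyed by role.
    """
    outdir = Path(output_dir)
    order = params.iEpiModel
    paths = {
        "log": outdir / LOG_FILENAME,
        "all": outdir / ALL_RESULTS_FILENAME,
        "minimized": outdir / params.out_file,
    }
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        with paths["log"].open("w") as fh:
            fh.write("# parameters\n")
            for name, value in vars(params).items():
                fh.write(f"{name} {value}\n")
            fh.write("# search log\n")
            for record in log_records:
                fh.write(record.rstrip("\n") + "\n")
        paths["all"].write_text("\n".join(_format_rows(ei_all, order)) + "\n")
        paths["minimized"].write_text("\n".join(_format_rows(ei_m, order)) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write output file {exc.filename}: {exc}") from exc
    return paths
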