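"""Reading and writing the package's on-disk formats.

Tidy time courses travel as CSV (cell_line, variant, replicate, time_min,
signal); sequences as FASTA (60-column wrap, via Biopython); reports as TSV;
fit results as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .data import TimeCourse, courses_from_frame, courses_to_frame
from .fitting import HierarchicalFitResult
from .grammar import TailDesign, design_report, render_sequence
from .simulate import SimulatedClone
from .stability import InstabilityResult

__all__ = [
    "read_time_courses",
    "write_time_courses",
    "write_designs_fasta",
    "write_design_table",
    "read_fasta",
    "write_clones_fasta",
    "write_clone_report",
    "write_instability_summary",
    "fit_result_to_dict",
    "write_fit_result",
]


def read_time_courses(path) -> list[TimeCourse]:
    return courses_from_frame(pd.read_csv(path))


def write_time_courses(courses: Iterable[TimeCourse], path) -> None:
    courses_to_frame(courses).to_csv(path, index=False)


def write_designs_fasta(
    designs: Sequence[TailDesign], path, alphabet: str = "DNA", strand: str = "sense"
) -> None:
    records = [
        SeqRecord(
            Seq(render_sequence(d, alphabet, strand)),
            id=d.name,
            description=f"{d.pattern} {alphabet.lower()} {strand}",
        )
        for d in designs
    ]
    SeqIO.write(records, path, "fasta")


def write_design_table(designs: Sequence[TailDesign], path) -> pd.DataFrame:
    rows = []
    for d in designs:
        report = design_report(d)
        rows.append(
            {
                "name": report["name"],
                "pattern": report["pattern"],
                "length": report["total_length"],
                "adenines": report["adenine_count"],
                "spacers": report["n_spacers"],
                "longest_run": report["longest_adenine_run"],
                "compliant": report["novel_design_compliant"],
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(path, sep="\t", index=False)
    return table


def read_fasta(path) -> list[tuple[str, str]]:
    """(record id, uppercase sequence) pairs from a FASTA file."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_clones_fasta(clones: Sequence[SimulatedClone], path) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.clone_id, description=c.true_class)
        for c in clones
    ]
    SeqIO.write(records, path, "fasta")


def write_clone_report(rows: Sequence[dict], path) -> pd.DataFrame:
    table = pd.DataFrame(rows)
    table.to_csv(path, sep="\t", index=False)
    return table


def write_instability_summary(
    result: InstabilityResult, path, variant: str = "", strain: str = ""
) -> pd.DataFrame:
    table = pd.DataFrame(
        [
            {
                "variant": variant,
                "strain": strain,
                "n": result.n_total,
                "n_altered": result.n_altered,
                "rate_percent": result.rate,
                "ci_low": result.ci_low,
                "ci_high": result.ci_high,
            }
        ]
    )
    table.to_csv(path, sep="\t", index=False)
    return table


def fit_result_to_dict(result: HierarchicalFitResult) -> dict:
    return {
        "cell_line": result.cell_line,
        "k_mat_hat": result.k_mat_hat,
        "lambda_fluor_hat": result.lambda_fluor_hat,
        "protein_half_life_min": result.protein_half_life,
        "maturation_half_life_min": result.maturation_half_life,
        "total_mae": result.total_mae,
        "identifiable": result.identifiable,
        "per_variant": result.per_variant.to_dict(orient="records"),
        "replicate_summary": result.replicate_summary.to_dict(orient="records"),
    }


def write_fit_result(result: HierarchicalFitResult, path) -> None:
    Path(path).write_text(json.dumps(fit_result_to_dict(result), indent=2))
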