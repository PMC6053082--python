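"""Summary statistics and static rendering of CE gene reports.

Ships a transcription of the published catalogue of prokaryotic genes under
long-lasting recurrent concerted evolution (19 bacterial, 7 archaeal) with
their species counts, minimum durations in Ma, protein-complex annotations
and pathway groupings; :func:`load_reference_table` returns it as a
DataFrame.  The three ammonia-oxidation genes without a characterised
complex (amoD, amoE, haoB) and the complex-less amoA/B/C neighbours carry
the shared pathway group so that complex-or-pathway co-membership counting
reflects the operon-level organisation of the pathway.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .ce_call import CEGeneReport
from .tree_infer import SupportTree

__all__ = [
    "load_reference_table",
    "summarize_durations",
    "complex_membership_counts",
    "render_report",
    "reports_to_frame",
]


def load_reference_table() -> pd.DataFrame:
    """The packaged table of known long-lasting concertedly evolving genes."""
    with resources.files("ceseek.data").joinpath("tables_1_2.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t", dtype={"gene": str}, keep_default_na=False)
    table["complex"] = table["complex"].replace("", pd.NA)
    table["pathway_group"] = table["pathway_group"].replace("", pd.NA)
    return table


def summarize_durations(table: pd.DataFrame,
                        thresholds: Sequence[float] = (500, 1000),
                        ) -> tuple[float, float, dict[float, int]]:
    """Mean, median and exceedance counts of the duration column (Ma).

    The median uses the midpoint convention for even row counts; ``n_over``
    counts rows with duration strictly greater than each threshold.
    """
    if "duration_ma" not in table.columns or len(table) == 0:
        raise ValueError("table has no duration rows")
    durations = pd.to_numeric(table["duration_ma"], errors="coerce").dropna()
    if durations.empty:
        raise ValueError("table has no duration rows")
    mean = float(durations.mean())
    median = float(durations.median())
    n_over = {float(t): int((durations > t).sum()) for t in thresholds}
    return mean, median, n_over


def complex_membership_counts(table: pd.DataFrame) -> tuple[int, int, int]:
    """(n_in_complex, n_same_group, n_total) over the gene report table.

    ``n_in_complex`` counts rows with a complex annotation; ``n_same_group``
    counts rows whose grouping label — pathway group when present, complex
    label otherwise — is shared by at least one other row.
    """
    n_total = len(table)
    complexes = table["complex"] if "complex" in table else pd.Series(dtype=str)
    present = complexes.notna() & (complexes.astype(str).str.strip() != "")
    n_in_complex = int(present.sum())

    groups = table.get("pathway_group", pd.Series(pd.NA, index=table.index))
    labels = groups.where(groups.notna(), complexes)
    labels = labels.dropna().astype(str).str.strip()
    labels = labels[labels != ""]
    counts = labels.value_counts()
    n_same_group = int(labels.map(counts).ge(2).sum())
    return n_in_complex, n_same_group, n_total


def reports_to_frame(reports: Iterable[CEGeneReport]) -> pd.DataFrame:
    rows = [{
        "family_id": r.family_id,
        "order": r.order_name,
        "n_species": r.n_species,
        "species": ",".join(r.species),
        "recurrent": r.recurrent,
        "duration_ma": r.duration_ma,
        "complex": r.complex_annotation,
        "tandem": r.tandem,
    } for r in reports]
    frame = pd.DataFrame(rows, columns=[
        "family_id", "order", "n_species", "species", "recurrent",
        "duration_ma", "complex", "tandem"])
    return frame.sort_values("family_id").reset_index(drop=True)


def render_report(reports: Sequence[CEGeneReport], out_dir: str | Path,
                  alignments: Mapping[str, Mapping[str, str]] | None = None,
                  trees: Mapping[str, SupportTree] | None = None) -> list[Path]:
    """Write a static per-gene report: summary TSV, per-family JSON detail
    and a plain-text tree rendering.  Deterministic ordering throughout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    summary = out / "ce_reports.tsv"
    reports_to_frame(reports).to_csv(summary, sep="\t", index=False)
    written.append(summary)

    for report in sorted(reports, key=lambda r: r.family_id):
        detail = {
            "family_id": report.family_id,
            "order": report.order_name,
            "species": report.species,
            "n_species": report.n_species,
            "recurrent": report.recurrent,
            "duration_ma": report.duration_ma,
            "complex": report.complex_annotation,
            "tandem": report.tandem,
        }
        if trees and report.family_id in trees:
            detail["tree_newick"] = trees[report.family_id].as_newick()
            detail["tree_ascii"] = trees[report.family_id].tree.as_ascii_plot(
                plot_metric="length")
        if alignments and report.family_id in alignments:
            detail["alignment"] = dict(sorted(alignments[report.family_id].items()))
        path = out / f"{report.family_id}.json"
        with open(path, "w") as fh:
            json.dump(detail, fh, indent=1, sort_keys=True)
        written.append(path)
    return written
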