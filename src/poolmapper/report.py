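"""Deconvolution reports: per-plate HTML well grids, FASTA, TSV tables.

The HTML mirrors the bench view of the experiment: one grid per plate,
wells colored by outcome (Grade-1, Grade-2, multi-well, ambiguous,
unresolved). The FASTA carries one record per assignment with the well
coordinates and grade in the header (``>22E04|grade1``) and the element's
representative full-length read as the sequence, ready for external
alignment (BLAST / Bowtie2) and the mapping stage.
"""

from __future__ import annotations

from pathlib import Path
from string import Template

import pandas as pd

from .deconvolve import DeconvolutionResult

_PAGE = Template(
    """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>$title</title>
<style>
body { font-family: sans-serif; margin: 1.5em; }
table.grid { border-collapse: collapse; margin-bottom: 1em; }
table.grid td, table.grid th { border: 1px solid #999; width: 3.2em; height: 2.2em;
  text-align: center; font-size: 80%; }
td.grade1 { background: #7ac27a; }
td.grade2 { background: #c2e0a0; }
td.multi { background: #e8c96a; }
td.ambiguous { background: #d98d8d; }
td.unresolved { background: #d9d9d9; }
.legend span { padding: 0.2em 0.6em; margin-right: 0.6em; border: 1px solid #999; }
</style></head><body>
<h1>$title</h1>
<p class="legend">
<span class="grade1" style="background:#7ac27a">Grade-1</span>
<span class="grade2" style="background:#c2e0a0">Grade-2</span>
<span class="multi" style="background:#e8c96a">multi-well</span>
<span class="ambiguous" style="background:#d98d8d">ambiguous</span>
<span class="unresolved" style="background:#d9d9d9">unresolved</span>
</p>
$body
</body></html>
"""
)


def _well_statuses(result: DeconvolutionResult) -> dict[tuple[str, str, str], str]:
    status: dict[tuple[str, str, str], str] = {
        w: "unresolved" for w in result.design.iter_wells()
    }
    for m in result.multi_well:
        for w in m.implied_wells:
            status[w] = "multi"
    for a in result.assignments:
        status[a.well] = "ambiguous" if a.ambiguous else f"grade{a.grade}"
    return status


def _plate_grid(result: DeconvolutionResult, plate: str, status) -> str:
    design = result.design
    head = "".join(f"<th>{c}</th>" for c in design.columns)
    rows_html = []
    for r in design.rows:
        cells = []
        for c in design.columns:
            cls = status[(plate, r, c)]
            cells.append(f'<td class="{cls}" title="{plate}{r}{c}">{r}{c}</td>')
        rows_html.append(f"<tr><th>{r}</th>{''.join(cells)}</tr>")
    return (
        f"<h2>Plate {plate}</h2>"
        f'<table class="grid"><tr><th></th>{head}</tr>{"".join(rows_html)}</table>'
    )


def write_fasta(result: DeconvolutionResult, path: str | Path) -> int:
    """FASTA of assigned elements, ID ``<plate><row><column>|grade<g>``."""
    n = 0
    with open(path, "wt") as out:
        for a in result.assignments:
            out.write(f">{a.well_label()}|grade{a.grade}\n{a.representative_read}\n")
            n += 1
    return n


def assignments_frame(result: DeconvolutionResult) -> pd.DataFrame:
    rows = []
    for a in result.assignments:
        rows.append(
            {
                "well": a.well_label(),
                "plate": a.plate,
                "row": a.row,
                "column": a.column,
                "grade": a.grade,
                "index_seq": a.index_seq,
                "ambiguous": a.ambiguous,
                "weak_dimension": a.weak_dimension or "",
                "rank_plate": a.ranks.get("plate"),
                "rank_row": a.ranks.get("row"),
                "rank_column": a.ranks.get("column"),
                "cov_plate": a.norm_cov.get("plate"),
                "cov_row": a.norm_cov.get("row"),
                "cov_column": a.norm_cov.get("column"),
                "representative_read": a.representative_read,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "well", "plate", "row", "column", "grade", "index_seq", "ambiguous",
            "weak_dimension", "rank_plate", "rank_row", "rank_column",
            "cov_plate", "cov_row", "cov_column", "representative_read",
        ],
    )


def multi_well_frame(result: DeconvolutionResult) -> pd.DataFrame:
    rows = [
        {
            "index_seq": m.index_seq,
            "plates": ";".join(m.plates),
            "rows": ";".join(m.rows),
            "columns": ";".join(m.columns),
            "n_implied_wells": len(m.implied_wells),
            "implied_wells": ";".join("".join(w) for w in m.implied_wells),
            "representative_read": m.representative_read,
        }
        for m in result.multi_well
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "index_seq", "plates", "rows", "columns", "n_implied_wells",
            "implied_wells", "representative_read",
        ],
    )


def emit_report(result: DeconvolutionResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the full report set under `out_dir`.

    Produces ``assignments.tsv``, ``assignments.fasta``, ``endogenous.tsv``,
    ``multi_well.tsv`` and ``report/index.html`` plus one HTML page per
    plate. Returns the paths written.
    """
    out_dir = Path(out_dir)
    report_dir = out_dir / "report"
    report_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["assignments_tsv"] = out_dir / "assignments.tsv"
    assignments_frame(result).to_csv(paths["assignments_tsv"], sep="\t", index=False)
    paths["assignments_fasta"] = out_dir / "assignments.fasta"
    write_fasta(result, paths["assignments_fasta"])
    paths["endogenous_tsv"] = out_dir / "endogenous.tsv"
    result.endogenous.to_csv(paths["endogenous_tsv"], sep="\t", index=False)
    paths["multi_well_tsv"] = out_dir / "multi_well.tsv"
    multi_well_frame(result).to_csv(paths["multi_well_tsv"], sep="\t", index=False)

    status = _well_statuses(result)
    design = result.design
    n_assigned = len({a.well for a in result.assignments})
    summary = (
        f"<p>{n_assigned} of {design.n_wells} wells assigned "
        f"({len(result.grade1)} Grade-1, {len(result.grade2)} Grade-2 assignments); "
        f"{len(result.multi_well)} multi-well elements; "
        f"{len(result.endogenous)} inferred endogenous indices; "
        f"{len(result.unresolved_wells)} unresolved wells.</p>"
    )
    links = []
    for plate in design.plates:
        page = report_dir / f"plate_{plate}.html"
        page.write_text(
            _PAGE.substitute(
                title=f"Plate {plate}", body=_plate_grid(result, plate, status)
            )
        )
        links.append(f'<li><a href="plate_{plate}.html">Plate {plate}</a></li>')
        paths[f"plate_{plate}"] = page
    grids = "".join(_plate_grid(result, p, status) for p in design.plates)
    index = report_dir / "index.html"
    index.write_text(
        _PAGE.substitute(
            title="Well assignment summary",
            body=summary + f"<ul>{''.join(links)}</ul>" + grids,
        )
    )
    paths["index_html"] = index
    return paths
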