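"""Trial-summary report writer.

Renders gated results in the layout of the published trial summary: rows are
tick species grouped under breed under vaccine formulation, columns are the
seven stage parameters plus cumulative efficacy E, and significance is
starred.  One-host species leave the larval/nymphal columns blank.  Negative
reductions are rendered with their sign and flagged in a footnote (they are
never gated into E by default).
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .stages import (
    EfficacyResult,
    StageParameter,
    THREE_HOST_PARAMETERS,
    round_half_away,
)

__all__ = ["report_frame", "write_report"]

_COLS = [p.value for p in THREE_HOST_PARAMETERS]


def _cell(result: EfficacyResult, param: StageParameter) -> str:
    est = result.reduction(param)
    if est is None:
        return ""
    star = " *" if est.significant else ""
    note = " !" if est.reduction_pct < 0 else ""
    return f"{round_half_away(est.reduction_pct)}%{star}{note}"


def report_frame(results: Sequence[EfficacyResult]) -> pd.DataFrame:
    """Tabular report: one row per group, ordered antigen > breed > species."""
    antigens, breeds, species_order = [], [], []
    for r in results:
        if r.antigen not in antigens:
            antigens.append(r.antigen)
        if r.breed not in breeds:
            breeds.append(r.breed)
        if r.tick_species not in species_order:
            species_order.append(r.tick_species)
    index = {(r.antigen, r.breed, r.tick_species): r for r in results}
    rows = []
    for antigen in antigens:
        for breed in breeds:
            for sp in species_order:
                r = index.pop((antigen, breed, sp), None)
                if r is None:
                    continue
                row = {"antigen": antigen, "breed": breed, "tick_species": sp}
                row.update({c: _cell(r, p) for c, p in zip(_COLS, THREE_HOST_PARAMETERS)})
                row["E"] = f"{r.efficacy_rounded}%"
                rows.append(row)
    # anything not covered by the factorial ordering still gets reported
    for r in index.values():
        row = {"antigen": r.antigen, "breed": r.breed, "tick_species": r.tick_species}
        row.update({c: _cell(r, p) for c, p in zip(_COLS, THREE_HOST_PARAMETERS)})
        row["E"] = f"{r.efficacy_rounded}%"
        rows.append(row)
    return pd.DataFrame(rows, columns=["antigen", "breed", "tick_species", *_COLS, "E"])


def write_report(results: Sequence[EfficacyResult], style: str = "text") -> str:
    """Render the report as human-readable text or tab-delimited rows.

    An incomplete factorial is rendered with the groups that exist; gaps are
    listed explicitly at the end rather than silently dropped.
    """
    df = report_frame(results)
    if style == "tsv":
        return df.to_csv(sep="\t", index=False)
    if style != "text":
        raise ValueError(f"unknown report style {style!r}")

    lines: list[str] = []
    widths = [18] + [8] * len(_COLS) + [6]
    header_cells = ["Group", *_COLS, "E"]

    def fmt_row(cells: Sequence[str]) -> str:
        return "  ".join(str(c).ljust(w) for c, w in zip(cells, widths)).rstrip()

    if df.empty:
        lines.append(fmt_row(header_cells))
        lines.append("(no results)")
        return "\n".join(lines) + "\n"

    expected_cells: set[tuple[str, str]] = set()
    seen_cells = {(r.breed, r.tick_species) for r in results}
    for antigen in df["antigen"].unique():
        sub = df[df["antigen"] == antigen]
        missing = seen_cells - {(b, s) for b, s in zip(sub["breed"], sub["tick_species"])}
        lines.append(f"Vaccination with {antigen}")
        lines.append(fmt_row(header_cells))
        for breed in sub["breed"].unique():
            lines.append(f"  {breed}")
            for _, row in sub[sub["breed"] == breed].iterrows():
                cells = [f"  {row['tick_species']}", *[row[c] for c in _COLS], row["E"]]
                lines.append(fmt_row(cells))
        for b, s in sorted(missing):
            lines.append(f"  [missing group: {b} / {s}]")
        lines.append("")
    lines.append("* significant (gated into E);  ! negative reduction, excluded from E")
    return "\n".join(lines) + "\n"
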