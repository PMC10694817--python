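"""Deterministic plain-text rendering of result tables.

Internal arithmetic is kept at full precision everywhere; rounding
(round-half-even, via Python's float formatting) happens only here, at
render time, to one decimal kJ/mol by default.  Rendered output embeds no
timestamps, so identical inputs give byte-identical reports.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd


def fmt_value(value, decimals: int = 1, signed: bool = False) -> str:
    """Format one cell; numbers round half-even at ``decimals`` places."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    if isinstance(value, (int, float)):
        spec = f"{{:{'+' if signed else ''}.{decimals}f}}"
        return spec.format(float(value))
    return str(value)


def render_table(
    table: pd.DataFrame | Sequence[Sequence],
    decimals: int = 1,
    signed: bool = False,
    header: Sequence[str] | None = None,
) -> str:
    """Render a rectangular table as Markdown-style pipe text.

    Accepts a DataFrame (index becomes the first column) or a list of
    rows; ragged rows are a hard error.
    """
    if isinstance(table, pd.DataFrame):
        head = [table.index.name or ""] + [str(c) for c in table.columns]
        rows = [
            [str(idx)] + [fmt_value(v, decimals, signed) for v in row]
            for idx, row in zip(table.index, table.itertuples(index=False))
        ]
    else:
        rows = [[fmt_value(v, decimals, signed) for v in r] for r in table]
        widths_set = {len(r) for r in rows}
        if len(widths_set) > 1:
            raise ValueError(f"ragged rows: lengths {sorted(widths_set)}")
        if header is not None:
            head = [str(h) for h in header]
            if rows and len(head) != len(rows[0]):
                raise ValueError("header width does not match rows")
        else:
            head = [""] * (len(rows[0]) if rows else 0)

    ncol = len(head)
    for r in rows:
        if len(r) != ncol:
            raise ValueError("ragged rows: row width does not match header")
    widths = [
        max([len(head[i])] + [len(r[i]) for r in rows]) for i in range(ncol)
    ]
    def line(cells):
        return "| " + " | ".join(c.ljust(w) for c, w in zip(cells, widths)) + " |"

    out = [line(head), line(["-" * w for w in widths])]
    out.extend(line(r) for r in rows)
    return "\n".join(out) + "\n"


__all__ = ["render_table", "fmt_value"]
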