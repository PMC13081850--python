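"""Design cards, automatic sequence naming, and tabular compilation.

Every generated sequence carries a *design card*: a flat, ordered map
from prefix-qualified variable names (``mut.positions``, ``bc.barcode``)
to the values the producing operations recorded for that sequence.
Operations sitting on inactive stack branches contribute nulls, so a
compiled table is rectangular and directly usable as covariates in
downstream analyses.

Sequence *names* are built from per-operation tokens: each tracked
operation contributes ``prefix_<internal state>`` (zero-padded, width at
least 2), and a stack contributes its selected branch label as a bare
token, placed before the branch's own tokens.  ``wt.mut_03.bc_01``
therefore reads: wild-type branch, mutation variant 3, barcode 1.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "IntegrityError",
    "render_token",
    "token_width",
    "compile_cards",
    "cards_to_csv",
    "print_library",
]


class IntegrityError(ValueError):
    """Duplicate names or conflicting card entries."""


def token_width(internal_cardinality: int) -> int:
    """Zero-pad width: max(2, digits of the largest internal state)."""
    return max(2, len(str(internal_cardinality - 1)))


def render_token(prefix: str, internal_state: int, internal_cardinality: int) -> str:
    return f"{prefix}_{internal_state:0{token_width(internal_cardinality)}d}"


def compile_cards(results) -> pd.DataFrame:
    """Compile GenerationResults into a DataFrame.

    Columns: ``name``, ``sequence``, then the union of card variable
    names in first-appearance order.  Missing variables are null.
    Duplicate names raise :class:`IntegrityError`.
    """
    names = []
    rows = []
    columns: list[str] = []
    seen_cols: set[str] = set()
    for r in results:
        names.append(r.name)
        rows.append(r.card)
        for k in r.card:
            if k not in seen_cols:
                seen_cols.add(k)
                columns.append(k)
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})[:5]
        raise IntegrityError(f"duplicate sequence names in card table: {dup}")
    frame = pd.DataFrame(
        {
            "name": names,
            "sequence": [r.sequence.chars for r in results],
        }
    )
    for col in columns:
        frame[col] = [row.get(col) for row in rows]
    return frame


def _serialize_cell(value):
    if isinstance(value, (list, tuple)):
        return ";".join(str(v) for v in value)
    return value


def cards_to_csv(frame: pd.DataFrame, path) -> None:
    """Write a card table as UTF-8 CSV; list values semicolon-joined."""
    out = frame.copy()
    for col in out.columns:
        out[col] = out[col].map(_serialize_cell)
    out.to_csv(path, index=False, encoding="utf-8")


def print_library(pool, n: int = 10, *, master_seed: int = 0,
                  plain: bool = False) -> str:
    """Styled listing of the first min(n, size) sequences: name, sequence."""
    from .seqmodel import render_ansi  # local import avoids cycle at import time

    if n < 1:
        raise ValueError("n must be >= 1")
    count = min(n, pool.size)
    lines = []
    for res in pool.iter_results(master_seed, range(count)):
        lines.append(f"{res.name}\t{render_ansi(res.sequence, plain=plain)}")
    return "\n".join(lines)
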