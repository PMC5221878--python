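"""Report formatting helpers: printed-value rounding and markdown tables."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

__all__ = ["printed_round", "markdown_table"]


def printed_round(x: float, ndigits: int = 2) -> float:
    """Round a value for reporting, matching chained printed precision.

    Published figure legends and tables typically quote derived quantities
    after they have passed through an intermediate printed precision (one
    extra decimal), so the reported value is the half-up rounding of the
    already once-rounded number.  This helper reproduces that two-stage
    chain: half-up at ``ndigits + 1`` decimals, then half-up at
    ``ndigits``.  E.g. 0.5649 -> 0.565 -> 0.57.
    """
    d = Decimal(repr(float(x)))
    inter = d.quantize(Decimal(1).scaleb(-(ndigits + 1)), rounding=ROUND_HALF_UP)
    final = inter.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP)
    return float(final)


def markdown_table(df: pd.DataFrame, float_fmt: str = "{:.3f}") -> str:
    """Render a DataFrame as a GitHub-style markdown table."""
    cols = list(df.columns)

    def fmt(v):
        if isinstance(v, float):
            return float_fmt.format(v)
        return str(v)

    lines = ["| " + " | ".join(cols) + " |", "|" + "---|" * len(cols)]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(fmt(row[c]) for c in cols) + " |")
    return "\n".join(lines)
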