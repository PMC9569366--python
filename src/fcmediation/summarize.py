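"""Survey and demographic summarization: counts to printed percentages.

Percentages are reported out of the cohort total and rounded half-up to two
decimals, matching how published cohort tables print them (e.g. 1363 of 5566
participants prints as 24.49).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import pandas as pd


def percentage(count: int, n_total: int) -> float:
    """100*count/n_total, rounded half-up to 2 decimals."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    frac = Decimal(100) * Decimal(count) / Decimal(n_total)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class SurveySummary:
    item: str
    n_total: int
    counts: dict = field(default_factory=dict)  # level -> count
    percentages: dict = field(default_factory=dict)  # level -> pct of n_total
    n_missing: int = 0
    unions: dict = field(default_factory=dict)  # name -> (count, pct)

    def union(self, name: str, levels: Sequence) -> tuple[int, float]:
        unknown = [l for l in levels if l not in self.counts]
        if unknown:
            raise KeyError(f"unknown level {unknown[0]!r} for item {self.item!r}")
        count = sum(self.counts[l] for l in levels)
        result = (count, percentage(count, self.n_total))
        self.unions[name] = result
        return result


def summarize_counts(
    item: str, counts: Mapping, n_total: int, n_missing: int = 0
) -> SurveySummary:
    """Summary from already-tabulated per-level counts (printed-table inputs)."""
    s = SurveySummary(item=item, n_total=int(n_total), n_missing=int(n_missing))
    for level, c in counts.items():
        s.counts[level] = int(c)
        s.percentages[level] = percentage(int(c), n_total)
    return s


def summarize_survey(
    table: pd.DataFrame,
    item: str,
    levels: Optional[Sequence] = None,
    n_total: Optional[int] = None,
) -> SurveySummary:
    """Tabulate one ordinal/categorical column into counts and percentages.

    ``levels`` fixes the expected response set (unknown observed responses
    raise an error naming the offender; expected-but-absent levels report 0
    count, 0.00%).  Missing values are tracked separately and percentages are
    taken out of ``n_total`` (default: number of table rows).
    """
    col = table[item]
    n = int(n_total) if n_total is not None else len(table)
    observed = col.dropna()
    if levels is not None:
        levels = list(levels)
        bad = set(observed.unique()) - set(levels)
        if bad:
            raise ValueError(f"unknown level {sorted(bad)[0]!r} in item {item!r}")
    else:
        levels = sorted(observed.unique())
    vc = observed.value_counts()
    counts = {l: int(vc.get(l, 0)) for l in levels}
    return summarize_counts(
        item, counts, n, n_missing=int(col.isna().sum())
    )
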