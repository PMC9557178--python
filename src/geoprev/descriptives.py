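"""Prevalence tables, trend series and the relative-reduction statistic.

Aggregation is child-count weighted throughout: prevalence for any cell of
the table is 100 * sum(Y) / sum(n) over the clusters it covers, never a mean
of per-cluster proportions.  No survey sampling weights are applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from geoprev.core_io import ClusterRecord

NATIONAL = "NATIONAL"
POOLED = "pooled"


@dataclass
class PrevalenceTable:
    """Region x wave counts with derived prevalence percentages.

    ``counts`` is a DataFrame indexed by (level, wave) with columns
    ``n_children``, ``n_underweight``, ``prevalence_percent``; levels include
    every region plus ``NATIONAL``; waves include every survey plus
    ``pooled``.
    """

    counts: pd.DataFrame

    def prevalence(self, level: str, wave: str) -> float:
        return float(self.counts.loc[(level, wave), "prevalence_percent"])

    def levels(self) -> list[str]:
        return list(self.counts.index.get_level_values(0).unique())

    def waves(self) -> list[str]:
        w = [
            x
            for x in self.counts.index.get_level_values(1).unique()
            if x != POOLED
        ]
        return sorted(w)

    def to_wide(self, digits: int = 1) -> pd.DataFrame:
        """Presentation table: levels x waves of rounded prevalences."""
        wide = self.counts["prevalence_percent"].unstack(level=1)
        cols = self.waves() + [POOLED]
        wide = wide[cols]
        return wide.map(lambda v: round_half_away(v, digits))


def round_half_away(value: float, digits: int = 1) -> float:
    """Round half away from zero (44.65 -> 44.7, -44.65 -> -44.7)."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def prevalence_table(records: list[ClusterRecord]) -> PrevalenceTable:
    """Count-weighted prevalence per region x wave, plus NATIONAL and pooled."""
    if not records:
        raise ValueError("records must be non-empty")
    df = pd.DataFrame(
        {
            "region": [r.region_id for r in records],
            "wave": [r.wave for r in records],
            "n_children": [r.n_children for r in records],
            "n_underweight": [r.n_underweight for r in records],
        }
    )
    pieces = []
    for level_name, grouped in (
        (None, df.groupby(["region", "wave"], sort=True)),
        (NATIONAL, df.groupby("wave", sort=True)),
    ):
        agg = grouped[["n_children", "n_underweight"]].sum().reset_index()
        if level_name is not None:
            agg.insert(0, "region", level_name)
        pieces.append(agg)
    counts = pd.concat(pieces, ignore_index=True)
    pooled = (
        counts.groupby("region", sort=False)[["n_children", "n_underweight"]]
        .sum()
        .reset_index()
    )
    pooled["wave"] = POOLED
    counts = pd.concat([counts, pooled], ignore_index=True)
    counts["prevalence_percent"] = (
        100.0 * counts["n_underweight"] / counts["n_children"]
    )
    counts = counts.set_index(["region", "wave"]).sort_index()
    return PrevalenceTable(counts=counts)


def reduction_rate(p_start: float, p_end: float) -> float:
    """Relative reduction 100*(p_start - p_end)/p_start, to one decimal."""
    if p_start <= 0:
        raise ValueError("p_start must be > 0")
    return round_half_away(100.0 * (p_start - p_end) / p_start, 1)


def trend_series(
    table: PrevalenceTable, level: str = NATIONAL
) -> list[tuple[str, float]]:
    """(wave, prevalence) pairs for one level, waves ascending."""
    if level not in table.levels():
        raise KeyError(f"level {level!r} not in table")
    return [(w, table.prevalence(level, w)) for w in table.waves()]
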