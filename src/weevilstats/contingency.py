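"""Cross-tabulation analysis of destructive-sampling records.

Builds two-way count tables from record-level data and runs the classical
chi-square test of independence with standardized residuals (Z scores,
flagged against the +/-1.96 threshold), Cramér's V effect size, percentage
breakdowns within either margin, and per-group descriptive summaries of
depth and distance-to-bole.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .vocab import FIELD_LEVELS

Z_THRESHOLD = 1.96


def _level_order(field_name: str, values) -> list:
    declared = FIELD_LEVELS.get(field_name)
    if declared is not None:
        return [lv for lv in declared if lv in set(values)]
    return sorted(set(values))


@dataclass(frozen=True)
class ChiSquareResult:
    """Chi-square test of independence on a two-way table.

    ``residuals`` holds per-cell standardized residuals; with the default
    Pearson form these are (O - E)/sqrt(E) and their squares sum to the
    chi-square statistic.
    """

    statistic: float
    df: int
    p: float
    expected: pd.DataFrame
    residuals: pd.DataFrame
    cramers_v: float
    n: int
    residual_type: str = "pearson"

    def significant_cells(self, threshold: float = Z_THRESHOLD) -> pd.DataFrame:
        """Boolean mask of cells whose |Z| exceeds ``threshold``."""
        return self.residuals.abs() > threshold

    def summary(self) -> str:
        from .report import format_p

        lines = [
            f"Chi-square test of independence (n = {self.n})",
            f"  chi2 = {self.statistic:.2f}, df = {self.df}, p = {format_p(self.p)}",
            f"  Cramér's V = {self.cramers_v:.3f}",
            f"Standardized residuals ({self.residual_type}); |Z| > {Z_THRESHOLD} flagged:",
            self.residuals.round(1).to_string(),
        ]
        return "\n".join(lines)


@dataclass
class CrossTab:
    """Labelled two-way count table with margins.

    Level order follows the declared vocabulary for known fields
    (treatment, outcome, stage); anything else is sorted.
    """

    counts: pd.DataFrame
    row_field: str = field(default="rows")
    col_field: str = field(default="columns")

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_records(cls, records: pd.DataFrame, row_factor: str, col_factor: str) -> "CrossTab":
        """Tabulate records by two categorical fields; every record counts once."""
        if len(records) == 0:
            raise ValueError("no records to tabulate (zero degrees of freedom)")
        for f in (row_factor, col_factor):
            if f not in records.columns:
                raise KeyError(f"unknown factor {f!r}; available: {list(records.columns)}")
        tab = pd.crosstab(records[row_factor], records[col_factor])
        tab = tab.reindex(
            index=_level_order(row_factor, tab.index),
            columns=_level_order(col_factor, tab.columns),
            fill_value=0,
        )
        tab.index.name = row_factor
        tab.columns.name = col_factor
        return cls(tab, row_field=row_factor, col_field=col_factor)

    @property
    def n(self) -> int:
        return int(np.asarray(self.counts).sum())

    @property
    def row_margins(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def __add__(self, other: "CrossTab") -> "CrossTab":
        rows = list(dict.fromkeys(list(self.counts.index) + list(other.counts.index)))
        cols = list(dict.fromkeys(list(self.counts.columns) + list(other.counts.columns)))
        a = self.counts.reindex(index=rows, columns=cols, fill_value=0)
        b = other.counts.reindex(index=rows, columns=cols, fill_value=0)
        return CrossTab((a + b).astype(int), self.row_field, self.col_field)

    def chi_square(self, residual_type: str = "pearson") -> ChiSquareResult:
        """Chi-square test of independence with standardized residuals.

        ``residual_type`` is ``"pearson"`` ((O-E)/sqrt(E), the form that sums
        in squares to the statistic) or ``"adjusted"`` (margin-adjusted,
        (O-E)/sqrt(E(1-r/n)(1-c/n))). No continuity correction is applied.
        """
        if self.n == 0:
            raise ValueError("empty table (n = 0)")
        for name, margins in (("row", self.row_margins), ("column", self.col_margins)):
            empty = margins[margins == 0]
            if len(empty):
                raise ValueError(
                    f"zero {name} margin for level(s) {list(empty.index)}; "
                    "drop the level explicitly before testing"
                )
        obs = np.asarray(self.counts, dtype=float)
        statistic, p, df, expected = stats.chi2_contingency(obs, correction=False)
        pearson = (obs - expected) / np.sqrt(expected)
        if residual_type == "pearson":
            resid = pearson
        elif residual_type == "adjusted":
            r = self.row_margins.to_numpy(dtype=float)[:, None] / self.n
            c = self.col_margins.to_numpy(dtype=float)[None, :] / self.n
            resid = pearson / np.sqrt((1 - r) * (1 - c))
        else:
            raise ValueError(f"unknown residual_type {residual_type!r}")
        v = float(np.sqrt(statistic / (self.n * (min(obs.shape) - 1))))
        wrap = lambda a: pd.DataFrame(a, index=self.counts.index, columns=self.counts.columns)
        return ChiSquareResult(
            statistic=float(statistic),
            df=int(df),
            p=float(p),
            expected=wrap(expected),
            residuals=wrap(resid),
            cramers_v=v,
            n=self.n,
            residual_type=residual_type,
        )

    def percent(self, axis: str = "rows") -> pd.DataFrame:
        """Percentage breakdown within rows or within columns."""
        if axis == "rows":
            margins = self.row_margins
            if (margins == 0).any():
                raise ValueError("zero row margin; percentages undefined")
            return self.counts.div(margins, axis=0) * 100
        if axis == "columns":
            margins = self.col_margins
            if (margins == 0).any():
                raise ValueError("zero column margin; percentages undefined")
            return self.counts.div(margins, axis=1) * 100
        raise ValueError("axis must be 'rows' or 'columns'")


def build_crosstab(records: pd.DataFrame, row_factor: str, col_factor: str) -> CrossTab:
    """Functional alias for :meth:`CrossTab.from_records`."""
    return CrossTab.from_records(records, row_factor, col_factor)


def chi_square_independence(table: CrossTab, residual_type: str = "pearson") -> ChiSquareResult:
    """Functional alias for :meth:`CrossTab.chi_square`."""
    return table.chi_square(residual_type=residual_type)


def percent_breakdown(table: CrossTab, axis: str = "rows") -> pd.DataFrame:
    """Functional alias for :meth:`CrossTab.percent`."""
    return table.percent(axis=axis)


def describe_by_group(
    records: pd.DataFrame, value_field: str, group_field: str = "outcome"
) -> pd.DataFrame:
    """Per-group mean/median/min/max of a numeric field (depth, distance).

    Groups declared in the vocabulary but absent from the records appear
    with NaN summaries rather than being dropped.
    """
    if not np.issubdtype(records[value_field].dtype, np.number):
        raise TypeError(f"{value_field!r} is not numeric")
    out = (
        records.groupby(group_field, sort=False)[value_field]
        .agg(["mean", "median", "min", "max"])
    )
    order = _level_order(group_field, records[group_field])
    declared = FIELD_LEVELS.get(group_field)
    if declared is not None:
        order = list(declared)
    return out.reindex(order)
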