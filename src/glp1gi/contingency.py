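"""Drug x event 2x2 contingency tables and cohort cross-tabulations.

The 2x2 table for a (drug, event) pair counts, within the analyzed report
universe::

                     event      other events
    target drug        a             b
    comparator pool    c             d

The default comparator is the *within-class* pool: the other three retained
GLP-1 receptor agonists.  Counting is event-level by default (one count per
report-drug-event row); case-level counting (distinct reports) is available
via ``unit="case"``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .fixture import CountFixture
from .reports import OUTCOMES, RETAINED_DRUGS

#: Age bands of the cohort characteristics view (years, inclusive edges).
AGE_BANDS_FINE = ((18, 44), (45, 54), (55, 64), (65, 130))
#: Age split of the stratified-events view.
AGE_BANDS_COARSE = ((0, 64), (65, 130))
YEAR_BANDS = ((2007, 2009), (2010, 2014), (2015, 2019), (2020, 2023))


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts for one (drug, event) pair against a comparator pool."""

    drug: str
    event: str
    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")
        if self.n == 0:
            raise ValueError("empty contingency table (N=0)")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)

    def swapped(self) -> "ContingencyTable":
        """Exchange target and comparator rows: (a,b,c,d) -> (c,d,a,b)."""
        return replace(self, a=self.c, b=self.d, c=self.a, d=self.b)

    def continuity_corrected(self) -> "ContingencyTable":
        """Haldane-Anscombe correction: +0.5 to every cell."""
        return replace(self, a=self.a + 0.5, b=self.b + 0.5,
                       c=self.c + 0.5, d=self.d + 0.5)

    def to_dict(self) -> dict:
        return {"drug": self.drug, "event": self.event,
                "a": self.a, "b": self.b, "c": self.c, "d": self.d, "n": self.n}


def _unit_counts(df: pd.DataFrame, mask: pd.Series, unit: str) -> int:
    sub = df[mask]
    if unit == "case":
        return sub["report_id"].nunique()
    return len(sub)


def build_2x2_from_reports(
    df: pd.DataFrame,
    drug: str,
    event: str,
    comparator: Iterable[str] | None = None,
    unit: str = "event",
) -> ContingencyTable:
    """Build the 2x2 table for (drug, event) from a normalized report table.

    ``comparator`` defaults to the other retained drugs; it must be
    non-empty and must not contain the target drug.  With ``unit="event"``
    every report-drug-event row counts once; with ``unit="case"`` distinct
    reports count once per cell.
    """
    if comparator is None:
        comparator = [d for d in RETAINED_DRUGS if d != drug]
    comparator = sorted(set(comparator))
    if not comparator:
        raise ValueError("comparator set is empty")
    if drug in comparator:
        raise ValueError(f"target drug {drug!r} present in comparator set")
    if unit not in ("event", "case"):
        raise ValueError(f"unknown counting unit {unit!r}")

    is_target = df["drug"] == drug
    is_comp = df["drug"].isin(comparator)
    is_event = df["event_pt"] == event
    a = _unit_counts(df, is_target & is_event, unit)
    b = _unit_counts(df, is_target & ~is_event, unit)
    c = _unit_counts(df, is_comp & is_event, unit)
    d = _unit_counts(df, is_comp & ~is_event, unit)
    return ContingencyTable(drug=drug, event=event, a=a, b=b, c=c, d=d)


def build_2x2_from_fixture(
    fixture: CountFixture, drug: str, event: str
) -> ContingencyTable:
    """Build the 2x2 table for (drug, event) from packaged published counts.

    ``a`` is the printed case count, ``b`` the drug's report total minus
    ``a``; ``c``/``d`` pool the other three drugs.  A missing printed count
    anywhere in the row raises (no imputation): the inflammatory-bowel-
    disease row, for instance, prints only one of the four counts.
    """
    if event not in fixture.events:
        raise KeyError(f"event {event!r} not in fixture")
    missing = [d for d in fixture.drugs if fixture.cases(event, d) is None]
    if missing:
        raise ValueError(
            f"fixture row {event!r} lacks case counts for {missing}; "
            "cannot build a 2x2 table without imputation"
        )
    if drug not in fixture.drugs:
        raise KeyError(f"drug {drug!r} not in fixture")
    a = fixture.cases(event, drug)
    b = fixture.drug_totals[drug] - a
    c = sum(fixture.cases(event, d) for d in fixture.drugs if d != drug)
    d = sum(fixture.drug_totals[d] for d in fixture.drugs if d != drug) - c
    return ContingencyTable(drug=drug, event=event, a=a, b=b, c=c, d=d)


# ---------------------------------------------------------------------------
# Cohort cross-tabulations


def round_half_up(x, decimals: int = 1):
    """Decimal display rounding: .5 always rounds away from zero."""
    factor = 10.0 ** decimals
    return np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x)


@dataclass
class StratifiedCounts:
    """Event-by-stratum counts with percentages of the stratum denominator.

    ``cells`` has one row per (event, stratum) with columns ``count`` and
    ``percent``; ``denominators`` maps stratum -> number of distinct
    reports.  Reports whose stratifying field is missing form an explicit
    ``"missing"`` stratum that is excluded from percentage denominators.
    """

    axis: str
    cells: pd.DataFrame
    denominators: dict[str, int]

    def percent(self, event: str, stratum: str) -> float:
        row = self.cells[
            (self.cells["event"] == event) & (self.cells["stratum"] == stratum)
        ]
        return float(row["percent"].iloc[0]) if len(row) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return self.cells.pivot(index="event", columns="stratum", values="count")

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "axis": self.axis,
                "denominators": self.denominators,
                "cells": self.cells.to_dict(orient="records"),
            },
            indent=2,
        )


def _band_label(lo: int, hi: int) -> str:
    if hi >= 130:
        return f"{lo}+"
    if lo <= 0:
        return f"<{hi + 1}"
    return f"{lo}-{hi}"


def _stratum_series(df: pd.DataFrame, axis: str) -> pd.Series:
    if axis == "sex":
        s = df["sex"].replace("unspecified", "missing")
    elif axis in ("age_band", "age65"):
        bands = AGE_BANDS_FINE if axis == "age_band" else AGE_BANDS_COARSE
        s = pd.Series("missing", index=df.index, dtype=object)
        for lo, hi in bands:
            mask = df["age_years"].notna() & (df["age_years"] >= lo) & (
                df["age_years"] <= hi
            )
            s[mask] = _band_label(lo, hi)
    elif axis == "year_band":
        s = pd.Series("missing", index=df.index, dtype=object)
        for lo, hi in YEAR_BANDS:
            yr = df["reporting_year"]
            mask = yr.notna() & (yr >= lo) & (yr <= hi)
            s[mask] = f"{lo}-{hi}"
    elif axis == "reporter":
        s = df["reporter"].replace("unspecified", "missing")
    elif axis == "indication":
        s = df["indication"].astype(object)
    elif axis == "drug":
        s = df["drug"].astype(object)
    else:
        raise ValueError(f"unknown crosstab axis {axis!r}")
    return s


def crosstab(df: pd.DataFrame, axis: str) -> StratifiedCounts:
    """Cross-tabulate events against a report characteristic.

    Axes: ``sex``, ``age_band`` (18-44/45-54/55-64/65+), ``age65``
    (<65/65+), ``year_band``, ``reporter``, ``indication``, ``drug``,
    ``outcome``.  Counts are distinct reports; percentages divide by the
    stratum's distinct-report denominator; a ``missing`` stratum collects
    reports without the characteristic and is excluded from denominators.
    """
    if axis == "outcome":
        return _outcome_crosstab(df)
    strata = _stratum_series(df, axis)
    work = df.assign(_stratum=strata)
    denom = (
        work.groupby("_stratum")["report_id"].nunique().to_dict()
    )
    cells = (
        work.groupby(["event_pt", "_stratum"])["report_id"]
        .nunique()
        .reset_index()
        .rename(columns={"event_pt": "event", "_stratum": "stratum",
                         "report_id": "count"})
    )
    cells["percent"] = [
        round_half_up(100.0 * cnt / denom[st], 1) if st != "missing" and denom[st]
        else np.nan
        for cnt, st in zip(cells["count"], cells["stratum"])
    ]
    return StratifiedCounts(axis=axis, cells=cells, denominators=denom)


def _outcome_crosstab(df: pd.DataFrame) -> StratifiedCounts:
    """Serious-outcome counts per drug (stratum = drug, rows = outcome)."""
    rows = []
    denom = df.groupby("drug")["report_id"].nunique().to_dict()
    for outcome in OUTCOMES:
        has = df[df["outcomes"].str.contains(outcome, regex=False)]
        per_drug = has.groupby("drug")["report_id"].nunique()
        for drug, cnt in per_drug.items():
            rows.append(
                {
                    "event": outcome,
                    "stratum": drug,
                    "count": int(cnt),
                    "percent": round_half_up(100.0 * cnt / denom[drug], 1),
                }
            )
    cells = pd.DataFrame(rows, columns=["event", "stratum", "count", "percent"])
    return StratifiedCounts(axis="outcome", cells=cells, denominators=denom)


def cohort_table(df: pd.DataFrame) -> pd.DataFrame:
    """Cohort characteristics by drug: sex, age band, year band, reporter,
    indication and serious outcomes, as count (percent of drug total)."""
    denom = df.groupby("drug")["report_id"].nunique()
    blocks = []
    for axis in ("sex", "age_band", "year_band", "reporter", "indication"):
        strata = _stratum_series(df, axis)
        work = df.assign(_value=strata)
        cnt = (
            work[work["_value"] != "missing"]
            .groupby(["_value", "drug"])["report_id"]
            .nunique()
            .unstack(fill_value=0)
        )
        cnt.index = pd.MultiIndex.from_product([[axis], cnt.index])
        blocks.append(cnt)
    out_cells = _outcome_crosstab(df).cells.pivot(
        index="event", columns="stratum", values="count"
    ).fillna(0).astype(int)
    out_cells.index = pd.MultiIndex.from_product([["outcome"], out_cells.index])
    blocks.append(out_cells)
    table = pd.concat(blocks)
    table.index.names = ["characteristic", "value"]
    for drug in table.columns:
        pct = round_half_up(100.0 * table[drug] / denom.get(drug, np.nan), 1)
        table[f"{drug}_pct"] = pct
    return table
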