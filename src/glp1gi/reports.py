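"""Report-level domain model, normalized-table IO and the inclusion pipeline.

Spontaneous adverse-event data are handled as a *normalized report table*:
one row per (report, drug, event) combination, held in a
:class:`pandas.DataFrame` with the columns of :data:`REPORT_COLUMNS`.  A
:class:`Report` dataclass gives the row-level semantics and validation; the
pipeline itself is vectorized over the frame.

The inclusion pipeline (:func:`apply_filters`) mirrors the selection used in
pharmacovigilance case/non-case studies of GLP-1 receptor agonists:
deduplication, restriction to the primary-suspect role, the retained drug
set, the gastrointestinal system-organ class, US reports, exclusion of
combination-therapy reports, exclusion of reports missing key fields, and a
reporting-year window.  Every stage is recorded in a :class:`FilterLog`
whose counts are conserved (``in = excluded + out``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Controlled vocabularies

DRUGS = (
    "exenatide",
    "liraglutide",
    "dulaglutide",
    "semaglutide",
    "albiglutide",
    "lixisenatide",
    "other",
)
#: The four agents retained for analysis (albiglutide and lixisenatide
#: reports are too sparse and are excluded upstream).
RETAINED_DRUGS = ("exenatide", "liraglutide", "dulaglutide", "semaglutide")

ROLE_CODES = ("primary_suspect", "secondary_suspect", "concomitant", "interacting")
SEXES = ("female", "male", "unspecified")
REPORTERS = ("consumer", "healthcare_professional", "unspecified")
INDICATIONS = ("diabetes_mellitus", "obesity", "weight_loss", "other", "missing")
OUTCOMES = ("disability", "life_threatening", "hospitalization", "death")

#: CTCAE severity grade of each serious outcome flag
#: (3 = disability/hospitalization, 4 = life-threatening, 5 = death).
OUTCOME_GRADE = {
    "disability": 3,
    "hospitalization": 3,
    "life_threatening": 4,
    "death": 5,
}

GI_SOC = "gastrointestinal"

#: Brand-name synonyms accepted by :func:`normalize_drug_name`.
BRAND_NAMES = {
    "byetta": "exenatide",
    "bydureon": "exenatide",
    "victoza": "liraglutide",
    "saxenda": "liraglutide",
    "trulicity": "dulaglutide",
    "adlyxin": "lixisenatide",
    "soliqua": "lixisenatide",
    "ozempic": "semaglutide",
    "rybelsus": "semaglutide",
    "wegovy": "semaglutide",
}

REPORT_COLUMNS = [
    "report_id",
    "case_id",
    "case_version",
    "drug",
    "role_code",
    "event_pt",
    "event_soc",
    "sex",
    "age_years",
    "reporting_year",
    "reporter",
    "country",
    "indication",
    "outcomes",
]

_ENUM_FIELDS = {
    "drug": (DRUGS, "other"),
    "role_code": (ROLE_CODES, "concomitant"),
    "sex": (SEXES, "unspecified"),
    "reporter": (REPORTERS, "unspecified"),
    "indication": (INDICATIONS, "missing"),
}

AGE_RANGE = (0.0, 130.0)
YEAR_RANGE = (2005, 2030)


def normalize_drug_name(name: str) -> str:
    """Map a free-text drug name (generic or US brand) to the drug enum.

    Matching is case-insensitive after trimming and collapsing internal
    whitespace; anything unrecognized maps to ``"other"``.
    """
    key = " ".join(str(name).split()).lower()
    if key in DRUGS:
        return key
    return BRAND_NAMES.get(key, "other")


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class Report:
    """One spontaneous adverse-event record at (report, drug, event) grain."""

    report_id: str
    case_id: str
    case_version: int
    drug: str
    role_code: str
    event_pt: str
    event_soc: str
    sex: str = "unspecified"
    age_years: float | None = None
    reporting_year: int | None = None
    reporter: str = "unspecified"
    country: str = ""
    indication: str = "missing"
    outcomes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for name, (allowed, _) in _ENUM_FIELDS.items():
            value = getattr(self, name)
            if value not in allowed:
                raise ValueError(f"{name}={value!r} not in {allowed}")
        if self.case_version < 1:
            raise ValueError("case_version must be >= 1")
        if self.age_years is not None and not (
            AGE_RANGE[0] <= self.age_years <= AGE_RANGE[1]
        ):
            raise ValueError(f"age_years={self.age_years} outside {AGE_RANGE}")
        if self.reporting_year is not None and not (
            YEAR_RANGE[0] <= self.reporting_year <= YEAR_RANGE[1]
        ):
            raise ValueError(f"reporting_year={self.reporting_year} outside {YEAR_RANGE}")
        unknown = set(self.outcomes) - set(OUTCOMES)
        if unknown:
            raise ValueError(f"unknown outcomes {sorted(unknown)}")
        object.__setattr__(self, "outcomes", frozenset(self.outcomes))

    @property
    def outcome_grades(self) -> dict[str, int]:
        """CTCAE grade for each serious outcome flagged on this report."""
        return {o: OUTCOME_GRADE[o] for o in sorted(self.outcomes)}


def reports_to_frame(reports: Iterable[Report]) -> pd.DataFrame:
    """Convert :class:`Report` objects to the normalized table layout."""
    rows = []
    for r in reports:
        d = {f.name: getattr(r, f.name) for f in dc_fields(Report)}
        d["outcomes"] = "|".join(sorted(r.outcomes))
        rows.append(d)
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return _coerce_frame(df)


def frame_to_reports(df: pd.DataFrame) -> list[Report]:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            Report(
                report_id=str(row.report_id),
                case_id=str(row.case_id),
                case_version=int(row.case_version),
                drug=row.drug,
                role_code=row.role_code,
                event_pt=row.event_pt,
                event_soc=row.event_soc,
                sex=row.sex,
                age_years=None if pd.isna(row.age_years) else float(row.age_years),
                reporting_year=None
                if pd.isna(row.reporting_year)
                else int(row.reporting_year),
                reporter=row.reporter,
                country="" if pd.isna(row.country) else str(row.country),
                indication=row.indication,
                outcomes=frozenset(
                    s for s in str(row.outcomes or "").split("|") if s
                ),
            )
        )
    return out


def _coerce_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["report_id"] = df["report_id"].astype(str)
    df["case_id"] = df["case_id"].astype(str)
    df["case_version"] = (
        pd.to_numeric(df["case_version"], errors="coerce").fillna(1).astype(int)
    )
    df["age_years"] = pd.to_numeric(df["age_years"], errors="coerce")
    df["reporting_year"] = pd.to_numeric(df["reporting_year"], errors="coerce").astype(
        "Int64"
    )
    df["outcomes"] = df["outcomes"].fillna("").astype(str)
    for col in ("drug", "role_code", "event_pt", "event_soc", "sex", "reporter",
                "country", "indication"):
        df[col] = df[col].fillna("").astype(str)
    return df


# ---------------------------------------------------------------------------
# Normalized-table IO


def read_normalized(
    path,
    delimiter: str | None = None,
    field_maps: Mapping[str, Mapping[str, str]] | None = None,
) -> pd.DataFrame:
    """Read a normalized report table (CSV by default, TSV accepted).

    ``field_maps`` optionally maps dialect values to the controlled
    vocabulary before validation (e.g. ``{"sex": {"F": "female"}}``).

    Unknown enum strings fall back to the enum's unspecified/other member;
    unparseable ages or years become missing.  Per-field warning counts are
    recorded in ``df.attrs["ingest_warnings"]``.  A missing mandatory column
    raises :class:`ValueError` naming the column.
    """
    if delimiter is None:
        delimiter = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"normalized table missing mandatory column(s): {missing}")
    df = df[REPORT_COLUMNS].copy()

    warnings: dict[str, int] = {}
    if field_maps:
        for col, mapping in field_maps.items():
            if col in df.columns:
                df[col] = df[col].map(lambda v, m=mapping: m.get(v, v))

    for col, (allowed, fallback) in _ENUM_FIELDS.items():
        bad = ~df[col].isin(allowed) & (df[col] != "")
        if bad.any():
            warnings[col] = int(bad.sum())
        df.loc[bad, col] = fallback
        df.loc[df[col] == "", col] = fallback

    for col, (lo, hi) in (("age_years", AGE_RANGE), ("reporting_year", YEAR_RANGE)):
        raw = df[col].mask(df[col] == "", np.nan)
        num = pd.to_numeric(raw, errors="coerce")
        out_of_range = num.notna() & ((num < lo) | (num > hi))
        unparseable = raw.notna() & num.isna()
        n_bad = int(out_of_range.sum() + unparseable.sum())
        if n_bad:
            warnings[col] = warnings.get(col, 0) + n_bad
        num[out_of_range] = np.nan
        df[col] = num

    bad_outcomes = df["outcomes"].map(
        lambda s: any(tok not in OUTCOMES for tok in s.split("|") if tok)
    )
    if bad_outcomes.any():
        warnings["outcomes"] = int(bad_outcomes.sum())
        df.loc[bad_outcomes, "outcomes"] = df.loc[bad_outcomes, "outcomes"].map(
            lambda s: "|".join(tok for tok in s.split("|") if tok in OUTCOMES)
        )

    df = _coerce_frame(df)
    df.attrs["ingest_warnings"] = warnings
    return df


def write_normalized(df: pd.DataFrame, path, delimiter: str = ",") -> None:
    """Write the normalized report table as delimited UTF-8 text."""
    out = df[REPORT_COLUMNS].copy()
    out["reporting_year"] = out["reporting_year"].astype("Int64")
    out.to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# Deduplication and filtering


def deduplicate(df: pd.DataFrame, key: str = "case_version") -> pd.DataFrame:
    """Drop duplicate report rows.

    ``key="case_version"`` (default) keeps, for each ``case_id``, only rows
    of the maximum ``case_version`` (FAERS convention: later versions
    supersede earlier ones), then collapses exact full-row duplicates.
    ``key="full_record"`` collapses exact duplicates only.
    """
    if key not in ("case_version", "full_record"):
        raise ValueError(f"unknown deduplication key {key!r}")
    if df.empty:
        return df.copy()
    out = df
    if key == "case_version":
        max_ver = out.groupby("case_id")["case_version"].transform("max")
        out = out[out["case_version"] == max_ver]
    out = out.drop_duplicates(subset=REPORT_COLUMNS)
    return out.sort_values(
        ["case_id", "case_version", "report_id", "drug", "event_pt"]
    ).reset_index(drop=True)


@dataclass
class FilterConfig:
    """Configuration of the inclusion pipeline, one attribute per stage."""

    required_role: str | None = "primary_suspect"
    countries: frozenset[str] | None = frozenset({"US"})
    drugs: frozenset[str] | None = frozenset(RETAINED_DRUGS)
    soc_whitelist: frozenset[str] | None = frozenset({GI_SOC})
    year_range: tuple[int, int] | None = None
    drop_missing: tuple[str, ...] = ("drug", "event_pt", "country")
    exclude_combination_reports: bool = True
    dedup_key: str = "case_version"

    def __post_init__(self) -> None:
        if self.year_range is not None and self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must satisfy min <= max")
        for f in ("countries", "drugs", "soc_whitelist"):
            v = getattr(self, f)
            if v is not None:
                setattr(self, f, frozenset(v))

    @classmethod
    def from_dict(cls, d: Mapping) -> "FilterConfig":
        kw = dict(d)
        if "year_range" in kw and kw["year_range"] is not None:
            kw["year_range"] = tuple(kw["year_range"])
        if "drop_missing" in kw:
            kw["drop_missing"] = tuple(kw["drop_missing"])
        return cls(**kw)


@dataclass
class FilterLog:
    """Ordered attrition record: one (in, excluded, out) triple per stage."""

    stages: list[tuple[str, int, int, int]] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_out: int) -> None:
        self.stages.append((name, n_in, n_in - n_out, n_out))

    def validate(self) -> None:
        for i, (name, n_in, n_exc, n_out) in enumerate(self.stages):
            if n_out != n_in - n_exc:
                raise AssertionError(f"stage {name}: {n_in} - {n_exc} != {n_out}")
            if i and self.stages[i - 1][3] != n_in:
                raise AssertionError(f"stage {name}: chain broken")

    @property
    def total_in(self) -> int:
        return self.stages[0][1] if self.stages else 0

    @property
    def total_out(self) -> int:
        return self.stages[-1][3] if self.stages else 0

    def to_json(self) -> str:
        return json.dumps(
            [
                {"stage": s, "reports_in": i, "reports_excluded": e, "reports_out": o}
                for s, i, e, o in self.stages
            ],
            indent=2,
        )

    def to_text(self) -> str:
        lines = ["stage                          in      excluded  out"]
        for s, i, e, o in self.stages:
            lines.append(f"{s:<30s} {i:<7d} {e:<9d} {o}")
        return "\n".join(lines)


def _combination_report_ids(df: pd.DataFrame) -> pd.Index:
    """Report ids whose suspect-drug set (primary or secondary suspect)
    spans more than one distinct drug — the strict reading of a
    'combination therapy' report."""
    suspects = df[df["role_code"].isin(["primary_suspect", "secondary_suspect"])]
    n_drugs = suspects.groupby("report_id")["drug"].nunique()
    return n_drugs[n_drugs > 1].index


def apply_filters(
    df: pd.DataFrame, config: FilterConfig | None = None
) -> tuple[pd.DataFrame, FilterLog]:
    """Apply the inclusion pipeline in its fixed stage order.

    Stage order: dedup, role_code, drug set, SOC whitelist, country,
    combination-report exclusion, missing-field exclusion, year range.
    A ``None`` stage parameter disables that stage (it is still logged,
    excluding nothing).  Returns the retained rows and the attrition log.
    """
    config = config or FilterConfig()
    log = FilterLog()

    out = deduplicate(df, key=config.dedup_key)
    log.add("dedup", len(df), len(out))

    combo_ids = (
        _combination_report_ids(out)
        if config.exclude_combination_reports
        else pd.Index([])
    )

    n = len(out)
    if config.required_role is not None:
        out = out[out["role_code"] == config.required_role]
    log.add("role_code", n, len(out))

    n = len(out)
    if config.drugs is not None:
        out = out[out["drug"].isin(config.drugs)]
    log.add("drug_set", n, len(out))

    n = len(out)
    if config.soc_whitelist is not None:
        out = out[out["event_soc"].isin(config.soc_whitelist)]
    log.add("soc_whitelist", n, len(out))

    n = len(out)
    if config.countries is not None:
        out = out[out["country"].isin(config.countries)]
    log.add("country", n, len(out))

    n = len(out)
    if config.exclude_combination_reports:
        out = out[~out["report_id"].isin(combo_ids)]
    log.add("combination_reports", n, len(out))

    n = len(out)
    for col in config.drop_missing:
        if col not in out.columns:
            raise ValueError(f"drop_missing names unknown field {col!r}")
        if col in ("age_years", "reporting_year"):
            out = out[out[col].notna()]
        elif col == "indication":
            out = out[out[col] != "missing"]
        elif col in ("sex", "reporter"):
            out = out[out[col] != "unspecified"]
        else:
            out = out[out[col] != ""]
    log.add("missing_fields", n, len(out))

    n = len(out)
    if config.year_range is not None:
        lo, hi = config.year_range
        yr = out["reporting_year"]
        out = out[yr.notna() & (yr >= lo) & (yr <= hi)]
    log.add("year_range", n, len(out))

    log.validate()
    return out.reset_index(drop=True), log
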